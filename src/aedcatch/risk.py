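"""Bayesian zero-inflated Poisson spatial regression (BYM-style).

The count model for zone i is a two-component mixture: with probability
``p_zero`` the observation is a structural zero; otherwise

    y_i ~ Poisson(lambda_i),   log lambda_i = alpha + x_i' beta + u_i + v_i

where ``u`` carries an intrinsic CAR (ICAR) prior on the zone adjacency
graph (sum-to-zero constrained) and ``v`` is an iid Gaussian effect — the
classic convolution (BYM) decomposition of spatial and unstructured
extra-Poisson variation. Posterior inference is by Metropolis-within-Gibbs
MCMC; a non-spatial EM fit (:func:`fit_zip_em`) provides fast point
estimates used for initialisation and as an independent check.

The posterior mean incidence per zone, E[(1 - p_zero) * lambda_i], is the
composite *risk surface* consumed as demand by the accessibility stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import gammaln
from shapely.strtree import STRtree

from .datamodel import ValidationError, Zone

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Adjacency

@dataclass
class Adjacency:
    """Symmetric neighbor structure over zones (no self-neighbors)."""

    n: int
    neighbors: list[np.ndarray]  # per-zone arrays of neighbor indices

    def __post_init__(self) -> None:
        self.neighbors = [np.asarray(nb, dtype=np.intp) for nb in self.neighbors]
        for i, nb in enumerate(self.neighbors):
            if i in nb:
                raise ValidationError(f"adjacency: zone {i} is its own neighbor")
        self.validate_symmetric()

    def validate_symmetric(self) -> None:
        sets = [set(nb.tolist()) for nb in self.neighbors]
        for i, nb in enumerate(sets):
            for j in nb:
                if i not in sets[j]:
                    raise ValidationError(f"adjacency not symmetric: {i} -> {j}")

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors], dtype=float)

    def edge_list(self) -> np.ndarray:
        """Unique undirected edges as an (m, 2) array with i < j."""
        edges = [(i, j) for i, nb in enumerate(self.neighbors) for j in nb if i < j]
        return np.array(edges, dtype=np.intp).reshape(-1, 2)

    def to_weight_matrix(self, row_standardize: bool = True) -> np.ndarray:
        W = np.zeros((self.n, self.n))
        for i, nb in enumerate(self.neighbors):
            W[i, nb] = 1.0
        if row_standardize:
            rs = W.sum(axis=1, keepdims=True)
            rs[rs == 0] = 1.0
            W = W / rs
        return W

    def color_classes(self) -> list[np.ndarray]:
        """Greedy proper coloring: zones in one class share no edge, so
        single-site updates within a class can run vectorized."""
        color = np.full(self.n, -1, dtype=int)
        for i in range(self.n):
            used = {color[j] for j in self.neighbors[i] if color[j] >= 0}
            c = 0
            while c in used:
                c += 1
            color[i] = c
        return [np.flatnonzero(color == c) for c in range(color.max() + 1)]


def build_adjacency(
    zones: Sequence[Zone], method: str = "queen", k: int = 4
) -> Adjacency:
    """Build the zone neighbor graph.

    ``queen``: polygons sharing at least a boundary point are neighbors;
    zones left with no neighbor (islands) are attached to the zone with
    the nearest centroid. ``knn``: symmetrized k-nearest-neighbor graph on
    centroids.
    """
    n = len(zones)
    if n < 2:
        raise ValidationError("need at least 2 zones for a spatial structure")
    nb_sets: list[set[int]] = [set() for _ in range(n)]
    centroids = np.array([z.centroid for z in zones], dtype=float)

    if method == "queen":
        geoms = [z.geometry for z in zones]
        if any(g is None for g in geoms):
            raise ValidationError("queen contiguity requires polygon geometry")
        tree = STRtree(geoms)
        for i, g in enumerate(geoms):
            for j in tree.query(g, predicate="intersects"):
                j = int(j)
                if j != i:
                    nb_sets[i].add(j)
                    nb_sets[j].add(i)
        # attach islands to the nearest centroid
        kdt = cKDTree(centroids)
        for i in range(n):
            if not nb_sets[i]:
                _, idx = kdt.query(centroids[i], k=2)
                j = int(idx[1])
                nb_sets[i].add(j)
                nb_sets[j].add(i)
                logger.warning("island zone %s attached to nearest zone %s",
                               zones[i].zone_id, zones[j].zone_id)
    elif method == "knn":
        if k < 1:
            raise ValidationError("knn requires k >= 1")
        kdt = cKDTree(centroids)
        _, idx = kdt.query(centroids, k=min(k + 1, n))
        for i in range(n):
            for j in np.atleast_1d(idx[i])[1:]:
                j = int(j)
                nb_sets[i].add(j)
                nb_sets[j].add(i)  # symmetrize
    else:
        raise ValueError(f"unknown adjacency method {method!r}")

    return Adjacency(n=n, neighbors=[np.array(sorted(s)) for s in nb_sets])


# --------------------------------------------------------------------------
# Covariates

def standardize_covariates(zones: Sequence[Zone]) -> tuple[np.ndarray, dict]:
    """Z-score the five zone covariates (population sd, ddof=0).

    Returns the n x 5 design matrix and a scaler record
    ``{"mean": ..., "scale": ..., "names": ...}`` so coefficients can be
    mapped back to the raw covariate scale. Constant columns become zeros
    (with a warning) rather than NaNs.
    """
    from .datamodel import COVARIATE_FIELDS

    if len(zones) < 2:
        raise ValidationError("standardization needs at least 2 zones")
    X = np.array([z.covariates for z in zones], dtype=float)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)  # ddof=0
    zero = scale == 0
    if zero.any():
        for j in np.flatnonzero(zero):
            logger.warning("covariate %s is constant; standardized to zeros",
                           COVARIATE_FIELDS[j])
    safe = np.where(zero, 1.0, scale)
    Z = (X - mean) / safe
    Z[:, zero] = 0.0
    return Z, {"mean": mean, "scale": scale, "names": list(COVARIATE_FIELDS)}


# --------------------------------------------------------------------------
# Parameters / samples containers

@dataclass
class ZIPSpatialParams:
    """True or fitted parameters of the ZIP spatial model."""

    alpha: float
    beta: np.ndarray
    p_zero: float
    tau_u: float = 1.0
    tau_v: float = 1.0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if not (0.0 <= self.p_zero <= 1.0):
            raise ValidationError("p_zero must be in [0, 1]")
        if self.tau_u <= 0 or self.tau_v <= 0:
            raise ValidationError("precisions must be > 0")


@dataclass
class PosteriorSamples:
    """Retained MCMC draws (post burn-in, thinned)."""

    alpha: np.ndarray          # (m,)
    beta: np.ndarray           # (m, p)
    p_zero: np.ndarray         # (m,)
    tau_u: np.ndarray          # (m,)
    tau_v: np.ndarray          # (m,)
    u: np.ndarray              # (m, n)
    v: np.ndarray              # (m, n)
    acceptance: dict = field(default_factory=dict)
    seed: Optional[int] = None
    config: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return len(self.alpha)


@dataclass
class RiskSurface:
    """Posterior mean (and sd) incidence per zone — the demand surface."""

    zone_ids: list[str]
    risk_mean: np.ndarray
    risk_sd: np.ndarray

    def __post_init__(self) -> None:
        self.risk_mean = np.asarray(self.risk_mean, dtype=float)
        self.risk_sd = np.asarray(self.risk_sd, dtype=float)
        if not np.all(np.isfinite(self.risk_mean)) or np.any(self.risk_mean < 0):
            raise ValidationError("risk_mean must be finite and >= 0")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.zone_ids, self.risk_mean.tolist()))


# --------------------------------------------------------------------------
# Non-spatial ZIP maximum likelihood via EM

def _poisson_newton(y, X1, w, eta0, max_iter=50, tol=1e-10):
    """Weighted Poisson regression (log link) by Newton-Raphson.

    Maximizes sum_i w_i * (y_i * eta_i - exp(eta_i)) over coefficients of
    the design X1 (with intercept column). Returns the coefficient vector.
    """
    coef = eta0.copy()
    for _ in range(max_iter):
        eta = X1 @ coef
        mu = np.exp(np.clip(eta, -30, 30))
        grad = X1.T @ (w * (y - mu))
        H = (X1 * (w * mu)[:, None]).T @ X1
        H += 1e-10 * np.eye(H.shape[0])
        step = np.linalg.solve(H, grad)
        # halve the step until the penalized objective does not decrease
        f0 = np.sum(w * (y * eta - mu))
        t = 1.0
        for _ in range(30):
            cand = coef + t * step
            eta_c = X1 @ cand
            f1 = np.sum(w * (y * eta_c - np.exp(np.clip(eta_c, -30, 30))))
            if f1 >= f0 - 1e-12:
                break
            t *= 0.5
        coef = coef + t * step
        if np.max(np.abs(t * step)) < tol:
            break
    return coef


def zip_loglik(y, eta, p_zero):
    """Log-likelihood of the ZIP model with Poisson log-mean eta."""
    mu = np.exp(np.clip(eta, -30, 30))
    is_zero = y == 0
    ll = np.empty_like(mu)
    # zeros: log(p + (1-p) e^{-mu}); use logaddexp for stability
    with np.errstate(divide="ignore"):
        ll[is_zero] = np.logaddexp(
            np.log(p_zero) if p_zero > 0 else -np.inf,
            np.log1p(-p_zero) - mu[is_zero] if p_zero < 1 else -np.inf,
        )
    pos = ~is_zero
    if p_zero < 1:
        ll[pos] = (
            np.log1p(-p_zero) + y[pos] * eta[pos] - mu[pos] - gammaln(y[pos] + 1)
        )
    else:
        ll[pos] = -np.inf
    return float(np.sum(ll))


def fit_zip_em(
    y: np.ndarray,
    X: Optional[np.ndarray] = None,
    *,
    fix_p_zero: Optional[float] = None,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> tuple[float, np.ndarray, float, float]:
    """Maximum-likelihood fit of the non-spatial ZIP regression by EM.

    E-step: posterior probability each observed zero is structural.
    M-step: update p_zero to the mean responsibility and refit the
    weighted Poisson regression. Converged when the log-likelihood
    improves by less than ``tol`` (default 1e-8) or after ``max_iter``
    iterations.

    Returns ``(alpha, beta, p_zero, loglik)``; ``beta`` is empty for an
    intercept-only fit (``X=None`` or zero columns).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if np.all(y == 0):
        raise ValidationError("degenerate data: all counts are zero")
    if X is None:
        X = np.empty((n, 0))
    X = np.asarray(X, dtype=float)
    X1 = np.column_stack([np.ones(n), X])

    p = float(np.mean(y == 0)) / 2 if fix_p_zero is None else float(fix_p_zero)
    coef = np.zeros(X1.shape[1])
    coef[0] = math.log(max(y[y > 0].mean(), 1e-8))
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = X1 @ coef
        mu = np.exp(np.clip(eta, -30, 30))
        # E-step: responsibility that a zero is structural
        z = np.zeros(n)
        if p > 0:
            zero = y == 0
            denom = p + (1 - p) * np.exp(-mu[zero])
            z[zero] = p / denom
        # M-step
        if fix_p_zero is None:
            p = float(np.mean(z))
        coef = _poisson_newton(y, X1, 1.0 - z, coef)
        ll = zip_loglik(y, X1 @ coef, p)
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    return float(coef[0]), coef[1:].copy(), float(p), ll


# --------------------------------------------------------------------------
# MCMC: Metropolis-within-Gibbs for the spatial ZIP

DEFAULT_PRIORS = {
    "alpha_sd": 10.0,      # alpha, beta ~ Normal(0, 10^2)
    "beta_sd": 10.0,
    "tau_shape": 1.0,      # tau_u, tau_v ~ Gamma(1, rate 0.01)
    "tau_rate": 0.01,
    "p_a": 1.0,            # p_zero ~ Beta(1, 1)
    "p_b": 1.0,
}

DEFAULT_MCMC = {"iterations": 10_000, "burn_in": 2_000, "thin": 4}


def _adapt(log_step: float, accept_rate: float, target: float, it: int) -> float:
    """Robbins-Monro style step-size adaptation (burn-in only)."""
    gamma = min(0.25, 2.0 / math.sqrt(it + 1))
    return log_step + gamma * (accept_rate - target)


def fit_zip_spatial_mcmc(
    y: np.ndarray,
    X: np.ndarray,
    adjacency: Adjacency,
    config: Optional[dict] = None,
) -> PosteriorSamples:
    """Posterior sampling for the ZIP + BYM model.

    Update scheme per sweep:

    * structural-zero indicators ``w_i`` for zones with ``y_i = 0``: Gibbs
      from Bernoulli(p / (p + (1-p) exp(-lambda_i)));
    * ``p_zero``: Gibbs from its Beta full conditional;
    * ``alpha`` and each ``beta_m``: adaptive random-walk Metropolis on the
      active-Poisson likelihood;
    * ``u``: single-site adaptive random-walk Metropolis with the ICAR
      full-conditional prior, vectorized over graph-coloring classes, then
      re-centered to enforce the sum-to-zero constraint;
    * ``v``: independent single-site Metropolis (fully vectorized);
    * ``tau_u``, ``tau_v``: Gibbs from their Gamma full conditionals
      (ICAR rank n-1 for tau_u).

    Deterministic given ``config['seed']``: the same seed yields
    bit-identical draws.
    """
    cfg = dict(DEFAULT_MCMC)
    cfg.update(config or {})
    priors = dict(DEFAULT_PRIORS)
    priors.update(cfg.pop("priors", {}))
    iterations = int(cfg["iterations"])
    burn_in = int(cfg["burn_in"])
    thin = max(1, int(cfg.get("thin", 1)))
    seed = cfg.get("seed", 0)
    target_acc = float(cfg.get("target_acceptance", 0.375))  # mid 30-45%

    if iterations <= burn_in:
        raise ValidationError("iterations must exceed burn_in")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, pdim = X.shape
    if len(y) != n or adjacency.n != n:
        raise ValidationError("y, X and adjacency dimensions disagree")
    adjacency.validate_symmetric()

    rng = np.random.default_rng(seed)
    degrees = adjacency.degrees
    colors = adjacency.color_classes()
    edges = adjacency.edge_list()
    # pre-sliced sparse adjacency rows per color class for fast neighbor sums
    from scipy import sparse

    indptr = np.concatenate([[0], np.cumsum([len(nb) for nb in adjacency.neighbors])])
    indices = (np.concatenate(adjacency.neighbors)
               if indptr[-1] else np.array([], dtype=np.intp))
    A = sparse.csr_matrix(
        (np.ones(indptr[-1]), indices, indptr), shape=(n, n))
    A_by_color = [A[idx] for idx in colors]

    # initialise from the EM fit when possible
    try:
        alpha, beta, p_zero, _ = fit_zip_em(y, X, max_iter=100)
    except ValidationError:
        raise
    beta = np.asarray(beta, dtype=float)
    u = np.zeros(n)
    v = np.zeros(n)
    tau_u = 1.0
    tau_v = 10.0
    is_zero_obs = y == 0
    w = np.zeros(n, dtype=bool)  # structural-zero indicator

    eta_fixed = alpha + X @ beta  # cached linear predictor without u, v
    log_steps_ab = np.full(1 + pdim, math.log(0.1))
    log_step_u = math.log(0.5)
    log_step_v = math.log(0.5)
    acc_ab = np.zeros(1 + pdim)
    n_ab = np.zeros(1 + pdim)
    acc_u = acc_v = n_u = n_v = 0.0

    n_keep = (iterations - burn_in) // thin
    out = {
        "alpha": np.empty(n_keep), "p_zero": np.empty(n_keep),
        "tau_u": np.empty(n_keep), "tau_v": np.empty(n_keep),
        "beta": np.empty((n_keep, pdim)),
        "u": np.empty((n_keep, n)), "v": np.empty((n_keep, n)),
    }
    keep = 0

    alpha_prec = 1.0 / priors["alpha_sd"] ** 2
    beta_prec = 1.0 / priors["beta_sd"] ** 2

    def active_loglik(eta, active):
        mu = np.exp(np.clip(eta, -30, 30))
        return np.where(active, y * eta - mu, 0.0)

    for it in range(iterations):
        eta = eta_fixed + u + v
        mu = np.exp(np.clip(eta, -30, 30))

        # --- structural-zero indicators (only observed zeros can be structural)
        if p_zero > 0:
            prob = p_zero / (p_zero + (1 - p_zero) * np.exp(-mu))
            w = np.where(is_zero_obs, rng.random(n) < prob, False)
        else:
            w = np.zeros(n, dtype=bool)
        active = ~w

        # --- p_zero | w  (Beta conjugacy)
        p_zero = rng.beta(priors["p_a"] + w.sum(), priors["p_b"] + n - w.sum())

        # --- alpha, beta: component-wise random-walk Metropolis
        ll_vec = active_loglik(eta, active)
        ll_cur = ll_vec.sum()
        for comp in range(1 + pdim):
            step = math.exp(log_steps_ab[comp])
            prop = rng.normal(0.0, step)
            if comp == 0:
                eta_prop = eta + prop
                lp_diff = -0.5 * alpha_prec * ((alpha + prop) ** 2 - alpha ** 2)
            else:
                xcol = X[:, comp - 1]
                eta_prop = eta + prop * xcol
                b = beta[comp - 1]
                lp_diff = -0.5 * beta_prec * ((b + prop) ** 2 - b ** 2)
            ll_prop = active_loglik(eta_prop, active).sum()
            n_ab[comp] += 1
            if math.log(rng.random()) < ll_prop - ll_cur + lp_diff:
                acc_ab[comp] += 1
                eta = eta_prop
                ll_cur = ll_prop
                if comp == 0:
                    alpha += prop
                else:
                    beta[comp - 1] += prop
            if it < burn_in and (it + 1) % 50 == 0 and n_ab[comp] > 0:
                log_steps_ab[comp] = _adapt(
                    log_steps_ab[comp], acc_ab[comp] / n_ab[comp], target_acc, it)
                acc_ab[comp] = n_ab[comp] = 0
        eta_fixed = alpha + X @ beta
        eta = eta_fixed + u + v

        # --- u: ICAR single-site Metropolis over color classes
        step_u = math.exp(log_step_u)
        for idx, A_c in zip(colors, A_by_color):
            m = len(idx)
            prop = rng.normal(0.0, step_u, size=m)
            u_new = u[idx] + prop
            nbsum = A_c @ u
            d = degrees[idx]
            # ICAR log prior difference: -tau_u/2 * d * (u_i - mean_nb)^2
            lp_diff = -0.5 * tau_u * (
                d * u_new ** 2 - 2 * u_new * nbsum - (d * u[idx] ** 2 - 2 * u[idx] * nbsum)
            )
            eta_i = eta[idx]
            eta_new = eta_i + prop
            act = active[idx]
            mu_i = np.exp(np.clip(eta_i, -30, 30))
            mu_new = np.exp(np.clip(eta_new, -30, 30))
            ll_diff = np.where(act, y[idx] * prop - (mu_new - mu_i), 0.0)
            accept = np.log(rng.random(m)) < ll_diff + lp_diff
            u[idx] = np.where(accept, u_new, u[idx])
            eta[idx] = np.where(accept, eta_new, eta_i)
            acc_u += accept.sum()
            n_u += m
        # sum-to-zero re-centering (fold the shift into alpha to keep eta)
        shift = u.mean()
        u -= shift
        alpha += shift
        eta_fixed = alpha + X @ beta
        if it < burn_in and (it + 1) % 50 == 0 and n_u > 0:
            log_step_u = _adapt(log_step_u, acc_u / n_u, target_acc, it)
            acc_u = n_u = 0.0

        # --- v: iid Gaussian effect, fully vectorized Metropolis
        step_v = math.exp(log_step_v)
        prop = rng.normal(0.0, step_v, size=n)
        v_new = v + prop
        lp_diff = -0.5 * tau_v * (v_new ** 2 - v ** 2)
        eta_new = eta + prop
        mu_cur = np.exp(np.clip(eta, -30, 30))
        mu_new = np.exp(np.clip(eta_new, -30, 30))
        ll_diff = np.where(active, y * prop - (mu_new - mu_cur), 0.0)
        accept = np.log(rng.random(n)) < ll_diff + lp_diff
        v = np.where(accept, v_new, v)
        eta = np.where(accept, eta_new, eta)
        acc_v += accept.sum()
        n_v += n
        if it < burn_in and (it + 1) % 50 == 0 and n_v > 0:
            log_step_v = _adapt(log_step_v, acc_v / n_v, target_acc, it)
            acc_v = n_v = 0.0

        # --- precisions (Gamma conjugacy; ICAR rank is n-1)
        if len(edges):
            ssq_u = np.sum((u[edges[:, 0]] - u[edges[:, 1]]) ** 2)
        else:
            ssq_u = 0.0
        tau_u = rng.gamma(priors["tau_shape"] + 0.5 * (n - 1),
                          1.0 / (priors["tau_rate"] + 0.5 * ssq_u))
        tau_v = rng.gamma(priors["tau_shape"] + 0.5 * n,
                          1.0 / (priors["tau_rate"] + 0.5 * np.sum(v ** 2)))

        # --- store
        if it >= burn_in and (it - burn_in) % thin == 0 and keep < n_keep:
            out["alpha"][keep] = alpha
            out["beta"][keep] = beta
            out["p_zero"][keep] = p_zero
            out["tau_u"][keep] = tau_u
            out["tau_v"][keep] = tau_v
            out["u"][keep] = u
            out["v"][keep] = v
            keep += 1

    acceptance = {
        "alpha_beta": float(np.mean(acc_ab / np.maximum(n_ab, 1))) if n_ab.sum() else None,
        "u": float(acc_u / n_u) if n_u else None,
        "v": float(acc_v / n_v) if n_v else None,
    }
    return PosteriorSamples(
        alpha=out["alpha"], beta=out["beta"], p_zero=out["p_zero"],
        tau_u=out["tau_u"], tau_v=out["tau_v"], u=out["u"], v=out["v"],
        acceptance=acceptance, seed=seed,
        config={"iterations": iterations, "burn_in": burn_in, "thin": thin,
                "priors": priors},
    )


def posterior_risk(
    samples: PosteriorSamples,
    X: np.ndarray,
    zones: Sequence[Zone],
    *,
    include_zero_inflation: bool = True,
) -> RiskSurface:
    """Posterior mean (and sd) incidence per zone.

    Per draw the zone incidence is ``(1 - p_zero) * exp(alpha + x'beta + u + v)``
    — the ZIP mixture mean. Set ``include_zero_inflation=False`` to report
    the Poisson-component mean ``lambda`` instead.
    """
    if samples.n_draws == 0:
        raise ValidationError("no posterior draws")
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if len(zones) != n or samples.u.shape[1] != n:
        raise ValidationError("dimension mismatch between samples, X and zones")
    eta = (
        samples.alpha[:, None]
        + samples.beta @ X.T
        + samples.u
        + samples.v
    )
    lam = np.exp(np.clip(eta, -30, 30))
    if include_zero_inflation:
        lam = (1.0 - samples.p_zero[:, None]) * lam
    return RiskSurface(
        zone_ids=[z.zone_id for z in zones],
        risk_mean=lam.mean(axis=0),
        risk_sd=lam.std(axis=0, ddof=0),
    )
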