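"""Model diagnostics: residuals, global Moran's I, zero-accessibility counts.

Moran's I on the fit residuals checks whether the spatial random effects
absorbed the spatial autocorrelation in the counts: an I near its
permutation-null expectation -1/(n-1) with a non-significant p-value means
no global clustering remains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .accessibility import AccessibilityResult
from .datamodel import ValidationError, Zone
from .risk import Adjacency, RiskSurface


@dataclass
class MoranResult:
    I: float
    expected_I: float
    p_value: float
    n_permutations: int
    seed: int


def residuals(
    observed: Sequence[float] | dict[str, float],
    risk: RiskSurface,
    zones: Sequence[Zone] | None = None,
) -> np.ndarray:
    """Raw residuals r_i = y_i - D_i, aligned with the risk surface order.

    ``observed`` may be an array aligned with ``risk.zone_ids`` or a
    zone_id -> count mapping.
    """
    if isinstance(observed, dict):
        missing = [zid for zid in risk.zone_ids if zid not in observed]
        if missing:
            raise ValidationError(f"observed counts missing for {missing[:5]}")
        y = np.array([observed[zid] for zid in risk.zone_ids], dtype=float)
    else:
        y = np.asarray(observed, dtype=float)
        if len(y) != len(risk.zone_ids):
            raise ValidationError("observed length does not match risk surface")
    return y - risk.risk_mean


def morans_i(
    values: np.ndarray,
    adjacency: Adjacency,
    n_permutations: int = 999,
    seed: int = 0,
) -> MoranResult:
    """Global Moran's I with row-standardized weights and a two-sided
    permutation test.

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z the centered
    values. The p-value counts permutations at least as extreme (in
    |I - E[I]|) as the observed statistic, with add-one smoothing:
    (count + 1) / (n_permutations + 1).
    """
    z = np.asarray(values, dtype=float)
    n = adjacency.n
    if len(z) != n:
        raise ValidationError("values length does not match adjacency")
    if np.ptp(z) == 0:
        raise ValidationError("Moran's I undefined for constant values")
    z = z - z.mean()
    W = adjacency.to_weight_matrix(row_standardize=True)
    s0 = W.sum()
    denom = float(z @ z)

    def stat(zv: np.ndarray) -> float:
        return float(n / s0 * (zv @ W @ zv) / (zv @ zv))

    I_obs = stat(z)
    e_i = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        zp = rng.permutation(z)
        if abs(stat(zp) - e_i) >= abs(I_obs - e_i):
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return MoranResult(I=I_obs, expected_I=e_i, p_value=p,
                       n_permutations=n_permutations, seed=seed)


def count_zero_accessibility(
    result: AccessibilityResult, tol: float = 1e-12
) -> tuple[int, list[str]]:
    """Number and ids of zones with exactly zero accessibility."""
    mask = np.abs(result.accessibility) <= tol
    ids = [zid for zid, m in zip(result.zone_ids, mask) if m]
    return len(ids), ids
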