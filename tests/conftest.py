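import numpy as np
import pytest

import aedcatch as ac


@pytest.fixture
def micro():
    """Hand-worked 3-zone / 2-AED fixture with known accessibility."""
    region, demand = ac.make_micro_fixture()
    return region, demand


@pytest.fixture(scope="session")
def small_city():
    """A 6x6 synthetic city with counts, sites and hospitals (seeded)."""
    params = ac.CityParams(nx=6, ny=6, seed=11)
    region = ac.generate_grid_city(params)
    adj = ac.build_adjacency(region.zones, method="queen")
    y = ac.simulate_counts(region.zones, params.true_model, adj, seed=12)
    for z, c in zip(region.zones, y):
        z.observed_count = int(c)
    sites, hospitals = ac.place_sites(region.zones, n_aed=4, n_ems=1,
                                      n_hospitals=1, seed=13)
    region.supply_sites = sites
    region.hospitals = hospitals
    return region, adj


def random_instance(rng, n_zones, n_sites, extent=2000.0):
    """A random accessibility problem: zones, demand surface, mixed sites."""
    attrs = dict(population=100.0, pop_density=1000.0, pct_elderly=10.0,
                 pct_housing=30.0, pct_transport=10.0, pct_public=5.0,
                 observed_count=0)
    zones = [
        ac.Zone(zone_id=f"z{i}", centroid=tuple(rng.uniform(0, extent, 2)), **attrs)
        for i in range(n_zones)
    ]
    demand = ac.RiskSurface(
        zone_ids=[z.zone_id for z in zones],
        risk_mean=rng.uniform(0.1, 3.0, n_zones),
        risk_sd=np.zeros(n_zones),
    )
    sites = []
    for j in range(n_sites):
        stype = "onsite_aed" if rng.random() < 0.7 else "ems_station"
        sites.append(ac.SupplySite(
            site_id=f"s{j}", site_type=stype,
            location=tuple(rng.uniform(0, extent, 2)),
            capacity=float(rng.uniform(0.5, 2.0)),
            catchment_radius=float(rng.uniform(150, 1200)),
        ))
    return zones, demand, sites
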