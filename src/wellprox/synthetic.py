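"""Synthetic landscapes for end-to-end testing of the exposure pipeline.

The generator emulates the statistical structure the analysis assumes
without mimicking any real geography: a rectangular tessellation of block
groups (populations in the 600-3,000 range typical of census block groups),
clustered well fields with coherent life histories (spud -> completion ->
production years with heavily skewed log-normal volumes -> retirement or
plugging, with a configurable fraction of plugged wells missing their
closing dates), and a planted demographic gradient that concentrates a
target group near well clusters so the downstream risk ratios have a known
expectation.

Two demographic modes are offered: *deterministic* (expected counts, no
sampling noise) supports exact parameter-recovery tests against
:func:`expected_rr`; *sampled* (multinomial/binomial draws) supports
null-calibration tests.  All randomness flows through seeded
``numpy.random.Generator`` substreams; identical seeds give identical
landscapes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Polygon, box

from .exposure import RACE_GROUPS, BlockGroupPeriod
from .wells import CANONICAL_PERIODS, StudyPeriod, WellRecord

#: California-like base race/ethnicity shares (sum to 1).
DEFAULT_BASE_SHARES = {
    "hispanic_latinx": 0.390,
    "nh_white": 0.375,
    "nh_asian": 0.143,
    "nh_black": 0.055,
    "nh_two_or_more": 0.030,
    "nh_aian": 0.004,
    "nh_other": 0.003,
}

#: socioeconomic universes as fractions of total population, and event rates
SOCIO_STRUCTURE = {
    # group: (universe_field, universe_frac_of_pop, numerator_field, rate)
    "poverty": ("poverty_universe", 0.98, "poverty_num", 0.125),
    "lt12_edu": ("edu_universe", 0.65, "lt12_edu_num", 0.17),
    "renter": ("total_households", 0.345, "renter_households", 0.45),
    "ling_isolated": ("total_adults", 0.75, "ling_isolated_adults", 0.20),
    "nonvoter": ("eligible_voters", 0.70, "nonvoters", 0.284),
}


@dataclass
class LandscapeConfig:
    """Parameters of one synthetic landscape.

    The planted disparity multiplies the target group's base share by
    ``1 + (disparity_multiplier - 1) * exp(-d / gradient_length_m)`` where
    ``d`` is the distance from a block group's centre to the nearest well
    cluster, then renormalizes the remaining groups; a multiplier of 1
    plants no disparity.  With ``snap_clusters_to_cells`` the cluster
    centres sit at the centres of distinct grid cells and
    ``cluster_dispersion_m`` may be set to 0, which makes the exposed area
    of each cluster cell exactly computable (see :func:`expected_rr`).
    """

    seed: int = 0
    # tessellation
    nx: int = 8
    ny: int = 8
    cell_size_m: float = 2000.0
    # well fields
    n_clusters: int = 3
    wells_per_cluster_mean: float = 8.0
    cluster_dispersion_m: float = 300.0
    snap_clusters_to_cells: bool = False
    # life-history date process
    spud_year_range: tuple[int, int] = (1950, 2017)
    preproduction_days_range: tuple[int, int] = (30, 240)
    production_lifetime_years_range: tuple[int, int] = (2, 30)
    abandonment_prob: float = 0.5
    missing_date_fraction: float = 0.443
    # annual production volume: log-normal (heavy right skew)
    boe_log_mean: float = math.log(1000.0)
    boe_log_sigma: float = 2.5
    # demographics
    population_range: tuple[int, int] = (600, 3000)
    population_mean: int = 1500
    base_shares: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_SHARES)
    )
    deterministic_demographics: bool = False
    # planted disparity
    disparity_group: str = "nh_black"
    disparity_multiplier: float = 1.0
    gradient_length_m: float = 2000.0
    # misc
    n_tribal_polygons: int = 2
    periods: tuple[StudyPeriod, ...] = CANONICAL_PERIODS

    def __post_init__(self) -> None:
        if self.nx <= 0 or self.ny <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size_m <= 0 or self.gradient_length_m <= 0:
            raise ValueError("scale parameters must be positive")
        s = sum(self.base_shares.values())
        if any(v < 0 for v in self.base_shares.values()) or abs(s - 1.0) > 1e-9:
            raise ValueError(f"race shares must be non-negative and sum to 1 (got {s})")


def _rng(config: LandscapeConfig, stream: int) -> np.random.Generator:
    """Independent substream; wells, demographics etc. never share draws."""
    return np.random.default_rng([config.seed, stream])


def cluster_centers(config: LandscapeConfig) -> np.ndarray:
    """(n_clusters, 2) cluster centre coordinates, deterministic per seed."""
    rng = _rng(config, 0)
    w, h = config.nx * config.cell_size_m, config.ny * config.cell_size_m
    if config.snap_clusters_to_cells:
        n_cells = config.nx * config.ny
        cells = rng.choice(n_cells, size=min(config.n_clusters, n_cells), replace=False)
        ix, iy = cells % config.nx, cells // config.nx
        return np.column_stack([
            (ix + 0.5) * config.cell_size_m,
            (iy + 0.5) * config.cell_size_m,
        ])
    return np.column_stack([rng.uniform(0, w, config.n_clusters),
                            rng.uniform(0, h, config.n_clusters)])


def _cell_centroids(config: LandscapeConfig) -> np.ndarray:
    ix, iy = np.meshgrid(np.arange(config.nx), np.arange(config.ny))
    return np.column_stack([
        (ix.ravel() + 0.5) * config.cell_size_m,
        (iy.ravel() + 0.5) * config.cell_size_m,
    ])


def _planted_shares(config: LandscapeConfig, dist_to_cluster: float) -> dict[str, float]:
    """Race shares at a given distance from the nearest well cluster."""
    base = config.base_shares
    target = config.disparity_group
    mult = 1.0 + (config.disparity_multiplier - 1.0) * math.exp(
        -dist_to_cluster / config.gradient_length_m
    )
    s_t = min(base[target] * mult, 0.95)
    scale = (1.0 - s_t) / (1.0 - base[target])
    shares = {g: base[g] * scale for g in base if g != target}
    shares[target] = s_t
    return shares


def _cell_demographics(
    config: LandscapeConfig,
    dist: float,
    period_index: int,
    rng: Optional[np.random.Generator],
) -> dict[str, float]:
    """Demographic counts for one cell-period; rng=None -> deterministic."""
    shares = _planted_shares(config, dist)
    if rng is None:
        pop = float(config.population_mean)
        counts = {g: shares[g] * pop for g in RACE_GROUPS if g != "nh_other"}
        counts["nh_other"] = pop - sum(counts.values())  # exact partition
    else:
        pop = float(rng.integers(config.population_range[0],
                                 config.population_range[1] + 1))
        draw = rng.multinomial(int(pop), [shares[g] for g in RACE_GROUPS])
        counts = {g: float(draw[i]) for i, g in enumerate(RACE_GROUPS)}
    demo = {"total_population": pop, **counts}
    for group, (uni, uni_frac, num, rate) in SOCIO_STRUCTURE.items():
        if group == "nonvoter" and period_index == 0:
            continue  # turnout data unavailable in the earliest period
        universe = float(round(uni_frac * pop))
        if rng is None:
            numerator = rate * universe
        else:
            numerator = float(rng.binomial(int(universe), rate))
        demo[uni] = universe
        demo[num] = numerator
    return demo


def generate_blockgroups(config: LandscapeConfig) -> list[BlockGroupPeriod]:
    """Rectangular block-group tessellation for every study period.

    Cell ``(i, j)`` covers ``[i*s, (i+1)*s] x [j*s, (j+1)*s]``; geoids encode
    the grid position and counties split the landscape at the x midpoint.
    """
    centers = cluster_centers(config)
    centroids = _cell_centroids(config)
    dists = np.sqrt(
        ((centroids[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    ).min(axis=1)
    rng = None if config.deterministic_demographics else _rng(config, 2)
    s = config.cell_size_m
    midline = config.nx * s / 2.0
    out: list[BlockGroupPeriod] = []
    for pi, period in enumerate(config.periods):
        for k in range(config.nx * config.ny):
            ix, iy = k % config.nx, k // config.nx
            geom = box(ix * s, iy * s, (ix + 1) * s, (iy + 1) * s)
            out.append(
                BlockGroupPeriod(
                    geoid=f"bg{ix:03d}{iy:03d}",
                    period=period.label,
                    geometry=geom,
                    demographics=_cell_demographics(config, float(dists[k]), pi, rng),
                    county="alpha" if centroids[k, 0] < midline else "beta",
                )
            )
    return out


def _random_date(rng: np.random.Generator, year: int) -> date:
    return date(year, int(rng.integers(1, 13)), int(rng.integers(1, 29)))


def generate_wells(config: LandscapeConfig) -> list[WellRecord]:
    """Clustered wells with coherent life histories.

    Per well: spud date, completion after a preproduction interval, annual
    log-normal production for the drawn lifetime, last production date, and
    with probability ``abandonment_prob`` an abandonment 1-3 years later
    (status ``plugged``).  A fraction ``missing_date_fraction`` of plugged
    wells then have their last-production and abandonment dates blanked,
    emulating legacy wells with no closing records.  The ordered-date
    invariant holds before blanking.
    """
    centers = cluster_centers(config)
    rng = _rng(config, 1)
    wells: list[WellRecord] = []
    wid = 0
    for cx, cy in centers:
        # every cluster is realized with at least one well
        n = max(1, int(rng.poisson(config.wells_per_cluster_mean)))
        for _ in range(n):
            if config.cluster_dispersion_m > 0:
                x = float(cx + rng.normal(0, config.cluster_dispersion_m))
                y = float(cy + rng.normal(0, config.cluster_dispersion_m))
            else:
                x, y = float(cx), float(cy)
            spud_year = int(rng.integers(config.spud_year_range[0],
                                         config.spud_year_range[1] + 1))
            spud = _random_date(rng, spud_year)
            completion = spud + timedelta(
                days=int(rng.integers(config.preproduction_days_range[0],
                                      config.preproduction_days_range[1] + 1))
            )
            first_prod = completion + timedelta(days=int(rng.integers(0, 91)))
            lifetime = int(rng.integers(config.production_lifetime_years_range[0],
                                        config.production_lifetime_years_range[1] + 1))
            last_year = first_prod.year + lifetime - 1
            annual = {
                int(y): float(rng.lognormal(config.boe_log_mean, config.boe_log_sigma))
                for y in range(first_prod.year, last_year + 1)
            }
            last_prod = max(first_prod, date(last_year, 12, 15))
            abandonment: Optional[date] = None
            status = "producing" if last_year >= 2019 else "idle"
            if rng.uniform() < config.abandonment_prob:
                abandonment = last_prod + timedelta(
                    days=int(rng.integers(365, 3 * 365 + 1))
                )
                status = "plugged"
            w = WellRecord(
                well_id=f"w{wid:05d}", x=x, y=y, status=status,
                spud_date=spud, completion_date=completion,
                first_prod_date=first_prod, last_prod_date=last_prod,
                abandonment_date=abandonment,
                well_type="OG", annual_boe=annual,
            )
            if status == "plugged" and rng.uniform() < config.missing_date_fraction:
                w.last_prod_date = None
                w.abandonment_date = None
            wells.append(w)
            wid += 1
    return wells


def generate_tribal_lands(config: LandscapeConfig) -> dict[str, Polygon]:
    """A few rectangular tribal-land polygons placed on random grid cells."""
    rng = _rng(config, 3)
    s = config.cell_size_m
    out = {}
    for i in range(config.n_tribal_polygons):
        ix = int(rng.integers(0, config.nx))
        iy = int(rng.integers(0, config.ny))
        out[f"tribal{i}"] = box(ix * s, iy * s, (ix + 1) * s, (iy + 1) * s)
    return out


def expected_rr(config: LandscapeConfig, radius_m: float = 1000.0) -> dict[str, float]:
    """Closed-form state-scope risk ratio per group under exact coverage.

    Defined only for the deterministic demographic mode with clusters
    snapped to distinct cell centres, zero dispersion, and a buffer radius
    no larger than half the cell size: each cluster cell then has exposed
    fraction equal to the area of the regular 64-gon buffer approximation
    over the cell area, and every other cell has fraction 0.  The ratio is
    computed directly from the planted composition, independent of the
    geometric and aggregation machinery it serves to check.  Raises in
    stochastic mode or any configuration without exact coverage.
    """
    if not config.deterministic_demographics:
        raise ValueError("expected_rr is defined only in deterministic mode")
    if not config.snap_clusters_to_cells or config.cluster_dispersion_m != 0:
        raise ValueError("expected_rr requires clusters snapped to cells with "
                         "zero dispersion")
    if radius_m > config.cell_size_m / 2.0:
        raise ValueError("expected_rr requires radius <= cell_size / 2")
    n_seg = 64
    gon_area = 0.5 * n_seg * radius_m**2 * math.sin(2.0 * math.pi / n_seg)
    f_exposed = gon_area / config.cell_size_m**2

    centers = cluster_centers(config)
    centroids = _cell_centroids(config)
    dists = np.sqrt(
        ((centroids[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    ).min(axis=1)
    fractions = np.where(dists < 1e-9, f_exposed, 0.0)

    pop = float(config.population_mean)
    group_tot: dict[str, float] = {g: 0.0 for g in RACE_GROUPS}
    group_exp: dict[str, float] = {g: 0.0 for g in RACE_GROUPS}
    pop_tot = pop_exp = 0.0
    for k in range(config.nx * config.ny):
        shares = _planted_shares(config, float(dists[k]))
        for g in RACE_GROUPS:
            group_tot[g] += shares[g] * pop
            group_exp[g] += shares[g] * pop * fractions[k]
        pop_tot += pop
        pop_exp += pop * fractions[k]
    rr = {
        g: (group_exp[g] / group_tot[g]) / (pop_exp / pop_tot)
        for g in RACE_GROUPS
    }
    rr["total_population"] = 1.0
    # uniform socioeconomic rates cancel: every indicator has expectation 1
    for group in SOCIO_STRUCTURE:
        rr[group] = 1.0
    return rr
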