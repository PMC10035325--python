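"""Group risk ratios and change analyses for well-exposure disparities.

The central statistic is the risk ratio

    RR = (group_exposed / group_total) / (pop_exposed / pop_total),

the exposed proportion of a demographic group relative to the exposed
proportion of the reference population.  RR > 1 means the group is
over-represented among people living near wells.  Ratios are computed at
any scope (statewide, a single county, or an exposure-intensity quintile);
socioeconomic indicators are compared against their own universes (renter
households against all households, linguistically isolated adults against
all adults, and so on).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .exposure import (
    RACE_GROUPS,
    SOCIO_PAIRS,
    BlockGroupPeriod,
    ExposureEstimate,
)
from .wells import WellRecord

#: group name -> (count field, universe field) for the RR numerator/denominator
GROUP_DEFS: dict[str, tuple[str, str]] = {
    **{g: (g, "total_population") for g in RACE_GROUPS},
    "total_population": ("total_population", "total_population"),
    "poverty": ("poverty_num", "poverty_universe"),
    "lt12_edu": ("lt12_edu_num", "edu_universe"),
    "renter": ("renter_households", "total_households"),
    "ling_isolated": ("ling_isolated_adults", "total_adults"),
    "nonvoter": ("nonvoters", "eligible_voters"),
}

DEFAULT_GROUPS = tuple(GROUP_DEFS)

#: no-change tolerance for floating-point production volumes
BOE_CHANGE_EPS = 1e-6


@dataclass(frozen=True)
class RiskRatioRecord:
    group: str
    stage: str
    period: str
    scope: str  # "state" | "county:<name>" | "quintile:<1..5>"
    group_exposed: float
    group_total: float
    pop_exposed: float
    pop_total: float
    rr: Optional[float]  # None = undefined (zero denominator)


@dataclass(frozen=True)
class PanelChangeRecord:
    metric: str  # "new_well_count" | "cumulative_boe"
    category: str  # "increase" | "decrease" | "no_change"
    demographic_sums: Mapping[str, float]


def risk_ratio(
    group_exposed: float,
    group_total: float,
    pop_exposed: float,
    pop_total: float,
) -> Optional[float]:
    """(group_exposed/group_total) / (pop_exposed/pop_total).

    Returns None (undefined, never 0) when any denominator of the ratio is
    zero.  Negative inputs or a numerator exceeding its denominator are
    fatal: they indicate corrupted aggregation upstream.
    """
    for name, v in (
        ("group_exposed", group_exposed),
        ("group_total", group_total),
        ("pop_exposed", pop_exposed),
        ("pop_total", pop_total),
    ):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    if group_exposed > group_total:
        raise ValueError(f"group_exposed {group_exposed} > group_total {group_total}")
    if pop_exposed > pop_total:
        raise ValueError(f"pop_exposed {pop_exposed} > pop_total {pop_total}")
    if group_total == 0 or pop_exposed == 0 or pop_total == 0:
        return None
    return (group_exposed / group_total) / (pop_exposed / pop_total)


def _in_scope(bg: BlockGroupPeriod, scope: str) -> bool:
    if scope == "state":
        return True
    if scope.startswith("county:"):
        return bg.county == scope.split(":", 1)[1]
    raise ValueError(f"unknown scope {scope!r}")


def _sum_counts(
    exposures: Mapping[tuple[str, str, str], ExposureEstimate],
    bgs: Sequence[BlockGroupPeriod],
    stage: str,
    period: str,
    num_field: str,
    uni_field: str,
) -> tuple[float, float, float, float]:
    """Aggregate (group_exposed, group_total, pop_exposed, pop_total)."""
    ge = gt = pe = pt = 0.0
    for bg in bgs:
        if num_field not in bg.demographics or uni_field not in bg.demographics:
            continue  # group not observed in this period (e.g. voter data)
        est = exposures.get((bg.geoid, period, stage))
        gt += bg.demographics[num_field]
        pt += bg.demographics[uni_field]
        if est is not None:
            ge += est.exposed_counts[num_field]
            pe += est.exposed_counts[uni_field]
    return ge, gt, pe, pt


def _index_exposures(
    exposures: Iterable[ExposureEstimate],
) -> dict[tuple[str, str, str], ExposureEstimate]:
    return {(e.geoid, e.period, e.stage): e for e in exposures}


def rr_table(
    exposures: Sequence[ExposureEstimate],
    bgs: Sequence[BlockGroupPeriod],
    scope: str = "state",
    stages: Sequence[str] = ("new", "active", "retired"),
    periods: Optional[Sequence[str]] = None,
    groups: Sequence[str] = DEFAULT_GROUPS,
) -> list[RiskRatioRecord]:
    """Risk ratios for every group x stage x period at one scope.

    The scope restricts both the exposed numerators and the reference totals
    (state = all block groups, county = that county's block groups only).
    Groups whose fields are absent from a period's demographics (the voter
    pair in the earliest period) are skipped for that period.
    """
    idx = _index_exposures(exposures)
    if periods is None:
        periods = sorted({bg.period for bg in bgs})
    records: list[RiskRatioRecord] = []
    for period in periods:
        in_scope = [
            bg for bg in bgs if bg.period == period and _in_scope(bg, scope)
        ]
        for stage in stages:
            for group in groups:
                num_field, uni_field = GROUP_DEFS[group]
                observed = [
                    bg for bg in in_scope if num_field in bg.demographics
                ]
                if not observed:
                    continue
                ge, gt, pe, pt = _sum_counts(idx, observed, stage, period, num_field, uni_field)
                records.append(
                    RiskRatioRecord(
                        group=group, stage=stage, period=period, scope=scope,
                        group_exposed=ge, group_total=gt,
                        pop_exposed=pe, pop_total=pt,
                        rr=risk_ratio(ge, gt, pe, pt),
                    )
                )
    return records


def quintile_assign(values: Mapping[str, float]) -> dict[str, int]:
    """Equal-frequency quintiles (1 = least exposed) of positive intensities.

    Ties all receive the quintile of the smallest rank in the tie group, so
    the assignment is deterministic and independent of input order.
    """
    for geoid, v in values.items():
        if v <= 0:
            raise ValueError(
                f"quintiles are defined on exposed block groups only; "
                f"{geoid} has non-positive intensity {v}"
            )
    n = len(values)
    if n == 0:
        return {}
    ordered = sorted(values, key=lambda g: (values[g], g))
    # rank of the first occurrence of each distinct value
    first_rank: dict[float, int] = {}
    for rank, geoid in enumerate(ordered):
        first_rank.setdefault(values[geoid], rank)
    return {
        geoid: first_rank[values[geoid]] * 5 // n + 1 for geoid in ordered
    }


def rr_by_quintile(
    exposures: Sequence[ExposureEstimate],
    bgs: Sequence[BlockGroupPeriod],
    period: str,
    stage: str = "active",
    groups: Sequence[str] = DEFAULT_GROUPS,
) -> list[RiskRatioRecord]:
    """Risk ratios stratified by quintile of centroid production intensity.

    Block groups with positive active-stage centroid BOE are ranked into
    equal-frequency quintiles.  Numerators (group exposed, population
    exposed) are summed within each quintile; denominators are the statewide
    totals, so the total-population group has RR exactly 1 in every occupied
    quintile.  Empty quintiles yield records with undefined RR rather than
    being dropped.
    """
    idx = _index_exposures(exposures)
    period_bgs = [bg for bg in bgs if bg.period == period]
    intensity = {}
    for bg in period_bgs:
        est = idx.get((bg.geoid, period, stage))
        if est is not None and est.centroid_boe > 0:
            intensity[bg.geoid] = est.centroid_boe
    quintiles = quintile_assign(intensity)

    records: list[RiskRatioRecord] = []
    for q in range(1, 6):
        q_bgs = [bg for bg in period_bgs if quintiles.get(bg.geoid) == q]
        for group in groups:
            num_field, uni_field = GROUP_DEFS[group]
            observed = [bg for bg in period_bgs if num_field in bg.demographics]
            if not observed:
                continue
            gt = sum(bg.demographics[num_field] for bg in observed)
            pt = sum(bg.demographics[uni_field] for bg in observed)
            ge = pe = 0.0
            for bg in q_bgs:
                if num_field not in bg.demographics:
                    continue
                est = idx.get((bg.geoid, period, stage))
                if est is not None:
                    ge += est.exposed_counts[num_field]
                    pe += est.exposed_counts[uni_field]
            records.append(
                RiskRatioRecord(
                    group=group, stage=stage, period=period,
                    scope=f"quintile:{q}",
                    group_exposed=ge, group_total=gt,
                    pop_exposed=pe, pop_total=pt,
                    rr=risk_ratio(ge, gt, pe, pt),
                )
            )
    return records


def panel_change(
    values_earlier: Mapping[str, float],
    values_later: Mapping[str, float],
    bgs_later: Sequence[BlockGroupPeriod],
    metric: str,
) -> list[PanelChangeRecord]:
    """Categorize block groups by the sign of change in an exposure metric.

    ``values_earlier``/``values_later`` map geoid to the per-block-group
    metric (new-well count or cumulative BOE) in each period; the geoid sets
    must match (same decennial boundaries).  Demographic sums within each
    category use the later period's counts.  "No change" means exact
    equality for well counts and |delta| < 1e-6 for production volumes.
    """
    if set(values_earlier) != set(values_later):
        only_a = set(values_earlier) - set(values_later)
        only_b = set(values_later) - set(values_earlier)
        raise ValueError(
            f"panel geoid sets differ (earlier-only {sorted(only_a)[:5]}, "
            f"later-only {sorted(only_b)[:5]})"
        )
    eps = BOE_CHANGE_EPS if metric == "cumulative_boe" else 0.0
    category_of: dict[str, str] = {}
    for geoid in values_earlier:
        delta = values_later[geoid] - values_earlier[geoid]
        if abs(delta) <= eps:
            category_of[geoid] = "no_change"
        elif delta > 0:
            category_of[geoid] = "increase"
        else:
            category_of[geoid] = "decrease"

    bg_by_geoid = {bg.geoid: bg for bg in bgs_later}
    records = []
    for category in ("increase", "decrease", "no_change"):
        sums: dict[str, float] = {}
        for geoid, cat in category_of.items():
            if cat != category:
                continue
            bg = bg_by_geoid.get(geoid)
            if bg is None:
                raise ValueError(f"panel geoid {geoid} missing from block groups")
            for g, v in bg.demographics.items():
                sums[g] = sums.get(g, 0.0) + v
        records.append(PanelChangeRecord(metric=metric, category=category,
                                         demographic_sums=sums))
    return records


def tribal_overlay(
    wells: Sequence[WellRecord],
    tribal_polygons: Mapping[str, BaseGeometry],
) -> dict[str, int]:
    """Boundary-inclusive count of wells inside each tribal-land polygon."""
    counts = {name: 0 for name in tribal_polygons}
    for w in wells:
        pt = Point(w.x, w.y)
        for name, poly in tribal_polygons.items():
            if poly.covers(pt):
                counts[name] += 1
    return counts


# --- report arithmetic -------------------------------------------------------

def percent_share(numerator: float, denominator: float, ndigits: int = 1) -> Optional[float]:
    """100 * numerator / denominator, rounded; None on a zero denominator."""
    if denominator == 0:
        return None
    return round(100.0 * numerator / denominator, ndigits)


def percent_change(old: float, new: float, ndigits: int = 1) -> Optional[float]:
    """Percent change from ``old`` to ``new``; None (undefined) on zero baseline."""
    if old == 0:
        return None
    return round(100.0 * (new - old) / old, ndigits)


def summarize_trends(
    exposures: Sequence[ExposureEstimate],
    bgs: Sequence[BlockGroupPeriod],
    stages: Sequence[str] = ("new", "active", "retired"),
) -> list[dict]:
    """Per-stage exposed totals, shares, period-over-period changes, averages.

    Returns flat report rows: for every stage and period the exposed
    population and its percent share (1 d.p.); for consecutive period pairs
    the percent change in exposed population; and for each stage the
    multi-period mean of exposed counts and of percent shares.
    """
    idx = _index_exposures(exposures)
    periods = sorted({bg.period for bg in bgs})
    pop_by_period = {
        p: sum(bg.demographics["total_population"] for bg in bgs if bg.period == p)
        for p in periods
    }
    rows: list[dict] = []
    for p_old, p_new in zip(periods, periods[1:]):
        rows.append({
            "kind": "population_change", "stage": "", "period": f"{p_old}->{p_new}",
            "value": percent_change(pop_by_period[p_old], pop_by_period[p_new]),
        })
    for stage in stages:
        exposed_by_period = {}
        for p in periods:
            total = sum(
                idx[(bg.geoid, p, stage)].exposed_counts["total_population"]
                for bg in bgs
                if bg.period == p and (bg.geoid, p, stage) in idx
            )
            exposed_by_period[p] = total
            rows.append({
                "kind": "exposed", "stage": stage, "period": p, "value": total,
            })
            rows.append({
                "kind": "exposed_share", "stage": stage, "period": p,
                "value": percent_share(total, pop_by_period[p]),
            })
        for p_old, p_new in zip(periods, periods[1:]):
            rows.append({
                "kind": "exposed_change", "stage": stage,
                "period": f"{p_old}->{p_new}",
                "value": percent_change(exposed_by_period[p_old], exposed_by_period[p_new]),
            })
        rows.append({
            "kind": "exposed_mean", "stage": stage, "period": "all",
            "value": sum(exposed_by_period.values()) / len(periods),
        })
        shares = [
            100.0 * exposed_by_period[p] / pop_by_period[p]
            for p in periods if pop_by_period[p] > 0
        ]
        rows.append({
            "kind": "exposed_share_mean", "stage": stage, "period": "all",
            "value": round(sum(shares) / len(shares), 1) if shares else None,
        })
    return rows
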