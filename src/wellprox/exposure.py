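"""Block-group exposure assessment: areal apportionment and centroid intensity.

Two complementary protocols, both on 1 km (default) well buffers in a
projected equal-area CRS:

* **Areal apportionment** answers *who is exposed*: the fraction of a block
  group's area covered by the union of buffers around wells in a given
  stage, multiplied into every demographic count under the uniform-density
  assumption (30% of the area overlapping means 30% of residents exposed).
* **Centroid intensity** answers *how much*: the number of staged wells --
  and, for active wells, their cumulative production volume -- within the
  buffer radius of the block group's geometric centroid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union
import shapely

from .wells import StageAssignment, StudyPeriod, WellRecord, cumulative_boe

logger = logging.getLogger(__name__)

DEFAULT_RADIUS_M = 1000.0
#: quad_segs=16 gives 64-segment circle approximations (reproducible area).
BUFFER_QUAD_SEGS = 16

#: Race/ethnicity groups partitioning total_population.
RACE_GROUPS = (
    "hispanic_latinx",
    "nh_aian",
    "nh_asian",
    "nh_black",
    "nh_white",
    "nh_other",
    "nh_two_or_more",
)

#: Socioeconomic indicators: numerator field -> its universe (denominator).
SOCIO_PAIRS = {
    "poverty_num": "poverty_universe",
    "lt12_edu_num": "edu_universe",
    "renter_households": "total_households",
    "ling_isolated_adults": "total_adults",
    "nonvoters": "eligible_voters",
}

DEMOGRAPHIC_FIELDS = (
    ("total_population",)
    + RACE_GROUPS
    + tuple(SOCIO_PAIRS)
    + tuple(SOCIO_PAIRS.values())
)


def ngon_area(radius: float, quad_segs: int = BUFFER_QUAD_SEGS) -> float:
    """Area of the regular polygon shapely uses to approximate a circle."""
    n = 4 * quad_segs
    return 0.5 * n * radius * radius * math.sin(2.0 * math.pi / n)


@dataclass
class BlockGroupPeriod:
    """One census block group observed in one study period.

    ``geometry`` is a valid (multi)polygon in projected metres;
    ``demographics`` maps group name to a non-negative count and must contain
    ``total_population`` plus the race/ethnicity partition; socioeconomic
    numerator/universe pairs are optional (voter fields are absent for
    periods predating available turnout data).
    """

    geoid: str
    period: str
    geometry: BaseGeometry
    demographics: dict[str, float]
    county: str = ""

    def __post_init__(self) -> None:
        if not self.geometry.is_valid:
            logger.warning("block group %s: invalid geometry repaired", self.geoid)
            self.geometry = self.geometry.buffer(0)
        if self.geometry.area <= 0:
            raise ValueError(f"block group {self.geoid}: zero-area geometry")
        for g, v in self.demographics.items():
            if v < 0:
                raise ValueError(f"block group {self.geoid}: negative count {g}={v}")

    @property
    def area(self) -> float:
        return self.geometry.area


@dataclass
class ExposureEstimate:
    """Exposure of one block-group-period to one well stage."""

    geoid: str
    period: str
    stage: str
    exposed_fraction: float
    exposed_counts: dict[str, float]
    centroid_well_count: int
    centroid_boe: float  # active stage only; 0 otherwise


def _staged_wells(
    wells: Sequence[WellRecord],
    assignments: Iterable[StageAssignment],
    stage: str,
    period: str,
) -> list[WellRecord]:
    """Wells whose assignment for ``period`` includes ``stage``.

    The pseudo-stage ``plugged`` selects on the cross-sectional flag.
    """
    by_id = {w.well_id: w for w in wells}
    out = []
    for a in assignments:
        if a.period != period:
            continue
        if stage == "plugged":
            if a.plugged_flag:
                out.append(by_id[a.well_id])
        elif stage in a.stages:
            out.append(by_id[a.well_id])
    return out


def stage_buffer(
    wells: Sequence[WellRecord],
    assignments: Iterable[StageAssignment],
    stage: str,
    period: str,
    radius_m: float = DEFAULT_RADIUS_M,
) -> BaseGeometry:
    """Union of radius-``radius_m`` discs around every staged well.

    Overlapping per-well buffers are dissolved into one region so that
    residents near several wells are never double counted.  Returns an empty
    geometry when no well qualifies.
    """
    if radius_m <= 0:
        raise ValueError(f"radius_m must be positive, got {radius_m}")
    staged = _staged_wells(wells, assignments, stage, period)
    if not staged:
        return Point(0, 0).buffer(0)  # empty polygon
    discs = [Point(w.x, w.y).buffer(radius_m, quad_segs=BUFFER_QUAD_SEGS) for w in staged]
    return unary_union(discs)


def areal_fraction(bg: BlockGroupPeriod, buffer_region: BaseGeometry) -> float:
    """Fraction of the block group's area covered by the buffer region."""
    if bg.area <= 0:
        raise ValueError(f"block group {bg.geoid}: zero-area geometry")
    if buffer_region.is_empty:
        return 0.0
    frac = bg.geometry.intersection(buffer_region).area / bg.area
    return min(1.0, max(0.0, frac))


def apportion(bg: BlockGroupPeriod, fraction: float) -> dict[str, float]:
    """Exposed count per demographic group, unrounded.

    Areal weights are continuous; counts stay real-valued so that race-group
    exposures sum exactly to the exposed total population.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    return {g: v * fraction for g, v in bg.demographics.items()}


def centroid_intensity(
    bg: BlockGroupPeriod,
    wells: Sequence[WellRecord],
    assignments: Iterable[StageAssignment],
    period: StudyPeriod,
    radius_m: float = DEFAULT_RADIUS_M,
    stages: Sequence[str] = ("new", "active", "retired"),
) -> tuple[dict[str, int], float]:
    """Well counts per stage within ``radius_m`` of the block group centroid.

    Returns ``(counts, active_boe)`` where ``active_boe`` is the cumulative
    period production of the counted active wells.  The distance predicate is
    boundary-inclusive.
    """
    c = bg.geometry.centroid
    if not bg.geometry.covers(c):
        logger.debug("block group %s: centroid falls outside polygon", bg.geoid)
    assignments = list(assignments)
    counts: dict[str, int] = {}
    active_boe = 0.0
    for stage in stages:
        staged = _staged_wells(wells, assignments, stage, period.label)
        near = [w for w in staged if math.hypot(w.x - c.x, w.y - c.y) <= radius_m]
        counts[stage] = len(near)
        if stage == "active":
            active_boe = sum(cumulative_boe(w, period) for w in near)
    return counts, active_boe


def assess_exposure(
    bgs: Sequence[BlockGroupPeriod],
    wells: Sequence[WellRecord],
    assignments: Sequence[StageAssignment],
    periods: Sequence[StudyPeriod],
    radius_m: float = DEFAULT_RADIUS_M,
) -> list[ExposureEstimate]:
    """Run both exposure protocols over every block-group-period and stage.

    Produces one estimate per geoid x period x stage for new/active/retired
    in every period, plus the plugged cross-section for the final period.
    Buffers are dissolved once per stage-period and reused across block
    groups.  Raises on duplicate (geoid, period).
    """
    keys = [(bg.geoid, bg.period) for bg in bgs]
    if len(set(keys)) != len(keys):
        dup = next(k for k in keys if keys.count(k) > 1)
        raise ValueError(f"duplicate block group key {dup}")

    period_by_label = {p.label: p for p in periods}
    final_label = max(periods, key=lambda p: p.end_year).label
    bgs_by_period: dict[str, list[BlockGroupPeriod]] = {}
    for bg in bgs:
        bgs_by_period.setdefault(bg.period, []).append(bg)

    out: list[ExposureEstimate] = []
    for label, period_bgs in bgs_by_period.items():
        period = period_by_label[label]
        stage_list = ["new", "active", "retired"]
        if label == final_label:
            stage_list.append("plugged")
        buffers = {
            s: stage_buffer(wells, assignments, s, label, radius_m) for s in stage_list
        }
        for bg in period_bgs:
            counts, active_boe = centroid_intensity(
                bg, wells, assignments, period, radius_m,
                stages=tuple(stage_list),
            )
            for s in stage_list:
                frac = areal_fraction(bg, buffers[s])
                out.append(
                    ExposureEstimate(
                        geoid=bg.geoid,
                        period=label,
                        stage=s,
                        exposed_fraction=frac,
                        exposed_counts=apportion(bg, frac),
                        centroid_well_count=counts[s],
                        centroid_boe=active_boe if s == "active" else 0.0,
                    )
                )
    return out
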