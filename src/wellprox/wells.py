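"""Well life-cycle classification.

Each well record carries the dates that delimit its development stages:
spudding opens preproduction, completion closes it, production is whatever
years report positive volume, and postproduction begins at the reported
abandonment date or -- for wells that simply stop reporting -- eight years
after the last production date, the statutory definition of a long-term
idle well.  A well is classified independently for every study period, and
a well may legitimately belong to several stages within one period (spudded
in the first year, producing in the second).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

STAGES = ("new", "active", "retired")

#: Well status markers accepted in input tables.
WELL_STATUSES = ("producing", "idle", "plugged", "unknown")


@dataclass(frozen=True)
class StudyPeriod:
    """An inclusive window of calendar years, e.g. 2005-2009."""

    label: str
    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.start_year > self.end_year:
            raise ValueError(
                f"period {self.label!r}: start_year {self.start_year} > "
                f"end_year {self.end_year}"
            )

    def contains_date(self, d: Optional[date]) -> bool:
        """True if ``d`` falls in any calendar year of the window."""
        return d is not None and self.start_year <= d.year <= self.end_year

    @property
    def start(self) -> date:
        return date(self.start_year, 1, 1)

    @property
    def end(self) -> date:
        return date(self.end_year, 12, 31)


#: The canonical ACS-aligned study periods.
CANONICAL_PERIODS: tuple[StudyPeriod, ...] = (
    StudyPeriod("2005-2009", 2005, 2009),
    StudyPeriod("2010-2014", 2010, 2014),
    StudyPeriod("2015-2019", 2015, 2019),
)

DEFAULT_REFERENCE_YEAR = 2019
IDLE_YEARS = 8


@dataclass
class WellRecord:
    """One well: location (projected metres), life-cycle dates, annual BOE.

    Any date may be absent (``None``).  ``annual_boe`` maps calendar year to
    the non-negative production volume in barrels of oil equivalent.
    """

    well_id: str
    x: float
    y: float
    status: str = "unknown"
    spud_date: Optional[date] = None
    completion_date: Optional[date] = None
    first_prod_date: Optional[date] = None
    last_prod_date: Optional[date] = None
    abandonment_date: Optional[date] = None
    well_type: str = ""
    annual_boe: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for year, boe in list(self.annual_boe.items()):
            if boe < 0:
                logger.warning(
                    "well %s: negative production %.1f BOE in %d clamped to 0",
                    self.well_id, boe, year,
                )
                self.annual_boe[year] = 0.0
        if (
            self.spud_date is not None
            and self.completion_date is not None
            and self.spud_date > self.completion_date
        ):
            logger.warning(
                "well %s: spud date %s after completion date %s",
                self.well_id, self.spud_date, self.completion_date,
            )


@dataclass(frozen=True)
class StageAssignment:
    """Stage membership of one well in one period.

    ``stages`` may hold several members (dual membership).  ``plugged_flag``
    is cross-sectional relative to the reference year and independent of the
    per-period stages.  ``retirement_source`` records whether a retired
    classification came from a reported abandonment date or from the
    eight-year idle rule.
    """

    well_id: str
    period: str
    stages: frozenset[str]
    plugged_flag: bool
    retirement_source: Optional[str] = None  # "abandonment" | "idle_rule"


def cumulative_boe(well: WellRecord, period: StudyPeriod) -> float:
    """Sum of annual production (BOE) over the period's calendar years."""
    return float(
        sum(
            boe
            for year, boe in well.annual_boe.items()
            if period.start_year <= year <= period.end_year
        )
    )


def is_new(well: WellRecord, period: StudyPeriod) -> bool:
    """True if the preproduction interval [spud, completion] touches the period.

    A missing completion date leaves the interval open-ended on the right.
    A missing spud date with a completion date collapses the interval to the
    completion date alone; with neither date the well is never new.
    """
    spud, comp = well.spud_date, well.completion_date
    if spud is None:
        if comp is None:
            return False
        logger.debug(
            "well %s: no spud date; preproduction collapsed to completion %s",
            well.well_id, comp,
        )
        return period.contains_date(comp)
    if spud > period.end:
        return False
    # open-ended on the right when completion is missing
    return comp is None or comp >= period.start


def is_active(well: WellRecord, period: StudyPeriod) -> bool:
    """True if the well produced >0 BOE cumulatively during the period."""
    return cumulative_boe(well, period) > 0


def _shift_years(d: date, years: int) -> date:
    """Calendar-exact shift; Feb 29 maps to Mar 1 in non-leap target years."""
    try:
        return d.replace(year=d.year + years)
    except ValueError:  # Feb 29 -> non-leap year
        return date(d.year + years, 3, 1)


def postproduction_start(well: WellRecord, idle_years: int = IDLE_YEARS) -> Optional[date]:
    """Date the well entered postproduction, or None if undeterminable.

    The reported abandonment date when present, otherwise the last production
    date shifted forward by ``idle_years`` (long-term idle rule).
    """
    if well.abandonment_date is not None:
        return well.abandonment_date
    if well.last_prod_date is not None:
        return _shift_years(well.last_prod_date, idle_years)
    return None


def retirement_source(well: WellRecord) -> Optional[str]:
    """How postproduction_start was determined, or None when it is absent."""
    if well.abandonment_date is not None:
        return "abandonment"
    if well.last_prod_date is not None:
        return "idle_rule"
    return None


def is_retired(well: WellRecord, period: StudyPeriod, idle_years: int = IDLE_YEARS) -> bool:
    """True if the well entered postproduction during the period."""
    return period.contains_date(postproduction_start(well, idle_years))


def is_plugged(well: WellRecord, reference_year: int = DEFAULT_REFERENCE_YEAR) -> bool:
    """Cross-sectional plugged status relative to the end of ``reference_year``.

    A well counts as plugged when its status marker says so and its
    abandonment date (if any) is not after the reference year; plugged wells
    with no dates at all are assumed plugged before the reference year.
    """
    if well.status != "plugged":
        return False
    ab = well.abandonment_date
    return ab is None or ab <= date(reference_year, 12, 31)


def assign_stages(
    wells: Iterable[WellRecord],
    periods: Sequence[StudyPeriod] = CANONICAL_PERIODS,
    reference_year: int = DEFAULT_REFERENCE_YEAR,
    idle_years: int = IDLE_YEARS,
) -> list[StageAssignment]:
    """Classify every well into its stages for every period.

    Returns one StageAssignment per well x period.  Raises ValueError on a
    duplicated well_id.
    """
    wells = list(wells)
    seen: set[str] = set()
    for w in wells:
        if w.well_id in seen:
            raise ValueError(f"duplicate well_id {w.well_id!r}")
        seen.add(w.well_id)

    out: list[StageAssignment] = []
    for w in wells:
        plugged = is_plugged(w, reference_year)
        source = retirement_source(w)
        for p in periods:
            stages = set()
            if is_new(w, p):
                stages.add("new")
            if is_active(w, p):
                stages.add("active")
            retired = is_retired(w, p, idle_years)
            if retired:
                stages.add("retired")
            out.append(
                StageAssignment(
                    well_id=w.well_id,
                    period=p.label,
                    stages=frozenset(stages),
                    plugged_flag=plugged,
                    retirement_source=source if retired else None,
                )
            )
    return out
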