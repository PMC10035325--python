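from datetime import date

import pytest
from shapely.geometry import box

from wellprox import BlockGroupPeriod, StudyPeriod, WellRecord

P1 = StudyPeriod("2005-2009", 2005, 2009)
P2 = StudyPeriod("2010-2014", 2010, 2014)
P3 = StudyPeriod("2015-2019", 2015, 2019)
PERIODS = (P1, P2, P3)


def make_well(well_id="w0", x=0.0, y=0.0, **kwargs) -> WellRecord:
    return WellRecord(well_id=well_id, x=x, y=y, **kwargs)


def make_bg(
    geoid="bg0",
    period="2005-2009",
    geometry=None,
    total=1000.0,
    shares=None,
    county="",
    extra=None,
) -> BlockGroupPeriod:
    """Square block group with a race partition scaled from ``shares``."""
    if geometry is None:
        geometry = box(0, 0, 1000, 1000)
    if shares is None:
        shares = {
            "hispanic_latinx": 0.5, "nh_white": 0.3, "nh_asian": 0.1,
            "nh_black": 0.05, "nh_aian": 0.02, "nh_other": 0.02,
            "nh_two_or_more": 0.01,
        }
    demo = {"total_population": total}
    demo.update({g: s * total for g, s in shares.items()})
    if extra:
        demo.update(extra)
    return BlockGroupPeriod(
        geoid=geoid, period=period, geometry=geometry, demographics=demo,
        county=county,
    )


@pytest.fixture
def periods():
    return PERIODS


def producing_well(well_id, x, y, years, boe=100.0, **kwargs):
    """Well active in the given years, spudded well before them."""
    first = min(years)
    return WellRecord(
        well_id=well_id, x=x, y=y, status="producing",
        spud_date=date(first - 2, 1, 15),
        completion_date=date(first - 1, 6, 1),
        first_prod_date=date(first, 1, 1),
        last_prod_date=date(max(years), 12, 15),
        annual_boe={y: boe for y in years},
        **kwargs,
    )
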