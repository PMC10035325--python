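"""Risk ratios, quintile stratification, panel change, and report arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Point, box

from wellprox import (
    CANONICAL_PERIODS,
    assess_exposure,
    panel_change,
    percent_change,
    percent_share,
    quintile_assign,
    risk_ratio,
    rr_by_quintile,
    rr_table,
    tribal_overlay,
)
from wellprox.disparity import GROUP_DEFS
from wellprox.exposure import RACE_GROUPS, ExposureEstimate
from conftest import make_bg, make_well, producing_well


class TestRiskRatio:
    def test_worked_example(self):
        rr = risk_ratio(100_941, 2_172_247, 1_169_930, 36_308_527)
        assert round(rr, 2) == 1.44

    def test_equal_proportions_give_one(self):
        assert risk_ratio(50, 1000, 500, 10_000) == 1.0

    def test_no_exposed_members_gives_zero(self):
        assert risk_ratio(0, 1000, 500, 10_000) == 0.0

    def test_zero_denominators_undefined_not_zero(self):
        assert risk_ratio(0, 0, 500, 10_000) is None
        assert risk_ratio(10, 100, 0, 10_000) is None

    @pytest.mark.parametrize(
        "args", [(-1, 10, 1, 10), (11, 10, 1, 10), (1, 10, 11, 10)]
    )
    def test_invalid_inputs_fatal(self, args):
        with pytest.raises(ValueError):
            risk_ratio(*args)

    def test_scale_invariance(self):
        base = risk_ratio(30, 400, 200, 5000)
        for c in (0.5, 3.0, 1e6):
            assert risk_ratio(30 * c, 400 * c, 200 * c, 5000 * c) == pytest.approx(base)


def _exposure(geoid, period, stage, fraction, bg, boe=0.0, n_wells=0):
    return ExposureEstimate(
        geoid=geoid, period=period, stage=stage, exposed_fraction=fraction,
        exposed_counts={g: v * fraction for g, v in bg.demographics.items()},
        centroid_well_count=n_wells, centroid_boe=boe,
    )


class TestRrTable:
    def test_single_blockgroup_forces_unity(self):
        bg = make_bg("a", period="2005-2009")
        ests = [_exposure("a", "2005-2009", "active", 0.4, bg)]
        for rec in rr_table(ests, [bg], stages=("active",)):
            assert rec.rr == pytest.approx(1.0)

    def test_two_blockgroup_hand_oracle(self):
        """Group A concentrated in the exposed block group."""
        shares_a = {"hispanic_latinx": 0.2, "nh_white": 0.2, "nh_asian": 0.0,
                    "nh_black": 0.6, "nh_aian": 0.0, "nh_other": 0.0,
                    "nh_two_or_more": 0.0}
        shares_b = {"hispanic_latinx": 0.4, "nh_white": 0.4, "nh_asian": 0.0,
                    "nh_black": 0.2, "nh_aian": 0.0, "nh_other": 0.0,
                    "nh_two_or_more": 0.0}
        bg_a = make_bg("a", total=1000.0, shares=shares_a)
        bg_b = make_bg("b", total=1000.0, shares=shares_b)
        ests = [
            _exposure("a", "2005-2009", "active", 1.0, bg_a),
            _exposure("b", "2005-2009", "active", 0.0, bg_b),
        ]
        recs = {r.group: r for r in
                rr_table(ests, [bg_a, bg_b], stages=("active",))}
        # hand: exposed A = 600 of 800 statewide; exposed pop = 1000 of 2000
        assert recs["nh_black"].rr == pytest.approx((600 / 800) / (1000 / 2000))
        assert recs["hispanic_latinx"].rr == pytest.approx((200 / 600) / 0.5)
        assert recs["total_population"].rr == pytest.approx(1.0)

    def test_county_scope_restricts_both_sums(self):
        bg_a = make_bg("a", county="kern")
        bg_b = make_bg("b", county="la",
                       shares={"hispanic_latinx": 1.0, "nh_white": 0.0,
                               "nh_asian": 0.0, "nh_black": 0.0, "nh_aian": 0.0,
                               "nh_other": 0.0, "nh_two_or_more": 0.0})
        ests = [
            _exposure("a", "2005-2009", "active", 0.5, bg_a),
            _exposure("b", "2005-2009", "active", 0.0, bg_b),
        ]
        recs = {r.group: r for r in
                rr_table(ests, [bg_a, bg_b], scope="county:kern", stages=("active",))}
        # single in-scope block group: every defined RR is 1
        assert recs["nh_black"].rr == pytest.approx(1.0)
        assert recs["nh_black"].pop_total == 1000.0

    def test_unknown_scope_fatal(self):
        with pytest.raises(ValueError, match="unknown scope"):
            rr_table([], [make_bg()], scope="galaxy")

    def test_mixture_identity(self):
        """Population-share-weighted group RRs average to exactly 1."""
        rng = np.random.default_rng(4)
        bgs, ests = [], []
        for i in range(12):
            raw = rng.uniform(0.01, 1, size=7)
            shares = dict(zip(RACE_GROUPS, raw / raw.sum()))
            bg = make_bg(f"bg{i}", total=float(rng.integers(600, 3000)), shares=shares)
            bgs.append(bg)
            ests.append(_exposure(f"bg{i}", "2005-2009", "active",
                                  float(rng.uniform()), bg))
        recs = {r.group: r for r in rr_table(ests, bgs, stages=("active",))}
        pop_total = recs["total_population"].pop_total
        mix = sum(
            (recs[g].group_total / pop_total) * recs[g].rr for g in RACE_GROUPS
        )
        assert mix == pytest.approx(1.0, abs=1e-9)


class TestQuintileAssign:
    def test_distinct_values_equal_frequency(self):
        values = {f"g{i}": float(i) for i in range(1, 11)}
        q = quintile_assign(values)
        assert [q[f"g{i}"] for i in range(1, 11)] == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    def test_total_tie_lowest_rank(self):
        q = quintile_assign({f"g{i}": 7.0 for i in range(9)})
        assert set(q.values()) == {1}

    def test_empty_input(self):
        assert quintile_assign({}) == {}

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            quintile_assign({"a": 0.0})

    def test_matches_sort_then_slice_oracle(self):
        rng = np.random.default_rng(17)
        values = {f"g{i}": float(v) for i, v in
                  enumerate(rng.lognormal(8, 2, size=100))}
        q = quintile_assign(values)
        # independent oracle: sort, slice into fifths, ties take the
        # quintile of their smallest rank
        ordered = sorted(values, key=lambda g: (values[g], g))
        n = len(ordered)
        expected = {}
        for rank, g in enumerate(ordered):
            first = min(r for r, h in enumerate(ordered) if values[h] == values[g])
            expected[g] = first * 5 // n + 1
        assert q == expected

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.1, max_value=1e6), min_size=1, max_size=60))
    def test_sizes_balanced_up_to_ties(self, vals):
        values = {f"g{i}": v for i, v in enumerate(vals)}
        q = quintile_assign(values)
        assert set(q.values()) <= {1, 2, 3, 4, 5}
        # without ties, quintile sizes differ by at most 1
        if len(set(vals)) == len(vals):
            from collections import Counter

            sizes = Counter(q.values()).values()
            assert max(sizes) - min(sizes) <= 1


class TestRrByQuintile:
    def _landscape(self, boes, shares_by_bg=None):
        bgs, ests = [], []
        for i, boe in enumerate(boes):
            shares = None if shares_by_bg is None else shares_by_bg[i]
            bg = make_bg(f"bg{i}", total=1000.0, shares=shares)
            bgs.append(bg)
            frac = 1.0 if boe > 0 else 0.0
            ests.append(_exposure(f"bg{i}", "2005-2009", "active", frac, bg,
                                  boe=boe))
        return bgs, ests

    def test_total_population_rr_is_one_in_every_occupied_quintile(self):
        bgs, ests = self._landscape([10, 100, 1000, 5000, 9000, 0, 0])
        recs = rr_by_quintile(ests, bgs, "2005-2009")
        for r in recs:
            if r.group == "total_population" and r.pop_exposed > 0:
                assert r.rr == pytest.approx(1.0)

    def test_planted_enrichment_monotone(self):
        """Group share rising with intensity gives nondecreasing quintile RRs."""
        boes = [float(b) for b in (10, 20, 300, 400, 5000, 6000, 70000, 80000,
                                   900000, 1000000)]
        shares_by_bg = []
        for i in range(10):
            s_black = 0.05 + 0.04 * i
            rest = 1.0 - s_black
            shares_by_bg.append({
                "nh_black": s_black, "hispanic_latinx": rest * 0.5,
                "nh_white": rest * 0.5, "nh_asian": 0.0, "nh_aian": 0.0,
                "nh_other": 0.0, "nh_two_or_more": 0.0,
            })
        bgs, ests = self._landscape(boes, shares_by_bg)
        rrs = [r.rr for r in rr_by_quintile(ests, bgs, "2005-2009")
               if r.group == "nh_black"]
        assert all(a <= b + 1e-12 for a, b in zip(rrs, rrs[1:]))

    def test_empty_quintile_emitted_as_undefined(self):
        # two exposed block groups leave quintiles 2-5 sparsely occupied
        bgs, ests = self._landscape([10, 20])
        recs = rr_by_quintile(ests, bgs, "2005-2009")
        scopes = {r.scope for r in recs}
        assert scopes == {f"quintile:{q}" for q in range(1, 6)}
        empty = [r for r in recs if r.group == "total_population" and r.pop_exposed == 0]
        assert empty and all(r.rr is None for r in empty)


class TestPanelChange:
    def test_sign_categories(self):
        bgs = [make_bg(g, period="2015-2019") for g in ("a", "b", "c")]
        recs = panel_change(
            {"a": 3, "b": 5, "c": 5}, {"a": 5, "b": 5, "c": 2}, bgs,
            "new_well_count",
        )
        by_cat = {r.category: r for r in recs}
        assert by_cat["increase"].demographic_sums["total_population"] == 1000.0
        assert by_cat["no_change"].demographic_sums["total_population"] == 1000.0
        assert by_cat["decrease"].demographic_sums["total_population"] == 1000.0

    def test_all_unchanged_single_category(self):
        bgs = [make_bg(g, period="2015-2019") for g in ("a", "b")]
        recs = panel_change({"a": 1, "b": 2}, {"a": 1, "b": 2}, bgs,
                            "new_well_count")
        by_cat = {r.category: r for r in recs}
        assert by_cat["no_change"].demographic_sums["total_population"] == 2000.0
        assert by_cat["increase"].demographic_sums == {}

    def test_boe_noise_tolerance(self):
        bgs = [make_bg("a", period="2015-2019")]
        recs = panel_change({"a": 100.0}, {"a": 100.0 + 1e-9}, bgs,
                            "cumulative_boe")
        assert {r.category for r in recs if r.demographic_sums} == {"no_change"}

    def test_geoid_mismatch_fatal(self):
        bgs = [make_bg("a", period="2015-2019")]
        with pytest.raises(ValueError, match="geoid sets differ"):
            panel_change({"a": 1}, {"b": 1}, bgs, "new_well_count")

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(8)
        geoids = [f"g{i}" for i in range(40)]
        v2 = {g: int(rng.integers(0, 6)) for g in geoids}
        v3 = {g: int(rng.integers(0, 6)) for g in geoids}
        bgs = [make_bg(g, period="2015-2019",
                       total=float(rng.integers(600, 3000))) for g in geoids]
        recs = {r.category: r for r in panel_change(v2, v3, bgs, "new_well_count")}
        oracle = {"increase": 0.0, "decrease": 0.0, "no_change": 0.0}
        pop = {bg.geoid: bg.demographics["total_population"] for bg in bgs}
        for g in geoids:
            d = v3[g] - v2[g]
            cat = "no_change" if d == 0 else ("increase" if d > 0 else "decrease")
            oracle[cat] += pop[g]
        for cat, total in oracle.items():
            assert recs[cat].demographic_sums.get("total_population", 0.0) == total
        # categories partition the pooled population
        assert sum(oracle.values()) == sum(pop.values())


class TestTribalOverlay:
    def test_inside_and_outside(self):
        polys = {"t1": box(0, 0, 100, 100), "t2": box(500, 500, 600, 600)}
        wells = [make_well("a", 50, 50), make_well("b", 1000, 1000)]
        assert tribal_overlay(wells, polys) == {"t1": 1, "t2": 0}

    def test_boundary_inclusive(self):
        polys = {"t": box(0, 0, 100, 100)}
        assert tribal_overlay([make_well("a", 0, 50)], polys) == {"t": 1}

    def test_matches_containment_scan(self):
        rng = np.random.default_rng(15)
        polys = {
            f"t{i}": box(x, y, x + 300, y + 300)
            for i, (x, y) in enumerate(rng.uniform(0, 2000, size=(5, 2)))
        }
        wells = [make_well(f"w{i}", float(x), float(y))
                 for i, (x, y) in enumerate(rng.uniform(0, 2500, size=(100, 2)))]
        counts = tribal_overlay(wells, polys)
        for name, poly in polys.items():
            brute = sum(1 for w in wells if poly.covers(Point(w.x, w.y)))
            assert counts[name] == brute


class TestReportArithmetic:
    def test_share_and_change_rounding(self):
        assert percent_share(13_102_161, 36_308_527) == 36.1
        assert percent_change(36_308_527, 39_283_497) == 8.2
        assert percent_change(5, 5) == 0.0

    def test_zero_baseline_undefined(self):
        assert percent_change(0, 10) is None
        assert percent_share(1, 0) is None
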