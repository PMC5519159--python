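"""Wasted-dispersal classification, survival limits and field summaries."""

import numpy as np
import pytest

from seedwaste import (
    DungPile,
    VegetationPlot,
    classify_wasted,
    estimate_survival_limit,
    scenario_sweep,
    seed_stats,
    summarize_distribution,
    value_at,
    wasted_report,
)
from seedwaste.dispersal import round_half_up

from conftest import flat_surface, surface_from_values
from oracles import brute_force_wasted_flags


def make_pile(x, y, guava=0, passion=0, site="LR", elevation=100.0):
    return DungPile(site=site, x=x, y=y, elevation=elevation,
                    seed_counts={"guava": guava, "passionfruit": passion})


def make_plot(x, y, guava=0, passion=0, site="LR", elevation=200.0):
    return VegetationPlot(site=site, x=x, y=y, elevation=elevation,
                          presence={"guava": guava, "passionfruit": passion})


def piles_on_surface(values, counts, species="guava"):
    """One pile per grid cell of a row-vector surface, with given seed counts."""
    surf = surface_from_values(np.asarray(values, dtype=float).reshape(1, -1))
    piles = [make_pile(float(i), 0.0, **{("guava" if species == "guava" else "passion"): c})
             for i, c in enumerate(counts)]
    return surf, piles


class TestValueAt:
    def test_cell_centre_lookup_on_hand_grid(self):
        vals = np.arange(9.0).reshape(3, 3) / 10.0
        surf = surface_from_values(vals)  # origin (0, 2), cell 1
        xs = np.array([0.0, 2.0, 1.0, 0.4, 1.6])
        ys = np.array([2.0, 0.0, 1.0, 1.9, 0.2])
        out = value_at(surf, xs, ys)
        # manual nearest-cell: (0,0)=.0, (2,2)=.8, (1,1)=.4, (0,0)=.0, (2,2)=.8
        np.testing.assert_array_equal(out, [0.0, 0.8, 0.4, 0.0, 0.8])

    def test_constant_surface_returns_constant(self):
        surf = flat_surface(0.42, n=5)
        out = value_at(surf, np.array([0.0, 2.0]), np.array([1.0, 3.0]))
        np.testing.assert_array_equal(out, [0.42, 0.42])

    def test_point_outside_extent_raises_with_offenders(self):
        surf = flat_surface(0.5, n=3)
        with pytest.raises(ValueError, match="outside"):
            value_at(surf, np.array([99.0]), np.array([0.0]))

    def test_masked_cell_flagged_as_missing(self):
        vals = np.array([[0.3, 0.7]])
        mask = np.array([[True, False]])
        from seedwaste import SuitabilitySurface
        surf = SuitabilitySurface(values=vals, mask=mask, cell_size=1.0, origin=(0.0, 0.0))
        out = value_at(surf, np.array([0.0, 1.0]), np.array([0.0, 0.0]))
        assert np.isnan(out[0]) and out[1] == 0.7


class TestSurvivalLimit:
    @pytest.mark.parametrize(
        "suits, expected",
        [((0.524, 0.668, 0.716), 0.524), ((0.487, 0.629, 0.691), 0.487), ((0.61,), 0.61)],
    )
    def test_limit_is_minimum_over_occupied_plots(self, suits, expected):
        surf, _ = piles_on_surface(list(suits), [0] * len(suits))
        plots = [make_plot(float(i), 0.0, guava=1) for i in range(len(suits))]
        limit = estimate_survival_limit(plots, surf, "guava")
        assert limit.limit == pytest.approx(expected)
        assert limit.provenance == "min-occupied-plot"

    def test_unoccupied_species_has_undefined_limit(self):
        surf, _ = piles_on_surface([0.5], [0])
        plots = [make_plot(0.0, 0.0, guava=0)]
        with pytest.raises(ValueError, match="survival limit undefined"):
            estimate_survival_limit(plots, surf, "guava")


class TestClassifyWasted:
    def test_seed_bearing_pile_below_limit_is_wasted(self):
        surf, piles = piles_on_surface([0.267], [100])
        flags = classify_wasted(piles, surf, 0.524, "guava")
        assert flags.tolist() == [True]

    def test_pile_exactly_at_limit_is_not_wasted(self):
        surf, piles = piles_on_surface([0.524], [100])
        flags = classify_wasted(piles, surf, 0.524, "guava")
        assert flags.tolist() == [False]

    def test_empty_pile_below_limit_is_not_wasted(self):
        surf, piles = piles_on_surface([0.1], [0])
        flags = classify_wasted(piles, surf, 0.524, "guava")
        assert flags.tolist() == [False]

    def test_agrees_with_brute_force_loop_on_random_piles(self):
        rng = np.random.default_rng(30)
        vals = rng.uniform(0, 1, 50)
        counts = rng.integers(0, 3, 50) * rng.integers(0, 500, 50)
        surf, piles = piles_on_surface(vals, counts)
        for limit in (0.2, 0.5, 0.8):
            fast = classify_wasted(piles, surf, limit, "guava")
            slow = brute_force_wasted_flags(piles, surf, limit, "guava")
            np.testing.assert_array_equal(fast, slow)

    def test_raising_limit_never_unflags_a_pile(self):
        rng = np.random.default_rng(31)
        vals = rng.uniform(0, 1, 200)
        counts = rng.integers(0, 2, 200) * 100
        surf, piles = piles_on_surface(vals, counts)
        flags_lo = classify_wasted(piles, surf, 0.3, "guava")
        flags_hi = classify_wasted(piles, surf, 0.7, "guava")
        assert np.all(flags_hi[flags_lo])  # lo-wasted stays wasted at hi

    def test_cellwise_suitability_increase_never_flags_new_piles(self):
        rng = np.random.default_rng(32)
        vals = rng.uniform(0, 0.8, 100)
        counts = rng.integers(0, 2, 100) * 50
        surf, piles = piles_on_surface(vals, counts)
        better = surf.with_values(np.clip(surf.values + 0.15, 0, 1))
        before = classify_wasted(piles, surf, 0.5, "guava")
        after = classify_wasted(piles, better, 0.5, "guava")
        assert np.all(before[after])  # wasted-after implies wasted-before


class TestWastedReport:
    def test_species_pile_percentage_reproduces_field_tally(self):
        # 96 guava-bearing piles of 222, 37 below the limit -> 38.5%
        surf, piles = piles_on_surface(
            [0.1] * 37 + [0.9] * 59 + [0.9] * 126,
            [10] * 96 + [0] * 126,
        )
        flags = classify_wasted(piles, surf, 0.524, "guava")
        report = wasted_report(piles, flags, "guava")
        assert report.n_piles_below == 37
        assert round_half_up(report.pct_of_species_piles, 1) == 38.5

    def test_all_pile_percentage_uses_full_denominator(self):
        # 29 of 222 piles -> 13.06... -> 13.1%
        surf, piles = piles_on_surface(
            [0.1] * 29 + [0.9] * 193,
            [5] * 79 + [0] * 143,
        )
        flags = classify_wasted(piles, surf, 0.487, "guava")
        report = wasted_report(piles, flags, "guava")
        assert report.n_piles_below == 29
        assert report.pct_of_all_piles == pytest.approx(100 * 29 / 222)
        assert round_half_up(report.pct_of_all_piles, 1) == 13.1

    def test_no_flags_give_zero_percentages(self):
        surf, piles = piles_on_surface([0.9, 0.8], [10, 0])
        flags = classify_wasted(piles, surf, 0.5, "guava")
        report = wasted_report(piles, flags, "guava")
        assert report.pct_of_species_piles == 0.0
        assert report.pct_seeds_wasted == 0.0

    def test_seed_weighting_matches_pile_weighting_for_equal_loads(self):
        rng = np.random.default_rng(33)
        vals = rng.uniform(0, 1, 80)
        counts = rng.integers(0, 2, 80) * 100  # equal loads among positives
        surf, piles = piles_on_surface(vals, counts)
        flags = classify_wasted(piles, surf, 0.5, "guava")
        report = wasted_report(piles, flags, "guava")
        assert report.pct_seeds_wasted == pytest.approx(report.pct_of_species_piles)


class TestScenarioSweep:
    def test_current_scenario_report_matches_direct_call(self):
        surf, piles = piles_on_surface([0.2, 0.6, 0.9], [10, 20, 0])
        sweep = scenario_sweep(piles, {"current": surf}, 0.5, "guava")
        direct = wasted_report(piles, classify_wasted(piles, surf, 0.5, "guava"), "guava")
        assert sweep[0].as_dict() == {**direct.as_dict(), "scenario_id": "current"}

    def test_uniform_improvement_reduces_wasted_seeds(self):
        rng = np.random.default_rng(34)
        vals = rng.uniform(0.2, 0.6, 60)
        counts = rng.integers(1, 100, 60)
        surf, piles = piles_on_surface(vals, counts)
        wetter = surf.with_values(np.clip(surf.values + 0.2, 0, 1), scenario_id="wet")
        reports = scenario_sweep(piles, {"current": surf, "wet": wetter}, 0.5, "guava")
        by_id = {r.scenario_id: r for r in reports}
        assert by_id["wet"].pct_seeds_wasted < by_id["current"].pct_seeds_wasted

    def test_surface_entirely_below_limit_wastes_every_species_pile(self):
        surf, piles = piles_on_surface([0.1, 0.2, 0.3], [5, 0, 9])
        reports = scenario_sweep(piles, {"bad": surf}, 0.5, "guava")
        assert reports[0].pct_of_species_piles == 100.0


class TestSummaries:
    def test_hand_built_units_match_manual_arithmetic(self):
        surf, _ = piles_on_surface([0.2, 0.4, 0.6, 0.8], [0] * 4)
        piles = [
            make_pile(0.0, 0.0, guava=5, elevation=50.0),
            make_pile(1.0, 0.0, guava=0, elevation=150.0),
            make_pile(2.0, 0.0, guava=7, elevation=250.0),
            make_pile(3.0, 0.0, guava=2, elevation=350.0),
        ]
        s = summarize_distribution(piles, surf, "guava", "pile")
        assert s.n_present == 3 and s.presence_pct == 75.0
        assert (s.elevation_min, s.elevation_max) == (50.0, 350.0)
        assert s.elevation_mean == pytest.approx((50 + 250 + 350) / 3)
        assert s.suitability_min == pytest.approx(0.2)
        assert s.suitability_mean == pytest.approx((0.2 + 0.6 + 0.8) / 3)

    def test_single_unit_collapses_ranges(self):
        surf, _ = piles_on_surface([0.6], [0])
        piles = [make_pile(0.0, 0.0, guava=3, elevation=120.0)]
        s = summarize_distribution(piles, surf, "guava", "pile")
        assert s.elevation_min == s.elevation_mean == s.elevation_max == 120.0

    def test_absent_species_marked_empty(self):
        surf, _ = piles_on_surface([0.6], [0])
        piles = [make_pile(0.0, 0.0, guava=0)]
        s = summarize_distribution(piles, surf, "passionfruit", "pile")
        assert s.empty and s.presence_pct == 0.0
        assert np.isnan(s.elevation_min)


class TestSeedStats:
    def test_field_totals_reproduce_published_means(self):
        # 138,529 guava seeds over 96 positive piles of 222 total
        counts = [1443] * 95 + [1444] + [0] * 126
        piles = [make_pile(float(i % 10), float(i // 10), guava=c) for i, c in enumerate(counts)]
        s = seed_stats(piles, "guava")
        assert s.total_seeds == 138529
        assert s.n_positive_piles == 96
        assert round(s.mean_per_positive_pile, 2) == 1443.01
        assert round(s.mean_per_pile) == 624

    def test_equal_counts_have_zero_sd(self):
        piles = [make_pile(float(i), 0.0, guava=7) for i in range(5)]
        s = seed_stats(piles, "guava")
        assert s.sd_per_positive_pile == 0.0

    def test_mean_identities_hold(self):
        rng = np.random.default_rng(35)
        counts = rng.integers(0, 50, 40)
        piles = [make_pile(float(i), 0.0, guava=int(c)) for i, c in enumerate(counts)]
        s = seed_stats(piles, "guava")
        assert s.mean_per_pile == pytest.approx(s.total_seeds / s.n_piles)
        if s.n_positive_piles:
            assert s.mean_per_positive_pile == pytest.approx(s.total_seeds / s.n_positive_piles)
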