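"""Closed-form gain predictions against independent numerical oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from massgain.analytic import (
    gain_index,
    gain_marker_only_exact,
    gain_marker_only_normal,
    gain_phenotype_only,
    gain_two_stage,
    optimal_two_stage,
    selection_intensity,
    truncate_marker_distribution,
)
from massgain.genetic_model import (
    build_nine_genotype_table,
    build_three_genotype_table,
    marker_table_for,
    partition_variance,
    scenario_grid,
)
from massgain.simulator import simulate_population
from massgain.strategies import select_marker_only

TSP_GRID = [i / 20 for i in range(1, 20)]


def truncated_mean_oracle(p):
    """Mean of the retained upper tail by numerical integration."""
    threshold = stats.norm.isf(p)
    value, _ = integrate.quad(lambda x: x * stats.norm.pdf(x), threshold, 12.0)
    return value / p


def truncate_by_enumeration(table, sp_m, copies=1600):
    """Brute-force truncation on an explicit finite population."""
    counts = (np.array(table.frequencies) * copies).round().astype(int)
    values = np.repeat(table.means, counts)
    kept = np.sort(values)[::-1][: round(sp_m * copies)]
    return kept.mean(), kept.var()


class TestSelectionIntensity:
    def test_no_truncation_no_intensity(self):
        assert selection_intensity(1.0) == 0.0

    @pytest.mark.parametrize("p", [0.05, 0.25, 0.5, 0.75, 0.95])
    def test_matches_numerical_integration(self, p):
        assert selection_intensity(p) == pytest.approx(
            truncated_mean_oracle(p), rel=1e-8
        )

    def test_decreasing_in_p(self):
        values = [selection_intensity(p) for p in TSP_GRID]
        assert all(a > b for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
    def test_domain_checked(self, p):
        with pytest.raises(ValueError):
            selection_intensity(p)


class TestPhenotypeOnlyGain:
    def test_known_values(self):
        assert gain_phenotype_only(0.5, 200, 1.0) == 0.0
        assert gain_phenotype_only(0.5, 200, 0.5) == pytest.approx(
            0.5 * truncated_mean_oracle(0.5) * math.sqrt(200), rel=1e-8
        )
        assert gain_phenotype_only(1.0, 200, 0.05) == pytest.approx(29.17, abs=0.01)


class TestMarkerTruncation:
    def test_three_genotype_enumeration(self):
        t = build_three_genotype_table(4.0, "none")
        assert gain_marker_only_exact(t, 0.25) == pytest.approx(4.0)
        assert gain_marker_only_exact(t, 0.75) == pytest.approx(4 / 3)
        assert gain_marker_only_exact(t, 1.0) == pytest.approx(0.0)

    def test_truncated_distribution_moments(self):
        t = build_three_genotype_table(4.0, "none")
        top = truncate_marker_distribution(t, 0.25)
        assert (top.mean, top.variance) == (4.0, 0.0)
        mid = truncate_marker_distribution(t, 0.75)
        assert mid.mean == pytest.approx(4 / 3)
        assert mid.variance == pytest.approx(2 * 16 / 9)
        assert mid.boundary_label is None  # 0.75 falls exactly on a class edge
        half = truncate_marker_distribution(t, 0.5)
        assert half.boundary_label == "Mm"
        assert half.boundary_retained_fraction == pytest.approx(0.5)
        full = truncate_marker_distribution(t, 1.0)
        assert (full.mean, full.variance) == (t.mean(), t.variance())

    @pytest.mark.parametrize("sp_m", [0.0625, 0.25, 0.4375, 0.75, 1.0])
    def test_nine_genotype_against_brute_force(self, sp_m):
        t = build_nine_genotype_table(2.0)
        result = truncate_marker_distribution(t, sp_m)
        mean, var = truncate_by_enumeration(t, sp_m)
        assert result.mean == pytest.approx(mean, rel=1e-9)
        assert result.variance == pytest.approx(var, rel=1e-9, abs=1e-9)
        assert sum(result.frequencies) == pytest.approx(1.0)

    def test_normal_approximation_improves_with_classes(self):
        s = partition_variance(200.0, 0.5, 0.5)
        three = marker_table_for(s, "three_genotype", "none")
        nine = marker_table_for(s, "nine_genotype")
        approx = gain_marker_only_normal(s.V_M, 0.5)
        err3 = abs(gain_marker_only_exact(three, 0.5) - approx)
        err9 = abs(gain_marker_only_exact(nine, 0.5) - approx)
        assert err9 < err3

    def test_exact_gain_matches_simulated_mean(self):
        """Cross-module oracle: enumeration equals the simulated expectation."""
        s = scenario_grid()[5]
        t = marker_table_for(s, "three_genotype", "none")
        gains = []
        for rep in range(300):
            pop = simulate_population(t, s, 400, rng=rep)
            gains.append(
                select_marker_only(pop, 0.5, np.random.default_rng(rep)).delta_g
            )
        ci = 1.96 * np.std(gains, ddof=1) / math.sqrt(len(gains))
        assert abs(np.mean(gains) - gain_marker_only_exact(t, 0.5)) <= ci


class TestTwoStageGain:
    def test_endpoints_recover_single_stage_formulas(self):
        s = scenario_grid()[5]
        t = marker_table_for(s, "three_genotype", "partial")
        for tsp in (0.1, 0.5):
            assert gain_two_stage(t, s.V_B, s.V_E, tsp, 1.0) == pytest.approx(
                gain_phenotype_only(s.H, s.V_P, tsp)
            )
            assert gain_two_stage(t, s.V_B, s.V_E, tsp, tsp) == pytest.approx(
                gain_marker_only_exact(t, tsp)
            )

    def test_optimum_for_low_heritability_high_predictiveness(self):
        # H=0.2, P=0.5: keeping exactly the best marker class first is optimal.
        s = scenario_grid()[1]
        t = marker_table_for(s, "three_genotype", "partial")
        spm_grid = [i / 20 for i in range(2, 21)]
        best_spm, best_gain = optimal_two_stage(t, s.V_B, s.V_E, 0.1, spm_grid)
        assert best_spm == 0.25
        assert best_gain == pytest.approx(
            gain_two_stage(t, s.V_B, s.V_E, 0.1, 0.25)
        )

    def test_degenerate_ties_resolve_to_largest_spm(self):
        t = build_three_genotype_table(0.0, "none")
        best_spm, best_gain = optimal_two_stage(t, 0.0, 0.0, 0.25, [0.25, 0.5, 1.0])
        assert best_spm == 1.0 and best_gain == 0.0

    def test_empty_grid_rejected(self):
        t = build_three_genotype_table(4.0, "none")
        with pytest.raises(ValueError):
            optimal_two_stage(t, 1.0, 1.0, 0.25, [])


class TestIndexGain:
    def test_limits(self):
        assert gain_index(0.5, 0.0, 200, 0.3) == pytest.approx(
            gain_phenotype_only(0.5, 200, 0.3)
        )
        assert gain_index(0.5, 1.0, 200, 0.3) == pytest.approx(
            gain_marker_only_normal(0.5 * 200, 0.3)
        )
        assert gain_index(1.0, 1.0, 200, 0.25) == pytest.approx(
            selection_intensity(0.25) * math.sqrt(200)
        )

    def test_known_value(self):
        assert gain_index(0.5, 0.8, 200, 0.05) == pytest.approx(18.83, abs=0.01)


@settings(derandomize=True, max_examples=100)
@given(H=st.floats(0.05, 1.0), P=st.floats(0.0, 1.0), tsp=st.sampled_from(TSP_GRID))
def test_index_dominates_single_information_gains(H, P, tsp):
    """The index bracket is at least max(1, P/H)."""
    V_P = 200.0
    index = gain_index(H, P, V_P, tsp)
    assert index >= gain_phenotype_only(H, V_P, tsp) - 1e-9
    assert index >= gain_marker_only_normal(P * H * V_P, tsp) - 1e-9


@pytest.mark.parametrize("population_kind,dominance", [
    ("three_genotype", "partial"), ("nine_genotype", None),
])
def test_derived_gains_non_increasing_in_tsp(population_kind, dominance):
    s = scenario_grid()[5]
    t = marker_table_for(s, population_kind, dominance)
    curves = {
        "pheno": [gain_phenotype_only(s.H, s.V_P, x) for x in TSP_GRID],
        "marker": [gain_marker_only_exact(t, x) for x in TSP_GRID],
        "index": [gain_index(s.H, s.P, s.V_P, x) for x in TSP_GRID],
    }
    for name, curve in curves.items():
        assert all(a >= b - 1e-12 for a, b in zip(curve, curve[1:])), name
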