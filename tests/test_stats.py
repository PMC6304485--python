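"""Rank tests against brute-force enumeration oracles; report assembly."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ivimr2 import (
    build_study_report,
    generate_cohort,
    kruskal_wallis,
    mann_whitney,
    paired_t,
    spearman,
    tabular_mode,
)
from ivimr2.stats import STAGE_CODES, strength_label


def _brute_force_kw_p(groups):
    """Independent oracle: enumerate all three-group relabelings, scipy H statistic."""
    assert len(groups) == 3
    pooled = np.concatenate(groups)
    n = len(pooled)
    n1, n2, _ = (len(g) for g in groups)
    h_obs = sps.kruskal(*groups).statistic
    count = total = 0
    for first in itertools.combinations(range(n), n1):
        rest = [i for i in range(n) if i not in first]
        for second in itertools.combinations(rest, n2):
            third = [i for i in rest if i not in second]
            gs = [pooled[list(first)], pooled[list(second)], pooled[third]]
            total += 1
            if sps.kruskal(*gs).statistic >= h_obs - 1e-12:
                count += 1
    return count / total


class TestKruskalWallis:
    def test_identical_groups_give_h0_p1(self):
        res = kruskal_wallis([[2.0, 2.0], [2.0], [2.0, 2.0, 2.0]])
        assert res.statistic == 0.0 and res.p_value == 1.0
        assert not res.significant

    def test_h_matches_scipy_with_ties(self):
        groups = [[1.0, 2.0, 2.0], [2.0, 3.0, 4.0], [4.0, 5.0, 6.0]]
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(sps.kruskal(*groups).statistic, rel=1e-12)

    def test_exact_p_matches_brute_force_enumeration(self):
        groups = [np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0]), np.array([7.0, 8.0, 9.0])]
        res = kruskal_wallis(groups)
        assert "exact" in res.flags
        assert res.statistic == pytest.approx(7.2, rel=1e-12)
        assert res.p_value == pytest.approx(_brute_force_kw_p(groups), abs=1e-12)

    def test_exact_p_with_ties_matches_brute_force(self):
        groups = [np.array([1.0, 2.0, 2.0]), np.array([2.0, 4.0]), np.array([5.0, 6.0])]
        res = kruskal_wallis(groups)
        assert res.p_value == pytest.approx(_brute_force_kw_p(groups), abs=1e-12)

    def test_large_sample_uses_chi_square(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(size=20), rng.normal(size=20), rng.normal(1.0, size=20)]
        res = kruskal_wallis(groups)
        assert res.p_value == pytest.approx(sps.kruskal(*groups).pvalue, rel=1e-10)

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])


class TestMannWhitney:
    def test_equal_samples_u_half_p_one(self):
        res = mann_whitney([1.0, 2.0], [1.0, 2.0])
        assert res.statistic == pytest.approx(2.0)  # n1*n2/2
        assert res.p_value == 1.0

    def test_small_sample_exact_enumeration(self):
        res = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2.0 / 6.0)
        assert "exact" in res.flags

    def test_exact_matches_scipy_exact_no_ties(self):
        a, b = [1.2, 3.4, 2.2, 5.0], [4.1, 6.3, 7.7]
        res = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res.p_value == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_large_sample_asymptotic(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=15), rng.normal(0.8, size=12)
        res = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-10)


class TestPairedT:
    def test_hand_computed_example(self):
        # differences {1,1,2}: mean 4/3, sd 1/sqrt(3), t = (4/3)/(1/3) = 4
        res = paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 5.0])
        assert res.statistic == pytest.approx(4.0, rel=1e-12)
        assert res.p_value == pytest.approx(float(sps.ttest_rel([2, 3, 5], [1, 2, 3]).pvalue))

    def test_constant_shift_degenerate_variance(self):
        res = paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.p_value == 0.0
        assert "degenerate_variance" in res.flags

    def test_zero_differences_carry_no_p(self):
        res = paired_t([1.0, 2.0], [1.0, 2.0])
        assert res.p_value is None
        assert "zero_differences" in res.flags

    def test_simulated_paired_lobe_difference_detected(self):
        """Paired D difference (irradiated vs control lobe) is significant in most seeds."""
        hits = 0
        for seed in range(30):
            cohort = generate_cohort(seed=seed)
            three_m = [r for r in cohort.survivors if r.timepoint == "3m"]
            res = paired_t([r.left.D for r in three_m], [r.right.D for r in three_m])
            if res.significant and res.statistic < 0:
                hits += 1
        assert hits >= 15  # majority of seeds at n=7 pairs


class TestSpearman:
    def test_perfect_monotone(self):
        res = spearman([1.0, 2.0, 3.0, 4.0], [0, 1, 2, 3])
        assert res.r == pytest.approx(1.0) and res.strength == "high"
        res = spearman([4.0, 3.0, 2.0, 1.0], [0, 1, 2, 3])
        assert res.r == pytest.approx(-1.0)

    def test_constant_input_flagged(self):
        res = spearman([2.0, 2.0, 2.0], [0, 1, 2])
        assert res.r is None and "constant_input" in res.flags

    @pytest.mark.parametrize(
        "r,label", [(0.819, "high"), (-0.85, "high"), (0.5, "mild"), (-0.79, "mild"), (0.424, "weak")]
    )
    def test_strength_bands(self, r, label):
        assert strength_label(r) == label

    @given(
        st.lists(st.floats(-50, 50), min_size=5, max_size=12, unique=True),
        st.sampled_from([np.exp, np.arctan, lambda v: v**3, lambda v: 2 * v + 1]),
    )
    @settings(deadline=None, max_examples=30)
    def test_invariant_under_strictly_monotone_transform(self, values, transform):
        stages = np.arange(len(values)) % 4
        transformed = transform(np.asarray(values))
        if len(np.unique(transformed)) != len(values):
            return  # transform collapsed float-adjacent values; ranks not preserved
        base = spearman(values, stages)
        trans = spearman(transformed, stages)
        if base.r is not None and trans.r is not None:
            assert trans.r == pytest.approx(base.r, abs=1e-12)


@pytest.fixture(scope="module")
def table():
    return tabular_mode(generate_cohort(seed=0))


class TestStudyReport:
    def test_stage_table_row_order(self, table):
        report = build_study_report(table)
        stages = report.stage_comparison["stage"].tolist()
        assert stages[:4] == ["control", "F0", "F1", "F2"]
        assert stages[-1] == "KW p"

    def test_correlation_block_covers_all_parameters(self, table):
        report = build_study_report(table)
        assert set(report.correlations) == {"D_star", "D", "f", "R2_star"}
        assert all(c.n == 46 for c in report.correlations.values())

    def test_right_lobes_only_mode(self, table):
        report = build_study_report(table, include_control_in_correlation=False)
        assert all(c.n == 23 for c in report.correlations.values())

    def test_identical_groups_give_flat_report(self):
        table = tabular_mode(generate_cohort(seed=0)).copy()
        for p in ("D_star", "D", "f", "R2_star"):
            table[p] = 1.0
        report = build_study_report(table)
        assert report.stage_comparison.iloc[-1]["R2_star"] == "1.000"
        assert all(c.r is None for c in report.correlations.values())

    def test_report_determinism(self, table):
        a = build_study_report(table).to_markdown()
        b = build_study_report(table.copy()).to_markdown()
        assert a == b

    def test_missing_stage_warns_and_omits(self, table):
        broken = table[table.stage != "F2"]
        report = build_study_report(broken)
        assert any("F2" in w for w in report.warnings)
        assert "F2" not in report.stage_comparison["stage"].tolist()

    def test_csv_and_json_outputs(self, table, tmp_path):
        report = build_study_report(table)
        written = report.to_csv(tmp_path)
        names = {p.name for p in written}
        assert {"stage_comparison.csv", "correlations.json", "timepoint_right.csv"} <= names
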