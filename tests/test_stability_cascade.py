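"""Slope regression, FDR, Mann-Whitney and classification logic.

Independent oracles: the pooled-variance two-sample t-test (closed form /
scipy.stats.ttest_ind) for the Wald slope test; full enumeration of rank
assignments for the exact Mann-Whitney null; hand step-up computation for
BH-FDR.
"""

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methdrift import (
    PipelineConfig,
    ValidationError,
    baseline_tests,
    bh_fdr,
    classify_control_stability,
    classify_treated_response,
    fit_cpg_slope,
    fit_slopes,
    mann_whitney,
    run_cascade,
    select_top_changes,
    summarize_counts,
)
from methdrift.stability_cascade import min_exact_mwu_p, percent

from conftest import make_matrix, make_sheet


def brute_force_mwu_p(a, b) -> float:
    """Two-sided exact Mann-Whitney p by enumerating every assignment of
    the pooled observations to the two groups (tie-free inputs)."""
    pooled = list(a) + list(b)
    n1 = len(a)

    def u_stat(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y)

    u_obs = max(u_stat(a, b), u_stat(b, a))
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in range(len(pooled)) if i not in comb]
        u = max(u_stat(ga, gb), u_stat(gb, ga))
        count += u >= u_obs
        total += 1
    return count / total


class TestSlope:
    def test_slope_equals_mean_difference(self):
        res = fit_cpg_slope([0.10, 0.12, 0.14, 0.30, 0.32, 0.34],
                            [0, 0, 0, 1, 1, 1])
        assert res.slope == pytest.approx(0.20, abs=1e-12)
        assert res.df == 4

    def test_wald_matches_pooled_t_closed_form(self):
        res = fit_cpg_slope([0.10, 0.12, 0.14, 0.30, 0.32, 0.34],
                            [0, 0, 0, 1, 1, 1])
        assert res.t == pytest.approx(12.247448713915885, abs=1e-9)
        assert res.p == pytest.approx(2.552167494419272e-4, rel=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.001, 0.999), min_size=6, max_size=6))
    def test_wald_equals_scipy_pooled_t_everywhere(self, values):
        x = [0, 0, 0, 1, 1, 1]
        res = fit_cpg_slope(values, x)
        a, b = values[:3], values[3:]
        assert res.slope == pytest.approx(np.mean(b) - np.mean(a), abs=1e-12)
        if not res.degenerate:
            t, p = stats.ttest_ind(b, a, equal_var=True)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_constant_probe_is_degenerate(self):
        res = fit_cpg_slope([0.5] * 6, [0, 0, 0, 1, 1, 1])
        assert res.slope == 0.0
        assert res.degenerate
        assert res.p == 1.0

    def test_degenerate_with_nonzero_slope_has_p_zero(self):
        res = fit_cpg_slope([0.2, 0.2, 0.2, 0.4, 0.4, 0.4], [0, 0, 0, 1, 1, 1])
        assert res.degenerate
        assert res.slope == pytest.approx(0.2)
        assert res.p == 0.0

    def test_bad_time_codes_rejected(self):
        with pytest.raises(ValidationError, match="time codes"):
            fit_cpg_slope([0.1, 0.2, 0.3, 0.4], [0, 1, 2, 2])

    def test_vectorized_fit_matches_per_probe(self):
        rng = np.random.default_rng(3)
        sheet = make_sheet(3)
        values = rng.random((20, 12))
        matrix = make_matrix(values, sheet)
        table = fit_slopes(matrix, sheet, "treated")
        ids, codes = sheet.time_codes("treated")
        cols = matrix.sample_columns(ids)
        for i, pid in enumerate(matrix.probe_ids):
            single = fit_cpg_slope(cols[i], codes, pid)
            assert table.loc[pid, "slope"] == pytest.approx(single.slope, abs=1e-14)
            assert table.loc[pid, "p"] == pytest.approx(single.p, abs=1e-12)

    def test_missing_value_excludes_probe_from_arm(self):
        sheet = make_sheet(3)
        values = np.full((2, 12), 0.5)
        values[0, 0] = np.nan  # treated_I_r1
        matrix = make_matrix(values, sheet)
        table = fit_slopes(matrix, sheet, "treated")
        assert table["excluded_missing"].tolist() == [True, False]
        assert np.isnan(table.iloc[0]["slope"])


class TestBhFdr:
    @pytest.mark.parametrize("p, expected", [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.2], [0.2]),
        ([0.001, 1.0], [0.002, 1.0]),
    ])
    def test_hand_step_up_values(self, p, expected):
        np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)

    def test_order_preserving(self):
        p = [0.5, 0.001, 0.04, 0.9]
        q = bh_fdr(p)
        q_sorted = bh_fdr(sorted(p))
        order = np.argsort(p)
        np.testing.assert_allclose(np.asarray(q)[order], q_sorted, atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_q_at_least_p_and_monotone(self, p):
        q = bh_fdr(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(np.asarray(q)[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])


class TestMannWhitney:
    def test_extreme_separation_exact_p(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.p == pytest.approx(0.1, abs=1e-12)

    def test_identical_constant_groups_tie_path(self):
        res = mann_whitney([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert res.method == "asymptotic"
        assert res.p == pytest.approx(1.0)

    def test_exact_matches_enumeration_all_20_arrangements(self):
        """Every tie-free 3v3 split of six distinct values agrees with the
        brute-force enumeration oracle."""
        values = [0.11, 0.23, 0.35, 0.47, 0.59, 0.61]
        for comb in itertools.combinations(range(6), 3):
            a = [values[i] for i in comb]
            b = [values[i] for i in range(6) if i not in comb]
            res = mann_whitney(a, b)
            assert res.method == "exact"
            assert res.p == pytest.approx(brute_force_mwu_p(a, b), abs=1e-12)

    def test_overlapping_groups_match_enumeration(self):
        a, b = [0.1, 0.2, 0.3], [0.25, 0.35, 0.45]
        res = mann_whitney(a, b)
        assert res.p == pytest.approx(brute_force_mwu_p(a, b), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])

    def test_vectorized_baseline_matches_scalar(self):
        rng = np.random.default_rng(7)
        sheet = make_sheet(3)
        values = rng.random((30, 12))
        values[5, :3] = values[5, 6]  # force ties on one probe
        matrix = make_matrix(values, sheet)
        table = baseline_tests(matrix, sheet)
        a = matrix.sample_columns(sheet.samples("treated", "I"))
        b = matrix.sample_columns(sheet.samples("control", "I"))
        for i, pid in enumerate(matrix.probe_ids):
            single = mann_whitney(a[i], b[i], pid)
            assert table.loc[pid, "method"] == single.method
            assert table.loc[pid, "U"] == pytest.approx(single.U)
            assert table.loc[pid, "p"] == pytest.approx(single.p, abs=1e-9)

    def test_min_exact_p_documents_3v3_floor(self):
        assert min_exact_mwu_p(3, 3) == pytest.approx(0.1)


class TestClassification:
    @pytest.mark.parametrize("slope, q, expected", [
        (0.01, 0.8, "stable_in_controls"),
        (0.05, 0.8, "culture_affected"),   # slope bound violated alone
        (0.01, 0.01, "culture_affected"),  # significance violated alone
        (0.025, 0.8, "stable_in_controls"),  # bound is inclusive
    ])
    def test_control_stability_conjunction(self, slope, q, expected):
        df = pd.DataFrame({"slope": [slope], "q": [q]}, index=["cg1"])
        out = classify_control_stability(df, PipelineConfig())
        assert out.iloc[0] == expected

    @pytest.mark.parametrize("t_slope, t_q, b_q, expected", [
        (0.01, 0.9, 0.9, "unchanged"),
        (0.15, 0.001, 0.9, "btz_affected"),
        (0.01, 0.9, 0.01, "btz_affected"),  # baseline divergence alone
        (0.05, 0.9, 0.9, "btz_affected"),   # treated slope bound alone
    ])
    def test_treated_response_negation_of_conjunction(self, t_slope, t_q, b_q,
                                                      expected):
        treated = pd.DataFrame({"slope": [t_slope], "q": [t_q]}, index=["cg1"])
        base = pd.DataFrame({"q": [b_q]}, index=["cg1"])
        out = classify_treated_response(treated, base, PipelineConfig())
        assert out.iloc[0] == expected

    def test_mismatched_probe_sets_rejected(self):
        treated = pd.DataFrame({"slope": [0.1], "q": [0.5]}, index=["cg1"])
        base = pd.DataFrame({"q": [0.5]}, index=["cg2"])
        with pytest.raises(ValidationError):
            classify_treated_response(treated, base, PipelineConfig())

    def test_top_selection_strict_threshold(self):
        df = pd.DataFrame({"slope": [0.15, -0.12, 0.05, 0.1, -0.1]},
                          index=[f"cg{i}" for i in range(5)])
        flags = select_top_changes(df, PipelineConfig())
        assert flags.tolist() == ["gain", "loss", "none", "none", "none"]

    def test_threshold_monotonicity(self, synthetic_run):
        """Raising tau_stable never shrinks the stable set; raising tau_top
        never grows the top set."""
        control = synthetic_run["result"].control_results
        btz = synthetic_run["result"].treated_results.loc[
            synthetic_run["result"].btz_affected]
        sizes_stable, sizes_top = [], []
        for tau in (0.01, 0.025, 0.05, 0.1):
            cfg = PipelineConfig(tau_stable=tau, tau_top=0.2)
            status = classify_control_stability(control, cfg)
            sizes_stable.append((status == "stable_in_controls").sum())
        for tau in (0.05, 0.1, 0.15, 0.19):
            cfg = PipelineConfig(tau_top=tau)
            flags = select_top_changes(btz, cfg)
            sizes_top.append((flags != "none").sum())
        assert sizes_stable == sorted(sizes_stable)
        assert sizes_top == sorted(sizes_top, reverse=True)


class TestSummarize:
    def test_partition_conservation(self, synthetic_run):
        res = synthetic_run["result"]
        s = res.summary()
        counts = res.table["label"].value_counts()
        assert (counts.get("culture_affected", 0) + counts.get("unchanged", 0)
                + counts.get("btz_affected", 0)) == s["total_assessed"]
        flags = res.table["top_flag"].value_counts()
        assert s["n_top"] == flags.get("gain", 0) + flags.get("loss", 0)
        assert set(res.table.index[res.table["top_flag"] != "none"]) <= set(
            res.table.index[res.table["label"] == "btz_affected"])

    @pytest.mark.parametrize("count, total, expected", [
        (447587, 735074, 60.9),
        (367538, 447587, 82.1),
        (49686, 80049, 62.1),
        (1, 8, 12.5),
        (1, 16, 6.3),  # 6.25 rounds half-up
    ])
    def test_percent_half_up_one_decimal(self, count, total, expected):
        assert percent(count, total) == expected

    def test_summary_fields_consistent(self):
        s = summarize_counts(total_assessed=1000, n_control_stable=800,
                             n_unchanged=700, n_btz_affected=100, n_hypo=60,
                             n_top_gain=7, n_top_loss=3)
        assert s["n_culture_excluded"] == 200
        assert s["n_top"] == 10
        assert s["pct_control_stable"] == 80.0
        assert s["pct_hypomethylated"] == 60.0


class TestRunCascade:
    def test_vacuous_baseline_warning_at_3v3(self):
        rng = np.random.default_rng(0)
        sheet = make_sheet(3)
        matrix = make_matrix(rng.uniform(0.4, 0.6, (50, 12)), sheet)
        with pytest.warns(UserWarning, match="vacuous"):
            run_cascade(matrix, sheet, PipelineConfig())

    def test_missing_values_logged_and_partition_intact(self):
        rng = np.random.default_rng(0)
        sheet = make_sheet(3)
        values = rng.uniform(0.49, 0.51, (50, 12))
        values[3, 0] = np.nan
        matrix = make_matrix(values, sheet)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res = run_cascade(matrix, sheet, PipelineConfig())
        assert res.excluded_missing == ["cg00000003"]
        assert len(res.table) == 49
        s = res.summary()
        assert s["n_excluded_missing"] == 1
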