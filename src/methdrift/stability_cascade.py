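"""Per-CpG regression/stability cascade.

The cascade attributes methylation changes to treatment in three steps, all
on the beta scale with the time point coded 0 (first harvest) / 1 (second
harvest) so that the OLS slope of beta on time equals the between-time-point
mean difference:

1. *Control stability.*  For every assessed probe, fit an OLS regression of
   beta on time code in the control arm and test the slope with a Wald
   t-test (df = n - 2).  Probes that are non-significant after BH-FDR
   (q > alpha) AND have |slope| <= tau_stable are stable; the rest changed
   under culture conditions alone and are excluded.
2. *Treated response.*  On control-stable probes, repeat the slope test in
   the treated arm, and additionally compare treated vs control samples at
   the first time point with a Mann-Whitney U test (baseline equivalence).
   Probes passing all three criteria (treated q > alpha, |treated slope| <=
   tau_stable, baseline q > alpha) are unchanged; every remaining probe is
   attributed to treatment.
3. *Top changes.*  Among treatment-attributed probes, those with
   |treated slope| strictly greater than tau_top (a change of more than
   tau_top * 100 percentage points of methylation) are flagged as top
   gain (slope > tau_top) or top loss (slope < -tau_top).

BH-FDR families are per stage: all control-arm Wald tests; treated-arm Wald
tests on control-stable probes; baseline Mann-Whitney tests on the same
probes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import BetaMatrix, PipelineConfig, SampleSheet, ValidationError

LABEL_CULTURE = "culture_affected"
LABEL_UNCHANGED = "unchanged"
LABEL_BTZ = "btz_affected"

TOP_NONE = "none"
TOP_GAIN = "gain"
TOP_LOSS = "loss"


@dataclass
class SlopeTestResult:
    """OLS slope test for one probe in one arm.

    With 0/1 time coding the slope equals mean(time II) - mean(time I); the
    Wald statistic is slope / se with df = n - 2 residual degrees of
    freedom.  ``degenerate`` marks probes with zero residual variance, for
    which p is 1 when the slope is 0 and 0 otherwise.
    """

    probe_id: str
    slope: float
    se: float
    t: float
    df: int
    p: float
    q: float | None = None
    degenerate: bool = False


@dataclass
class BaselineTestResult:
    """Mann-Whitney U comparison of treated vs control betas at baseline."""

    probe_id: str
    U: float
    p: float
    q: float | None = None
    method: str = "exact"


def fit_cpg_slope(values: Sequence[float], design: Sequence[float],
                  probe_id: str = "") -> SlopeTestResult:
    """Fit the per-probe OLS regression of beta on the 0/1 time code.

    Equivalent to the pooled-variance two-sample t-test on the two time
    points; the closed form is used directly.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(design, dtype=float)
    if y.shape != x.shape:
        raise ValidationError("values and design must have equal length")
    codes = np.unique(x)
    if not np.array_equal(codes, [0.0, 1.0]):
        raise ValidationError(f"time codes must be exactly {{0, 1}}, got {codes}")
    n0 = int((x == 0).sum())
    n1 = int((x == 1).sum())
    if n0 < 2 or n1 < 2:
        raise ValidationError("need >= 2 samples per time point")
    slope, se, t, df, p, degen = _slope_stats(
        y[x == 0][None, :], y[x == 1][None, :]
    )
    return SlopeTestResult(probe_id, float(slope[0]), float(se[0]), float(t[0]),
                           int(df), float(p[0]), degenerate=bool(degen[0]))


def _slope_stats(y0: np.ndarray, y1: np.ndarray):
    """Vectorized closed-form OLS of beta on 0/1 time code.

    y0, y1: (n_probes, n0) and (n_probes, n1) arrays.  Returns
    (slope, se, t, df, p, degenerate).
    """
    n0, n1 = y0.shape[1], y1.shape[1]
    df = n0 + n1 - 2
    m0 = y0.mean(axis=1)
    m1 = y1.mean(axis=1)
    slope = m1 - m0
    ss = ((y0 - m0[:, None]) ** 2).sum(axis=1) + ((y1 - m1[:, None]) ** 2).sum(axis=1)
    s2 = ss / df
    se = np.sqrt(s2 * (1.0 / n0 + 1.0 / n1))
    # residual SS below float-roundoff scale counts as zero variance
    degenerate = ss <= 1e-24
    se = np.where(degenerate, 0.0, se)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope / se
    t = np.where(degenerate, np.sign(slope) * np.inf, t)
    t = np.where(degenerate & (slope == 0.0), 0.0, t)
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # zero residual variance: no sampling noise, p degenerates to 0/1
    p = np.where(degenerate, np.where(slope == 0.0, 1.0, 0.0), p)
    return slope, se, t, df, p, degenerate


def fit_slopes(matrix: BetaMatrix, sheet: SampleSheet, arm: str) -> pd.DataFrame:
    """Slope tests for every probe of one arm, as a DataFrame indexed by
    probe_id with columns slope, se, t, df, p, degenerate, excluded_missing.

    Probes with any missing beta in the arm are excluded from the test
    (all statistics NaN, excluded_missing True).
    """
    ids_i = sheet.samples(arm, "I")
    ids_ii = sheet.samples(arm, "II")
    y0 = matrix.sample_columns(ids_i)
    y1 = matrix.sample_columns(ids_ii)
    ok = ~(np.isnan(y0).any(axis=1) | np.isnan(y1).any(axis=1))
    slope = np.full(len(matrix.probe_ids), np.nan)
    se = np.full_like(slope, np.nan)
    t = np.full_like(slope, np.nan)
    p = np.full_like(slope, np.nan)
    degen = np.zeros(len(slope), dtype=bool)
    s, e, tt, df, pp, dg = _slope_stats(y0[ok], y1[ok])
    slope[ok], se[ok], t[ok], p[ok], degen[ok] = s, e, tt, pp, dg
    return pd.DataFrame(
        {
            "slope": slope,
            "se": se,
            "t": t,
            "df": len(ids_i) + len(ids_ii) - 2,
            "p": p,
            "degenerate": degen,
            "excluded_missing": ~ok,
        },
        index=pd.Index(matrix.probe_ids, name="probe_id"),
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


# ------------------------------------------------------- Mann-Whitney U

def _u_null_sf(n1: int, n2: int) -> np.ndarray:
    """Upper-tail P(U >= u) of the exact tie-free Mann-Whitney null.

    Counts rank configurations by the classic recurrence on the number of
    partitions of u into at most n1 parts each <= n2.
    """
    n = n1 + n2
    max_sum = n1 * n2 + n1 * (n1 + 1) // 2
    # count[i][r]: n1-subsets of ranks 1..k with i members summing to r
    count = np.zeros((n1 + 1, max_sum + 1))
    count[0, 0] = 1.0
    for k in range(1, n + 1):
        for i in range(min(k, n1), 0, -1):
            count[i, k:] += count[i - 1, :-k] if k else count[i - 1]
    min_sum = n1 * (n1 + 1) // 2
    pmf = count[n1][min_sum:] / math.comb(n, n1)  # pmf over U = R1 - min_sum
    return np.cumsum(pmf[::-1])[::-1]  # sf[u] = P(U >= u)


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float],
                 probe_id: str = "") -> BaselineTestResult:
    """Two-sided Mann-Whitney U test.

    Exact p by full enumeration of the null when both groups have <= 8
    observations and there are no ties; mid-rank, tie-corrected normal
    approximation otherwise.  The method used is recorded on the result.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if a.size <= 8 and b.size <= 8 and not has_ties:
        method = "exact"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        method = "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return BaselineTestResult(probe_id, float(res.statistic), float(res.pvalue),
                              method=method)


def baseline_tests(matrix: BetaMatrix, sheet: SampleSheet) -> pd.DataFrame:
    """Vectorized baseline-equivalence tests (treated vs control, time I).

    Per probe: Mann-Whitney U of the treated-arm time-I betas against the
    control-arm time-I betas.  Tie-free probes use the exact enumeration
    null (shared across probes for fixed group sizes); probes with ties use
    the tie-corrected normal approximation with continuity correction.
    Probes with missing baseline values are excluded (NaN, excluded_missing).
    """
    a = matrix.sample_columns(sheet.samples("treated", "I"))
    b = matrix.sample_columns(sheet.samples("control", "I"))
    n1, n2 = a.shape[1], b.shape[1]
    n = n1 + n2
    ok = ~(np.isnan(a).any(axis=1) | np.isnan(b).any(axis=1))
    U = np.full(a.shape[0], np.nan)
    p = np.full(a.shape[0], np.nan)
    method = np.full(a.shape[0], "", dtype=object)

    combined = np.concatenate([a[ok], b[ok]], axis=1)
    ranks = stats.rankdata(combined, axis=1)  # mid-ranks
    r1 = ranks[:, :n1].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u_max = np.maximum(u1, n1 * n2 - u1)

    sorted_rows = np.sort(combined, axis=1)
    tied = (np.diff(sorted_rows, axis=1) == 0).any(axis=1)

    p_ok = np.empty(u1.shape)
    meth_ok = np.where(tied, "asymptotic", "exact").astype(object)
    if (~tied).any():
        sf = _u_null_sf(n1, n2)
        p_ok[~tied] = np.minimum(1.0, 2.0 * sf[u_max[~tied].astype(int)])
    if tied.any():
        # tied rows are rare with continuous betas; delegate to the scalar
        # tie-corrected path so both routes agree exactly
        rows_a = a[ok][tied]
        rows_b = b[ok][tied]
        pt = np.empty(rows_a.shape[0])
        for i in range(rows_a.shape[0]):
            if np.ptp(np.concatenate([rows_a[i], rows_b[i]])) == 0.0:
                pt[i] = 1.0  # all values identical: no evidence either way
            else:
                pt[i] = stats.mannwhitneyu(rows_a[i], rows_b[i],
                                           alternative="two-sided",
                                           method="asymptotic").pvalue
        p_ok[tied] = pt
    U[ok], p[ok], method[ok] = u1, p_ok, meth_ok
    return pd.DataFrame(
        {"U": U, "p": p, "method": method, "excluded_missing": ~ok},
        index=pd.Index(matrix.probe_ids, name="probe_id"),
    )


def min_exact_mwu_p(n1: int, n2: int) -> float:
    """Smallest attainable two-sided exact Mann-Whitney p for given sizes."""
    return min(1.0, 2.0 / math.comb(n1 + n2, n1))


# ------------------------------------------------------- classification

def classify_control_stability(results: pd.DataFrame,
                               config: PipelineConfig) -> pd.Series:
    """Partition control-arm probes into stable vs culture-affected.

    Stable requires BOTH a non-significant FDR-adjusted Wald test
    (q > alpha) AND |slope| <= tau_stable; any probe failing either
    criterion changed under culture conditions alone.
    """
    if "q" not in results.columns:
        raise ValidationError("control results must carry BH-FDR q values")
    stable = (results["q"] > config.alpha) & (results["slope"].abs() <= config.tau_stable)
    return pd.Series(
        np.where(stable, "stable_in_controls", LABEL_CULTURE),
        index=results.index, name="control_status",
    )


def classify_treated_response(treated_results: pd.DataFrame,
                              baseline_results: pd.DataFrame,
                              config: PipelineConfig) -> pd.Series:
    """Partition control-stable probes into unchanged vs treatment-attributed.

    Unchanged requires treated-arm stability (q > alpha and |slope| <=
    tau_stable) and baseline equivalence to controls (baseline q > alpha);
    every other probe is attributed to treatment.
    """
    if set(treated_results.index) != set(baseline_results.index):
        only_t = set(treated_results.index) - set(baseline_results.index)
        only_b = set(baseline_results.index) - set(treated_results.index)
        raise ValidationError(
            f"treated/baseline probe sets differ: only treated {sorted(only_t)[:5]}, "
            f"only baseline {sorted(only_b)[:5]}"
        )
    base = baseline_results.reindex(treated_results.index)
    unchanged = (
        (treated_results["q"] > config.alpha)
        & (treated_results["slope"].abs() <= config.tau_stable)
        & (base["q"] > config.alpha)
    )
    return pd.Series(
        np.where(unchanged, LABEL_UNCHANGED, LABEL_BTZ),
        index=treated_results.index, name="label",
    )


def select_top_changes(btz_results: pd.DataFrame,
                       config: PipelineConfig) -> pd.Series:
    """Flag treatment-attributed probes with |slope| strictly above tau_top
    as top gain (positive slope) or top loss (negative slope)."""
    slope = btz_results["slope"]
    flags = np.where(slope > config.tau_top, TOP_GAIN,
                     np.where(slope < -config.tau_top, TOP_LOSS, TOP_NONE))
    return pd.Series(flags, index=btz_results.index, name="top_flag")


def percent(count: int, total: int) -> float:
    """Percentage rounded half-up to one decimal (exact decimal arithmetic)."""
    if total == 0:
        raise ValidationError("cannot take a percentage of a zero total")
    ratio = (Decimal(count) * 100) / Decimal(total)
    return float(ratio.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_counts(*, total_assessed: int, n_control_stable: int,
                     n_unchanged: int, n_btz_affected: int, n_hypo: int,
                     n_top_gain: int, n_top_loss: int,
                     n_excluded_missing: int = 0) -> dict:
    """Count/percentage summary of a cascade run.

    Percentages are half-up rounded to one decimal: stable as % of all
    assessed probes, unchanged as % of control-stable probes,
    hypomethylated and top as % of treatment-attributed probes.
    """
    n_excluded = total_assessed - n_control_stable
    n_top = n_top_gain + n_top_loss
    return {
        "total_assessed": total_assessed,
        "n_excluded_missing": n_excluded_missing,
        "n_control_stable": n_control_stable,
        "pct_control_stable": percent(n_control_stable, total_assessed),
        "n_culture_excluded": n_excluded,
        "n_unchanged": n_unchanged,
        "pct_unchanged": percent(n_unchanged, n_control_stable) if n_control_stable else None,
        "n_btz_affected": n_btz_affected,
        "n_hypomethylated": n_hypo,
        "pct_hypomethylated": percent(n_hypo, n_btz_affected) if n_btz_affected else None,
        "n_top": n_top,
        "pct_top": percent(n_top, n_btz_affected) if n_btz_affected else None,
        "n_top_gain": n_top_gain,
        "n_top_loss": n_top_loss,
    }


@dataclass
class CascadeResult:
    """All per-probe and summary outputs of one cascade run."""

    table: pd.DataFrame           # per-probe results and labels
    control_results: pd.DataFrame
    treated_results: pd.DataFrame
    baseline_results: pd.DataFrame
    config: PipelineConfig
    excluded_missing: list[str] = field(default_factory=list)

    @property
    def stable_in_controls(self) -> list[str]:
        t = self.table
        return list(t.index[t["label"].isin([LABEL_UNCHANGED, LABEL_BTZ])])

    @property
    def btz_affected(self) -> list[str]:
        return list(self.table.index[self.table["label"] == LABEL_BTZ])

    @property
    def top_probes(self) -> list[str]:
        return list(self.table.index[self.table["top_flag"] != TOP_NONE])

    def summary(self) -> dict:
        t = self.table
        btz = t[t["label"] == LABEL_BTZ]
        return summarize_counts(
            total_assessed=len(t),
            n_control_stable=int((t["label"] != LABEL_CULTURE).sum()),
            n_unchanged=int((t["label"] == LABEL_UNCHANGED).sum()),
            n_btz_affected=len(btz),
            n_hypo=int((btz["slope_treated"] < 0).sum()),
            n_top_gain=int((t["top_flag"] == TOP_GAIN).sum()),
            n_top_loss=int((t["top_flag"] == TOP_LOSS).sum()),
            n_excluded_missing=len(self.excluded_missing),
        )


def run_cascade(matrix: BetaMatrix, sheet: SampleSheet,
                config: PipelineConfig) -> CascadeResult:
    """Run the full three-stage cascade on a validated matrix and design.

    Probes with missing betas in a tested arm are dropped from that arm's
    family (and hence from the final partition) and listed on the result.
    """
    sheet.check_matrix(matrix)

    n1 = len(sheet.samples("treated", "I"))
    n2 = len(sheet.samples("control", "I"))
    if min_exact_mwu_p(n1, n2) > config.alpha:
        warnings.warn(
            f"baseline Mann-Whitney with {n1} vs {n2} replicates cannot reach "
            f"p <= {config.alpha} (minimum exact two-sided p = "
            f"{min_exact_mwu_p(n1, n2):.3g}); the baseline-equivalence "
            "criterion is vacuous at this replication level",
            UserWarning, stacklevel=2,
        )

    control = fit_slopes(matrix, sheet, "control")
    tested_c = control[~control["excluded_missing"]].copy()
    tested_c["q"] = bh_fdr(tested_c["p"].to_numpy())
    control_status = classify_control_stability(tested_c, config)
    stable_ids = list(control_status.index[control_status == "stable_in_controls"])

    sub = matrix.subset_probes(stable_ids)
    treated = fit_slopes(sub, sheet, "treated")
    baseline = baseline_tests(sub, sheet)
    keep = ~(treated["excluded_missing"] | baseline["excluded_missing"])
    tested_t = treated[keep].copy()
    tested_b = baseline[keep].copy()
    tested_t["q"] = bh_fdr(tested_t["p"].to_numpy())
    tested_b["q"] = bh_fdr(tested_b["p"].to_numpy())

    label = classify_treated_response(tested_t, tested_b, config)
    btz_ids = list(label.index[label == LABEL_BTZ])
    top = select_top_changes(tested_t.loc[btz_ids], config)

    excluded_missing = sorted(
        set(control.index[control["excluded_missing"]])
        | set(treated.index[treated["excluded_missing"]])
        | set(baseline.index[baseline["excluded_missing"]])
    )

    assessed = [p for p in matrix.probe_ids if p not in set(excluded_missing)]
    table = pd.DataFrame(index=pd.Index(assessed, name="probe_id"))
    table["slope_control"] = tested_c["slope"].reindex(table.index)
    table["q_control"] = tested_c["q"].reindex(table.index)
    table["slope_treated"] = tested_t["slope"].reindex(table.index)
    table["q_treated"] = tested_t["q"].reindex(table.index)
    table["U_baseline"] = tested_b["U"].reindex(table.index)
    table["q_baseline"] = tested_b["q"].reindex(table.index)
    lab = pd.Series(LABEL_CULTURE, index=table.index)
    lab.loc[label.index] = label
    table["label"] = lab
    flags = pd.Series(TOP_NONE, index=table.index)
    flags.loc[top.index] = top
    table["top_flag"] = flags

    return CascadeResult(
        table=table,
        control_results=tested_c,
        treated_results=tested_t,
        baseline_results=tested_b,
        config=config,
        excluded_missing=excluded_missing,
    )
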