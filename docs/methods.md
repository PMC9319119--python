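# Methods

## Model and procedure

`methdrift` operates on beta values — per-CpG methylation fractions in
[0, 1] as reported by Illumina-style arrays after upstream processing and
normalization, which are outside this package's scope (it consumes a
finished beta matrix; IDAT parsing, probe QC and normalization belong to
dedicated array pipelines).

For one CpG in one arm, with time point coded x = 0 (first harvest) and
x = 1 (second harvest), the package fits

    beta_ij = beta_0 + beta_1 * x_j + e_ij,    e_ij ~ N(0, sigma^2)

by ordinary least squares. Under 0/1 coding the slope beta_1 is exactly
the difference of the two time-point means, so a slope of 0.1 is a
methylation change of 10 percentage points; the Wald test of beta_1 = 0
(t = beta_1/SE, df = n − 2, classical OLS standard errors) is the
pooled-variance two-sample t-test, and the implementation uses that
closed form directly. The per-arm test families are corrected with
Benjamini–Hochberg FDR.

The cascade then proceeds:

1. control-arm stability: stable ⇔ q > alpha AND |slope| ≤ tau_stable;
   the rest is excluded as culture-affected;
2. treated-arm stability plus baseline equivalence (Mann–Whitney U of
   treated vs control betas at the first time point): unchanged ⇔ treated
   q > alpha AND |treated slope| ≤ tau_stable AND baseline q > alpha;
   everything else is attributed to treatment;
3. top changes: |treated slope| strictly > tau_top, split by sign into
   gains and losses.

Stability is deliberately a *conjunction* — a CpG must be both
statistically quiet and numerically flat to count as stable — and change
is its complement. The stability bound uses ≤ while top selection uses a
strict >, so a slope of exactly tau_top is not a top change.

Three separate BH families are used (control Wald tests on all assessed
probes; treated Wald tests on control-stable probes; baseline Mann–Whitney
tests on the same probes), matching the sequential structure of the
cascade: each stage conditions on the previous stage's survivors, so its
family is the set of tests actually performed at that stage.

### Assumptions

- Two time points, linear-in-time coding; no mixed effects or probe-wise
  variance shrinkage. Replicates are independent incubations.
- Classical (non-robust) OLS standard errors.
- Betas within a (probe, arm, time point) cell are exchangeable.

### Degenerate probes

A probe whose residuals are exactly zero (all replicates identical within
both time points) has no estimable noise. Such probes are flagged
`degenerate`; p is reported as 1 when the slope is 0 (a constant probe
carries no evidence of change and is treated as stable) and as 0 when the
slope is non-zero. Residual sums of squares below 1e-24 (squared-beta
units, i.e. float-roundoff scale) count as zero.

### Mann–Whitney details

The scalar test uses the exact null distribution when both groups have
≤ 8 observations and no ties, and the mid-rank, tie-corrected normal
approximation with continuity correction otherwise; the method used is
recorded per probe. The vectorized batch path computes U from mid-ranks
and evaluates exact p-values from a rank-sum null computed once per group
size (a subset-sum dynamic program); rows with ties fall back to the
scalar tie-corrected path so both routes agree exactly.

With 3 vs 3 replicates the smallest attainable exact two-sided p is
2/C(6,3) = 0.1, so at alpha = 0.05 the baseline-equivalence criterion can
never exclude a probe at this replication level. The criterion is
implemented as specified and the pipeline emits a warning when it is
vacuous for the given design; it becomes active from 4 vs 4 replicates
(minimum p = 2/70).

## Tunable parameters

| parameter | unit | default | rationale |
|---|---|---|---|
| `alpha` | probability | 0.05 | conventional FDR level of the modeled analysis |
| `tau_stable` | beta (fraction) | 0.025 | stability band of ±2.5 percentage points: changes smaller than array-replicate noise are not biologically interpretable |
| `tau_top` | beta (fraction) | 0.1 | top changes must exceed 10 percentage points of methylation |
| `seed` | integer | 0 | master seed; all stage randomness derives from it |

Percentages in summaries are rounded half-up to one decimal using exact
decimal arithmetic, so printed values are reproducible and independent of
binary float representation.

## Synthetic-data generator

The generator emulates the modeled study's design: two arms × two time
points × 3 replicates, with planted per-probe classes

| class | default fraction | planted effect (beta scale) |
|---|---|---|
| stable | 0.875 | none |
| culture_drift | 0.100 | ±0.1 between time points, both arms |
| btz_hyper | 0.009 | +0.2 in the treated arm only |
| btz_hypo | 0.014 | −0.2 in the treated arm only |
| baseline_divergent | 0.002 | ±0.15 treated-arm offset at both time points |

The mix mirrors the regime of long-term culture experiments: the vast
majority of probes stable, a drifting minority on the order of 10%, and
well under 1% large treatment effects, skewed towards loss of
methylation. Baseline means are drawn from a bimodal mixture — 40%
Beta(2, 18), 40% Beta(18, 2), 20% Uniform(0.05, 0.95) — reproducing the
U-shaped marginal distribution of array betas; baselines that would push
an expected value outside [0, 1] are re-drawn from a feasible window, and
any remaining violation is an error at design time, never a silent clip.

Replicate noise is additive Gaussian on the logit scale (logit-normal,
default latent sd 0.02), chosen because betas are bounded and array noise
is heteroscedastic, shrinking near 0 and 1. A latent sd of 0.02 maps to at
most ~0.005 on the beta scale (at beta = 0.5), a tight-replicate regime
consistent with averaging many beads per probe. The sd parameter is on the
latent scale throughout.

Annotation, peak and gene-set generators plant recoverable enrichment: a
category bias multiplies that category's sampling *probability* for the
chosen class (the remaining categories share the leftover mass), so a 2×
gene-body bias is recovered as a fold change of ≈ 2 against the
background; peak placement covers background probes at one rate and
treatment-responsive probes at a multiplied rate, so a 0.1× multiplier
plants the open-chromatin depletion pattern.

What the generator does **not** emulate: Infinium I/II probe-type
chemistry, chip/batch/position effects, spatial correlation of
neighboring CpGs, probe cross-reactivity, or missingness mechanisms.
Passing recovery tests therefore demonstrates the cascade's statistical
behavior under its own model assumptions — clean replicates, independent
probes, logit-normal noise — not robustness to array artifacts, which
upstream processing is assumed to have handled.

One master seed drives independent named substreams (design, betas,
annotation, peaks, gene sets), so adding a stage never perturbs the draws
of earlier stages and regenerated fixtures are byte-identical for a seed.

## Enrichment

Each category is tested one-vs-rest with a 1-df chi-square goodness of
fit, E = n·K/N, chi2 = (k − E)²/E + ((n−k) − (n−E))²/(n−E) — per-category
tests rather than one omnibus k-category test, because enrichment and
depletion are interpreted per category. This statistic is algebraically
the squared standardized binomial deviation. No continuity correction by
default (counts in intended use are large; a flag enables it). Gene-region
groups are multi-membership: a probe counts once per group it carries, and
probes with no group form an explicit `intergenic` category so memberships
partition; probes with no regulatory feature form `none`. The significance
flag is driven by the raw p at alpha, with BH-FDR across categories
reported alongside. A category absent from the background has an undefined
fold change and is flagged, never reported as infinite.

Probe positions are 1-based (manifest convention); BED peaks are 0-based
half-open; the conversion (pos − 1) happens exactly once, in the overlap
operation. By default a probe chromosome absent from the peak set is an
error listing the unmatched names (catching chr1-vs-1 naming mismatches);
with the strict check off such probes are simply flagged uncovered.

## Gene-set over-representation

Probes map to genes by unique union of their (semicolon-separated)
manifest symbols; how multi-mapped probes should be de-duplicated is not
standardized, and unique union is this package's stated choice. The
background is the genes with ≥ 1 assessed probe. Each set is intersected
with the background and tested with the upper-tail hypergeometric
P(X ≥ k); only enrichment is tested, matching how such results are
interpreted. This replaces web-service over-representation tools with an
offline, testable equivalent that accepts standard GMT input; term-level
results depend on the gene-set snapshot supplied and are not part of the
package's claims.

## Clustering and specificity

Ward linkage on Euclidean distances over raw betas (no z-scoring by
default — the displayed quantity is the methylation fraction itself;
scaling sits behind a flag). Merge ties are broken by the linkage
implementation's deterministic order, so trees are reproducible across
runs; leaf order and merge heights are exported (Newick + text matrix)
alongside the heatmap. Design purity of a k-cluster cut is the fraction
of samples whose cluster's majority (arm, time point) label matches their
own.

The specificity check re-runs the *same* slope/stability code path (no
reimplementation drift) on an independent dataset at the previously
selected probes and reports the fraction stable there; the converse
analysis — the other study's probes evaluated in this data — is the same
function with the datasets swapped. Probes absent from the other matrix
are reported and skipped; no overlap at all is an error.

## Numerical choices

- Beta-matrix writer emits `%.17g` and the reader parses with round-trip
  float precision, so write→read preserves every value bit-exactly.
- BH-FDR delegates to statsmodels' step-up implementation behind the
  package's `bh_fdr` surface; tests pin it to hand-computed step-up values.
- The exact Mann–Whitney null is computed by a subset-sum dynamic program
  and cached per group size; tests pin it to full enumeration.
- Percent rounding: half-up at one decimal via `decimal.Decimal`. One
  published percentage in the modeled study's top-change chain (687 of
  80,049 printed as 0.8%) is not consistent with any standard rounding of
  the ratio (0.858% → 0.9%); the package prints 0.9 and documents the
  discrepancy here rather than reproducing it.

## Problem sizes

The test suite and acceptance script run synthetic studies at 2,000–10,000
probes with 10–20 replicate experiments — sizes at which planted-effect
recovery rates and fold changes are estimated with comfortable margins
while the suite stays fast on a single CPU. Full EPIC scale (~850k probes)
runs through the same vectorized code paths.

## Known limitations

- Two time points only; no dose-response or >2-cycle modeling.
- The baseline-equivalence criterion is toothless at 3 vs 3 replicates
  (see above) — a property of the modeled design, surfaced as a warning.
- FDP control of the final treatment-attributed set inherits BH's
  guarantees per family but the conjunction/complement logic is not a
  formal multiple-testing procedure for the composite null; planted-effect
  recovery is established by simulation, not proof.
- Enrichment backgrounds are not matched for probe density or CpG
  content; permutation nulls are out of scope.
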