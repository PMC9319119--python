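"""Synthetic longitudinal methylation data with planted CpG classes.

Emulates a two-arm (treated / control) x two-time-point x n-replicate
methylation-array experiment.  Each probe is assigned one of five planted
classes:

- ``stable``: no change in either arm;
- ``culture_drift``: the same between-time-point change in both arms
  (what long-term culture does to untreated cells);
- ``btz_hyper`` / ``btz_hypo``: a gain / loss of methylation in the treated
  arm only;
- ``baseline_divergent``: no change over time, but the treated arm sits at
  a different level than controls from the start.

Baseline means are drawn from a bimodal mixture (beta modes near 0.1 and
0.9 plus a uniform component), mimicking the U-shaped beta-value
distribution of methylation arrays.  Replicate noise is additive Gaussian
on the logit scale (logit-normal): beta values stay strictly inside (0, 1)
and noise is naturally heteroscedastic, shrinking near the boundaries as
array noise does.  The ``noise_sd`` parameter is on the latent (logit)
scale.

One master seed drives independent, stage-named substreams, so adding a
stage never perturbs the draws of earlier stages.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import (
    CGI_CATEGORIES,
    GENE_GROUPS,
    INTERGENIC,
    NO_REG_FEATURE,
    BetaMatrix,
    GeneSetCollection,
    IntervalSet,
    ProbeAnnotation,
    SampleSheet,
    ValidationError,
)

CLASSES = ("stable", "culture_drift", "btz_hyper", "btz_hypo", "baseline_divergent")

#: Default planted-class mix: overwhelmingly stable probes, a drifting
#: minority, and a small treatment-responsive fraction skewed towards loss
#: of methylation (hypo > hyper).
DEFAULT_PROPORTIONS: dict[str, float] = {
    "stable": 0.875,
    "culture_drift": 0.100,
    "btz_hyper": 0.009,
    "btz_hypo": 0.014,
    "baseline_divergent": 0.002,
}

DEFAULT_BTZ_DELTA = 0.2      # planted treatment effect, beta scale
DEFAULT_DRIFT_DELTA = 0.1    # planted culture-drift effect, beta scale
DEFAULT_BASELINE_OFFSET = 0.15
DEFAULT_NOISE_SD = 0.02      # replicate noise sd on the logit scale

# EPIC-like marginal frequencies for the synthetic annotation
CGI_WEIGHTS = {"Island": 0.20, "N_Shore": 0.12, "S_Shore": 0.10,
               "N_Shelf": 0.05, "S_Shelf": 0.05, "OpenSea": 0.48}
GENE_GROUP_WEIGHTS = {"TSS1500": 0.13, "TSS200": 0.10, "5UTR": 0.09,
                      "1stExon": 0.05, "Body": 0.38, "3UTR": 0.04,
                      INTERGENIC: 0.21}
REG_FEATURE_WEIGHTS = {NO_REG_FEATURE: 0.70, "Promoter_Associated": 0.12,
                       "Unclassified_Cell_type_specific": 0.06,
                       "NonGene_Associated": 0.04,
                       "Promoter_Associated_Cell_type_specific": 0.04,
                       "Unclassified": 0.04}


def _rng(seed: int, stage: str) -> np.random.Generator:
    """Independent substream for a named stage of the generator."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF,
                               spawn_key=(zlib.crc32(stage.encode()),))
    )


@dataclass
class SyntheticTruth:
    """Planted per-probe ground truth.

    ``table`` is indexed by probe_id with columns planted_class,
    baseline_mean, delta_control, delta_treated, baseline_offset (treated-
    arm shift present at both time points; non-zero only for
    baseline_divergent probes) and noise_sd (latent scale).
    """

    table: pd.DataFrame
    n_replicates: int = 3

    def __post_init__(self) -> None:
        t = self.table
        bad = set(t["planted_class"]) - set(CLASSES)
        if bad:
            raise ValidationError(f"unknown planted class(es): {sorted(bad)}")
        exp_cols = {
            "control I": t["baseline_mean"],
            "control II": t["baseline_mean"] + t["delta_control"],
            "treated I": t["baseline_mean"] + t["baseline_offset"],
            "treated II": t["baseline_mean"] + t["baseline_offset"] + t["delta_treated"],
        }
        for name, vals in exp_cols.items():
            out = (vals < 0) | (vals > 1)
            if out.any():
                pid = t.index[out][0]
                raise ValidationError(
                    f"expected beta outside [0, 1] for {name} at probe {pid!r}: "
                    f"{float(vals[out].iloc[0]):.3f}"
                )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    def classes(self) -> pd.Series:
        return self.table["planted_class"]


def generate_design(n_probes: int,
                    class_proportions: Mapping[str, float] | None = None,
                    n_replicates: int = 3,
                    seed: int = 0,
                    btz_delta: float = DEFAULT_BTZ_DELTA,
                    drift_delta: float = DEFAULT_DRIFT_DELTA,
                    baseline_offset: float = DEFAULT_BASELINE_OFFSET,
                    noise_sd: float = DEFAULT_NOISE_SD) -> SyntheticTruth:
    """Draw a planted truth table for ``n_probes`` CpGs.

    Class counts follow ``class_proportions`` up to rounding (largest-
    remainder apportionment), deterministically for a given seed.  Baseline
    means come from a bimodal mixture: 40% Beta(2, 18) (mode near 0.1),
    40% Beta(18, 2) (mode near 0.9), 20% Uniform(0.05, 0.95); means are
    re-drawn from the uniform component where the planted delta would push
    the expectation outside [0, 1].
    """
    props = dict(DEFAULT_PROPORTIONS if class_proportions is None else class_proportions)
    unknown = set(props) - set(CLASSES)
    if unknown:
        raise ValidationError(f"unknown planted class(es): {sorted(unknown)}")
    for c in CLASSES:
        props.setdefault(c, 0.0)
    total = sum(props.values())
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"class proportions must sum to 1 (got {total!r})")
    if n_replicates < 2:
        raise ValidationError("need n_replicates >= 2")

    # largest-remainder apportionment of n_probes over classes
    raw = {c: props[c] * n_probes for c in CLASSES}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n_probes - sum(counts.values())
    for c in sorted(CLASSES, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1

    rng = _rng(seed, "design")
    classes = np.repeat(list(counts.keys()), list(counts.values()))
    rng.shuffle(classes)

    n = len(classes)
    baseline = _draw_baseline(rng, n)
    delta_control = np.zeros(n)
    delta_treated = np.zeros(n)
    offset = np.zeros(n)

    is_drift = classes == "culture_drift"
    drift_sign = rng.choice([-1.0, 1.0], size=n)
    delta_control[is_drift] = drift_sign[is_drift] * drift_delta
    delta_treated[is_drift] = delta_control[is_drift]  # drift hits both arms

    delta_treated[classes == "btz_hyper"] = btz_delta
    delta_treated[classes == "btz_hypo"] = -btz_delta

    div_sign = rng.choice([-1.0, 1.0], size=n)
    is_div = classes == "baseline_divergent"
    offset[is_div] = div_sign[is_div] * baseline_offset

    # keep every expected cell value inside [0, 1]: re-draw offending
    # baselines from a uniform window that leaves room for the planted shift
    lo = np.maximum(0.0, -np.minimum.reduce([np.zeros(n), delta_control,
                                             delta_treated + offset, offset]))
    hi = 1.0 - np.maximum.reduce([np.zeros(n), delta_control,
                                  delta_treated + offset, offset])
    bad = (baseline < lo + 1e-3) | (baseline > hi - 1e-3)
    baseline[bad] = rng.uniform(lo[bad] + 1e-3, hi[bad] - 1e-3)

    table = pd.DataFrame(
        {
            "planted_class": classes,
            "baseline_mean": baseline,
            "delta_control": delta_control,
            "delta_treated": delta_treated,
            "baseline_offset": offset,
            "noise_sd": noise_sd,
        },
        index=pd.Index([f"cg{i:08d}" for i in range(n)], name="probe_id"),
    )
    return SyntheticTruth(table, n_replicates=n_replicates)


def _draw_baseline(rng: np.random.Generator, n: int) -> np.ndarray:
    comp = rng.choice(3, size=n, p=[0.4, 0.4, 0.2])
    out = np.empty(n)
    out[comp == 0] = rng.beta(2, 18, size=(comp == 0).sum())
    out[comp == 1] = rng.beta(18, 2, size=(comp == 1).sum())
    out[comp == 2] = rng.uniform(0.05, 0.95, size=(comp == 2).sum())
    return np.clip(out, 1e-3, 1 - 1e-3)


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_betas(truth: SyntheticTruth, noise_sd: float | None = None,
                   seed: int = 0) -> tuple[BetaMatrix, SampleSheet]:
    """Simulate replicate beta values from a planted truth table.

    Each cell's expected beta is baseline_mean plus the arm/time-appropriate
    planted shift; replicate noise is drawn on the logit scale and mapped
    back through the logistic function, so emitted values lie strictly
    inside (0, 1).  Deterministic given the seed.
    """
    if noise_sd is None:
        noise_sd = float(truth.table["noise_sd"].iloc[0]) if len(truth.table) else DEFAULT_NOISE_SD
    if noise_sd <= 0:
        raise ValidationError("noise_sd must be > 0")
    t = truth.table
    nrep = truth.n_replicates
    conds = [("treated", "I"), ("treated", "II"), ("control", "I"), ("control", "II")]
    expected = {
        ("control", "I"): t["baseline_mean"].to_numpy(),
        ("control", "II"): (t["baseline_mean"] + t["delta_control"]).to_numpy(),
        ("treated", "I"): (t["baseline_mean"] + t["baseline_offset"]).to_numpy(),
        ("treated", "II"): (t["baseline_mean"] + t["baseline_offset"]
                            + t["delta_treated"]).to_numpy(),
    }
    rng = _rng(seed, "betas")
    cols: list[np.ndarray] = []
    sample_ids: list[str] = []
    rows = []
    for arm, tp in conds:
        mu = np.clip(expected[(arm, tp)], 1e-6, 1 - 1e-6)
        latent = _logit(mu)
        for rep in range(1, nrep + 1):
            noise = rng.normal(0.0, noise_sd, size=len(t))
            cols.append(_expit(latent + noise))
            sample_ids.append(f"{arm}_{tp}_r{rep}")
            rows.append({"sample_id": f"{arm}_{tp}_r{rep}", "arm": arm,
                         "time_point": tp, "replicate": rep})
    values = np.column_stack(cols) if cols else np.empty((0, 0))
    matrix = BetaMatrix(truth.probe_ids, sample_ids, values)
    sheet = SampleSheet(pd.DataFrame(rows).set_index("sample_id"))
    return matrix, sheet


def generate_annotation(truth: SyntheticTruth,
                        enrich_spec: Mapping[str, Mapping[str, Mapping[str, float]]] | None = None,
                        seed: int = 0,
                        n_genes: int = 2000) -> ProbeAnnotation:
    """Draw a manifest-like annotation for the planted probes.

    Categories are sampled from EPIC-like marginal weights; ``enrich_spec``
    maps a planted class to per-scheme category weight multipliers, e.g.
    ``{"btz_hyper": {"gene_group": {"Body": 2.0}}}`` doubles the Body
    sampling weight for that class, planting a ~2x enrichment to be
    recovered downstream.  Gene symbols come from a synthetic universe of
    ``n_genes`` names; intergenic probes carry no genes.
    """
    spec = enrich_spec or {}
    schemes = {"cgi_relation": CGI_WEIGHTS, "gene_group": GENE_GROUP_WEIGHTS,
               "regulatory_feature": REG_FEATURE_WEIGHTS}
    for cls, per_scheme in spec.items():
        if cls not in CLASSES:
            raise ValidationError(f"unknown planted class {cls!r} in enrich_spec")
        for scheme, mults in per_scheme.items():
            if scheme not in schemes:
                raise ValidationError(f"unknown scheme {scheme!r} in enrich_spec")
            unknown = set(mults) - set(schemes[scheme])
            if unknown:
                raise ValidationError(
                    f"unknown categor(ies) {sorted(unknown)} for scheme {scheme!r}"
                )

    rng = _rng(seed, "annotation")
    t = truth.table
    n = len(t)
    classes = t["planted_class"].to_numpy()

    def draw(scheme: str) -> np.ndarray:
        # a bias multiplies the biased categories' sampling *probability*
        # (so the planted fold change vs the base frequency equals the
        # multiplier); unbiased categories share the remaining mass
        base = schemes[scheme]
        cats = list(base)
        base_p = np.array([base[c] for c in cats])
        base_p = base_p / base_p.sum()
        out = np.empty(n, dtype=object)
        for cls in np.unique(classes):
            mults = spec.get(cls, {}).get(scheme, {})
            biased = np.array([mults.get(c, np.nan) for c in cats])
            is_biased = ~np.isnan(biased)
            p = base_p.copy()
            p[is_biased] = base_p[is_biased] * biased[is_biased]
            mass = p[is_biased].sum()
            if mass >= 1.0:
                raise ValidationError(
                    f"bias for class {cls!r} scheme {scheme!r} demands "
                    f"probability mass {mass:.3f} >= 1"
                )
            if (~is_biased).any():
                p[~is_biased] *= (1.0 - mass) / base_p[~is_biased].sum()
            m = classes == cls
            out[m] = rng.choice(cats, size=m.sum(), p=p)
        return out

    cgi = draw("cgi_relation")
    gg = draw("gene_group")
    reg = draw("regulatory_feature")
    gene_universe = [f"GENE{i:05d}" for i in range(n_genes)]
    genes: list[list[str]] = []
    gene_group: list[list[str]] = []
    for i in range(n):
        if gg[i] == INTERGENIC:
            gene_group.append([])
            genes.append([])
        else:
            gene_group.append([gg[i]])
            k = int(rng.integers(1, 3))
            genes.append(sorted(rng.choice(gene_universe, size=k, replace=False)))

    chroms = rng.choice([f"chr{i}" for i in range(1, 23)], size=n)
    pos = rng.integers(1, 200_000_000, size=n)
    table = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "cgi_relation": cgi,
            "gene_group": gene_group,
            "regulatory_feature": reg,
            "genes": genes,
        },
        index=pd.Index(t.index, name="probe_id"),
    )
    return ProbeAnnotation(table)


def generate_peaks(annotation: ProbeAnnotation, truth: SyntheticTruth,
                   background_rate: float = 0.5,
                   btz_rate_multiplier: float = 1.0,
                   seed: int = 0, peak_halfwidth: int = 100) -> IntervalSet:
    """Place open-chromatin peaks over a controlled fraction of probes.

    Background probes land inside a peak with probability
    ``background_rate``; treatment-responsive (btz_*) probes with
    ``background_rate * btz_rate_multiplier`` — a multiplier of 0.1 plants
    the depletion pattern of methylation changes falling in closed
    chromatin.  Each covered probe gets its own peak of +-
    ``peak_halfwidth`` bp around the probe position.
    """
    rate_btz = background_rate * btz_rate_multiplier
    if not 0.0 <= rate_btz <= 1.0 or not 0.0 <= background_rate <= 1.0:
        raise ValidationError("peak coverage rates must lie in [0, 1]")
    rng = _rng(seed, "peaks")
    t = annotation.table
    is_btz = truth.table["planted_class"].reindex(t.index).isin(
        ["btz_hyper", "btz_hypo"]).to_numpy()
    rate = np.where(is_btz, rate_btz, background_rate)
    covered = rng.random(len(t)) < rate
    records = []
    for pid in t.index[covered]:
        pos0 = int(t.at[pid, "pos"]) - 1  # 1-based -> 0-based
        start = max(0, pos0 - peak_halfwidth)
        records.append((t.at[pid, "chrom"], start, pos0 + peak_halfwidth + 1))
    return IntervalSet(records)


def generate_gene_sets(annotation: ProbeAnnotation, truth: SyntheticTruth,
                       n_sets: int = 20, set_size: int = 50,
                       n_enriched: int = 2, enrich_fraction: float = 0.5,
                       seed: int = 0) -> GeneSetCollection:
    """Build a GMT-style collection from the synthetic gene universe.

    The first ``n_enriched`` sets draw ``enrich_fraction`` of their members
    from genes harboring treatment-responsive probes (planted
    over-representation); the remainder are uniform draws.
    """
    rng = _rng(seed, "gene_sets")
    t = annotation.table
    all_genes = sorted({g for gl in t["genes"] for g in gl})
    is_btz = truth.table["planted_class"].reindex(t.index).isin(
        ["btz_hyper", "btz_hypo"]).to_numpy()
    btz_genes = sorted({g for gl in t["genes"][is_btz] for g in gl})
    if not all_genes:
        raise ValidationError("annotation carries no genes")
    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        if i < n_enriched and btz_genes:
            k_btz = min(len(btz_genes), int(round(set_size * enrich_fraction)))
            members = set(rng.choice(btz_genes, size=k_btz, replace=False))
            pool = [g for g in all_genes if g not in members]
            members |= set(rng.choice(pool, size=min(len(pool), set_size - k_btz),
                                      replace=False))
        else:
            members = set(rng.choice(all_genes, size=min(len(all_genes), set_size),
                                     replace=False))
        sets[f"SET{i:03d}"] = sorted(members)
    return GeneSetCollection(sets)
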