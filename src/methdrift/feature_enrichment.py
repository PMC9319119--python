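"""Categorical enrichment of a CpG subset against annotation backgrounds.

For each annotation category (CpG-island relation, gene-region group,
regulatory feature) and for open-chromatin peak membership, the input set
is compared with the assessed background by a one-vs-rest chi-square
goodness-of-fit test with 1 degree of freedom:

    E = n_in * K_bg / N_bg
    chi2 = (k_in - E)^2 / E + ((n_in - k_in) - (n_in - E))^2 / (n_in - E)

together with the fold change fc = (k_in / n_in) / (K_bg / N_bg).  A
per-category test (rather than one omnibus k-category test) is used because
enrichment and depletion are reported per category.

Gene-region groups are a multi-membership scheme: a probe counts once in
every group it carries, and probes with no group form an explicit
``intergenic`` category so the scheme still partitions probe-category
memberships.  Probes with no regulatory feature form the ``none`` category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .core_io import (
    CGI_CATEGORIES,
    GENE_GROUPS,
    INTERGENIC,
    NO_REG_FEATURE,
    IntervalSet,
    ProbeAnnotation,
    ValidationError,
)
from .stability_cascade import bh_fdr

SCHEMES = ("cgi_relation", "gene_group", "regulatory_feature")


@dataclass
class EnrichmentResult:
    """One category's observed/expected comparison.

    ``fc`` is None (flagged via ``fc_undefined``) when the category is
    absent from the background.
    """

    category: str
    k_in: int
    n_in: int
    K_bg: int
    N_bg: int
    fc: float | None
    chi2: float
    p: float
    significant: bool
    fc_undefined: bool = False
    q: float | None = None


def _memberships(annotation: ProbeAnnotation, probes: Sequence[str],
                 scheme: str) -> list[str]:
    """Category memberships of the given probes under one scheme (a probe
    can contribute several memberships under gene_group)."""
    sub = annotation.table.loc[list(probes)]
    if scheme == "cgi_relation":
        return list(sub["cgi_relation"])
    if scheme == "gene_group":
        out: list[str] = []
        for groups in sub["gene_group"]:
            out.extend(groups if groups else [INTERGENIC])
        return out
    if scheme == "regulatory_feature":
        return list(sub["regulatory_feature"])
    raise ValidationError(f"unknown scheme {scheme!r} (expected one of {SCHEMES})")


def _gof_result(category: str, k_in: int, n_in: int, K_bg: int, N_bg: int,
                alpha: float, continuity: bool = False) -> EnrichmentResult:
    if K_bg == 0:
        return EnrichmentResult(category, k_in, n_in, K_bg, N_bg, fc=None,
                                chi2=np.nan, p=np.nan, significant=False,
                                fc_undefined=True)
    expected = n_in * K_bg / N_bg
    fc = (k_in / n_in) / (K_bg / N_bg)
    if expected == 0.0 or expected == n_in:
        # background all-in or all-out of the category: no test possible
        chi2, p = 0.0, 1.0
    else:
        d = abs(k_in - expected)
        if continuity:
            d = max(0.0, d - 0.5)
        chi2 = d**2 / expected + d**2 / (n_in - expected)
        p = float(stats.chi2.sf(chi2, df=1))
    return EnrichmentResult(category, k_in, n_in, K_bg, N_bg, fc=fc,
                            chi2=float(chi2), p=p, significant=bool(p <= alpha))


def category_enrichment(input_probes: Iterable[str],
                        background_probes: Iterable[str],
                        annotation: ProbeAnnotation, scheme: str,
                        alpha: float = 0.05,
                        continuity: bool = False) -> list[EnrichmentResult]:
    """Per-category fold change and goodness-of-fit against the background.

    ``background_probes`` should be all assessed probes; the input must be a
    subset of it.  n_in / N_bg count probe-category memberships, so a probe
    carrying two gene groups contributes twice under that scheme.
    """
    inp = list(dict.fromkeys(input_probes))
    bg = list(dict.fromkeys(background_probes))
    if not inp:
        raise ValidationError("input probe set is empty")
    missing = set(inp) - set(bg)
    if missing:
        raise ValidationError(
            f"input is not a subset of the background: {sorted(missing)[:5]}"
        )
    mem_in = pd.Series(_memberships(annotation, inp, scheme))
    mem_bg = pd.Series(_memberships(annotation, bg, scheme))
    cats = _scheme_categories(scheme, mem_bg)
    n_in, N_bg = len(mem_in), len(mem_bg)
    count_in = mem_in.value_counts()
    count_bg = mem_bg.value_counts()
    results = [
        _gof_result(c, int(count_in.get(c, 0)), n_in, int(count_bg.get(c, 0)),
                    N_bg, alpha, continuity)
        for c in cats
    ]
    tested = [r for r in results if not r.fc_undefined]
    qs = bh_fdr([r.p for r in tested])
    for r, q in zip(tested, qs):
        r.q = float(q)
    return results


def _scheme_categories(scheme: str, bg_memberships: pd.Series) -> list[str]:
    if scheme == "cgi_relation":
        return list(CGI_CATEGORIES)
    if scheme == "gene_group":
        return [*GENE_GROUPS, INTERGENIC]
    # regulatory features are an open vocabulary; use what the background has
    cats = sorted(set(bg_memberships) - {NO_REG_FEATURE})
    return cats + [NO_REG_FEATURE]


def interval_overlap_flags(probes: ProbeAnnotation, peaks: IntervalSet,
                           strict: bool = True) -> pd.Series:
    """True for each probe whose (1-based) position falls inside a peak.

    BED peaks are 0-based half-open, so probe position ``pos`` overlaps a
    peak (chrom, start, end) iff start <= pos - 1 < end; the conversion
    happens here and nowhere else.  With ``strict`` (default), probe
    chromosomes absent from the peak set raise an error listing the
    unmatched names — catching chr1-vs-1 naming mismatches instead of
    silently reporting zero overlap.  With strict off, such probes are
    flagged False.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in peaks.records:
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    t = probes.table
    unmatched = sorted(set(t["chrom"]) - set(trees))
    if strict and unmatched:
        raise ValidationError(
            "probe chromosome(s) absent from the peak set "
            f"(naming mismatch? e.g. chr1 vs 1): {unmatched[:10]}"
        )
    flags = [
        bool(trees[chrom].at(int(pos) - 1)) if chrom in trees else False
        for chrom, pos in zip(t["chrom"], t["pos"])
    ]
    return pd.Series(flags, index=t.index, name="in_peak")


def open_chromatin_enrichment(input_probes: Iterable[str],
                              background_probes: Iterable[str],
                              annotation: ProbeAnnotation, peaks: IntervalSet,
                              alpha: float = 0.05,
                              strict: bool = True) -> EnrichmentResult:
    """Fold change and goodness-of-fit for the single in-peak category."""
    inp = list(dict.fromkeys(input_probes))
    bg = list(dict.fromkeys(background_probes))
    if not inp:
        raise ValidationError("input probe set is empty")
    missing = set(inp) - set(bg)
    if missing:
        raise ValidationError(
            f"input is not a subset of the background: {sorted(missing)[:5]}"
        )
    flags = interval_overlap_flags(annotation.subset(bg), peaks, strict=strict)
    k_in = int(flags.loc[inp].sum())
    K_bg = int(flags.sum())
    return _gof_result("open_chromatin", k_in, len(inp), K_bg, len(bg), alpha)


def enrichment_table(results: dict[str, list[EnrichmentResult]]) -> pd.DataFrame:
    """Flatten per-scheme results into one tidy DataFrame."""
    rows = []
    for scheme, res in results.items():
        for r in res:
            rows.append({
                "scheme": scheme, "category": r.category, "k_in": r.k_in,
                "n_in": r.n_in, "K_bg": r.K_bg, "N_bg": r.N_bg, "fc": r.fc,
                "chi2": r.chi2, "p": r.p, "q": r.q, "significant": r.significant,
            })
    return pd.DataFrame(rows)
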