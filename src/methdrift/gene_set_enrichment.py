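"""Hypergeometric over-representation of genes harboring selected CpGs.

Probes map to genes by unique union of their manifest gene symbols; the
background is the set of genes with at least one assessed probe.  Each gene
set is intersected with the background and tested with the upper-tail
hypergeometric probability P(X >= k) (population N = background genes,
K = set size within background, n = input genes, k = overlap), followed by
BH-FDR across all tested sets.  Only enrichment is tested; sets with no
background gene are skipped and reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from scipy import stats

from .core_io import GeneSetCollection, ProbeAnnotation, ValidationError
from .stability_cascade import bh_fdr

logger = logging.getLogger(__name__)


@dataclass
class GeneSetResult:
    name: str
    k: int   # overlap
    K: int   # set size within background
    n: int   # input genes within background
    N: int   # background genes
    p: float
    q: float | None = None


def probes_to_genes(probes: Iterable[str], annotation: ProbeAnnotation) -> set[str]:
    """Unique union of gene symbols over the given probes; probes with an
    empty gene list contribute nothing."""
    sub = annotation.subset(list(dict.fromkeys(probes)))
    return {g for genes in sub.table["genes"] for g in genes}


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ora_test(input_genes: Iterable[str], gene_sets: GeneSetCollection,
             background: Iterable[str], alpha: float = 0.05) -> list[GeneSetResult]:
    """Over-representation test of the input genes in every gene set.

    Raises when an input gene is not in the background (the background must
    be the gene universe the input was derived from).
    """
    inp = set(input_genes)
    bg = set(background)
    outside = inp - bg
    if outside:
        raise ValidationError(
            f"input gene(s) outside the background: {sorted(outside)[:5]}"
        )
    N, n = len(bg), len(inp)
    results: list[GeneSetResult] = []
    for name, genes in gene_sets.sets.items():
        in_bg = set(genes) & bg
        K = len(in_bg)
        if K == 0:
            logger.info("gene set %s has no background gene; skipped", name)
            continue
        k = len(in_bg & inp)
        results.append(GeneSetResult(name, k, K, n, N,
                                     p=hypergeom_upper_tail(k, N, K, n)))
    qs = bh_fdr([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results
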