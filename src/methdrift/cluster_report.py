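"""Hierarchical clustering of selected CpGs, cross-dataset specificity,
and run-report assembly.

Clustering is agglomerative Ward linkage on Euclidean distances over raw
beta values (no z-scoring by default, since the displayed quantity is the
methylation fraction itself).  The specificity check re-runs the cascade's
slope/stability criteria on an independent dataset at the previously
selected probes, and reports the fraction that remain stable there; the
converse check (their probes evaluated in our data) is the same function
with the roles of the datasets swapped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core_io import BetaMatrix, PipelineConfig, SampleSheet, ValidationError
from .stability_cascade import bh_fdr, fit_slopes


@dataclass
class ClusterTree:
    """Ward merge history over one axis of a beta matrix.

    ``linkage`` is the (n-1) x 4 scipy linkage matrix (children ids,
    merge height, cluster size); ``leaf_order`` the dendrogram leaf order.
    """

    linkage: np.ndarray
    labels: list[str]
    axis: str
    method: str = "ward"

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.linkage.shape != (n - 1, 4):
            raise ValidationError(
                f"linkage shape {self.linkage.shape} inconsistent with {n} leaves"
            )
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-10):
            raise ValidationError("merge heights must be non-decreasing (ultrametric)")

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, k: int) -> pd.Series:
        """Assign each leaf to one of k flat clusters."""
        if k > len(self.labels):
            raise ValidationError(f"cannot cut {len(self.labels)} leaves into {k} clusters")
        assign = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(assign, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        """Serialize the merge history as a Newick string with heights as
        branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


def ward_cluster(matrix: BetaMatrix, axis: str = "samples") -> ClusterTree:
    """Ward/Euclidean agglomerative clustering of samples or probes.

    Requires complete data on the clustered probes; callers must exclude or
    impute probes with missing betas first.
    """
    if axis not in ("samples", "probes"):
        raise ValidationError(f"axis must be 'samples' or 'probes', got {axis!r}")
    if matrix.missing_mask.any():
        raise ValidationError(
            "matrix has missing beta values; exclude or impute the affected "
            "probes before clustering"
        )
    data = matrix.values.T if axis == "samples" else matrix.values
    labels = matrix.sample_ids if axis == "samples" else matrix.probe_ids
    if data.shape[0] < 2:
        raise ValidationError("need at least 2 items on the clustered axis")
    linkage = hierarchy.linkage(pdist(data, metric="euclidean"), method="ward")
    return ClusterTree(linkage, list(labels), axis)


def treatment_separation_score(tree: ClusterTree, sheet: SampleSheet,
                               k: int = 2) -> float:
    """Purity of a k-cluster cut with respect to (arm, time point) labels.

    Purity is the fraction of samples whose cluster's majority design label
    matches their own; 1.0 means the cut separates the design groups
    perfectly.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    clusters = tree.cut(k)
    labels = sheet.table.loc[clusters.index]
    design = labels["arm"].astype(str) + "/" + labels["time_point"].astype(str)
    correct = 0
    for c in clusters.unique():
        members = design[clusters == c]
        correct += int((members == members.mode().iloc[0]).sum())
    return correct / len(clusters)


def cross_dataset_specificity(probes: Sequence[str], other_matrix: BetaMatrix,
                              other_sheet: SampleSheet, config: PipelineConfig,
                              arm: str = "treated") -> tuple[float, pd.DataFrame]:
    """Evaluate previously selected probes in an independent experiment.

    Runs the cascade's slope test (same code path) on the other dataset's
    ``arm`` at the overlapping probes and applies the stability criteria
    (BH-FDR q > alpha and |slope| <= tau_stable).  Returns the fraction of
    evaluable probes classified stable plus the per-probe table (including
    the skipped, non-overlapping probes).
    """
    probes = list(dict.fromkeys(probes))
    if not probes:
        raise ValidationError("probe set is empty")
    present = [p for p in probes if p in set(other_matrix.probe_ids)]
    missing = [p for p in probes if p not in set(other_matrix.probe_ids)]
    if not present:
        raise ValidationError(
            f"no overlap between the probe set and the other matrix "
            f"(first missing: {missing[:5]})"
        )
    sub = other_matrix.subset_probes(present)
    res = fit_slopes(sub, other_sheet, arm)
    tested = res[~res["excluded_missing"]].copy()
    tested["q"] = bh_fdr(tested["p"].to_numpy())
    tested["stable"] = (tested["q"] > config.alpha) & (
        tested["slope"].abs() <= config.tau_stable
    )
    fraction = float(tested["stable"].mean())
    table = tested.reindex(probes)
    table["skipped_missing"] = table.index.isin(missing)
    return fraction, table


def heatmap_export(matrix: BetaMatrix, sample_tree: ClusterTree,
                   probe_tree: ClusterTree | None, out_prefix: str | Path,
                   fmt: str = "png") -> Path:
    """Render the selected-probe heatmap in tree leaf order, plus a
    plain-text matrix dump (same ordering) for diffing."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sample_order = sample_tree.leaf_order
    probe_order = probe_tree.leaf_order if probe_tree else matrix.probe_ids
    frame = matrix.to_frame().loc[probe_order, sample_order]
    out_prefix = Path(out_prefix)
    frame.to_csv(out_prefix.with_suffix(".tsv"), sep="\t")
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(sample_order)), 6))
    im = ax.imshow(frame.to_numpy(), aspect="auto", cmap="RdYlBu_r",
                   vmin=0.0, vmax=1.0)
    ax.set_xticks(range(len(sample_order)), sample_order, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_ylabel(f"{len(probe_order)} CpGs")
    fig.colorbar(im, ax=ax, label="beta")
    fig.tight_layout()
    img = out_prefix.with_suffix(f".{fmt}")
    fig.savefig(img, dpi=150)
    plt.close(fig)
    return img


def build_report(*, summary: dict, enrichment: pd.DataFrame | None,
                 ora: pd.DataFrame | None, purity: float | None,
                 specificity: float | None, config: PipelineConfig,
                 skipped_stages: Sequence[str] = ()) -> dict:
    """Assemble the machine-readable run report.

    Deterministic for identical inputs: no timestamps; configuration and
    versions are echoed so a report identifies its run exactly.
    """
    import methdrift

    for name, value in (("summary", summary),):
        if value is None:
            raise ValidationError(f"missing stage output: {name}")
    report = {
        "config": {"alpha": config.alpha, "tau_stable": config.tau_stable,
                   "tau_top": config.tau_top, "seed": config.seed},
        "versions": {"methdrift": methdrift.__version__},
        "summary": summary,
        "enrichment": enrichment.to_dict(orient="records") if enrichment is not None else None,
        "gene_set_ora": ora.to_dict(orient="records") if ora is not None else None,
        "clustering_purity": purity,
        "specificity_fraction_stable": specificity,
        "skipped_stages": list(skipped_stages),
    }
    return report


def report_to_markdown(report: dict) -> str:
    """Human-readable rendering of a run report."""
    s = report["summary"]
    lines = [
        "# methdrift run report",
        "",
        "## Cascade counts",
        f"- assessed probes: {s['total_assessed']}"
        + (f" ({s['n_excluded_missing']} dropped for missing values)"
           if s.get("n_excluded_missing") else ""),
        f"- stable in controls: {s['n_control_stable']} ({s['pct_control_stable']}%)",
        f"- excluded as culture-affected: {s['n_culture_excluded']}",
        f"- unchanged under treatment: {s['n_unchanged']} ({s['pct_unchanged']}%)",
        f"- attributed to treatment: {s['n_btz_affected']}"
        + (f" ({s['pct_hypomethylated']}% hypomethylated)"
           if s.get("pct_hypomethylated") is not None else ""),
        f"- top changes (|slope| > {report['config']['tau_top']}): {s['n_top']} "
        f"({s['n_top_gain']} gain, {s['n_top_loss']} loss)",
        "",
    ]
    if report.get("clustering_purity") is not None:
        lines += [f"## Clustering", f"- 2-cluster design purity: {report['clustering_purity']:.3f}", ""]
    if report.get("specificity_fraction_stable") is not None:
        lines += ["## Cross-dataset specificity",
                  f"- fraction stable in the other dataset: "
                  f"{report['specificity_fraction_stable']:.3f}", ""]
    if report.get("skipped_stages"):
        lines += ["## Skipped stages", *(f"- {st}" for st in report["skipped_stages"]), ""]
    return "\n".join(lines)


def write_report(report: dict, out_dir: str | Path) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / "report.json"
    md_path = out_dir / "report.md"
    json_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    md_path.write_text(report_to_markdown(report))
    return json_path, md_path
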