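"""Data model and file I/O for the pipeline.

Containers wrap pandas objects and enforce the domain constraints on
construction, so every downstream stage can assume a validated object:
beta values in [0, 1], unique probe/sample identifiers, a complete
two-arm / two-time-point design, half-open BED intervals, non-empty gene
sets.  Malformed input always raises :class:`ValidationError`; no reader
returns a partially loaded object.

Coordinate conventions: annotation positions are 1-based (Illumina manifest
convention); BED intervals are 0-based half-open.  Conversion between the
two happens exactly once, inside the interval-overlap operation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ARMS = ("treated", "control")
TIME_POINTS = ("I", "II")

CGI_CATEGORIES = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")
GENE_GROUPS = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR")
INTERGENIC = "intergenic"
NO_REG_FEATURE = "none"


class ValidationError(ValueError):
    """Raised when an input file or object violates a domain constraint."""


@dataclass
class BetaMatrix:
    """Probe x sample matrix of methylation fractions (beta values).

    ``values`` is a float array of shape (n_probes, n_samples); missing
    entries are NaN and tracked by :attr:`missing_mask`.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        dup = _duplicates(self.probe_ids)
        if dup:
            raise ValidationError(f"duplicate probe id(s): {sorted(dup)[:5]}")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise ValidationError(f"duplicate sample id(s): {sorted(dup)[:5]}")
        bad = np.argwhere(
            ~np.isnan(self.values) & ((self.values < 0.0) | (self.values > 1.0))
        )
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"beta value out of [0, 1] at probe {self.probe_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}: {self.values[i, j]}"
            )

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    def subset_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        idx = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in probe_ids if p not in idx]
        if missing:
            raise ValidationError(f"probe id(s) not in matrix: {missing[:5]}")
        rows = [idx[p] for p in probe_ids]
        return BetaMatrix(list(probe_ids), list(self.sample_ids), self.values[rows])

    def sample_columns(self, sample_ids: Sequence[str]) -> np.ndarray:
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise ValidationError(f"sample id(s) not in matrix: {missing[:5]}")
        return self.values[:, [idx[s] for s in sample_ids]]


@dataclass
class SampleSheet:
    """Maps each sample to (arm, time_point, replicate).

    ``table`` is indexed by sample_id with columns arm, time_point,
    replicate.  Every (arm, time_point) cell must hold at least two samples
    so that a residual variance is estimable.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"arm", "time_point", "replicate"}
        if not required.issubset(self.table.columns):
            raise ValidationError(
                f"sample sheet missing column(s): {sorted(required - set(self.table.columns))}"
            )
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample id(s) in sheet: {dups[:5]}")
        bad_arm = set(self.table["arm"]) - set(ARMS)
        if bad_arm:
            raise ValidationError(f"unknown arm token(s): {sorted(bad_arm)} (expected {ARMS})")
        bad_tp = set(self.table["time_point"]) - set(TIME_POINTS)
        if bad_tp:
            raise ValidationError(
                f"unknown time_point token(s): {sorted(bad_tp)} (expected {TIME_POINTS})"
            )
        reps = pd.to_numeric(self.table["replicate"], errors="coerce")
        if reps.isna().any() or (reps < 1).any():
            raise ValidationError("replicate must be a positive integer for every sample")
        counts = self.table.groupby(["arm", "time_point"], observed=True).size()
        for arm in ARMS:
            for tp in TIME_POINTS:
                n = counts.get((arm, tp), 0)
                if n < 2:
                    raise ValidationError(
                        f"design cell ({arm}, time point {tp}) has {n} sample(s); "
                        "at least 2 are required for variance estimation"
                    )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples(self, arm: str, time_point: str | None = None) -> list[str]:
        sel = self.table["arm"] == arm
        if time_point is not None:
            sel &= self.table["time_point"] == time_point
        return list(self.table.index[sel])

    def time_codes(self, arm: str) -> tuple[list[str], np.ndarray]:
        """Samples of one arm with their 0/1 time codes (I -> 0, II -> 1)."""
        ids = self.samples(arm)
        codes = (self.table.loc[ids, "time_point"] == "II").to_numpy(dtype=float)
        return ids, codes

    def check_matrix(self, matrix: BetaMatrix) -> None:
        sheet_ids = set(self.table.index)
        mat_ids = set(matrix.sample_ids)
        if sheet_ids != mat_ids:
            raise ValidationError(
                f"sample sheet / matrix mismatch: only in sheet {sorted(sheet_ids - mat_ids)[:5]}, "
                f"only in matrix {sorted(mat_ids - sheet_ids)[:5]}"
            )


@dataclass
class ProbeAnnotation:
    """Per-probe genomic annotation (Illumina-manifest-like).

    ``table`` is indexed by probe_id with columns chrom, pos (1-based),
    cgi_relation (one of six categories), gene_group (list of group strings,
    empty for intergenic probes), regulatory_feature (string, ``"none"``
    when absent) and genes (list of symbols, possibly empty).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "cgi_relation", "gene_group", "regulatory_feature", "genes"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"annotation missing column(s): {sorted(missing)}")
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise ValidationError(f"duplicate probe id(s) in annotation: {dups[:5]}")
        bad = set(self.table["cgi_relation"]) - set(CGI_CATEGORIES)
        if bad:
            raise ValidationError(f"unknown cgi_relation categor(ies): {sorted(bad)}")
        pos = pd.to_numeric(self.table["pos"], errors="coerce")
        if pos.isna().any() or (pos < 1).any():
            raise ValidationError("annotation pos must be a 1-based integer >= 1")
        for pid, groups in self.table["gene_group"].items():
            unknown = set(groups) - set(GENE_GROUPS)
            if unknown:
                raise ValidationError(f"unknown gene_group {sorted(unknown)} at probe {pid!r}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    def subset(self, probe_ids: Iterable[str]) -> "ProbeAnnotation":
        ids = list(probe_ids)
        missing = [p for p in ids if p not in self.table.index]
        if missing:
            raise ValidationError(f"probe id(s) not annotated: {missing[:5]}")
        return ProbeAnnotation(self.table.loc[ids])


@dataclass
class IntervalSet:
    """Genomic intervals in 0-based half-open (BED) coordinates."""

    records: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        for i, (chrom, start, end) in enumerate(self.records):
            if start < 0:
                raise ValidationError(f"record {i}: negative start {start}")
            if start >= end:
                raise ValidationError(
                    f"record {i} ({chrom}:{start}-{end}): start must be < end"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def chroms(self) -> set[str]:
        return {c for c, _, _ in self.records}


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style); names unique, sets non-empty."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class PipelineConfig:
    """Tunable thresholds of the cascade.

    alpha: FDR significance level for all three test families (default 0.05).
    tau_stable: stability bound on |slope| on the beta scale (default 0.025).
    tau_top: top-change bound on |slope|, strict inequality (default 0.1,
        i.e. a methylation change of more than 10 percentage points).
    seed: master seed for every stochastic stage.
    """

    alpha: float = 0.05
    tau_stable: float = 0.025
    tau_top: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.tau_stable < self.tau_top:
            raise ValidationError(
                f"need 0 < tau_stable < tau_top, got {self.tau_stable}, {self.tau_top}"
            )


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


# ---------------------------------------------------------------- readers

def read_beta_matrix(path: str | Path, dialect: str = "tsv") -> BetaMatrix:
    """Read a probe x sample beta matrix (first column probe ids, header
    row sample ids).  ``dialect`` is ``"tsv"`` or ``"csv"``; no sniffing."""
    sep = _sep(dialect)
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric beta value in {path}: {exc}") from exc
    return BetaMatrix(
        [str(p) for p in df.index], [str(s) for s in df.columns], values
    )


def write_beta_matrix(matrix: BetaMatrix, path: str | Path, dialect: str = "tsv") -> None:
    # %.17g round-trips every IEEE double bit-exactly
    matrix.to_frame().to_csv(path, sep=_sep(dialect), index_label="probe_id",
                             float_format="%.17g")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a CSV sample sheet with columns sample_id, arm, time_point,
    replicate."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path, dtype={"sample_id": str, "arm": str, "time_point": str})
    if "sample_id" not in df.columns:
        raise ValidationError(f"sample sheet {path} lacks a sample_id column")
    return SampleSheet(df.set_index("sample_id"))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, index_label="sample_id")


def read_annotation(path: str | Path) -> ProbeAnnotation:
    """Read a probe-annotation CSV with manifest-style columns.

    Expected columns: probe_id, CHR, MAPINFO, cgi_relation, gene_group
    (semicolon-separated, may be blank), regulatory_feature (may be blank),
    genes (semicolon-separated, may be blank).
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"probe_id", "CHR", "MAPINFO", "cgi_relation", "gene_group",
                "regulatory_feature", "genes"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"annotation {path} missing column(s): {sorted(missing)}")
    table = pd.DataFrame(
        {
            "chrom": df["CHR"].to_numpy(),
            "pos": pd.to_numeric(df["MAPINFO"], errors="coerce").to_numpy(),
            "cgi_relation": df["cgi_relation"].to_numpy(),
            "gene_group": [_split_semicolon(s) for s in df["gene_group"]],
            "regulatory_feature": [
                s if s else NO_REG_FEATURE for s in df["regulatory_feature"]
            ],
            "genes": [_split_semicolon(s) for s in df["genes"]],
        },
        index=pd.Index(df["probe_id"], name="probe_id"),
    )
    return ProbeAnnotation(table)


def write_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    t = annotation.table
    out = pd.DataFrame(
        {
            "probe_id": t.index,
            "CHR": t["chrom"].to_numpy(),
            "MAPINFO": t["pos"].to_numpy(),
            "cgi_relation": t["cgi_relation"].to_numpy(),
            "gene_group": [";".join(g) for g in t["gene_group"]],
            "regulatory_feature": [
                "" if r == NO_REG_FEATURE else r for r in t["regulatory_feature"]
            ],
            "genes": [";".join(g) for g in t["genes"]],
        }
    )
    out.to_csv(path, index=False)


def _split_semicolon(s: str) -> list[str]:
    return [tok for tok in str(s).split(";") if tok] if s else []


def read_bed(path: str | Path) -> IntervalSet:
    """Read a BED3+ file (0-based half-open); extra columns are ignored."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    records: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0:
                raise ValidationError(f"{path}:{lineno}: negative start {start}")
            if start >= end:
                raise ValidationError(
                    f"{path}:{lineno}: start {start} must be < end {end}"
                )
            records.append((chrom, start, end))
    return IntervalSet(records)


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals.records:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line set name, description, then gene symbols."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs name, description and >= 1 gene"
                )
            name = parts[0]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            genes = [g for g in parts[2:] if g]
            if not genes:
                raise ValidationError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets[name] = genes
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def _sep(dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise ValidationError(f"unknown dialect {dialect!r} (expected 'tsv' or 'csv')")
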