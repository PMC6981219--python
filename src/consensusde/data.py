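"""Core data types and file I/O for counts, designs, annotation, and results.

Conventions used throughout the package:

* Counts are raw nonnegative integers, genes in rows, samples in columns.
  Expected-count matrices (non-integral) are rejected, not rounded, so the
  count-model assumptions stay explicit.
* The condition reference level is the first declared label (control);
  log2 fold changes are treatment minus control everywhere.
* Gene order is preserved from input everywhere; nothing re-sorts silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AnnotationError, DesignError, IdentifierError, StructuralError

__all__ = [
    "CountMatrix",
    "StudyDesign",
    "GeneAnnotation",
    "DEResult",
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "gene_lengths_from_gtf",
    "read_gene_lengths",
    "write_gene_lengths",
    "write_de_table",
    "read_de_table",
]


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: dict[str, int] = {}
    for i, x in enumerate(ids):
        if x in seen:
            raise IdentifierError(f"duplicate {kind} id {x!r} (positions {seen[x]} and {i})")
        seen[x] = i


@dataclass
class CountMatrix:
    """Gene x sample matrix of raw read counts.

    Parameters
    ----------
    gene_ids, sample_ids
        Unique identifiers for rows and columns.
    counts
        Nonnegative integer array of shape ``(n_genes, n_samples)``.
    gene_lengths_bp
        Optional per-gene collapsed transcript length in base pairs,
        required only by length-aware normalizations (RPKM).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    gene_lengths_bp: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise StructuralError(
                f"counts shape {arr.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        farr = arr.astype(float)
        if np.any(~np.isfinite(farr)):
            g, s = np.argwhere(~np.isfinite(farr))[0]
            raise ValueError(
                f"non-finite count at gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )
        if np.any(farr < 0):
            g, s = np.argwhere(farr < 0)[0]
            raise ValueError(
                f"negative count at gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )
        if np.any(farr != np.rint(farr)):
            g, s = np.argwhere(farr != np.rint(farr))[0]
            raise ValueError(
                f"non-integer count at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}: {arr[g, s]!r}"
            )
        self.counts = farr.astype(np.int64)
        if self.gene_lengths_bp is not None:
            lengths = np.asarray(self.gene_lengths_bp)
            if lengths.shape != (len(self.gene_ids),):
                raise AnnotationError("gene_lengths_bp must hold one value per gene")
            if np.any(lengths <= 0) or np.any(lengths != np.rint(lengths)):
                bad = self.gene_ids[int(np.argwhere((lengths <= 0) | (lengths != np.rint(lengths)))[0][0])]
                raise AnnotationError(f"gene length for {bad!r} is not a positive integer")
            self.gene_lengths_bp = lengths.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def library_sizes(self) -> np.ndarray:
        """Per-sample total counts."""
        return self.counts.sum(axis=0)

    def with_lengths(self, lengths: Mapping[str, int]) -> "CountMatrix":
        """Return a copy annotated with gene lengths taken from a mapping."""
        missing = [g for g in self.gene_ids if g not in lengths]
        if missing:
            raise AnnotationError(f"no length for gene {missing[0]!r} ({len(missing)} missing)")
        return CountMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(self.sample_ids),
            counts=self.counts.copy(),
            gene_lengths_bp=np.array([lengths[g] for g in self.gene_ids]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class StudyDesign:
    """Two-group sample assignment.

    The first distinct label encountered in ``condition`` is taken as the
    reference (control) level; the second is the treatment level.
    """

    sample_ids: list[str]
    condition: list[str]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.condition = [str(c) for c in self.condition]
        _check_unique(self.sample_ids, "sample")
        if len(self.condition) != len(self.sample_ids):
            raise DesignError("condition must hold one label per sample")
        levels = list(dict.fromkeys(self.condition))
        if len(levels) != 2:
            raise DesignError(f"exactly two condition levels required, got {levels!r}")
        for lev in levels:
            n = sum(c == lev for c in self.condition)
            if n < 2:
                raise DesignError(f"condition level {lev!r} has {n} sample(s); need >= 2")
        self._levels = levels

    @property
    def levels(self) -> tuple[str, str]:
        """(control, treatment) labels in declared order."""
        return (self._levels[0], self._levels[1])

    @property
    def control_mask(self) -> np.ndarray:
        return np.array([c == self._levels[0] for c in self.condition])

    @property
    def treatment_mask(self) -> np.ndarray:
        return np.array([c == self._levels[1] for c in self.condition])

    @property
    def group_indicator(self) -> np.ndarray:
        """0 for control samples, 1 for treatment samples."""
        return self.treatment_mask.astype(int)

    def aligned_to(self, counts: CountMatrix) -> "StudyDesign":
        """Return this design reordered to the sample order of ``counts``.

        Raises if the sample sets differ in either direction.
        """
        lookup = {s: c for s, c in zip(self.sample_ids, self.condition)}
        missing = [s for s in counts.sample_ids if s not in lookup]
        if missing:
            raise IdentifierError(f"design has no entry for sample {missing[0]!r}")
        extra = [s for s in self.sample_ids if s not in set(counts.sample_ids)]
        if extra:
            raise IdentifierError(f"design sample {extra[0]!r} absent from count matrix")
        return StudyDesign(
            sample_ids=list(counts.sample_ids),
            condition=[lookup[s] for s in counts.sample_ids],
        )


@dataclass
class GeneAnnotation:
    """Collapsed exon structure of one gene.

    ``merged_exon_intervals`` are non-overlapping, sorted, 1-based inclusive
    genomic intervals; ``collapsed_length_bp`` is the total number of bases
    they cover.
    """

    gene_id: str
    merged_exon_intervals: list[tuple[int, int]]
    collapsed_length_bp: int

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for start, end in self.merged_exon_intervals:
            if end < start:
                raise AnnotationError(f"gene {self.gene_id!r}: interval ({start},{end}) has end < start")
            if start <= prev_end:
                raise AnnotationError(f"gene {self.gene_id!r}: intervals overlap or are unsorted")
            prev_end = end
        covered = sum(end - start + 1 for start, end in self.merged_exon_intervals)
        if covered != self.collapsed_length_bp:
            raise AnnotationError(
                f"gene {self.gene_id!r}: collapsed_length_bp {self.collapsed_length_bp} "
                f"!= covered span {covered}"
            )


@dataclass
class DEResult:
    """Per-gene differential-expression results for one grid cell."""

    normalization: str
    model: str
    gene_ids: list[str]
    log2_fold_change: np.ndarray
    statistic: np.ndarray
    p_value: np.ndarray
    q_value: np.ndarray
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        self.log2_fold_change = np.asarray(self.log2_fold_change, dtype=float)
        self.statistic = np.asarray(self.statistic, dtype=float)
        self.p_value = np.asarray(self.p_value, dtype=float)
        self.q_value = np.asarray(self.q_value, dtype=float)
        for name in ("log2_fold_change", "statistic", "p_value", "q_value"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise StructuralError(f"{name} must have one value per gene")
        for name in ("p_value", "q_value"):
            arr = getattr(self, name)
            if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
                raise ValueError(f"{name} outside [0, 1]")
        if not self.flags:
            self.flags = [""] * n
        elif len(self.flags) != n:
            raise StructuralError("flags must hold one entry per gene")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "log2FC": self.log2_fold_change,
                "stat": self.statistic,
                "pvalue": self.p_value,
                "qvalue": self.q_value,
            }
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _mtx_sidecars(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(str(stem) + ".genes.txt"), Path(str(stem) + ".samples.txt")


def read_counts(path: str | Path, format: str = "tsv") -> CountMatrix:
    """Read a count matrix from TSV or MatrixMarket coordinate format.

    TSV layout: header row of sample ids, first column of gene ids.
    MTX layout: a ``.mtx`` file with sidecar ``<stem>.genes.txt`` and
    ``<stem>.samples.txt`` files holding one identifier per line.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return CountMatrix(
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            counts=df.to_numpy(),
        )
    if format == "mtx":
        from scipy.io import mmread

        genes_path, samples_path = _mtx_sidecars(path)
        for p in (genes_path, samples_path):
            if not p.exists():
                raise FileNotFoundError(f"MTX sidecar id file missing: {p}")
        mat = np.asarray(mmread(str(path)).todense())
        gene_ids = genes_path.read_text().split()
        sample_ids = samples_path.read_text().split()
        return CountMatrix(gene_ids=gene_ids, sample_ids=sample_ids, counts=mat)
    raise ValueError(f"unknown counts format {format!r} (expected 'tsv' or 'mtx')")


def write_counts(cm: CountMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write a count matrix; inverse of :func:`read_counts`."""
    path = Path(path)
    if format == "tsv":
        cm.to_frame().to_csv(path, sep="\t", index_label="gene_id")
        return
    if format == "mtx":
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix

        mmwrite(str(path), coo_matrix(cm.counts))
        genes_path, samples_path = _mtx_sidecars(path)
        genes_path.write_text("\n".join(cm.gene_ids) + "\n")
        samples_path.write_text("\n".join(cm.sample_ids) + "\n")
        return
    raise ValueError(f"unknown counts format {format!r} (expected 'tsv' or 'mtx')")


def read_design(path: str | Path) -> StudyDesign:
    """Read a two-column (sample_id, condition) TSV into a validated design."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise DesignError(f"design file {path} needs two columns (sample_id, condition)")
    return StudyDesign(
        sample_ids=[str(s) for s in df.iloc[:, 0]],
        condition=[str(c) for c in df.iloc[:, 1]],
    )


def write_design(design: StudyDesign, path: str | Path) -> None:
    pd.DataFrame({"sample_id": design.sample_ids, "condition": design.condition}).to_csv(
        path, sep="\t", index=False
    )


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals as a sorted non-overlapping list."""
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def gene_lengths_from_gtf(path: str | Path) -> dict[str, int]:
    """Collapsed gene lengths from a GTF annotation.

    Exons of all isoforms of a gene are merged (union of intervals) and the
    covered length in bp is returned — the merged-isoform ("collapsed")
    length. Strand is ignored. Genes that appear in the file but have no
    exon features are excluded with a warning.
    """
    import gffutils

    # pre-scan coordinates: gffutils is lenient about inverted intervals
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 5 and int(fields[4]) < int(fields[3]):
                raise AnnotationError(
                    f"{path} line {lineno}: end {fields[4]} < start {fields[3]}"
                )

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons_by_gene: dict[str, list[tuple[int, int]]] = {}
    declared_genes: list[str] = []
    for feat in db.all_features():
        gid_attr = feat.attributes.get("gene_id")
        if not gid_attr:
            continue
        gid = gid_attr[0]
        if feat.featuretype == "exon":
            if feat.end < feat.start:
                raise AnnotationError(
                    f"gene {gid!r}: exon ({feat.start},{feat.end}) has end < start"
                )
            exons_by_gene.setdefault(gid, []).append((feat.start, feat.end))
        elif gid not in declared_genes:
            declared_genes.append(gid)
    for gid in declared_genes:
        if gid not in exons_by_gene:
            warnings.warn(f"gene {gid!r} has no exon features; excluded from lengths")
    lengths: dict[str, int] = {}
    for gid, exons in exons_by_gene.items():
        merged = merge_intervals(exons)
        lengths[gid] = sum(e - s + 1 for s, e in merged)
    return lengths


def read_gene_lengths(path: str | Path) -> dict[str, int]:
    """Read a two-column (gene_id, length_bp) TSV into a mapping."""
    df = pd.read_csv(path, sep="\t")
    return {str(g): int(v) for g, v in zip(df.iloc[:, 0], df.iloc[:, 1])}


def write_gene_lengths(cm: CountMatrix, path: str | Path) -> None:
    if cm.gene_lengths_bp is None:
        raise AnnotationError("count matrix has no gene lengths to write")
    pd.DataFrame({"gene_id": cm.gene_ids, "length_bp": cm.gene_lengths_bp}).to_csv(
        path, sep="\t", index=False
    )


def write_de_table(result: DEResult, path: str | Path) -> None:
    """Write one grid cell's results as TSV (gene order preserved)."""
    result.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_de_table(path: str | Path, normalization: str = "", model: str = "") -> DEResult:
    """Read a TSV written by :func:`write_de_table`."""
    df = pd.read_csv(path, sep="\t")
    return DEResult(
        normalization=normalization,
        model=model,
        gene_ids=[str(g) for g in df["gene_id"]],
        log2_fold_change=df["log2FC"].to_numpy(),
        statistic=df["stat"].to_numpy(),
        p_value=df["pvalue"].to_numpy(),
        q_value=df["qvalue"].to_numpy(),
    )
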