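"""Readers/writers for the external formats the pipeline touches.

Formats
-------
- per-cell x per-variant mitochondrial allele counts: long-format TSV with
  columns ``variant``, ``cell``, ``alt``, ``coverage``, ``quality``;
- cell annotation: TSV keyed by cell barcode;
- gene expression: MatrixMarket triplet + ``barcodes.tsv`` / ``features.tsv``
  sidecars (optionally gzipped), features x cells on disk;
- per-cell nuclear SNV ref/alt read counts: TSV;
- clone trees: Newick with bootstrap supports as internal-node labels.

The allele-count reader knows about the upstream convention of storing
mitochondrial coverage doubled: ``halve_coverage=True`` restores true per-cell
coverage and refuses (rather than silently corrupting) inputs where any stored
coverage entry is odd. Mean base quality is undefined where coverage is zero
and is represented as NaN throughout — 0 is a legal Phred score and must not
be conflated with "no data".
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "MT_GENOME_LENGTH",
    "AlleleCountMatrix",
    "CellAnnotation",
    "ExpressionMatrix",
    "SNVCountTable",
    "parse_variant_id",
    "read_allele_matrix",
    "write_allele_matrix",
    "read_cell_annotation",
    "write_cell_annotation",
    "read_expression_mtx",
    "write_expression_mtx",
    "read_snv_table",
    "write_snv_table",
    "write_newick",
]

#: Length of the rCRS human mitochondrial reference (bp).
MT_GENOME_LENGTH = 16569

_VARIANT_RE = re.compile(r"^([0-9]+)([ACGT])>([ACGT])$")


def parse_variant_id(variant_id: str) -> tuple[int, str, str]:
    """Parse a ``"<pos><ref>><alt>"`` mitochondrial variant label.

    Positions are 1-based rCRS coordinates, e.g. ``"6150G>A"``.
    """
    m = _VARIANT_RE.match(str(variant_id))
    if m is None:
        raise ValueError(
            f"malformed variant id {variant_id!r}; expected '<pos><ref>><alt>' "
            "with ref/alt in {A,C,G,T}, e.g. '6150G>A'"
        )
    pos, ref, alt = int(m.group(1)), m.group(2), m.group(3)
    if not 1 <= pos <= MT_GENOME_LENGTH:
        raise ValueError(
            f"variant position {pos} outside the mitochondrial genome "
            f"[1, {MT_GENOME_LENGTH}]"
        )
    if ref == alt:
        raise ValueError(f"variant {variant_id!r} has identical ref and alt allele")
    return pos, ref, alt


# ---------------------------------------------------------------------------
# allele counts
# ---------------------------------------------------------------------------


@dataclass
class AlleleCountMatrix:
    """Per-cell x per-variant mitochondrial allele counts.

    ``alt_counts``/``coverage`` are dense integer arrays of shape
    ``(n_cells, n_variants)``; ``base_quality`` holds mean Phred quality with
    NaN wherever coverage is zero.
    """

    variant_ids: list[str]
    cell_ids: list[str]
    alt_counts: np.ndarray
    coverage: np.ndarray
    base_quality: np.ndarray

    def __post_init__(self) -> None:
        self.variant_ids = [str(v) for v in self.variant_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.alt_counts = np.asarray(self.alt_counts, dtype=np.int64)
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        self.base_quality = np.asarray(self.base_quality, dtype=float)
        self.validate()

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def validate(self) -> None:
        shape = (self.n_cells, self.n_variants)
        for name in ("alt_counts", "coverage", "base_quality"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if len(set(self.cell_ids)) != self.n_cells:
            raise ValueError("duplicate cell ids in allele matrix")
        if len(set(self.variant_ids)) != self.n_variants:
            raise ValueError("duplicate variant ids in allele matrix")
        for v in self.variant_ids:
            parse_variant_id(v)
        if (self.coverage < 0).any():
            raise ValueError("negative coverage entries")
        if (self.alt_counts < 0).any():
            raise ValueError("negative alt-count entries")
        bad = self.alt_counts > self.coverage
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValueError(
                f"alt count exceeds coverage for cell {self.cell_ids[i]!r}, "
                f"variant {self.variant_ids[j]!r}"
            )
        zero_cov = self.coverage == 0
        if np.isfinite(self.base_quality[zero_cov]).any():
            raise ValueError("base quality must be NaN where coverage is zero")

    def allele_frequency(self) -> np.ndarray:
        """AF = alt/coverage; 0 where coverage is 0 (use ``coverage`` to mask)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            af = np.where(self.coverage > 0, self.alt_counts / np.maximum(self.coverage, 1), 0.0)
        return af

    def variant_index(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"variant {variant_id!r} not in matrix") from None


def read_allele_matrix(path: str | os.PathLike, halve_coverage: bool = False) -> AlleleCountMatrix:
    """Read a long-format allele-count TSV.

    With ``halve_coverage=True`` every stored coverage value must be even
    (the upstream doubled-coverage convention) and is divided by two; alt
    counts and base qualities are untouched.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"variant": str, "cell": str})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["variant", "cell", "alt", "coverage", "quality"])
    required = ["variant", "cell", "alt", "coverage"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"allele matrix file {path} missing columns {missing}")
    if "quality" not in df.columns:
        df["quality"] = np.nan
    if df.duplicated(["variant", "cell"]).any():
        dup = df[df.duplicated(["variant", "cell"])].iloc[0]
        raise ValueError(
            f"duplicate record for variant {dup['variant']!r}, cell {dup['cell']!r}"
        )

    variant_ids = list(pd.unique(df["variant"]))
    cell_ids = list(pd.unique(df["cell"]))
    vi = pd.Categorical(df["variant"], categories=variant_ids).codes
    ci = pd.Categorical(df["cell"], categories=cell_ids).codes
    shape = (len(cell_ids), len(variant_ids))
    alt = np.zeros(shape, dtype=np.int64)
    cov = np.zeros(shape, dtype=np.int64)
    qual = np.full(shape, np.nan)
    alt[ci, vi] = df["alt"].to_numpy(dtype=np.int64)
    cov[ci, vi] = df["coverage"].to_numpy(dtype=np.int64)
    qual[ci, vi] = df["quality"].to_numpy(dtype=float)

    if halve_coverage:
        odd = (cov % 2) != 0
        if odd.any():
            i, j = map(int, np.argwhere(odd)[0])
            raise ValueError(
                f"halve_coverage=True but coverage {int(cov[i, j])} is odd for "
                f"cell {cell_ids[i]!r}, variant {variant_ids[j]!r}"
            )
        cov = cov // 2
        bad = alt > cov
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValueError(
                f"alt count exceeds halved coverage for cell {cell_ids[i]!r}, "
                f"variant {variant_ids[j]!r}"
            )
    qual[cov == 0] = np.nan
    return AlleleCountMatrix(variant_ids, cell_ids, alt, cov, qual)


def write_allele_matrix(m: AlleleCountMatrix, path: str | os.PathLike) -> None:
    """Write the dense long-format TSV (one row per cell/variant pair)."""
    n_c, n_v = m.n_cells, m.n_variants
    ci, vi = np.meshgrid(np.arange(n_c), np.arange(n_v), indexing="ij")
    ci, vi = ci.ravel(), vi.ravel()
    qual = m.base_quality[ci, vi]
    df = pd.DataFrame(
        {
            "variant": np.asarray(m.variant_ids, dtype=object)[vi],
            "cell": np.asarray(m.cell_ids, dtype=object)[ci],
            "alt": m.alt_counts[ci, vi],
            "coverage": m.coverage[ci, vi],
            "quality": [("" if not np.isfinite(q) else format(q, ".6g")) for q in qual],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cell annotation
# ---------------------------------------------------------------------------

_ANNOTATION_COLUMNS = [
    "cell_id",
    "sample_id",
    "patient_id",
    "tissue",
    "cell_type",
    "is_epithelial",
    "is_reference",
]


@dataclass
class CellAnnotation:
    """Per-cell metadata table.

    Reference cells are the non-epithelial populations (fibroblast,
    endothelial, immune) that serve as the background-noise null for somatic
    mitochondrial variants; a cell can never be both reference and epithelial.
    Columns beyond the required set are carried through untouched.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cell annotation missing required columns {missing}")
        df["cell_id"] = df["cell_id"].astype(str)
        for col in ("is_epithelial", "is_reference"):
            df[col] = _coerce_bool(df[col], col)
        if df["cell_id"].duplicated().any():
            dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
            raise ValueError(f"duplicate cell id {dup!r} in annotation")
        conflict = df["is_reference"] & df["is_epithelial"]
        if conflict.any():
            bad = df.loc[conflict, "cell_id"].iloc[0]
            raise ValueError(
                f"cell {bad!r} marked both reference and epithelial; reference "
                "cells are non-epithelial by definition"
            )
        self.table = df.reset_index(drop=True)

    @property
    def cell_ids(self) -> list[str]:
        return self.table["cell_id"].tolist()

    def indexed(self) -> pd.DataFrame:
        return self.table.set_index("cell_id")

    def reference_cells(self) -> list[str]:
        return self.table.loc[self.table["is_reference"], "cell_id"].tolist()

    def epithelial_cells(self) -> list[str]:
        return self.table.loc[self.table["is_epithelial"], "cell_id"].tolist()

    def subset(self, cell_ids: list[str]) -> "CellAnnotation":
        idx = self.indexed()
        missing = [c for c in cell_ids if c not in idx.index]
        if missing:
            raise KeyError(f"cells absent from annotation: {missing[:5]}")
        return CellAnnotation(idx.loc[cell_ids].reset_index())


def _coerce_bool(s: pd.Series, name: str) -> pd.Series:
    if s.dtype == bool:
        return s
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "t": True, "f": False, "yes": True, "no": False,
    }
    out = s.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        bad = s[out.isna()].iloc[0]
        raise ValueError(f"cannot parse boolean column {name!r} value {bad!r}")
    return out.astype(bool)


def read_cell_annotation(path: str | os.PathLike) -> CellAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return CellAnnotation(df)


def write_cell_annotation(ann: CellAnnotation, path: str | os.PathLike) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Sparse gene-expression counts, stored cells x genes in memory.

    On disk the conventional orientation is features x cells; the reader and
    writer transpose at the boundary.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: sp.csr_matrix = field(repr=False)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative expression counts")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def _find_sidecar(dir_path: str, stem: str) -> str:
    for name in (stem, stem + ".gz"):
        p = os.path.join(dir_path, name)
        if os.path.exists(p):
            return p
    raise FileNotFoundError(f"no {stem}[.gz] in {dir_path}")


def read_expression_mtx(dir_path: str | os.PathLike) -> ExpressionMatrix:
    """Read ``matrix.mtx`` / ``barcodes.tsv`` / ``features.tsv`` (.gz allowed)."""
    dir_path = os.fspath(dir_path)
    mtx = scipy.io.mmread(_find_sidecar(dir_path, "matrix.mtx"))
    barcodes = pd.read_csv(
        _find_sidecar(dir_path, "barcodes.tsv"), sep="\t", header=None, dtype=str
    )[0].tolist()
    features = pd.read_csv(
        _find_sidecar(dir_path, "features.tsv"), sep="\t", header=None, dtype=str
    )[0].tolist()
    if mtx.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"matrix shape {mtx.shape} does not match {len(features)} features "
            f"x {len(barcodes)} barcodes"
        )
    return ExpressionMatrix(features, barcodes, sp.csr_matrix(mtx.T))


def write_expression_mtx(em: ExpressionMatrix, dir_path: str | os.PathLike) -> None:
    dir_path = os.fspath(dir_path)
    os.makedirs(dir_path, exist_ok=True)
    scipy.io.mmwrite(os.path.join(dir_path, "matrix.mtx"), sp.coo_matrix(em.counts.T))
    with open(os.path.join(dir_path, "barcodes.tsv"), "w") as fh:
        fh.write("".join(c + "\n" for c in em.cell_ids))
    with open(os.path.join(dir_path, "features.tsv"), "w") as fh:
        fh.write("".join(g + "\n" for g in em.gene_ids))


# ---------------------------------------------------------------------------
# nuclear SNV counts
# ---------------------------------------------------------------------------


@dataclass
class SNVCountTable:
    """Per-cell nuclear SNV read counts (SCReadCounts-style layout).

    One record per (cell, SNV) with reference and alternative read counts.
    ``good_reads`` is their sum and the VAF is alt/good_reads, defined only
    where good_reads > 0.
    """

    records: pd.DataFrame = field(repr=False)

    _COLUMNS = ["cell_id", "snv_id", "ref_reads", "alt_reads"]

    def __post_init__(self) -> None:
        df = self.records.copy()
        missing = [c for c in self._COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"SNV table missing columns {missing}")
        df["cell_id"] = df["cell_id"].astype(str)
        df["snv_id"] = df["snv_id"].astype(str)
        for col in ("ref_reads", "alt_reads"):
            df[col] = df[col].astype(np.int64)
            if (df[col] < 0).any():
                raise ValueError(f"negative {col} in SNV table")
        if df.duplicated(["cell_id", "snv_id"]).any():
            raise ValueError("duplicate (cell, SNV) record in SNV table")
        self.records = df.reset_index(drop=True)

    @property
    def good_reads(self) -> pd.Series:
        return self.records["ref_reads"] + self.records["alt_reads"]

    @property
    def vaf(self) -> pd.Series:
        gr = self.good_reads
        return self.records["alt_reads"].where(gr > 0).div(gr.where(gr > 0))

    @property
    def snv_ids(self) -> list[str]:
        return list(pd.unique(self.records["snv_id"]))

    def __len__(self) -> int:
        return len(self.records)


def read_snv_table(path: str | os.PathLike) -> SNVCountTable:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "snv_id": str})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=SNVCountTable._COLUMNS)
    return SNVCountTable(df)


def write_snv_table(t: SNVCountTable, path: str | os.PathLike) -> None:
    t.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def write_newick(tree, path: str | os.PathLike) -> None:
    """Write a clone tree as Newick, supports as internal-node labels.

    ``tree`` is a :class:`mtclone.phylogeny.CloneTree`; branch lengths are
    kept and each internal node is labelled with its bipartition's bootstrap
    support (three decimals).
    """
    skt = getattr(tree, "tree", tree)
    tips = list(skt.tips())
    if not tips:
        raise ValueError("cannot write an empty tree")
    for tip in tips:
        if tip.name is None or str(tip.name) == "":
            raise ValueError("tree has an unlabeled leaf")
    out = skt.copy()
    for node in out.non_tips(include_self=True):
        sup = getattr(node, "support", None)
        node.name = format(float(sup), ".3f") if sup is not None else None
        # scikit-bio's writer would otherwise emit a "support:name" label
        node.support = None
    out.write(os.fspath(path), format="newick")
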