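"""Expression-matrix containers and file I/O.

Matrices are genes x samples tables of already-normalized expression values
(unitless intensities).  GCT v1.2 is the canonical on-disk format, with plain
header-row TSV accepted as a dialect; labels and gene lists are TSV/plain
text.  No normalization or imputation is performed here: non-finite values
are an error, and gene identifiers are matched by exact, case-sensitive
string comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    BuildError,
    DimensionError,
    FormatError,
    LabelError,
    UniquenessError,
)
from .hierarchy import SubtypeHierarchy


def _check_unique(ids: list[str], kind: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise UniquenessError(f"duplicate {kind} id {dup!r}")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of normalized expression values.

    Identifiers are unique strings; values are finite float64.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise DimensionError("expression values must be a 2-d matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DimensionError(
                f"value matrix is {self.values.shape}, expected "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.isfinite(self.values).all():
            raise FormatError("expression matrix contains NaN or infinite values")

    # -- accessors ----------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        """Genes x samples DataFrame view."""
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=np.float64))

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        """Restrict to the given genes, in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows, :])

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in samples]
        return ExpressionMatrix(list(self.gene_ids), list(samples), self.values[:, cols])

    def sample_vector(self, sample_id: str) -> pd.Series:
        """One sample's profile as a gene-indexed Series."""
        j = self.sample_ids.index(sample_id)
        return pd.Series(self.values[:, j], index=self.gene_ids, name=sample_id)


@dataclass
class LabeledReference:
    """A reference cohort: expression matrix plus a leaf-subtype label per sample."""

    matrix: ExpressionMatrix
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unlabeled = [s for s in self.matrix.sample_ids if s not in self.labels]
        if unlabeled:
            raise BuildError(f"samples without a subtype label: {unlabeled[:5]}")

    def validate_against(self, hierarchy: SubtypeHierarchy) -> None:
        leaves = set(hierarchy.leaves())
        bad = sorted({v for v in self.labels.values() if v not in leaves})
        if bad:
            raise LabelError(
                f"labels {bad} are not hierarchy leaves; valid leaves: "
                f"{', '.join(hierarchy.leaves())}"
            )


# ---------------------------------------------------------------------------
# GCT
# ---------------------------------------------------------------------------

def read_gct(path) -> ExpressionMatrix:
    """Read a GCT v1.2 file.

    Layout: line 1 ``#1.2``; line 2 ``<n_genes>\\t<n_samples>``; line 3 the
    header ``Name\\tDescription\\t<sample ids...>``; then one row per gene.
    The Description column is ignored on input.
    """
    with open(path) as fh:
        version = fh.readline().rstrip("\n")
        if not version.startswith("#1.2"):
            raise FormatError(f"{path}: line 1 is {version!r}, expected '#1.2'")
        dims = fh.readline().rstrip("\n").split("\t")
        if len(dims) < 2:
            raise FormatError(f"{path}: line 2 must be '<n_genes>\\t<n_samples>'")
        try:
            n_genes, n_samples = int(dims[0]), int(dims[1])
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer dimensions on line 2: {dims}") from exc
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0] != "Name":
            raise FormatError(
                f"{path}: line 3 must start with 'Name\\tDescription', got {header[:2]}"
            )
        sample_ids = header[2:]
        if len(sample_ids) != n_samples:
            raise DimensionError(
                f"{path}: header names {len(sample_ids)} samples, line 2 declares {n_samples}"
            )
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=4):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != n_samples + 2:
                raise DimensionError(
                    f"{path}:{lineno}: row has {len(parts) - 2} values, expected {n_samples}"
                )
            gene_ids.append(parts[0])
            try:
                rows.append([float(v) for v in parts[2:]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric expression value") from exc
    if len(gene_ids) != n_genes:
        raise DimensionError(
            f"{path}: {len(gene_ids)} data rows, line 2 declares {n_genes} genes"
        )
    values = np.array(rows, dtype=np.float64) if rows else np.empty((0, n_samples))
    return ExpressionMatrix(gene_ids, sample_ids, values)


def write_gct(matrix: ExpressionMatrix, path, descriptions: dict[str, str] | None = None) -> None:
    """Write a GCT v1.2 file; the Description column defaults to 'na'."""
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
        fh.write("Name\tDescription\t" + "\t".join(matrix.sample_ids) + "\n")
        for i, gene in enumerate(matrix.gene_ids):
            row = "\t".join(repr(float(v)) for v in matrix.values[i])
            fh.write(f"{gene}\t{descriptions.get(gene, 'na')}\t{row}\n")


# ---------------------------------------------------------------------------
# TSV dialects
# ---------------------------------------------------------------------------

def read_tsv_matrix(path) -> ExpressionMatrix:
    """Read a plain TSV matrix: header row of sample ids, first column gene ids."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise UniquenessError(f"{path}: duplicate gene id {dup!r}")
    try:
        values = frame.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value") from exc
    return ExpressionMatrix(
        [str(g) for g in frame.index], [str(s) for s in frame.columns], values
    )


def write_tsv_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_labels(path, hierarchy: SubtypeHierarchy | None = None) -> dict[str, str]:
    """Read a labels TSV with columns ``sample_id`` and ``subtype``.

    If a hierarchy is given, any label that is not one of its leaves raises a
    LabelError naming the valid leaves.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "subtype"}
    if not required.issubset(frame.columns):
        raise FormatError(
            f"{path}: labels file needs columns {sorted(required)}, found {list(frame.columns)}"
        )
    if frame["sample_id"].duplicated().any():
        dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise UniquenessError(f"{path}: duplicate sample id {dup!r}")
    labels = dict(zip(frame["sample_id"], frame["subtype"]))
    if hierarchy is not None:
        leaves = set(hierarchy.leaves())
        bad = sorted({v for v in labels.values() if v not in leaves})
        if bad:
            raise LabelError(
                f"{path}: labels {bad} are not hierarchy leaves; valid leaves: "
                f"{', '.join(hierarchy.leaves())}"
            )
    return labels


def write_labels(labels: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tsubtype\n")
        for sample, subtype in labels.items():
            fh.write(f"{sample}\t{subtype}\n")


def read_gene_list(path) -> list[str]:
    """Read a gene-list file: one gene id per line, '#' comments allowed."""
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.append(line)
    _check_unique(genes, "gene")
    return genes


def write_gene_list(genes: list[str], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(g + "\n")
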