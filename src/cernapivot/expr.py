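"""Expression-matrix data model, FPKM normalization, filtering, and TSV I/O.

The central container is :class:`ExpressionMatrix`: a genes x samples value
matrix tagged with a unit (``counts``, ``fpkm`` or ``log2fpkm``), per-gene
metadata (transcript length in bp, biotype mRNA/lncRNA) and a sample sheet
(condition tumor/control, optional pair id for matched designs).

FPKM (fragments per kilobase of transcript per million mapped fragments) is
computed from raw counts as

    fpkm[g, s] = counts[g, s] * 1e9 / (total_counts[s] * length_bp[g])

with the per-sample library size taken as the column sum of the supplied
count matrix.  Downstream analyses work on log2(fpkm + 1); the pseudocount
of 1 keeps zero counts at exactly zero on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_UNITS = ("counts", "fpkm", "log2fpkm")
VALID_BIOTYPES = ("mRNA", "lncRNA")
VALID_CONDITIONS = ("tumor", "control")


class ExpressionError(ValueError):
    """Raised for malformed expression matrices or incompatible operations."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with gene metadata and sample sheet.

    Parameters
    ----------
    values
        DataFrame indexed by gene_id with one column per sample_id.
    lengths
        Transcript length in bp per gene (positive integers), aligned to
        ``values.index``.
    biotypes
        Per-gene biotype, one of ``mRNA`` or ``lncRNA``.
    samples
        Sample sheet indexed by sample_id with a ``condition`` column
        (``tumor`` or ``control``) and an optional ``pair_id`` column.
    unit
        One of ``counts``, ``fpkm``, ``log2fpkm``.
    """

    values: pd.DataFrame
    lengths: pd.Series
    biotypes: pd.Series
    samples: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ExpressionError(f"unknown unit tag {self.unit!r}")
        if self.values.index.has_duplicates:
            raise ExpressionError("duplicate gene_ids")
        if self.values.columns.has_duplicates:
            raise ExpressionError("duplicate sample_ids")
        self.lengths = self.lengths.reindex(self.values.index)
        self.biotypes = self.biotypes.reindex(self.values.index)
        if len(self.values) and self.lengths.isna().any():
            missing = self.values.index[self.lengths.isna()].tolist()
            raise ExpressionError(f"missing length_bp for genes {missing[:5]}")
        if len(self.values) and (self.lengths <= 0).any():
            raise ExpressionError("gene lengths must be positive")
        bad = set(self.biotypes.dropna().unique()) - set(VALID_BIOTYPES)
        if bad:
            raise ExpressionError(f"unknown biotype(s) {sorted(bad)}")
        if "condition" not in self.samples.columns:
            raise ExpressionError("sample sheet lacks a condition column")
        if not set(self.values.columns) <= set(self.samples.index):
            raise ExpressionError("samples in matrix missing from sample sheet")
        self.samples = self.samples.loc[list(self.values.columns)]
        badc = set(self.samples["condition"]) - set(VALID_CONDITIONS)
        if badc:
            raise ExpressionError(f"unknown condition(s) {sorted(badc)}")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and not np.all(np.isfinite(arr)):
            raise ExpressionError("non-finite expression values")
        if self.unit in ("counts", "fpkm") and arr.size and (arr < 0).any():
            raise ExpressionError(f"negative values in a {self.unit} matrix")

    # -- convenience ------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def condition_samples(self, condition: str) -> list[str]:
        """Sample ids belonging to one condition, in sheet order."""
        return list(self.samples.index[self.samples["condition"] == condition])

    def genes_of_biotype(self, biotype: str) -> pd.Index:
        return self.values.index[self.biotypes == biotype]

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = [g for g in gene_ids]
        missing = set(ids) - set(self.values.index)
        if missing:
            raise ExpressionError(f"unknown gene_ids {sorted(missing)[:5]}")
        return replace(
            self,
            values=self.values.loc[ids],
            lengths=self.lengths.loc[ids],
            biotypes=self.biotypes.loc[ids],
        )


def compute_fpkm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Normalize a count matrix to FPKM.

    Library size for each sample is the column sum of the supplied counts.
    Raises if the matrix is not in counts or if any sample has zero total
    (an empty sample makes the normalization undefined).
    """
    if matrix.unit != "counts":
        raise ExpressionError(f"compute_fpkm expects counts, got {matrix.unit}")
    counts = matrix.values.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if counts.size and (totals == 0).any():
        empty = matrix.sample_ids[totals == 0].tolist()
        raise ExpressionError(f"zero column sum for sample(s) {empty}")
    lengths = matrix.lengths.to_numpy(dtype=float)[:, None]
    fpkm = counts * 1e9 / (totals[None, :] * lengths)
    return replace(
        matrix,
        values=pd.DataFrame(fpkm, index=matrix.gene_ids, columns=matrix.sample_ids),
        unit="fpkm",
    )


def log2_fpkm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(fpkm + 1) transform (pseudocount 1 keeps zeros at zero)."""
    if matrix.unit != "fpkm":
        raise ExpressionError(f"log2_fpkm expects fpkm, got {matrix.unit}")
    return replace(matrix, values=np.log2(matrix.values + 1.0), unit="log2fpkm")


def filter_expressed(
    matrix: ExpressionMatrix, min_fpkm: float = 0.5, min_samples: int = 2
) -> ExpressionMatrix:
    """Keep genes with fpkm >= min_fpkm in at least min_samples samples.

    Gene order is preserved.  ``min_fpkm=0`` is the identity.
    """
    if matrix.unit != "fpkm":
        raise ExpressionError(f"filter_expressed expects fpkm, got {matrix.unit}")
    if min_samples > matrix.values.shape[1]:
        raise ExpressionError(
            f"min_samples={min_samples} exceeds sample count {matrix.values.shape[1]}"
        )
    keep = (matrix.values >= min_fpkm).sum(axis=1) >= min_samples
    return matrix.subset_genes(matrix.gene_ids[keep])


# -- TSV I/O --------------------------------------------------------------
#
# Layout: a single expression TSV whose first line is '#unit=<tag>', then a
# header row 'gene_id  length_bp  biotype  <sample...>'; the sample sheet is
# a sibling TSV (default: <path> with a '.samples.tsv' suffix) with columns
# sample_id, condition, pair_id.


def _samples_path(path: Path) -> Path:
    return path.with_name(path.name + ".samples.tsv")


def write_expression(
    matrix: ExpressionMatrix, path: str | Path, samples_path: str | Path | None = None
) -> None:
    path = Path(path)
    samples_path = Path(samples_path) if samples_path else _samples_path(path)
    table = pd.DataFrame(
        {"length_bp": matrix.lengths.astype(int), "biotype": matrix.biotypes}
    ).join(matrix.values)
    table.index.name = "gene_id"
    with open(path, "w") as fh:
        fh.write(f"#unit={matrix.unit}\n")
        table.to_csv(fh, sep="\t")  # default float repr: lossless round trip
    sheet = matrix.samples.copy()
    sheet.index.name = "sample_id"
    sheet.to_csv(samples_path, sep="\t")


def read_expression(
    path: str | Path, samples_path: str | Path | None = None
) -> ExpressionMatrix:
    path = Path(path)
    samples_path = Path(samples_path) if samples_path else _samples_path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#unit="):
            raise ExpressionError("expression TSV must start with a '#unit=' line")
        unit = first.split("=", 1)[1]
        table = pd.read_csv(fh, sep="\t", index_col="gene_id")
    if table.index.has_duplicates:
        raise ExpressionError("duplicated gene row(s) in expression TSV")
    meta_cols = ["length_bp", "biotype"]
    for c in meta_cols:
        if c not in table.columns:
            raise ExpressionError(f"expression TSV lacks column {c}")
    values = table.drop(columns=meta_cols)
    values = values.apply(pd.to_numeric)  # non-numeric cells raise here
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
    return ExpressionMatrix(
        values=values,
        lengths=table["length_bp"],
        biotypes=table["biotype"],
        samples=samples,
        unit=unit,
    )
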