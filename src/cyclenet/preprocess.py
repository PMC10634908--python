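"""Time-course expression containers, tab-separated I/O, and the
expression-level filter that defines the analysis gene universe.

A study consists of one TPM matrix per (experiment, condition) pair —
two independent experiments (``V1``, ``V2``) sequenced under two ambient
temperatures (``18C``, ``25C``) in the original design — each with
per-sample metadata giving the Zeitgeber time (ZT, hours since lights-on),
replicate index, experiment and condition labels.

A gene enters the analysis universe only if it is consistently expressed:
within *every* experiment its median TPM must exceed the threshold
(default 5) in at least one of the conditions.  The threshold is a strict
inequality: a median of exactly 5 fails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: columns required in a sample-metadata table, in canonical order
META_COLUMNS = ("sample_id", "zt_hours", "replicate", "experiment", "condition")

#: name of the gene-identifier column in a TPM matrix TSV
GENE_COLUMN = "gene_id"


@dataclass
class TimeCourseMatrix:
    """A gene × sample TPM matrix with aligned per-sample metadata.

    Parameters
    ----------
    values
        DataFrame of non-negative TPM values, genes on the index, sample
        identifiers on the columns.
    sample_meta
        DataFrame with one row per sample and columns
        ``sample_id, zt_hours, replicate, experiment, condition``.
        Rows are reordered on construction to match the column order of
        ``values``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ValueError("duplicate gene identifiers in matrix")
        if v.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers in matrix")
        if not np.issubdtype(np.asarray(v.values).dtype, np.number):
            raise ValueError("TPM matrix must be numeric")
        if np.isnan(v.values).any():
            raise ValueError("TPM matrix contains missing values")
        if (v.values < 0).any():
            raise ValueError("TPM values must be non-negative")
        meta = self.sample_meta
        missing = set(META_COLUMNS) - set(meta.columns)
        if missing:
            raise ValueError(f"sample metadata lacks columns: {sorted(missing)}")
        meta = meta.set_index("sample_id", drop=False)
        if set(meta.index) != set(v.columns):
            raise ValueError("sample metadata does not match matrix columns")
        # align metadata row order with matrix column order
        self.sample_meta = meta.loc[list(v.columns)].reset_index(drop=True)

    # -- convenience accessors -------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def zt_hours(self) -> np.ndarray:
        """ZT sampling times, aligned with the matrix columns."""
        return self.sample_meta["zt_hours"].to_numpy(dtype=float)

    def subset_genes(self, genes: Sequence[str]) -> "TimeCourseMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}...")
        return TimeCourseMatrix(self.values.loc[list(genes)], self.sample_meta.copy())


def concat_samples(matrices: Iterable[TimeCourseMatrix]) -> TimeCourseMatrix:
    """Pool samples of several matrices sharing one gene universe.

    Used e.g. to combine the V1 and V2 experiments of one condition before
    a variance computation.  Gene sets must be identical; sample
    identifiers must not collide.
    """
    mats = list(matrices)
    if not mats:
        raise ValueError("no matrices to concatenate")
    genes = mats[0].genes
    for m in mats[1:]:
        if set(m.genes) != set(genes):
            raise ValueError("matrices do not share a gene universe")
    values = pd.concat([m.values.loc[genes] for m in mats], axis=1)
    meta = pd.concat([m.sample_meta for m in mats], ignore_index=True)
    return TimeCourseMatrix(values, meta)


# -- TSV round trip -------------------------------------------------------

def write_tpm_matrix(mat: TimeCourseMatrix, matrix_path: Path | str,
                     meta_path: Path | str, float_format: str = "%.6g") -> None:
    """Write a matrix + metadata pair as tab-separated text."""
    mat.values.rename_axis(GENE_COLUMN).to_csv(
        matrix_path, sep="\t", float_format=float_format)
    mat.sample_meta.loc[:, list(META_COLUMNS)].to_csv(
        meta_path, sep="\t", index=False)


def read_tpm_matrix(matrix_path: Path | str, meta_path: Path | str) -> TimeCourseMatrix:
    """Read a matrix + metadata pair written by :func:`write_tpm_matrix`."""
    matrix_path, meta_path = Path(matrix_path), Path(meta_path)
    for p in (matrix_path, meta_path):
        if not p.exists():
            raise FileNotFoundError(f"input file not found: {p}")
    values = pd.read_csv(matrix_path, sep="\t", index_col=0).astype(float)
    values.index = values.index.astype(str)
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str})
    return TimeCourseMatrix(values, meta)


def write_gene_list(genes: Sequence[str], path: Path | str) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gene_list(path: Path | str) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


# -- the expression filter ------------------------------------------------

def median_expression_filter(
    matrices: Mapping[tuple[str, str], TimeCourseMatrix],
    threshold: float = 5.0,
) -> list[str]:
    """Select genes with median TPM strictly above ``threshold`` in at
    least one condition, consistently across every experiment.

    Parameters
    ----------
    matrices
        Mapping keyed by ``(experiment, condition)``; the full experiment ×
        condition grid must be present.
    threshold
        TPM cutoff applied to the per-condition median over all of that
        matrix's samples (all timepoints and replicates).  Strict ``>``.

    Returns
    -------
    list of retained gene identifiers, in the gene order of the first
    matrix.  Genes absent from any matrix are dropped with a warning.
    """
    if not matrices:
        raise ValueError("no matrices supplied")
    experiments = sorted({e for e, _ in matrices})
    conditions = sorted({c for _, c in matrices})
    for e in experiments:
        for c in conditions:
            if (e, c) not in matrices:
                raise ValueError(f"missing experiment/condition combination: ({e}, {c})")

    mats = list(matrices.values())
    first_order = mats[0].genes
    common = set(first_order)
    for m in mats[1:]:
        common &= set(m.genes)
    n_dropped = len(set().union(*(set(m.genes) for m in mats))) - len(common)
    if n_dropped:
        log.warning("dropping %d genes absent from at least one matrix", n_dropped)
    genes = [g for g in first_order if g in common]

    retained = pd.Series(True, index=genes)
    for e in experiments:
        passes_e = pd.Series(False, index=genes)
        for c in conditions:
            med = matrices[(e, c)].values.loc[genes].median(axis=1)
            passes_e |= med > threshold
        retained &= passes_e
    return [g for g in genes if retained[g]]
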