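"""Core data containers for paired exonic/intronic count matrices.

The central object is :class:`StabilityDataset`, which holds two gene x sample
count matrices measured on the *same* genes and samples: reads falling in
constitutive exons (a proxy for mature, spliced mRNA abundance) and reads
falling in purely intronic regions (a proxy for unspliced pre-mRNA abundance,
and hence transcription). Differential-stability inference works on the
*stacked* gene x 2n matrix in which each sample contributes one intronic and
one exonic pseudo-library; the intronic block always comes first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

INTRONIC = "intronic"
EXONIC = "exonic"


class DataFormatError(ValueError):
    """Raised when an input table violates the count-matrix contract."""


@dataclass
class StabilityDataset:
    """Paired exonic/intronic count matrices with aligned gene/sample order.

    Parameters
    ----------
    gene_ids : list of str
        Gene identifiers, one per row.
    exonic_counts : ndarray of shape (n_genes, n_samples)
        Non-negative integer read counts in constitutive exons.
    intronic_counts : ndarray of shape (n_genes, n_samples)
        Non-negative integer read counts in purely intronic regions.
    sample_ids : list of str
        Sample identifiers, one per column, shared by both matrices.
    """

    gene_ids: list[str]
    exonic_counts: np.ndarray
    intronic_counts: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.exonic_counts = _as_count_matrix(self.exonic_counts, "exonic")
        self.intronic_counts = _as_count_matrix(self.intronic_counts, "intronic")
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.exonic_counts.shape != self.intronic_counts.shape:
            raise DataFormatError(
                f"exonic {self.exonic_counts.shape} and intronic "
                f"{self.intronic_counts.shape} matrices differ in shape"
            )
        if self.exonic_counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataFormatError("matrix shape does not match gene/sample labels")
        if len(self.gene_ids) < 1:
            raise DataFormatError("need at least one gene")
        if len(self.sample_ids) < 2:
            raise DataFormatError("need at least two samples")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Return (exonic, intronic) counts as labelled DataFrames."""
        idx = pd.Index(self.gene_ids, name="gene_id")
        cols = pd.Index(self.sample_ids)
        return (
            pd.DataFrame(self.exonic_counts, index=idx, columns=cols),
            pd.DataFrame(self.intronic_counts, index=idx, columns=cols),
        )


@dataclass
class StackedCounts:
    """Gene x 2n matrix: intronic block (samples 1..n) then exonic block."""

    matrix: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def column_labels(self) -> list[tuple[str, str]]:
        """(sample_id, feature_type) per column, intronic block first."""
        return [(s, INTRONIC) for s in self.sample_ids] + [
            (s, EXONIC) for s in self.sample_ids
        ]


def _as_count_matrix(arr, name: str) -> np.ndarray:
    a = np.asarray(arr)
    if a.ndim != 2:
        raise DataFormatError(f"{name} counts must be a 2-D matrix")
    if not np.issubdtype(a.dtype, np.integer):
        rounded = np.rint(a)
        if not np.all(np.isfinite(a)) or np.any(np.abs(a - rounded) > 0):
            raise DataFormatError(f"{name} counts contain non-integer entries")
        a = rounded.astype(np.int64)
    if np.any(a < 0):
        raise DataFormatError(f"{name} counts contain negative entries")
    return a.astype(np.int64)


def _validate_table(df: pd.DataFrame, which: str) -> None:
    arr = df.to_numpy()
    try:
        farr = arr.astype(float)
    except (TypeError, ValueError) as exc:
        raise DataFormatError(f"{which} table has non-numeric entries: {exc}") from exc
    bad = ~np.isfinite(farr) | (farr < 0) | (np.rint(farr) != farr)
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise DataFormatError(
            f"{which} table: invalid count {farr[g, s]!r} at "
            f"gene {df.index[g]!r}, sample {df.columns[s]!r} "
            "(counts must be non-negative integers)"
        )


def load_count_tables(exonic_path, intronic_path) -> StabilityDataset:
    """Load a :class:`StabilityDataset` from two TSV count tables.

    Both files must be tab-separated with a header row of sample IDs and a
    first column of gene IDs. Genes and samples are restricted to the
    intersection of the two tables; ordering follows the exonic file.
    """
    exo = pd.read_csv(exonic_path, sep="\t", index_col=0)
    intr = pd.read_csv(intronic_path, sep="\t", index_col=0)
    _validate_table(exo, "exonic")
    _validate_table(intr, "intronic")

    genes = [g for g in exo.index if g in set(intr.index)]
    samples = [s for s in exo.columns if s in set(intr.columns)]
    if not genes or not samples:
        raise DataFormatError(
            "empty gene or sample intersection between exonic and intronic tables"
        )
    n_drop_g = (len(exo.index) - len(genes)) + (len(intr.index) - len(genes))
    n_drop_s = (len(exo.columns) - len(samples)) + (len(intr.columns) - len(samples))
    if n_drop_g:
        logger.warning("dropped %d gene rows absent from one of the tables", n_drop_g)
    if n_drop_s:
        logger.warning("dropped %d sample columns absent from one of the tables", n_drop_s)

    exo = exo.loc[genes, samples]
    intr = intr.loc[genes, samples]
    return StabilityDataset(
        gene_ids=genes,
        exonic_counts=exo.to_numpy(),
        intronic_counts=intr.to_numpy(),
        sample_ids=samples,
    )


def load_sample_table(path) -> pd.DataFrame:
    """Load the sample covariate table (TSV with a 'sample_id' column)."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise DataFormatError("sample table must contain a 'sample_id' column")
    return df.set_index("sample_id")


def align_samples(samples: pd.DataFrame, dataset: StabilityDataset) -> pd.DataFrame:
    """Reorder the sample table to the dataset's sample order."""
    missing = [s for s in dataset.sample_ids if s not in samples.index]
    if missing:
        raise DataFormatError(f"sample table is missing samples: {missing}")
    return samples.loc[dataset.sample_ids]


def stack(dataset: StabilityDataset) -> StackedCounts:
    """Concatenate intronic then exonic counts into a gene x 2n matrix."""
    m = np.hstack([dataset.intronic_counts, dataset.exonic_counts])
    return StackedCounts(matrix=m, gene_ids=list(dataset.gene_ids),
                         sample_ids=list(dataset.sample_ids))


def unstack(stacked: StackedCounts) -> StabilityDataset:
    """Inverse of :func:`stack`."""
    n = stacked.n_samples
    return StabilityDataset(
        gene_ids=list(stacked.gene_ids),
        exonic_counts=stacked.matrix[:, n:],
        intronic_counts=stacked.matrix[:, :n],
        sample_ids=list(stacked.sample_ids),
    )


def filter_genes(
    dataset: StabilityDataset,
    min_total_intronic: int = 10,
    min_total_exonic: int = 10,
    exclude_ids=(),
) -> StabilityDataset:
    """Drop genes with insufficient counts or on an exclusion list.

    Genes are retained when their total intronic count is at least
    ``min_total_intronic``, their total exonic count at least
    ``min_total_exonic``, and their ID is not in ``exclude_ids`` (e.g. a
    user-supplied cell-cycle list — such genes are not at steady state, which
    the stability model assumes).
    """
    if min_total_intronic < 0 or min_total_exonic < 0:
        raise ValueError("count thresholds must be non-negative")
    exclude = set(exclude_ids)
    tot_i = dataset.intronic_counts.sum(axis=1)
    tot_e = dataset.exonic_counts.sum(axis=1)
    ids = np.asarray(dataset.gene_ids, dtype=object)
    low_i = tot_i < min_total_intronic
    low_e = tot_e < min_total_exonic
    excl = np.array([g in exclude for g in ids])
    keep = ~(low_i | low_e | excl)
    logger.info(
        "gene filter: %d low-intronic, %d low-exonic, %d excluded, %d retained",
        int(low_i.sum()), int(low_e.sum()), int(excl.sum()), int(keep.sum()),
    )
    if not keep.any():
        raise DataFormatError("gene filtering removed every gene")
    return StabilityDataset(
        gene_ids=[g for g, k in zip(dataset.gene_ids, keep) if k],
        exonic_counts=dataset.exonic_counts[keep],
        intronic_counts=dataset.intronic_counts[keep],
        sample_ids=list(dataset.sample_ids),
    )
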