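"""Depth downsampling and quantile normalization.

Sequencing depth is equalized across samples by drawing ``target_depth``
reads *without replacement* from each sample's mapped reads.  Operating on
count bins (each gene plus the intergenic bin), this is a single draw from
the multivariate hypergeometric distribution and is distributionally
identical to uniform subsampling of the underlying read records.  The
intergenic bin participates: all mapped reads are subsampled, not only the
gene-assigned ones.

After downsampling, count matrices are quantile-normalized across samples
before any correlation metric: each entry is replaced by the across-sample
mean of its rank, tied values receiving the average of the means of the
ranks they span.
"""

from __future__ import annotations

import hashlib
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation_io import ReadAccounting, SampleRecord
from .errors import AnnotationMismatchError, InsufficientDepthError, ValidationError

INTERGENIC_BIN = "__intergenic"


def subseed(master_seed: int, tag: str) -> int:
    """Derive a stream seed from (master seed, tag), stable across runs.

    Hash-derived so that changing cohort composition never shifts another
    sample's draws.
    """
    digest = hashlib.sha256(f"{master_seed}:{tag}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def downsample_mapped(
    accounting: ReadAccounting, target_depth: int, seed: int
) -> ReadAccounting:
    """Subsample a sample's mapped reads to exactly ``target_depth``.

    Per-bin counts are one multivariate hypergeometric draw over the gene
    bins plus the intergenic bin; the raw-read total is rescaled
    proportionally.  Deterministic given ``seed``.
    """
    if target_depth <= 0:
        raise ValidationError("target_depth must be positive")
    if accounting.mapped_reads < target_depth:
        raise InsufficientDepthError(
            f"mapped_reads ({accounting.mapped_reads}) < target depth ({target_depth})"
        )
    genes = list(accounting.gene_counts)
    colors = np.array(
        [accounting.gene_counts[g] for g in genes] + [accounting.intergenic_mapped],
        dtype=np.int64,
    )
    rng = np.random.default_rng(seed)
    draw = rng.multivariate_hypergeometric(colors, target_depth)
    raw = round(accounting.total_raw_reads * target_depth / accounting.mapped_reads)
    return ReadAccounting(
        total_raw_reads=int(raw),
        mapped_reads=target_depth,
        gene_counts={g: int(c) for g, c in zip(genes, draw[:-1])},
        intergenic_mapped=int(draw[-1]),
    )


def downsample_cohort(
    samples: Sequence[SampleRecord],
    annotation: pd.DataFrame,
    target_depth: int,
    seed: int,
) -> tuple[pd.DataFrame, dict[str, ReadAccounting]]:
    """Downsample every sample and assemble the genes × samples count matrix.

    Per-sample seeds are derived from ``(seed, sample_id)``.  The matrix rows
    are the annotation's gene universe; genes absent from a sample's counts
    are zero.  Returns the matrix plus each sample's downsampled accounting
    (which still carries the intergenic bin the matrix omits).
    """
    accountings: dict[str, ReadAccounting] = {}
    columns: dict[str, pd.Series] = {}
    universe = annotation.index
    for sample in samples:
        unknown = [g for g in sample.accounting.gene_counts if g not in universe]
        if unknown:
            raise AnnotationMismatchError(
                f"sample {sample.sample_id}: genes not in annotation: {unknown[:5]}"
            )
        down = downsample_mapped(
            sample.accounting, target_depth, subseed(seed, sample.sample_id)
        )
        accountings[sample.sample_id] = down
        columns[sample.sample_id] = pd.Series(down.gene_counts, dtype="int64")
    matrix = pd.DataFrame(columns, index=universe, dtype="float64").fillna(0).astype("int64")
    matrix.index.name = "gene_id"
    return matrix, accountings


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Classic rank-average quantile normalization across samples (columns).

    Each column is sorted, the across-sample mean of every rank is computed,
    and each original entry is assigned the mean for its rank; a tied group
    receives the average of the means of the ranks it spans.  Requires at
    least two samples.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("quantile normalization needs >= 2 samples")
    values = matrix.to_numpy(dtype=float)
    order = np.argsort(values, axis=0, kind="stable")
    sorted_values = np.take_along_axis(values, order, axis=0)
    rank_means = sorted_values.mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        assigned = rank_means
        _, inverse = np.unique(sorted_values[:, j], return_inverse=True)
        sums = np.bincount(inverse, weights=assigned)
        counts = np.bincount(inverse)
        assigned = (sums / counts)[inverse]
        out[order[:, j], j] = assigned
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
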