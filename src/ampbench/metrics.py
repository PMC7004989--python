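"""The five quality metrics and their per-protocol aggregation.

Per sample (computed on accounting downsampled to the configured depth):

* **total mapping rate** — mapped reads / raw reads;
* **transcriptomic mapping ratio** — reads on standard-class gene models /
  mapped reads; rRNA- and mtRNA-class reads are excluded from the numerator
  only, so the standard, rRNA+mtRNA and intergenic fractions of mapped reads
  sum to one;
* **gene model discovery rate** — the number of genes with *more than*
  ``min_reads`` uniquely mapped reads (strictly greater; the default 5 means
  a gene needs >= 6 reads) at the downsampled depth.

Per replicate group / protocol (computed on the quantile-normalized,
downsampled matrix):

* **reproducibility** — mean pairwise Pearson correlation between technical
  replicates;
* **accuracy** — mean Pearson correlation of each sample against a bulk
  reference profile.

Correlations are computed on normalized counts without a log transform by
default; ``log1p=True`` applies log(1+x) first.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import ReadAccounting, SampleRecord
from .errors import AnnotationMismatchError, UndefinedMetricError


@dataclass(frozen=True)
class MetricsRow:
    """Per-sample values of the three depth-normalized metrics."""

    sample_id: str
    total_mapping_rate: float
    transcriptomic_mapping_ratio: float
    genes_detected: int
    genes_detected_comparison: int | None = None


@dataclass(frozen=True)
class ProtocolSummary:
    """One protocol's row of the five-metric comparison table."""

    protocol: str
    mean_total_mapping_rate: float
    mean_transcriptomic_mapping_ratio: float
    mean_genes_detected: float
    reproducibility: float | None
    accuracy: float | None
    sample_count: int


def total_mapping_rate(accounting: ReadAccounting) -> float:
    """Fraction of raw reads that mapped to the genome/transcriptome."""
    if accounting.total_raw_reads == 0:
        raise UndefinedMetricError("total mapping rate undefined: zero raw reads")
    return accounting.mapped_reads / accounting.total_raw_reads


def transcriptomic_mapping_ratio(
    accounting: ReadAccounting, annotation: pd.DataFrame
) -> float:
    """Fraction of mapped reads on standard gene models (rRNA/mtRNA excluded)."""
    if accounting.mapped_reads == 0:
        raise UndefinedMetricError("transcriptomic ratio undefined: zero mapped reads")
    classes = annotation["gene_class"]
    standard = 0
    for gene, count in accounting.gene_counts.items():
        if gene not in classes.index:
            raise AnnotationMismatchError(f"gene {gene!r} missing from annotation")
        if classes[gene] == "standard":
            standard += count
    return standard / accounting.mapped_reads


def gene_discovery_rate(gene_counts: Mapping[str, int], min_reads: int = 5) -> int:
    """Number of genes with strictly more than ``min_reads`` reads."""
    return int(sum(1 for c in gene_counts.values() if c > min_reads))


def pairwise_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation; errors on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise UndefinedMetricError("correlation needs two equal-length vectors, n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0 or sy == 0:
        raise UndefinedMetricError("correlation undefined for a constant vector")
    return float((xc * yc).sum() / (sx * sy))


def _maybe_log(matrix: pd.DataFrame, log1p: bool) -> pd.DataFrame:
    return np.log1p(matrix) if log1p else matrix


def reproducibility(
    matrix: pd.DataFrame,
    replicate_groups: Mapping[str, str],
    log1p: bool = False,
) -> float | None:
    """Mean pairwise Pearson correlation within replicate groups.

    ``matrix`` must already be downsampled and quantile-normalized.  Returns
    ``None`` (not zero) when no group has two samples in the matrix.
    """
    matrix = _maybe_log(matrix, log1p)
    by_group: dict[str, list[str]] = {}
    for sid in matrix.columns:
        if sid in replicate_groups:
            by_group.setdefault(replicate_groups[sid], []).append(sid)
    correlations = []
    for members in by_group.values():
        for a, b in itertools.combinations(members, 2):
            correlations.append(
                pairwise_pearson(matrix[a].to_numpy(), matrix[b].to_numpy())
            )
    if not correlations:
        return None
    return float(np.mean(correlations))


def accuracy_vs_bulk(
    matrix: pd.DataFrame, bulk_profile: pd.Series, log1p: bool = False
) -> float:
    """Mean Pearson correlation of each sample against the bulk reference."""
    if set(matrix.index) != set(bulk_profile.index):
        raise AnnotationMismatchError("bulk profile gene set differs from matrix")
    bulk = bulk_profile.reindex(matrix.index)
    matrix = _maybe_log(matrix, log1p)
    bulk = np.log1p(bulk) if log1p else bulk
    correlations = [
        pairwise_pearson(matrix[sid].to_numpy(), bulk.to_numpy())
        for sid in matrix.columns
    ]
    return float(np.mean(correlations))


def compute_sample_metrics(
    sample_id: str,
    downsampled: ReadAccounting,
    annotation: pd.DataFrame,
    min_reads: int = 5,
    comparison: ReadAccounting | None = None,
) -> MetricsRow:
    """Assemble the per-sample metric row from downsampled accounting."""
    return MetricsRow(
        sample_id=sample_id,
        total_mapping_rate=total_mapping_rate(downsampled),
        transcriptomic_mapping_ratio=transcriptomic_mapping_ratio(downsampled, annotation),
        genes_detected=gene_discovery_rate(downsampled.gene_counts, min_reads),
        genes_detected_comparison=(
            gene_discovery_rate(comparison.gene_counts, min_reads)
            if comparison is not None
            else None
        ),
    )


def summarize_protocols(
    samples: Sequence[SampleRecord],
    rows: Mapping[str, MetricsRow],
    normalized_matrix: pd.DataFrame | None,
    bulk_profile: pd.Series | None = None,
    log1p: bool = False,
) -> list[ProtocolSummary]:
    """Average per-sample metrics per protocol; protocols keep input order.

    Reproducibility is computed within each protocol's replicate groups;
    accuracy against the bulk profile when one is supplied.  Either is
    absent (``None``) when it cannot be computed.
    """
    protocols: list[str] = []
    members: dict[str, list[SampleRecord]] = {}
    for sample in samples:
        if sample.protocol not in members:
            protocols.append(sample.protocol)
            members[sample.protocol] = []
        members[sample.protocol].append(sample)

    summaries = []
    for protocol in protocols:
        group = members[protocol]
        ids = [s.sample_id for s in group]
        sub = None
        if normalized_matrix is not None:
            present = [sid for sid in ids if sid in normalized_matrix.columns]
            sub = normalized_matrix[present] if present else None
        repro = None
        if sub is not None and sub.shape[1] >= 2:
            repro = reproducibility(
                sub, {s.sample_id: s.replicate_group for s in group}, log1p=log1p
            )
        acc = None
        if sub is not None and sub.shape[1] >= 1 and bulk_profile is not None:
            acc = accuracy_vs_bulk(sub, bulk_profile, log1p=log1p)
        summaries.append(
            ProtocolSummary(
                protocol=protocol,
                mean_total_mapping_rate=float(
                    np.mean([rows[sid].total_mapping_rate for sid in ids])
                ),
                mean_transcriptomic_mapping_ratio=float(
                    np.mean([rows[sid].transcriptomic_mapping_ratio for sid in ids])
                ),
                mean_genes_detected=float(
                    np.mean([rows[sid].genes_detected for sid in ids])
                ),
                reproducibility=repro,
                accuracy=acc,
                sample_count=len(group),
            )
        )
    return summaries


def metrics_frame(rows: Sequence[MetricsRow]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            (
                r.sample_id,
                r.total_mapping_rate,
                r.transcriptomic_mapping_ratio,
                r.genes_detected,
                r.genes_detected_comparison,
            )
            for r in rows
        ],
        columns=[
            "sample_id",
            "total_mapping_rate",
            "transcriptomic_mapping_ratio",
            "genes_detected",
            "genes_detected_comparison",
        ],
    )
    if df["genes_detected_comparison"].isna().all():
        df = df.drop(columns=["genes_detected_comparison"])
    return df


def summary_frame(summaries: Sequence[ProtocolSummary]) -> pd.DataFrame:
    """Protocol summary table; rates reported in percent, as in the field."""
    return pd.DataFrame(
        [
            (
                s.protocol,
                100 * s.mean_total_mapping_rate,
                100 * s.mean_transcriptomic_mapping_ratio,
                s.mean_genes_detected,
                s.reproducibility,
                s.accuracy,
                s.sample_count,
            )
            for s in summaries
        ],
        columns=[
            "protocol",
            "total_mapping_rate_pct",
            "transcriptomic_mapping_ratio_pct",
            "mean_genes_detected",
            "reproducibility",
            "accuracy",
            "sample_count",
        ],
    )


def write_metrics(rows: Sequence[MetricsRow], path: str | Path) -> None:
    metrics_frame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")


def write_summary(summaries: Sequence[ProtocolSummary], path: str | Path) -> None:
    summary_frame(summaries).to_csv(path, sep="\t", index=False, na_rep="NA")
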