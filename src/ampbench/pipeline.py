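"""Pipeline orchestration: load → QC → downsample → metrics → normalize → summary.

Each stage is a plain function over the domain objects so the CLI can expose
them individually; :func:`run_pipeline` chains them and writes the artifact
files (exclusion log, kept-sample list, downsampled matrix and accounting,
per-sample metrics, normalized matrix, protocol summary, run log).  A rerun
with identical config and seed reproduces every artifact byte for byte: no
timestamps enter the outputs, and all randomness derives from the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .annotation_io import (
    ReadAccounting,
    SampleRecord,
    load_cohort,
    read_count_matrix,
    read_gene_annotation,
    read_sample_metadata,
    write_count_matrix,
)
from .errors import ConfigError, FormatError
from .metrics import (
    MetricsRow,
    compute_sample_metrics,
    summarize_protocols,
    write_metrics,
    write_summary,
)
from .qc_filters import ExclusionLog, FilterConfig, apply_exclusions
from .resample import downsample_cohort, quantile_normalize, subseed

log = logging.getLogger("ampbench")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one benchmark run (YAML- or JSON-loadable)."""

    annotation: str
    metadata: str
    output_dir: str
    counts_dir: str | None = None
    counts_matrix: str | None = None
    bulk_profile: str | None = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    target_depth: int = 3_000_000
    comparison_depth: int | None = None
    min_reads: int = 5
    log1p: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.counts_dir is None) == (self.counts_matrix is None):
            raise ConfigError("exactly one of counts_dir / counts_matrix is required")
        if self.target_depth <= 0:
            raise ConfigError("target_depth must be positive")
        if self.comparison_depth is not None and not (
            0 < self.comparison_depth <= self.target_depth
        ):
            raise ConfigError("comparison_depth must be in (0, target_depth]")
        out = Path(self.output_dir).resolve()
        for p in (self.annotation, self.metadata, self.counts_dir, self.counts_matrix):
            if p is not None and Path(p).resolve() == out:
                raise ConfigError("output_dir must be distinct from input paths")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "filters" in data and isinstance(data["filters"], dict):
            data["filters"] = FilterConfig(**data["filters"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


@dataclass
class PipelineResult:
    kept: list[SampleRecord]
    exclusion_log: ExclusionLog
    matrix: pd.DataFrame
    normalized: pd.DataFrame | None
    rows: dict[str, MetricsRow]
    summary: pd.DataFrame


def load_inputs(
    config: PipelineConfig,
) -> tuple[pd.DataFrame, list[SampleRecord], pd.Series | None]:
    """Read annotation, assemble the cohort, and read the bulk profile if any."""
    for path in filter(None, (config.annotation, config.metadata, config.counts_dir,
                              config.counts_matrix, config.bulk_profile)):
        if not Path(path).exists():
            raise FormatError(f"input path does not exist: {path}")
    annotation = read_gene_annotation(config.annotation)
    metadata = read_sample_metadata(config.metadata)
    if config.counts_dir is not None:
        samples = load_cohort(metadata, config.counts_dir)
    else:
        samples = _cohort_from_matrix(metadata, read_count_matrix(config.counts_matrix))
    bulk = None
    if config.bulk_profile is not None:
        bulk_df = pd.read_csv(config.bulk_profile, sep="\t", index_col=0)
        bulk = bulk_df.iloc[:, 0]
    return annotation, samples, bulk


def _cohort_from_matrix(
    metadata: pd.DataFrame, matrix: pd.DataFrame
) -> list[SampleRecord]:
    """Matrix mode needs per-sample totals in the metadata table."""
    for col in ("total_raw_reads", "mapped_reads"):
        if col not in metadata.columns:
            raise FormatError(
                f"matrix-mode metadata needs a {col!r} column for read accounting"
            )
    samples = []
    for _, row in metadata.iterrows():
        sid = str(row["sample_id"])
        if sid not in matrix.columns:
            raise FormatError(f"sample {sid!r} missing from count matrix")
        gene_counts = {g: int(c) for g, c in matrix[sid].items()}
        mapped = int(row["mapped_reads"])
        accounting = ReadAccounting(
            total_raw_reads=int(row["total_raw_reads"]),
            mapped_reads=mapped,
            gene_counts=gene_counts,
            intergenic_mapped=mapped - sum(gene_counts.values()),
        )
        meta = row.to_dict()
        samples.append(
            SampleRecord(
                sample_id=sid,
                protocol=str(row["protocol"]),
                replicate_group=str(row["replicate_group"]),
                input_pg=float(row["input_pg"]),
                accounting=accounting,
                arna_yield=_opt(meta, "arna_yield"),
                negative_control_yield=_opt(meta, "negative_control_yield"),
                library_conc_ng_per_ul=_opt(meta, "library_conc_ng_per_ul"),
                library_yield_ng=_opt(meta, "library_yield_ng"),
            )
        )
    return samples


def _opt(row: dict, key: str) -> float | None:
    value = row.get(key)
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    return float(value)


def stage_qc(
    samples: Sequence[SampleRecord], config: PipelineConfig
) -> tuple[list[SampleRecord], ExclusionLog]:
    """Apply the exclusion rules; the depth rule also enforces target_depth."""
    filters = config.filters
    effective_min = max(filters.mapped_min_reads, config.target_depth)
    if effective_min != filters.mapped_min_reads:
        filters = FilterConfig(
            arna_yield_min_ratio=filters.arna_yield_min_ratio,
            conc_max_ng_per_ul=filters.conc_max_ng_per_ul,
            library_min_ng=filters.library_min_ng,
            mapped_min_reads=effective_min,
        )
    return apply_exclusions(samples, filters)


def stage_downsample(
    kept: Sequence[SampleRecord],
    annotation: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, dict[str, ReadAccounting], dict[str, ReadAccounting] | None]:
    matrix, accountings = downsample_cohort(
        kept, annotation, config.target_depth, config.seed
    )
    comparison = None
    if config.comparison_depth is not None:
        _, comparison = downsample_cohort(
            kept, annotation, config.comparison_depth, subseed(config.seed, "comparison")
        )
    return matrix, accountings, comparison


def stage_metrics(
    kept: Sequence[SampleRecord],
    accountings: dict[str, ReadAccounting],
    annotation: pd.DataFrame,
    config: PipelineConfig,
    comparison: dict[str, ReadAccounting] | None = None,
) -> dict[str, MetricsRow]:
    rows = {}
    for sample in kept:
        rows[sample.sample_id] = compute_sample_metrics(
            sample.sample_id,
            accountings[sample.sample_id],
            annotation,
            min_reads=config.min_reads,
            comparison=comparison[sample.sample_id] if comparison else None,
        )
    return rows


def stage_report(
    kept: Sequence[SampleRecord],
    rows: dict[str, MetricsRow],
    matrix: pd.DataFrame,
    bulk: pd.Series | None,
    config: PipelineConfig,
) -> tuple[pd.DataFrame | None, list]:
    normalized = quantile_normalize(matrix) if matrix.shape[1] >= 2 else None
    summaries = summarize_protocols(
        kept, rows, normalized, bulk_profile=bulk, log1p=config.log1p
    )
    return normalized, summaries


def _config_hash(config: PipelineConfig) -> str:
    canonical = json.dumps(asdict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write all artifacts under ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotation, samples, bulk = load_inputs(config)
    log.info("loaded %d samples, %d genes", len(samples), len(annotation))

    kept, exclusion_log = stage_qc(samples, config)
    exclusion_log.write(out / "exclusion_log.tsv")
    pd.DataFrame({"sample_id": [s.sample_id for s in kept]}).to_csv(
        out / "kept_samples.tsv", sep="\t", index=False
    )
    log.info("QC kept %d / %d samples", len(kept), len(samples))

    if not kept:
        log.warning("no samples survived QC; writing empty outputs")
        matrix = pd.DataFrame(index=annotation.index.copy())
        matrix.index.name = "gene_id"
        rows: dict[str, MetricsRow] = {}
        normalized, summaries = None, []
    else:
        matrix, accountings, comparison = stage_downsample(kept, annotation, config)
        _write_accounting(accountings, out / "downsampled_accounting.tsv")
        rows = stage_metrics(kept, accountings, annotation, config, comparison)
        normalized, summaries = stage_report(kept, rows, matrix, bulk, config)

    write_count_matrix(matrix, out / "downsampled_matrix.tsv")
    if normalized is not None:
        write_count_matrix(normalized, out / "normalized_matrix.tsv")
    write_metrics([rows[s.sample_id] for s in kept], out / "sample_metrics.tsv")
    write_summary(summaries, out / "protocol_summary.tsv")
    _write_run_log(config, len(samples), len(kept), out / "run_log.json")
    summary = pd.read_csv(out / "protocol_summary.tsv", sep="\t")
    return PipelineResult(kept, exclusion_log, matrix, normalized, rows, summary)


def _write_accounting(accountings: dict[str, ReadAccounting], path: Path) -> None:
    pd.DataFrame(
        [
            (sid, a.total_raw_reads, a.mapped_reads, a.intergenic_mapped)
            for sid, a in accountings.items()
        ],
        columns=["sample_id", "total_raw_reads", "mapped_reads", "intergenic_mapped"],
    ).to_csv(path, sep="\t", index=False)


def _write_run_log(config: PipelineConfig, n_in: int, n_kept: int, path: Path) -> None:
    import numpy
    import scipy

    payload = {
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "samples_in": n_in,
        "samples_kept": n_kept,
        "versions": {
            "ampbench": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
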