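"""Sample exclusion filters.

Four rules, applied in a fixed order, remove failed samples before any
metric is computed:

1. ``arna_yield`` — the sample failed to yield amplified RNA compared with
   the negative (water) control run in parallel; operationalised as
   ``arna_yield <= ratio * negative_control_yield`` (ratio defaults to 1).
2. ``conc_outlier`` — abnormally high library concentration
   (> 100 ng/µl), symptomatic of dimer-dominated libraries.
3. ``low_library_yield`` — library amount below the 200 ng minimum required
   for sequencing.
4. ``low_mapped`` — fewer than 3,000,000 mapped reads, the depth every
   sample is later downsampled to.

A sample is logged under the *first* rule it fails.  Samples lacking the
measurement a rule needs skip that rule (they cannot fail it); only the
mapped-depth rule is always applicable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .annotation_io import SampleRecord
from .errors import ConfigError

RULE_IDS = ("arna_yield", "conc_outlier", "low_library_yield", "low_mapped")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the four exclusion rules (all strictly positive)."""

    arna_yield_min_ratio: float = 1.0
    conc_max_ng_per_ul: float = 100.0
    library_min_ng: float = 200.0
    mapped_min_reads: int = 3_000_000

    def __post_init__(self) -> None:
        for name in (
            "arna_yield_min_ratio",
            "conc_max_ng_per_ul",
            "library_min_ng",
            "mapped_min_reads",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class ExclusionEntry:
    sample_id: str
    rule_id: str
    measured_value: float
    threshold: float


@dataclass
class ExclusionLog:
    """Audit trail: one entry per excluded sample (first failing rule wins)."""

    entries: list[ExclusionEntry] = field(default_factory=list)

    @property
    def excluded_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.sample_id, e.rule_id, e.measured_value, e.threshold) for e in self.entries],
            columns=["sample_id", "rule_id", "measured_value", "threshold"],
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _first_failure(sample: SampleRecord, config: FilterConfig) -> ExclusionEntry | None:
    if sample.arna_yield is not None and sample.negative_control_yield is not None:
        threshold = config.arna_yield_min_ratio * sample.negative_control_yield
        if sample.arna_yield <= threshold:
            return ExclusionEntry(sample.sample_id, "arna_yield", sample.arna_yield, threshold)
    if sample.library_conc_ng_per_ul is not None:
        if sample.library_conc_ng_per_ul > config.conc_max_ng_per_ul:
            return ExclusionEntry(
                sample.sample_id,
                "conc_outlier",
                sample.library_conc_ng_per_ul,
                config.conc_max_ng_per_ul,
            )
    if sample.library_yield_ng is not None:
        if sample.library_yield_ng < config.library_min_ng:
            return ExclusionEntry(
                sample.sample_id,
                "low_library_yield",
                sample.library_yield_ng,
                config.library_min_ng,
            )
    if sample.accounting.mapped_reads < config.mapped_min_reads:
        return ExclusionEntry(
            sample.sample_id,
            "low_mapped",
            float(sample.accounting.mapped_reads),
            float(config.mapped_min_reads),
        )
    return None


def apply_exclusions(
    cohort: Sequence[SampleRecord], config: FilterConfig | None = None
) -> tuple[list[SampleRecord], ExclusionLog]:
    """Partition a cohort into (kept, excluded-with-log).

    Every input sample ends up in exactly one of the two outputs; an empty
    kept set is a valid outcome.
    """
    config = config or FilterConfig()
    kept: list[SampleRecord] = []
    log = ExclusionLog()
    for sample in cohort:
        entry = _first_failure(sample, config)
        if entry is None:
            kept.append(sample)
        else:
            log.entries.append(entry)
    return kept, log
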