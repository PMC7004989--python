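"""Reading and writing of gene annotation, count data, and sample metadata.

The on-disk contracts are deliberately plain: tab-delimited text with headers.
Three tables flow into the pipeline:

* a **gene annotation** table (``gene_id``, ``gene_class``, ``length_bp``,
  ``gc_fraction``) assigning every gene to one of the classes ``standard``,
  ``rRNA`` or ``mtRNA`` — the class drives metric exclusions, length and GC
  are the covariates amplification bias acts on;
* per-sample **counts**, either in the two-column htseq-count dialect (gene
  rows plus trailing ``__``-prefixed special counters) or as a genes ×
  samples matrix;
* a **sample metadata** table carrying the wet-lab measurements the
  exclusion filters need (input mass, aRNA yield, negative-control yield,
  library concentration and yield).  Absent measurements are encoded as the
  literal string ``NA`` and surface in Python as ``None`` — the filters must
  be able to distinguish "not measured" from zero.

All tables are read fully into memory; cohorts at this scale are small.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import (
    ConsistencyError,
    FormatError,
    ValidationError,
)

GENE_CLASSES = ("standard", "rRNA", "mtRNA")

#: htseq-count special counters that represent reads absent from the genome
#: alignment; everything else prefixed ``__`` is mapped but not gene-assigned.
UNMAPPED_SPECIALS = frozenset({"not_aligned"})

ANNOTATION_COLUMNS = ("gene_id", "gene_class", "length_bp", "gc_fraction")
METADATA_COLUMNS = (
    "sample_id",
    "protocol",
    "replicate_group",
    "input_pg",
    "arna_yield",
    "negative_control_yield",
    "library_conc_ng_per_ul",
    "library_yield_ng",
)


@dataclass(frozen=True)
class ReadAccounting:
    """Read-level bookkeeping for one sample.

    Invariants (enforced at construction): ``mapped_reads <= total_raw_reads``
    and ``sum(gene_counts) + intergenic_mapped == mapped_reads``.  The
    ``intergenic_mapped`` bin holds reads that aligned to the genome but were
    not uniquely assigned to a gene model.
    """

    total_raw_reads: int
    mapped_reads: int
    gene_counts: dict[str, int]
    intergenic_mapped: int

    def __post_init__(self) -> None:
        if self.total_raw_reads < 0 or self.mapped_reads < 0 or self.intergenic_mapped < 0:
            raise ConsistencyError("read totals must be non-negative")
        if self.mapped_reads > self.total_raw_reads:
            raise ConsistencyError(
                f"mapped_reads ({self.mapped_reads}) exceeds "
                f"total_raw_reads ({self.total_raw_reads})"
            )
        negative = [g for g, c in self.gene_counts.items() if c < 0]
        if negative:
            raise ConsistencyError(f"negative gene counts: {negative[:5]}")
        assigned = sum(self.gene_counts.values()) + self.intergenic_mapped
        if assigned != self.mapped_reads:
            raise ConsistencyError(
                f"gene counts + intergenic ({assigned}) != mapped_reads "
                f"({self.mapped_reads})"
            )


@dataclass(frozen=True)
class SampleRecord:
    """One sample: read accounting plus the wet-lab metadata QC filters use.

    Metadata fields are ``None`` when the measurement was not taken (e.g.
    reference-RNA runs have no aRNA yield record); they are never silently
    zero.
    """

    sample_id: str
    protocol: str
    replicate_group: str
    input_pg: float
    accounting: ReadAccounting
    arna_yield: float | None = None
    negative_control_yield: float | None = None
    library_conc_ng_per_ul: float | None = None
    library_yield_ng: float | None = None


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation TSV into a DataFrame indexed by ``gene_id``.

    Raises :class:`FormatError` on missing columns and
    :class:`ValidationError` on duplicate gene ids, unknown classes, or
    out-of-range length / GC values.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation {path}: missing column(s) {missing}")
    return validate_annotation(df.set_index("gene_id"))


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Validate an annotation DataFrame (index gene_id) and return it."""
    if annotation.index.has_duplicates:
        dupes = annotation.index[annotation.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene_id(s): {dupes[:5]}")
    bad_class = annotation.loc[~annotation["gene_class"].isin(GENE_CLASSES)]
    if len(bad_class):
        first = bad_class.iloc[0]
        raise ValidationError(
            f"unknown gene_class {first['gene_class']!r} for gene "
            f"{bad_class.index[0]!r}"
        )
    if (annotation["length_bp"] < 1).any():
        bad = annotation.index[annotation["length_bp"] < 1][0]
        raise ValidationError(f"length_bp < 1 for gene {bad!r}")
    gc = annotation["gc_fraction"]
    if ((gc < 0) | (gc > 1)).any():
        bad = annotation.index[(gc < 0) | (gc > 1)][0]
        raise ValidationError(f"gc_fraction outside [0,1] for gene {bad!r}")
    return annotation


def write_gene_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index_label="gene_id")


def read_htseq_counts(path: str | Path) -> tuple[dict[str, int], dict[str, int]]:
    """Parse an htseq-count two-column file.

    Returns ``(gene_counts, special_counters)`` with the ``__`` prefix
    stripped from special-counter names.  Row order is not assumed: gene rows
    after special rows are accepted.
    """
    gene_counts: dict[str, int] = {}
    specials: dict[str, int] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(row)}")
            name, raw_count = row
            try:
                count = int(raw_count)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer count {raw_count!r}"
                ) from None
            if count < 0:
                raise FormatError(f"{path}:{lineno}: negative count {count}")
            if name.startswith("__"):
                specials[name[2:]] = specials.get(name[2:], 0) + count
            else:
                if name in gene_counts:
                    raise FormatError(f"{path}:{lineno}: duplicate gene row {name!r}")
                gene_counts[name] = count
    return gene_counts, specials


def write_htseq_counts(
    gene_counts: Mapping[str, int],
    specials: Mapping[str, int],
    path: str | Path,
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for gene, count in gene_counts.items():
            w.writerow([gene, count])
        for name, count in specials.items():
            w.writerow([f"__{name}", count])


def assemble_sample(
    metadata_row: Mapping[str, object],
    gene_counts: Mapping[str, int],
    special_counters: Mapping[str, int],
) -> SampleRecord:
    """Build a SampleRecord whose ReadAccounting invariants hold by construction.

    Mapped reads = gene-assigned reads + mapped-but-unassigned specials
    (``no_feature``, ``ambiguous``, ``alignment_not_unique``,
    ``too_low_aQual``, ...); raw reads additionally include ``not_aligned``.
    """
    unmapped = sum(c for k, c in special_counters.items() if k in UNMAPPED_SPECIALS)
    intergenic = sum(c for k, c in special_counters.items() if k not in UNMAPPED_SPECIALS)
    gene_total = sum(gene_counts.values())
    mapped = gene_total + intergenic
    accounting = ReadAccounting(
        total_raw_reads=mapped + unmapped,
        mapped_reads=mapped,
        gene_counts=dict(gene_counts),
        intergenic_mapped=intergenic,
    )

    def _opt(key: str) -> float | None:
        value = metadata_row.get(key)
        if value is None or (isinstance(value, float) and pd.isna(value)) or value == "NA":
            return None
        return float(value)  # type: ignore[arg-type]

    return SampleRecord(
        sample_id=str(metadata_row["sample_id"]),
        protocol=str(metadata_row["protocol"]),
        replicate_group=str(metadata_row["replicate_group"]),
        input_pg=float(metadata_row["input_pg"]),  # type: ignore[arg-type]
        accounting=accounting,
        arna_yield=_opt("arna_yield"),
        negative_control_yield=_opt("negative_control_yield"),
        library_conc_ng_per_ul=_opt("library_conc_ng_per_ul"),
        library_yield_ng=_opt("library_yield_ng"),
    )


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV. Only the literal string ``NA`` is absent."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=["NA"])
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata {path}: missing column(s) {missing}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample_id(s): {dupes[:5]}")
    return df


def write_sample_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def load_cohort(metadata: pd.DataFrame, counts_dir: str | Path) -> list[SampleRecord]:
    """Assemble SampleRecords from a metadata table plus per-sample htseq files.

    Count files are looked up as ``<counts_dir>/<sample_id>.tsv``.
    """
    counts_dir = Path(counts_dir)
    cohort = []
    for _, row in metadata.iterrows():
        gene_counts, specials = read_htseq_counts(counts_dir / f"{row['sample_id']}.tsv")
        cohort.append(assemble_sample(row.to_dict(), gene_counts, specials))
    return cohort


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes × samples TSV matrix (first column gene_id).

    Ragged rows or duplicate ids raise :class:`FormatError` /
    :class:`ValidationError`.
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0]
    if len(header) < 2:
        raise FormatError(f"{path}: need a gene_id column plus >=1 sample column")
    sample_ids = header[1:]
    gene_ids, values = [], []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
            )
        gene_ids.append(row[0])
        try:
            values.append([float(v) for v in row[1:]])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric count") from None
    matrix = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    if matrix.index.has_duplicates:
        raise ValidationError(f"{path}: duplicate gene ids")
    if (matrix.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative entries")
    # preserve integer counts exactly when the file held integers
    as_int = matrix.round()
    if (matrix == as_int).all().all():
        matrix = as_int.astype("int64")
    return matrix


def write_count_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")
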