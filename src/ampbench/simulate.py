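"""Stochastic simulator of single-cell RNA amplification chemistries.

The simulator generates synthetic cohorts with the statistical structure the
benchmark metrics see, as mechanistic caricatures of three amplification
strategies:

* ``ivt_linear`` — aRNA amplification by in-vitro transcription: per round,
  each template yields a Poisson number of copies, and each product survives
  the bead-purification cleanup independently.  Linear amplification is
  abundance-preserving in expectation, whatever the yield or loss.
* ``pcr_exponential`` — PCR (SMARTer-style): a Galton–Watson branching
  process in which each molecule duplicates per cycle with a per-gene
  probability whose logit shifts with GC content and log-length — short,
  low-GC fragments amplify preferentially, so the expected fold
  ``(1 + e_g)^cycles`` distorts relative abundances.
* ``nugen_spa`` — isothermal linear DNA amplification (SPIA): modelled as a
  single linear amplification round, plus input-dependent primer-dimer
  contamination: at low template concentration the primers self-amplify and
  a fraction of reads (scaling inversely with input mass) becomes
  unmappable.

The full pipeline per sample: Poisson capture of molecules from a log-normal
abundance profile (scaled by input mass in pg), protocol-specific
amplification, then a single multinomial "sequencer" that allocates reads to
unmapped / intergenic / rRNA / mtRNA / standard-gene classes, the gene-level
split within each class proportional to amplified molecule counts.  Every
stage is reproducible from the master seed; per-sample and per-stage streams
are hash-derived so cohort composition never shifts another sample's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .annotation_io import (
    ReadAccounting,
    SampleRecord,
    write_gene_annotation,
    write_htseq_counts,
    write_sample_metadata,
)
from .errors import ConfigError
from .resample import subseed

PROTOCOL_MODELS = ("ivt_linear", "pcr_exponential", "nugen_spa")

#: Named protocol presets mapping wet-lab protocols onto simulator models.
PROTOCOL_PRESETS: dict[str, dict] = {
    "modified_aRNA": {"protocol_model": "ivt_linear", "ivt_rounds": 2},
    "original_aRNA": {"protocol_model": "ivt_linear", "ivt_rounds": 3},
    "SMARTer": {"protocol_model": "pcr_exponential"},
    "NuGEN": {"protocol_model": "nugen_spa"},
}


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of one synthetic cohort.

    Defaults mirror the benchmark's reference condition: 25 technical
    replicates of 10 pg input sequenced deep enough to clear a 3-million
    mapped-read cutoff, ~100,000 polyadenylated molecules captured per
    10 pg, two IVT rounds with 50% recovery per cleanup.
    """

    n_genes: int = 20_000
    abundance_sigma: float = 1.5
    rrna_fraction: float = 0.03
    mt_fraction: float = 0.04
    intergenic_fraction: float = 0.13
    unmapped_fraction: float = 0.08
    input_pg: float = 10.0
    molecules_per_10pg: int = 100_000
    protocol: str = "modified_aRNA"
    protocol_model: str = "ivt_linear"
    ivt_rounds: int = 2
    ivt_yield_per_molecule: float = 200.0
    purification_retention: float = 0.5
    pcr_cycles: int = 18
    pcr_efficiency_base: float = 0.25
    pcr_gc_coeff: float = -1.0
    pcr_length_coeff: float = -0.5
    dimer_fraction_at_5pg: float = 0.6
    reads_per_sample: int = 3_250_000
    n_replicates: int = 25
    n_rrna_genes: int = 5
    n_mt_genes: int = 13
    arna_fail_fraction: float = 0.0
    conc_fail_fraction: float = 0.0
    library_fail_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        fractions = (
            self.rrna_fraction,
            self.mt_fraction,
            self.intergenic_fraction,
            self.unmapped_fraction,
        )
        if any(f < 0 or f >= 1 for f in fractions):
            raise ConfigError("class fractions must lie in [0, 1)")
        if sum(fractions) >= 1:
            raise ConfigError("class fractions must sum to < 1")
        if self.n_genes < 3:
            raise ConfigError("n_genes must be >= 3")
        if self.protocol_model not in PROTOCOL_MODELS:
            raise ConfigError(f"unknown protocol_model {self.protocol_model!r}")
        if min(self.molecules_per_10pg, self.reads_per_sample, self.n_replicates) <= 0:
            raise ConfigError("molecule counts, depths and replicates must be positive")
        if self.input_pg <= 0:
            raise ConfigError("input_pg must be positive")
        if not (0 < self.purification_retention <= 1):
            raise ConfigError("purification_retention must be in (0, 1]")
        if not (0 < self.pcr_efficiency_base <= 1):
            raise ConfigError("pcr_efficiency_base must be in (0, 1]")
        if not (0 <= self.dimer_fraction_at_5pg < 1):
            raise ConfigError("dimer_fraction_at_5pg must be in [0, 1)")

    @classmethod
    def for_protocol(cls, protocol: str, **overrides) -> "SimulationConfig":
        """Config for a named preset protocol, with optional field overrides."""
        if protocol not in PROTOCOL_PRESETS:
            raise ConfigError(
                f"unknown protocol {protocol!r}; presets: {sorted(PROTOCOL_PRESETS)}"
            )
        params = {"protocol": protocol, **PROTOCOL_PRESETS[protocol], **overrides}
        return cls(**params)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "protocol" in data and data["protocol"] in PROTOCOL_PRESETS:
            protocol = data.pop("protocol")
            return cls.for_protocol(protocol, **data)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


#: Depth of the scaled benchmark: 1/30 of the 3-million-read study depth.
SCALED_BENCHMARK_DEPTH = 100_000


def scaled_benchmark_config(
    protocol: str, input_pg: float = 10.0, seed: int = 0, **overrides
) -> SimulationConfig:
    """Config for the scaled-down benchmark used by the acceptance checks.

    Sequencing depth and captured-molecule number are both scaled by the same
    factor (~1/30) relative to the full-depth defaults, preserving the
    reads-per-captured-molecule regime in which one captured molecule yields
    ~20 reads and gene detection is presence-dominated — the regime of the
    full-scale benchmark.  Downsample cohorts to
    :data:`SCALED_BENCHMARK_DEPTH` mapped reads.
    """
    params = {
        "input_pg": input_pg,
        "seed": seed,
        "reads_per_sample": 350_000,
        "molecules_per_10pg": 3_300,
        **overrides,
    }
    return SimulationConfig.for_protocol(protocol, **params)


@dataclass
class SimulatedCohort:
    """A simulated cohort plus its ground truth."""

    config: SimulationConfig
    annotation: pd.DataFrame
    samples: list[SampleRecord]
    abundances: pd.Series
    bulk_profile: pd.Series


def simulate_annotation(
    n_genes: int,
    seed: int,
    n_rrna: int = 5,
    n_mt: int = 13,
) -> pd.DataFrame:
    """Synthetic gene annotation: log-uniform lengths in [300, 10000] bp,
    GC uniform in [0.3, 0.7], with small fixed rRNA and mtRNA gene sets."""
    if n_genes < 3:
        raise ConfigError("n_genes must be >= 3")
    n_rrna = max(1, min(n_rrna, (n_genes - 1) // 2))
    n_mt = max(1, min(n_mt, n_genes - n_rrna - 1))
    rng = np.random.default_rng(seed)
    lengths = np.exp(rng.uniform(np.log(300), np.log(10_000), size=n_genes))
    gc = rng.uniform(0.3, 0.7, size=n_genes)
    width = len(str(n_genes))
    ids = (
        [f"RRNA{i + 1:02d}" for i in range(n_rrna)]
        + [f"MT{i + 1:02d}" for i in range(n_mt)]
        + [f"GENE{i + 1:0{width}d}" for i in range(n_genes - n_rrna - n_mt)]
    )
    classes = ["rRNA"] * n_rrna + ["mtRNA"] * n_mt + ["standard"] * (n_genes - n_rrna - n_mt)
    annotation = pd.DataFrame(
        {
            "gene_class": classes,
            "length_bp": np.maximum(1, lengths.round().astype(int)),
            "gc_fraction": gc,
        },
        index=pd.Index(ids, name="gene_id"),
    )
    return annotation


def simulate_abundances(annotation: pd.DataFrame, sigma: float, seed: int) -> pd.Series:
    """Log-normal relative transcript abundances over the gene universe."""
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(mean=0.0, sigma=sigma, size=len(annotation))
    return pd.Series(raw / raw.sum(), index=annotation.index, name="abundance")


def capture_molecules(
    abundances: pd.Series,
    input_pg: float,
    molecules_per_10pg: int,
    seed: int,
) -> pd.Series:
    """Poisson capture of molecules from the input mass.

    Expected total is ``molecules_per_10pg * input_pg / 10``; per-gene counts
    are independent Poisson with mean proportional to abundance.
    """
    values = np.asarray(abundances, dtype=float)
    if abs(values.sum() - 1.0) > 1e-6:
        raise ConfigError("abundances must sum to 1")
    rng = np.random.default_rng(seed)
    total = molecules_per_10pg * input_pg / 10.0
    counts = rng.poisson(values * total)
    return pd.Series(counts, index=abundances.index, name="molecules")


def amplify_ivt(
    molecules: pd.Series,
    ivt_rounds: int,
    yield_per_molecule: float,
    purification_retention: float,
    seed: int,
) -> pd.Series:
    """Linear (IVT) amplification: Poisson copies then cleanup survival, per round.

    No sequence-covariate bias: expected relative abundances are preserved.
    """
    if ivt_rounds < 1:
        raise ConfigError("ivt_rounds must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.asarray(molecules, dtype=np.int64)
    for _ in range(ivt_rounds):
        copies = rng.poisson(counts.astype(float) * yield_per_molecule)
        counts = rng.binomial(copies, purification_retention)
    return pd.Series(counts, index=molecules.index, name="amplified")


def pcr_efficiency(
    annotation: pd.DataFrame,
    efficiency_base: float,
    gc_coeff: float,
    length_coeff: float,
) -> pd.Series:
    """Per-gene per-cycle duplication probability.

    ``logistic(logit(base) + gc_coeff * (gc - 0.5) + length_coeff *
    (log10(length) - 3))``; base 1 gives deterministic doubling.
    """
    eta = (
        logit(efficiency_base)
        + gc_coeff * (annotation["gc_fraction"].to_numpy() - 0.5)
        + length_coeff * (np.log10(annotation["length_bp"].to_numpy()) - 3.0)
    )
    return pd.Series(expit(eta), index=annotation.index, name="efficiency")


def amplify_pcr(
    molecules: pd.Series,
    pcr_cycles: int,
    efficiency_base: float,
    gc_coeff: float,
    length_coeff: float,
    annotation: pd.DataFrame,
    seed: int,
) -> pd.Series:
    """Exponential (PCR) amplification as a Galton–Watson branching process.

    Each molecule duplicates with per-gene probability ``e_g`` every cycle;
    the expected fold is ``(1 + e_g)^cycles``.
    """
    if pcr_cycles < 1:
        raise ConfigError("pcr_cycles must be >= 1")
    e_g = pcr_efficiency(annotation, efficiency_base, gc_coeff, length_coeff)
    e = e_g.reindex(molecules.index).to_numpy()
    rng = np.random.default_rng(seed)
    counts = np.asarray(molecules, dtype=np.int64)
    for _ in range(pcr_cycles):
        counts = counts + rng.binomial(counts, e)
    return pd.Series(counts, index=molecules.index, name="amplified")


def primer_dimer_fraction(
    protocol_model: str, input_pg: float, dimer_fraction_at_5pg: float
) -> float:
    """Primer-dimer read fraction; nonzero only for the SPIA model.

    Scales inversely with input mass (template shortage lets primers
    self-amplify), capped at 0.95.
    """
    if protocol_model != "nugen_spa":
        return 0.0
    return min(0.95, dimer_fraction_at_5pg * 5.0 / input_pg)


def _class_probabilities(
    amplified: pd.Series,
    annotation: pd.DataFrame,
    rrna_fraction: float,
    mt_fraction: float,
    intergenic_fraction: float,
    unmapped_fraction: float,
    dimer_fraction: float,
) -> np.ndarray:
    """Per-bin probabilities: one per gene, then intergenic, then unmapped."""
    unmapped = unmapped_fraction + dimer_fraction
    if unmapped >= 1:
        raise ConfigError(
            f"unmapped + dimer fraction ({unmapped:.3f}) must stay below 1"
        )
    # dimers displace mapped reads: rescale every mapped class to the mass left
    scale = (1.0 - unmapped) / (1.0 - unmapped_fraction)
    masses = {
        "rRNA": rrna_fraction * scale,
        "mtRNA": mt_fraction * scale,
        "standard": (
            1.0 - unmapped_fraction - rrna_fraction - mt_fraction - intergenic_fraction
        )
        * scale,
    }
    intergenic = intergenic_fraction * scale

    counts = amplified.reindex(annotation.index).fillna(0).to_numpy(dtype=float)
    classes = annotation["gene_class"].to_numpy()
    probs = np.zeros(len(annotation))
    spare = 0.0
    for cls, mass in masses.items():
        member = classes == cls
        weight = counts[member].sum()
        if weight > 0:
            probs[member] = mass * counts[member] / weight
        elif member.any() and cls != "standard":
            probs[member] = mass / member.sum()  # uniform fallback within class
        else:
            spare += mass  # no template at all: mass joins the mapped remainder
    if spare > 0:
        mapped = probs.sum() + intergenic
        if mapped > 0:
            rescale = (mapped + spare) / mapped
            probs *= rescale
            intergenic *= rescale
    return np.concatenate([probs, [intergenic, unmapped]])


def sequence_reads(
    amplified: pd.Series,
    annotation: pd.DataFrame,
    rrna_fraction: float,
    mt_fraction: float,
    intergenic_fraction: float,
    unmapped_fraction: float,
    dimer_fraction: float,
    reads_per_sample: int,
    seed: int,
) -> ReadAccounting:
    """Allocate reads by a single multinomial draw over gene/class bins."""
    if reads_per_sample < 1:
        raise ConfigError("reads_per_sample must be >= 1")
    probs = _class_probabilities(
        amplified,
        annotation,
        rrna_fraction,
        mt_fraction,
        intergenic_fraction,
        unmapped_fraction,
        dimer_fraction,
    )
    rng = np.random.default_rng(seed)
    draw = rng.multinomial(reads_per_sample, probs / probs.sum())
    gene_counts = {g: int(c) for g, c in zip(annotation.index, draw[:-2])}
    intergenic, unmapped = int(draw[-2]), int(draw[-1])
    return ReadAccounting(
        total_raw_reads=reads_per_sample,
        mapped_reads=reads_per_sample - unmapped,
        gene_counts=gene_counts,
        intergenic_mapped=intergenic,
    )


def _amplify(
    config: SimulationConfig,
    molecules: pd.Series,
    annotation: pd.DataFrame,
    seed: int,
) -> pd.Series:
    if config.protocol_model == "pcr_exponential":
        return amplify_pcr(
            molecules,
            config.pcr_cycles,
            config.pcr_efficiency_base,
            config.pcr_gc_coeff,
            config.pcr_length_coeff,
            annotation,
            seed,
        )
    rounds = config.ivt_rounds if config.protocol_model == "ivt_linear" else 1
    return amplify_ivt(
        molecules,
        rounds,
        config.ivt_yield_per_molecule,
        config.purification_retention,
        seed,
    )


def _bulk_profile(
    abundances: pd.Series, annotation: pd.DataFrame, config: SimulationConfig
) -> pd.Series:
    """Noiseless expected read profile at infinite input, no amplification bias."""
    classes = annotation["gene_class"]
    std_mass = 1.0 - (
        config.unmapped_fraction
        + config.rrna_fraction
        + config.mt_fraction
        + config.intergenic_fraction
    )
    masses = {
        "standard": std_mass,
        "rRNA": config.rrna_fraction,
        "mtRNA": config.mt_fraction,
    }
    profile = pd.Series(0.0, index=annotation.index, name="expected_reads")
    for cls, mass in masses.items():
        member = classes == cls
        weight = abundances[member].sum()
        if weight > 0:
            profile[member] = mass * abundances[member] / weight * config.reads_per_sample
    return profile


def _metadata_for_sample(
    rng: np.random.Generator, config: SimulationConfig
) -> dict[str, float]:
    """Wet-lab metadata draws; a configurable fraction fail each QC rule."""
    negative_control = max(1.0, rng.normal(50.0, 5.0))
    if rng.random() < config.arna_fail_fraction:
        arna = negative_control * rng.uniform(0.2, 0.9)
    else:
        arna = max(negative_control * 1.5, rng.normal(2000.0, 300.0))
    if rng.random() < config.conc_fail_fraction:
        conc = rng.uniform(120.0, 200.0)
    else:
        conc = max(1.0, rng.normal(25.0, 5.0))
    if rng.random() < config.library_fail_fraction:
        library = rng.uniform(50.0, 150.0)
    else:
        library = max(250.0, rng.normal(800.0, 100.0))
    return {
        "arna_yield": arna,
        "negative_control_yield": negative_control,
        "library_conc_ng_per_ul": conc,
        "library_yield_ng": library,
    }


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a cohort of technical replicates sharing one ground truth.

    All replicates share one abundance profile and replicate group; capture,
    amplification, sequencing and metadata noise are independent per sample.
    Fully reproducible from ``config.seed``.
    """
    annotation = simulate_annotation(
        config.n_genes,
        subseed(config.seed, "annotation"),
        n_rrna=config.n_rrna_genes,
        n_mt=config.n_mt_genes,
    )
    abundances = simulate_abundances(
        annotation, config.abundance_sigma, subseed(config.seed, "abundances")
    )
    bulk = _bulk_profile(abundances, annotation, config)
    dimer = primer_dimer_fraction(
        config.protocol_model, config.input_pg, config.dimer_fraction_at_5pg
    )
    samples = []
    for i in range(config.n_replicates):
        sid = f"{config.protocol}_{i + 1:03d}"
        molecules = capture_molecules(
            abundances,
            config.input_pg,
            config.molecules_per_10pg,
            subseed(config.seed, f"{sid}:capture"),
        )
        amplified = _amplify(config, molecules, annotation, subseed(config.seed, f"{sid}:amplify"))
        accounting = sequence_reads(
            amplified,
            annotation,
            config.rrna_fraction,
            config.mt_fraction,
            config.intergenic_fraction,
            config.unmapped_fraction,
            dimer,
            config.reads_per_sample,
            subseed(config.seed, f"{sid}:sequence"),
        )
        meta_rng = np.random.default_rng(subseed(config.seed, f"{sid}:metadata"))
        metadata = _metadata_for_sample(meta_rng, config)
        samples.append(
            SampleRecord(
                sample_id=sid,
                protocol=config.protocol,
                replicate_group=f"{config.protocol}_rg1",
                input_pg=config.input_pg,
                accounting=accounting,
                **metadata,
            )
        )
    return SimulatedCohort(
        config=config,
        annotation=annotation,
        samples=samples,
        abundances=abundances,
        bulk_profile=bulk,
    )


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> None:
    """Write a cohort in the pipeline's on-disk contracts.

    Produces annotation.tsv, metadata.tsv, bulk_profile.tsv, abundances.tsv,
    sim_config.yaml and one htseq-style count file per sample under
    ``counts/``; the intergenic and unmapped bins are encoded as the
    ``__no_feature`` and ``__not_aligned`` special counters.
    """
    out = Path(out_dir)
    (out / "counts").mkdir(parents=True, exist_ok=True)
    write_gene_annotation(cohort.annotation, out / "annotation.tsv")
    cohort.abundances.to_csv(out / "abundances.tsv", sep="\t", header=True)
    cohort.bulk_profile.to_csv(out / "bulk_profile.tsv", sep="\t", header=True)
    cohort.config.to_yaml(out / "sim_config.yaml")
    rows = []
    for sample in cohort.samples:
        acc = sample.accounting
        write_htseq_counts(
            acc.gene_counts,
            {
                "no_feature": acc.intergenic_mapped,
                "not_aligned": acc.total_raw_reads - acc.mapped_reads,
            },
            out / "counts" / f"{sample.sample_id}.tsv",
        )
        rows.append(
            {
                "sample_id": sample.sample_id,
                "protocol": sample.protocol,
                "replicate_group": sample.replicate_group,
                "input_pg": sample.input_pg,
                "arna_yield": sample.arna_yield,
                "negative_control_yield": sample.negative_control_yield,
                "library_conc_ng_per_ul": sample.library_conc_ng_per_ul,
                "library_yield_ng": sample.library_yield_ng,
            }
        )
    write_sample_metadata(pd.DataFrame(rows), out / "metadata.tsv")
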