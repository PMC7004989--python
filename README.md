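# ampbench

Benchmarking single-cell RNA **amplification protocols** from read-count
data: quality-control filters, fixed-depth downsampling, quantile
normalization, the five standard quality metrics, and a mechanistic
simulator of linear (IVT/aRNA), exponential (PCR/SMARTer) and isothermal
(SPIA/NuGEN) amplification chemistries.

Single-cell and Patch-Seq experiments start from ~5–10 pg of RNA and must
amplify it ~10⁵-fold.  PCR amplifies exponentially and is prone to bias
(favouring short, low-GC fragments) and per-molecule stochasticity; linear
methods copy templates proportionally per round and are more robust at low
input, while SPIA suffers primer self-amplification (dimers) when template
is scarce.  `ampbench` implements the evaluation pipeline used to compare
such protocols and a synthetic-cohort generator so the whole analysis is
testable without sequencing data.

## The five metrics

For a sample with `R` raw reads, `M` mapped reads, and per-gene uniquely
mapped counts `c_g` (gene classes: standard, rRNA, mtRNA; plus an
intergenic bin for mapped-but-unassigned reads):

* **total mapping rate** = `M / R`
* **transcriptomic mapping ratio** = `Σ_standard c_g / M`
  (rRNA/mtRNA excluded from the numerator, so standard + rRNA/mtRNA +
  intergenic fractions sum to 1)
* **gene model discovery rate** = `#{g : c_g > 5}` at a fixed downsampled
  depth (3,000,000 mapped reads by default)
* **reproducibility** = mean pairwise Pearson `r` between technical
  replicates, on quantile-normalized downsampled counts
* **accuracy** = mean Pearson `r` of each sample against a bulk reference
  profile

Samples are first excluded if their aRNA yield does not beat the negative
control, their library concentration exceeds 100 ng/µl, their library yield
is under 200 ng, or they have fewer than 3,000,000 mapped reads; depth is
then equalized by multivariate-hypergeometric downsampling (sampling reads
without replacement over count bins).

## Worked example

Simulate a 25-replicate cohort of the two-round IVT protocol at the scaled
benchmark depth, run the full pipeline, and print the protocol summary:

```python
from ampbench.benchmark import benchmark_protocol

frame = benchmark_protocol("modified_aRNA", input_pg=10.0, n_cohorts=2, master_seed=1)
print(frame[["cohort", "total_mapping_rate", "genes_detected", "reproducibility"]])
```

```
   cohort  total_mapping_rate  genes_detected  reproducibility
0       0            0.919975         2283.88         0.428901
1       1            0.919951         2303.64         0.503711
```

Each row is one simulated cohort of 25 technical replicates downsampled to
100,000 mapped reads: ~92 % of reads map (the configured clean-library
rate), ~2,300 of 20,000 genes exceed the >5-read detection threshold at
this depth, and replicate expression profiles correlate at `r` ≈ 0.4 (a
scale-dependent value; deeper cohorts score higher).  Running the same with
`"SMARTer"` yields fewer detected genes and lower reproducibility — the
cost of PCR's GC/length bias and branching noise — and `"NuGEN"` at 5 pg
input collapses to a ~32 % mapping rate as primer dimers take over the
library.

The same analysis is available from a shell:

```
ampbench simulate --protocol modified_aRNA --out cohort/ --seed 1
ampbench run --config pipeline.yaml
```

where `pipeline.yaml` points at the cohort's annotation, counts and
metadata files (see `docs/methods.md` for the file contracts; `qc`,
`downsample`, `metrics` and `report` subcommands expose the individual
stages).

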