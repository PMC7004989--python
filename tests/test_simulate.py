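"""Simulator mechanics: capture, amplification models, sequencing, cohorts."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from ampbench.errors import ConfigError
from ampbench.simulate import (
    SimulationConfig,
    amplify_ivt,
    amplify_pcr,
    capture_molecules,
    primer_dimer_fraction,
    sequence_reads,
    simulate_abundances,
    simulate_annotation,
    simulate_cohort,
    write_cohort,
)


class TestSimulateAnnotation:
    def test_deterministic_given_seed(self):
        a = simulate_annotation(100, seed=1)
        b = simulate_annotation(100, seed=1)
        pd.testing.assert_frame_equal(a, b)

    def test_contains_rrna_and_mt_genes(self):
        ann = simulate_annotation(50, seed=0)
        classes = set(ann["gene_class"])
        assert {"standard", "rRNA", "mtRNA"} <= classes

    def test_covariates_within_bounds(self):
        ann = simulate_annotation(500, seed=2)
        assert ann["gc_fraction"].between(0.3, 0.7).all()
        assert ann["length_bp"].between(300, 10_000).all()

    def test_too_few_genes_rejected(self):
        with pytest.raises(ConfigError):
            simulate_annotation(2, seed=0)


class TestCaptureMolecules:
    @pytest.fixture
    def abundances(self):
        ann = simulate_annotation(100, seed=3)
        return simulate_abundances(ann, sigma=1.0, seed=3)

    def test_poisson_total_matches_input_mass(self, abundances):
        totals = [
            capture_molecules(abundances, 10.0, 100_000, seed=s).sum()
            for s in range(100)
        ]
        # total is Poisson(100,000): SD of the mean over 100 draws
        se = np.sqrt(100_000 / 100)
        assert abs(np.mean(totals) - 100_000) < 3 * se

    def test_half_input_halves_expected_total(self, abundances):
        totals = [
            capture_molecules(abundances, 5.0, 100_000, seed=s).sum()
            for s in range(100)
        ]
        se = np.sqrt(50_000 / 100)
        assert abs(np.mean(totals) - 50_000) < 3 * se

    def test_zero_abundance_gene_never_captured(self, abundances):
        values = abundances.copy()
        values.iloc[0] = 0.0
        values /= values.sum()
        for seed in range(20):
            assert capture_molecules(values, 10.0, 10_000, seed=seed).iloc[0] == 0

    def test_unnormalized_abundances_rejected(self, abundances):
        with pytest.raises(ConfigError):
            capture_molecules(abundances * 2, 10.0, 1000, seed=0)


class TestAmplifyIvt:
    def test_zero_yield_is_absorbing(self):
        molecules = pd.Series([10, 20, 30])
        out = amplify_ivt(molecules, 2, 0.0, 1.0, seed=0)
        assert (out == 0).all()

    def test_single_round_mean_fold_equals_yield(self):
        molecules = pd.Series([100])
        outs = [amplify_ivt(molecules, 1, 50.0, 1.0, seed=s).iloc[0] for s in range(1000)]
        # output is Poisson(100 * 50); SE of mean over 1000 draws
        se = np.sqrt(5000 / 1000)
        assert abs(np.mean(outs) - 5000) < 3 * se

    def test_relative_abundances_preserved_in_expectation(self):
        molecules = pd.Series([1000, 3000, 6000])
        rel_in = molecules / molecules.sum()
        rels = np.array([
            (lambda o: o / o.sum())(amplify_ivt(molecules, 2, 20.0, 0.5, seed=s))
            for s in range(200)
        ])
        se = rels.std(axis=0, ddof=1) / np.sqrt(len(rels))
        assert (np.abs(rels.mean(axis=0) - rel_in.to_numpy()) < 4 * se).all()


class TestAmplifyPcr:
    def test_perfect_efficiency_doubles_every_cycle(self):
        ann = simulate_annotation(4, seed=1)
        molecules = pd.Series([3, 5, 7, 11], index=ann.index)
        out = amplify_pcr(molecules, 6, 1.0, -1.0, -0.5, ann, seed=0)
        assert (out == molecules * 2**6).all()

    def test_zero_input_stays_zero(self):
        ann = simulate_annotation(3, seed=1)
        molecules = pd.Series([0, 10, 0], index=ann.index)
        out = amplify_pcr(molecules, 10, 0.5, 0.0, 0.0, ann, seed=0)
        assert out.iloc[0] == 0 and out.iloc[2] == 0

    def test_negative_gc_coefficient_disfavors_high_gc(self):
        # equal lengths isolate the GC effect; compare to (1+e)^c closed form
        ann = pd.DataFrame(
            {"gene_class": ["standard"] * 5, "length_bp": [1000] * 5,
             "gc_fraction": np.linspace(0.3, 0.7, 5)},
            index=pd.Index([f"G{i}" for i in range(5)], name="gene_id"),
        )
        molecules = pd.Series([1000] * 5, index=ann.index)
        cycles, base, gc_coeff = 10, 0.3, -1.5
        sims = np.array([
            amplify_pcr(molecules, cycles, base, gc_coeff, 0.0, ann, seed=s).to_numpy()
            for s in range(300)
        ])
        e = expit(logit(base) + gc_coeff * (ann["gc_fraction"].to_numpy() - 0.5))
        closed_form = 1000 * (1 + e) ** cycles
        se = sims.std(axis=0, ddof=1) / np.sqrt(len(sims))
        assert (np.abs(sims.mean(axis=0) - closed_form) < 4 * se).all()
        rel = sims.mean(axis=0) / sims.mean(axis=0).sum()
        assert (np.diff(rel) < 0).all()  # strictly decreasing in GC
        assert rel[-1] < molecules.iloc[-1] / molecules.sum()


class TestPrimerDimer:
    def test_zero_for_linear_protocols(self):
        assert primer_dimer_fraction("ivt_linear", 5.0, 0.5) == 0.0
        assert primer_dimer_fraction("pcr_exponential", 5.0, 0.5) == 0.0

    def test_reference_input_returns_configured_fraction(self):
        assert primer_dimer_fraction("nugen_spa", 5.0, 0.5) == 0.5

    def test_low_input_capped(self):
        assert primer_dimer_fraction("nugen_spa", 2.5, 0.5) == 0.95


class TestSequenceReads:
    @pytest.fixture
    def setup(self):
        ann = simulate_annotation(50, seed=4)
        amplified = pd.Series(
            np.random.default_rng(4).integers(0, 1000, len(ann)), index=ann.index
        )
        return ann, amplified

    def test_accounting_identity_holds(self, setup):
        ann, amplified = setup
        acc = sequence_reads(amplified, ann, 0.03, 0.04, 0.13, 0.08, 0.0, 3_250_000, seed=0)
        assert acc.total_raw_reads == 3_250_000
        assert sum(acc.gene_counts.values()) + acc.intergenic_mapped == acc.mapped_reads

    def test_dimers_depress_mapping_rate(self, setup):
        ann, amplified = setup
        rates = []
        for seed in range(50):
            acc = sequence_reads(amplified, ann, 0.0, 0.0, 0.0, 0.05, 0.9, 10_000, seed=seed)
            rates.append(acc.mapped_reads / acc.total_raw_reads)
        # expected mapped fraction 1 - (0.05 + 0.9) = 0.05
        se = np.sqrt(0.05 * 0.95 / 10_000 / 50)
        assert abs(np.mean(rates) - 0.05) < 4 * se

    def test_no_standard_template_routes_reads_to_other_classes(self, setup):
        ann, _ = setup
        amplified = pd.Series(0, index=ann.index)
        amplified[ann["gene_class"] == "rRNA"] = 100
        acc = sequence_reads(amplified, ann, 0.03, 0.04, 0.13, 0.08, 0.0, 10_000, seed=1)
        standard_genes = ann.index[ann["gene_class"] == "standard"]
        assert sum(acc.gene_counts[g] for g in standard_genes) == 0
        assert acc.mapped_reads > 0

    def test_excessive_dimer_mass_rejected(self, setup):
        ann, amplified = setup
        with pytest.raises(ConfigError):
            sequence_reads(amplified, ann, 0.03, 0.04, 0.13, 0.08, 0.95, 1000, seed=0)


class TestSimulateCohort:
    CFG = dict(n_genes=100, n_replicates=3, reads_per_sample=5_000,
               molecules_per_10pg=1_000)

    def test_reproducible_from_seed(self, tmp_path):
        config = SimulationConfig(seed=11, **self.CFG)
        for d in ("a", "b"):
            write_cohort(simulate_cohort(config), tmp_path / d)
        for f in sorted((tmp_path / "a").rglob("*")):
            if f.is_file():
                twin = tmp_path / "b" / f.relative_to(tmp_path / "a")
                assert f.read_bytes() == twin.read_bytes(), f.name

    def test_replicates_share_one_group(self):
        cohort = simulate_cohort(SimulationConfig(seed=1, **{**self.CFG, "n_replicates": 25}))
        assert len(cohort.samples) == 25
        assert len({s.replicate_group for s in cohort.samples}) == 1

    def test_no_failure_fractions_means_all_kept(self):
        from ampbench.qc_filters import FilterConfig, apply_exclusions

        cohort = simulate_cohort(SimulationConfig(seed=2, **self.CFG))
        kept, log = apply_exclusions(
            cohort.samples, FilterConfig(mapped_min_reads=1000)
        )
        assert len(kept) == len(cohort.samples) and not log.entries

    def test_failure_fractions_trigger_matching_rules(self):
        from ampbench.qc_filters import FilterConfig, apply_exclusions

        config = SimulationConfig(seed=3, arna_fail_fraction=1.0, **self.CFG)
        cohort = simulate_cohort(config)
        kept, log = apply_exclusions(cohort.samples, FilterConfig(mapped_min_reads=1000))
        assert not kept
        assert {e.rule_id for e in log.entries} == {"arna_yield"}

    def test_bulk_profile_covers_gene_universe(self):
        cohort = simulate_cohort(SimulationConfig(seed=4, **self.CFG))
        assert set(cohort.bulk_profile.index) == set(cohort.annotation.index)
        assert cohort.bulk_profile.sum() == pytest.approx(
            (1 - 0.13 - 0.08 + 0.0) * 5_000, rel=1e-6
        )


class TestConfigValidation:
    def test_fraction_sum_must_stay_below_one(self):
        with pytest.raises(ConfigError):
            SimulationConfig(rrna_fraction=0.5, mt_fraction=0.3, intergenic_fraction=0.2)

    def test_unknown_protocol_model_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(protocol_model="rolling_circle")

    def test_preset_lookup(self):
        config = SimulationConfig.for_protocol("original_aRNA")
        assert config.protocol_model == "ivt_linear" and config.ivt_rounds == 3
        with pytest.raises(ConfigError):
            SimulationConfig.for_protocol("unknown")
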