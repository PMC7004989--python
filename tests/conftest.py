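import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def annotation5():
    """Five genes: three standard, one rRNA, one mtRNA."""
    return pd.DataFrame(
        {
            "gene_class": ["standard", "standard", "standard", "rRNA", "mtRNA"],
            "length_bp": [1000, 2500, 400, 5000, 900],
            "gc_fraction": [0.45, 0.60, 0.35, 0.52, 0.40],
        },
        index=pd.Index(["G1", "G2", "G3", "R1", "M1"], name="gene_id"),
    )


@pytest.fixture
def small_cohort():
    """Tiny simulated cohort for end-to-end checks."""
    from ampbench.simulate import SimulationConfig, simulate_cohort

    config = SimulationConfig(
        n_genes=300,
        n_replicates=5,
        reads_per_sample=30_000,
        molecules_per_10pg=2_000,
        seed=7,
    )
    return simulate_cohort(config)
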