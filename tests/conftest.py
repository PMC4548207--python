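import pandas as pd
import pytest

from mitoribo import (
    SimulationConfig,
    add_rpkm,
    generate_transcriptome,
    simulate_counts,
    simulate_expression,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast 300-gene configuration with all three planted classes."""
    return SimulationConfig(
        n_genes=300,
        library_size_fp=600_000,
        library_size_mrna=600_000,
        frac_te_repressed=0.10,
        frac_te_activated=0.02,
        frac_mrna_regulated_g1=0.05,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_transcriptome(small_config) -> pd.DataFrame:
    return generate_transcriptome(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config, small_transcriptome) -> pd.DataFrame:
    return simulate_expression(small_config, small_transcriptome)


@pytest.fixture(scope="session")
def small_expression(small_config, small_transcriptome, small_truth) -> pd.DataFrame:
    counts = simulate_counts(small_truth, small_transcriptome, small_config)
    return add_rpkm(counts, small_transcriptome)
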