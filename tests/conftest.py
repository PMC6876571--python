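import matplotlib
import pytest

matplotlib.use("Agg")

from incprint import AnalysisConfig, SimulationConfig, simulate_screen  # noqa: E402


@pytest.fixture(scope="session")
def small_sim():
    """Down-scaled screen (400 proteins, control + 2 test RNAs)."""
    config = SimulationConfig(
        n_proteins=400,
        n_common_binders=40,
        rna_ids=("MS2", "RNA_A", "RNA_B"),
        seed=11,
    )
    return simulate_screen(config)


@pytest.fixture(scope="session")
def small_analysis_config():
    return AnalysisConfig(n_common_binders=40, min_binder_overlap=15)


@pytest.fixture(scope="session")
def default_sim():
    """One full-size screen under the default study conditions."""
    return simulate_screen(SimulationConfig(seed=7))
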