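import numpy as np
import pandas as pd
import pytest

from cytoresponse import SimulationConfig, simulate_counts
from cytoresponse.de import CountMatrix


@pytest.fixture(scope="session")
def two_group_null():
    """2,000-gene null simulation, 3 vs 3, constant dispersion 0.1."""
    cfg = SimulationConfig(
        n_genes=2000, effect_log2fc=0.0, treatments=("CTL", "IL1B"),
        times=("8h",), replicates_per_group=3, dispersion_intercept=0.1,
        dispersion_slope=0.0, cellline_sd=0.0, seed=101,
    )
    return simulate_counts(cfg)


@pytest.fixture(scope="session")
def planted_two_group():
    """Two-group simulation with planted |log2FC| = 2 classes."""
    cfg = SimulationConfig(
        n_genes=2000, pi_shared_up=0.15, pi_shared_down=0.10, pi_specific=0,
        pi_timeflip=0, effect_log2fc=2.0, treatments=("CTL", "IL1B"),
        times=("8h",), replicates_per_group=3, dispersion_intercept=0.1,
        dispersion_slope=1.0, cellline_sd=0.0,
        baseline_logmean_range=(5.64, 11.0), seed=77,
    )
    return simulate_counts(cfg)


@pytest.fixture(scope="session")
def full_design_run():
    """Full 5-treatment x 2-time x 3-line simulation (session-wide)."""
    cfg = SimulationConfig(n_genes=2500, seed=5)
    return simulate_counts(cfg)


@pytest.fixture()
def tiny_counts():
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.poisson(50, size=(30, 6)),
        index=[f"G{i:03d}" for i in range(30)],
        columns=[f"S{j}" for j in range(6)],
    )
    return CountMatrix(counts)
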