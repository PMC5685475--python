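import numpy as np
import pandas as pd
import pytest

from conswitch.io import CountMatrix, GeneAnnotation
from conswitch.simulate import SimulationConfig, simulate_expression


@pytest.fixture
def small_counts() -> CountMatrix:
    """4 genes x 6 samples (3 days x 2 replicates), hand-set counts."""
    counts = np.array([
        [10, 12, 100, 110, 105, 95],
        [50, 55, 52, 48, 51, 49],
        [0, 0, 0, 1, 0, 0],
        [200, 180, 20, 25, 22, 18],
    ])
    return CountMatrix(
        gene_ids=np.array(["gA", "gB", "gC", "gD"], dtype=object),
        sample_ids=np.array([f"s{i}" for i in range(6)], dtype=object),
        day=np.array([0, 0, 1, 1, 2, 2]),
        replicate=np.array([1, 2, 1, 2, 1, 2]),
        counts=counts,
        gene_length_bp=np.array([1000, 2000, 1500, 500]),
    )


@pytest.fixture
def small_annotation() -> GeneAnnotation:
    return GeneAnnotation(pd.DataFrame({
        "chromosome": ["chr1", "chr1", "chr2", "chr2"],
        "tss_bp": [100, 5000, 100, 9000],
        "strand": ["+", "-", "+", "+"],
        "is_tf": [True, False, False, True],
        "is_cone_specific": [False, True, False, False],
        "pathways": [{"pw1"}, {"pw1", "pw2"}, set(), {"pw2"}],
    }, index=["gA", "gB", "gC", "gD"]))


@pytest.fixture(scope="session")
def default_sim():
    """One default-config synthetic expression data set, shared."""
    cfg = SimulationConfig(seed=11)
    cm, ann, truth = simulate_expression(cfg)
    return cfg, cm, ann, truth


@pytest.fixture(scope="session")
def peak_sim():
    """A reduced synthetic ATAC data set, shared across modules."""
    from conswitch.simulate import simulate_peaks
    cfg = SimulationConfig(seed=17, n_peaks=1500)
    return cfg, simulate_peaks(cfg)
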