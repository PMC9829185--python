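import numpy as np
import pytest

from pleioscan.bench import BenchConfig, SimParams, run_benchmark
from pleioscan.panel import HaplotypePanel, PanelConfig, compute_ld, synthesize_panel


@pytest.fixture(scope="session")
def tiny_panel() -> HaplotypePanel:
    """Hand-written 6-haplotype x 3-SNP panel with known correlations."""
    hap = np.array(
        [
            [0, 0, 1],
            [1, 1, 0],
            [0, 0, 1],
            [1, 1, 1],
            [0, 1, 0],
            [1, 0, 0],
        ],
        dtype=np.uint8,
    )
    return HaplotypePanel(hap, np.array([100, 200, 300]), ("a", "b", "c"))


@pytest.fixture(scope="session")
def small_panel() -> HaplotypePanel:
    """Coalescent panel small enough for per-test simulation work."""
    return synthesize_panel(400, 60, PanelConfig(length_bp=60_000), seed=17)


@pytest.fixture(scope="session")
def small_ld(small_panel):
    return compute_ld(small_panel)


@pytest.fixture(scope="session")
def bench_result():
    """One tiny benchmark run shared by bench and acceptance-property tests."""
    cfg = BenchConfig(
        T=120,
        replicates=8,
        n_panels=5,
        n_hap=600,
        m=120,
        pool_h0=400,
        pool_h1=150,
        pool_h2_per_bin=60,
        n_v_grid=(10_000, 20_000, 30_000),
        sim=SimParams(n2=4000, n_null=500),
    )
    return run_benchmark(cfg, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
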