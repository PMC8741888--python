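import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from ssrmarkers import PipelineConfig, SimConfig, build_library, run_pipeline_reads


@pytest.fixture(scope="session")
def small_library():
    """8 loci x 12 diploid individuals, error-free, coverage 1."""
    cfg = SimConfig(n_loci=8, n_individuals=12, coverage=1, seed=11)
    pairs, truth = build_library(cfg)
    return cfg, pairs, truth


@pytest.fixture(scope="session")
def full_library():
    """The study-scale library: 20 loci x 36 diploid individuals,
    error-free, coverage 2."""
    cfg = SimConfig(n_loci=20, n_individuals=36, coverage=2, seed=7)
    pairs, truth = build_library(cfg)
    return cfg, pairs, truth


@pytest.fixture(scope="session")
def default_cfg():
    return PipelineConfig(restriction_pattern="GATC", prefix="Sim", rng_seed=7)


@pytest.fixture(scope="session")
def full_run(full_library, default_cfg):
    _, pairs, _ = full_library
    return run_pipeline_reads(pairs, default_cfg)
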