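"""Shared fixtures: simulated clades at two scales, reused across modules."""

import pytest

from cisrcne.cli import PipelineConfig, run_pipeline
from cisrcne.simulate import CladeSimConfig, simulate_clade


@pytest.fixture(scope="session")
def small_clade():
    """60 kb clade without rearrangements: fast, fully collinear."""
    return simulate_clade(
        CladeSimConfig(
            genome_length=60_000, n_genes=8, n_planted_cne=8,
            rearrangements=(), seed=3,
        )
    )


@pytest.fixture(scope="session")
def default_clade():
    """Default 200 kb clade with inversion + translocation and dropout."""
    return simulate_clade(CladeSimConfig(seed=7))


@pytest.fixture(scope="session")
def default_pipeline(default_clade):
    """Full pipeline products on the default clade."""
    cfg = PipelineConfig()
    result = run_pipeline(
        default_clade.blocks, default_clade.ref_genes, default_clade.tree, cfg
    )
    return cfg, result
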