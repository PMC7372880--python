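"""Shared fixtures: small synthetic datasets and one default-size run."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from cypminer.synthgen import SimConfig, emit_transcriptome

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_sim():
    """A small two-species transcriptome with ground truth (seed 7)."""
    cfg = SimConfig(seed=7, n_families=3, subfamilies_per_family=2,
                    members_per_subfamily=2, decoy_count=5)
    return cfg, emit_transcriptome(cfg)


@pytest.fixture(scope="session")
def default_sim():
    """The default-size study conditions (>= 500 CYP transcripts, seed 1)."""
    cfg = SimConfig(seed=1)
    return cfg, emit_transcriptome(cfg)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default study conditions."""
    from cypminer.pipeline import RunConfig, run_pipeline

    out = tmp_path_factory.mktemp("run_default")
    cfg = RunConfig(outdir=str(out), seed=1, sim=SimConfig(seed=1))
    report = run_pipeline(cfg)
    return cfg, out, report


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
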