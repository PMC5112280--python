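"""Shared fixtures: one small synthetic study reused across the suite.

The session fixture runs the full pipeline once on a deliberately small
simulated study (tens of kilobases, thousands of reads) so individual tests
can interrogate any stage's in-memory state or on-disk outputs without
re-running the expensive parts.
"""

from __future__ import annotations

import numpy as np
import pytest

from fiberma.pipeline import PipelineConfig, run_all
from fiberma.simulate import SimulationConfig, simulate_all


def small_sim_config(seed: int = 7, **overrides) -> SimulationConfig:
    base = dict(
        seed=seed,
        genome_length=80_000,
        n_known_loci=6,
        n_novel_loci=5,
        reads_per_library=4_000,
        mirna_fraction=0.12,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def sim_small():
    """(cfg, truth, libraries) for a small seeded study."""
    cfg = small_sim_config()
    truth, libraries = simulate_all(cfg)
    return cfg, truth, libraries


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """Full pipeline run on the small study: (config, output dir, state)."""
    out = tmp_path_factory.mktemp("run")
    cfg = PipelineConfig(seed=7)
    cfg.sim = small_sim_config()
    # capture per-stage state by monkey-wiring run_all's internals
    from fiberma import pipeline as pl

    state_box: dict = {}
    orig = pl._STAGE_FUNCS["report"]

    def capturing_report(config, state, outdir):
        state_box["state"] = state
        return orig(config, state, outdir)

    pl._STAGE_FUNCS["report"] = capturing_report
    try:
        run_all(cfg, out, log_level="WARNING")
    finally:
        pl._STAGE_FUNCS["report"] = orig
    return cfg, out, state_box["state"]


@pytest.fixture()
def rng():
    return np.random.default_rng(11)
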