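import logging

import numpy as np
import pytest

from hlofpipe.config import RunConfig
from hlofpipe.pipeline import run_study
from hlofpipe.synthetic_data import PopulationSpec, SimConfig, generate_study

logging.getLogger("hlofpipe").setLevel(logging.ERROR)


def small_sim_config(seed: int = 11, **overrides) -> SimConfig:
    """A reduced five-population cohort that still clears the 200-called rule."""
    kwargs = dict(
        seed=seed,
        populations=(
            PopulationSpec("COSMO", 120, 0.005, 2.0e6, 60.0),
            PopulationSpec("ISL_A", 60, 0.020, 2.5e6, 59.0),
            PopulationSpec("ISL_B", 50, 0.015, 2.5e6, 45.0),
            PopulationSpec("ISL_C", 40, 0.030, 2.5e6, 59.0),
            PopulationSpec("ISL_D", 30, 0.030, 2.5e6, 30.0),
        ),
        n_genes=80,
        n_true_hlof=12,
        artifact_counts={k: 3 for k in (
            "LAST10PCT", "LOW_MAPABILITY", "OFF_TARGET", "FEW_SAMPLES",
            "ANCESTRAL", "MNP_CODON", "FRAME_RESCUE", "INFRAME",
            "HWE_EXCESS", "LOW_COVERAGE", "NEAR_FIXED")},
        n_neutral_sites=300,
        trait_count=40,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """One small synthetic study shared by the whole session."""
    outdir = tmp_path_factory.mktemp("study")
    return generate_study(small_sim_config(), outdir)


@pytest.fixture(scope="session")
def pipeline_run(study):
    return run_study(study.directory, RunConfig())


@pytest.fixture(scope="session")
def survivor_keys(pipeline_run):
    return {(c.variant.contig, c.variant.pos, c.variant.ref, c.variant.alt)
            for c in pipeline_run.survivors}


def candidate_by_key(run, key):
    for c in run.candidates:
        v = c.variant
        if (v.contig, v.pos, v.ref, v.alt) == tuple(key):
            return c
    return None


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
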