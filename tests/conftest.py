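import warnings

import numpy as np
import pytest

from longrr.genotypes import compute_grm, impute_mean, qc_filter
from longrr.phenotypes import compute_blues
from longrr.simulate import SimulationConfig, simulate_markers, simulate_trajectories


def model_exact_config(**overrides) -> SimulationConfig:
    """Study conditions under which the random regression model is exactly
    the generating process: a single unreplicated experiment, no experiment
    effects, complete genotypes and a mean curve inside the basis span."""
    kw = dict(
        n_experiments=1,
        n_replicated=0,
        sigma_experiment=0.0,
        missing_rate=0.0,
        mean_family="linear",
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


def simulate_dataset(cfg):
    """Markers, records, truth, GRM and per-treatment BLUEs for a config."""
    markers = simulate_markers(cfg)
    records, truth = simulate_trajectories(markers, cfg)
    grm = compute_grm(impute_mean(qc_filter(markers, 0.0, 0.0)))
    return markers, records, truth, grm


@pytest.fixture(scope="session")
def small_dataset():
    """60 accessions x 300 SNPs x 20 days, model-exact conditions."""
    cfg = model_exact_config(n_accessions=60, n_markers=300, seed=11)
    markers, records, truth, grm = simulate_dataset(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        blues = compute_blues(records, "control")
    return dict(cfg=cfg, markers=markers, records=records, truth=truth,
                grm=grm, blues=blues)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
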