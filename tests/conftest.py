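"""Shared fixtures: synthetic cohorts, blob factories, planted-signal fits."""

import numpy as np
import pytest

from omicspred import (
    GeneratorConfig, ModelSpec, OmicsBlock, fit_lasso_cox, generate_cohort,
    select_lambda,
)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort at the reference study conditions."""
    return generate_cohort(GeneratorConfig(seed=12))


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort for fast workflow tests."""
    config = GeneratorConfig(n_patients=120, n_proteins=12, n_mirnas=15,
                             n_informative_proteins=4, n_informative_mirnas=4,
                             seed=5)
    return generate_cohort(config)


def make_blobs(n_per, separation, p=4, seed=0, weights=(0.5, 0.5)):
    """Two spherical truncated-Gaussian blobs whose centers are
    ``separation`` (in within-blob SD units) apart in Euclidean distance,
    all dims informative. Draws are clipped at 2.5 SD so a 6-sigma
    separation guarantees disjoint blobs while 3 sigma still overlaps."""
    rng = np.random.default_rng(seed)
    n0 = int(round(2 * n_per * weights[0]))
    n1 = 2 * n_per - n0
    shift = separation / np.sqrt(p)
    x = np.vstack([np.clip(rng.normal(size=(n0, p)), -2.5, 2.5),
                   np.clip(rng.normal(size=(n1, p)), -2.5, 2.5) + shift])
    truth = np.r_[np.zeros(n0, int), np.ones(n1, int)]
    ids = np.array([f"B{i:04d}" for i in range(2 * n_per)])
    block = OmicsBlock(ids, [f"f{j}" for j in range(p)], x)
    return block, truth


@pytest.fixture
def blob_factory():
    return make_blobs


def simulate_single_signal(seed, n=200, p=6, log_hr=1.5):
    """Survival data where only the first covariate carries a planted log
    hazard ratio; the remaining columns are pure noise."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, p))
    t = rng.exponential(1.0 / np.exp(log_hr * x[:, 0]))
    c = rng.exponential(np.median(t) * 2, size=n)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    return x, time, event


@pytest.fixture(scope="session")
def planted_signal_fits():
    """CV-tuned Lasso Cox fits over 20 planted-single-signal datasets.

    Shared by the variable-selection and importance-ranking checks so the
    simulation runs once per session.
    """
    fits = []
    for seed in range(20):
        x, time, event = simulate_single_signal(seed)
        sel = select_lambda(x, family="cox", time=time, event=event,
                            n_folds=10, seed=seed)
        fits.append(fit_lasso_cox(x, time, event, sel.lam))
    return fits


@pytest.fixture
def cox_spec():
    return ModelSpec.for_outcome(("demo",), "death_transplant")
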