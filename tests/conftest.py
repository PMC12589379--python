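"""Shared fixtures: scaled-down phantom specs and pre-simulated cohorts."""

import numpy as np
import pytest

from petref.phantom import PhantomSpec, simulate_cohort

TINY_SHAPE = (24, 20, 14)


def tiny_spec(**kw) -> PhantomSpec:
    """Smallest legal grid, 6 candidates, discovery-only cohort by default."""
    defaults = dict(
        shape=TINY_SHAPE,
        n_candidates=6,
        contaminated_candidates=(4, 5),
        cohort={"discovery": {"PSP-RS": 4, "HC": 4}},
        seed=0,
    )
    defaults.update(kw)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Tiny noiseless cohort without between-subject variability."""
    spec = tiny_spec(
        sigma0=0.0,
        between_subject_sd=0.0,
        subject_scale_sd=0.0,
        cohort={"discovery": {"PSP-RS": 2, "HC": 2}},
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Tiny cohort at default noise levels."""
    return simulate_cohort(tiny_spec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
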