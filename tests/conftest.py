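"""Shared fixtures: simulated recordings and cohorts used across test modules.

Everything is generated programmatically with fixed seeds; the heavier
simulations are session-scoped so each recording is built once.
"""

import numpy as np
import pytest

from csfdyn import (
    CohortSimConfig,
    default_drainage_config,
    default_infusion_config,
    generate_cohort,
    simulate_drainage,
    simulate_infusion_test,
)
from csfdyn.signal import RapExtractor

#: compressed-time drainage analysis settings (10-s windows, 40-window span,
#: wash-in of one correlation span plus the descent settling time)
DRAINAGE_ANALYSIS = dict(window_s=10.0, span_n=40)
WASHIN_S = 580.0


@pytest.fixture(scope="session")
def infusion_rec_r13():
    """Noise-free infusion test at R = 13, run to plateau."""
    cfg = default_infusion_config(r_out=13.0, fs=20.0, seed=3)
    return simulate_infusion_test(cfg, terminate_on_rout=False)


@pytest.fixture(scope="session")
def infusion_rec_r25():
    """Infusion test at R = 25 with the clinical termination rule active."""
    cfg = default_infusion_config(r_out=25.0, fs=20.0, seed=3)
    return simulate_infusion_test(cfg)


@pytest.fixture(scope="session")
def drainage_recs():
    """Compressed-time drainage recordings for rho in {0, 1}, fixed seed."""
    cfg = default_drainage_config(seed=11)
    return {
        0.0: simulate_drainage(cfg, rho=0.0),
        1.0: simulate_drainage(cfg, rho=1.0),
    }


@pytest.fixture(scope="session")
def drainage_recs_noisefree():
    """Noise-free drainage recordings: below the AMP breakpoint the pulse
    amplitude is exactly flat, so RAP degenerates rather than sampling a
    null correlation."""
    cfg = default_drainage_config(noise_sd=0.0, seed=21)
    return {
        0.0: simulate_drainage(cfg, rho=0.0),
        1.0: simulate_drainage(cfg, rho=1.0),
    }


@pytest.fixture(scope="session")
def drainage_raps(drainage_recs):
    ex = RapExtractor(**DRAINAGE_ANALYSIS)
    return {rho: ex.fit_transform(rec) for rho, rec in drainage_recs.items()}


@pytest.fixture(scope="session")
def cohort2000():
    """Fast-mode synthetic cohort with the default discriminative structure."""
    cohort, truth = generate_cohort(CohortSimConfig(n=2000, seed=11))
    return cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
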