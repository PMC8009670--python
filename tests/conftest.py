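"""Shared fixtures: deterministic synthetic cells and cohorts.

Everything is generated at test time from fixed seeds; session scope
keeps the expensive simulations to one run each.
"""

from __future__ import annotations

import numpy as np
import pytest

from picquant import (
    RampSpec,
    SimCellParams,
    sample_cohort,
    simulate_cclamp_ramp,
    simulate_vclamp_ramp,
)
from picquant.synth import rheobase

VC_RAMP = RampSpec(start_level=-80.0, peak_level=-40.0, speed=5.0, baseline_duration=1.0)


@pytest.fixture(scope="session")
def noiseless_params() -> SimCellParams:
    """Default cell with noise and PIC kinetics switched off."""
    return SimCellParams(noise_sd_vc=0.0, noise_sd_cc=0.0, tau_pic=0.0)


@pytest.fixture(scope="session")
def noiseless_vc_sweep(noiseless_params):
    return simulate_vclamp_ramp(noiseless_params, VC_RAMP, 10000.0)


@pytest.fixture(scope="session")
def noiseless_cc_sweep(noiseless_params):
    rb = rheobase(noiseless_params)
    ramp = RampSpec(0.0, rb + 4.0, (rb + 4.0) / 4.0, baseline_duration=1.0)
    return simulate_cclamp_ramp(noiseless_params, ramp, 10000.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Mixed-genotype young-adult cohort, 6 cells per genotype."""
    from picquant.reference import reference_cohort_spec

    spec = reference_cohort_spec(("P30-P60",), n_per_group=6, seed=7)
    return sample_cohort(spec)


def make_sweep(rng: np.random.Generator, mode: str = "VC", n: int = 200):
    """Small random-but-valid sweep for IO round-trip tests."""
    rate = float(rng.choice([1000.0, 5000.0, 10000.0]))
    t = np.arange(n) / rate
    return dict(
        time=t,
        command=rng.normal(size=n),
        response=rng.normal(size=n),
        mode=mode,
        sampling_rate=rate,
    )
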