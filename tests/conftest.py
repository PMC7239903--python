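import warnings

import numpy as np
import pytest

from ripplering.synth import (
    SessionConfig,
    Stabilization,
    build_ground_truth,
    simulate_units,
)


@pytest.fixture(autouse=True)
def _quiet_clamp_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def decode_session():
    """24 HD units, kappa = 2, long wake: shared by tuning/decoding tests."""
    cfg = SessionConfig(
        n_hd=24,
        n_nonhd=0,
        wake_s=600.0,
        nrem_s=60.0,
        rem_s=0.0,
        diffusion_wake=0.1,
        hd_kappa=2.0,
        hd_peak_rate_range=(20.0, 50.0),
        with_lfp=False,
    )
    truth = build_ground_truth(cfg, 3)
    units = simulate_units(truth)
    return truth, units


@pytest.fixture(scope="session")
def contrast_session():
    """50 HD-like + 50 bursty non-HD units across three brain states."""
    cfg = SessionConfig(
        n_hd=50,
        n_nonhd=50,
        wake_s=400.0,
        nrem_s=400.0,
        rem_s=200.0,
        burst_range=(0.5, 0.9),
        with_lfp=False,
    )
    truth = build_ground_truth(cfg, 8)
    units = simulate_units(truth)
    return truth, units


@pytest.fixture(scope="session")
def detection_session():
    """Default-scale session with LFP for detector recovery tests."""
    from ripplering.synth import synthesize_lfp

    cfg = SessionConfig(
        n_hd=24,
        n_nonhd=24,
        wake_s=60.0,
        nrem_s=300.0,
        rem_s=30.0,
        swr_rate_hz=0.4,
        with_lfp=False,
    )
    truth = build_ground_truth(cfg, 2)
    units = simulate_units(truth)
    lfp = synthesize_lfp(truth, seed=2)
    return truth, units, lfp
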