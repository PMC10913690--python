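"""Shared fixtures: synthetic records and processed sessions.

Everything is generated at test time by the forward simulator with fixed
seeds; the heavier session simulations are session-scoped so unit and
acceptance tests share one computation.
"""

import numpy as np
import pytest

import hemophase as hp


@pytest.fixture(scope="session")
def default_config():
    return hp.PipelineConfig()


@pytest.fixture(scope="session")
def clean_window():
    """Noiseless, constant-rate 20 s acquisition plus its processing result."""
    params = hp.SimulationParams(seed=1, duration_s=20.0, noise_rel=0.0, hrv_frac=0.0)
    record, truth = hp.simulate_window(params)
    result = hp.process_record(record)
    return params, record, truth, result


@pytest.fixture(scope="session")
def challenge_session():
    """90-min oral-challenge session at the observed coupling scale."""
    params = hp.session_params(seed=11)
    record, glucose, truth = hp.simulate_session(params)
    result = hp.process_record(record)
    series = result.minute_series()
    return record, glucose, truth, result, series


@pytest.fixture(scope="session")
def flat_session():
    """Sugar-free control: constant glucose, same noise/drift conditions."""
    params = hp.session_params(seed=12)
    record, glucose, truth = hp.simulate_session(params, glucose_profile=hp.flat_profile)
    result = hp.process_record(record)
    series = result.minute_series()
    return record, glucose, truth, result, series


def make_sinusoid_window(
    freq_hz=1.25,
    sample_rate=128.0,
    n=512,
    a_hbo2=1.0,
    a_hb=0.5,
    dtheta=0.0,
    t0=0.0,
):
    """AnalysisWindow holding exact on-bin sinusoids (no trimming involved).

    With n samples at sample_rate the resampled FFT length equals n, the
    grid spacing is exact, and freq_hz lands on an integer bin whenever
    freq_hz * n / sample_rate is an integer.
    """
    t = t0 + np.arange(n) / sample_rate
    phase = 2 * np.pi * freq_hz * t
    x1 = a_hbo2 * np.sin(phase)
    x2 = a_hb * np.sin(phase - dtheta)
    return hp.AnalysisWindow(
        start_time=float(t[0]),
        end_time=float(t[-1]),
        times=t,
        n_hbo2=x1 - x1.mean(),
        n_hb=x2 - x2.mean(),
        boundaries=np.array([0, n - 1]),
        beat_count=int(freq_hz * n / sample_rate),
    )
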