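"""Shared fixtures: simulated recordings at the pipeline's study conditions.

The 20-minute recordings are session-scoped because several tests score the
same end-to-end run; everything is generated from fixed seeds at import
time of the fixture, never stored on disk.
"""

from __future__ import annotations

import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from mousecg import (
    BeatAnnotations,
    NoiseSpec,
    SimulationConfig,
    detect_r_peaks,
    preprocess_chain,
    simulate_record,
)

SILENT = dict(baseline_amp_mv=0.0, white_sd_mv=0.0, emg_sd_mv=0.0)


def run_detection(record, target_rate_hz=1000.0, lead="II"):
    """Preprocess `record` and detect R peaks on `lead`."""
    from mousecg import PreprocessConfig

    bandpassed, detection = preprocess_chain(
        record, PreprocessConfig(target_rate_hz=target_rate_hz)
    )
    annotations = detect_r_peaks(
        detection.lead(lead), bandpassed.lead(lead), detection.sample_rate
    )
    return bandpassed, detection, annotations


def reference_annotations(truth, sample_rate):
    return BeatAnnotations(
        peak_indices=truth.true_peak_indices,
        source="reference",
        sample_rate=sample_rate,
    )


@pytest.fixture(scope="session")
def noiseless_short():
    """60 s noiseless recording at 1000 Hz: detection must be sample-exact."""
    config = SimulationConfig(
        duration_s=60, sample_rate=1000, rr_sd_ms=3, noise=NoiseSpec(**SILENT), seed=11
    )
    record, truth = simulate_record(config)
    return config, record, truth


@pytest.fixture(scope="session")
def noiseless_20min():
    """20-minute noiseless recording at 2000 Hz (worked at 1000 Hz downstream)."""
    config = SimulationConfig(
        duration_s=1200, sample_rate=2000, rr_sd_ms=3, noise=NoiseSpec(**SILENT), seed=12
    )
    record, truth = simulate_record(config)
    return config, record, truth


@pytest.fixture(scope="session")
def noisy_20min():
    """20-minute recording with white noise at 20% of the R amplitude."""
    config = SimulationConfig(
        duration_s=1200,
        sample_rate=2000,
        rr_sd_ms=3,
        noise=NoiseSpec(baseline_amp_mv=0.1, white_sd_mv=0.2, emg_sd_mv=0.1),
        seed=13,
    )
    record, truth = simulate_record(config)
    return config, record, truth


@pytest.fixture(scope="session")
def default_noise_20min():
    """20-minute recording at the generator's default conditions (wander only)."""
    config = SimulationConfig(duration_s=1200, sample_rate=2000, rr_sd_ms=3, seed=14)
    record, truth = simulate_record(config)
    return config, record, truth
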