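"""Shared fixtures: small deterministic layouts, recordings, and cohorts."""

import numpy as np
import pytest
from hypothesis import settings

import alphavar as av
from alphavar.roi import ROIDefinition

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=25)
settings.load_profile("ci")


SMALL = dict(n_sensors=16, n_temporal_per_side=4, sampling_rate=300.0)


@pytest.fixture(scope="session")
def small_layout():
    return av.make_layout(16, 4)


@pytest.fixture(scope="session")
def small_config():
    """A light cohort: 16 sensors, 300 Hz, 220 s (110 two-second epochs)."""
    return av.CohortConfig(
        n_per_group=2, duration_s=220.0, epochs_analyzed=90, seed=11, **SMALL
    )


@pytest.fixture(scope="session")
def quiet_config():
    """Same geometry with background, line noise and artifacts disabled."""
    return av.CohortConfig(
        n_per_group=2,
        duration_s=220.0,
        epochs_analyzed=90,
        noise_psd_ref=0.0,
        line_amp=0.0,
        artifact_rate=0.0,
        seed=11,
        **SMALL,
    )


@pytest.fixture(scope="session")
def temporal_roi(small_layout):
    return ROIDefinition(
        left=small_layout.temporal_ids("left"),
        right=small_layout.temporal_ids("right"),
        k_per_side=4,
        source_band="low_alpha",
    )


@pytest.fixture(scope="session")
def small_recording(small_config):
    spec = av.sample_cohort_specs(small_config)[0]
    return av.simulate_subject(spec, small_config, seed=42), spec


@pytest.fixture(scope="session")
def small_epochs(small_recording, small_config):
    recording, _ = small_recording
    res = av.preprocess_recording(
        recording, target_rate=small_config.sampling_rate, n_select=90, seed=3
    )
    return res.epochs


@pytest.fixture(scope="session")
def small_spectra(small_epochs):
    return av.compute_epoch_spectra(small_epochs)


def sine_recording(freq, fs=600.0, duration=10.0, amp=1.0, layout=None, phase=0.0):
    """A pure-sinusoid recording on every channel (test helper)."""
    layout = layout or av.make_layout(8, 4)
    t = np.arange(int(round(duration * fs))) / fs
    sig = amp * np.sin(2 * np.pi * freq * t + phase)
    data = np.tile(sig, (layout.n_sensors, 1))
    return av.Recording(
        subject_id="sine", layout=layout, sampling_rate=fs, data=data
    )
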