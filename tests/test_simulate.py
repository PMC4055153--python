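import dataclasses

import numpy as np
import pytest

import alphavar as av
from alphavar.exceptions import InvalidArgumentError
from alphavar.simulate import alpha_component_freqs
from alphavar.spectral import LOW_ALPHA
from alphavar.variability import band_cv


def test_same_seed_bit_identical(small_config):
    spec = av.sample_cohort_specs(small_config)[0]
    a = av.simulate_subject(spec, small_config, seed=9)
    b = av.simulate_subject(spec, small_config, seed=9)
    assert np.array_equal(a.data, b.data)
    assert a.annotations == b.annotations


def test_cohort_reproducible_from_config_seed(small_config):
    a = av.sample_cohort_specs(small_config)
    b = av.sample_cohort_specs(small_config)
    assert a == b


def test_cohort_composition_and_matching(small_config):
    cfg = dataclasses.replace(small_config, n_per_group=5)
    specs = av.sample_cohort_specs(cfg)
    tins = [s for s in specs if s.group == "tinnitus"]
    cons = [s for s in specs if s.group == "control"]
    assert len(tins) == len(cons) == 5
    for t, c in zip(tins, cons):
        assert (t.age, t.sex) == (c.age, c.sex)  # matched by construction
        assert t.duration > 0 and t.distress is not None
        assert c.duration is None and c.distress is None


def test_duration_model_example_without_jitter():
    cfg = av.CohortConfig(
        n_per_group=2, n_sensors=16, n_temporal_per_side=4,
        sampling_rate=300.0, duration_s=220.0,
        duration_model=(2.0, 1.0), cv_jitter_sd=0.0, seed=1,
    )
    specs = av.sample_cohort_specs(cfg)
    for s in specs:
        if s.group == "tinnitus":
            assert s.alpha_cv_target == pytest.approx(1.0 / s.duration + 2.0)


def test_component_pair_straddles_peak():
    assert alpha_component_freqs(9.0) == (8.5, 9.0)
    assert alpha_component_freqs(9.3) == (9.0, 9.5)
    assert alpha_component_freqs(11.0) == (10.5, 11.0)


def test_zero_cv_target_without_noise_gives_constant_epoch_power(
    quiet_config, temporal_roi
):
    spec = av.SubjectSpec(
        subject_id="flat", group="control", age=40.0, sex="m",
        alpha_mean_amp=quiet_config.alpha_amp, alpha_cv_target=0.0,
        alpha_peak_freq=9.0,
    )
    rec = av.simulate_subject(spec, quiet_config, seed=4)
    res = av.preprocess_recording(
        rec, target_rate=quiet_config.sampling_rate, n_select=90, seed=0
    )
    spectra = av.compute_epoch_spectra(res.epochs)
    table = av.band_average(spectra, LOW_ALPHA)
    roi_cols = list(temporal_roi.left + temporal_roi.right)
    series = table[roi_cols].mean(axis=1)
    assert series.std(ddof=1) / series.mean() < 0.01  # leakage tolerance only


def test_power_scales_as_amplitude_squared(quiet_config, temporal_roi):
    def band_power(amp, seed=8):
        spec = av.SubjectSpec(
            subject_id="amp", group="control", age=40.0, sex="m",
            alpha_mean_amp=amp, alpha_cv_target=0.0, alpha_peak_freq=9.0,
        )
        rec = av.simulate_subject(spec, quiet_config, seed=seed)
        res = av.preprocess_recording(
            rec, target_rate=quiet_config.sampling_rate, n_select=90, seed=0
        )
        spectra = av.compute_epoch_spectra(res.epochs)
        table = av.band_average(spectra, LOW_ALPHA)
        return table[list(temporal_roi.left)].mean().mean()

    ratio = band_power(2 * quiet_config.alpha_amp) / band_power(quiet_config.alpha_amp)
    assert abs(ratio - 4.0) < 0.2


def test_background_spectral_slope_matches_exponent(small_config):
    cfg = dataclasses.replace(
        small_config, line_amp=0.0, artifact_rate=0.0, noise_exponent=1.0
    )
    spec = av.SubjectSpec(
        subject_id="bg", group="control", age=40.0, sex="m",
        alpha_mean_amp=0.0, alpha_cv_target=0.0, alpha_peak_freq=9.0,
    )
    rec = av.simulate_subject(spec, cfg, seed=5)
    res = av.preprocess_recording(rec, target_rate=cfg.sampling_rate, n_select=90, seed=0)
    spectra = av.compute_epoch_spectra(res.epochs)
    f = spectra.grid.values
    mask = (f >= 2.0) & (f <= 40.0)
    mean_psd = spectra.power[:, :, mask].mean(axis=(0, 1))
    slope = np.polyfit(np.log(f[mask]), np.log(mean_psd), 1)[0]
    assert abs(slope + 1.0) < 0.3


def test_artifact_annotations_within_recording(small_recording):
    rec, _ = small_recording
    assert len(rec.annotations) >= 1
    for start, stop, kind in rec.annotations:
        assert 0 <= start < stop <= rec.duration_s
        assert kind == "blink"


def test_duration_too_short_rejected():
    with pytest.raises(InvalidArgumentError):
        av.CohortConfig(
            n_per_group=2, n_sensors=16, n_temporal_per_side=4,
            sampling_rate=300.0, duration_s=1.0,
        )


def test_low_rate_rejected():
    with pytest.raises(InvalidArgumentError):
        av.CohortConfig(n_per_group=2, sampling_rate=150.0, duration_s=220.0)


def test_calibration_tracks_targets_across_subjects(small_config, temporal_roi):
    """Realized epoch-power CV correlates strongly with the planted target.

    The sample CV of 90 heavy-tailed epoch powers carries irreducible
    measurement noise, so each subject's realized CV is measured on four
    independent recordings and averaged.
    """
    rng = np.random.default_rng(2)
    targets, realized = [], []
    for i in range(50):
        tgt = float(rng.uniform(0.3, 3.8))
        spec = av.SubjectSpec(
            subject_id=f"c{i}", group="control", age=40.0, sex="m",
            alpha_mean_amp=small_config.alpha_amp, alpha_cv_target=tgt,
            alpha_peak_freq=9.0,
        )
        values = []
        for rep in range(4):
            rec = av.simulate_subject(spec, small_config, seed=300 + 4 * i + rep)
            res = av.preprocess_recording(
                rec, target_rate=small_config.sampling_rate, n_select=90,
                seed=4 * i + rep,
            )
            cvmap = av.compute_cv(av.compute_epoch_spectra(res.epochs))
            out = band_cv(cvmap, LOW_ALPHA, temporal_roi)
            values.append(0.5 * (out["left"] + out["right"]))
        targets.append(tgt)
        realized.append(np.mean(values))
    assert np.corrcoef(targets, realized)[0, 1] > 0.9
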