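import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import curve_fit

import alphavar as av
from alphavar.exceptions import InsufficientDataError, InvalidArgumentError
from alphavar.preprocess import STAGE_ORDER

from .conftest import sine_recording


class TestDftNotch:
    def test_exact_removal_of_integer_cycle_line(self):
        rec = sine_recording(50.0, fs=600.0, duration=10.0)  # 100 cycles / 2 s
        out = av.dft_notch(rec, 50.0)
        assert np.max(np.abs(out.data)) < 1e-10 * np.max(np.abs(rec.data))

    def test_orthogonal_content_untouched(self):
        rec = sine_recording(10.0, fs=600.0, duration=10.0)
        out = av.dft_notch(rec, 50.0)
        assert np.allclose(out.data, rec.data, atol=1e-9)

    def test_zero_in_zero_out(self):
        rec = sine_recording(10.0, amp=0.0)
        out = av.dft_notch(rec, 50.0)
        assert np.all(out.data == 0)

    def test_line_freq_above_nyquist_rejected(self):
        rec = sine_recording(10.0, fs=90.0)
        with pytest.raises(InvalidArgumentError):
            av.dft_notch(rec, 50.0)


class TestDownsample:
    def test_sample_count_scaling_from_hardware_rate(self):
        rec = sine_recording(10.0, fs=2034.51, duration=30.0)
        out = av.downsample(rec, 600.0)
        expected = rec.n_samples * 600.0 / 2034.51
        assert abs(out.n_samples - expected) <= 1
        assert out.sampling_rate == 600.0

    def test_identity_at_equal_rate(self):
        rec = sine_recording(10.0, fs=600.0)
        out = av.downsample(rec, 600.0)
        assert out is rec

    def test_alpha_amplitude_preserved(self):
        rec = sine_recording(10.0, fs=2034.51, duration=30.0)
        out = av.downsample(rec, 600.0)

        def model(t, a, ph):
            return a * np.sin(2 * np.pi * 10.0 * t + ph)

        # ignore filter edges
        n = out.n_samples
        sl = slice(n // 4, 3 * n // 4)
        t = np.arange(n)[sl] / 600.0
        popt, _ = curve_fit(model, t, out.data[0, sl], p0=[1.0, 0.0])
        assert abs(abs(popt[0]) - 1.0) < 0.02

    def test_upsampling_rejected(self):
        rec = sine_recording(10.0, fs=600.0)
        with pytest.raises(InvalidArgumentError):
            av.downsample(rec, 1200.0)


class TestSegmentEpochs:
    @pytest.mark.parametrize(
        "duration,expected", [(300.0, 150), (301.0, 150), (2.0, 1)]
    )
    def test_floor_rule(self, duration, expected):
        rec = sine_recording(10.0, fs=600.0, duration=duration)
        eps = av.segment_epochs(rec, 2.0)
        assert eps.n_epochs == expected
        assert eps.epochs.shape[2] == 1200
        assert not eps.artifact_flags.any()

    def test_too_short_rejected(self):
        rec = sine_recording(10.0, fs=600.0, duration=1.5)
        with pytest.raises(InvalidArgumentError):
            av.segment_epochs(rec, 2.0)


class TestFlagArtifacts:
    def _epochs(self, data, fs=600.0):
        lay = av.make_layout(8, 4)
        rec = av.Recording(subject_id="x", layout=lay, sampling_rate=fs, data=data)
        return av.segment_epochs(rec, 2.0)

    def test_all_zero_no_flags(self):
        eps = self._epochs(np.zeros((8, 12000)))
        out = av.flag_artifacts(eps, ptp_threshold=1.0, z_threshold=5.0)
        assert not out.artifact_flags.any()

    def test_spike_epoch_flagged_exactly(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((8, 12000))
        data[3, 5 * 1200 + 100] += 50.0  # spike in epoch 5
        eps = self._epochs(data)
        out = av.flag_artifacts(eps, ptp_threshold=25.0, z_threshold=1e9)
        assert list(np.where(out.artifact_flags)[0]) == [5]

    def test_infinite_thresholds_vacuous(self):
        rng = np.random.default_rng(1)
        eps = self._epochs(rng.standard_normal((8, 12000)))
        out = av.flag_artifacts(eps, ptp_threshold=np.inf, z_threshold=np.inf)
        assert not out.artifact_flags.any()

    @given(
        lo=st.floats(min_value=1.0, max_value=20.0),
        hi_extra=st.floats(min_value=0.1, max_value=30.0),
    )
    def test_flags_monotone_in_threshold(self, lo, hi_extra):
        rng = np.random.default_rng(7)
        data = rng.standard_normal((8, 12000))
        data[2, 3 * 1200 : 3 * 1200 + 50] += 12.0
        eps = self._epochs(data)
        low = av.flag_artifacts(eps, ptp_threshold=lo, z_threshold=3.0)
        high = av.flag_artifacts(eps, ptp_threshold=lo + hi_extra, z_threshold=6.0)
        # lower thresholds flag a superset
        assert np.all(low.artifact_flags | ~high.artifact_flags)


class TestSelectCleanEpochs:
    def _flagged(self, n_epochs, flagged_idx=()):
        lay = av.make_layout(8, 4)
        rng = np.random.default_rng(5)
        rec = av.Recording(
            subject_id="x",
            layout=lay,
            sampling_rate=100.0,
            data=rng.standard_normal((8, n_epochs * 200)),
        )
        eps = av.segment_epochs(rec, 2.0)
        eps.artifact_flags[list(flagged_idx)] = True
        return eps

    def test_selection_count_and_duration(self):
        eps = av.select_clean_epochs(self._flagged(150), 90, seed=0)
        assert eps.n_selected == 90
        assert eps.n_selected * eps.epoch_length_s == 180.0
        assert not (eps.selected & eps.artifact_flags).any()

    def test_exhaustive_selection(self):
        eps = av.select_clean_epochs(self._flagged(90), 90, seed=0)
        assert eps.selected.all()

    def test_shortfall_reported(self):
        with pytest.raises(InsufficientDataError, match="short by 1"):
            av.select_clean_epochs(self._flagged(90, flagged_idx=[0]), 90, seed=0)

    def test_reproducible_and_seed_sensitive(self):
        eps = self._flagged(150)
        a = av.select_clean_epochs(eps, 90, seed=1).selected
        b = av.select_clean_epochs(eps, 90, seed=1).selected
        c = av.select_clean_epochs(eps, 90, seed=2).selected
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_selection_unbiased_across_seeds(self):
        from scipy.stats import chisquare

        eps = self._flagged(6)
        counts = np.zeros(6)
        for seed in range(400):
            counts += av.select_clean_epochs(eps, 3, seed=seed).selected
        # each epoch should be chosen about 200 times
        assert chisquare(counts).pvalue > 1e-3


def test_pipeline_runner_applies_fixed_stage_order(small_recording, small_config):
    recording, _ = small_recording
    res = av.preprocess_recording(
        recording, target_rate=small_config.sampling_rate, n_select=90, seed=0
    )
    assert res.stages == STAGE_ORDER == (
        "notch", "downsample", "segment", "flag", "select"
    )
    assert res.counts["n_selected"] == 90
    assert res.counts["selected_seconds"] == 180.0
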