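"""Movement-onset detection and mean+3·SD baseline-noise correction."""

import numpy as np
import pytest

from vibemg.exceptions import OnsetError, ThresholdError
from vibemg.activation import (
    apply_threshold,
    detect_movement_onset,
    estimate_threshold,
)
from vibemg.preprocess import Envelope, bandpass, rectify, rms_envelope

FS = 1024.0


def _env(values, fs_env=4.0):
    values = np.asarray(values, dtype=float)
    return Envelope(values=values, fs_env_hz=fs_env, window_s=1 / fs_env, source_fs_hz=FS)


def _rom_with_lead_in(lead_s=2.0, move_s=10.0, amp=45.0, fs=FS):
    t = np.arange(int(move_s * fs)) / fs
    move = amp * (1 - np.cos(2 * np.pi * t))  # 60 bpm
    return np.concatenate([np.zeros(int(lead_s * fs)), move])


class TestOnset:
    def test_onset_after_flat_lead_in(self):
        rom = _rom_with_lead_in(lead_s=2.0)
        onset = detect_movement_onset(rom, FS)
        assert onset == pytest.approx(2.0, abs=0.25)  # within one envelope sample

    def test_movement_from_start_returns_zero_with_warning(self):
        rom = _rom_with_lead_in(lead_s=0.0)
        with pytest.warns(UserWarning, match="onset set to 0"):
            assert detect_movement_onset(rom, FS) == 0.0

    def test_constant_rom_raises(self):
        with pytest.raises(OnsetError, match="no movement"):
            detect_movement_onset(np.full(int(5 * FS), 30.0), FS)

    def test_slow_drift_below_speed_threshold_raises(self):
        t = np.arange(int(10 * FS)) / FS
        rom = 0.05 * np.sin(2 * np.pi * 0.2 * t)  # peak speed ~0.06 deg/s
        with pytest.raises(OnsetError, match="no movement"):
            detect_movement_onset(rom, FS)


class TestEstimateThreshold:
    def test_threshold_is_mean_plus_3sd_of_realized_window(self, rng):
        pre = rng.normal(2.0, 0.5, 200)
        env = _env(np.concatenate([np.abs(pre), np.full(100, 50.0)]))
        thr = estimate_threshold(env, onset_s=200 / 4.0)
        a, b = thr.window_bounds
        window = env.values[a:b]
        # oracle: direct mean + 3 * population SD on the realized window
        assert thr.threshold == pytest.approx(
            float(np.mean(window) + 3 * np.std(window)), rel=1e-12
        )
        assert thr.threshold == pytest.approx(3.5, abs=0.5)
        assert b - a <= 60 and a <= thr.min_index < b

    def test_constant_pre_onset_gives_threshold_equal_to_level(self):
        env = _env(np.concatenate([np.full(100, 1.0), np.full(40, 9.0)]))
        thr = estimate_threshold(env, onset_s=25.0)
        assert thr.noise_sd == 0.0
        assert thr.threshold == 1.0

    def test_window_clipped_at_signal_start(self):
        values = np.full(200, 5.0)
        values[10] = 0.1  # pre-onset minimum at envelope index 10
        thr = estimate_threshold(_env(values), onset_s=25.0)  # onset index 100
        assert thr.min_index == 10
        assert thr.window_bounds == (0, 40)  # 10-30 clips to 0; 10+30 = 40

    def test_window_clipped_at_onset_by_default(self):
        values = np.concatenate([np.full(12, 1.0), np.full(100, 80.0)])
        values[6] = 0.5
        thr = estimate_threshold(_env(values), onset_s=3.0)  # onset index 12
        assert thr.window_bounds == (0, 12)
        assert thr.threshold < 2.0  # movement samples excluded from noise stats
        thr_unclipped = estimate_threshold(_env(values), onset_s=3.0, clip_to_onset=False)
        assert thr_unclipped.window_bounds == (0, 36)

    def test_first_occurrence_tie_break(self):
        values = np.full(100, 2.0)
        values[[20, 40]] = 1.0
        thr = estimate_threshold(_env(values), onset_s=20.0)
        assert thr.min_index == 20

    def test_onset_at_zero_raises(self):
        with pytest.raises(ThresholdError, match="pre-onset"):
            estimate_threshold(_env(np.ones(100)), onset_s=0.0)


class TestApplyThreshold:
    def test_subtract_and_zero_below(self):
        env = _env([1.0, 4.0, 2.0])
        thr = estimate_threshold(_env([2.0, 2.0]), onset_s=0.5)
        assert thr.threshold == 2.0
        cenv = apply_threshold(env, thr)
        np.testing.assert_array_equal(cenv.values, [0.0, 2.0, 0.0])
        np.testing.assert_array_equal(cenv.active_mask, [False, True, False])

    def test_zero_threshold_is_identity_on_positive_signal(self, rng):
        env = _env(np.abs(rng.normal(5, 1, 50)))
        thr = estimate_threshold(_env([0.0, 0.0]), onset_s=0.5)
        cenv = apply_threshold(env, thr)
        np.testing.assert_array_equal(cenv.values, env.values)
        assert cenv.active_mask.all()

    def test_monotone_in_threshold(self, rng):
        """Raising the threshold never increases any corrected sample."""
        env = _env(np.abs(rng.normal(5, 2, 100)))
        lo = estimate_threshold(_env([3.0, 3.0]), onset_s=0.5)
        hi = estimate_threshold(_env([4.0, 4.0]), onset_s=0.5)
        out_lo = apply_threshold(env, lo).values
        out_hi = apply_threshold(env, hi).values
        assert np.all(out_hi <= out_lo)

    def test_translation_invariance(self, rng):
        """Adding a constant shifts the threshold exactly and leaves output unchanged."""
        values = np.abs(rng.normal(5, 2, 120))
        c = 11.25
        thr0 = estimate_threshold(_env(values), onset_s=10.0)
        thr1 = estimate_threshold(_env(values + c), onset_s=10.0)
        assert thr1.min_index == thr0.min_index
        assert thr1.threshold == pytest.approx(thr0.threshold + c, rel=1e-12)
        out0 = apply_threshold(_env(values), thr0).values
        out1 = apply_threshold(_env(values + c), thr1).values
        np.testing.assert_allclose(out1, out0, atol=1e-9)


def test_noise_only_trial_mostly_suppressed(rng):
    """On pure instrumentation noise the mean+3·SD threshold retains <2% of samples."""
    x = rng.normal(0.0, 8.0, int(60 * FS))
    env = rms_envelope(rectify(bandpass(x, FS)), FS)
    thr = estimate_threshold(env, onset_s=15.0, clip_to_onset=True)
    cenv = apply_threshold(env, thr)
    frac_active = cenv.active_mask[60:].mean()  # beyond the noise window itself
    assert frac_active < 0.02
    # retained energy is near zero relative to the raw noise envelope level
    assert np.sqrt(np.mean(cenv.values**2)) < 0.05 * np.mean(env.values)
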