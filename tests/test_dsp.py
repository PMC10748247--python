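"""Filter-chain properties: frequency response, linearity, bend logic."""

from __future__ import annotations

import logging

import numpy as np
import pytest
from scipy import signal as sp_signal

import scratchkit as sk
from scratchkit.dsp import (
    DspConfig,
    band_power,
    bend_state,
    highpass_butterworth,
    moving_average,
    process_recording,
    read_processed,
    write_processed,
)

FS = 20.0


def _fit_amplitude(y: np.ndarray, f: float, fs: float,
                   skip_s: float = 20.0) -> float:
    """Least-squares amplitude of the f-Hz component in the steady state
    (a sampled peak underestimates amplitude when fs/f is small)."""
    tail = y[int(skip_s * fs):]
    t = np.arange(tail.size) / fs
    design = np.column_stack([np.sin(2 * np.pi * f * t),
                              np.cos(2 * np.pi * f * t)])
    coef, *_ = np.linalg.lstsq(design, tail, rcond=None)
    return float(np.hypot(*coef))


class TestHighpass:
    def test_dc_rejection(self):
        """A constant input rings down below 1e-3 of its value once the
        ~6 s transient of the 4th-order filter has passed."""
        x = np.full(int(60 * FS), 7.5)
        y = highpass_butterworth(x, 0.5, 4, FS)
        assert np.abs(y[int(6 * FS):]).max() < 1e-3 * 7.5
        assert np.abs(y[-1]) < 1e-6 * 7.5

    def test_passband_gain_at_5hz_within_1pct(self):
        """A 5 Hz unit sine is passed with amplitude within 1% of the
        filter's analytic magnitude response (itself within 1% of 1)."""
        t = np.arange(int(60 * FS)) / FS
        y = highpass_butterworth(np.sin(2 * np.pi * 5 * t), 0.5, 4, FS)
        sos = sp_signal.butter(4, 0.5, "highpass", fs=FS, output="sos")
        _, h = sp_signal.sosfreqz(sos, worN=[5.0], fs=FS)
        analytic = np.abs(h[0])
        amp = _fit_amplitude(y, 5.0, FS)
        assert amp == pytest.approx(analytic, rel=0.01)
        assert amp == pytest.approx(1.0, rel=0.01)

    def test_cutoff_gain_is_minus_3db(self):
        """Butterworth definition: |H| = 1/sqrt(2) at the cutoff, +-1%."""
        t = np.arange(int(600 * FS)) / FS
        y = highpass_butterworth(np.sin(2 * np.pi * 0.5 * t), 0.5, 4, FS)
        amp = _fit_amplitude(y, 0.5, FS, skip_s=300.0)
        assert amp == pytest.approx(1 / np.sqrt(2), rel=0.01)

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            highpass_butterworth(np.zeros(10), 10.0, 4, FS)

    def test_linearity(self, rng):
        x = rng.normal(size=400)
        y = rng.normal(size=400)
        lhs = highpass_butterworth(3.0 * x - 2.0 * y, 0.5, 4, FS)
        rhs = 3.0 * highpass_butterworth(x, 0.5, 4, FS) \
            - 2.0 * highpass_butterworth(y, 0.5, 4, FS)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)


class TestMovingAverage:
    def test_constant_is_preserved(self):
        np.testing.assert_allclose(moving_average(np.full(100, 3.3)), 3.3)

    def test_two_block_example(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        out = moving_average(x, window=20, step=20)
        np.testing.assert_array_equal(out,
                                      np.concatenate([np.zeros(20),
                                                      np.ones(20)]))

    @pytest.mark.parametrize("n", [1, 29, 30, 31, 200])
    def test_output_length_equals_input_length(self, rng, n):
        assert moving_average(rng.normal(size=n)).size == n

    def test_window_longer_than_signal_gives_global_mean(self):
        x = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(moving_average(x, window=30), 2.0)

    def test_linearity(self, rng):
        x = rng.normal(size=100)
        y = rng.normal(size=100)
        np.testing.assert_allclose(
            moving_average(2 * x + y),
            2 * moving_average(x) + moving_average(y), atol=1e-12,
        )


class TestBendState:
    def test_threshold_semantics(self):
        x = np.array([12.0, -12.0, 0.0, 10.0, -10.0, 9.99])
        np.testing.assert_array_equal(bend_state(x), [1, 1, 0, 1, 1, 0])

    def test_output_strictly_binary(self, rng):
        out = bend_state(rng.normal(0, 20, size=500))
        assert set(np.unique(out)) <= {0, 1}


class TestProcessRecording:
    def test_all_zero_recording_gives_all_zero_channels(self):
        rec = sk.SensorRecording(stretch=np.zeros((5, 200)),
                                 accel=np.zeros((3, 200)))
        pc = process_recording(rec)
        assert pc.matrix().shape == (200, 13)
        assert not pc.matrix().any()

    def test_thirteen_channels_from_eight_raw(self):
        rec, _ = sk.generate_action(sk.ActionSpec("wave"),
                                    sk.SynthConfig(seed=1))
        pc = process_recording(rec)
        assert pc.filtered.shape == (8, rec.n_samples)
        assert pc.bend.shape == (5, rec.n_samples)
        assert pc.matrix().shape == (rec.n_samples, 13)

    def test_finger_scratch_retains_band_power(self):
        """Fast-path stretch channels keep the 3-8 Hz oscillation: band
        power during a finger scratch exceeds idle band power >10x."""
        cfg = sk.SynthConfig(seed=8)
        scratch, _ = sk.generate_action(sk.ActionSpec("scratch_finger"),
                                        cfg)
        idle, _ = sk.generate_action(sk.ActionSpec("idle"), cfg)
        p_scratch = max(
            band_power(process_recording(scratch).filtered[ch], FS, (3, 8))
            for ch in range(5)
        )
        p_idle = max(
            band_power(process_recording(idle).filtered[ch], FS, (3, 8))
            for ch in range(5)
        )
        assert p_scratch > 10 * p_idle

    def test_arm_scratch_sets_bend_channels(self):
        """Curled fingers during an arm-dominant bout keep the bend
        channels predominantly active through the bout centre; idle
        without offsets never trips them."""
        for seed in range(3):
            cfg = sk.SynthConfig(seed=seed)
            rec, lab = sk.generate_action(sk.ActionSpec("scratch_arm"), cfg)
            pc_c, _ = sk.extract_center(process_recording(rec), lab)
            duty = pc_c.bend.mean(axis=1)
            assert duty.mean() > 0.5
            assert (duty > 0.25).all()
            idle, ilab = sk.generate_action(sk.ActionSpec("idle"), cfg)
            assert not process_recording(idle).bend.any()

    def test_bend_survives_full_slow_path_for_step_offset(self):
        """A 33 mOhm bent-finger offset (about 10 mm of extension) maps to
        bend = 1 through the slow path while the offset is fresh."""
        stretch = np.zeros((5, 200))
        stretch[2] = 33.0
        rec = sk.SensorRecording(stretch=stretch, accel=np.zeros((3, 200)))
        pc = process_recording(rec)
        # first two seconds after the step: clearly bent
        assert pc.bend[2, :40].all()
        assert not pc.bend[[0, 1, 3, 4]].any()

    def test_short_recording_warns_but_processes(self, caplog):
        rec = sk.SensorRecording(stretch=np.zeros((5, 40)),
                                 accel=np.zeros((3, 40)))
        with caplog.at_level(logging.WARNING, logger="scratchkit.dsp"):
            pc = process_recording(rec)
        assert pc.n_samples == 40
        assert any("warm-up" in r.message for r in caplog.records)

    def test_processed_csv_round_trip(self, tmp_path):
        rec, _ = sk.generate_action(sk.ActionSpec("scratch_arm"),
                                    sk.SynthConfig(seed=4))
        pc = process_recording(rec)
        path = tmp_path / "proc.csv"
        write_processed(pc, path)
        back = read_processed(path)
        np.testing.assert_allclose(back.filtered, pc.filtered, rtol=1e-9)
        np.testing.assert_array_equal(back.bend, pc.bend)

    def test_configurable_slow_cutoff(self):
        """The slow-path cutoff is configurable; the 0.5 Hz alternative
        erases sustained offsets, which is why 0.03 Hz is the default."""
        stretch = np.zeros((5, 200))
        stretch[0] = 33.0
        rec = sk.SensorRecording(stretch=stretch, accel=np.zeros((3, 200)))
        alt = process_recording(rec, DspConfig(slow_cutoff_hz=0.5,
                                               slow_filter_order=4))
        default = process_recording(rec)
        assert default.bend[0].sum() > alt.bend[0].sum()
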