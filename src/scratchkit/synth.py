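"""Labelled synthetic glove recordings.

The generator emulates the signal structure of scratching as seen by a
five-finger stretch-sensor glove with a palm accelerometer:

* **Finger-dominant scratching** — rapid finger flexion puts a 3–8 Hz
  oscillation on one to five stretch channels, riding on a bent-finger
  baseline offset.
* **Arm-dominant scratching** — the fingers stay curled (sustained stretch
  offsets on all five channels) while the 3–8 Hz oscillation appears on the
  accelerometer axes.
* **Rubbing** — mimics either scratching style and may additionally carry
  x-axis accelerometer energy, which plain scratching does not.
* **Non-scratching actions** (idle, waving, typing, tapping, moving objects,
  opening/closing the hand) produce sub-3 Hz or broadband low-amplitude
  activity.

Waveforms are sinusoids with jittered frequency and phase plus white noise
and slow sinusoidal drift — a deliberately simple family that reproduces the
oscillatory profiles without claiming biomechanical fidelity. "Intensive"
variants use the upper half of the frequency band and 1.5x amplitude.
Bout envelopes ramp over 0.25 s to avoid discontinuities; truth labels
still cover the full bout. The milliohm scale is fixed by the device
calibration of 10 mΩ per 3 mm of sensor extension, so the default
bent-finger offset of 33 mΩ corresponds to roughly 10 mm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from scratchkit.io import LabelTrack, SensorRecording

#: Action vocabulary. Scratching and rubbing are ground-truth positives.
ACTIONS = (
    "idle",
    "wave",
    "type_keyboard",
    "tap_desk",
    "move_object",
    "open_close_hand",
    "scratch_finger",
    "scratch_arm",
    "rub",
)
SCRATCH_ACTIONS = frozenset({"scratch_finger", "scratch_arm", "rub"})
INTENSITIES = ("normal", "intensive")


@dataclass(frozen=True)
class ActionSpec:
    """One scripted action bout (default 10 s, rest-to-rest)."""

    action: str
    intensity: str = "normal"
    duration_s: float = 10.0
    body_site: str = ""

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")
        if self.intensity not in INTENSITIES:
            raise ValueError(f"unknown intensity {self.intensity!r}")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")

    @property
    def scratch_truth(self) -> bool:
        """True iff the action counts as scratching (rubbing included)."""
        return self.action in SCRATCH_ACTIONS


@dataclass
class SynthConfig:
    """Tunable signal-model parameters.

    ``bend_offset_mohm`` defaults to 33 mΩ (≈10 mm of extension at the
    10 mΩ / 3 mm calibration), comfortably above the 10 mΩ bend threshold.
    """

    sample_rate_hz: float = 20.0
    scratch_freq_band_hz: tuple[float, float] = (3.0, 8.0)
    bend_offset_mohm: float = 33.0
    oscillation_amp_mohm: float = 20.0
    accel_amp_g: float = 0.5
    drift_amp_mohm: float = 4.0
    drift_period_s: float = 60.0
    drift_amp_g: float = 0.05
    noise_sd_mohm: float = 1.0
    noise_sd_g: float = 0.02
    bend_wander_frac: float = 0.45
    bend_wander_band_hz: tuple[float, float] = (0.1, 0.2)
    ramp_s: float = 0.25
    rub_ax_energy: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.scratch_freq_band_hz
        if not (0 < lo < hi):
            raise ValueError("scratch_freq_band_hz must satisfy 0 < lo < hi")
        if hi >= self.sample_rate_hz / 2:
            raise ValueError(
                "scratch frequency band must lie below the Nyquist frequency"
            )
        for name in (
            "bend_offset_mohm",
            "oscillation_amp_mohm",
            "accel_amp_g",
            "drift_amp_mohm",
            "drift_amp_g",
            "noise_sd_mohm",
            "noise_sd_g",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _envelope(n: int, fs: float, ramp_s: float) -> np.ndarray:
    """Raised-cosine on/off ramps over the first/last ``ramp_s`` seconds."""
    env = np.ones(n)
    r = min(int(round(ramp_s * fs)), n // 2)
    if r > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(r) / r))
        env[:r] = ramp
        env[-r:] = ramp[::-1]
    return env


def _oscillation(
    n: int,
    fs: float,
    band: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-amplitude sinusoid with frequency jittered inside ``band``.

    The instantaneous frequency performs a slow random walk within the band
    so repeated bouts are not phase-locked copies of each other.
    """
    f0 = rng.uniform(*band)
    # slow jitter: +-5% of the band width per second
    jitter = rng.standard_normal(n) * 0.05 * (band[1] - band[0]) / fs
    f = np.clip(f0 + np.cumsum(jitter), band[0], band[1])
    phase = rng.uniform(0, 2 * np.pi) + 2 * np.pi * np.cumsum(f) / fs
    return np.sin(phase)


def _bend_offset(
    t: np.ndarray, cfg: SynthConfig, rng: np.random.Generator,
) -> np.ndarray:
    """A curled-finger baseline: sustained offset with slow wander.

    A real curled finger is never perfectly static — the hand repositions
    while scratching, so the offset carries a slow (0.1–0.2 Hz by default)
    fluctuation of ``bend_wander_frac`` relative amplitude. That energy is
    what lets the bend state survive the slow processing path, whose
    high-pass stage eventually removes any strictly constant offset.
    """
    base = cfg.bend_offset_mohm * rng.uniform(0.8, 1.2)
    f = rng.uniform(*cfg.bend_wander_band_hz)
    phase = rng.uniform(0, 2 * np.pi)
    return base * (
        1 + cfg.bend_wander_frac * np.sin(2 * np.pi * f * t + phase)
    )


def _band(cfg: SynthConfig, intensity: str) -> tuple[float, float]:
    lo, hi = cfg.scratch_freq_band_hz
    mid = (lo + hi) / 2
    return (mid, hi) if intensity == "intensive" else (lo, mid)


def _amp_scale(intensity: str) -> float:
    return 1.5 if intensity == "intensive" else 1.0


def generate_action(
    spec: ActionSpec, cfg: SynthConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[SensorRecording, LabelTrack]:
    """Synthesize one action bout and its ground-truth label track.

    Returns a recording of ``round(duration_s * sample_rate_hz)`` samples
    whose labels are all ``spec.scratch_truth``. With ``noise_sd`` and drift
    set to zero an idle bout is identically zero on all channels.
    """
    cfg = cfg or SynthConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    fs = cfg.sample_rate_hz
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs

    stretch = np.zeros((5, n))
    accel = np.zeros((3, n))

    # background: slow sinusoidal drift with random phase, per channel
    if cfg.drift_amp_mohm > 0 or cfg.drift_amp_g > 0:
        for ch in range(5):
            stretch[ch] += cfg.drift_amp_mohm * np.sin(
                2 * np.pi * t / cfg.drift_period_s + rng.uniform(0, 2 * np.pi)
            )
        for ax in range(3):
            accel[ax] += cfg.drift_amp_g * np.sin(
                2 * np.pi * t / cfg.drift_period_s + rng.uniform(0, 2 * np.pi)
            )

    env = _envelope(n, fs, cfg.ramp_s)
    band = _band(cfg, spec.intensity)
    amp = _amp_scale(spec.intensity)
    act = spec.action

    if act == "idle":
        pass
    elif act == "wave":
        # side-to-side arm motion: ~1-2.5 Hz accelerometer sway, fingers
        # extended (no bend offsets) — the case the bend channels disambiguate
        for ax in (1, 2):
            accel[ax] += (
                0.6 * cfg.accel_amp_g
                * _oscillation(n, fs, (1.0, 2.5), rng) * env
            )
    elif act == "type_keyboard":
        # sporadic low-amplitude key presses on random fingers
        for ch in range(5):
            presses = rng.random(n) < 2.0 / fs  # ~2 presses/s per finger
            pulse = np.convolve(
                presses.astype(float), np.hanning(max(int(0.15 * fs), 3)),
                mode="same",
            )
            stretch[ch] += 0.2 * cfg.oscillation_amp_mohm * pulse
        accel[2] += 0.05 * cfg.accel_amp_g * rng.standard_normal(n)
    elif act == "tap_desk":
        accel[2] += (
            0.4 * cfg.accel_amp_g * _oscillation(n, fs, (1.5, 2.5), rng) * env
        )
        stretch[1] += 0.1 * cfg.oscillation_amp_mohm * _oscillation(
            n, fs, (1.5, 2.5), rng
        ) * env
    elif act == "move_object":
        # grasp: slow flexion of all fingers, one slow reach on the accel
        grasp = cfg.bend_offset_mohm * 0.8 * np.sin(
            np.pi * np.clip(t / spec.duration_s, 0, 1)
        )
        for ch in range(5):
            stretch[ch] += grasp * rng.uniform(0.7, 1.0)
        accel[0] += 0.3 * cfg.accel_amp_g * np.sin(
            2 * np.pi * t / spec.duration_s
        )
    elif act == "open_close_hand":
        # all five fingers flex together at ~1-2 Hz
        osc = _oscillation(n, fs, (1.0, 2.0), rng)
        for ch in range(5):
            stretch[ch] += (
                0.8 * cfg.oscillation_amp_mohm * osc * rng.uniform(0.8, 1.0)
                * env
            )
    elif act == "scratch_finger":
        # 1-5 bent, oscillating fingers; quiet accelerometer
        k = int(rng.integers(1, 6))
        fingers = rng.choice(5, size=k, replace=False)
        for ch in fingers:
            stretch[ch] += env * (
                _bend_offset(t, cfg, rng)
                + amp * cfg.oscillation_amp_mohm
                * _oscillation(n, fs, band, rng)
            )
        accel_jitter = 0.05 * cfg.accel_amp_g
        for ax in range(3):
            accel[ax] += accel_jitter * rng.standard_normal(n) * env
    elif act == "scratch_arm":
        # curled fingers (sustained offsets on all five) + accel oscillation
        for ch in range(5):
            stretch[ch] += env * _bend_offset(t, cfg, rng)
        for ax in (1, 2):
            accel[ax] += (
                amp * cfg.accel_amp_g * _oscillation(n, fs, band, rng) * env
            )
    elif act == "rub":
        # mimic one of the two scratch styles ...
        if rng.random() < 0.5:
            k = int(rng.integers(2, 6))
            for ch in rng.choice(5, size=k, replace=False):
                stretch[ch] += env * (
                    _bend_offset(t, cfg, rng)
                    + amp * cfg.oscillation_amp_mohm
                    * _oscillation(n, fs, band, rng)
                )
        else:
            for ch in range(5):
                stretch[ch] += env * _bend_offset(t, cfg, rng)
            for ax in (1, 2):
                accel[ax] += (
                    amp * cfg.accel_amp_g * _oscillation(n, fs, band, rng)
                    * env
                )
        # ... optionally with the x-axis energy scratching never shows
        if cfg.rub_ax_energy:
            accel[0] += (
                0.7 * amp * cfg.accel_amp_g
                * _oscillation(n, fs, band, rng) * env
            )

    if cfg.noise_sd_mohm > 0:
        stretch += cfg.noise_sd_mohm * rng.standard_normal((5, n))
    if cfg.noise_sd_g > 0:
        accel += cfg.noise_sd_g * rng.standard_normal((3, n))

    rec = SensorRecording(
        stretch=stretch, accel=accel, sample_rate_hz=fs,
        session_meta={"action": act, "intensity": spec.intensity},
    )
    labels = np.full(n, int(spec.scratch_truth), dtype=np.int64)
    codes = np.full(n, ACTIONS.index(act), dtype=np.int64)
    return rec, LabelTrack(labels=labels, action_codes=codes,
                           source="synthetic_truth")


def generate_session(
    script: Sequence[tuple[ActionSpec, float]],
    cfg: SynthConfig | None = None,
    lead_in_s: float = 0.0,
) -> tuple[SensorRecording, LabelTrack]:
    """Concatenate scripted actions separated by idle gaps.

    ``script`` is a sequence of ``(spec, gap_after_s)`` pairs; each action is
    followed by an idle gap of the given duration. ``lead_in_s`` seconds of
    idle precede the first action. A script of one action with zero gaps is
    identical to :func:`generate_action` under the same seed stream.
    """
    if not script:
        raise ValueError("script must be nonempty")
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)

    recs: list[SensorRecording] = []
    labs: list[LabelTrack] = []

    def _idle(duration: float) -> None:
        if duration > 0:
            r, l = generate_action(
                ActionSpec("idle", duration_s=duration), cfg, rng=rng
            )
            recs.append(r)
            labs.append(l)

    _idle(lead_in_s)
    for spec, gap_s in script:
        r, l = generate_action(spec, cfg, rng=rng)
        recs.append(r)
        labs.append(l)
        _idle(gap_s)

    rec = SensorRecording(
        stretch=np.concatenate([r.stretch for r in recs], axis=1),
        accel=np.concatenate([r.accel for r in recs], axis=1),
        sample_rate_hz=cfg.sample_rate_hz,
    )
    track = LabelTrack(
        labels=np.concatenate([l.labels for l in labs]),
        action_codes=np.concatenate([l.action_codes for l in labs]),
        source="synthetic_truth",
    )
    return rec, track


def session_preset_30min(
    cfg: SynthConfig | None = None, bout_s: float = 5.0,
) -> tuple[SensorRecording, LabelTrack]:
    """The 30-minute monitoring scenario: momentary scratches every 4 min.

    At 20 Hz the session is exactly 36,000 samples with 7 scratch bouts
    starting at minutes 4, 8, ..., 28. Bouts alternate between finger- and
    arm-dominant scratching.
    """
    cfg = cfg or SynthConfig()
    total_s = 30 * 60.0
    interval_s = 4 * 60.0
    n_bouts = 7
    script = []
    for i in range(n_bouts):
        action = "scratch_finger" if i % 2 == 0 else "scratch_arm"
        start = interval_s * (i + 1)
        next_start = interval_s * (i + 2)
        gap = (next_start if i < n_bouts - 1 else total_s) - start - bout_s
        script.append((ActionSpec(action, duration_s=bout_s), gap))
    return generate_session(script, cfg, lead_in_s=interval_s - 0.0)


def default_catalog() -> list[ActionSpec]:
    """A balanced 12-entry action catalog: 6 non-scratching actions plus
    normal and intensive variants of both scratching styles and rubbing."""
    specs = [ActionSpec(a) for a in (
        "idle", "wave", "type_keyboard", "tap_desk", "move_object",
        "open_close_hand",
    )]
    for a in ("scratch_finger", "scratch_arm", "rub"):
        specs.append(ActionSpec(a, "normal"))
        specs.append(ActionSpec(a, "intensive"))
    return specs


def generate_training_corpus(
    catalog: Iterable[ActionSpec],
    n_reps: int,
    cfg: SynthConfig | None = None,
) -> list[tuple[SensorRecording, LabelTrack]]:
    """``n_reps`` seeded variants of every catalog entry.

    Per-item seeds are spawned deterministically from ``cfg.seed``, so the
    same configuration always yields a bit-identical corpus.
    """
    catalog = list(catalog)
    if not catalog:
        raise ValueError("catalog must be nonempty")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    cfg = cfg or SynthConfig()
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(len(catalog) * n_reps)
    out = []
    idx = 0
    for spec in catalog:
        for _ in range(n_reps):
            rng = np.random.default_rng(children[idx])
            idx += 1
            out.append(generate_action(spec, cfg, rng=rng))
    return out
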