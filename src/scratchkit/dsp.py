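"""Dual-path signal processing: 8 raw channels -> 13 processed channels.

Two causal paths run in parallel:

* **Fast path** — a 0.5 Hz, 4th-order high-pass Butterworth filter on all
  8 channels (5 stretch + 3 accelerometer). It removes drift and slow
  postural changes while passing the 3–8 Hz scratching oscillations
  essentially unattenuated.
* **Slow path** (stretch channels only) — a 0.03 Hz high-pass to remove
  sensor drift, then a moving average (30-sample window at a 20-sample
  period) to smooth rapid changes, then a 10 mΩ magnitude threshold that
  classifies each finger as "bent" (1) or "extended" (0). 10 mΩ corresponds
  to about 3 mm of sensor extension. The bend channels let a classifier
  separate arm-dominant scratching (curled fingers) from hand-waving, whose
  accelerometer profile is otherwise similar.

Filtering is causal (forward-only), matching live streaming on the device;
filters start from zero state, so roughly the first five seconds of any
recording are transient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from scratchkit.io import SensorRecording

logger = logging.getLogger(__name__)

#: Processed channel names, fixed order: 5 filtered stretch, 3 filtered
#: accel, 5 binary bend states.
PROCESSED_COLUMNS = (
    "d1f", "d2f", "d3f", "d4f", "d5f",
    "axf", "ayf", "azf",
    "b1", "b2", "b3", "b4", "b5",
)

WARMUP_S = 5.0


@dataclass
class DspConfig:
    """Filter-chain parameters (defaults are the deployed values)."""

    fast_cutoff_hz: float = 0.5
    slow_cutoff_hz: float = 0.03
    filter_order: int = 4
    slow_filter_order: int = 1
    ma_window: int = 30
    ma_step: int = 20
    bend_threshold_mohm: float = 10.0

    def __post_init__(self) -> None:
        if self.filter_order < 1 or self.slow_filter_order < 1:
            raise ValueError("filter orders must be >= 1")
        if self.ma_window < 1 or self.ma_step < 1:
            raise ValueError("ma_window and ma_step must be >= 1")
        if self.bend_threshold_mohm <= 0:
            raise ValueError("bend_threshold_mohm must be positive")


@dataclass
class ProcessedChannels:
    """The 13-channel processed representation of a recording.

    ``filtered`` is ``(8, N)``: high-pass stretch D1..D5 then accel AX..AZ.
    ``bend`` is ``(5, N)`` with values in {0, 1} (1 = bent).
    """

    filtered: np.ndarray
    bend: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        self.filtered = np.asarray(self.filtered, dtype=float)
        self.bend = np.asarray(self.bend)
        if self.filtered.ndim != 2 or self.filtered.shape[0] != 8:
            raise ValueError("filtered must be (8, N)")
        if self.bend.shape != (5, self.filtered.shape[1]):
            raise ValueError("bend must be (5, N) aligned with filtered")
        if self.bend.size and not np.isin(self.bend, (0, 1)).all():
            raise ValueError("bend states must be strictly binary")

    @property
    def n_samples(self) -> int:
        return self.filtered.shape[1]

    def matrix(self) -> np.ndarray:
        """``(N, 13)`` sample-major matrix in :data:`PROCESSED_COLUMNS`
        order, the input layout expected by the window classifier."""
        return np.vstack([self.filtered, self.bend.astype(float)]).T


def highpass_butterworth(
    x: np.ndarray, cutoff_hz: float, order: int, fs: float,
) -> np.ndarray:
    """Causal forward high-pass Butterworth filtering of one channel.

    Implemented in second-order sections for numerical stability at very
    low normalized cutoffs (0.03 Hz at 20 Hz sampling). Zero initial state:
    a step input decays with the filter's own transient.
    """
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={fs / 2}) Hz"
        )
    if order < 1:
        raise ValueError("order must be >= 1")
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=fs,
                        output="sos")
    return signal.sosfilt(sos, np.asarray(x, dtype=float))


def moving_average(
    x: np.ndarray, window: int = 30, step: int = 20,
) -> np.ndarray:
    """Strided moving average expanded back to per-sample length.

    Window *j* covers samples ``[j*step, j*step + window)``; its mean is
    held (zero-order hold) over the output block ``[j*step, (j+1)*step)``,
    with the final window's mean held to the end of the signal so the
    output always has the input's length. If ``window > len(x)`` a single
    average over all samples is held everywhere.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n == 0:
        return x.copy()
    if window > n:
        return np.full(n, x.mean())
    n_win = (n - window) // step + 1
    starts = np.arange(n_win) * step
    means = np.array([x[s:s + window].mean() for s in starts])
    out = np.empty(n)
    for j, m in enumerate(means):
        lo = j * step
        hi = (j + 1) * step if j < n_win - 1 else n
        out[lo:hi] = m
    return out


def bend_state(
    x_processed: np.ndarray, threshold_mohm: float = 10.0,
) -> np.ndarray:
    """Binary bent/extended state: 1 where ``|x| >= threshold`` else 0.

    Ties count as bent — the scratch-sensitive choice.
    """
    if threshold_mohm <= 0:
        raise ValueError("threshold must be positive")
    return (np.abs(np.asarray(x_processed, dtype=float))
            >= threshold_mohm).astype(np.int64)


def process_recording(
    rec: SensorRecording, cfg: DspConfig | None = None,
) -> ProcessedChannels:
    """Run both processing paths on a recording.

    Fast path: ``fast_cutoff_hz`` high-pass on all 8 channels. Slow path
    (stretch only): ``slow_cutoff_hz`` high-pass, moving average, bend
    threshold. Recordings shorter than the ~5 s filter warm-up are
    processed anyway with a logged warning.
    """
    cfg = cfg or DspConfig()
    fs = rec.sample_rate_hz
    n = rec.n_samples
    if 0 < n < WARMUP_S * fs:
        logger.warning(
            "recording of %.2f s is shorter than the %.0f s filter warm-up; "
            "output is dominated by the transient", n / fs, WARMUP_S,
        )

    raw = rec.channels()  # (8, N)
    if n == 0:
        return ProcessedChannels(
            filtered=np.empty((8, 0)), bend=np.empty((5, 0), dtype=np.int64),
            sample_rate_hz=fs,
        )

    filtered = np.vstack([
        highpass_butterworth(raw[ch], cfg.fast_cutoff_hz, cfg.filter_order,
                             fs)
        for ch in range(8)
    ])
    bend = np.vstack([
        bend_state(
            moving_average(
                highpass_butterworth(rec.stretch[ch], cfg.slow_cutoff_hz,
                                     cfg.slow_filter_order, fs),
                cfg.ma_window, cfg.ma_step,
            ),
            cfg.bend_threshold_mohm,
        )
        for ch in range(5)
    ])
    return ProcessedChannels(filtered=filtered, bend=bend,
                             sample_rate_hz=fs)


def write_processed(pc: ProcessedChannels, path) -> None:
    """Write the 13-channel matrix as CSV in :data:`PROCESSED_COLUMNS`
    order."""
    import pandas as pd

    df = pd.DataFrame(pc.matrix(), columns=list(PROCESSED_COLUMNS))
    df.to_csv(path, index=False, float_format="%.10g")


def read_processed(path, sample_rate_hz: float = 20.0) -> ProcessedChannels:
    """Read a processed CSV written by :func:`write_processed`."""
    import pandas as pd

    df = pd.read_csv(path)
    if tuple(df.columns) != PROCESSED_COLUMNS:
        raise ValueError(
            f"{path}: columns {list(df.columns)} do not match "
            f"{list(PROCESSED_COLUMNS)}"
        )
    mat = df.to_numpy(dtype=float).T  # (13, N)
    return ProcessedChannels(
        filtered=mat[:8], bend=mat[8:13].astype(np.int64),
        sample_rate_hz=sample_rate_hz,
    )


def band_power(
    x: np.ndarray, fs: float, band: tuple[float, float],
) -> float:
    """Total periodogram power of ``x`` inside ``band`` (Hz, inclusive)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return 0.0
    freqs, pxx = signal.periodogram(x, fs=fs, detrend=False)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.trapezoid(pxx[mask], freqs[mask])) if mask.sum() > 1 \
        else float(pxx[mask].sum())
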