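"""Sliding-window segmentation of processed channels.

Windows are 30 samples long (1.5 s at 20 Hz) and advance by 20 samples
(1 s), so each window consists of the sample at the point of sampling and
the 29 samples before it. Incomplete windows are discarded. A window's
binary label is the median of its per-sample labels; the exact 15/15 tie
resolves to 1 (scratch), the detection-favouring choice. For training data
each action bout carries a uniform truth label, so the median reduces to
that label; sequence data (validation sessions) genuinely exercises the
median at scratch on/offsets.

Training slices take the central 7 s of each 10 s bout to exclude the
transitions from and back to rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from scratchkit.dsp import ProcessedChannels
from scratchkit.io import LabelTrack


@dataclass
class WindowSet:
    """Stacked fixed-length windows with one binary label each.

    ``windows`` is ``(W, window_len, 13)``; ``starts`` holds each window's
    first sample index in its source; ``source_ids`` tracks which source a
    window came from after :func:`stack_actions`.
    """

    windows: np.ndarray
    labels: np.ndarray
    starts: np.ndarray
    window_len: int = 30
    stride: int = 20
    source_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        if self.windows.ndim != 3:
            raise ValueError("windows must be (W, window_len, n_channels)")
        w = self.windows.shape[0]
        if self.windows.shape[1] != self.window_len:
            raise ValueError(
                f"every window must have exactly {self.window_len} samples"
            )
        if self.labels.shape != (w,) or self.starts.shape != (w,):
            raise ValueError("labels and starts must have one entry per "
                             "window")
        if w and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("window labels must be binary")
        if self.source_ids is None:
            self.source_ids = np.zeros(w, dtype=np.int64)
        else:
            self.source_ids = np.asarray(self.source_ids, dtype=np.int64)
            if self.source_ids.shape != (w,):
                raise ValueError("source_ids must have one entry per window")

    def __len__(self) -> int:
        return self.windows.shape[0]

    @property
    def n_channels(self) -> int:
        return self.windows.shape[2]

    def save(self, path: str | Path) -> None:
        """Persist as a single-file ``.npz`` array bundle."""
        np.savez_compressed(
            path, windows=self.windows, labels=self.labels,
            starts=self.starts, source_ids=self.source_ids,
            window_len=self.window_len, stride=self.stride,
        )

    @classmethod
    def load(cls, path: str | Path) -> "WindowSet":
        with np.load(path) as z:
            return cls(
                windows=z["windows"], labels=z["labels"], starts=z["starts"],
                source_ids=z["source_ids"],
                window_len=int(z["window_len"]), stride=int(z["stride"]),
            )


def extract_center(
    processed: ProcessedChannels,
    labels: LabelTrack,
    duration_s: float = 7.0,
) -> tuple[ProcessedChannels, LabelTrack]:
    """Take the centred ``duration_s`` slice of a processed bout.

    With an odd number of samples to trim, the extra sample is dropped from
    the end. A source shorter than the requested duration is an error.
    """
    n = processed.n_samples
    want = int(round(duration_s * processed.sample_rate_hz))
    if n < want:
        raise ValueError(
            f"source of {n} samples is shorter than the requested "
            f"{want}-sample centre slice"
        )
    start = (n - want) // 2
    sl = slice(start, start + want)
    out = ProcessedChannels(
        filtered=processed.filtered[:, sl], bend=processed.bend[:, sl],
        sample_rate_hz=processed.sample_rate_hz,
    )
    track = LabelTrack(
        labels=labels.labels[sl],
        action_codes=None if labels.action_codes is None
        else labels.action_codes[sl],
        source=labels.source,
    )
    return out, track


def label_window(point_labels: np.ndarray) -> int:
    """Binary median label of one window; the exact tie resolves to 1."""
    point_labels = np.asarray(point_labels)
    if not np.isin(point_labels, (0, 1)).all():
        raise ValueError("point labels must be binary")
    ones = int(point_labels.sum())
    n = point_labels.size
    # median of n binary values; at the even-length tie, favour detection
    return 1 if 2 * ones >= n else 0


def make_windows(
    processed: ProcessedChannels,
    labels: LabelTrack,
    window_len: int = 30,
    stride: int = 20,
) -> WindowSet:
    """Section processed channels into complete sliding windows.

    Yields ``floor((N - window_len)/stride) + 1`` windows for
    ``N >= window_len`` and none otherwise (incomplete windows are
    discarded). Each window is labelled with :func:`label_window` over the
    matching slice of the per-sample labels.
    """
    if window_len < 1 or stride < 1:
        raise ValueError("window_len and stride must be >= 1")
    if len(labels) != processed.n_samples:
        raise ValueError("labels must align with processed channels")
    mat = processed.matrix()  # (N, 13)
    n = mat.shape[0]
    n_ch = mat.shape[1]
    if n < window_len:
        return WindowSet(
            windows=np.empty((0, window_len, n_ch)),
            labels=np.empty(0, dtype=np.int64),
            starts=np.empty(0, dtype=np.int64),
            window_len=window_len, stride=stride,
        )
    starts = np.arange(0, n - window_len + 1, stride)
    windows = np.stack([mat[s:s + window_len] for s in starts])
    win_labels = np.array(
        [label_window(labels.labels[s:s + window_len]) for s in starts],
        dtype=np.int64,
    )
    return WindowSet(windows=windows, labels=win_labels, starts=starts,
                     window_len=window_len, stride=stride)


def stack_actions(sets: list[WindowSet]) -> WindowSet:
    """Concatenate per-action window sets into one training array.

    Per-window labels and start indices are preserved; ``source_ids``
    records the position of the originating set so provenance survives
    stacking. An empty list yields an empty set with default geometry.
    """
    if not sets:
        return WindowSet(
            windows=np.empty((0, 30, 13)), labels=np.empty(0, dtype=np.int64),
            starts=np.empty(0, dtype=np.int64),
        )
    lens = {(s.window_len, s.stride, s.n_channels) for s in sets}
    if len(lens) != 1:
        raise ValueError(f"incompatible window geometries: {lens}")
    window_len, stride, _ = next(iter(lens))
    return WindowSet(
        windows=np.concatenate([s.windows for s in sets]),
        labels=np.concatenate([s.labels for s in sets]),
        starts=np.concatenate([s.starts for s in sets]),
        source_ids=np.concatenate([
            np.full(len(s), i, dtype=np.int64) for i, s in enumerate(sets)
        ]),
        window_len=window_len, stride=stride,
    )
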