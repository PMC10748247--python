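"""Reading and writing glove recordings, label tracks, and reports.

File dialect: comma-separated, one header row, UTF-8, ``.`` decimal
separator. Units are fixed by the schema — stretch channels in milliohms of
resistance change relative to the relaxed baseline, accelerometer axes in g.
Timestamps are stored explicitly but ``sample_rate_hz`` is authoritative;
a disagreement of more than one sample over the file is logged as a warning
(hardware clocks jitter), never raised as an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Raw-recording CSV column order: time, thumb..little finger, accel x/y/z.
RECORDING_COLUMNS = (
    "t_s",
    "d1_mohm",
    "d2_mohm",
    "d3_mohm",
    "d4_mohm",
    "d5_mohm",
    "ax_g",
    "ay_g",
    "az_g",
)

STRETCH_CHANNELS = ("d1", "d2", "d3", "d4", "d5")
ACCEL_CHANNELS = ("ax", "ay", "az")

LABEL_SOURCES = ("manual", "model", "synthetic_truth")


class SchemaError(ValueError):
    """Header or column structure does not match the documented schema."""


class FormatError(ValueError):
    """File body violates the format (bad cells, non-monotone time)."""


@dataclass
class SensorRecording:
    """An 8-channel raw glove recording at a fixed sample rate.

    Attributes
    ----------
    stretch:
        ``(5, N)`` array, resistance change in mΩ. Channel order is fixed:
        D1 thumb, D2 index, D3 middle, D4 ring, D5 little.
    accel:
        ``(3, N)`` array in g, order AX, AY, AZ.
    sample_rate_hz:
        Sampling frequency; the glove samples at 20 Hz.
    subject_id:
        Opaque subject tag carried through to reports.
    session_meta:
        Free-form annotations (e.g. EASI or PP-NRS scores); never computed on.
    """

    stretch: np.ndarray
    accel: np.ndarray
    sample_rate_hz: float = 20.0
    subject_id: str = ""
    session_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stretch = np.asarray(self.stretch, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        if self.stretch.ndim != 2 or self.stretch.shape[0] != 5:
            raise ValueError(
                f"stretch must be (5, N), got {self.stretch.shape}"
            )
        if self.accel.ndim != 2 or self.accel.shape[0] != 3:
            raise ValueError(f"accel must be (3, N), got {self.accel.shape}")
        if self.stretch.shape[1] != self.accel.shape[1]:
            raise ValueError(
                "stretch and accel must share the same number of samples: "
                f"{self.stretch.shape[1]} != {self.accel.shape[1]}"
            )
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.stretch.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def channels(self) -> np.ndarray:
        """All 8 raw channels stacked ``(8, N)``: D1..D5 then AX..AZ."""
        return np.vstack([self.stretch, self.accel])


@dataclass
class LabelTrack:
    """Per-sample binary scratch labels aligned to a recording.

    ``labels`` are strictly 0 (non-scratching) or 1 (scratching). Scratching
    and rubbing actions are both labelled 1; everything else is 0.
    """

    labels: np.ndarray
    action_codes: np.ndarray | None = None
    source: str = "synthetic_truth"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be strictly binary (0 or 1)")
        if self.source not in LABEL_SOURCES:
            raise ValueError(
                f"source must be one of {LABEL_SOURCES}, got {self.source!r}"
            )
        if self.action_codes is not None:
            self.action_codes = np.asarray(self.action_codes)
            if self.action_codes.shape != self.labels.shape:
                raise ValueError("action_codes must align with labels")

    def __len__(self) -> int:
        return self.labels.size


def read_recording(path: str | Path) -> SensorRecording:
    """Parse a raw recording CSV into a :class:`SensorRecording`.

    The header must be exactly ``t_s,d1_mohm..d5_mohm,ax_g,ay_g,az_g``.
    Malformed numeric cells raise :class:`FormatError` rather than being
    dropped; non-monotone timestamps are a :class:`FormatError`; an empty
    body yields an ``N=0`` recording.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if tuple(df.columns) != RECORDING_COLUMNS:
        raise SchemaError(
            f"{path}: header {list(df.columns)} does not match schema "
            f"{list(RECORDING_COLUMNS)}"
        )
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: malformed numeric cell ({exc})") from exc
    if values.size and not np.isfinite(values).all():
        raise FormatError(f"{path}: non-finite value in body")

    if values.shape[0] == 0:
        return SensorRecording(
            stretch=np.empty((5, 0)), accel=np.empty((3, 0))
        )

    t = values[:, 0]
    if t.size > 1 and not (np.diff(t) > 0).all():
        raise FormatError(f"{path}: timestamps are not strictly increasing")

    # sample_rate_hz is authoritative; timestamps are advisory only.
    sample_rate = 20.0
    if t.size > 1:
        implied = (t.size - 1) / (t[-1] - t[0])
        # >1-sample cumulative disagreement over the file is only a warning.
        if abs(implied - sample_rate) * (t[-1] - t[0]) > 1.0:
            sample_rate = float(round(implied, 6))
            logger.warning(
                "%s: timestamp-implied rate %.3f Hz disagrees with the "
                "default 20 Hz by more than one sample; using implied rate",
                path,
                implied,
            )

    return SensorRecording(
        stretch=values[:, 1:6].T,
        accel=values[:, 6:9].T,
        sample_rate_hz=sample_rate,
    )


def write_recording(rec: SensorRecording, path: str | Path) -> None:
    """Write a recording as CSV parseable by :func:`read_recording`.

    Non-finite values are refused. An ``N=0`` recording produces a
    header-only file.
    """
    if not (np.isfinite(rec.stretch).all() and np.isfinite(rec.accel).all()):
        raise ValueError("refusing to write non-finite sample values")
    t = np.arange(rec.n_samples) / rec.sample_rate_hz
    data = np.column_stack([t, rec.stretch.T, rec.accel.T]) if rec.n_samples \
        else np.empty((0, 9))
    df = pd.DataFrame(data, columns=RECORDING_COLUMNS)
    df.to_csv(path, index=False, float_format="%.10g")


def read_labels(path: str | Path) -> LabelTrack:
    """Read a label CSV: one 0/1 per line (header optional: ``label``)."""
    path = Path(path)
    lines = [
        ln.strip()
        for ln in path.read_text(encoding="utf-8").splitlines()
        if ln.strip()
    ]
    if lines and lines[0].lower() == "label":
        lines = lines[1:]
    vals = []
    for ln in lines:
        # tolerate a single comma-separated row as well as one value per line
        for tok in ln.split(","):
            tok = tok.strip()
            if tok not in ("0", "1"):
                raise FormatError(
                    f"{path}: label {tok!r} is not 0 or 1"
                )
            vals.append(int(tok))
    return LabelTrack(labels=np.array(vals, dtype=np.int64), source="manual")


def write_labels(track: LabelTrack, path: str | Path) -> None:
    """Write one 0/1 per line with a ``label`` header."""
    Path(path).write_text(
        "label\n" + "".join(f"{v}\n" for v in track.labels), encoding="utf-8"
    )


def write_report_csv(rows: list[Mapping], path: str | Path) -> None:
    """Write a list of flat mappings (e.g. subject reports) as CSV."""
    pd.DataFrame(rows).to_csv(path, index=False)
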