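"""Uniformly sampled ICP recordings with protocol event annotations.

The on-disk interchange format is plain CSV: a waveform file with columns
``time_s,icp_mmhg`` and an events file with columns ``time_s,label``. Event
labels come from a controlled vocabulary describing infusion-test and
lumbar-drainage protocols. Times are seconds from recording start (0-based);
segments are half-open intervals ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, ProtocolError

EVENT_LABELS = (
    "baseline_start",
    "infusion_start",
    "infusion_stop",
    "drainage_start",
    "day1_end",
    "day2_end",
)

_TIME_TOL = 1e-9


@dataclass
class IcpRecording:
    """A uniformly sampled intracranial-pressure series.

    Parameters
    ----------
    t : ndarray
        Sample times in seconds, strictly increasing and uniform.
    p : ndarray
        Pressure samples in mmHg.
    fs : float
        Sampling rate in Hz.
    events : pandas.DataFrame
        Columns ``time_s`` (float) and ``label`` (one of :data:`EVENT_LABELS`),
        sorted by time and contained within the recording span.
    patient_id : str
        Opaque identifier.
    meta : dict
        Free-form provenance (simulator config, termination reason, ...).
    """

    t: np.ndarray
    p: np.ndarray
    fs: float
    events: pd.DataFrame
    patient_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.t.shape != self.p.shape:
            raise ValueError("t and p must have the same shape")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("sample times must be strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.fs)) > 1e-6:
                raise ValueError("sample times must be uniform at 1/fs")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.events = self.events.reset_index(drop=True)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0

    def event_time(self, label: str) -> float:
        """Return the time of the first event with ``label``.

        Raises :class:`ProtocolError` when the label is absent.
        """
        hits = self.events.loc[self.events["label"] == label, "time_s"]
        if hits.empty:
            raise ProtocolError(f"required event {label!r} not found in annotations")
        return float(hits.iloc[0])

    def has_event(self, label: str) -> bool:
        return bool((self.events["label"] == label).any())

    def slice(self, t0: float, t1: float) -> tuple[np.ndarray, np.ndarray]:
        """Samples with t in the half-open interval [t0, t1)."""
        m = (self.t >= t0 - _TIME_TOL) & (self.t < t1 - _TIME_TOL)
        return self.t[m], self.p[m]


def make_events(pairs) -> pd.DataFrame:
    """Build a validated events table from ``(time_s, label)`` pairs."""
    df = pd.DataFrame(pairs, columns=["time_s", "label"])
    bad = ~df["label"].isin(EVENT_LABELS)
    if bad.any():
        raise ProtocolError(f"unknown event labels: {sorted(df.loc[bad, 'label'].unique())}")
    return df.sort_values("time_s", kind="stable").reset_index(drop=True)


def write_waveform(rec: IcpRecording, path) -> None:
    pd.DataFrame({"time_s": rec.t, "icp_mmhg": rec.p}).to_csv(
        path, index=False, float_format="%.12g"
    )


def write_events(rec: IcpRecording, path) -> None:
    rec.events.to_csv(path, index=False, float_format="%.12g")


def _read_csv(path, columns):
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - rewrap as ParseError
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc
    if list(df.columns) != list(columns):
        raise ParseError(f"{path}: expected header {','.join(columns)}, got {','.join(df.columns)}")
    return df


def read_waveform(path, patient_id: str = "") -> IcpRecording:
    """Read a ``time_s,icp_mmhg`` CSV into an :class:`IcpRecording`.

    Errors name the offending line (header is line 1, first data row line 2).
    """
    df = _read_csv(path, ("time_s", "icp_mmhg"))
    if len(df) < 2:
        raise ParseError(f"{path}: need at least 2 samples to establish a sampling rate")
    t = df["time_s"].to_numpy(float)
    p = df["icp_mmhg"].to_numpy(float)
    nan_rows = np.flatnonzero(~np.isfinite(p))
    if nan_rows.size:
        raise ParseError(f"{path}: non-finite pressure at line {nan_rows[0] + 2}")
    dt = np.diff(t)
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        raise ParseError(f"{path}: time not increasing at line {bad[0] + 3}")
    fs = 1.0 / float(np.median(dt))
    if np.max(np.abs(dt - 1.0 / fs)) > 1e-6:
        j = int(np.argmax(np.abs(dt - 1.0 / fs)))
        raise ParseError(f"{path}: non-uniform sampling at line {j + 3}")
    events = pd.DataFrame({"time_s": pd.Series(dtype=float), "label": pd.Series(dtype=str)})
    return IcpRecording(t=t, p=p, fs=fs, events=events, patient_id=patient_id)


def read_events(path) -> pd.DataFrame:
    """Read a ``time_s,label`` CSV; labels must be in :data:`EVENT_LABELS`."""
    df = _read_csv(path, ("time_s", "label"))
    for i, lab in enumerate(df["label"]):
        if lab not in EVENT_LABELS:
            raise ParseError(f"{path}: unknown event label {lab!r} at line {i + 2}")
    t = df["time_s"].to_numpy(float)
    if np.any(~np.isfinite(t)):
        raise ParseError(f"{path}: non-finite event time")
    return df.sort_values("time_s", kind="stable").reset_index(drop=True)


def attach_events(rec: IcpRecording, events: pd.DataFrame) -> IcpRecording:
    """Return a copy of ``rec`` carrying ``events`` (validated against the span)."""
    t0, t1 = float(rec.t[0]), float(rec.t[-1])
    out = events.reset_index(drop=True)
    outside = (out["time_s"] < t0 - _TIME_TOL) | (out["time_s"] > t1 + _TIME_TOL)
    if outside.any():
        raise ProtocolError("event annotation outside recording span")
    return IcpRecording(
        t=rec.t, p=rec.p, fs=rec.fs, events=out, patient_id=rec.patient_id, meta=dict(rec.meta)
    )
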