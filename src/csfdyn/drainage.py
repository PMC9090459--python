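"""Segment-wise RAP maxima over a continuous lumbar-drainage test.

A 48-h drainage recording is split into a pre-drainage baseline, day 1 and
day 2. The summary statistics are the per-segment maxima RAP1max / RAP2max /
RAP3max (baseline, day 1, day 2) and the relative declines

    dRAPKmax% = 100 * (RAP1max - RAP(K+1)max) / RAP1max,

i.e. the fraction of the baseline compensatory-reserve index recovered after
K days of drainage. Maxima are taken after a 5-point moving-median smoothing
of the valid RAP points (suppressible), guarding against single-window
spikes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import InsufficientDataError
from .recording import IcpRecording

SEGMENTS = ("baseline", "day1", "day2")


@dataclass
class DrainageSummary:
    rap1max: float
    rap2max: float
    rap3max: float
    drap1max_pct: float
    drap2max_pct: float
    icp_dra_mean: float
    drained_volume_ml: float
    flags: dict

    def to_dict(self) -> dict:
        return {
            "rap1max": self.rap1max,
            "rap2max": self.rap2max,
            "rap3max": self.rap3max,
            "drap1max_pct": self.drap1max_pct,
            "drap2max_pct": self.drap2max_pct,
            "icp_dra_mean_mmhg": self.icp_dra_mean,
            "drained_volume_ml": self.drained_volume_ml,
            "flags": dict(self.flags),
        }


def _event_time(events: pd.DataFrame, label: str) -> float:
    from .errors import ProtocolError

    hits = events.loc[events["label"] == label, "time_s"]
    if hits.empty:
        raise ProtocolError(f"required event {label!r} not found")
    return float(hits.iloc[0])


def segment_rap(series: pd.DataFrame, events: pd.DataFrame,
                washin_s: float = 0.0) -> dict:
    """Split a RAP series into baseline / day1 / day2 sub-series.

    Segments are half-open on ``t_mid``: baseline ``[start, drainage_start)``,
    day1 ``[drainage_start, day1_end)``, day2 ``[day1_end, day2_end]`` (the
    final boundary is closed so the last emitted point belongs to day 2).
    Invalid points are excluded from all segments. Empty segments are
    returned empty (callers decide whether that is an error).

    ``washin_s`` excludes a wash-in interval after ``drainage_start`` and
    ``day1_end`` from the day segments. A moving-correlation point emitted
    shortly after a boundary is still computed largely from pre-boundary
    windows — and the drainage-onset pressure descent itself drives AMP and
    mean ICP together, transiently inflating the correlation — so a wash-in
    of at least one correlation span makes the day maxima reflect the settled
    post-boundary state. The default keeps the raw event segmentation.
    """
    if washin_s < 0:
        raise ValueError("washin_s must be nonnegative")
    t_drain = _event_time(events, "drainage_start")
    t_day1 = _event_time(events, "day1_end")
    t_day2 = _event_time(events, "day2_end")
    valid = series.loc[series["valid"].astype(bool)]
    t = valid["t_mid"]
    return {
        "baseline": valid.loc[t < t_drain],
        "day1": valid.loc[(t >= t_drain + washin_s) & (t < t_day1)],
        "day2": valid.loc[(t >= t_day1 + washin_s) & (t <= t_day2)],
    }


def _truncated_moving_median(values: np.ndarray, k: int = 5) -> np.ndarray:
    """Centered k-point moving median with windows truncated at the edges."""
    half = k // 2
    n = values.size
    return np.array(
        [np.median(values[max(0, i - half) : min(n, i + half + 1)]) for i in range(n)]
    )


def rap_max(segment: pd.DataFrame, smooth: bool = True, min_points: int = 5) -> float:
    """Segment RAPmax: maximum of the (optionally median-smoothed) valid points."""
    vals = segment.loc[segment["valid"].astype(bool), "rap"].to_numpy(float)
    if vals.size < min_points:
        raise InsufficientDataError(
            f"segment has {vals.size} valid RAP points (need {min_points})"
        )
    if smooth:
        vals = _truncated_moving_median(vals, 5)
    return float(np.max(vals))


def delta_rap_max_pct(baseline_max: float, interim_max: float) -> float:
    """Relative RAPmax decline, ``100*(baseline - interim)/baseline`` (%).

    Negative when the interim maximum exceeds the baseline maximum.
    """
    if baseline_max <= 0:
        raise ValueError("baseline RAPmax must be positive")
    return 100.0 * (baseline_max - interim_max) / baseline_max


def summarize_drainage(series: pd.DataFrame, events: pd.DataFrame,
                       rec: IcpRecording | None = None,
                       drain_rate_ml_h: float | None = None,
                       smooth: bool = True, washin_s: float = 0.0) -> DrainageSummary:
    """Assemble the drainage summary for one patient.

    ``rec`` supplies the raw pressure for the mean drainage-phase ICP and the
    time-compression factor for drained-volume bookkeeping; both fields are
    NaN-with-reason when unavailable. Component failures (e.g. an empty
    segment) are recorded in ``flags`` and the affected fields set to NaN.
    """
    segments = segment_rap(series, events, washin_s=washin_s)
    flags: dict = {}
    maxima = {}
    for name, key in zip(SEGMENTS, ("rap1max", "rap2max", "rap3max")):
        try:
            maxima[key] = rap_max(segments[name], smooth=smooth)
        except InsufficientDataError as exc:
            maxima[key] = float("nan")
            flags[key] = str(exc)

    def delta(interim_key):
        try:
            if np.isnan(maxima["rap1max"]) or np.isnan(maxima[interim_key]):
                return float("nan")
            return delta_rap_max_pct(maxima["rap1max"], maxima[interim_key])
        except ValueError as exc:
            flags[f"drap_{interim_key}"] = str(exc)
            return float("nan")

    icp_dra = float("nan")
    drained = float("nan")
    if rec is not None:
        t_drain = _event_time(events, "drainage_start")
        t_day2 = _event_time(events, "day2_end")
        _, p = rec.slice(t_drain, t_day2 + 0.5 / rec.fs)
        if p.size:
            icp_dra = float(np.mean(p))
        compression = float(rec.meta.get("time_compression", 1.0))
        rate = drain_rate_ml_h if drain_rate_ml_h is not None else rec.meta.get(
            "drain_rate_ml_h"
        )
        if rate is not None:
            drained = float(rate) * (t_day2 - t_drain) * compression / 3600.0
    else:
        flags["icp_dra_mean"] = "no recording supplied"

    return DrainageSummary(
        rap1max=maxima["rap1max"],
        rap2max=maxima["rap2max"],
        rap3max=maxima["rap3max"],
        drap1max_pct=delta("rap2max"),
        drap2max_pct=delta("rap3max"),
        icp_dra_mean=icp_dra,
        drained_volume_ml=drained,
        flags=flags,
    )


class DrainageSummarizer(BaseEstimator):
    """Estimator-style wrapper: ``fit(series, events[, rec])`` -> ``summary_``."""

    def __init__(self, smooth: bool = True, drain_rate_ml_h: float | None = None,
                 washin_s: float = 0.0):
        self.smooth = smooth
        self.drain_rate_ml_h = drain_rate_ml_h
        self.washin_s = washin_s

    def fit(self, series: pd.DataFrame, events: pd.DataFrame,
            rec: IcpRecording | None = None):
        self.summary_ = summarize_drainage(
            series, events, rec, self.drain_rate_ml_h, self.smooth, self.washin_s
        )
        return self
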