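"""Constant-rate infusion-test analysis: baseline, plateau, Rout, model fit.

The primary outflow-resistance estimator is the two-point plateau form of the
constant-rate infusion relation,

    Rout = (Pp - Pb) / I_inf   [mmHg*min/ml],

with Pb the steady baseline mean ICP and Pp the plateau mean ICP under
infusion at I_inf (1.5 ml/min by protocol). A full nonlinear CSF-dynamics
model fit (outflow resistance R, elastance E, reference pressure P0) over the
numerically integrated storage equation is available as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .errors import (
    FitFailedError,
    InsufficientDataError,
    ProtocolError,
    UnstableBaselineError,
)
from .recording import IcpRecording

TERMINATION_REASONS = ("plateau_reached", "rout_exceeds_18", "max_duration")


@dataclass
class InfusionResult:
    """Result of one infusion-test analysis (fields mirror the report JSON)."""

    pb: float                      # baseline mean ICP, mmHg
    pp: float                      # plateau mean ICP, mmHg
    i_inf: float                   # infusion rate, ml/min
    rout: float                    # (pp - pb) / i_inf, mmHg*min/ml
    baseline_interval: tuple       # (t0, t1), s
    plateau_interval: tuple        # (t0, t1), s
    termination_reason: str
    plateau_flagged: bool = False  # Pp taken from last stable rolling mean
    protocol_pressure_ok: bool = True  # plateau stayed <= 15 mmHg (compliance flag)
    fit: dict | None = None        # optional full-model fit {r, e, p0, rss}

    def to_dict(self) -> dict:
        d = {
            "pb_mmhg": self.pb,
            "pp_mmhg": self.pp,
            "i_inf_ml_min": self.i_inf,
            "rout_mmhg_min_ml": self.rout,
            "baseline_interval_s": list(self.baseline_interval),
            "plateau_interval_s": list(self.plateau_interval),
            "termination_reason": self.termination_reason,
            "plateau_flagged": self.plateau_flagged,
            "protocol_pressure_ok": self.protocol_pressure_ok,
        }
        if self.fit is not None:
            d["fit"] = dict(self.fit)
        return d


def _second_means(t, p):
    """Average samples onto a 1-s grid; returns (grid_start_times, means)."""
    if t.size == 0:
        return np.array([]), np.array([])
    rel = t - t[0]
    idx = np.floor(rel).astype(int)
    n = idx[-1] + 1
    sums = np.bincount(idx, weights=p, minlength=n)
    counts = np.bincount(idx, minlength=n)
    good = counts > 0
    return t[0] + np.flatnonzero(good).astype(float), sums[good] / counts[good]


def _rolling_minute(means):
    """Trailing 60-s rolling means of a 1-s series (defined from index 59)."""
    if means.size < 60:
        return np.array([])
    c = np.concatenate([[0.0], np.cumsum(means)])
    return (c[60:] - c[:-60]) / 60.0


def detect_baseline(rec: IcpRecording, min_baseline_s: float = 600.0,
                    steadiness_mmhg: float = 1.0):
    """Locate the steady pre-infusion baseline and return ``(Pb, interval)``.

    The baseline is the longest pre-infusion span over which the trailing
    1-min rolling means stay within a ``steadiness_mmhg`` band; it must be at
    least ``min_baseline_s`` long. Raises :class:`ProtocolError` when the
    ``infusion_start`` event is missing and :class:`UnstableBaselineError`
    when no steady span exists.
    """
    t_inf = rec.event_time("infusion_start")
    t, p = rec.slice(rec.t[0], t_inf)
    if t.size == 0:
        raise UnstableBaselineError("no pre-infusion samples")
    sec_t, sec_m = _second_means(t, p)
    roll = _rolling_minute(sec_m)
    if roll.size == 0:
        raise UnstableBaselineError("pre-infusion span shorter than 1 min")
    roll_t = sec_t[59:]  # trailing convention: rolling mean timestamped at span end

    # longest window of the rolling-mean series with max-min < threshold
    best = (0, 0)
    lo = 0
    from collections import deque

    maxq: deque = deque()
    minq: deque = deque()
    for hi in range(roll.size):
        while maxq and roll[maxq[-1]] <= roll[hi]:
            maxq.pop()
        maxq.append(hi)
        while minq and roll[minq[-1]] >= roll[hi]:
            minq.pop()
        minq.append(hi)
        while roll[maxq[0]] - roll[minq[0]] >= steadiness_mmhg:
            lo += 1
            if maxq[0] < lo:
                maxq.popleft()
            if minq[0] < lo:
                minq.popleft()
        if hi - lo > best[1] - best[0]:
            best = (lo, hi)
    lo, hi = best
    # rolling means are trailing: span [lo, hi] covers raw time
    # [roll_t[lo] - 59, roll_t[hi]]
    t0 = float(roll_t[lo] - 59.0)
    t1 = float(roll_t[hi]) + 1.0
    if t1 - t0 < min_baseline_s:
        raise UnstableBaselineError(
            f"longest steady pre-infusion span is {t1 - t0:.0f} s "
            f"(need {min_baseline_s:.0f} s)"
        )
    m = (t >= t0) & (t < t1)
    return float(np.mean(p[m])), (t0, t1)


def detect_plateau(rec: IcpRecording, i_inf: float | None = None,
                   slope_thresh: float = 0.2, sustain_s: float = 300.0,
                   rout_threshold: float = 18.0,
                   pb: float | None = None, pp_tail_s: float = 180.0):
    """Find the infusion plateau; returns ``(Pp, interval, termination_reason)``.

    The plateau is the final span whose trailing 1-min rolling-mean slope
    stays below ``slope_thresh`` mmHg/min for at least ``sustain_s``; Pp is
    the mean pressure over its trailing ``pp_tail_s`` (the early part of the
    span still carries the tail of the exponential rise, which would bias the
    plateau estimate low). When no plateau exists, the running two-point Rout
    is examined: if it exceeded ``rout_threshold`` the reason is
    ``rout_exceeds_18`` and Pp is the last stable rolling mean (flagged);
    otherwise ``max_duration``.
    """
    t_start = rec.event_time("infusion_start")
    t_stop = rec.event_time("infusion_stop") if rec.has_event("infusion_stop") else rec.t[-1]
    if i_inf is None:
        i_inf = float(rec.meta.get("i_inf", 1.5))
    t, p = rec.slice(t_start, t_stop)
    if t.size == 0 or (t[-1] - t[0]) < sustain_s:
        raise InsufficientDataError("infusion phase shorter than the plateau criterion span")
    sec_t, sec_m = _second_means(t, p)
    roll = _rolling_minute(sec_m)
    roll_t = sec_t[59:]
    if roll.size <= 60:
        raise InsufficientDataError("infusion phase too short for slope analysis")
    slope = roll[60:] - roll[:-60]  # mmHg per minute
    slope_t = roll_t[60:]
    flat = np.abs(slope) < slope_thresh

    # final contiguous flat run of length >= sustain_s
    run_start = None
    spans = []
    for j, f in enumerate(flat):
        if f and run_start is None:
            run_start = j
        elif not f and run_start is not None:
            spans.append((run_start, j - 1))
            run_start = None
    if run_start is not None:
        spans.append((run_start, flat.size - 1))
    spans = [s for s in spans if slope_t[s[1]] - slope_t[s[0]] >= sustain_s]

    if spans:
        j0, j1 = spans[-1]
        t0, t1 = float(slope_t[j0] - 60.0), float(slope_t[j1]) + 1.0
        t_pp = max(t0, t1 - pp_tail_s)
        m = (t >= t_pp) & (t < t1)
        return float(np.mean(p[m])), (t0, t1), "plateau_reached"

    if pb is None:
        pb, _ = detect_baseline(rec)
    running_rout = (roll - pb) / i_inf
    pp = float(roll[-1])
    interval = (float(roll_t[-1] - 59.0), float(roll_t[-1]) + 1.0)
    if np.nanmax(running_rout) > rout_threshold:
        return pp, interval, "rout_exceeds_18"
    return pp, interval, "max_duration"


def compute_rout(pb: float, pp: float, i_inf: float) -> float:
    """Two-point outflow resistance ``(Pp - Pb) / I_inf`` in mmHg*min/ml."""
    if i_inf <= 0:
        raise ValueError("infusion rate must be positive")
    if pp < pb:
        raise ValueError("plateau pressure below baseline (negative rise)")
    return (pp - pb) / i_inf


def analyze_infusion(rec: IcpRecording, i_inf: float | None = None,
                     min_baseline_s: float = 600.0,
                     steadiness_mmhg: float = 1.0,
                     slope_thresh: float = 0.2,
                     sustain_s: float = 300.0,
                     rout_threshold: float = 18.0,
                     with_fit: bool = False) -> InfusionResult:
    """End-to-end infusion-test analysis of one recording."""
    if i_inf is None:
        i_inf = float(rec.meta.get("i_inf", 1.5))
    pb, b_int = detect_baseline(rec, min_baseline_s, steadiness_mmhg)
    pp, p_int, reason = detect_plateau(
        rec, i_inf, slope_thresh, sustain_s, rout_threshold, pb=pb
    )
    fit = None
    if with_fit:
        r, e, p0, rss = fit_csf_model(rec, i_inf)
        fit = {"r": r, "e": e, "p0": p0, "rss": rss}
    return InfusionResult(
        pb=pb,
        pp=pp,
        i_inf=i_inf,
        rout=compute_rout(pb, pp, i_inf),
        baseline_interval=b_int,
        plateau_interval=p_int,
        termination_reason=reason,
        plateau_flagged=reason != "plateau_reached",
        protocol_pressure_ok=pp <= 15.0,
        fit=fit,
    )


def _integrate_rise(pb, t_rel_min, r, e, p0, i_inf, n_sub=6):
    """RK4-integrate the storage ODE from Pb over the (minute-unit) time grid.

    The baseline steady state ties the formation rate to the parameters:
    I_f = (Pb - P0)/R. Returns model pressures at ``t_rel_min``.
    """
    q = pb - p0
    if q <= 0 or r <= 0 or e <= 0:
        return None
    i_f = q / r
    itot = i_f + i_inf
    out = np.empty(t_rel_min.size)
    prev = 0.0
    for i, tm in enumerate(t_rel_min):
        span = tm - prev
        steps = max(1, int(np.ceil(span * n_sub)))
        h = span / steps if steps else 0.0
        for _ in range(steps):
            k1 = e * q * (itot - q / r)
            q2 = q + 0.5 * h * k1
            k2 = e * q2 * (itot - q2 / r)
            q3 = q + 0.5 * h * k2
            k3 = e * q3 * (itot - q3 / r)
            q4 = q + h * k3
            k4 = e * q4 * (itot - q4 / r)
            q = q + h * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
            if q <= 0:
                return None
        out[i] = p0 + q
        prev = tm
    return out


def fit_csf_model(rec: IcpRecording, i_inf: float | None = None,
                  n_starts: int | None = None):
    """Least-squares fit of (R, E, P0) to the 1-min-averaged infusion curve.

    Multi-start Levenberg–Marquardt over a coarse parameter grid seeded by the
    two-point estimates. Returns ``(r, e, p0, rss)``; raises
    :class:`FitFailedError` (carrying the best incumbent) when the recording
    shows no infusion response or no start converges.
    """
    if i_inf is None:
        i_inf = float(rec.meta.get("i_inf", 1.5))
    pb, _ = detect_baseline(rec)
    t_start = rec.event_time("infusion_start")
    t_stop = rec.event_time("infusion_stop") if rec.has_event("infusion_stop") else rec.t[-1]
    t, p = rec.slice(t_start, t_stop)
    sec_t, sec_m = _second_means(t, p)
    # 1-min averages of the infusion phase
    n_min = sec_m.size // 60
    if n_min < 5:
        raise InsufficientDataError("infusion phase too short to fit (need 5 min)")
    minute_means = sec_m[: n_min * 60].reshape(n_min, 60).mean(axis=1)
    minute_t = np.arange(n_min) + 0.5  # minutes since infusion start

    rise = float(np.max(minute_means) - pb)
    if rise < 1.0:
        raise FitFailedError("no infusion response (pressure rise < 1 mmHg)")

    r_guess = max(rise / i_inf, 1.0)

    def residuals(theta):
        r, e, p0 = theta
        model = _integrate_rise(pb, minute_t, r, e, p0, i_inf)
        if model is None:
            return np.full(minute_means.size, 1e3)
        return model - minute_means

    starts = []
    for r0 in (r_guess, 0.7 * r_guess, 1.3 * r_guess):
        for e0 in (0.05, 0.15, 0.3):
            for p00 in (1.0, 0.5 * pb, 0.8 * pb):
                starts.append((r0, e0, p00))
    if n_starts is not None:
        starts = starts[:n_starts]

    best = None
    for theta0 in starts:
        try:
            sol = least_squares(
                residuals, theta0,
                bounds=([0.5, 1e-3, -5.0], [60.0, 2.0, pb - 0.5]),
                xtol=1e-12, ftol=1e-12, max_nfev=400,
            )
        except Exception:  # noqa: BLE001 - a failed start is just skipped
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[1]:
            best = (sol, rss)
    if best is None:
        raise FitFailedError("all fit starts failed")
    sol, rss = best
    if not sol.success:
        raise FitFailedError("fit did not converge", incumbent=tuple(sol.x) + (rss,))
    r, e, p0 = sol.x
    return float(r), float(e), float(p0), rss


class InfusionAnalyzer(BaseEstimator):
    """Estimator-style wrapper over :func:`analyze_infusion`.

    ``fit(rec)`` analyzes one recording and exposes fitted attributes
    ``pb_``, ``pp_``, ``rout_``, ``termination_reason_`` and ``result_``.
    """

    def __init__(self, i_inf: float = 1.5, min_baseline_s: float = 600.0,
                 steadiness_mmhg: float = 1.0, slope_thresh: float = 0.2,
                 sustain_s: float = 300.0, rout_threshold: float = 18.0,
                 with_fit: bool = False):
        self.i_inf = i_inf
        self.min_baseline_s = min_baseline_s
        self.steadiness_mmhg = steadiness_mmhg
        self.slope_thresh = slope_thresh
        self.sustain_s = sustain_s
        self.rout_threshold = rout_threshold
        self.with_fit = with_fit

    def fit(self, X: IcpRecording, y=None):
        res = analyze_infusion(
            X, self.i_inf, self.min_baseline_s, self.steadiness_mmhg,
            self.slope_thresh, self.sustain_s, self.rout_threshold,
            with_fit=self.with_fit,
        )
        self.result_ = res
        self.pb_ = res.pb
        self.pp_ = res.pp
        self.rout_ = res.rout
        self.termination_reason_ = res.termination_reason
        return self
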