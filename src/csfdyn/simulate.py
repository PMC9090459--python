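"""Marmarou-type CSF-dynamics simulator.

The slow (trend) component of ICP follows the nonlinear storage equation

    dP/dt = E * (P - P0) * [ I_ext(t) + I_f - (P - P0) / R_out ]

whose steady state under constant net inflow I = I_ext + I_f is
``P = P0 + R_out * I``. On top of the trend the simulator superimposes, additively:

* a cardiac pulse ``a(P) * sin(2*pi*f_cardiac*t)`` whose amplitude follows the
  piecewise-linear AMP law ``a(P) = a0 + k_amp * max(P - P_bp, 0)`` — flat below
  the breakpoint pressure (linear part of the pressure–volume curve, preserved
  compensatory reserve), rising above it (exponential part, exhausted reserve);
* a respiratory sinusoid;
* slow "B-wave" activity modeled as a bounded (reflected) random walk on the CSF
  formation rate, scaled so the induced pressure modulation has amplitude
  ``slow_wave_amp`` — this supplies the mean-ICP variance that a moving
  AMP-vs-ICP correlation (RAP) needs to be non-degenerate;
* white Gaussian measurement noise.

Keeping the oscillatory terms additive on the trend solution keeps the
ground-truth steady states closed-form, so analysis modules can be checked
against exact values. The trend ODE is integrated with fixed-step classical
Runge–Kutta (RK4) at step ``min(0.1 s, 1/fs)``, testable by step-halving.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .recording import IcpRecording, make_events

PHASE_LABELS = ("baseline", "infusion", "drainage", "rest")


@dataclass
class SimConfig:
    """Physiological and acquisition parameters of one simulated subject.

    Defaults give a baseline ICP of ``P0 + R_out*I_f = 9.55 mmHg``, below the
    15-mmHg safety ceiling required of candidates for infusion testing, with a
    literature-typical elastance and formation rate.
    """

    r_out: float = 13.0        # resistance to CSF outflow, mmHg*min/ml
    e_coef: float = 0.11       # elastance coefficient, 1/ml
    p0: float = 5.0            # reference pressure of the P-V curve, mmHg
    i_f: float = 0.35          # CSF formation rate, ml/min
    f_cardiac: float = 1.2     # heart rate, Hz
    f_resp: float = 0.25       # respiratory rate, Hz
    a0: float = 1.0            # floor pulse amplitude, mmHg
    k_amp: float = 0.5         # AMP-vs-ICP slope above the breakpoint
    p_bp: float = 8.0          # AMP breakpoint pressure, mmHg
    resp_amp: float = 0.3      # respiratory modulation amplitude, mmHg
    slow_wave_amp: float = 1.0     # B-wave pressure modulation amplitude, mmHg
    slow_wave_tau_s: float = 60.0  # B-wave traversal time scale, s
    noise_sd: float = 0.2      # measurement noise, mmHg
    fs: float = 100.0          # sampling rate, Hz
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.r_out <= 0:
            raise ValueError("r_out must be positive")
        if self.e_coef <= 0:
            raise ValueError("e_coef must be positive")
        if self.i_f <= 0:
            raise ValueError("i_f must be positive")
        if self.fs < 20:
            raise ValueError("fs must be at least 20 Hz")
        if not (0.67 <= self.f_cardiac <= 3.0):
            raise ValueError("f_cardiac must lie in [0.67, 3] Hz")
        if self.a0 < 0:
            raise ValueError("a0 must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.slow_wave_amp < 0:
            raise ValueError("slow_wave_amp must be nonnegative")
        return self

    def baseline_pressure(self) -> float:
        """Closed-form steady baseline, ``P0 + R_out * I_f``."""
        return self.p0 + self.r_out * self.i_f

    def steady_pressure(self, i_ext: float) -> float:
        """Closed-form steady state under constant external flow (ml/min)."""
        return self.p0 + self.r_out * (self.i_f + i_ext)


@dataclass
class Phase:
    label: str
    duration_min: float
    i_ext: float = 0.0  # ml/min; positive = infusion, negative = drainage


@dataclass
class Protocol:
    """Ordered protocol phases driving the external-flow term of the ODE."""

    phases: list = field(default_factory=list)

    def validate(self) -> "Protocol":
        if not self.phases:
            raise ValueError("protocol must contain at least one phase")
        for ph in self.phases:
            if ph.label not in PHASE_LABELS:
                raise ValueError(f"unknown phase label {ph.label!r}")
            if ph.duration_min <= 0:
                raise ValueError("phase durations must be positive")
        return self

    @property
    def total_s(self) -> float:
        return sum(ph.duration_min for ph in self.phases) * 60.0


def infusion_protocol(
    baseline_min: float = 10.0,
    infusion_min: float = 20.0,
    rest_min: float = 2.0,
    i_inf: float = 1.5,
) -> Protocol:
    """Constant-rate infusion-test protocol (default 1.5 ml/min)."""
    return Protocol(
        [
            Phase("baseline", baseline_min, 0.0),
            Phase("infusion", infusion_min, i_inf),
            Phase("rest", rest_min, 0.0),
        ]
    )


def _phase_events(protocol: Protocol):
    """Map phase boundaries onto the controlled event vocabulary."""
    events = []
    t = 0.0
    prev = None
    for ph in protocol.phases:
        if ph.label == "baseline":
            events.append((t, "baseline_start"))
        elif ph.label == "infusion":
            events.append((t, "infusion_start"))
        elif ph.label == "drainage":
            events.append((t, "drainage_start"))
        if prev == "infusion" and ph.label != "infusion":
            events.append((t, "infusion_stop"))
        t += ph.duration_min * 60.0
        prev = ph.label
    if prev == "infusion":
        events.append((t, "infusion_stop"))
    return events


def _slow_trajectory(config, i_ext, duration_s, dt, delta_if=None):
    """RK4-integrate the trend ODE; returns P at times k*dt, k=0..N.

    ``i_ext`` is either a per-step array of external flows (ml/min; treated
    as constant within each step, which keeps the integrand smooth inside
    protocol phases and phase boundaries exact) or a callable of time, in
    which case the RK4 stages evaluate it at their own stage times.
    ``delta_if`` is an optional per-step additive perturbation of the
    formation rate (B-waves). Drainage that would drive P to the reference
    pressure P0 is clamped: the trend is floored 0.05 mmHg above P0
    (clamping is reported via the second return value).
    """
    e, p0, r, i_f = config.e_coef, config.p0, config.r_out, config.i_f
    n = int(round(duration_s / dt))
    out = np.empty(n + 1)
    q = config.baseline_pressure() - p0
    if q <= 0:
        raise ValueError("initial pressure not above P0; integration would diverge")
    out[0] = p0 + q
    clamped = False
    floor = 0.05
    callable_flow = callable(i_ext)
    c = e / 60.0  # per-second rate factor
    for k in range(n):
        dif = delta_if[k] if delta_if is not None else 0.0
        if callable_flow:
            t = k * dt
            ie0 = i_ext(t)
            iem = i_ext(t + 0.5 * dt)
            ie1 = i_ext(t + dt)
        else:
            ie0 = iem = ie1 = i_ext[k]
        i0 = ie0 + i_f + dif
        im = iem + i_f + dif
        i1 = ie1 + i_f + dif
        k1 = c * q * (i0 - q / r)
        q2 = q + 0.5 * dt * k1
        k2 = c * q2 * (im - q2 / r)
        q3 = q + 0.5 * dt * k2
        k3 = c * q3 * (im - q3 / r)
        q4 = q + dt * k3
        k4 = c * q4 * (i1 - q4 / r)
        q = q + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        if q < floor:
            q = floor
            clamped = True
        out[k + 1] = p0 + q
    return out, clamped


def _slow_wave_deltas(config, n_steps, dt, rng):
    """Bounded (reflected) random walk on the formation rate, ml/min.

    The walk is bounded at ``±slow_wave_amp / r_out`` so the induced pressure
    modulation spans ``±slow_wave_amp``; the step size makes the walk traverse
    the band in about ``slow_wave_tau_s`` seconds.
    """
    if config.slow_wave_amp == 0:
        return None
    bound = config.slow_wave_amp / config.r_out
    step_sd = bound * math.sqrt(dt / config.slow_wave_tau_s)
    z = rng.standard_normal(n_steps) * step_sd
    out = np.empty(n_steps)
    x = 0.0
    for k in range(n_steps):
        x += z[k]
        if x > bound:
            x = 2 * bound - x
        elif x < -bound:
            x = -2 * bound - x
        out[k] = x
    return out


def simulate_pressure(
    config: SimConfig,
    protocol: Protocol,
    i_ext_fn=None,
    patient_id: str = "",
    _substeps: int = 1,
) -> IcpRecording:
    """Simulate an ICP recording under a phase protocol.

    ``i_ext_fn`` optionally overrides the piecewise-constant external flow of
    the protocol with an arbitrary function of time (used by the drainage
    generator for its ramped withdrawal). Identical ``(config, protocol,
    seed)`` produce bit-identical recordings.
    """
    config.validate()
    protocol.validate()
    fs = config.fs
    dt = min(0.1, 1.0 / fs) / _substeps
    duration_s = protocol.total_s
    n_steps = int(round(duration_s / dt))
    rng = np.random.default_rng(config.seed)

    bounds = np.cumsum([0.0] + [ph.duration_min * 60.0 for ph in protocol.phases])
    flows = np.array([ph.i_ext for ph in protocol.phases])

    if i_ext_fn is None:
        # per-step flow from the phase containing the step's left edge
        step_t = np.arange(n_steps) * dt
        idx = np.clip(np.searchsorted(bounds, step_t, side="right") - 1, 0, len(flows) - 1)
        i_ext_fn_ = flows[idx]
    else:
        i_ext_fn_ = i_ext_fn

    delta_if = _slow_wave_deltas(config, n_steps, dt, rng)
    p_slow, clamped = _slow_trajectory(config, i_ext_fn_, duration_s, dt, delta_if)

    stride = max(1, int(round((1.0 / fs) / dt)))
    t = np.arange(0, n_steps + 1, stride) * dt
    ps = p_slow[::stride]
    amp = config.a0 + config.k_amp * np.maximum(ps - config.p_bp, 0.0)
    p = (
        ps
        + amp * np.sin(2 * np.pi * config.f_cardiac * t)
        + config.resp_amp * np.sin(2 * np.pi * config.f_resp * t)
    )
    if config.noise_sd > 0:
        p = p + config.noise_sd * rng.standard_normal(t.size)

    events = make_events(_phase_events(protocol))
    rec = IcpRecording(
        t=t,
        p=p,
        fs=fs,
        events=events,
        patient_id=patient_id,
        meta={
            "config": config,
            "protocol": protocol,
            "drainage_clamped": clamped,
        },
    )
    return rec


# --------------------------------------------------------------------------
# Infusion-test generator with the clinical termination rules
# --------------------------------------------------------------------------

def default_infusion_config(**overrides) -> SimConfig:
    """Config suited to infusion testing: quiet baseline (B-waves suppressed)."""
    cfg = SimConfig(slow_wave_amp=0.0, noise_sd=0.0)
    return replace(cfg, **overrides)


def _decide_infusion_duration(
    config, baseline_min, max_infusion_min, post_plateau_min, i_inf,
    terminate_on_rout, rout_threshold, min_infusion_min,
    slope_thresh=0.05, sustain_s=300.0,
):
    """Run the online termination rules on the deterministic trend.

    Returns (infusion duration in s, termination reason). The decision pass
    uses the noise-free, B-wave-free trend so the recorded protocol is a
    deterministic function of the physiological parameters. The protocol's
    plateau confirmation (slope < 0.05 mmHg/min sustained 5 min) is stricter
    than the analysis-side plateau detector, so the recorded plateau segment
    is essentially fully converged before the post-plateau clock starts.
    """
    dt = 1.0
    pb = config.baseline_pressure()

    def flow(t):
        return i_inf if t >= 0 else 0.0

    dur = max_infusion_min * 60.0
    traj, _ = _slow_trajectory(config, flow, dur, dt)
    # trajectory starts at the baseline steady state; 1-min rolling means
    # on a 1-s grid, defined from 60 s into the infusion
    csum = np.concatenate([[0.0], np.cumsum(traj)])
    tgrid = np.arange(60, int(dur) + 1)
    roll = (csum[tgrid] - csum[tgrid - 60]) / 60.0

    min_s = min_infusion_min * 60.0
    slope = np.full(roll.size, np.nan)
    slope[60:] = roll[60:] - roll[:-60]  # mmHg per minute

    flat = np.abs(slope) < slope_thresh
    sustain = int(sustain_s)
    plateau_confirm_t = None
    run = 0
    for j in range(flat.size):
        run = run + 1 if flat[j] else 0
        if run >= sustain:
            plateau_confirm_t = float(tgrid[j])
            break

    if terminate_on_rout:
        rout_run = (roll - pb) / i_inf
        exceed = np.flatnonzero((rout_run > rout_threshold) & (tgrid >= min_s))
        if exceed.size:
            t_exceed = float(tgrid[exceed[0]])
            if plateau_confirm_t is None or t_exceed < plateau_confirm_t:
                return t_exceed, "rout_exceeds_18"

    if plateau_confirm_t is not None:
        t_inf = min(plateau_confirm_t + post_plateau_min * 60.0, dur)
        return t_inf, "plateau_reached"
    return dur, "max_duration"


def simulate_infusion_test(
    config: SimConfig | None = None,
    baseline_min: float = 10.0,
    i_inf: float = 1.5,
    max_infusion_min: float = 45.0,
    post_plateau_min: float = 10.0,
    min_infusion_min: float = 5.0,
    terminate_on_rout: bool = True,
    rout_threshold: float = 18.0,
    patient_id: str = "",
) -> IcpRecording:
    """Simulate a constant-rate infusion test with protocol termination rules.

    The infusion runs until either (a) a pressure plateau is confirmed (1-min
    rolling-mean slope below 0.2 mmHg/min sustained for 5 min), after which
    recording continues for ``post_plateau_min`` under infusion, or (b) the
    running two-point Rout estimate exceeds ``rout_threshold`` before a plateau
    is confirmed (never before ``min_infusion_min`` of infusion), or (c) the
    ``max_infusion_min`` cap. The applied reason is recorded in
    ``rec.meta['termination_reason']``. Set ``terminate_on_rout=False`` to run
    every test to plateau regardless of the estimate (ground-truth mode).
    """
    cfg = (config or default_infusion_config()).validate()
    t_inf_s, reason = _decide_infusion_duration(
        cfg, baseline_min, max_infusion_min, post_plateau_min, i_inf,
        terminate_on_rout, rout_threshold, min_infusion_min,
    )
    protocol = Protocol(
        [
            Phase("baseline", baseline_min, 0.0),
            Phase("infusion", t_inf_s / 60.0, i_inf),
            Phase("rest", 2.0, 0.0),
        ]
    )
    rec = simulate_pressure(cfg, protocol, patient_id=patient_id)
    rec.meta["termination_reason"] = reason
    rec.meta["i_inf"] = i_inf
    return rec


# --------------------------------------------------------------------------
# Continuous lumbar-drainage generator
# --------------------------------------------------------------------------

def default_drainage_config(**overrides) -> SimConfig:
    """Config suited to drainage monitoring: prominent B-waves, desk-scale rate.

    The breakpoint sits 2 mmHg below the resting operating point and the
    B-wave band is wide (±1.5 mmHg), so partial reserve recovery shows up as
    a graded RAP decline: the fraction of slow-wave excursions falling below
    the breakpoint grows smoothly as the operating point descends.
    """
    cfg = SimConfig(
        fs=20.0, p_bp=7.5, slow_wave_amp=1.5, slow_wave_tau_s=30.0, noise_sd=0.2
    )
    return replace(cfg, **overrides)


def simulate_drainage(
    config: SimConfig | None = None,
    rho: float = 1.0,
    baseline_h: float = 8.0,
    day_h: float = 24.0,
    compression: float = 60.0,
    drain_rate_ml_h: float = 12.5,
    p_low: float | None = None,
    patient_id: str = "",
) -> IcpRecording:
    """Simulate a 48-h external-lumbar-drainage recording.

    ``rho`` is the latent reserve-recovery fraction in [0, 1]: it scales how far
    the operating point is drawn below the AMP breakpoint by the end of day 2.
    With ``rho=1`` the trend descends well below the breakpoint (AMP flattens,
    RAP collapses toward 0 — recovered compensatory reserve); with ``rho=0``
    the operating point never leaves the exponential region and RAP stays high.
    The descent is fast early in day 1 and completes early in day 2, mirroring
    the clinically observed prompt RAP response to drainage onset.

    ``compression`` divides all protocol durations (48 h -> desk-scale
    minutes); day-boundary events are scaled accordingly and the factor is
    recorded in ``meta['time_compression']`` so bookkeeping (e.g. drained
    volume at 10-15 ml/h of real time) can be done on the clinical time base.
    Pass ``compression=1`` for a real-time recording.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    cfg = (config or default_drainage_config()).validate()
    if compression < 1.0:
        raise ValueError("compression must be >= 1")
    if compression > 1.0:
        # compressed-time mode scales the trend dynamics with the protocol so
        # the recording keeps its shape: the storage time constant 1/(E*I) is
        # divided by the same factor as the durations (steady states, which
        # are E-independent, are untouched)
        cfg = replace(cfg, e_coef=cfg.e_coef * compression)
    if p_low is None:
        p_low = cfg.p_bp - 1.7
    base_s = baseline_h * 3600.0 / compression
    day_s = day_h * 3600.0 / compression
    t_drain = base_s
    t_day1 = base_s + day_s
    t_end = base_s + 2 * day_s

    p_base = cfg.baseline_pressure()
    depth = rho * (p_base - p_low)
    # the operating point responds promptly to drainage (the clinical RAP
    # drop is visible within minutes of opening the drain): ~70% of the total
    # descent settles early in day 1, the remainder early in day 2
    tau1 = day_s / 24.0
    tau2 = day_s / 24.0

    def g(t):
        if t < t_drain:
            return 0.0
        if t < t_day1:
            return 0.7 * (1.0 - math.exp(-(t - t_drain) / tau1))
        g1 = 0.7 * (1.0 - math.exp(-day_s / tau1))
        return g1 + (1.0 - g1) * (1.0 - math.exp(-(t - t_day1) / tau2))

    def i_ext(t):
        p_target = p_base - depth * g(t)
        return (p_target - cfg.p0) / cfg.r_out - cfg.i_f

    protocol = Protocol(
        [
            Phase("baseline", base_s / 60.0, 0.0),
            Phase("drainage", 2 * day_s / 60.0, 0.0),
        ]
    )
    rec = simulate_pressure(cfg, protocol, i_ext_fn=i_ext, patient_id=patient_id)
    events = pd.concat(
        [
            rec.events,
            make_events([(t_day1, "day1_end"), (t_end, "day2_end")]),
        ]
    ).sort_values("time_s", kind="stable").reset_index(drop=True)
    # day2_end coincides with the final sample; keep it within span
    events.loc[events["time_s"] > rec.t[-1], "time_s"] = float(rec.t[-1])
    rec.events = events
    rec.meta.update(
        {
            "rho": rho,
            "time_compression": compression,
            "drain_rate_ml_h": drain_rate_ml_h,
            "drained_volume_ml": drain_rate_ml_h * 2 * day_h,
            "p_low": p_low,
        }
    )
    return rec
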