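"""ICP waveform reduction: windowed (mean ICP, AMP) pairs and the RAP index.

AMP is the *fundamental* (cardiac-frequency) amplitude of the ICP pulse wave,
estimated spectrally per window: linear detrend, Hann taper, FFT, peak search
within the cardiac band, and main-lobe energy summation (which makes the
estimate insensitive to the peak falling between FFT bins). RAP is the moving
Pearson correlation between AMP and mean ICP over the most recent ``span_n``
windows: near 0 on the linear part of the pressure–volume curve (AMP does not
respond to slow ICP variation — preserved compensatory reserve), near 1 on the
exponential part (AMP tracks ICP — exhausted reserve).

Windowing granularity follows the convention established for bedside RAP
monitoring: 10-s windows, 40-window correlation span (~6.7 min), advancing one
window per step. Both are parameters.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.signal import detrend
from scipy.signal.windows import hann
from sklearn.base import BaseEstimator, TransformerMixin

from .recording import IcpRecording

CARDIAC_BAND = (0.67, 3.0)  # 40-180 bpm

#: Degeneracy floors for the RAP correlation. AMP variation below 0.01 mmHg
#: across a span is measurement-level jitter, not a pulse-amplitude response
#: (below the breakpoint the true AMP is exactly flat), so such spans are
#: flagged rather than yielding a spurious near-null correlation draw.
_AMP_STD_FLOOR = 0.01
_MEAN_STD_FLOOR = 1e-6


def extract_amp(samples, fs, band=CARDIAC_BAND, method="spectral"):
    """Estimate the fundamental pulse amplitude of one pressure window.

    Returns ``(amp_mmhg, f_peak_hz, valid)``. The window is linearly
    detrended and Hann-tapered; the amplitude is recovered from the spectral
    energy in the main lobe around the in-band peak, and the peak frequency is
    refined by parabolic interpolation. The window is flagged invalid when the
    in-band peak does not stand out (less than 3x the median in-band level) or
    the samples are degenerate.

    ``method="peak_to_peak"`` instead returns half the peak-to-peak excursion
    of the detrended window (a time-domain alternative for sensitivity
    analysis; it includes respiratory/noise contributions).
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 64:
        raise ValueError("extract_amp needs at least 64 samples")
    if np.ptp(x) == 0 or not np.all(np.isfinite(x)):
        return 0.0, np.nan, False
    y = detrend(x, type="linear")
    if method == "peak_to_peak":
        return float(np.ptp(y) / 2.0), np.nan, True
    if method != "spectral":
        raise ValueError(f"unknown AMP method {method!r}")

    w = hann(n, sym=False)
    yw = y * w
    spec = np.fft.rfft(yw)
    mag = np.abs(spec)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(in_band):
        return 0.0, np.nan, False
    band_idx = np.flatnonzero(in_band)
    k = band_idx[np.argmax(mag[band_idx])]

    med = np.median(mag[band_idx])
    valid = med > 0 and mag[k] >= 3.0 * med

    # parabolic refinement of the peak frequency
    f_peak = freqs[k]
    if 0 < k < mag.size - 1 and mag[k - 1] > 0 and mag[k + 1] > 0:
        a, b, c = np.log(mag[k - 1 : k + 2])
        denom = a - 2 * b + c
        if denom < 0:
            f_peak = freqs[k] + 0.5 * (a - c) / denom * (fs / n)

    # main-lobe energy summation (Hann main lobe spans ~4 bins)
    lo, hi = max(k - 3, 1), min(k + 3, mag.size - 1)
    lobe_energy = np.sum(mag[lo : hi + 1] ** 2)
    amp = 2.0 * np.sqrt(lobe_energy / (n * np.sum(w**2)))
    return float(amp), float(f_peak), bool(valid)


def window_stats(rec: IcpRecording, window_s: float = 10.0, band=CARDIAC_BAND,
                 amp_method: str = "spectral") -> pd.DataFrame:
    """Reduce a recording to consecutive non-overlapping window statistics.

    Returns a DataFrame with columns ``t_start, t_end, mean_icp, amp, f_peak,
    valid``. Windows containing non-finite samples or with degenerate
    amplitude are flagged invalid (mean ICP is still reported).
    """
    n_per = int(round(window_s * rec.fs))
    if n_per < 64:
        raise ValueError("window_s * fs must be at least 64 samples")
    n_win = rec.t.size // n_per
    if n_win == 0:
        warnings.warn("recording shorter than one window; empty result")
        return pd.DataFrame(
            columns=["t_start", "t_end", "mean_icp", "amp", "f_peak", "valid"]
        )
    rows = []
    for i in range(n_win):
        seg = rec.p[i * n_per : (i + 1) * n_per]
        t0 = float(rec.t[i * n_per])
        finite = np.all(np.isfinite(seg))
        mean_icp = float(np.mean(seg)) if finite else np.nan
        if finite:
            amp, f_peak, valid = extract_amp(seg, rec.fs, band, amp_method)
        else:
            amp, f_peak, valid = 0.0, np.nan, False
        rows.append((t0, t0 + window_s, mean_icp, amp, f_peak, valid))
    return pd.DataFrame(
        rows, columns=["t_start", "t_end", "mean_icp", "amp", "f_peak", "valid"]
    )


def _pearson(x, y):
    """Direct-summation Pearson correlation (no intermediate library call)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm = x - x.mean()
    ym = y - y.mean()
    sx = np.sqrt(np.sum(xm * xm))
    sy = np.sqrt(np.sum(ym * ym))
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.sum(xm * ym) / (sx * sy))


def compute_rap(windows: pd.DataFrame, span_n: int = 40, min_valid_frac: float = 0.75
                ) -> pd.DataFrame:
    """Moving AMP-vs-mean-ICP correlation over the trailing ``span_n`` windows.

    One point is emitted per window position from the first full span onward,
    timestamped at the centre of the trailing window (causal, real-time
    convention). A point is valid only when at least ``min_valid_frac*span_n``
    of its windows are valid and both coordinates have non-zero variance;
    degenerate points carry ``rap=0`` with ``valid=False`` so the series stays
    time-aligned.

    Returns a DataFrame with columns ``t_mid, rap, valid, window_count``.
    """
    if span_n < 3:
        raise ValueError("span_n must be at least 3")
    n = len(windows)
    if n < span_n:
        warnings.warn("fewer windows than the RAP span; empty series")
        return pd.DataFrame(columns=["t_mid", "rap", "valid", "window_count"])
    mean_icp = windows["mean_icp"].to_numpy(float)
    amp = windows["amp"].to_numpy(float)
    ok = windows["valid"].to_numpy(bool)
    t_mid = (windows["t_start"].to_numpy(float) + windows["t_end"].to_numpy(float)) / 2.0

    need = int(np.ceil(min_valid_frac * span_n))
    rows = []
    for i in range(span_n - 1, n):
        sl = slice(i - span_n + 1, i + 1)
        m = ok[sl]
        count = int(m.sum())
        rap, valid = 0.0, False
        if count >= need:
            x = mean_icp[sl][m]
            y = amp[sl][m]
            if np.std(x) > _MEAN_STD_FLOOR and np.std(y) > _AMP_STD_FLOOR:
                r = _pearson(x, y)
                if np.isfinite(r):
                    rap, valid = r, True
        rows.append((t_mid[i], rap, valid, count))
    return pd.DataFrame(rows, columns=["t_mid", "rap", "valid", "window_count"])


class RapExtractor(BaseEstimator, TransformerMixin):
    """Transformer: :class:`IcpRecording` -> RAP series DataFrame.

    Parameters mirror the functional API (`window_s`, `span_n`, cardiac band,
    AMP estimator). ``fit`` is stateless and returns ``self``; ``transform``
    accepts a recording and returns the RAP series; the intermediate window
    table from the last transform is kept in ``windows_``.
    """

    def __init__(self, window_s: float = 10.0, span_n: int = 40,
                 band=CARDIAC_BAND, amp_method: str = "spectral",
                 min_valid_frac: float = 0.75):
        self.window_s = window_s
        self.span_n = span_n
        self.band = band
        self.amp_method = amp_method
        self.min_valid_frac = min_valid_frac

    def fit(self, X: IcpRecording | None = None, y=None):
        return self

    def transform(self, X: IcpRecording) -> pd.DataFrame:
        self.windows_ = window_stats(X, self.window_s, self.band, self.amp_method)
        return compute_rap(self.windows_, self.span_n, self.min_valid_frac)
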