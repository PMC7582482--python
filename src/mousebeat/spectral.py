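"""Short-term HRV: paired fragment selection, SDNN and spectral power.

Short-term analysis works on 2-min, arrhythmia-free windows matched on
mean RR between simultaneously recorded subjects. Time-domain HRV is
SDNN; frequency-domain HRV integrates a least-squares (Lomb-Scargle)
spectrum of the unevenly sampled tachogram over murine LF (0.15-1.5 Hz)
and HF (1.5-5 Hz) bands, with a resampled Welch periodogram available as
a cross-check. Spectral densities are scaled so the integral over the
resolvable range approximates the NN variance (ms^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import interpolate, signal

from .arrhythmia import ArrhythmiaEvent
from .ecg import RRSeries
from .hrv import sinus_nn_intervals

__all__ = [
    "LF_BAND_HZ",
    "HF_BAND_HZ",
    "PairedFragment",
    "SpectralSummary",
    "sdnn",
    "lomb_psd",
    "welch_psd",
    "band_powers",
    "select_paired_fragments",
    "analyze_nn_fragment",
]

#: murine frequency bands (Hz); ~10x above the human conventions
LF_BAND_HZ = (0.15, 1.5)
HF_BAND_HZ = (1.5, 5.0)


def sdnn(nn_ms: np.ndarray) -> float:
    """Sample standard deviation (ddof=1) of NN intervals, ms."""
    nn = np.asarray(nn_ms, dtype=float)
    if nn.size < 2:
        raise ValueError("SDNN requires at least 2 NN intervals")
    return float(np.std(nn, ddof=1))


def lomb_psd(
    t_ms: np.ndarray,
    nn_ms: np.ndarray,
    f_max_hz: float = HF_BAND_HZ[1],
    oversample: int = 8,
    min_span_s: float = 60.0,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided least-squares spectral density of an uneven tachogram.

    ``t_ms`` are the beat times the NN values are attached to. The raw
    Lomb-Scargle periodogram of the mean-subtracted series is scaled by
    2T/N so that a sinusoidal modulation of amplitude ``a`` ms
    integrates to a^2/2 ms^2 and broadband power approximates the NN
    variance (the rectangular-window equivalent-bandwidth argument).
    """
    t = np.asarray(t_ms, dtype=float) / 1000.0
    y = np.asarray(nn_ms, dtype=float)
    if t.size != y.size:
        raise ValueError("t_ms and nn_ms must align")
    span = t[-1] - t[0]
    if span < min_span_s:
        raise ValueError(f"fragment spans {span:.1f} s; need >= {min_span_s:.0f} s")
    y = y - y.mean()
    df = 1.0 / (oversample * span)
    f = np.arange(df, f_max_hz + df / 2, df)
    if np.allclose(y, 0):
        return f, np.zeros_like(f)
    p = signal.lombscargle(t, y, 2 * np.pi * f)
    dens = p * 2.0 * span / t.size
    return f, dens


def welch_psd(
    t_ms: np.ndarray,
    nn_ms: np.ndarray,
    resample_hz: float = 20.0,
    nperseg_s: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-check estimator: cubic resampling + averaged periodogram."""
    t = np.asarray(t_ms, dtype=float) / 1000.0
    y = np.asarray(nn_ms, dtype=float)
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    yi = interpolate.CubicSpline(t, y)(grid)
    yi = yi - yi.mean()
    nper = min(yi.size, int(nperseg_s * resample_hz))
    return signal.welch(yi, fs=resample_hz, nperseg=nper)


@dataclass
class SpectralSummary:
    sdnn_ms: float
    total_power_ms2: float
    lf_power_ms2: float
    hf_power_ms2: float
    lf_band_hz: tuple[float, float] = LF_BAND_HZ
    hf_band_hz: tuple[float, float] = HF_BAND_HZ


def band_powers(
    f_hz: np.ndarray,
    dens: np.ndarray,
    lf_band: tuple[float, float] = LF_BAND_HZ,
    hf_band: tuple[float, float] = HF_BAND_HZ,
) -> tuple[float, float, float]:
    """(total, lf, hf) trapezoidal band powers; total spans (0, hf_hi]."""
    f = np.asarray(f_hz)
    d = np.asarray(dens)
    if hf_band[1] > f[-1] + (f[1] - f[0]):
        raise ValueError(
            f"HF band edge {hf_band[1]} Hz beyond resolvable range {f[-1]:.3g} Hz"
        )
    def integ(lo: float, hi: float) -> float:
        m = (f >= lo) & (f <= hi)
        if m.sum() < 2:
            raise ValueError(
                f"band ({lo}, {hi}) Hz under-resolved at df={f[1] - f[0]:.2g} Hz"
            )
        return float(np.trapezoid(d[m], f[m]))
    total = integ(f[0], hf_band[1])
    return total, integ(*lf_band), integ(*hf_band)


def analyze_nn_fragment(series: RRSeries, estimator: str = "lomb") -> SpectralSummary:
    """SDNN + band powers for one arrhythmia-free fragment."""
    from .ecg import FLAG_SINUS

    good = series.beat_flags == FLAG_SINUS
    keep = good[:-1] & good[1:]
    nn = series.rr[keep]
    if nn.size < 2:
        raise ValueError("fragment has too few NN intervals")
    t = series.r_times[1:][keep]  # attach each interval to its closing beat
    if estimator == "lomb":
        f, d = lomb_psd(t, nn)
    elif estimator == "welch":
        f, d = welch_psd(t, nn)
    else:
        raise ValueError("estimator must be 'lomb' or 'welch'")
    total, lf, hf = band_powers(f, d)
    return SpectralSummary(sdnn(sinus_nn_intervals(series)), total, lf, hf)


@dataclass
class PairedFragment:
    index: int
    start_ms: float
    end_ms: float
    wt_mean_rr_ms: float
    mfs_mean_rr_ms: float

    @property
    def delta_rr_ms(self) -> float:
        return abs(self.wt_mean_rr_ms - self.mfs_mean_rr_ms)


def _window_rr(series: RRSeries, t0: float, t1: float) -> np.ndarray:
    """RR intervals whose both endpoint beats fall inside [t0, t1)."""
    r = series.r_times
    inside = (r >= t0) & (r < t1)
    keep = inside[:-1] & inside[1:]
    return series.rr[keep]


def select_paired_fragments(
    wt: RRSeries,
    mfs: RRSeries,
    wt_events: list[ArrhythmiaEvent],
    mfs_events: list[ArrhythmiaEvent],
    window_s: float = 120.0,
    delta_rr_tol_ms: float = 5.0,
    min_beats: int = 100,
) -> list[PairedFragment]:
    """Aligned, non-overlapping, event-free 120 s windows matched on mean RR.

    Windows advance in steps of ``window_s`` over the simultaneous
    recording span; a window qualifies when neither subject has a
    classified event intersecting it, both contain ``min_beats``
    intervals, and the mean-RR difference is within
    ``delta_rr_tol_ms``. Selection provenance (start time, both means)
    is recorded on every returned pair.
    """
    t0 = max(wt.r_times[0], mfs.r_times[0])
    t1 = min(wt.r_times[-1], mfs.r_times[-1])
    win_ms = window_s * 1000.0
    pairs: list[PairedFragment] = []
    spans = [
        [(e.t_start_ms, e.t_end_ms) for e in evs] for evs in (wt_events, mfs_events)
    ]
    k = 0
    start = t0
    while start + win_ms <= t1:
        end = start + win_ms
        busy = any(a < end and b > start for ab in spans for a, b in ab)
        if not busy:
            rr_w = _window_rr(wt, start, end)
            rr_m = _window_rr(mfs, start, end)
            if rr_w.size >= min_beats and rr_m.size >= min_beats:
                mw, mm = float(rr_w.mean()), float(rr_m.mean())
                if abs(mw - mm) <= delta_rr_tol_ms:
                    pairs.append(PairedFragment(k, start, end, mw, mm))
                    k += 1
        start += win_ms
    if not pairs:
        warnings.warn("no qualifying paired fragments found", stacklevel=2)
    return pairs
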