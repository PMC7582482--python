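"""Core ECG containers, fragmentation and beat detection.

Times follow two conventions used consistently across the package:
raw traces are indexed in seconds (sample rate ``fs`` in Hz), while
beat-level quantities (R-peak times, RR intervals, P-wave times) are in
milliseconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

__all__ = [
    "ECGTrace",
    "Fragment",
    "RRSeries",
    "PWaveMap",
    "fragment_trace",
    "detect_r_peaks",
    "detect_p_waves",
    "rr_intervals",
]

#: beat_flags codes
FLAG_SINUS = 0
FLAG_ARRHYTHMIC = 1
FLAG_UNCLASSIFIED = 2


@dataclass
class ECGTrace:
    """Uniformly sampled single-lead voltage series (mV)."""

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    genotype: str = ""  # "WT" or "MFS"
    start_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sample rate must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise ValueError("ECGTrace expects a 1-D voltage series")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("ECG samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times_s(self) -> np.ndarray:
        return self.start_s + np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class Fragment:
    """One analysis window of a parent trace (half-open, seconds)."""

    parent_id: str
    index: int
    start_s: float
    end_s: float
    partial: bool = False

    @property
    def length_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class RRSeries:
    """Ordered R-peak times (ms) with derived inter-beat intervals.

    ``rr[i] = r_times[i+1] - r_times[i]``; ``beat_flags`` holds one code
    per beat (0 sinus, 1 arrhythmic, 2 unclassified); ``p_times`` is an
    optional per-beat P-wave time (NaN where absent).
    """

    r_times: np.ndarray
    beat_flags: np.ndarray = None  # type: ignore[assignment]
    p_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r_times = np.asarray(self.r_times, dtype=float)
        if self.r_times.size and np.any(np.diff(self.r_times) <= 0):
            raise ValueError("r_times must be strictly increasing")
        if self.beat_flags is None:
            self.beat_flags = np.full(self.r_times.size, FLAG_UNCLASSIFIED, dtype=int)
        else:
            self.beat_flags = np.asarray(self.beat_flags, dtype=int)
            if self.beat_flags.size != self.r_times.size:
                raise ValueError("beat_flags must align with r_times")
        if self.p_times is not None:
            self.p_times = np.asarray(self.p_times, dtype=float)
            if self.p_times.size != self.r_times.size:
                raise ValueError("p_times must align with r_times")

    @property
    def rr(self) -> np.ndarray:
        return np.diff(self.r_times)

    @property
    def n_beats(self) -> int:
        return int(self.r_times.size)

    def copy(self) -> "RRSeries":
        return RRSeries(
            self.r_times.copy(),
            self.beat_flags.copy(),
            None if self.p_times is None else self.p_times.copy(),
        )


@dataclass
class PWaveMap:
    """Per-beat P-wave annotations plus unconducted (orphan) P waves.

    ``p_times``/``pr_ms`` align with the beats they were detected for
    (NaN = absent); ``orphan_times`` are P deflections found inside long
    RR pauses with no accompanying QRS, all in ms.
    """

    p_times: np.ndarray
    pr_ms: np.ndarray
    orphan_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def orphans_in(self, t0_ms: float, t1_ms: float) -> np.ndarray:
        m = (self.orphan_times > t0_ms) & (self.orphan_times < t1_ms)
        return self.orphan_times[m]


# ---------------------------------------------------------------------------
# fragmentation


def fragment_trace(trace: ECGTrace, fragment_s: float = 1200.0) -> list[Fragment]:
    """Tile a trace into half-open windows of ``fragment_s`` seconds.

    The default of 1200 s (20 min) matches 24 h telemetry practice:
    86400 s yields 72 full fragments. A trailing remainder is returned
    flagged ``partial`` and is excluded from per-fragment statistics by
    the summary layer. Fragment k spans [k*fragment_s, (k+1)*fragment_s).
    """
    if fragment_s <= 0:
        raise ValueError("fragment_s must be positive")
    dur = trace.duration_s
    if dur < fragment_s:
        warnings.warn(
            f"trace of {dur:.1f} s is shorter than one {fragment_s:.0f} s fragment",
            stacklevel=2,
        )
        return []
    n_full = int(dur // fragment_s)
    frags = [
        Fragment(trace.subject_id, k, trace.start_s + k * fragment_s,
                 trace.start_s + (k + 1) * fragment_s)
        for k in range(n_full)
    ]
    rem = dur - n_full * fragment_s
    if rem > 1.0 / trace.fs:
        frags.append(
            Fragment(trace.subject_id, n_full,
                     trace.start_s + n_full * fragment_s,
                     trace.start_s + dur, partial=True)
        )
    return frags


# ---------------------------------------------------------------------------
# beat detection


def detect_r_peaks(
    trace: ECGTrace,
    band_hz: tuple[float, float] = (10.0, 200.0),
    refractory_ms: float = 30.0,
    smooth_ms: float = 8.0,
    threshold_frac: float = 0.25,
    threshold_quantile: float = 0.99,
    block_s: float = 2.0,
) -> np.ndarray:
    """Detect R-peak times (ms) from a single-lead trace.

    Pipeline: zero-phase band-pass over ``band_hz``, squared-envelope
    smoothing over ``smooth_ms``, then an adaptive threshold set per
    ``block_s`` block at ``threshold_frac`` times the block's
    ``threshold_quantile`` envelope level. Candidate peaks closer than
    the refractory period (default 30 ms; murine rates stay well below
    the implied 2000 bpm ceiling) are suppressed, and each detection is
    refined to the local maximum of the raw signal.

    Returns an empty array (with a warning) on flat or contentless input.
    """
    fs = trace.fs
    if fs < 500:
        raise ValueError("R-peak detection requires fs >= 500 Hz")
    x = trace.samples
    if x.size < int(0.05 * fs) or np.ptp(x) == 0:
        warnings.warn("signal too short or flat: no beats detected", stacklevel=2)
        return np.empty(0)

    hi = min(band_hz[1], 0.45 * fs)
    sos = signal.butter(3, (band_hz[0], hi), btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, x)
    env = uniform_filter1d(filt**2, max(1, int(round(smooth_ms * fs / 1000.0))))
    if env.max() <= 0:
        warnings.warn("contentless signal: no beats detected", stacklevel=2)
        return np.empty(0)

    # blockwise adaptive threshold, linearly stretched back to sample grid
    nblk = max(1, int(np.ceil(x.size / (block_s * fs))))
    blocks = np.array_split(env, nblk)
    blk_thr = np.array([threshold_frac * np.quantile(b, threshold_quantile) for b in blocks])
    floor = threshold_frac * np.quantile(env, threshold_quantile) * 0.05
    blk_thr = np.maximum(blk_thr, floor)
    thr = np.repeat(blk_thr, [b.size for b in blocks])

    dist = max(1, int(round(refractory_ms * fs / 1000.0)))
    peaks, _ = signal.find_peaks(env, height=thr, distance=dist)
    if peaks.size == 0:
        warnings.warn("no envelope peaks above threshold", stacklevel=2)
        return np.empty(0)

    # refine to local raw-signal maximum (R is the dominant positive wave)
    half = int(round(0.008 * fs))
    refined = np.empty(peaks.size, dtype=int)
    for i, p in enumerate(peaks):
        a, b = max(0, p - half), min(x.size, p + half + 1)
        refined[i] = a + int(np.argmax(x[a:b]))
    refined = np.unique(refined)
    # drop refinements collapsed inside the refractory period
    keep = np.concatenate([[True], np.diff(refined) >= dist])
    refined = refined[keep]
    return trace.start_s * 1000.0 + refined * 1000.0 / fs


def detect_p_waves(
    trace: ECGTrace,
    r_times_ms: np.ndarray,
    window_ms: tuple[float, float] = (12.0, 45.0),
    p_sigma_ms: float = 3.4,
    baseline_sigma_ms: float = 10.0,
    floor_frac: float = 0.4,
    pause_factor: float = 1.6,
    t_guard_ms: float = 50.0,
    orphan_snr: float = 5.0,
) -> PWaveMap:
    """Locate P waves preceding each detected beat and inside long pauses.

    The trace is filtered with a difference of Gaussians matched to the
    P width (``p_sigma_ms`` minus ``baseline_sigma_ms``): an FIR
    band-pass with no ringing tails, so the large QRS-T complexes leave
    no slow recovery swings inside pauses.

    Conducted P: for every beat the most prominent *interior* local
    maximum ``window_ms`` before the R peak (interior, because the
    monotone QRS skirt cannot form one); present when its prominence
    exceeds ``floor_frac`` times the median over all beats — an adaptive
    floor, robust because sinus beats dominate any 24 h recording.

    Unconducted (orphan) P: pauses longer than ``pause_factor`` times
    the local rhythm are scanned between ``t_guard_ms`` after the left
    beat (clearing its T wave) and the right beat's own pre-R window; a
    peak counts when it rises ``orphan_snr`` noise standard deviations
    above the pause median. The noise scale is estimated once per trace
    from the median absolute first difference of the matched-filtered
    signal (robust: cardiac waves occupy a small sample fraction), with
    the difference-to-level variance ratio of the Gaussian kernel
    dividing it back to a level scale.
    """
    fs = trace.fs
    r = np.asarray(r_times_ms, dtype=float)
    if r.size < 2:
        return PWaveMap(np.full(r.size, np.nan), np.full(r.size, np.nan))

    x = trace.samples
    ym = gaussian_filter1d(x, p_sigma_ms * fs / 1000.0)  # matched smoothing
    y = ym - gaussian_filter1d(x, baseline_sigma_ms * fs / 1000.0)

    def idx(t_ms: float) -> int:
        return int(round((t_ms / 1000.0 - trace.start_s) * fs))

    def best_peak(a: int, b: int) -> tuple[int, float] | None:
        """Most prominent interior local maximum of y[a:b], or None."""
        a, b = max(0, a), min(y.size, b)
        if b - a < 5:
            return None
        pk, props = signal.find_peaks(y[a:b], prominence=0)
        if pk.size == 0:
            return None
        i = int(np.argmax(props["prominences"]))
        return a + pk[i], float(props["prominences"][i])

    amps = np.full(r.size, np.nan)
    times = np.full(r.size, np.nan)
    for i, rt in enumerate(r):
        hit = best_peak(idx(rt - window_ms[1]), idx(rt - window_ms[0]))
        if hit is not None:
            j, amp = hit
            amps[i] = amp
            times[i] = trace.start_s * 1000.0 + j * 1000.0 / fs

    med = np.nanmedian(amps)
    if not np.isfinite(med) or med <= 0:
        return PWaveMap(np.full(r.size, np.nan), np.full(r.size, np.nan))
    floor = floor_frac * med
    present = amps >= floor
    p_times = np.where(present, times, np.nan)
    pr = r - p_times

    # scan long pauses for unconducted P waves on the matched-filtered
    # signal: pauses hold no QRS/T, so the plain matched filter keeps the
    # full P amplitude. One noise scale, pooled over all pause interiors
    # (their samples are overwhelmingly baseline), serves every pause —
    # a single short pause holding a T tail plus a P bump cannot estimate
    # its own floor.
    rr = np.diff(r)
    med_rr = np.median(rr)
    windows: list[tuple[int, int]] = []
    for i in np.nonzero(rr > pause_factor * med_rr)[0]:
        a, b = max(0, idx(r[i] + t_guard_ms)), min(ym.size, idx(r[i + 1] - window_ms[1]))
        if b - a >= 10:
            windows.append((a, b))
    orphans: list[float] = []
    if windows:
        pooled = np.concatenate([ym[a:b] for a, b in windows])
        s_k = p_sigma_ms * fs / 1000.0  # kernel sigma in samples
        diff_ratio = np.sqrt(2.0 * (1.0 - np.exp(-1.0 / (4.0 * s_k**2))))
        sigma = 1.4826 * np.median(np.abs(np.diff(pooled))) / diff_ratio
        for a, b in windows:
            seg = ym[a:b]
            base = np.median(seg)
            pk, _ = signal.find_peaks(seg)
            if pk.size == 0:
                continue
            j = pk[int(np.argmax(seg[pk]))]
            if sigma > 0 and (seg[j] - base) >= orphan_snr * sigma:
                orphans.append(trace.start_s * 1000.0 + (a + j) * 1000.0 / fs)
    return PWaveMap(p_times, pr, np.asarray(orphans, dtype=float))


def rr_intervals(r_times_ms: np.ndarray) -> RRSeries:
    """Build an RRSeries (flags initialised to unclassified) from peak times."""
    r = np.asarray(r_times_ms, dtype=float)
    if r.size < 2:
        return RRSeries(np.empty(0))
    if np.any(np.diff(r) <= 0):
        raise ValueError("r_times must be strictly increasing")
    return RRSeries(r)
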