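"""Ground-truthed synthetic inputs: murine ECG and myocardial-wall images.

The generators here define the study conditions every downstream stage is
validated against. Defaults emulate resting mouse sinus rhythm (mean RR
~100 ms, i.e. 600 bpm) with autonomic modulation in the murine LF
(0.15-1.5 Hz) and HF (1.5-5 Hz) bands, six classes of injected
arrhythmic events, a template-rendered single-lead waveform at 2 kHz,
and HE-stain-like mid-ventricular cross-sections with a controllable
free-space fraction between trabecular lamellae.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ecg import FLAG_ARRHYTHMIC, FLAG_SINUS, ECGTrace, RRSeries

__all__ = [
    "RRSpec",
    "EventSpec",
    "BeatTruth",
    "InjectedEvent",
    "WallImageSpec",
    "WallImage",
    "EVENT_TYPES",
    "generate_rr_series",
    "inject_events",
    "synthesize_ecg",
    "generate_wall_image",
]

EVENT_TYPES = (
    "extrasystole_single",
    "extrasystole_doublet",
    "extrasystole_run",
    "sinus_arrest",
    "blocked_p",
    "av_block",
)

LABEL_SINUS = "sinus"
LABEL_ECTOPIC = "ectopic"
LABEL_DROPPED = "dropped_qrs"

#: default P-R interval (ms) used for synthetic P-wave placement
PR_BASE_MS = 20.0
#: P-R escalation applied to the three beats preceding an AV-block pause
AV_PR_FACTORS = (1.25, 1.5, 1.8)


# ---------------------------------------------------------------------------
# RR-interval generation


@dataclass(frozen=True)
class RRSpec:
    """Beat-interval model: Gaussian jitter plus LF/HF sinusoidal modulation.

    ``lf_mod``/``hf_mod`` are (frequency Hz, amplitude ms) pairs sampled
    at the running beat times, mimicking sympathetic and respiratory
    modulation of the sinus node.
    """

    mean_rr_ms: float = 100.0
    sd_rr_ms: float = 2.0
    lf_mod: tuple[float, float] = (0.0, 0.0)
    hf_mod: tuple[float, float] = (0.0, 0.0)
    duration_s: float = 600.0
    seed: int = 0

    def validate(self) -> None:
        if self.mean_rr_ms <= 0:
            raise ValueError("mean_rr_ms must be positive")
        if self.sd_rr_ms < 0 or self.lf_mod[1] < 0 or self.hf_mod[1] < 0:
            raise ValueError("sd_rr_ms and modulation amplitudes must be >= 0")
        nyq = 1000.0 / (2.0 * self.mean_rr_ms)  # beat-rate Nyquist, Hz
        for name, (f, a) in (("lf_mod", self.lf_mod), ("hf_mod", self.hf_mod)):
            if a > 0 and not (0 < f < nyq):
                raise ValueError(
                    f"{name} frequency {f} Hz outside (0, {nyq:.3g}) Hz beat Nyquist"
                )
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


def generate_rr_series(spec: RRSpec, max_resample: int = 100) -> RRSeries:
    """Generate sinus beat times until cumulative time covers the duration.

    Each interval is ``mean + N(0, sd) + lf + hf`` evaluated at the
    current beat time; non-positive draws are resampled (bounded by
    ``max_resample`` attempts, after which the spec is declared
    infeasible). Identical specs produce identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    f_lf, a_lf = spec.lf_mod
    f_hf, a_hf = spec.hf_mod
    t_ms = 0.0
    times = [0.0]
    dur_ms = spec.duration_s * 1000.0
    while t_ms < dur_ms:
        det = (
            spec.mean_rr_ms
            + a_lf * np.sin(2 * np.pi * f_lf * t_ms / 1000.0)
            + a_hf * np.sin(2 * np.pi * f_hf * t_ms / 1000.0)
        )
        rr = det + rng.normal(0.0, spec.sd_rr_ms) if spec.sd_rr_ms > 0 else det
        tries = 0
        while rr <= 0:
            tries += 1
            if tries > max_resample:
                raise ValueError(
                    "infeasible RRSpec: interval positivity failed after "
                    f"{max_resample} resampling attempts (mean {det:.3g} ms, "
                    f"sd {spec.sd_rr_ms:.3g} ms)"
                )
            rr = det + rng.normal(0.0, spec.sd_rr_ms)
        t_ms += rr
        times.append(t_ms)
    r = np.asarray(times)
    return RRSeries(r, beat_flags=np.full(r.size, FLAG_SINUS, dtype=int))


# ---------------------------------------------------------------------------
# event injection


@dataclass(frozen=True)
class EventSpec:
    """How many events of one type to inject and with which parameters.

    ``prematurity`` is the ectopic coupling interval as a fraction of the
    local cycle (0, 1); ``pause_multiple`` scales the sinus-arrest pause
    (> 1, and kept away from integer multiples of the cycle so the pause
    is distinguishable from blocked conduction); ``run_length`` is the
    number of consecutive ectopics in an ``extrasystole_run``.
    """

    event_type: str
    count: int
    prematurity: float = 0.6
    pause_multiple: float = 2.5
    run_length: int = 3

    def validate(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event_type {self.event_type!r}")
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if not 0 < self.prematurity < 1:
            raise ValueError("prematurity must lie in (0, 1)")
        if self.pause_multiple <= 1:
            raise ValueError("pause_multiple must exceed 1")
        if self.event_type == "extrasystole_run" and self.run_length < 3:
            raise ValueError("run_length must be >= 3")


@dataclass(frozen=True)
class InjectedEvent:
    event_type: str
    beat_start: int  # first affected beat (truth indexing)
    beat_end: int  # last affected beat, inclusive
    t_start_ms: float
    t_end_ms: float


@dataclass
class BeatTruth:
    """Ground truth for every beat, including non-conducted ones.

    ``beat_times`` lists all atrial/ventricular cycles; beats labelled
    ``dropped_qrs`` have a P wave but no QRS and therefore do not appear
    in the companion RRSeries. ``p_times`` is NaN where no P exists
    (ectopic ventricular beats, arrest gaps).
    """

    beat_times: np.ndarray
    beat_labels: list[str]
    p_times: np.ndarray
    event_log: list[InjectedEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.p_times = np.asarray(self.p_times, dtype=float)
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        if len(self.beat_labels) != self.beat_times.size:
            raise ValueError("beat_labels must align with beat_times")
        for ev in self.event_log:
            if not (0 <= ev.beat_start <= ev.beat_end < self.beat_times.size):
                raise ValueError(f"event {ev} maps outside beat range")

    def conducted_mask(self) -> np.ndarray:
        return np.array([lab != LABEL_DROPPED for lab in self.beat_labels])

    def r_times(self) -> np.ndarray:
        return self.beat_times[self.conducted_mask()]


def _events_per_type(specs: list[EventSpec]) -> list[tuple[EventSpec, int]]:
    out = []
    for s in specs:
        s.validate()
        out.extend((s, i) for i in range(s.count))
    return out


def inject_events(
    rr: RRSeries,
    specs: list[EventSpec],
    seed: int = 0,
    margin_beats: int = 12,
    positions: dict[int, list[int]] | None = None,
) -> tuple[RRSeries, BeatTruth]:
    """Inject arrhythmic events into an all-sinus series.

    Event morphologies, all expressed through the local cycle length
    ``b`` (the interval at the host position):

    * extrasystole (single/doublet/run of k): k premature beats at
      coupling ``prematurity*b`` followed by a compensatory pause such
      that the local cycle sum is preserved exactly
      (``k`` premature + pause = ``(k+1)*b``);
    * sinus_arrest: one interval stretched to ``pause_multiple*b`` with
      no P wave in the gap;
    * blocked_p: one QRS dropped with its P wave retained on time
      (RR seen ~ 2b);
    * av_block: blocked_p preceded by progressive P-R prolongation over
      the three preceding conducted beats.

    Host positions are drawn without replacement, each event reserving
    ``margin_beats`` beats on both sides; explicitly ``positions``-pinned
    or random placements that would overlap are rejected with a
    diagnostic. Returns the conducted-beat RRSeries plus the full truth.
    """
    if np.any(rr.beat_flags != FLAG_SINUS):
        raise ValueError("inject_events requires an all-sinus base series")
    rng = np.random.default_rng(seed)

    times = rr.r_times.copy()
    n = times.size
    labels = [LABEL_SINUS] * n
    pr = np.full(n, PR_BASE_MS)
    has_p = np.ones(n, dtype=bool)

    jobs = _events_per_type(specs)
    if not jobs:
        truth = BeatTruth(times, labels, times - pr, [])
        return rr.copy(), truth

    # choose host beat indices without overlap
    lo, hi = margin_beats + 4, n - margin_beats - 6
    if hi - lo < len(jobs):
        raise ValueError(
            f"too few host beats: {n} beats cannot accommodate {len(jobs)} events"
        )
    occupied = np.zeros(n, dtype=bool)

    def reserve(j: int, span: int) -> None:
        a, b = j - margin_beats, j + span + margin_beats
        if a < 1 or b >= n - 1:
            raise ValueError(f"event at beat {j} falls outside usable range")
        if occupied[a:b].any():
            raise ValueError(
                f"overlapping injection at beat {j}: slot [{a}, {b}) already reserved"
            )
        occupied[a:b] = True

    placements: list[tuple[EventSpec, int]] = []
    pinned = positions or {}
    for k, (s, _) in enumerate(jobs):
        span = {"extrasystole_single": 2, "extrasystole_doublet": 3,
                "extrasystole_run": s.run_length + 1}.get(s.event_type, 2)
        if k in pinned:
            j = pinned[k][0] if isinstance(pinned[k], list) else pinned[k]
            reserve(j, span)
        else:
            for _try in range(2000):
                j = int(rng.integers(lo, hi))
                try:
                    reserve(j, span)
                    break
                except ValueError:
                    continue
            else:
                raise ValueError("could not place all events without overlap; "
                                 "use a longer base series or fewer events")
        placements.append((s, j))
    placements.sort(key=lambda p: p[1])

    log: list[InjectedEvent] = []
    for s, j in placements:
        b = times[j + 1] - times[j]
        et = s.event_type
        if et in ("extrasystole_single", "extrasystole_doublet", "extrasystole_run"):
            k = {"extrasystole_single": 1, "extrasystole_doublet": 2}.get(et, s.run_length)
            # replace sinus beats j+1..j+k with k premature beats; the beat
            # after the compensatory pause lands at exactly t_j + (k+1)*b
            new_t = times[j] + s.prematurity * b * np.arange(1, k + 1)
            shift = (times[j] + (k + 1) * b) - times[j + k + 1]
            times[j + k + 1:] += shift
            times[j + 1:j + k + 1] = new_t
            for m in range(j + 1, j + k + 1):
                labels[m] = LABEL_ECTOPIC
                has_p[m] = False
            log.append(InjectedEvent(et, j + 1, j + k, times[j + 1], times[j + k + 1]))
        elif et == "sinus_arrest":
            shift = (s.pause_multiple - 1.0) * b
            times[j + 1:] += shift
            log.append(InjectedEvent(et, j, j + 1, times[j], times[j + 1]))
        elif et in ("blocked_p", "av_block"):
            labels[j + 1] = LABEL_DROPPED
            if et == "av_block":
                # escalate over the three conducted beats preceding the
                # dropped QRS; the non-conducted P itself stays on time
                for off, fac in zip((-3, -2, -1), AV_PR_FACTORS):
                    pr[j + 1 + off] = PR_BASE_MS * fac
            log.append(InjectedEvent(et, j + 1, j + 1, times[j], times[j + 2]))

    p_times = np.where(has_p, times - pr, np.nan)
    truth = BeatTruth(times, labels, p_times, log)

    cond = truth.conducted_mask()
    flags = np.full(n, FLAG_SINUS, dtype=int)
    for ev in log:
        a = max(0, ev.beat_start)
        bnd = min(n - 1, ev.beat_end)
        flags[a:bnd + 1] = FLAG_ARRHYTHMIC
    out = RRSeries(times[cond], beat_flags=flags[cond], p_times=p_times[cond])
    return out, truth


# ---------------------------------------------------------------------------
# waveform synthesis


def _add_gaussian(x: np.ndarray, fs: float, t_ms: float, amp: float, sigma_ms: float) -> None:
    c = t_ms / 1000.0 * fs
    s = sigma_ms / 1000.0 * fs
    a, b = int(max(0, np.floor(c - 4 * s))), int(min(x.size, np.ceil(c + 4 * s) + 1))
    if b <= a:
        return
    i = np.arange(a, b)
    x[i] += amp * np.exp(-0.5 * ((i - c) / s) ** 2)


def synthesize_ecg(
    truth: BeatTruth,
    fs: float = 2000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    duration_s: float | None = None,
    r_amp: float = 1.0,
    p_amp: float = 0.12,
    t_amp: float = 0.2,
    p_width_ms: float = 8.0,
    qrs_width_ms: float = 10.0,
    t_width_ms: float = 25.0,
    qt_offset_ms: float = 30.0,
    subject_id: str = "",
    genotype: str = "",
) -> ECGTrace:
    """Render each beat as P/QRS/T Gaussian templates plus white noise.

    ``dropped_qrs`` beats render their P wave only. Template widths are
    murine defaults (P 8 ms, QRS 10 ms, T 25 ms full width); a sample
    rate below 1 kHz cannot resolve the ~10 ms QRS and is rejected.
    """
    if fs < 1000:
        raise ValueError("fs must be >= 1000 Hz to resolve a ~10 ms murine QRS")
    t_last = truth.beat_times[-1] / 1000.0
    dur = duration_s if duration_s is not None else t_last + 0.15
    n = int(round(dur * fs))
    if t_last > dur:
        raise ValueError("duration_s shorter than the last beat time")
    x = np.zeros(n)
    # full widths -> gaussian sigma (FWHM / 2.355)
    s_p, s_q, s_t = (w / 2.355 for w in (p_width_ms, qrs_width_ms, t_width_ms))
    for t, lab, pt in zip(truth.beat_times, truth.beat_labels, truth.p_times):
        if np.isfinite(pt):
            _add_gaussian(x, fs, pt, p_amp, s_p)
        if lab != LABEL_DROPPED:
            _add_gaussian(x, fs, t, r_amp, s_q)
            _add_gaussian(x, fs, t + qt_offset_ms, t_amp, s_t)
    if noise_sd > 0:
        x += np.random.default_rng(seed).normal(0.0, noise_sd, n)
    return ECGTrace(x, fs, subject_id=subject_id, genotype=genotype)


# ---------------------------------------------------------------------------
# myocardial-wall images


@dataclass(frozen=True)
class WallImageSpec:
    """Geometry and rendering of a synthetic mid-ventricular cross-section.

    A compact annular wall (``inner_radius``..``outer_radius``) carries
    ``finger_count`` radial trabecular fingers extending ``finger_len``
    pixels toward the lumen; the gaps between fingers are the
    inter-lamellar free space. ``target_fraction`` is the requested
    free-space fraction of the wall ROI; finger angular width is solved
    from it, and the generator reports the fraction actually achieved by
    pixel count.
    """

    size: int = 512
    outer_radius: int = 215
    inner_radius: int = 174
    finger_count: int = 24
    finger_len: int = 82
    target_fraction: float = 0.2
    tissue_rgb: tuple[int, int, int] = (190, 90, 140)
    background_rgb: tuple[int, int, int] = (245, 243, 248)
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.inner_radius < self.outer_radius < self.size // 2:
            raise ValueError("require 0 < inner_radius < outer_radius < size/2")
        if self.finger_count and not 0 < self.finger_len < self.inner_radius:
            raise ValueError("finger_len must lie in (0, inner_radius)")
        if not 0 <= self.target_fraction < 1:
            raise ValueError("target_fraction must lie in [0, 1)")


@dataclass
class WallImage:
    image: np.ndarray  # uint8 RGB
    tissue_mask: np.ndarray  # bool, truth foreground
    roi_mask: np.ndarray  # bool, truth wall ROI
    achieved_fraction: float


def generate_wall_image(spec: WallImageSpec) -> WallImage:
    """Render the section and report the achieved free-space fraction.

    The truth ROI is the annulus from the outer wall down to the finger
    tips (or just the compact wall when ``finger_count`` is 0, i.e. a
    fully compact solid annulus). The achieved fraction is computed by
    exact pixel count of background inside the ROI. A target fraction
    outside what the geometry can reach raises with the feasible range.
    """
    spec.validate()
    s = spec.size
    yy, xx = np.indices((s, s))
    c = (s - 1) / 2.0
    r = np.hypot(yy - c, xx - c)
    theta = np.arctan2(yy - c, xx - c)  # [-pi, pi]

    wall = (r <= spec.outer_radius) & (r >= spec.inner_radius)
    if spec.finger_count == 0:
        tissue = wall
        roi = wall.copy()
        if spec.target_fraction > 0:
            raise ValueError(
                "target fraction unreachable with 0 fingers: achievable range is [0, 0]"
            )
    else:
        r_tip = spec.inner_radius - spec.finger_len
        band = (r < spec.inner_radius) & (r >= r_tip)
        roi = (r <= spec.outer_radius) & (r >= r_tip)
        # solve finger angular fill from the target fraction
        band_px = int(band.sum())
        roi_px = int(roi.sum())
        f_max = band_px / roi_px
        if not 0 <= spec.target_fraction <= f_max:
            raise ValueError(
                f"target fraction {spec.target_fraction:.3f} unreachable: "
                f"achievable range is [0, {f_max:.3f}] for this geometry"
            )
        free_band_frac = spec.target_fraction * roi_px / band_px
        fill = 1.0 - free_band_frac  # angular fraction occupied by fingers
        half_w = np.pi * fill / spec.finger_count  # half-width per finger
        phase = np.mod(theta, 2 * np.pi / spec.finger_count)
        on_finger = np.minimum(phase, 2 * np.pi / spec.finger_count - phase) <= half_w
        tissue = wall | (band & on_finger)

    free = roi & ~tissue
    achieved = free.sum() / roi.sum()

    img = np.empty((s, s, 3), dtype=float)
    img[...] = np.asarray(spec.background_rgb, dtype=float)
    img[tissue] = np.asarray(spec.tissue_rgb, dtype=float)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img += rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return WallImage(img, tissue, roi, float(achieved))
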