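"""Arrhythmic-event detection, classification and tabulation.

Candidate beats are flagged from deviating RR intervals relative to a
local median; runs of candidates are merged and classified into six
categories (single/doublet/run extrasystoles, sinus arrest, blocked
P wave, AV block) by explicit RR/P-wave rules. Every event carries a
rule trace and a review flag so that the semi-automatic audit step of
telemetry practice remains possible. Counts tabulate per subject and
genotype with relative percentages of the per-genotype totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ecg import FLAG_ARRHYTHMIC, FLAG_SINUS, PWaveMap, RRSeries
from .simulate import EVENT_TYPES

__all__ = [
    "ArrhythmiaEvent",
    "EventTable",
    "flag_deviant_rr",
    "classify_events",
    "apply_event_flags",
    "tabulate_events",
]


@dataclass
class ArrhythmiaEvent:
    event_type: str  # one of EVENT_TYPES or "unclassified"
    beat_start: int
    beat_end: int  # inclusive
    t_start_ms: float
    t_end_ms: float
    review_flag: bool = False
    rule_trace: list[str] = field(default_factory=list)


def flag_deviant_rr(
    rr_ms: np.ndarray,
    window: int = 9,
    short_frac: float = 0.80,
    long_frac: float = 1.50,
) -> np.ndarray:
    """Indices of RR intervals deviating from their local median.

    The local median spans ``window`` neighbouring intervals and excludes
    the interval under test, so a single extreme value cannot mask
    itself. Interval i is a candidate when
    ``rr[i] < short_frac * median`` or ``rr[i] > long_frac * median``.
    Series no longer than the window yield no candidates.
    """
    rr = np.asarray(rr_ms, dtype=float)
    n = rr.size
    if n <= window:
        return np.empty(0, dtype=int)
    k = window + 1  # window of k values centred on i, self removed below
    half = k // 2
    padded = np.pad(rr, (half, k - half - 1), mode="edge")
    win = np.lib.stride_tricks.sliding_window_view(padded, k)  # (n, k)
    win = np.delete(win, half, axis=1)  # exclude self
    med = np.median(win, axis=1)
    cand = (rr < short_frac * med) | (rr > long_frac * med)
    return np.nonzero(cand)[0]


def _local_base(rr: np.ndarray, a: int, b: int, window: int = 9) -> float:
    """Median of sinus-looking intervals flanking segment [a, b]."""
    left = rr[max(0, a - window):a]
    right = rr[b + 1:b + 1 + window]
    pool = np.concatenate([left, right])
    if pool.size == 0:
        return float(np.median(rr))
    return float(np.median(pool))


def classify_events(
    series: RRSeries,
    candidates: np.ndarray,
    p_waves: PWaveMap | None = None,
    short_frac: float = 0.80,
    long_frac: float = 1.50,
    pause_tol: float = 0.15,
    pr_prolong_frac: float = 1.3,
    pr_elev_frac: float = 1.15,
    pr_elev_min: int = 2,
    pr_slack_ms: float = 3.0,
    merge_gap: int = 1,
) -> list[ArrhythmiaEvent]:
    """Type each merged candidate segment by explicit RR/P rules.

    Decision order per segment (local base cycle ``b`` = median of
    flanking intervals):

    1. leading premature interval(s) (< ``short_frac * b``) followed by a
       compensatory pause: extrasystole, typed single/doublet/run by the
       number of consecutive premature beats;
    2. a lone long interval L with an unconducted P wave inside and
       L within ``pause_tol`` of 2b: blocked P wave;
    3. rule 2 preceded by progressive P-R prolongation over the three
       preceding conducted beats: AV block;
    4. a lone long interval with no P in the pause and L farther than
       ``pause_tol * b`` from every integer multiple of b: sinus arrest;
    5. anything else: unclassified, review-flagged.

    Without P-wave information rules 2-4 degrade to a review-flagged
    best guess based on RR arithmetic alone (never silently).
    """
    rr = series.rr
    r = series.r_times
    events: list[ArrhythmiaEvent] = []
    cand = np.sort(np.asarray(candidates, dtype=int))
    if cand.size == 0:
        return events

    # merge candidates separated by at most merge_gap intervening beats
    segments: list[tuple[int, int]] = []
    a = b = int(cand[0])
    for i in cand[1:]:
        if i - b <= merge_gap + 1:
            b = int(i)
        else:
            segments.append((a, b))
            a = b = int(i)
    segments.append((a, b))

    for a, b in segments:
        base = _local_base(rr, a, b)
        trace = [f"segment=[{a},{b}]", f"base={base:.1f}ms"]
        seg = rr[a:b + 1]
        is_short = seg < short_frac * base

        if is_short[0]:
            k = 1
            while k < seg.size and is_short[k]:
                k += 1
            trace.append(f"premature_run={k}")
            comp_idx = a + k
            if comp_idx < rr.size and rr[comp_idx] > base:
                trace.append(f"compensatory={rr[comp_idx]:.1f}ms")
            et = ("extrasystole_single" if k == 1
                  else "extrasystole_doublet" if k == 2
                  else "extrasystole_run")
            end_beat = min(comp_idx + 1, r.size - 1)
            events.append(ArrhythmiaEvent(et, a, end_beat, r[a], r[end_beat],
                                          review_flag=False, rule_trace=trace))
            continue

        long_idx = [a + i for i, v in enumerate(seg) if v > long_frac * base]
        if len(long_idx) >= 1:
            i0 = long_idx[0]
            pause = rr[i0]
            trace.append(f"pause={pause:.1f}ms")
            # tolerances are +/- pause_tol of ONE base cycle: a pause of
            # 2.3b must read as "not an integer multiple" rather than as
            # a borderline doubled cycle
            near_double = abs(pause - 2 * base) <= pause_tol * base
            k_near = round(pause / base)
            near_integer = abs(pause - k_near * base) <= pause_tol * base and k_near >= 2

            if p_waves is None:
                et = "blocked_p" if near_double else "sinus_arrest"
                trace.append("no_p_info:best_guess")
                events.append(ArrhythmiaEvent(et, i0, i0 + 1, r[i0], r[i0 + 1],
                                              review_flag=True, rule_trace=trace))
                continue

            orphans = p_waves.orphans_in(r[i0], r[i0 + 1])
            if orphans.size and near_double:
                trace.append(f"p_in_pause@{orphans[0]:.0f}ms")
                et = "blocked_p"
                # AV block: progressive P-R prolongation on preceding beats
                prs = p_waves.pr_ms[max(0, i0 - 2):i0 + 1]
                prs = prs[np.isfinite(prs)]
                ref = np.nanmedian(p_waves.pr_ms)
                # a single outlying PR must not fake a Wenckebach ramp:
                # demand >= pr_elev_min of the preceding PRs elevated
                if (prs.size >= 2
                        and np.all(np.diff(prs) >= -pr_slack_ms)
                        and np.isfinite(ref)
                        and prs[-1] >= pr_prolong_frac * ref
                        and int((prs >= pr_elev_frac * ref).sum()) >= pr_elev_min):
                    trace.append(
                        f"pr_prolongation={np.array2string(prs, precision=0)}"
                    )
                    et = "av_block"
                events.append(ArrhythmiaEvent(et, i0, i0 + 1, r[i0], r[i0 + 1],
                                              review_flag=False, rule_trace=trace))
                continue
            if orphans.size == 0 and not near_integer:
                trace.append("no_p_in_pause")
                events.append(ArrhythmiaEvent("sinus_arrest", i0, i0 + 1,
                                              r[i0], r[i0 + 1],
                                              review_flag=False, rule_trace=trace))
                continue
            trace.append("ambiguous_pause")
            events.append(ArrhythmiaEvent("unclassified", i0, i0 + 1, r[i0],
                                          r[i0 + 1], review_flag=True,
                                          rule_trace=trace))
            continue

        trace.append("no_rule_matched")
        end_beat = min(b + 1, r.size - 1)
        events.append(ArrhythmiaEvent("unclassified", a, end_beat, r[a],
                                      r[end_beat], review_flag=True,
                                      rule_trace=trace))
    return events


def apply_event_flags(series: RRSeries, events: list[ArrhythmiaEvent]) -> RRSeries:
    """Return a copy with beats inside events flagged arrhythmic, others sinus."""
    out = series.copy()
    out.beat_flags[:] = FLAG_SINUS
    for ev in events:
        out.beat_flags[ev.beat_start:ev.beat_end + 1] = FLAG_ARRHYTHMIC
    return out


@dataclass
class EventTable:
    """Per-subject counts, per-genotype totals and relative percentages."""

    counts: pd.DataFrame  # index: subject, columns: EVENT_TYPES + Total
    genotype_totals: pd.DataFrame  # index: genotype
    percentages: pd.DataFrame  # index: genotype, % of genotype total (1 decimal)


def tabulate_events(
    events_by_subject: dict[str, "list[ArrhythmiaEvent] | dict[str, int]"],
    genotypes: dict[str, str],
) -> EventTable:
    """Tabulate classified events into the per-genotype summary table.

    Accepts either classified event lists or precomputed per-type count
    dicts per subject. Relative percentages are each type's share of the
    genotype total, rounded to one decimal; a genotype with zero events
    gets "-" placeholders (returned as NaN in the percentage frame).
    """
    rows = {}
    for subj, ev in events_by_subject.items():
        if isinstance(ev, dict):
            counts = {t: int(ev.get(t, 0)) for t in EVENT_TYPES}
        else:
            counts = {t: 0 for t in EVENT_TYPES}
            for e in ev:
                if e.event_type in counts:
                    counts[e.event_type] += 1
        rows[subj] = counts
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=list(EVENT_TYPES))
    df["Total"] = df.sum(axis=1)
    df.index.name = "subject"

    geno = pd.Series({s: genotypes[s] for s in df.index}, name="genotype")
    totals = df.groupby(geno).sum()
    totals.index.name = "genotype"

    pct = totals[list(EVENT_TYPES)].div(totals["Total"], axis=0) * 100.0
    pct = pct.round(1)
    pct[totals["Total"] == 0] = np.nan
    return EventTable(df, totals, pct)
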