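# mousebeat

Computational phenotyping of cardiac rhythm and myocardial structure in
mouse models of Marfan syndrome (fibrillin-1 deficiency) and similar
cardiomyopathy studies. The package covers the full desk side of a
murine telemetry + histology experiment:

- **Synthetic data with ground truth** — murine sinus rhythm (mean RR
  ≈ 100 ms) with LF/HF autonomic modulation, six classes of injected
  arrhythmic events (single/doublet/run extrasystoles, sinus arrest,
  blocked P wave, AV block), template-rendered single-lead ECG at
  2 kHz, and HE-like mid-ventricular section images with a controllable
  inter-lamellar free-space fraction.
- **ECG core** — CSV / WFDB-style I/O, 20-min fragmentation, automatic
  R-peak and P-wave detection with per-beat confidence and review flags.
- **Long-term HRV** — heart-rate variability as the full width at half
  maximum (FWHM) of the sinus RR-interval histogram, per fragment and
  per subject.
- **Arrhythmia screening** — deviant-RR candidates, rule-based
  six-class typing with an audit trace on every event, and the
  per-genotype count/percentage table.
- **Short-term HRV** — paired, event-free 2-min fragments matched on
  mean RR; SDNN and Lomb–Scargle spectral power in murine LF
  (0.15–1.5 Hz) and HF (1.5–5 Hz) bands.
- **Non-compaction index** — free-space fraction inside the
  ventricular-wall ROI of a histology section, measured in triplicate
  and normalised to the wild-type mean within each staining batch.
- **Statistics** — Shapiro–Wilk-gated t / Mann–Whitney comparisons
  with *exact* enumeration at telemetry-scale group sizes (n = 4),
  Pearson chi-square on event-type frequencies, mean ± SE reporting.

## The statistics at the core

Long-term HRV is the width of the RR distribution at half its modal
height: for a histogram with counts c and bin centers x,
`FWHM = x_right − x_left` where the crossings of `max(c)/2` are found
by linear interpolation between adjacent centers (for Gaussian RR this
converges to 2.3548 σ). Events are screened from RR deviations —
`RR_i < 0.80·m_i` or `RR_i > 1.50·m_i` with `m_i` the local 9-beat
median — and typed by RR/P-wave rules (compensatory-pause arithmetic,
P presence in the pause, P-R prolongation). Short-term HRV is
`SDNN = sd(NN)` and band-integrated Lomb–Scargle power calibrated so a
sinusoidal RR modulation of amplitude `a` ms carries `a²/2` ms². The
non-compaction index is `(#ROI pixels without tissue) / (#ROI pixels)`,
normalised so the wild-type batch mean is exactly 1. The exact
Mann–Whitney p enumerates all C(n₁+n₂, n₁) rank assignments in
rational arithmetic.

Full model assumptions, parameter defaults and numerical choices are in
[docs/methods.md](docs/methods.md).

## Worked example

```python
import numpy as np
from mousebeat import simulate as sim, ecg, arrhythmia as arr, hrv, spectral as sp, stats as st

# 20 min of synthetic mouse ECG with known injected events
spec = sim.RRSpec(mean_rr_ms=100, sd_rr_ms=2, duration_s=1200, seed=7)
rr = sim.generate_rr_series(spec)
events_in = [sim.EventSpec("extrasystole_single", 3),
             sim.EventSpec("sinus_arrest", 2, pause_multiple=2.3),
             sim.EventSpec("blocked_p", 2)]
rr, truth = sim.inject_events(rr, events_in, seed=8)
trace = sim.synthesize_ecg(truth, noise_sd=0.05, seed=9)

# detect beats, classify events, summarise HRV
r = ecg.detect_r_peaks(trace)
pw = ecg.detect_p_waves(trace, r)
series = ecg.rr_intervals(r)
found = arr.classify_events(series, arr.flag_deviant_rr(series.rr), pw)
series = arr.apply_event_flags(series, found)
nn = hrv.sinus_nn_intervals(series)
h = hrv.build_rr_histogram(nn)
print(f"beats detected: {r.size}, events: "
      + ", ".join(f"{e.event_type}@{e.t_start_ms/1000:.1f}s" for e in found))
print(f"mean RR {nn.mean():.1f} ms, FWHM-HRV {hrv.fwhm(h):.2f} ms, SDNN {sp.sdnn(nn):.2f} ms")

u, p = st.mann_whitney_exact([31, 63, 37, 19], [64, 1181, 249, 78])
print(f"exact Mann-Whitney: U={u:.0f}, two-sided p={float(p):.4f}")
```

prints

```
beats detected: 12002, events: sinus_arrest@212.1s, extrasystole_single@282.3s, blocked_p@383.0s, extrasystole_single@392.9s, blocked_p@770.6s, extrasystole_single@862.7s, sinus_arrest@1183.2s
mean RR 100.0 ms, FWHM-HRV 5.44 ms, SDNN 2.24 ms
exact Mann-Whitney: U=0, two-sided p=0.0286
```

All seven injected events are recovered with their correct types and
times. The FWHM (5.44 ms) and SDNN (2.24 ms) are consistent with the
generator's 2 ms Gaussian RR jitter (Gaussian FWHM = 2.3548 σ ≈
4.7 ms, plus binning width), and the exact Mann–Whitney on the
per-mouse event totals shows the complete separation of the two
genotypes: U = 0, p = 2/70 ≈ 0.0286.

A thin CLI wraps the same functions: `mousebeat simulate`,
`mousebeat analyze`, `mousebeat compaction`, `mousebeat report`
(see `mousebeat --help`).

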