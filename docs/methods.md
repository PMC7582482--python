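# Methods

`mousebeat` re-implements, as a tested pipeline, the computational
phenotyping used to characterise cardiac rhythm and myocardial structure
in fibrillin-1-deficient (Marfan-model) mice versus wild-type
littermates: 24 h single-lead ECG analysis (long-term heart-rate
variability, arrhythmic-event screening), paired short-term HRV
(SDNN and spectral power), a myocardial non-compaction index from
mid-ventricular histology, and the small-sample statistical layer.
Because no recordings or micrographs are distributed with the original
study, every stage is validated against a ground-truthed synthetic-data
module that emulates the study's conditions.

## Synthetic murine ECG

**Beat-interval model.** Sinus RR intervals are generated as
`RR_i = mean + N(0, sd) + a_LF sin(2π f_LF t_i) + a_HF sin(2π f_HF t_i)`
evaluated at the running beat time. Defaults: mean RR 100 ms (600 bpm,
resting mouse), sd 2 ms, modulation off unless requested. Non-positive
draws are resampled (bounded); modulation frequencies must stay below
the beat-rate Nyquist (5 Hz at 100 ms). Identical seeds give identical
series.

**Event morphologies.** Six classes are injected into an all-sinus
series, all parameterised by the local cycle length `b`:

- *extrasystole* (single / doublet / run of k ≥ 3): k premature beats at
  coupling `0.6·b` followed by a compensatory pause; the local cycle sum
  is preserved exactly (`k` premature intervals + pause = `(k+1)·b`), so
  a single extrasystole in a 100 ms rhythm reads `…100, 60, 140, 100…`.
  A non-compensated variant is available via the prematurity parameter.
- *sinus arrest*: one interval stretched to `2.5·b` by default (2.3 in
  several validation fixtures) with no P wave in the gap; the multiple is
  kept away from integers so the pause is distinguishable from blocked
  conduction.
- *blocked P wave*: one QRS dropped with its P wave retained on time;
  the visible RR is ~2·b.
- *AV block*: a blocked P preceded by progressive P-R prolongation
  (Wenckebach-like, factors 1.25/1.5/1.8 of the 20 ms base P-R) over the
  three preceding conducted beats — the only surface-ECG-detectable
  variant, and what keeps the class separable from a plain blocked P.

Placements are random without overlap (12-beat guard); the truth log
records every cycle, label (`sinus` / `ectopic` / `dropped_qrs`), P-wave
time and event span.

**Waveform.** Each beat renders Gaussian P/QRS/T templates (full widths
8 / 10 / 25 ms; amplitudes 0.12 / 1.0 / 0.2 mV; T offset +30 ms) at
2 kHz with additive white noise. Dropped beats render P only. The
original recording hardware's waveform shape is unspecified, so these
are declared plumbing choices, not claims; the validation noise level is
0.05 of the R amplitude.

## Beat detection

R peaks: zero-phase 10–200 Hz band-pass, squared envelope smoothed over
8 ms, blockwise adaptive threshold (25% of the 99th envelope percentile
per 2 s block), 30 ms refractory period, refinement to the raw-signal
local maximum. On synthetic traces at noise 0.05·R this achieves
sensitivity and PPV ≥ 0.99 (±5 ms matching); each parameter is a keyword
argument.

P waves: the trace is filtered with FIR Gaussian kernels matched to the
P width (difference of Gaussians for per-beat search; plain matched
smoothing inside pauses). IIR band-passes were rejected because their
recovery tails after the large QRS-T complexes generate spurious peaks
inside pauses. Conducted P = most prominent interior local maximum
12–45 ms before each R, accepted above 40% of the median prominence
(adaptive, since sinus beats dominate). Unconducted P = highest peak in
a pause interior (50 ms T-wave guard), accepted 5 noise-SDs above the
pause median, with the noise scale pooled over all pause interiors —
a single short pause containing a T tail plus a P bump cannot estimate
its own floor.

## Long-term HRV (histogram FWHM)

Traces are tiled into half-open 20-min fragments (a 24 h trace gives
72); trailing partial fragments are excluded from per-fragment
statistics. Sinus-only ("NN") intervals exclude event beats plus one
neighbour on each side. Per fragment, RR intervals are binned at 1 ms
(~2% relative resolution at murine RR; configurable) with two empty
guard bins per side, and HRV is the full width at half maximum: half of
the peak count, crossings located by linear interpolation between
adjacent bin centers, maximal-count plateaus treated as one peak,
histogram edges used when a peak touches the boundary. Fragments with
< 50 sinus intervals are not evaluable. Subject values aggregate
fragment values by unweighted mean (median and pooled-histogram
alternatives are provided, since the aggregation behind per-group
figures is not uniquely determined); group values are mean ± SE. On
simulated Gaussian RR the estimator converges to 2.3548σ, with a small
negative bias (~0.1 ms at σ = 4 ms, 0.5 ms bins) from binning plus
linear interpolation.

## Arrhythmia screening

Candidates are RR intervals below 0.80× or above 1.50× the local median
(9 neighbouring intervals, the tested interval excluded). Adjacent
candidates (gap ≤ 1 beat) merge into one segment, preventing doublets
from double-counting as two singles. Classification per segment, in
order: (1) leading premature interval(s) followed by a compensatory
pause → extrasystole, typed by run length; (2) lone long interval with
an unconducted P inside and length within ±0.15·b of 2·b → blocked P;
(3) rule 2 plus a preceding P-R ramp (monotone within 3 ms slack, last
P-R ≥ 1.3× the trace median, and ≥ 2 of the 3 preceding P-Rs elevated
≥ 1.15× — the two-of-three requirement stops a single misread P from
faking a Wenckebach ramp) → AV block; (4) lone long interval with no P
inside and farther than 0.15·b from every integer multiple of b → sinus
arrest; (5) otherwise unclassified and review-flagged. Pause tolerances
are expressed in units of one base cycle: ±15% of 2b would place a
2.3·b arrest exactly on the blocked-P boundary. Missing P information
downgrades rules 2–4 to a review-flagged best guess. Every event
carries its rule trace, preserving the manual-review audit step of
telemetry practice. Tabulation yields per-subject counts, genotype
totals and each type's share of the genotype total (1 decimal).

Validated end-to-end on 2 h synthetic traces with 20 events of each
type (sd 2 ms, noise 0.05·R): per-type sensitivity ≥ 0.9 (typically
0.95–1.0) and no spurious events across seeds.

## Short-term HRV

Paired selection slides aligned, non-overlapping 120 s windows over the
simultaneous span of two recordings and keeps windows that are
event-free in both and matched on mean RR within 5 ms (both values
recorded per pair; the matching tolerance is a declared choice — the
original selection criterion is stated only as "similar"). SDNN is the
ddof-1 standard deviation of NN intervals. Spectra use least-squares
(Lomb–Scargle) analysis of the mean-subtracted, unevenly sampled
tachogram, scaled by `2T/N` so that a sinusoidal modulation of
amplitude `a` ms integrates to `a²/2` ms² and broadband power matches
the NN variance within ~10% (rectangular-window equivalent-bandwidth
argument); a cubic-resampled Welch estimator is the cross-check
alternative. Band powers integrate trapezoidally over murine bands —
LF 0.15–1.5 Hz, HF 1.5–5 Hz, total (0, 5] Hz — roughly ten times the
human conventions, matching rodent telemetry presets; power is reported
in ms², the standard HRV convention for unit-less published tables.

## Non-compaction index

The index is minimal and declared: the free-space area fraction inside
the ventricular-wall ROI. Segmentation thresholds the stain-saturation
channel at the histogram valley (median despeckle radius 2 px first),
falling back to the midpoint of Otsu class means for near-noiseless
two-level images and refusing unimodal content. The ROI closes the
tissue mask (radius 2% of image width — enough to bridge inter-lamellar
gaps), fills holes, and removes large holes of the *closed* outline
(> 5% of the ROI) as chamber lumens: space between lamellae counts,
the cavity does not. A provided ROI mask overrides. Each section is
measured in triplicate with the threshold jittered ±2 intensity levels
(deterministic), the mean reported and the spread logged. Because
absolute staining varies between sessions, indices are normalised to
the wild-type mean within each staining/imaging batch (WT batch mean
≡ 1); batches without a WT section refuse normalisation. On synthetic
sections (truth by exact pixel count) the pipeline recovers the
free-space fraction within ±0.005 and is stable under 2× decimation to
< 0.01.

The synthetic sections are idealised: two stain colours, radially
symmetric trabeculae, no stain gradients, tears, folds or out-of-focus
regions. Passing tests therefore demonstrate the correctness of the
thresholding/ROI/normalisation arithmetic, not robustness to real
histology artefacts — that is what the provided-ROI override and the
triplicate spread are for.

## Statistics

Two-group comparisons gate on Shapiro–Wilk normality (valid 3 ≤ n ≤ 50)
in both groups at α = 0.05: pass → two-sample t (pooled variance by
default, Welch available); fail → Mann–Whitney U, computed by *exact
enumeration* of all C(n₁+n₂, n₁) rank assignments in rational
arithmetic whenever min(n) ≤ 8 (the cohort sizes here are n = 4), with
midranks for ties; the tie-corrected, continuity-corrected normal
approximation is always attached for comparison because commercial
packages often print only the asymptotic value. All tests are
two-sided; descriptives are mean ± SE (dash when n < 2). Event-type
frequencies use the Pearson chi-square statistic with margin-based
expectations; cells with expected counts below 5 are flagged, not
dropped.

On the published per-mouse 24 h event totals ({31, 63, 37, 19} vs
{64, 1181, 249, 78}) the groups separate completely, so U = 0 and the
exact two-sided p is 2/70 ≈ 0.0286 — a value fixed by enumeration and
not equal to the p printed for this comparison in the original report
(0.019), which is reproducible neither by exact enumeration nor by the
standard normal approximation. The package reports its own exact and
asymptotic values, labelled, and does not attempt to match the printed
number.

## Problem sizes and numerical choices

Validation experiments are sized for desk-scale reproduction: the
event-recovery screen uses a 2 h trace with 20 events per type (the
published screening spans 24 h per animal); FWHM calibration uses 10⁵
Gaussian intervals; spectral calibration uses 2-min fragments; the
compaction cohort is 3 + 3 sections in one batch, mirroring the
published per-age-group design. The published group-level physiology
(mean RR 97.3 vs 102.1 ms, FWHM 16.1 vs 11.3 ms, SDNN 5.31 vs 2.77 ms,
Fig.-level index values) derives from the authors' animals and is used
here only to parameterise synthetic cohorts, never as a recovery
target. All thresholds named above (detector bands, candidate
fractions 0.80/1.50, pause tolerance 0.15, P-R ramp criteria, histogram
bin width, band edges, pairing tolerance, closing radius, lumen
fraction) are keyword arguments with the stated defaults.

## Known limitations

- Single-lead analysis only; no QRS-morphology, QT or ST measurements.
- The AV-block category detects Wenckebach-like (progressive-P-R)
  block only; fixed-ratio second-degree block without P-R prolongation
  classifies as blocked P.
- The P-wave detector assumes upright P waves and a stable P-R around
  20 ms, as rendered by the synthesiser; inverted or biphasic P waves
  would need template changes.
- Histology segmentation assumes a bimodal stain histogram; faint or
  uneven staining falls back to review via the provided-ROI path.
- No circadian stratification of the 24 h statistics and no nonlinear
  HRV indices.
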