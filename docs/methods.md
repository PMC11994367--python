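# Methods

This note documents the models, numerical choices and limitations behind
`glycoecg`. Headline numbers quoted here are the ones the test suite and
`scripts/acceptance.py` themselves compute.

## Signal model and preprocessing

An 8-s single-lead ECG sampled at fs = 1400 Hz (n = 11200) is modelled as
beats plus three additive disturbances: sub-hertz baseline wander from
respiration and movement, narrowband powerline interference at 60 Hz, and
wideband sensor noise.

Preprocessing is wavelet multiresolution analysis with a Symlet-4 mother
wavelet at 10 levels. Detail level j spans (fs/2^(j+1), fs/2^j) Hz and the
deepest approximation spans (0, fs/2^(levels+1)); at 1400 Hz:

| component | band (Hz) | role |
|---|---|---|
| A10 | 0 – 0.68 | baseline wander — removed |
| D10 | 0.68 – 1.37 | baseline transition band — removed by default (see below) |
| D8–D9 | 1.37 – 5.5 | P/T-wave energy — kept in the corrected signal |
| D4–D7 | 5.5 – 87.5 | QRS band — kept; alone they form the QRS-emphasis signal |
| D1–D3 | 87.5 – 700 | wideband noise — removed |

**Powerline handling.** At 1400 Hz the 60 Hz line falls inside D4
(43.75–87.5 Hz), a band that must be kept for QRS detection, so no detail
level can be discarded to remove it. Instead a second-order IIR notch
(60 Hz, Q = 30, default on) is applied to the raw trace *before*
decomposition, with `scipy.signal.filtfilt`: zero-phase filtering is
essential because a causal notch would shift R-peak times and bias every
RR interval. A pure 60 Hz sinusoid is attenuated to below 10% RMS.

**Baseline correction margin.** Symlet-4 filters are short (8 taps) and
their band transitions wide: a 0.3 Hz sinusoid — squarely inside the A10
band — leaves ≈ 7% of its RMS in the D10 coefficients, in every padding
mode. Zeroing only A10 therefore suppresses wander by ≈ 93%, not the
> 95% the pipeline targets. Baseline correction consequently removes A10
plus the deepest `baseline_detail_margin` detail levels (default 1, i.e.
D10); the residual falls to ≈ 1.2% RMS. The margin is configurable;
`baseline_detail_margin: 0` restores approximation-only correction. The
cost is loss of content below 1.37 Hz, which carries the beat-repetition
fundamental but none of the QRS shape; R-peak detection and HR/HRV
recovery are unaffected (verified in the benchmarks below).

**Boundary extension.** The transform defaults to symmetric extension,
which minimizes edge artifacts on an 8-s window. Symmetric extension
duplicates edge energy into the boundary coefficients, so Parseval holds
only approximately (≈ 4×10⁻³ relative on white noise at this length);
with zero extension, which adds no energy, the orthonormal filter bank
conserves energy to machine precision (< 10⁻¹² relative) — the energy
test uses that mode. Perfect reconstruction holds in both modes to
< 10⁻⁸ relative error. `pywt`'s periodization mode was rejected as a
default: at n = 11200 a subband goes odd-length at level 6 and the mode's
internal padding breaks exact energy conservation anyway.

**Band remapping.** By default the decomposition depth and QRS detail
levels are recomputed from the actual sampling rate so the physical bands
above are preserved for non-1400 Hz records (e.g. at 700 Hz: 9 levels,
QRS details 3–6). `band_mapping: literal` forces the canonical level
indices regardless of rate.

## R-peak detection

Candidates are strict local maxima of the QRS-emphasis signal over a
±5-sample neighbourhood. The amplitude window accepts candidates at
≥ `window_fraction` (default 0.6) of the signal's global maximum — a
conventional QRS threshold, exposed as a parameter since the R deflection
dominates the QRS band by construction of the reconstruction. A 0.30 s
refractory rule (200 bpm physiological ceiling) keeps the larger of any
close pair (ties: earlier). Each surviving peak is then refined to the
maximum of the full-band corrected signal within ±25 ms, and the
refractory rule is re-applied after refinement so successive R times
always respect it. Raising `window_fraction` can only remove peaks
(monotonicity), and detection is invariant to positive rescaling of the
record — both are property-tested.

Degenerate inputs: a constant or empty signal raises a no-peaks error;
fewer than three detected beats emits a warning and flags the feature
vector as non-classifiable rather than producing a misleading HR/HRV
pair.

## Features

- RR intervals: successive differences of the R times (s).
- HRV: sample standard deviation (ddof = 1) of the RR intervals — an
  SDNN-style dispersion over one short record. The population variant
  (ddof = 0) is available via a flag; at 8–14 intervals per record the
  difference is a few percent.
- HR: 60 / mean(RR) bpm by default; a count-based variant
  (beats / duration) is available but is biased by partial beats at the
  record edges.

## Synthetic ECG generator

The generator exists to give every downstream stage exact ground truth;
its defaults are the stress conditions the detector is benchmarked under
(baseline amplitude 0.3 of the R peak, 60 Hz amplitude 0.1, white noise
sd 0.02).

- **Beat template**: five Gaussians (P, Q, R, S, T) at fixed offsets from
  the R center; R amplitude 1.0, all others ≤ 0.30. Q and S are symmetric
  about R (±30 ms, −0.15): with an asymmetric Q/S pair the continuous
  beat maximum sits ≈ 0.2 ms off the R center — more than half a sample
  at 1400 Hz — which would detach the ground truth from the observable
  peak. Symmetry pins the noise-free argmax to the R center exactly.
- **RR intervals**: i.i.d. truncated normal (mean 60/HR, sd `sdnn`,
  bounds 0.25–2.0 s). HRV here is a single marginal dispersion number, so
  serial RR structure (respiratory sinus arrhythmia, long-range
  correlation) is deliberately not modelled. Parameterizations where
  truncation shifts the mean RR by > 5% are rejected.
- **Edge policy**: R centers are kept ≥ 0.3 s from the record start and
  ≥ 0.05 s from its end, so every ground-truth peak has both neighbours
  and a full ±25 ms refinement window inside the record. Ground-truth R
  times are the template centers snapped to the sample grid.

## Synthetic cohort generator

Rows are allocated to three glycemic strata by largest-remainder (exact,
deterministic; ties to the earlier stratum). Within a stratum, glucose
and HRV are uniform on the empirical bands: normal 70–150 mg/dL with HRV
0.02–0.2 s, mild hyperglycemia 150–200 mg/dL with 0.009–0.019 s, severe
200–500 mg/dL with 0.002–0.009 s (the severe band's lower edge, 0.002 s,
is a floor added because only the upper edge is empirically stated). HR
couples to glucose as 60 + 0.08·(glucose − 70) + N(0, 5) bpm, clamped to
45–120 — a slope chosen to produce a moderate positive HR–glucose
correlation; it is a test-harness assumption, not a physiological claim.
Diagnosis is `healthy` for the normal stratum and `dm` otherwise, which
makes the two classification tasks coincide on synthetic cohorts — real
cohorts break that coincidence (diabetic subjects measured at normal
glucose), and that is why the glucose-class task is the more reliable
one.

**What passing synthetic benchmarks does and does not show.** The
generator's HRV bands are disjoint between strata, so a synthetic cohort
is Bayes-separable in HRV alone; clinical populations are not. Synthetic
results therefore validate the machinery (detection, features,
statistics, classifiers) — they do not estimate clinical accuracy.
Likewise the ECG simulator's disturbances are stationary sinusoids plus
white noise; electrode motion artifacts, muscle noise and ectopic beats
are absent, so the detection rate below is an upper bound on behavior
with ambulatory data.

## Classifiers and evaluation

Features are (HR, HRV), z-scored with training-split statistics by
default — HR (≈ 45–120) would otherwise dominate HRV (≈ 0.002–0.2) in
every Euclidean distance and RBF kernel; the raw-scale variant remains
available.

- **KNN** (authored here): Euclidean distances, k = 5 default (k must be
  odd). Distance ties break by training-row order, vote ties by the class
  with smaller mean distance among the k, then lexicographic label
  order. Verified query-by-query against a full-sort brute-force oracle.
- **SVM**: soft-margin RBF kernel, C = 1, gamma = 1/(d·Var(X))
  (scikit-learn's `SVC(gamma="scale")`), deterministic given inputs.

The split is stratified per class (nearest-integer rounding, exact
halves to training; seeded shuffle), giving 140/70 on a 210-row cohort.
Confusion matrices put the positive class (healthy, or normal glucose)
in the top row: counts [[TP, FN], [FP, TN]], a row-normalized percentage
matrix, and per-class accuracies TP/(TP+FN) and TN/(TN+FP).

One behavior worth knowing: the mild-hyperglycemia HRV band ends at
0.019 s and the normal band starts at 0.02 s — a 0.001 s gap, about
0.015 sd after standardization. An RBF SVM at C = 1 with variance-scaled
gamma cannot resolve a margin that narrow, so normal-class rows with HRV
just above 0.02 s are occasionally labelled hyperglycemic; normal-class
accuracy on a 39-row validation arm fluctuates roughly between 85 and
100% across cohort seeds while the hyperglycemia class stays at 97–100%.
This is a property of the fixed (C, gamma) operating point, not of the
data pipeline.

## Benchmark problem sizes and computed results

Problem sizes were chosen so the full suite runs in well under a minute
of simulation per benchmark: 500 records for detection, 200 for
HR/HRV recovery, 210 rows for the cohort.

At these sizes the suite and `scripts/acceptance.py` compute (seed 1):

- perfect-detection rate (every true R within ±20 ms, zero spurious)
  over 500 stressed records: **100.0%** (bar: ≥ 99.8%);
- HR recovered within ±0.5 bpm and HRV within ±15% on every record with
  sdnn ≥ 0.01 s (observed worst case ≈ 0.03 bpm and ≈ 11%);
- SVM per-class validation accuracies on the 210-row cohort:
  hyperglycemia **100%**, normal **97.4%** (seed-dependent; see above).

## Known limitations

- Single-lead, 8-s records only; no multi-lead fusion, no long-record
  (Holter) HRV indices, no frequency-domain or nonlinear HRV.
- The amplitude-window detector assumes upright R deflections; inverted
  leads would need a polarity flip upstream.
- The time-column dialect of ECG text files is auto-detected
  (seconds vs sample index); sample-index files require an explicit
  nominal rate.
- Correlations are descriptive: no significance tests or normality
  diagnostics are performed.
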