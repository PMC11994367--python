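# glycoecg

Non-invasive hyperglycemia screening from short single-lead ECG records.

Blood glucose is normally tracked by finger-prick measurement. Because
sustained hyperglycemia disturbs autonomic regulation of the heart,
short-record ECG features carry a glycemic signature: heart-rate
variability (HRV) collapses as glucose rises while heart rate (HR) drifts
upward. `glycoecg` implements the complete screening pipeline for 8-second
single-lead records sampled at 1400 Hz:

1. **Wavelet preprocessing** — 10-level discrete wavelet transform
   (Symlet-4 mother wavelet). Baseline wander (respiration/motion, the
   deepest approximation band A10, 0–0.68 Hz) and high-frequency noise
   (D1–D3, >87.5 Hz) are removed; a zero-phase 60 Hz notch (Q=30) handles
   powerline interference. A QRS-emphasis signal is rebuilt from details
   D4–D7 (~5.5–87.5 Hz), the band of the R deflection.
2. **R-peak detection** — strict local maxima of the QRS-band signal are
   accepted inside an amplitude window (≥ 0.6 of the global maximum), a
   0.30 s refractory rule removes double detections, and each peak is
   refined to the corrected-signal maximum within ±25 ms.
3. **Feature extraction** — RR intervals RRᵢ = tᵢ₊₁ − tᵢ from the R
   times, then HR = 60 / mean(RR) (bpm) and HRV = sd(RR) (the SDNN-style
   sample standard deviation, seconds).
4. **Correlation** — Pearson r = Sxy/(Sx·Sy) of glucose against HR, HRV
   and the HR/HRV ratio, with the conventional strength bands
   (|r| < 0.30 low, 0.30–0.70 moderate, > 0.70 high).
5. **Classification** — normal glucose (70–150 mg/dL) versus
   hyperglycemia (> 150 mg/dL), or healthy versus diabetic, from
   standardized (HR, HRV): a from-scratch k-nearest-neighbours vote
   (k = 5, Euclidean distance) and an RBF-kernel soft-margin SVM (C = 1),
   evaluated on a seeded stratified 2/3–1/3 split with per-class
   confusion-matrix accuracies.

Since clinical recordings cannot be redistributed, the package ships a
**synthetic module**: an ECG simulator (sum-of-Gaussians PQRST template,
truncated-normal RR intervals, baseline/powerline/white-noise
disturbances) with exact ground-truth R times, and a cohort generator
reproducing the empirical HRV stratification by glycemic state
(normal: 0.02–0.2 s, mild hyperglycemia: 0.009–0.019 s, severe: < 0.009 s).
Every stage is validated against this ground truth.

## Worked example

```python
from glycoecg import (SynthesisParams, synthesize_ecg, extract_features,
                      load_example_cohort, correlation_profile)

record, truth = synthesize_ecg(SynthesisParams(mean_hr=72, sdnn=0.03, seed=42))
fv = extract_features(record)
print(f"true    hr={truth.true_hr:.3f} bpm  hrv={truth.true_hrv:.5f} s")
print(f"derived hr={fv.hr:.3f} bpm  hrv={fv.hrv:.5f} s  ({fv.n_beats} beats)")

profile = correlation_profile(load_example_cohort())
print(profile.to_dict())
```

prints

```
true    hr=71.209 bpm  hrv=0.03355 s
derived hr=71.202 bpm  hrv=0.03359 s  (9 beats)
{'n': 11, 'r_hr': 0.7328503886407444, 'r_hrv': -0.6676245974649186,
 'r_hr_over_hrv': 0.9576713761253443, 'r_multiple': 0.7623303883403634,
 'n_ratio_excluded': 0,
 'strengths': {'hr': 'high', 'hrv': 'moderate', 'ratio': 'high'}}
```

The simulated record's HR is recovered to 0.007 bpm and its HRV to
0.04 ms despite 30% baseline wander, 10% powerline interference and 2%
white noise. On the bundled 11-subject example cohort, glucose correlates
positively with HR (r = +0.73), negatively with HRV (r = −0.67) and
strongly with the HR/HRV ratio (r = +0.96): exactly the signature the
classifiers exploit.

The same stages are available from the shell:

```sh
glycoecg --seed 7 --output-dir out simulate --n 5 --cohort-n 210
glycoecg --output-dir out extract out/ecg_0000.txt
glycoecg --output-dir out correlate out/cohort.csv
glycoecg --seed 7 --output-dir out classify out/cohort.csv --task normal_vs_hyper
glycoecg --seed 7 --output-dir out pipeline          # all of the above
```

Every run writes a `manifest.json` (config echo, seed, version, input
digests); identical config + seed reproduces outputs byte-for-byte.

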