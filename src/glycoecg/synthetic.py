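"""Synthetic ECG records and cohort tables with known ground truth.

Every downstream stage — wavelet preprocessing, R-peak detection, HR/HRV
recovery, correlation, classification — is validated against signals whose
true beat times and against cohorts whose true class structure are known
by construction.

The beat morphology is a fixed sum-of-Gaussians PQRST template: five bumps
at fixed offsets from the R center, R amplitude 1.0, all others below 0.35
in magnitude. Q and S are symmetric about R so the continuous maximum of a
noise-free beat coincides exactly with the template R center. Disturbances
are additive: sinusoidal baseline wander (respiration-band, default
0.3 Hz), sinusoidal powerline interference (default 60 Hz) and white
Gaussian noise — the three contaminants a resting short-record acquisition
actually faces.

RR intervals are i.i.d. truncated normal. HRV in this pipeline is a single
dispersion number (an SDNN-style standard deviation over one short record),
so only the marginal RR spread matters; serial structure such as
respiratory sinus arrhythmia is deliberately out of scope.

Cohort feature tables follow the empirical stratification of short-record
HRV by glycemic state: normoglycemic subjects show RR dispersion roughly
in 0.02–0.2 s, mild hyperglycemia 0.009–0.019 s, severe hyperglycemia
below 0.009 s, with a moderate positive HR–glucose coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .io import COHORT_COLUMNS, ECGRecord

#: Physiological truncation bounds for a single RR interval, seconds
#: (240 bpm ceiling, 30 bpm floor).
RR_BOUNDS = (0.25, 2.0)

#: PQRST template: (offset from R in s, amplitude relative to R, Gaussian sd in s).
#: Q and S are symmetric so the noise-free beat maximum sits exactly on R.
BEAT_TEMPLATE = (
    ("P", -0.20, 0.15, 0.030),
    ("Q", -0.03, -0.15, 0.012),
    ("R", 0.00, 1.00, 0.012),
    ("S", 0.03, -0.15, 0.012),
    ("T", 0.28, 0.30, 0.055),
)

#: Keep-out margins for R centers at the record edges, seconds. A strict
#: local maximum needs neighbours on both sides and the peak-refinement
#: window extends ±25 ms, so R centers stay inside [start, duration - end].
EDGE_MARGIN = (0.30, 0.05)

#: Per-stratum generative ranges: glucose (mg/dL) and HRV (s) bands.
COHORT_STRATA: dict[str, dict[str, tuple[float, float]]] = {
    "normal": {"glucose": (70.0, 150.0), "hrv": (0.02, 0.2)},
    "mild_hyper": {"glucose": (150.0, 200.0), "hrv": (0.009, 0.019)},
    "severe_hyper": {"glucose": (200.0, 500.0), "hrv": (0.002, 0.009)},
}

#: HR model: hr = HR_BASE + HR_SLOPE * (glucose - 70) + N(0, HR_NOISE_SD),
#: clamped to HR_CLAMP. The slope gives a moderate positive HR-glucose
#: correlation; this is a test-harness model, not a physiological claim.
HR_BASE = 60.0
HR_SLOPE = 0.08
HR_NOISE_SD = 5.0
HR_CLAMP = (45.0, 120.0)


@dataclass
class SynthesisParams:
    """Knobs of the single-record ECG simulator.

    Defaults are the stress conditions the detection pipeline is scored
    under: 8 s at 1400 Hz with baseline wander at 30% of the R amplitude,
    60 Hz interference at 10%, and 2% white noise.
    """

    fs: float = 1400.0
    duration: float = 8.0
    mean_hr: float = 72.0
    sdnn: float = 0.03
    baseline_amp: float = 0.3
    baseline_freq: float = 0.3
    powerline_amp: float = 0.1
    powerline_freq: float = 60.0
    white_noise_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if not self.fs > 2 * self.powerline_freq:
            raise ParameterError(
                f"fs={self.fs} must exceed twice the powerline frequency "
                f"({self.powerline_freq} Hz)"
            )
        if not 20.0 <= self.mean_hr <= 250.0:
            raise ParameterError(f"mean_hr={self.mean_hr} outside [20, 250] bpm")
        if self.sdnn < 0:
            raise ParameterError("sdnn must be non-negative")
        if not self.duration > 2 * (60.0 / self.mean_hr):
            raise ParameterError(
                "duration must cover at least two mean RR intervals"
            )


@dataclass
class GroundTruth:
    """Exact beat timing of a synthesized record.

    ``r_times`` are the template R centers snapped to the sample grid;
    ``true_hr`` and ``true_hrv`` are the reference values feature
    extraction is scored against.
    """

    r_times: np.ndarray
    rr_intervals: np.ndarray = field(init=False)
    true_hr: float = field(init=False)
    true_hrv: float = field(init=False)

    def __post_init__(self) -> None:
        self.r_times = np.asarray(self.r_times, dtype=float)
        if np.any(np.diff(self.r_times) <= 0):
            raise ParameterError("r_times must be strictly increasing")
        self.rr_intervals = np.diff(self.r_times)
        self.true_hr = 60.0 / float(np.mean(self.rr_intervals))
        self.true_hrv = float(np.std(self.rr_intervals, ddof=1))


def generate_rr_sequence(
    mean_hr: float, sdnn: float, n_beats: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw ``n_beats`` i.i.d. RR intervals (seconds).

    Intervals follow a normal with mean ``60/mean_hr`` and std ``sdnn``,
    truncated to physiological bounds (0.25–2.0 s). A ``sdnn`` so large
    that truncation shifts the mean by more than 5% is rejected.
    """
    if n_beats < 1:
        raise ParameterError("n_beats must be >= 1")
    if sdnn < 0:
        raise ParameterError("sdnn must be non-negative")
    if not 20.0 <= mean_hr <= 250.0:
        raise ParameterError(f"mean_hr={mean_hr} outside [20, 250] bpm")
    mean_rr = 60.0 / mean_hr
    if sdnn == 0.0:
        return np.full(n_beats, mean_rr)
    lo, hi = RR_BOUNDS
    a, b = (lo - mean_rr) / sdnn, (hi - mean_rr) / sdnn
    dist = stats.truncnorm(a, b, loc=mean_rr, scale=sdnn)
    if abs(dist.mean() - mean_rr) > 0.05 * mean_rr:
        raise ParameterError(
            f"sdnn={sdnn} shifts the truncated mean RR by more than 5%"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return dist.rvs(size=n_beats, random_state=rng)


def synthesize_ecg(params: SynthesisParams) -> tuple[ECGRecord, GroundTruth]:
    """Simulate one single-lead ECG record with exact beat ground truth.

    Returns the record and a :class:`GroundTruth` whose ``r_times`` are the
    template R centers snapped to the sample grid; identical params (and
    seed) give bit-identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = int(round(params.fs * params.duration))
    t = np.arange(n) / params.fs

    # Beat schedule: first R inside [0.3, 0.7] s, subsequent R's from the
    # RR sequence, last R kept clear of the record end.
    start_margin, end_margin = EDGE_MARGIN
    first_r = start_margin + 0.4 * rng.random()
    max_beats = int(np.ceil(params.duration / RR_BOUNDS[0])) + 2
    rr = generate_rr_sequence(params.mean_hr, params.sdnn, max_beats, rng)
    r_cont = first_r + np.concatenate([[0.0], np.cumsum(rr)])
    r_cont = r_cont[r_cont < params.duration - end_margin]
    r_idx = np.round(r_cont * params.fs).astype(int)
    r_times = r_idx / params.fs

    x = np.zeros(n)
    for _, off, amp, sd in BEAT_TEMPLATE:
        centers = r_times + off
        x += amp * np.exp(-((t[None, :] - centers[:, None]) ** 2) / (2 * sd**2)).sum(axis=0)

    x += params.baseline_amp * np.sin(2 * np.pi * params.baseline_freq * t)
    x += params.powerline_amp * np.sin(2 * np.pi * params.powerline_freq * t)
    if params.white_noise_sd > 0:
        x += rng.normal(0.0, params.white_noise_sd, size=n)

    record = ECGRecord(samples=x, fs=params.fs, t0=0.0)
    return record, GroundTruth(r_times=r_times)


def _allocate(n: int, mix: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of ``n`` rows over strata (deterministic;
    ties go to the earlier stratum in canonical order)."""
    order = [s for s in COHORT_STRATA if s in mix]
    props = np.array([mix[s] for s in order], dtype=float)
    if np.any(props < 0):
        raise ParameterError("class-mix proportions must be non-negative")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ParameterError(f"class-mix proportions must sum to 1, got {props.sum()}")
    raw = props * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    # stable sort on descending fractional part keeps canonical order on ties
    for i in np.argsort(-(raw - counts), kind="stable")[:short]:
        counts[i] += 1
    return dict(zip(order, counts.tolist()))


def generate_cohort_features(
    n: int,
    class_mix: Mapping[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a cohort table of (glucose, HR, HRV) rows by stratum.

    ``class_mix`` maps stratum names (``normal``, ``mild_hyper``,
    ``severe_hyper``) to proportions summing to 1; rows are allocated
    deterministically (largest remainder). Glucose and HRV are uniform on
    the stratum bands; HR couples positively to glucose with Gaussian
    scatter, clamped to 45–120 bpm. Diagnosis is ``healthy`` for the
    normal stratum and ``dm`` for both hyperglycemic strata.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if class_mix is None:
        class_mix = {"normal": 0.55, "mild_hyper": 0.25, "severe_hyper": 0.20}
    unknown = set(class_mix) - set(COHORT_STRATA)
    if unknown:
        raise ParameterError(f"unknown stratum name(s): {sorted(unknown)}")
    counts = _allocate(n, class_mix)
    rng = np.random.default_rng(seed)

    rows = []
    sid = 0
    for stratum, count in counts.items():
        bands = COHORT_STRATA[stratum]
        glucose = rng.uniform(*bands["glucose"], size=count)
        hrv = rng.uniform(*bands["hrv"], size=count)
        hr = HR_BASE + HR_SLOPE * (glucose - 70.0) + rng.normal(0, HR_NOISE_SD, count)
        hr = np.clip(hr, *HR_CLAMP)
        diagnosis = "healthy" if stratum == "normal" else "dm"
        for g, h, v in zip(glucose, hr, hrv):
            sid += 1
            rows.append(
                {
                    "subject_id": f"S{sid:04d}",
                    "glucose_mg_dl": g,
                    "hr_bpm": h,
                    "hrv_s": v,
                    "diagnosis": diagnosis,
                    "stratum": stratum,
                }
            )
    table = pd.DataFrame(rows, columns=list(COHORT_COLUMNS) + ["stratum"])
    return table
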