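"""R-peak detection and HR/HRV feature extraction.

Detection is amplitude-windowed: strict local maxima of the QRS-band
reconstruction are accepted when they reach a fixed fraction (default
0.6) of the global maximum, a refractory rule removes double detections,
and each accepted peak is then refined to the corresponding maximum of
the full-band corrected signal. From the resulting R times the pipeline
derives the two classifier inputs: heart rate (bpm) and an SDNN-style
heart-rate variability (the sample standard deviation of the RR
intervals within the record, in seconds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelextrema

from .config import PipelineConfig
from .errors import (
    InsufficientBeatsWarning,
    InsufficientDataError,
    NoPeaksError,
    ParameterError,
)
from .io import ECGRecord
from .wavelet import ProcessedSignal, preprocess_ecg


@dataclass
class DetectionParams:
    """Amplitude-window R-peak detector settings.

    ``window_fraction`` is the acceptance threshold relative to the global
    maximum of the QRS-band signal; ``refractory`` is the minimum
    physiological R-to-R separation (0.30 s ~ a 200 bpm ceiling);
    ``local_max_neighborhood`` is the half-width (samples) over which a
    candidate must be a strict local maximum; ``refine_window`` is the
    half-width (s) of the corrected-signal window the final peak position
    is read from.
    """

    window_fraction: float = 0.6
    refractory: float = 0.30
    local_max_neighborhood: int = 5
    refine_window: float = 0.025

    def __post_init__(self) -> None:
        if not 0 < self.window_fraction <= 1:
            raise ParameterError("window_fraction must lie in (0, 1]")
        if self.refractory <= 0:
            raise ParameterError("refractory must be positive")
        if self.local_max_neighborhood < 1:
            raise ParameterError("local_max_neighborhood must be >= 1")


@dataclass
class RPeakSet:
    """Detected R peaks of one record (times in s, amplitudes in corrected
    signal units, indices into the sample array)."""

    times: np.ndarray
    amplitudes: np.ndarray
    indices: np.ndarray
    fs: float

    @property
    def n(self) -> int:
        return int(self.times.size)


@dataclass
class FeatureVector:
    """Per-record classifier input: HR (bpm) and HRV (s).

    ``valid`` is False when fewer than three beats were found, in which
    case the vector must not enter correlation or classification.
    """

    hr: float
    hrv: float
    n_beats: int
    record_id: str | None = None
    valid: bool = True


def _refractory_filter(
    idx: np.ndarray, amp: np.ndarray, fs: float, refractory: float
) -> np.ndarray:
    """Greedy refractory suppression: visit candidates by descending
    amplitude (ties: earlier time) and drop any within ``refractory``
    seconds of an already-kept peak. Returns kept indices, time-sorted."""
    order = np.lexsort((idx, -amp))
    kept: list[int] = []
    min_gap = refractory * fs
    for i in order:
        if all(abs(idx[i] - idx[j]) >= min_gap for j in kept):
            kept.append(i)
    return np.sort(idx[kept])


def detect_r_peaks(
    processed: ProcessedSignal, params: DetectionParams | None = None
) -> RPeakSet:
    """Amplitude-window R-peak detection on a preprocessed record.

    Candidates are strict local maxima of the QRS-band signal; those
    reaching ``window_fraction`` of its global maximum survive, the
    refractory rule keeps the larger of any close pair, and each peak is
    refined to the maximum of the corrected signal within
    ``refine_window`` seconds.

    Raises :class:`NoPeaksError` on a constant signal and warns
    (:class:`InsufficientBeatsWarning`) when fewer than three peaks
    remain.
    """
    p = params or DetectionParams()
    y = np.asarray(processed.qrs_emphasis, float)
    z = np.asarray(processed.corrected, float)
    fs = processed.fs
    if y.size == 0 or z.size == 0:
        raise NoPeaksError("empty signal")
    if np.ptp(y) == 0:
        raise NoPeaksError("constant signal has no peaks")

    cand = argrelextrema(y, np.greater, order=p.local_max_neighborhood)[0]
    if cand.size == 0:
        raise NoPeaksError("no local maxima found")
    m = float(y.max())
    cand = cand[y[cand] >= p.window_fraction * m]
    if cand.size == 0:
        raise NoPeaksError("no local maxima inside the amplitude window")

    kept = _refractory_filter(cand, y[cand], fs, p.refractory)

    # Refine each peak to the corrected-signal maximum nearby.
    half = int(round(p.refine_window * fs))
    refined = []
    for i in kept:
        lo, hi = max(0, i - half), min(z.size, i + half + 1)
        refined.append(lo + int(np.argmax(z[lo:hi])))
    refined = np.unique(refined)
    # Refinement can pull two peaks together; re-apply the refractory rule
    # so successive R times always respect it.
    refined = _refractory_filter(refined, z[refined], fs, p.refractory)

    if refined.size < 3:
        warnings.warn(
            f"only {refined.size} R peak(s) detected; HR/HRV unreliable",
            InsufficientBeatsWarning,
            stacklevel=2,
        )
    return RPeakSet(
        times=refined / fs,
        amplitudes=z[refined],
        indices=refined,
        fs=fs,
    )


def compute_rr_intervals(peaks: RPeakSet | np.ndarray) -> np.ndarray:
    """RR intervals (s): successive differences of the R-peak times."""
    times = peaks.times if isinstance(peaks, RPeakSet) else np.asarray(peaks, float)
    if times.size < 2:
        raise InsufficientDataError("need at least 2 R peaks for RR intervals")
    return np.diff(times)


def compute_hrv(rr: np.ndarray, sample: bool = True) -> float:
    """Standard deviation of the RR intervals, seconds (SDNN-style).

    Uses the n-1 (sample) estimator by default; ``sample=False`` gives
    the population variant.
    """
    rr = np.asarray(rr, float)
    if rr.size < 2:
        raise InsufficientDataError("need at least 2 RR intervals for HRV")
    return float(np.std(rr, ddof=1 if sample else 0))


def compute_hr(rr: np.ndarray) -> float:
    """Heart rate in bpm as 60 / mean(RR)."""
    rr = np.asarray(rr, float)
    if rr.size < 1:
        raise InsufficientDataError("need at least 1 RR interval for HR")
    return 60.0 / float(np.mean(rr))


def extract_features(
    record: ECGRecord,
    config: PipelineConfig | None = None,
    detection: DetectionParams | None = None,
    hr_method: str = "mean_rr",
) -> FeatureVector:
    """Full per-record chain: preprocess, detect peaks, compute HR and HRV.

    ``hr_method="mean_rr"`` (default) computes 60/mean(RR);
    ``"count"`` uses beats-per-record-duration instead, which is
    sensitive to partial beats at the record edges.
    """
    if hr_method not in ("mean_rr", "count"):
        raise ParameterError(f"unknown hr_method {hr_method!r}")
    processed = preprocess_ecg(record, config)
    peaks = detect_r_peaks(processed, detection)
    if peaks.n < 3:
        return FeatureVector(
            hr=float("nan"), hrv=float("nan"), n_beats=peaks.n,
            record_id=record.subject_id, valid=False,
        )
    rr = compute_rr_intervals(peaks)
    hrv = compute_hrv(rr)
    if hr_method == "count":
        hr = 60.0 * peaks.n / record.duration
    else:
        hr = compute_hr(rr)
    return FeatureVector(
        hr=hr, hrv=hrv, n_beats=peaks.n, record_id=record.subject_id, valid=True
    )


def score_detection(
    true_times: np.ndarray, detected_times: np.ndarray, tol: float = 0.020
) -> tuple[int, int, int]:
    """Match detected against ground-truth R times (one-to-one, greedy in
    time order, within ±``tol`` seconds).

    Returns (matched, missed, spurious); a record counts as perfectly
    detected when missed == spurious == 0.
    """
    true_times = np.asarray(true_times, float)
    det = np.asarray(detected_times, float)
    used = np.zeros(det.size, dtype=bool)
    matched = 0
    for t in true_times:
        err = np.abs(det - t)
        err[used] = np.inf
        if err.size and err.min() <= tol:
            used[int(np.argmin(err))] = True
            matched += 1
    missed = true_times.size - matched
    spurious = int((~used).sum())
    return matched, missed, spurious
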