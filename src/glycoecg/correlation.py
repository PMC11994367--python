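"""Pearson correlation of glucose with the ECG-derived features.

The profile mirrors the three-way structure used when screening features
against blood glucose: r(glucose, HR), r(glucose, HRV) and r(glucose,
HR/HRV). HRV falls with rising glucose while HR rises, so the HR/HRV
ratio amplifies both effects into a single positively-coupled index. A
multiple-correlation reading of "combined" (glucose regressed on HR and
HRV jointly) is also computed for comparison; the ratio is the reported
default.

Strength bands follow the conventional reading of |r|: below 0.30 low,
0.30-0.70 moderate, above 0.70 high.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, UndefinedCorrelationError
from .io import validate_cohort


def strength_label(r: float) -> str:
    """Conventional |r| band: low < 0.30 <= moderate <= 0.70 < high."""
    a = abs(r)
    if a < 0.30:
        return "low"
    if a <= 0.70:
        return "moderate"
    return "high"


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient r = S_xy / (S_x * S_y).

    Computed by direct summation of centered products; S_x and S_y are
    the standard deviations. Raises
    :class:`UndefinedCorrelationError` when either array is constant.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise InsufficientDataError("need at least 3 pairs for a correlation")
    xm = x - x.mean()
    ym = y - y.mean()
    sx = np.sqrt(np.dot(xm, xm))
    sy = np.sqrt(np.dot(ym, ym))
    if sx == 0 or sy == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant array")
    r = float(np.dot(xm, ym) / (sx * sy))
    return min(1.0, max(-1.0, r))


def multiple_correlation(y: np.ndarray, x1: np.ndarray, x2: np.ndarray) -> float:
    """Multiple correlation R of y on (x1, x2): sqrt of the OLS R^2."""
    y = np.asarray(y, float)
    design = np.column_stack([np.ones_like(y), x1, x2])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise UndefinedCorrelationError("constant response")
    return float(np.sqrt(max(0.0, 1.0 - np.sum(resid**2) / ss_tot)))


@dataclass
class CorrelationProfile:
    """Glucose-vs-feature correlation summary for one cohort."""

    r_hr: float
    r_hrv: float
    r_ratio: float
    r_multiple: float
    n: int
    n_ratio_excluded: int

    @property
    def strengths(self) -> dict[str, str]:
        return {
            "hr": strength_label(self.r_hr),
            "hrv": strength_label(self.r_hrv),
            "ratio": strength_label(self.r_ratio),
        }

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "r_hr": self.r_hr,
            "r_hrv": self.r_hrv,
            "r_hr_over_hrv": self.r_ratio,
            "r_multiple": self.r_multiple,
            "n_ratio_excluded": self.n_ratio_excluded,
            "strengths": self.strengths,
        }


def correlation_profile(table: pd.DataFrame) -> CorrelationProfile:
    """Correlate glucose with HR, HRV and the elementwise HR/HRV ratio.

    Rows with HRV = 0 are excluded from the ratio correlation (the ratio
    is undefined there); their count is reported.
    """
    validate_cohort(table, for_analysis=True)
    if len(table) < 3:
        raise InsufficientDataError("need at least 3 complete rows")
    g = table["glucose_mg_dl"].to_numpy(float)
    hr = table["hr_bpm"].to_numpy(float)
    hrv = table["hrv_s"].to_numpy(float)

    nonzero = hrv > 0
    n_excluded = int((~nonzero).sum())
    if nonzero.sum() < 3:
        raise InsufficientDataError("fewer than 3 rows with nonzero HRV for the ratio")
    return CorrelationProfile(
        r_hr=pearson_r(g, hr),
        r_hrv=pearson_r(g, hrv),
        r_ratio=pearson_r(g[nonzero], hr[nonzero] / hrv[nonzero]),
        r_multiple=multiple_correlation(g, hr, hrv),
        n=len(table),
        n_ratio_excluded=n_excluded,
    )
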