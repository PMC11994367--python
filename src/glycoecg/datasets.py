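"""Bundled example data.

An 11-record sample of per-subject measurements (glucose 80-500 mg/dL
with DWT-derived HR and HRV) used throughout the tests and the README
worked example. The rows span the full glycemic range — normoglycemic
subjects with large RR dispersion down to severe hyperglycemia with
dispersion of a few milliseconds — so the expected correlation sign
pattern (HR up, HRV down with glucose) is visible even at n=11.
"""

from __future__ import annotations

import pandas as pd

from .io import COHORT_COLUMNS

_EXAMPLE_ROWS = [
    # (subject_id, glucose mg/dL, HR bpm, HRV s)
    ("S01", 90, 71.33, 0.044035),
    ("S02", 109, 71.76, 0.024101),
    ("S03", 101, 74.278, 0.02682),
    ("S04", 151, 82.799, 0.009005),
    ("S05", 80, 53.881, 0.057756),
    ("S06", 162, 68.265, 0.018142),
    ("S07", 116, 64.043, 0.04764),
    ("S08", 500, 101.62, 0.0042798),
    ("S09", 182, 85.505, 0.0125568),
    ("S10", 291, 73.77, 0.0068605),
    ("S11", 183, 60.69, 0.017971),
]


def load_example_cohort() -> pd.DataFrame:
    """The bundled 11-row example cohort (diagnosis unknown)."""
    table = pd.DataFrame(
        [(s, g, hr, hrv, "unknown") for s, g, hr, hrv in _EXAMPLE_ROWS],
        columns=list(COHORT_COLUMNS),
    )
    table["glucose_mg_dl"] = table["glucose_mg_dl"].astype(float)
    return table
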