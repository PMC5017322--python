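"""Analysis configuration: detection and metric knobs, YAML-loadable.

YAML schema (all keys optional, defaults shown)::

    detection:
      lowpass_hz: 10.0          # zero-phase low-pass cutoff for peak picking; null disables
      filter_order: 4
      min_peak_spacing_s: 0.25  # caps cadence at 240 steps/min
      prominence_factor: 0.5    # peak prominence >= factor * SD of windowed AP
    ml_abs: true                # report |step-lag extremum| for the ML axis
    demean: true                # zero-mean windowed signals before RMS/autocorrelation
    symmetry_cap_pct: 999.0     # reporting cap on the symmetry ratio
    icc_variant: consistency    # or "agreement"
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class DetectionConfig:
    lowpass_hz: float | None = 10.0
    filter_order: int = 4
    min_peak_spacing_s: float = 0.25
    prominence_factor: float = 0.5


@dataclass
class AnalysisConfig:
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    ml_abs: bool = True
    demean: bool = True
    symmetry_cap_pct: float = 999.0
    icc_variant: str = "consistency"


def load_config(path=None) -> AnalysisConfig:
    """Build an AnalysisConfig from a YAML file; defaults where absent."""
    cfg = AnalysisConfig()
    if path is None:
        return cfg
    data = yaml.safe_load(Path(path).read_text()) or {}
    det = data.pop("detection", {}) or {}
    valid_det = {f.name for f in fields(DetectionConfig)}
    for key, val in det.items():
        if key not in valid_det:
            raise KeyError(f"unknown detection config key {key!r}")
        setattr(cfg.detection, key, val)
    valid = {f.name for f in fields(AnalysisConfig)} - {"detection"}
    for key, val in data.items():
        if key not in valid:
            raise KeyError(f"unknown config key {key!r}")
        setattr(cfg, key, val)
    return cfg
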