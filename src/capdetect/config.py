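"""YAML-backed run configuration.

A single YAML file can override any of the detection constants; keys mirror
the dataclass fields of the individual modules.  Defaults everywhere are the
published constants (90-s epochs, 30-s step, 1.5x RMS, 1.6x variability,
1-s merge gap, band edges 0.3-4.5 / 7-25 Hz, 13 +/- 2 Hz sigma stop band).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .detect_local import DetectorConfig
from .detect_multitrace import MultiTraceConfig
from .preprocess import FilterBankConfig
from .synthetic import SimConfig


@dataclass
class RunConfig:
    filters: FilterBankConfig = field(default_factory=FilterBankConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    multitrace: MultiTraceConfig = field(default_factory=MultiTraceConfig)
    simulation: SimConfig = field(default_factory=SimConfig)
    min_overlap_s: int = 1   # TP matching criterion


def _build(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name in data:
            v = data[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) and f.name != "stage_plan" else v
    return cls(**kwargs)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a RunConfig from YAML; a missing path yields all defaults."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig(
        filters=_build(FilterBankConfig, data.get("filters", {})),
        detector=_build(DetectorConfig, data.get("detector", {})),
        multitrace=_build(MultiTraceConfig, data.get("multitrace", {})),
        simulation=_build(SimConfig, data.get("simulation", {})),
    )
    if "min_overlap_s" in data:
        cfg.min_overlap_s = int(data["min_overlap_s"])
    return cfg
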