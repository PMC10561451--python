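"""Run configuration: nested sections, strict validation, provenance hash.

A run config has one section per pipeline stage plus a global seed and
output directory.  Unknown keys — at the top level or inside any section —
are rejected before any compute, and every output file written by the
pipeline carries the config hash in its provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import yaml

from fociscreen.cell_classify import CellClassifier
from fociscreen.foci_quant import FociDetector
from fociscreen.segmentation import NucleusSegmenter
from fociscreen.synthdata import FociDoseModel, ScreenDesign, SimConfig

__all__ = ["RunConfig", "load_config"]

_SECTION_KEYS = {
    "synthdata": {f.name for f in dataclasses.fields(SimConfig)},
    "dose_model": {f.name for f in dataclasses.fields(FociDoseModel)},
    "screen": {f.name for f in dataclasses.fields(ScreenDesign)}
    | {"n_select", "readout"},
    "segmentation": set(NucleusSegmenter().get_params())
    | {"crop_size", "exclude_border"},
    "foci": set(FociDetector().get_params()),
    "classifier": set(CellClassifier().get_params())
    | {"positivity_threshold", "n_train", "n_val"},
    "pipeline": {"mode", "n_fields_per_well"},
}


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "results"
    synthdata: dict = dc_field(default_factory=dict)
    dose_model: dict = dc_field(default_factory=dict)
    screen: dict = dc_field(default_factory=dict)
    segmentation: dict = dc_field(default_factory=dict)
    foci: dict = dc_field(default_factory=dict)
    classifier: dict = dc_field(default_factory=dict)
    pipeline: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        for section, allowed in _SECTION_KEYS.items():
            values = getattr(self, section)
            if not isinstance(values, dict):
                raise ValueError(f"section {section!r} must be a mapping")
            unknown = sorted(set(values) - allowed)
            if unknown:
                raise ValueError(
                    f"unknown keys in section {section!r}: {unknown}"
                )

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown top-level config keys: {unknown}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        # outdir is a delivery detail, not part of scientific provenance
        payload = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    # section expansions -------------------------------------------------
    def sim_config(self) -> SimConfig:
        raw = dict(self.synthdata)
        for key in ("image_size", "nucleus_brightness_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return SimConfig(**raw)

    def dose_model_obj(self) -> FociDoseModel:
        return FociDoseModel(**self.dose_model)

    def screen_design(self) -> ScreenDesign:
        raw = {
            k: v for k, v in self.screen.items() if k not in ("n_select", "readout")
        }
        return ScreenDesign(**raw)

    @property
    def n_select(self) -> int:
        return int(self.screen.get("n_select", 12))

    @property
    def readout(self) -> str:
        readout = self.screen.get("readout", "pct_positive")
        if readout not in ("pct_positive", "foci_per_cell"):
            raise ValueError(f"unknown readout {readout!r}")
        return readout


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)
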