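"""File formats: two-page field TIFFs, truth tables, plate layouts.

Field files follow the documented filename convention
``{plate}_{well}_{field:02d}.tif`` — a 16-bit multi-page TIFF with page 1
the nuclear channel and page 2 the green channel.  Ground truth is a CSV
(one row per cell) plus a JSON sidecar holding the planted foci lists.
Plate layouts are CSVs with columns
``plate, well, role, compound_id, dose_uM, duration_h[, effect_e]``.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from fociscreen.synthdata import FieldImage, GroundTruthField

__all__ = [
    "field_filename",
    "write_field_tiff",
    "read_field_tiff",
    "write_truth",
    "parse_plate_layout",
]

LAYOUT_COLUMNS = ("plate", "well", "role", "compound_id", "dose_uM", "duration_h")
VALID_ROLES = ("control", "dox", "compound", "reference")


def field_filename(plate: str, well: str, field: int) -> str:
    return f"{plate}_{well}_{field:02d}.tif"


def write_field_tiff(field: FieldImage, directory: str | Path) -> Path:
    """Write one field as a 2-page 16-bit TIFF (nuclear page first)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / field_filename(field.plate, field.well, field.field)
    stack = np.stack([field.nuclear, field.green]).astype(np.uint16)
    tifffile.imwrite(path, stack)
    return path


_FIELD_RE = re.compile(r"^(?P<plate>.+)_(?P<well>[^_]+)_(?P<field>\d+)\.tiff?$")


def read_field_tiff(path: str | Path) -> FieldImage:
    """Read a 2-page 16-bit field TIFF; identity parsed from the filename."""
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim != 3 or pages.shape[0] != 2:
        n = pages.shape[0] if pages.ndim == 3 else 1
        raise ValueError(
            f"{path.name}: expected a 2-page TIFF (nuclear, green); got {n} page(s)"
        )
    if pages.dtype != np.uint16:
        raise ValueError(f"{path.name}: expected 16-bit pages, got {pages.dtype}")
    m = _FIELD_RE.match(path.name)
    if not m:
        raise ValueError(
            f"{path.name}: filename does not follow plate_well_field.tif"
        )
    return FieldImage(
        nuclear=pages[0],
        green=pages[1],
        plate=m["plate"],
        well=m["well"],
        field=int(m["field"]),
    )


def write_truth(truth: GroundTruthField, directory: str | Path) -> tuple[Path, Path]:
    """Write a field's ground truth as CSV + JSON foci sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{truth.plate}_{truth.well}_{truth.field:02d}"
    csv_path = directory / f"{stem}_truth.csv"
    json_path = directory / f"{stem}_foci.json"
    truth.to_frame().to_csv(csv_path, index=False)
    json_path.write_text(json.dumps(truth.foci_sidecar(), indent=1, sort_keys=True))
    return csv_path, json_path


def _parse_dose(value) -> float:
    """Accept plain numbers or strings with a 'uM'/'µM' suffix."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    s = str(value).strip()
    s = re.sub(r"(uM|µM|um)$", "", s, flags=re.IGNORECASE).strip()
    try:
        return float(s)
    except ValueError as exc:
        raise ValueError(f"cannot parse dose {value!r} as micromolar") from exc


def parse_plate_layout(path: str | Path) -> pd.DataFrame:
    """Read and validate a plate-layout CSV.

    Every plate must carry at least one control and one DOX well; duplicate
    (plate, well) pairs and unknown roles are rejected.
    """
    layout = pd.read_csv(path, dtype={"plate": str, "well": str, "compound_id": str})
    missing = [c for c in LAYOUT_COLUMNS if c not in layout.columns]
    if missing:
        raise ValueError(f"layout is missing columns {missing}")
    layout["compound_id"] = layout["compound_id"].fillna("")
    bad_roles = sorted(set(layout["role"]) - set(VALID_ROLES))
    if bad_roles:
        raise ValueError(f"unknown roles {bad_roles}; expected one of {VALID_ROLES}")
    dupes = layout.duplicated(subset=["plate", "well"])
    if dupes.any():
        pairs = layout.loc[dupes, ["plate", "well"]].to_records(index=False).tolist()
        raise ValueError(f"duplicate wells in layout: {pairs}")
    layout["dose_uM"] = layout["dose_uM"].map(_parse_dose)
    layout["duration_h"] = layout["duration_h"].astype(float)
    if "effect_e" not in layout.columns:
        layout["effect_e"] = 0.0
    offenders = []
    for plate, grp in layout.groupby("plate"):
        roles = set(grp["role"])
        if "control" not in roles or "dox" not in roles:
            offenders.append(plate)
    if offenders:
        raise ValueError(
            f"plates missing a control or DOX well: {sorted(offenders)}"
        )
    return layout
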