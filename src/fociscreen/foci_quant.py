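"""Threshold-based ("traditional") foci recognition and foci-per-cell counts.

This is the granularity-style analysis: a white top-hat isolates bright
structures smaller than the structuring element, a robust (median/MAD)
threshold inside the nucleus picks candidate pixels, and local maxima with a
minimal separation become foci.  Robust statistics are used so bright foci
do not inflate their own detection threshold.

Crops flagged ``low_dynamic_range`` (flat green, typically non-signaling
cells) are returned as ``not_evaluable`` rather than zero-foci: whether a
cell belongs in the denominator is the classifier's decision, not the
counter's.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.feature import peak_local_max
from skimage.morphology import disk, white_tophat
from sklearn.base import BaseEstimator

from fociscreen.segmentation import CellCrop

__all__ = ["Focus", "FociDetection", "FociDetector", "detect_foci", "foci_per_cell"]


@dataclass(frozen=True)
class Focus:
    center: tuple[int, int]  # integer pixel maximum (row, col)
    prominence: float  # top-hat height above the intranuclear median
    equivalent_diameter: float  # of the connected candidate region


@dataclass
class FociDetection:
    foci: list[Focus] = dc_field(default_factory=list)
    not_evaluable: bool = False

    @property
    def foci_count(self) -> int:
        return len(self.foci)


class FociDetector(BaseEstimator):
    """Granularity-style spot detector (estimator-shaped; stateless fit).

    Parameters
    ----------
    d_min, d_max : expected focus diameter range (px).
    tophat_radius : structuring-disk radius for the white top-hat;
        defaults to ``ceil(d_max / 2)``.
    detection_k : threshold in robust-SD units (1.4826 * MAD) above the
        intranuclear top-hat median.
    min_separation : minimal center distance between detected maxima (px).
    min_prominence : absolute floor (normalized units) a candidate must
        clear; guards the noise-free limit where the MAD collapses to 0.
    """

    def __init__(
        self,
        d_min: int = 3,
        d_max: int = 9,
        tophat_radius: int | None = None,
        detection_k: float = 4.0,
        min_separation: int = 3,
        min_prominence: float = 0.05,
    ) -> None:
        self.d_min = d_min
        self.d_max = d_max
        self.tophat_radius = tophat_radius
        self.detection_k = detection_k
        self.min_separation = min_separation
        self.min_prominence = min_prominence

    def fit(self, X=None, y=None) -> "FociDetector":
        self.fitted_ = True
        return self

    def _validate(self) -> int:
        if self.d_min < 1 or self.d_min > self.d_max:
            raise ValueError("need 1 <= d_min <= d_max")
        if self.detection_k <= 0:
            raise ValueError("detection_k must be > 0")
        radius = (
            self.tophat_radius
            if self.tophat_radius is not None
            else int(np.ceil(self.d_max / 2))
        )
        if radius < 1:
            raise ValueError("tophat_radius must be >= 1")
        return radius

    def detect(self, crop: CellCrop) -> FociDetection:
        """Detect foci on the normalized green channel of one crop.

        Deterministic for fixed input and parameters; focus centers are
        integer pixel maxima with ties resolved by the (fixed) processing
        order of ``peak_local_max``.
        """
        radius = self._validate()
        if crop.green_norm is None:
            raise ValueError("crop must be normalized before foci detection")
        if crop.low_dynamic_range:
            return FociDetection(foci=[], not_evaluable=True)
        mask = crop.mask
        # fill outside-nucleus pixels with the intranuclear median so the
        # top-hat sees no step at the mask boundary (no rim artifacts)
        inside_med = float(np.median(crop.green_norm[mask]))
        work = np.where(mask, crop.green_norm, inside_med)
        th = white_tophat(work, footprint=disk(radius))
        vals = th[mask]
        med = float(np.median(vals))
        mad = float(np.median(np.abs(vals - med)))
        thr = med + self.detection_k * 1.4826 * mad
        candidates = (th > thr) & (th >= med + self.min_prominence) & mask
        if not candidates.any():
            return FociDetection(foci=[])
        regions, _ = ndi.label(candidates)
        areas = np.bincount(regions.ravel())
        # a bright focus can clip at the normalization ceiling into a flat
        # plateau; light smoothing turns each plateau into a single maximum
        peaks_img = ndi.gaussian_filter(th, max(self.d_min / 3.0, 0.8))
        coords = peak_local_max(
            peaks_img,
            min_distance=max(int(self.min_separation), 1),
            exclude_border=False,
            labels=regions,
        )
        foci = []
        for r, c in coords:
            if not candidates[r, c]:
                continue
            area = areas[regions[r, c]]
            foci.append(
                Focus(
                    center=(int(r), int(c)),
                    prominence=float(th[r, c] - med),
                    equivalent_diameter=float(2.0 * np.sqrt(area / np.pi)),
                )
            )
        return FociDetection(foci=foci)

    def detect_many(self, crops: list[CellCrop]) -> pd.DataFrame:
        """Per-cell results table for a list of crops."""
        rows = []
        for crop in crops:
            det = self.detect(crop)
            rows.append(
                {
                    "plate": crop.plate,
                    "well": crop.well,
                    "field": crop.field,
                    "cell_id": crop.cell_id,
                    "foci_count": det.foci_count,
                    "not_evaluable": det.not_evaluable,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["plate", "well", "field", "cell_id", "foci_count", "not_evaluable"],
        )


def detect_foci(crop: CellCrop, params: dict | None = None) -> FociDetection:
    """Functional wrapper over :class:`FociDetector`."""
    return FociDetector(**(params or {})).detect(crop)


def foci_per_cell(records: pd.DataFrame) -> pd.DataFrame:
    """Per-well mean foci per cell over evaluable cells.

    ``records`` needs columns plate, well, foci_count, not_evaluable.
    Returns one row per (plate, well) with ``mean_foci_per_cell`` (NaN with
    ``missing=True`` when a well has zero evaluable cells — never reported
    as 0), ``n_evaluable`` and ``n_cells``.
    """
    required = {"plate", "well", "foci_count", "not_evaluable"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    out = []
    for (plate, well), grp in records.groupby(["plate", "well"], sort=True):
        ok = grp[~grp["not_evaluable"].astype(bool)]
        n_eval = len(ok)
        mean = float(ok["foci_count"].mean()) if n_eval else float("nan")
        out.append(
            {
                "plate": plate,
                "well": well,
                "mean_foci_per_cell": mean,
                "n_evaluable": n_eval,
                "n_cells": len(grp),
                "missing": n_eval == 0,
            }
        )
    return pd.DataFrame(
        out,
        columns=["plate", "well", "mean_foci_per_cell", "n_evaluable", "n_cells", "missing"],
    )
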