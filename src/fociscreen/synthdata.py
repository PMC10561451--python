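"""Synthetic two-channel fluorescence fields, wells and whole screens.

Emulates the imaging regime of an EGFP-53BP1 reporter cardiomyocyte assay:
a nuclear-stain channel ("DAPI channel") with strong nucleus-to-nucleus
brightness variation, and a green reporter channel ("FITC channel") in which
signaling cells show diffuse intranuclear fluorescence plus Gaussian damage
foci, while a fraction of cells express no reporter at all (non-signaling).
Foci counts follow a saturating dose law with per-cell Poisson variation, so
doxorubicin (DOX) dose/duration trends and compound rescue effects are
reproducible with exact ground truth.

Every output is a pure function of (config, treatment/design, seed).  Seeds
for plates, wells and fields are derived from the top-level seed with
``numpy.random.SeedSequence.spawn`` (a deterministic counter scheme).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from fociscreen.cell_classify import label_truth

__all__ = [
    "SimConfig",
    "FociDoseModel",
    "Treatment",
    "ScreenDesign",
    "FieldImage",
    "TrueCell",
    "GroundTruthField",
    "generate_field",
    "generate_well",
    "simulate_screen",
    "make_single_cell_crops",
    "make_planted_crop",
]

#: Default DOX concentration (uM) of the damage-model wells and default
#: compound co-treatment concentration (uM) in a screen.
DOX_MODEL_DOSE_UM = 0.5
COMPOUND_DOSE_UM = 50.0


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters for one imaged field.

    Intensities are linear camera counts; images are clipped to
    ``[0, 2**bit_depth - 1]`` and stored as unsigned integers.
    """

    image_size: tuple[int, int] = (1024, 1024)
    pixel_scale_um: float = 0.325  # metadata only (40x objective regime)
    cells_per_field: float = 80.0  # Poisson mean
    nucleus_radius_mean: float = 14.0  # px
    nucleus_radius_sd: float = 2.0
    #: multiplicative per-nucleus gain interval for the nuclear channel;
    #: wide by default to reproduce strong Hoechst-brightness variation.
    nucleus_brightness_range: tuple[float, float] = (0.3, 1.0)
    nucleus_base_intensity: float = 3000.0  # counts at gain 1
    #: per-cell green gain: point mass at 0 with prob. p_nonsignal, else
    #: log-normal with this median and log-sd.
    p_nonsignal: float = 0.1
    expression_median_gain: float = 1.0
    expression_sigma_log: float = 0.5
    green_diffuse_level: float = 600.0  # counts at gain 1 inside the nucleus
    focus_amplitude: float = 4.0  # peak rel. to the cell's diffuse green
    focus_sigma: float = 1.5  # px
    #: minimal center-to-center distance between planted foci (px);
    #: 0 disables the constraint (realistic clustering allowed).
    min_focus_separation: float = 0.0
    background_level: float = 100.0
    read_noise_sd: float = 5.0
    photon_noise: bool = True
    #: fractional amplitude of a low-order background gradient (stress case).
    background_gradient: float = 0.0
    #: generate tangent nucleus pairs to stress watershed splitting.
    touching_pairs: bool = False
    allow_border_cells: bool = False
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_nonsignal <= 1.0:
            raise ValueError(f"p_nonsignal must be in [0, 1], got {self.p_nonsignal}")
        lo, hi = self.nucleus_brightness_range
        if not (0.0 < lo <= hi):
            raise ValueError("nucleus_brightness_range must satisfy 0 < lo <= hi")
        if self.expression_median_gain <= 0:
            raise ValueError("expression_median_gain must be > 0")
        if self.focus_sigma <= 0:
            raise ValueError("focus_sigma must be > 0")
        if self.cells_per_field < 0:
            raise ValueError("cells_per_field must be >= 0")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError("bit_depth must be one of 8, 12, 16")

    @property
    def max_count(self) -> int:
        return 2**self.bit_depth - 1


@dataclass(frozen=True)
class FociDoseModel:
    """Saturating foci-vs-dose law with Poisson per-cell counts.

    Mean foci per cell: ``lambda0 + (1 - e) * f_dur * delta(dose)`` with
    ``delta(dose) = (lambda_max - lambda0) * dose / (dose + ec50_dose)``.
    ``e`` is a compound's fractional rescue of the DOX-induced increment
    (0 = inactive, 1 = full rescue); ``f_dur`` is ``duration_factor`` for
    long (>= 24 h) treatments and 1 otherwise.  ``delta`` is nondecreasing
    in dose and the mean is nonincreasing in ``e`` at fixed dose.
    """

    lambda0: float = 0.5  # baseline foci per signaling cell, untreated
    lambda_max: float = 12.0  # saturating mean under DOX
    ec50_dose: float = 0.3  # uM DOX at half effect
    duration_factor: float = 1.4  # long-treatment multiplier

    def __post_init__(self) -> None:
        if self.lambda0 < 0 or self.lambda_max < self.lambda0:
            raise ValueError("need 0 <= lambda0 <= lambda_max")
        if self.ec50_dose <= 0:
            raise ValueError("ec50_dose must be > 0")

    def delta(self, dose: float) -> float:
        return (self.lambda_max - self.lambda0) * dose / (dose + self.ec50_dose)

    def mean_foci(self, dose: float, effect: float = 0.0, duration_h: float = 1.0) -> float:
        if dose < 0:
            raise ValueError("dose must be >= 0")
        if not 0.0 <= effect <= 1.0:
            raise ValueError("compound effect must be in [0, 1]")
        f_dur = self.duration_factor if duration_h >= 24.0 else 1.0
        return self.lambda0 + (1.0 - effect) * f_dur * self.delta(dose)


@dataclass(frozen=True)
class Treatment:
    """Treatment of one well: DOX dose, duration and compound rescue effect."""

    dose_uM: float = 0.0
    duration_h: float = 1.0
    effect: float = 0.0
    compound_id: str | None = None
    role: str = "control"  # control | dox | compound | reference


@dataclass(frozen=True)
class ScreenDesign:
    """Plate design of a primary screen.

    Each plate carries control and DOX wells plus compound wells (compound
    at 50 uM co-incubated with 0.5 uM DOX for 1 h); every compound is
    replicated ``n_replicates`` times across independent plate sets.
    """

    n_compounds: int = 315
    n_replicates: int = 3
    wells_per_plate: int = 96
    controls_per_plate: int = 4
    dox_per_plate: int = 4
    dox_dose_uM: float = DOX_MODEL_DOSE_UM
    compound_dose_uM: float = COMPOUND_DOSE_UM
    duration_h: float = 1.0
    cells_per_well: float = 200.0  # Poisson mean, fast mode
    #: compound_id -> true fractional effect e in [0, 1]; compounds absent
    #: from the table are inactive (e = 0).
    true_effects: dict[str, float] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.controls_per_plate < 1 or self.dox_per_plate < 1:
            raise ValueError("every plate needs >= 1 control and >= 1 DOX well")
        if self.compound_wells_per_plate < 1:
            raise ValueError("plate geometry leaves no compound wells")
        for cid, e in self.true_effects.items():
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"effect for {cid} must be in [0, 1], got {e}")

    @property
    def compound_wells_per_plate(self) -> int:
        return self.wells_per_plate - self.controls_per_plate - self.dox_per_plate

    @property
    def compound_ids(self) -> list[str]:
        width = len(str(self.n_compounds))
        return [f"C{i + 1:0{width}d}" for i in range(self.n_compounds)]


@dataclass
class FieldImage:
    """One imaged field: co-registered nuclear and green intensity grids."""

    nuclear: np.ndarray  # uint16, page 1
    green: np.ndarray  # uint16, page 2
    plate: str = "P1"
    well: str = "A01"
    field: int = 0

    def __post_init__(self) -> None:
        if self.nuclear.shape != self.green.shape:
            raise ValueError("channel grids must share a shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.nuclear.shape


@dataclass
class TrueCell:
    """Ground-truth record of one rendered cell."""

    cell_id: int
    centroid: tuple[float, float]  # (row, col), 0-based
    radius: float
    nucleus_gain: float
    expression_gain: float
    #: (row, col, amplitude, sigma) per planted focus; non-signaling cells
    #: keep their drawn foci for bookkeeping but render no green signal.
    foci: list[tuple[float, float, float, float]]
    true_class: str

    @property
    def foci_count(self) -> int:
        return len(self.foci)


@dataclass
class GroundTruthField:
    cells: list[TrueCell]
    plate: str
    well: str
    field: int
    seed: int
    treatment: Treatment

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "plate": self.plate,
                "well": self.well,
                "field": self.field,
                "cell_id": c.cell_id,
                "row": c.centroid[0],
                "col": c.centroid[1],
                "radius": c.radius,
                "nucleus_gain": c.nucleus_gain,
                "expression_gain": c.expression_gain,
                "foci_count": c.foci_count,
                "true_class": c.true_class,
            }
            for c in self.cells
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "plate", "well", "field", "cell_id", "row", "col", "radius",
                "nucleus_gain", "expression_gain", "foci_count", "true_class",
            ],
        )

    def foci_sidecar(self) -> dict:
        return {
            "plate": self.plate,
            "well": self.well,
            "field": self.field,
            "seed": self.seed,
            "foci": {
                str(c.cell_id): [list(f) for f in c.foci] for c in self.cells
            },
        }


class PlacementError(RuntimeError):
    """Raised when non-overlapping nucleus placement fails (field too dense)."""


def _derive_seed(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1, dtype=np.uint32)[0])


def _place_nuclei(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    config: SimConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping nucleus centers and radii.

    Returns (centers[n, 2], radii[n]).  When ``config.touching_pairs`` is
    set, cells are placed as tangent pairs to exercise watershed splitting.
    """
    h, w = shape
    radii = np.clip(
        rng.normal(config.nucleus_radius_mean, config.nucleus_radius_sd, size=n),
        5.0,
        None,
    )
    centers: list[np.ndarray] = []
    placed_r: list[float] = []
    min_sep = 3.0
    max_attempts = 300 * max(n, 1)
    attempts = 0
    i = 0
    while i < n:
        r = radii[i]
        margin = 2.0 if config.allow_border_cells else r + 2.0
        if h - 2 * margin <= 1 or w - 2 * margin <= 1:
            raise PlacementError(
                f"field {shape} too small for nucleus radius {r:.1f}"
            )
        attempts += 1
        if attempts > max_attempts:
            raise PlacementError(
                f"could not place {n} non-overlapping nuclei of mean radius "
                f"{config.nucleus_radius_mean:.1f} px in a {h}x{w} field after "
                f"{max_attempts} attempts; reduce cells_per_field"
            )
        c = np.array(
            [rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)]
        )
        ok = True
        for cj, rj in zip(centers, placed_r):
            if np.hypot(*(c - cj)) < r + rj + min_sep:
                ok = False
                break
        if not ok:
            continue
        if config.touching_pairs and i + 1 < n:
            # place the partner tangent to this nucleus
            r2 = radii[i + 1]
            for _ in range(50):
                theta = rng.uniform(0, 2 * np.pi)
                c2 = c + (r + r2) * np.array([np.sin(theta), np.cos(theta)])
                m2 = 2.0 if config.allow_border_cells else r2 + 2.0
                if not (m2 <= c2[0] <= h - m2 and m2 <= c2[1] <= w - m2):
                    continue
                if all(
                    np.hypot(*(c2 - cj)) >= r2 + rj + min_sep
                    for cj, rj in zip(centers, placed_r)
                ):
                    centers.extend([c, c2])
                    placed_r.extend([r, r2])
                    i += 2
                    break
            else:
                continue
        else:
            centers.append(c)
            placed_r.append(r)
            i += 1
    if not centers:
        return np.zeros((0, 2)), np.zeros(0)
    return np.asarray(centers), np.asarray(placed_r)


def _sample_foci_positions(
    rng: np.random.Generator,
    k: int,
    radius: float,
    config: SimConfig,
) -> np.ndarray:
    """Uniform positions in the nucleus disc (with a margin for the spot
    width), optionally enforcing a minimal pairwise separation."""
    r_eff = max(radius - max(2.0, 2.0 * config.focus_sigma), 1.0)
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < k and attempts < 200 * max(k, 1):
        attempts += 1
        rho = r_eff * np.sqrt(rng.uniform())
        theta = rng.uniform(0, 2 * np.pi)
        p = rho * np.array([np.sin(theta), np.cos(theta)])
        if config.min_focus_separation > 0 and any(
            np.hypot(*(p - q)) < config.min_focus_separation for q in pts
        ):
            continue
        pts.append(p)
    return np.asarray(pts) if pts else np.zeros((0, 2))


def _render_cells(
    shape: tuple[int, int],
    cells: list[TrueCell],
    config: SimConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Render noise-free nuclear and green photon-rate grids."""
    nuc = np.zeros(shape, dtype=np.float64)
    grn = np.zeros(shape, dtype=np.float64)
    edge = 1.5  # px soft nuclear rim
    h, w = shape
    for c in cells:
        r0, c0 = c.centroid
        ext = int(np.ceil(c.radius + 4 * edge))
        rs = slice(max(int(r0) - ext, 0), min(int(r0) + ext + 1, h))
        cs = slice(max(int(c0) - ext, 0), min(int(c0) + ext + 1, w))
        yy, xx = np.mgrid[rs, cs]
        d = np.hypot(yy - r0, xx - c0)
        profile = 1.0 / (1.0 + np.exp((d - c.radius) / edge))
        nuc[rs, cs] += config.nucleus_base_intensity * c.nucleus_gain * profile
        if c.expression_gain > 0:
            diffuse = config.green_diffuse_level * c.expression_gain
            grn[rs, cs] += diffuse * profile
            for fr, fc, amp, sig in c.foci:
                fext = int(np.ceil(4 * sig))
                frs = slice(max(int(fr) - fext, 0), min(int(fr) + fext + 1, h))
                fcs = slice(max(int(fc) - fext, 0), min(int(fc) + fext + 1, w))
                fy, fx = np.mgrid[frs, fcs]
                grn[frs, fcs] += amp * np.exp(
                    -((fy - fr) ** 2 + (fx - fc) ** 2) / (2.0 * sig**2)
                )
    return nuc, grn


def _camera(
    rng: np.random.Generator, rate: np.ndarray, config: SimConfig
) -> np.ndarray:
    """Apply background, gradient, shot noise, read noise and quantization."""
    h, w = rate.shape
    bg = np.full_like(rate, config.background_level)
    if config.background_gradient > 0:
        gy = np.linspace(-1, 1, h)[:, None]
        gx = np.linspace(-1, 1, w)[None, :]
        bg *= 1.0 + config.background_gradient * 0.5 * (gy + gx)
    signal = rate + bg
    if config.photon_noise:
        signal = rng.poisson(np.clip(signal, 0, None)).astype(np.float64)
    if config.read_noise_sd > 0:
        signal = signal + rng.normal(0.0, config.read_noise_sd, size=signal.shape)
    return np.clip(np.round(signal), 0, config.max_count).astype(np.uint16)


def _draw_cells(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    config: SimConfig,
    treatment: Treatment,
    model: FociDoseModel,
    positivity_threshold: int,
) -> list[TrueCell]:
    centers, radii = _place_nuclei(rng, n, shape, config)
    mean_foci = model.mean_foci(treatment.dose_uM, treatment.effect, treatment.duration_h)
    lo, hi = config.nucleus_brightness_range
    cells: list[TrueCell] = []
    for i in range(n):
        nucleus_gain = rng.uniform(lo, hi)
        if rng.uniform() < config.p_nonsignal:
            expr = 0.0
        else:
            expr = config.expression_median_gain * np.exp(
                rng.normal(0.0, config.expression_sigma_log)
            )
        k = int(rng.poisson(mean_foci))
        pts = _sample_foci_positions(rng, k, radii[i], config)
        diffuse = config.green_diffuse_level * max(expr, 1e-12)
        foci = [
            (
                centers[i][0] + p[0],
                centers[i][1] + p[1],
                float(config.focus_amplitude * diffuse * rng.uniform(0.8, 1.2)),
                float(config.focus_sigma),
            )
            for p in pts
        ]
        cells.append(
            TrueCell(
                cell_id=i + 1,
                centroid=(float(centers[i][0]), float(centers[i][1])),
                radius=float(radii[i]),
                nucleus_gain=float(nucleus_gain),
                expression_gain=float(expr),
                foci=foci,
                true_class=label_truth(expr, len(pts), positivity_threshold),
            )
        )
    return cells


def generate_field(
    config: SimConfig,
    treatment: Treatment,
    seed: int,
    model: FociDoseModel | None = None,
    plate: str = "P1",
    well: str = "A01",
    field: int = 0,
    positivity_threshold: int = 5,
    n_cells: int | None = None,
) -> tuple[FieldImage, GroundTruthField]:
    """Render one two-channel field plus its complete ground truth.

    ``n_cells`` overrides the Poisson draw (useful for exact-count tests).
    Identical (config, treatment, seed) give bit-identical output.
    """
    model = model or FociDoseModel()
    rng = np.random.default_rng(seed)
    n = int(rng.poisson(config.cells_per_field)) if n_cells is None else int(n_cells)
    cells = _draw_cells(
        rng, n, config.image_size, config, treatment, model, positivity_threshold
    )
    nuc_rate, grn_rate = _render_cells(config.image_size, cells, config)
    img = FieldImage(
        nuclear=_camera(rng, nuc_rate, config),
        green=_camera(rng, grn_rate, config),
        plate=plate,
        well=well,
        field=field,
    )
    truth = GroundTruthField(
        cells=cells, plate=plate, well=well, field=field, seed=seed,
        treatment=treatment,
    )
    return img, truth


def generate_well(
    config: SimConfig,
    treatment: Treatment,
    n_fields: int,
    seed: int,
    model: FociDoseModel | None = None,
    plate: str = "P1",
    well: str = "A01",
    positivity_threshold: int = 5,
) -> list[tuple[FieldImage, GroundTruthField]]:
    """Render ``n_fields`` fields of one well with seeds spawned from the
    well seed."""
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_fields)
    return [
        generate_field(
            config,
            treatment,
            _derive_seed(children[i]),
            model=model,
            plate=plate,
            well=well,
            field=i,
            positivity_threshold=positivity_threshold,
        )
        for i in range(n_fields)
    ]


def _well_names(n: int) -> list[str]:
    rows = "ABCDEFGH"
    names = [f"{r}{c:02d}" for r in rows for c in range(1, 13)]
    if n > len(names):
        names = [f"W{i + 1:03d}" for i in range(n)]
    return names[:n]


def build_screen_layout(design: ScreenDesign) -> pd.DataFrame:
    """Expand a :class:`ScreenDesign` into one row per (replicate, plate,
    well) with roles, treatments and true effects."""
    for cid in design.true_effects:
        if cid not in set(design.compound_ids):
            raise ValueError(f"unknown compound in true-effects table: {cid!r}")
    rows = []
    per_plate = design.compound_wells_per_plate
    n_plates = int(np.ceil(design.n_compounds / per_plate))
    wells = _well_names(design.wells_per_plate)
    for rep in range(1, design.n_replicates + 1):
        for p in range(n_plates):
            plate = f"R{rep}P{p + 1:02d}"
            compounds = design.compound_ids[p * per_plate : (p + 1) * per_plate]
            iw = 0
            for _ in range(design.controls_per_plate):
                rows.append((rep, plate, wells[iw], "control", "", 0.0, design.duration_h, 0.0))
                iw += 1
            for _ in range(design.dox_per_plate):
                rows.append((rep, plate, wells[iw], "dox", "", design.dox_dose_uM, design.duration_h, 0.0))
                iw += 1
            for cid in compounds:
                e = float(design.true_effects.get(cid, 0.0))
                rows.append((rep, plate, wells[iw], "compound", cid, design.dox_dose_uM, design.duration_h, e))
                iw += 1
    return pd.DataFrame(
        rows,
        columns=["replicate", "plate", "well", "role", "compound_id", "dose_uM", "duration_h", "effect_e"],
    )


def simulate_screen(
    design: ScreenDesign,
    config: SimConfig,
    model: FociDoseModel,
    seed: int,
    mode: str = "fast",
    positivity_threshold: int = 5,
    n_fields_per_well: int = 1,
):
    """Simulate a whole primary screen.

    ``mode="fast"`` bypasses pixel rendering and emits per-well true cell
    records directly (the generator's statistical law, no imaging), so
    whole-screen statistics run in seconds.  ``mode="images"`` returns a
    generator of rendered wells for pipeline runs.  Returns
    ``(layout, cells_or_field_iter, true_effect_table, provenance)``.
    """
    if mode not in ("fast", "images"):
        raise ValueError(f"unknown mode {mode!r}")
    layout = build_screen_layout(design)
    effects = pd.DataFrame(
        {
            "compound_id": design.compound_ids,
            "effect_e": [float(design.true_effects.get(c, 0.0)) for c in design.compound_ids],
        }
    )
    provenance = {
        "mode": mode,
        "seed": int(seed),
        "n_compounds": design.n_compounds,
        "n_replicates": design.n_replicates,
        "positivity_threshold": int(positivity_threshold),
    }
    well_seqs = np.random.SeedSequence(seed).spawn(len(layout))

    if mode == "fast":
        records = []
        for idx, row in enumerate(layout.itertuples(index=False)):
            rng = np.random.default_rng(_derive_seed(well_seqs[idx]))
            n = int(rng.poisson(design.cells_per_well))
            mean = model.mean_foci(row.dose_uM, row.effect_e, row.duration_h)
            nonsig = rng.uniform(size=n) < config.p_nonsignal
            expr = np.where(
                nonsig,
                0.0,
                config.expression_median_gain
                * np.exp(rng.normal(0.0, config.expression_sigma_log, size=n)),
            )
            counts = rng.poisson(mean, size=n)
            for j in range(n):
                records.append(
                    (
                        row.replicate, row.plate, row.well, row.role,
                        row.compound_id, j + 1, float(expr[j]), int(counts[j]),
                        label_truth(float(expr[j]), int(counts[j]), positivity_threshold),
                    )
                )
        cells = pd.DataFrame(
            records,
            columns=[
                "replicate", "plate", "well", "role", "compound_id",
                "cell_id", "expression_gain", "foci_count", "true_class",
            ],
        )
        return layout, cells, effects, provenance

    def field_iter():
        for idx, row in enumerate(layout.itertuples(index=False)):
            treatment = Treatment(
                dose_uM=row.dose_uM,
                duration_h=row.duration_h,
                effect=row.effect_e,
                compound_id=row.compound_id or None,
                role=row.role,
            )
            yield row, generate_well(
                config,
                treatment,
                n_fields_per_well,
                _derive_seed(well_seqs[idx]),
                model=model,
                plate=row.plate,
                well=row.well,
                positivity_threshold=positivity_threshold,
            )

    return layout, field_iter(), effects, provenance


# ---------------------------------------------------------------------------
# single-cell crop factories (training/benchmark data with exact truth)
# ---------------------------------------------------------------------------

def make_single_cell_crops(
    n: int,
    config: SimConfig,
    seed: int,
    model: FociDoseModel | None = None,
    class_mix: tuple[float, float, float] = (0.2, 0.4, 0.4),
    crop_size: int = 64,
    positivity_threshold: int = 5,
):
    """Render ``n`` single-cell crops with exact truth labels.

    ``class_mix`` gives sampling weights for (non_signaling, foci_negative,
    foci_positive); foci counts are drawn from the dose law conditioned on
    the target class, and the returned label is always recomputed with
    :func:`label_truth` from the realized cell.  Returns
    ``(crops, labels, truth_cells)`` where crops are normalized
    :class:`~fociscreen.segmentation.CellCrop` objects built on the true
    nucleus mask.
    """
    from fociscreen.segmentation import CellCrop, normalize_crop

    model = model or FociDoseModel()
    rng = np.random.default_rng(seed)
    mix = np.asarray(class_mix, dtype=float)
    mix = mix / mix.sum()
    classes = ("non_signaling", "foci_negative", "foci_positive")
    mean_neg = model.mean_foci(0.0)
    mean_pos = model.mean_foci(DOX_MODEL_DOSE_UM)
    half = crop_size // 2
    field_size = crop_size + 32
    crops, labels, cells = [], [], []
    for i in range(n):
        target = classes[rng.choice(3, p=mix)]
        if target == "non_signaling":
            expr = 0.0
            k = int(rng.poisson(mean_pos if rng.uniform() < 0.5 else mean_neg))
        else:
            expr = config.expression_median_gain * np.exp(
                rng.normal(0.0, config.expression_sigma_log)
            )
            mean = mean_neg if target == "foci_negative" else mean_pos
            for _ in range(200):
                k = int(rng.poisson(mean))
                lab = label_truth(expr, k, positivity_threshold)
                if lab == target:
                    break
            else:  # force the boundary case
                k = positivity_threshold if target == "foci_positive" else 0
        radius = float(
            np.clip(rng.normal(config.nucleus_radius_mean, config.nucleus_radius_sd), 6.0, half - 4.0)
        )
        center = (field_size / 2.0, field_size / 2.0)
        pts = _sample_foci_positions(rng, k, radius, config)
        diffuse = config.green_diffuse_level * max(expr, 1e-12)
        foci = [
            (
                center[0] + p[0],
                center[1] + p[1],
                float(config.focus_amplitude * diffuse * rng.uniform(0.8, 1.2)),
                float(config.focus_sigma),
            )
            for p in pts
        ]
        cell = TrueCell(
            cell_id=i + 1,
            centroid=center,
            radius=radius,
            nucleus_gain=float(rng.uniform(*config.nucleus_brightness_range)),
            expression_gain=float(expr),
            foci=foci,
            true_class=label_truth(expr, len(foci), positivity_threshold),
        )
        nuc_rate, grn_rate = _render_cells((field_size, field_size), [cell], config)
        nuc = _camera(rng, nuc_rate, config)
        grn = _camera(rng, grn_rate, config)
        r0 = int(round(center[0])) - half
        c0 = int(round(center[1])) - half
        win = (slice(r0, r0 + crop_size), slice(c0, c0 + crop_size))
        yy, xx = np.mgrid[0:crop_size, 0:crop_size]
        mask = (
            np.hypot(yy + r0 - center[0], xx + c0 - center[1]) <= radius
        )
        crop = CellCrop(
            nuclear=nuc[win].astype(np.float64),
            green_raw=grn[win].astype(np.float64),
            mask=mask,
            plate="SIM",
            well="A01",
            field=0,
            cell_id=i + 1,
        )
        crops.append(normalize_crop(crop))
        labels.append(cell.true_class)
        cells.append(cell)
    return crops, labels, cells


def make_planted_crop(
    n_foci: int,
    seed: int,
    config: SimConfig | None = None,
    crop_size: int = 64,
    radius: float = 24.0,
    separation: float = 18.0,
    expression_gain: float = 1.0,
    noise: bool = True,
):
    """Single-cell benchmark crop with exactly ``n_foci`` planted foci kept
    at pairwise separation >= ``separation`` px (fewer are placed, and
    reported, if the disc cannot hold them).

    Returns ``(normalized CellCrop, truth TrueCell)``.  With ``noise=False``
    the camera applies no shot/read noise (exact-count regime).
    """
    from fociscreen.segmentation import CellCrop, normalize_crop

    base = config or SimConfig()
    cfg = dataclasses.replace(
        base,
        min_focus_separation=float(separation),
        photon_noise=bool(noise) and base.photon_noise,
        read_noise_sd=base.read_noise_sd if noise else 0.0,
    )
    rng = np.random.default_rng(seed)
    field_size = crop_size + 32
    center = (field_size / 2.0, field_size / 2.0)
    radius = float(min(radius, crop_size / 2.0 - 2.0))
    pts = _sample_foci_positions(rng, n_foci, radius, cfg)
    diffuse = cfg.green_diffuse_level * expression_gain
    foci = [
        (
            center[0] + p[0],
            center[1] + p[1],
            float(cfg.focus_amplitude * diffuse),
            float(cfg.focus_sigma),
        )
        for p in pts
    ]
    cell = TrueCell(
        cell_id=1,
        centroid=center,
        radius=radius,
        nucleus_gain=0.8,
        expression_gain=float(expression_gain),
        foci=foci,
        true_class=label_truth(expression_gain, len(foci), 5),
    )
    nuc_rate, grn_rate = _render_cells((field_size, field_size), [cell], cfg)
    nuc = _camera(rng, nuc_rate, cfg)
    grn = _camera(rng, grn_rate, cfg)
    half = crop_size // 2
    r0 = int(round(center[0])) - half
    c0 = int(round(center[1])) - half
    win = (slice(r0, r0 + crop_size), slice(c0, c0 + crop_size))
    yy, xx = np.mgrid[0:crop_size, 0:crop_size]
    mask = np.hypot(yy + r0 - center[0], xx + c0 - center[1]) <= radius
    crop = CellCrop(
        nuclear=nuc[win].astype(np.float64),
        green_raw=grn[win].astype(np.float64),
        mask=mask,
        plate="SIM",
        well="A01",
        field=0,
        cell_id=1,
    )
    return normalize_crop(crop), cell
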