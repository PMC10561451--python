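"""End-to-end orchestration: simulate -> segment -> quantify -> classify ->
summarize -> RPS -> rank/select -> QC.

Every stage logs its counts (fields, nuclei found, crops kept, cells
classified) so exclusions are auditable, and all outputs are pure functions
of (config, seed): re-running the same config yields byte-identical CSVs
with the deterministic ``feature_baseline`` backend.  Each output file
embeds the config hash on a leading comment line; read the CSVs back with
``comment='#'``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from fociscreen import __version__
from fociscreen.cell_classify import (
    CellClassifier,
    TrainingSet,
    classify,
    records_to_frame,
)
from fociscreen.config import RunConfig
from fociscreen.foci_quant import FociDetector
from fociscreen.screen_stats import (
    aggregate_and_rank,
    compute_rps,
    screen_qc,
    summarize_wells,
)
from fociscreen.segmentation import NucleusSegmenter, extract_crops, normalize_crop
from fociscreen.synthdata import make_single_cell_crops, simulate_screen

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "train_default_classifier", "wells_to_rps"]


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# fociscreen {__version__} config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False, float_format="%.6g", lineterminator="\n")


def train_default_classifier(config: RunConfig, seed: int) -> CellClassifier:
    """Train the configured backend on generator-rendered labeled crops."""
    cc = dict(config.classifier)
    n_train = int(cc.pop("n_train", 900))
    n_val = int(cc.pop("n_val", 300))
    positivity = int(cc.pop("positivity_threshold", 5))
    sim = config.sim_config()
    crops, labels, _ = make_single_cell_crops(
        n_train + n_val, sim, seed=seed, positivity_threshold=positivity
    )
    split = ["train"] * n_train + ["val"] * n_val
    tset = TrainingSet(
        crops=crops,
        labels=labels,
        split=split,
        provenance={"positivity_threshold": positivity, "n_train": n_train, "n_val": n_val},
    )
    backend = cc.pop("backend", "feature_baseline")
    clf = CellClassifier(backend=backend, random_state=seed, **cc)
    tr_crops, tr_labels = tset.subset("train")
    clf.fit(tr_crops, tr_labels)
    if n_val:
        from fociscreen.cell_classify import evaluate

        va_crops, va_labels = tset.subset("val")
        clf.validation_ = evaluate(clf, va_crops, va_labels)
        logger.info(
            "classifier trained: backend=%s val macro accuracy=%.3f",
            backend, clf.validation_["macro_accuracy"],
        )
    return clf


def wells_to_rps(wells: pd.DataFrame, readout_col: str) -> tuple[list[pd.Series], pd.DataFrame]:
    """Per-replicate compound RPS tables plus a well table with an ``rps``
    column (all wells normalized by their plate's compound-well median)."""
    wells = wells.copy()
    wells["rps"] = np.nan
    replicate_tables: dict[int, list[pd.Series]] = {}
    for (rep, plate), grp in wells.groupby(["replicate", "plate"], sort=True):
        comp = grp[grp["role"] == "compound"]
        series = pd.Series(
            comp[readout_col].to_numpy(), index=comp["compound_id"].to_numpy()
        )
        rps = compute_rps(series)
        med = float(series.dropna().median())
        wells.loc[grp.index, "rps"] = 100.0 * grp[readout_col] / med
        replicate_tables.setdefault(int(rep), []).append(rps)
    tables = [
        pd.concat(parts) for _, parts in sorted(replicate_tables.items())
    ]
    return tables, wells


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run the full screen pipeline and write the results bundle.

    Returns a dict with the layout, per-well summaries (incl. RPS), ranked
    compound results, QC tables and provenance.
    """
    out = Path(outdir if outdir is not None else config.outdir)
    cfg_hash = config.config_hash
    sim = config.sim_config()
    model = config.dose_model_obj()
    design = config.screen_design()
    mode = config.pipeline.get("mode", "fast")
    n_fields = int(config.pipeline.get("n_fields_per_well", 1))
    positivity = int(config.classifier.get("positivity_threshold", 5))
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    seed_train = int(seeds[0].generate_state(1, dtype=np.uint32)[0])
    seed_screen = int(seeds[1].generate_state(1, dtype=np.uint32)[0])

    layout, payload, effects, provenance = simulate_screen(
        design, sim, model, seed_screen, mode=mode,
        positivity_threshold=positivity, n_fields_per_well=n_fields,
    )
    logger.info("simulated screen: %d wells, mode=%s", len(layout), mode)

    predictions = None
    if mode == "fast":
        cells = payload  # truth records carry the class labels directly
    else:
        clf = train_default_classifier(config, seed_train)
        seg = NucleusSegmenter(
            **{
                k: v
                for k, v in config.segmentation.items()
                if k not in ("crop_size", "exclude_border")
            }
        )
        det = FociDetector(**config.foci)
        crop_size = int(config.segmentation.get("crop_size", 64))
        exclude_border = bool(config.segmentation.get("exclude_border", True))
        frames = []
        n_nuclei = n_crops = 0
        for row, well_fields in payload:
            for field, _truth in well_fields:
                label_map, instances = seg.segment(field)
                crops = [
                    normalize_crop(c)
                    for c in extract_crops(
                        field, label_map, instances,
                        crop_size=crop_size, exclude_border=exclude_border,
                        background_fill=sim.background_level,
                    )
                ]
                n_nuclei += len(instances)
                n_crops += len(crops)
                if not crops:
                    continue
                counts = [det.detect(c).foci_count for c in crops]
                records = classify(clf, crops, foci_counts=counts)
                frame = records_to_frame(records)
                frame.insert(0, "replicate", row.replicate)
                frame["role"] = row.role
                frame["compound_id"] = row.compound_id
                frames.append(frame)
        logger.info("segmented %d nuclei, kept %d crops", n_nuclei, n_crops)
        predictions = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        cells = predictions

    wells = summarize_wells(cells, layout)

    if config.readout == "pct_positive":
        readout_col = "pct_foci_positive"
    else:
        readout_col = "mean_foci_per_cell"
        if mode == "fast":
            means = (
                cells.groupby(["replicate", "plate", "well"])["foci_count"]
                .mean()
                .rename("mean_foci_per_cell")
                .reset_index()
            )
        else:
            evaluable = cells[cells["class"] != "non_signaling"]
            means = (
                evaluable.groupby(["replicate", "plate", "well"])["foci_count"]
                .mean()
                .rename("mean_foci_per_cell")
                .reset_index()
            )
        wells = wells.merge(means, on=["replicate", "plate", "well"], how="left")

    tables, wells = wells_to_rps(wells, readout_col)
    results = aggregate_and_rank(tables, n_select=config.n_select)
    qc = screen_qc(results, wells)
    logger.info(
        "ranked %d compounds; %d selected", len(results), int(results["selected"].sum())
    )

    _write_csv(wells, out / "well_summaries.csv", cfg_hash)
    _write_csv(results, out / "compound_results.csv", cfg_hash)
    _write_csv(qc["ecdf"], out / "qc_ecdf.csv", cfg_hash)
    _write_csv(qc["histograms"], out / "qc_histograms.csv", cfg_hash)
    _write_csv(effects, out / "true_effects.csv", cfg_hash)
    if predictions is not None and len(predictions):
        _write_csv(predictions, out / "cell_predictions.csv", cfg_hash)
    comparison = qc["control_vs_selected"]
    provenance = {
        **provenance,
        "version": __version__,
        "config_hash": cfg_hash,
        "readout": config.readout,
        "qc_mann_whitney": None
        if comparison is None
        else {
            "u": comparison.u,
            "p_value": comparison.p_value,
            "n1": comparison.n1,
            "n2": comparison.n2,
            "method": comparison.method,
        },
    }
    out.mkdir(parents=True, exist_ok=True)
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1, sort_keys=True))
    return {
        "layout": layout,
        "wells": wells,
        "results": results,
        "qc": qc,
        "effects": effects,
        "provenance": provenance,
        "predictions": predictions,
    }
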