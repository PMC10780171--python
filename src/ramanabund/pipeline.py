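"""End-to-end orchestration: simulate -> preprocess -> extract -> fit -> abundance.

``run_pipeline`` chains the stages on a directory of inputs (or a freshly
simulated dataset), writes the artifact bundle (ranking.csv, fits.json,
abundance.tsv, stats.tsv, heatmap.tsv, report.json) and embeds the resolved
configuration hash in every artifact for reproducibility.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance as ab
from . import extract as ex
from . import io as rio
from . import preprocess as pp
from . import synthetic as syn
from .config import PipelineConfig

log = logging.getLogger("ramanabund")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_inputs(input_dir: Path, config: PipelineConfig) -> rio.SpectrumSet:
    w, mat, ids = rio.read_matrix(input_dir / "matrix.csv")
    labels = rio.read_labels(input_dir / "labels.csv")
    labels = labels.rename(columns={"id": "spectrum_id"})
    if "spectrum_id" not in labels.columns:
        labels.insert(0, "spectrum_id", ids)
    if "cell_id" not in labels.columns:
        labels["cell_id"] = [str(s).rsplit("r", 1)[0] for s in labels["spectrum_id"]]
    if "phase" not in labels.columns:
        labels["phase"] = [config.phase_boundaries.phase_of(t)
                           for t in labels["culture_time_h"]]
    return rio.SpectrumSet(w, mat, labels)


def run_pipeline(config: PipelineConfig | None = None,
                 input_dir: str | Path | None = None,
                 out_dir: str | Path = "artifacts",
                 simulate: bool = False,
                 design: syn.GeneratorDesign | None = None) -> dict:
    """Run the full chain and write the artifact bundle; returns the report."""
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    report: dict = {"config_hash": chash, "config": cfg.to_dict()}

    # --- input / simulate
    stage = "simulate" if simulate else "load"
    try:
        if simulate:
            sset, truth = syn.generate_dataset(design, seed=cfg.seed)
            rio.write_matrix(sset, out / "matrix.csv", header_comment=f"config={chash}")
            rio.write_labels(sset.labels, out / "labels.csv")
            truth.areas.assign(**{c: truth.labels[c] for c in truth.labels.columns}) \
                .to_json(out / "truth.json", orient="split")
        else:
            if input_dir is None:
                raise ValueError("input_dir required unless simulate=True")
            sset = _load_inputs(Path(input_dir), cfg)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- preprocess
    try:
        cells = rio.average_replicates(sset, "cell_id")
        proc, snr_report = pp.preprocess_set(cells, cfg)
        snr_df = snr_report.to_frame()
        snr_df.insert(0, "cell_id", proc.labels["cell_id"].to_numpy())
        snr_df.to_csv(out / "snr.csv", index=False)
        vals = snr_report.values
        report["snr"] = {
            "median": float(np.median(vals)),
            "fraction_in_3_7": float(np.mean((vals >= 3) & (vals <= 7))),
            "ks_by_group": {str(k): list(v) for k, v in snr_report.ks_by_group.items()},
        }
        rio.write_matrix(proc, out / "matrix.proc.csv", header_comment=f"config={chash}")
    except Exception as exc:
        raise StageError("preprocess", exc) from exc

    # --- embedding + classification + gain ranking
    try:
        _, sil = ex.embed_pca_lda(proc, cfg.variance_keep)
        report["silhouette"] = sil
        model_t, rep_t = ex.train_growth_classifier(
            proc, "culture_time", seed=cfg.seed, config=cfg)
        model_p, rep_p = ex.train_growth_classifier(
            proc, "phase", seed=cfg.seed, config=cfg)
        report["accuracy"] = {
            "culture_time": rep_t.accuracy,
            "phase": rep_p.accuracy,
        }
        report["auc_by_phase"] = rep_p.auc
        report["best_params"] = {"culture_time": rep_t.best_params,
                                 "phase": rep_p.best_params}
        ranking = ex.rank_gain(model_t, proc.wavenumbers, mode=cfg.gain_mode)
        table = ex.AssignmentTable(tolerance=cfg.assignment_tolerance)
        frame = ex.ranking_frame(ranking, table, cfg.top_k, cfg.dedupe_window)
        frame.insert(0, "config_hash", chash)
        frame.to_csv(out / "ranking.csv", index=False)
        peaks = [(wn, cls) for wn, cls, _ in ex.select_characteristic_peaks(
            ranking, table, cfg.top_k, cfg.dedupe_window)]
        report["characteristic_peaks"] = [{"wavenumber_cm1": wn, "biomolecule": cls}
                                          for wn, cls in peaks]
    except Exception as exc:
        raise StageError("extract", exc) from exc

    # --- quantification
    try:
        if not peaks:
            log.warning("no characteristic peaks selected; falling back to "
                        "assignment-table defaults")
            peaks = [(wn, cls) for wn, cls in table.assignments.items()
                     if cls != "excluded"]
        atable = ab.quantify(proc, peaks, mode="auto", config=cfg)
        fits = {
            "config_hash": chash,
            "peaks": [{"wavenumber_cm1": wn, "biomolecule": cls} for wn, cls in peaks],
            "areas": atable.areas.to_dict(orient="list"),
            "methods": atable.methods.to_dict(orient="list"),
            "cells": atable.labels["cell_id"].tolist(),
            "fit_details": atable.fit_details.to_dict(orient="records")
            if atable.fit_details is not None else [],
        }
        (out / "fits.json").write_text(json.dumps(fits, indent=1))
        adf = pd.concat(
            [atable.labels[["cell_id", "culture_time_h", "phase"]], atable.areas],
            axis=1)
        adf.to_csv(out / "abundance.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError("fit", exc) from exc

    # --- statistics
    try:
        stats = ab.anova_by_phase(atable, bonferroni=cfg.anova_bonferroni)
        stats.table.to_csv(out / "stats.tsv", sep="\t", index=False)
        hm = ab.heatmap_matrix(atable)
        hm.to_csv(out / "heatmap.tsv", sep="\t")
        report["anova"] = {
            row["peak"]: {"F": row["F"], "p": row["p"], "stars": row["stars"]}
            for _, row in stats.table.iterrows()}
    except Exception as exc:
        raise StageError("abundance", exc) from exc

    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report
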