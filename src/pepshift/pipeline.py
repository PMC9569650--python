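"""End-to-end orchestration of the conformational-analysis workflow.

Runs, in order: secondary-shift analysis and structure calling, proline
cis/trans analysis, amide temperature coefficients, clustering of the
candidate ensemble, chemical-shift-driven conformer selection, ³J and
Q-factor validation, and per-residue dynamics metrics.  All outputs land
in a fresh run directory together with a metadata manifest recording every
preset, threshold and seed; inputs are never mutated.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coupling import JCouplingRecord, KarplusParams, ensemble_j, fit_temp_coefficient, validate_j
from .dynamics import RelaxationFilterModel, S2Coefficients, predict_s2, rmsf, t2_filter
from .ensemble import (
    ToyShiftPredictor,
    _mean_shift_table,
    global_cs_rmsd,
    kelley_cluster,
    pairwise_rmsd,
    predict_shifts,
    q_factor,
    select_ensemble,
)
from .io import (
    RunConfig,
    read_jcoupling_csv,
    read_pdb_ensemble,
    read_r2_csv,
    read_shift_csv,
    read_temp_series_csv,
    write_pdb_ensemble,
)
from .shifts import RandomCoilModel, call_secondary_structure, cis_population, classify_proline, secondary_shifts

logger = logging.getLogger("pepshift")

__all__ = ["run_pipeline"]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow on an input bundle; return a report dict.

    Expects in ``config.input_dir``: ``ensemble.pdb`` and
    ``observed_shifts.csv`` (required), plus optional ``temp_series.csv``,
    ``jcoupling.csv``, ``r2.csv`` and ``proline_peaks.csv``.  Missing
    optional inputs degrade the corresponding stage to "partial" rather
    than failing the run.  Deterministic given config and seeds.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {"stages": {}}
    rc = RandomCoilModel.from_packaged(config.random_coil_table)
    predictor = ToyShiftPredictor(rc)
    karplus = KarplusParams.preset(config.karplus_preset)

    # --- observed shifts and secondary-shift analysis ---------------------
    obs = _stage("read_shifts")(read_shift_csv)(indir / "observed_shifts.csv", config.peptide_id)
    sec_obs = _stage("secondary_shifts")(secondary_shifts)(obs, rc)
    calls = _stage("structure_calls")(call_secondary_structure)(
        sec_obs, window=config.structure_window, threshold_ppm=config.structure_threshold_ppm
    )
    sec_out = sec_obs.data.copy()
    sec_out.to_csv(outdir / "secondary_shifts.csv", index=False)
    pd.DataFrame(
        {"residue_index": calls.index, "ca_minus_cb_ppm": sec_obs.ca_minus_cb.reindex(calls.index), "call": calls.values}
    ).to_csv(outdir / "structure_calls.csv", index=False)
    report["stages"]["secondary_shifts"] = {
        "n_cells": int(len(sec_obs.data)),
        "calls": {c: int((calls == c).sum()) for c in ("helix", "strand", "coil")},
    }

    # --- proline cis/trans analysis ---------------------------------------
    proline_path = indir / "proline_peaks.csv"
    if proline_path.exists():
        peaks = pd.read_csv(proline_path)
        rows = []
        for res_idx, grp in peaks.groupby("residue_index"):
            by_form = {r.form: r for r in grp.itertuples()}
            trans = by_form.get("trans")
            cis = by_form.get("cis")
            major = max(by_form.values(), key=lambda r: r.intensity)
            rec = classify_proline(
                major.cb_ppm, major.cg_ppm, residue_index=int(res_idx),
                trans_max=config.proline_trans_max_ppm, cis_min=config.proline_cis_min_ppm,
            )
            frac = cis_population(
                cis.intensity if cis is not None else 0.0,
                trans.intensity if trans is not None else 0.0,
            )
            rows.append(
                {
                    "residue_index": int(res_idx),
                    "delta_bg_ppm": rec.delta_bg,
                    "configuration": rec.configuration,
                    "cis_fraction": frac,
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "proline.csv", index=False)
        report["stages"]["proline"] = {"n_prolines": len(rows)}
    else:
        report["stages"]["proline"] = "partial: proline_peaks.csv absent"

    # --- amide temperature coefficients ------------------------------------
    temp_path = indir / "temp_series.csv"
    if temp_path.exists():
        series = read_temp_series_csv(temp_path)
        coeffs = [_stage("tempco")(fit_temp_coefficient)(s) for s in series]
        pd.DataFrame(
            [
                {
                    "residue_index": c.residue_index,
                    "slope_ppb_per_K": c.slope_ppb_per_K,
                    "stderr_ppb_per_K": c.stderr_ppb_per_K,
                    "classification": c.classification,
                }
                for c in coeffs
            ]
        ).to_csv(outdir / "temp_coefficients.csv", index=False)
        report["stages"]["tempco"] = {"n_residues": len(coeffs)}
    else:
        report["stages"]["tempco"] = "partial: temp_series.csv absent"

    # --- candidate ensemble: clustering and CS-driven selection -------------
    ens = _stage("read_ensemble")(read_pdb_ensemble)(indir / "ensemble.pdb", config.peptide_id)
    if config.cluster_before_select:
        d = pairwise_rmsd(ens)
        clus = kelley_cluster(d)
        rep_ids = sorted(clus.representatives.values())
        report["stages"]["cluster"] = {
            "n_clusters": clus.n_clusters,
            "linkage": "average",
            "n_models": ens.n_models,
        }
    else:
        rep_ids = list(range(ens.n_models))
        report["stages"]["cluster"] = "skipped: every conformer is its own representative"

    predicted = {cid: predict_shifts(ens, cid, predictor) for cid in rep_ids}
    sel = _stage("select")(select_ensemble)(
        obs, predicted, n=config.select_n, mode=config.select_mode, seed=config.seed
    )
    sel.ranking.to_csv(outdir / "ranking.csv", index=False)
    write_pdb_ensemble(ens.subset(sel.selected_ids), outdir / "selected_ensemble.pdb")
    report["stages"]["selection"] = {
        "mode": sel.mode,
        "n_selected": len(sel.selected_ids),
        "ensemble_cs_rmsd_ppm": sel.ensemble_cs_rmsd,
        "mean_of_scores_ppm": sel.mean_of_scores,
        "warning": sel.warning,
    }

    # --- validation: Q factor and 3J correlation ----------------------------
    validation: dict = {"partial": []}
    mean_pred = _mean_shift_table([predicted[c] for c in sel.selected_ids])
    sec_pred = secondary_shifts(mean_pred, rc)
    try:
        qrep = q_factor(sec_obs, sec_pred)
        validation["q_pooled"] = qrep.q_pooled
        validation["q_per_class"] = qrep.q_per_class
        qrep.per_residue_cumulative.to_csv(outdir / "cumulative_shift_diff.csv", index=False)
    except ValueError as exc:
        validation["partial"].append(f"q_factor: {exc}")
    j_path = indir / "jcoupling.csv"
    if j_path.exists():
        jobs = read_jcoupling_csv(j_path)
        jpred = ensemble_j(ens.subset(sel.selected_ids), karplus)
        merged = jobs.merge(jpred, on="residue_index", how="inner").dropna(subset=["j_obs_hz", "j_pred_hz"])
        records = [
            JCouplingRecord(
                residue_index=int(r.residue_index), j_obs_hz=float(r.j_obs_hz), j_pred_hz=float(r.j_pred_hz)
            )
            for r in merged.itertuples()
        ]
        jv = validate_j(records)
        validation["j_correlation_r"] = jv["r"]
        validation["j_rmsd_hz"] = jv["rmsd_hz"]
        merged.to_csv(outdir / "jcoupling_validation.csv", index=False)
    else:
        validation["partial"].append("jcoupling.csv absent; 3J validation skipped")
    validation["status"] = "partial" if validation["partial"] else "complete"
    report["stages"]["validation"] = validation

    # --- dynamics metrics ---------------------------------------------------
    sel_ens = ens.subset(sel.selected_ids)
    prof = rmsf(sel_ens)
    prof.to_csv(outdir / "rmsf.csv", index=False)
    s2 = predict_s2(sec_obs, S2Coefficients(preset_id=config.s2_preset))
    s2.to_csv(outdir / "s2.csv", index=False)
    report["stages"]["dynamics"] = {"rmsf_mean_A": float(prof["rmsf_A"].mean())}
    r2_path = indir / "r2.csv"
    if r2_path.exists():
        r2 = read_r2_csv(r2_path)
        frames = []
        for T in config.filter_durations_s:
            ft = t2_filter(RelaxationFilterModel(filter_s=T, r2_hz=r2, noise_floor=config.noise_floor))
            ft.insert(0, "filter_s", T)
            frames.append(ft)
        pd.concat(frames, ignore_index=True).to_csv(outdir / "t2_filter.csv", index=False)
    else:
        report["stages"]["dynamics"]["t2_filter"] = "partial: r2.csv absent"

    # --- manifest -----------------------------------------------------------
    manifest = {
        "pepshift_version": __version__,
        "config": config.to_dict(),
        "random_coil_table": rc.source_id,
        "karplus_preset": karplus.preset_id,
        "shift_predictor": predictor.predictor_id,
        "s2_preset": config.s2_preset,
        "clustering_linkage": "average",
        "seed": config.seed,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    config.write_yaml(outdir / "effective_config.yaml")
    report["manifest"] = manifest
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True, default=str))
    return report
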