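"""Top-level orchestration: config-driven end-to-end pipeline runs.

A single JSON config drives simulation (or loading) of inputs, clutter
filtering of IQ phantoms, preprocessing, and the statistical analyses
(activation GLM, connectivity, stabilized ICA).  Every stage writes its
outputs with a JSON sidecar echoing the full parameter set and seed, so
any stage can be re-run in isolation, and a QC report (CNR, matching
score, calm score, exclusion flag) summarizes the session.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .activation import HRFModel, bonferroni_mask, build_regressor, glm_fit, rcbv_raster
from .clutter import FIXED_NCUT_ANESTHETIZED, adaptive_ncut, power_doppler, svd_decompose, svd_filter
from .connectivity import extract_regions, fc_matrix, fc_specificity
from .geometry import ProbeGeometry, build_schedule
from .ica import icasso
from .preprocess import detrend, preprocess_resting, slice_timing_correct
from .qc import QCReport, cnr, matching_score
from .synth import (
    PhantomSpec,
    SimulationSpec,
    make_atlas,
    make_iq_phantom,
    make_stimulus,
    simulate_pd_series,
)

__all__ = ["default_config", "validate_config", "run_pipeline"]

_TOP_KEYS = {
    "seed",
    "n_subjects",
    "probe",
    "schedule",
    "phantom",
    "simulation",
    "stimulus",
    "preprocess",
    "activation",
    "connectivity",
    "ica",
    "mode",
}


def default_config() -> dict:
    """Desk-scale defaults for an end-to-end smoke run."""
    return {
        "seed": 0,
        "n_subjects": 1,
        "mode": "awake",  # "awake" (resting) or "anesthetized" (task)
        "probe": {"n_arrays": 4, "elements_per_array": 64, "pitch_mm": 0.110, "inter_array_mm": 2.1, "fwhm_mm": 0.5},
        "schedule": {"n_positions": 4, "t_integration_s": 0.4, "t_translation_s": 0.2},
        "phantom": {"shape": [24, 24], "n_frames": 200, "n_cut": FIXED_NCUT_ANESTHETIZED, "adaptive": False},
        "simulation": {
            "shape": [16, 4, 16],
            "n_volumes": 300,
            "latent_std_pct": 2.0,
            "homotopic_r": 0.6,
            "noise_sigma_pct": 0.5,
            "drift_amp_pct": 1.0,
            "response_pct": {},
            "motion_episodes": [],
        },
        "stimulus": None,
        "preprocess": {
            "band_hz": [0.01, 0.1],
            "calm_threshold": 0.05,
            "calm_min_s": 60.0,
            "window_s": 24.0,
            "min_calm_total_s": 600.0,
            "gsr": True,
            "detrend_degree": 3,
        },
        "activation": {"alpha": 0.05, "correction": "bonferroni"},
        "connectivity": {"alpha": 0.05},
        "ica": {"n_components": 4, "n_runs": 20, "z_thresh": 3.0},
    }


def validate_config(config: dict) -> dict:
    """Merge a user config over the defaults; unknown keys are an error."""
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = default_config()
    for k, v in config.items():
        if isinstance(v, dict) and isinstance(merged.get(k), dict):
            merged[k] = {**merged[k], **v}
        else:
            merged[k] = v
    return merged


def _homotopic_corr(table: pd.DataFrame, r: float) -> np.ndarray:
    ids = table["id"].to_numpy()
    pos = {int(v): i for i, v in enumerate(ids)}
    corr = np.eye(len(ids))
    for _, row in table.iterrows():
        i, j = pos[int(row["id"])], pos[int(row["mirror_id"])]
        corr[i, j] = corr[j, i] = r
    return corr


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the configured pipeline; returns artifact paths and QC reports."""
    cfg = validate_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    artifacts: dict = {"config": cfg, "outputs": {}, "qc": []}

    geometry = ProbeGeometry(
        n_arrays=cfg["probe"]["n_arrays"],
        elements_per_array=cfg["probe"]["elements_per_array"],
        pitch_mm=cfg["probe"]["pitch_mm"],
        inter_array_mm=cfg["probe"]["inter_array_mm"],
        elevation_fwhm_mm=cfg["probe"]["fwhm_mm"],
    )
    schedule = build_schedule(
        geometry,
        cfg["schedule"]["n_positions"],
        cfg["schedule"]["t_integration_s"],
        cfg["schedule"]["t_translation_s"],
    )
    schedule.to_csv(out / "schedule.csv")
    artifacts["outputs"]["schedule"] = str(out / "schedule.csv")

    # --- IQ phantom -> clutter filter -> Power Doppler + CNR --------------
    phantom_cnr = None
    if cfg.get("phantom"):
        pcfg = cfg["phantom"]
        spec = PhantomSpec(shape=tuple(pcfg["shape"]), n_frames=pcfg["n_frames"], seed=seed)
        block = make_iq_phantom(spec)
        if pcfg.get("adaptive"):
            n_cut = adaptive_ncut(svd_decompose(block))
        else:
            n_cut = min(int(pcfg["n_cut"]), block.n_frames - 1)
        pd_img = power_doppler(svd_filter(block, n_cut))
        vessel = spec.vessel_mask
        background = ~vessel
        phantom_cnr = cnr(pd_img, vessel, background)
        np.savetxt(out / "phantom_pd.csv", pd_img, delimiter=",")
        sio.write_sidecar(out / "phantom_pd.csv", {"n_cut": int(n_cut), "seed": seed, **{k: v for k, v in pcfg.items()}})
        artifacts["outputs"]["phantom_pd"] = str(out / "phantom_pd.csv")

    # --- simulate subjects -------------------------------------------------
    scfg = cfg["simulation"]
    shape = tuple(scfg["shape"])
    labels, table = make_atlas(shape)
    sio.save_labels_nifti(labels, out / "labels.nii.gz", table)
    artifacts["outputs"]["labels"] = str(out / "labels.nii.gz")
    corr = _homotopic_corr(table, float(scfg["homotopic_r"]))

    stimulus = None
    if cfg.get("stimulus"):
        st = cfg["stimulus"]
        stimulus = make_stimulus(st["baseline_s"], st["n_stimuli"], st["on_duration_s"], st["period_s"], schedule.tr_s)

    n_sub = int(cfg["n_subjects"])
    subject_means = []
    preprocessed = []
    segments_all = []
    for s in range(n_sub):
        spec = SimulationSpec(
            labels=labels,
            n_volumes=len(stimulus) if stimulus is not None else int(scfg["n_volumes"]),
            tr_s=schedule.tr_s,
            network_corr=corr,
            latent_std_pct=float(scfg["latent_std_pct"]),
            response_pct={int(k): float(v) for k, v in scfg["response_pct"].items()},
            drift_amp_pct=float(scfg["drift_amp_pct"]),
            motion_episodes=[tuple(e) for e in scfg["motion_episodes"]],
            noise_sigma_pct=float(scfg["noise_sigma_pct"]),
            slice_onsets_s=np.resize(schedule.slice_onset_s, shape[2]),
            seed=seed + 1000 * s,
        )
        vol = simulate_pd_series(spec, stimulus)
        sio.save_pd_nifti(vol, out / f"sub-{s:02d}_pd.nii.gz")
        subject_means.append(vol.data.mean(axis=-1))

        ppcfg = cfg["preprocess"]
        if cfg["mode"] == "anesthetized":
            v = detrend(slice_timing_correct(vol), degree=int(ppcfg["detrend_degree"]))
            preprocessed.append((vol, v))
            segments_all.append(None)
        else:
            v, segments, excluded = preprocess_resting(
                vol,
                band_hz=tuple(ppcfg["band_hz"]),
                threshold_ratio=float(ppcfg["calm_threshold"]),
                min_duration_s=float(ppcfg["calm_min_s"]),
                window_s=float(ppcfg["window_s"]),
                min_calm_total_s=float(ppcfg["min_calm_total_s"]),
                gsr=bool(ppcfg["gsr"]),
                detrend_degree=int(ppcfg["detrend_degree"]),
            )
            preprocessed.append((vol, v))
            segments_all.append(segments)

    template = np.mean(subject_means, axis=0)
    for s in range(n_sub):
        segs = segments_all[s]
        report = QCReport(
            cnr_db=phantom_cnr,
            matching_score=matching_score(subject_means[s], template) if n_sub > 1 else None,
            calm_score_s=segs.calm_score_s if segs is not None else None,
            excluded=(preprocessed[s][1] is None),
            parameters={"seed": seed + 1000 * s, "mode": cfg["mode"]},
        )
        report.to_json(out / f"sub-{s:02d}_qc.json")
        artifacts["qc"].append(report)

    # --- analyses ----------------------------------------------------------
    if cfg["mode"] == "anesthetized" and stimulus is not None:
        acfg = cfg["activation"]
        hrf = HRFModel()
        reg = build_regressor(stimulus, hrf, schedule.tr_s)
        rows = []
        for s, (raw, v) in enumerate(preprocessed):
            n = v.n_volumes
            X = np.column_stack([np.ones(n), reg[:n]])
            # GLM on the raw (undetrended) series keeps the intercept a real baseline
            Y = raw.data.reshape(-1, n).T
            res = glm_fit(Y, X)
            mask = bonferroni_mask(res.p, alpha=float(acfg["alpha"]))
            raster = rcbv_raster(raw.data, labels, res.intercept.reshape(shape), mask.reshape(shape))
            pd.DataFrame(raster.rcbv_pct, index=raster.region_ids).to_csv(out / f"sub-{s:02d}_raster.csv")
            rows.append({"subject": s, "n_sig_voxels": int(mask.sum())})
        pd.DataFrame(rows).to_csv(out / "activation_summary.csv", index=False)
        artifacts["outputs"]["activation_summary"] = str(out / "activation_summary.csv")
    elif cfg["mode"] == "awake":
        ccfg = cfg["connectivity"]
        rows = []
        ts_all = []
        for s, (raw, v) in enumerate(preprocessed):
            if v is None:
                rows.append({"subject": s, "excluded": True, "r_specific": np.nan, "r_unspecific": np.nan})
                continue
            ts = extract_regions(v, labels, table)
            ts_all.append(ts)
            fc = fc_matrix(ts)
            pd.DataFrame(fc.r, index=ts.table["acronym"], columns=ts.table["acronym"]).to_csv(
                out / f"sub-{s:02d}_fc.csv"
            )
            r_spec, r_unspec = fc_specificity(ts)
            rows.append({"subject": s, "excluded": False, "r_specific": r_spec, "r_unspecific": r_unspec})
        pd.DataFrame(rows).to_csv(out / "connectivity_summary.csv", index=False)
        artifacts["outputs"]["connectivity_summary"] = str(out / "connectivity_summary.csv")

        icfg = cfg["ica"]
        if ts_all:
            concat = np.concatenate([ (raw_v[1].data.reshape(-1, raw_v[1].n_volumes)) for raw_v in preprocessed if raw_v[1] is not None ], axis=1)
            comps = icasso(
                concat,
                n_components=int(icfg["n_components"]),
                n_runs=int(icfg["n_runs"]),
                seed=seed,
                z_thresh=float(icfg["z_thresh"]),
            )
            pd.DataFrame(
                [{"component": i, "iq": c.iq, "n_members": c.n_members, "n_sig_voxels": int(c.mask.sum())} for i, c in enumerate(comps)]
            ).to_csv(out / "ica_stability.csv", index=False)
            artifacts["outputs"]["ica_stability"] = str(out / "ica_stability.csv")

    with open(out / "provenance.json", "w") as fh:
        json.dump({"config": cfg}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return artifacts
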