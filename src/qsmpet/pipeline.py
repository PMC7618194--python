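"""Pipeline stages binding the library together: simulate, casecontrol,
voxelwise, plsr, patlak and a collating report. Each stage reads its inputs
from disk, writes artifacts plus a JSON summary into the output directory,
and is fully reproducible from (config, seed)."""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cg
from . import io as qio
from . import plsr as pls
from . import robust as rs
from . import voxelwise as vw
from .patlak import patlak_fit

__all__ = [
    "run_simulate",
    "run_casecontrol",
    "run_correlate",
    "run_voxelwise",
    "run_plsr",
    "run_patlak",
    "run_report",
]

_CONFOUNDERS = ["age", "sex", "smoking", "thc_positive"]


def _write_json(obj, path, overwrite):
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass --overwrite to replace it")
    path.write_text(json.dumps(obj, indent=2, default=float))
    return path


def run_simulate(out_dir, seed: int = 0, config: cg.EffectConfig | None = None,
                 overwrite: bool = False, write_maps: bool = True):
    """Generate and write the full synthetic dataset (cohort, maps, TACs)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config or cg.EffectConfig(seed=seed)
    subjects = cg.generate_subjects(cfg)
    roi = cg.generate_roi_measures(subjects, cfg)
    qio.write_cohort(subjects, roi, out / "cohort.csv", overwrite=overwrite)
    meta = {"seed": cfg.seed, "stage": "simulate", "config": vars(cfg).copy()}
    if write_maps:
        maps = cg.generate_voxel_maps(subjects, roi, cfg)
        for name in ("sn_vta", "striatum"):
            stack = maps[name]
            aff = np.eye(4)
            aff[:3, :3] = np.diag(stack.voxel_size)
            aff[:3, 3] = stack.origin
            qio.write_volume(stack.data, out / f"{name}_stack.nii.gz",
                             overwrite=overwrite, sidecar=meta, affine=aff)
            qio.write_volume(stack.mask.astype(np.float32), out / f"{name}_mask.nii.gz",
                             overwrite=overwrite, affine=aff)
    tac = cg.generate_tacs(ki_true=0.01, seed=cfg.seed)
    qio.write_tac(tac, out / "tac.csv", overwrite=overwrite)
    _write_json(meta, out / "simulate.json", overwrite)
    return out


def run_casecontrol(cohort_csv, out_dir, seed: int = 0, covariates=None,
                    overwrite: bool = False):
    """Robust case-control model of SN-VTA susceptibility + Cohen's d."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = qio.read_cohort(cohort_csv)
    covs = covariates or _CONFOUNDERS
    design = rs.DesignSpec(response="sn_vta_susceptibility",
                           predictor_of_interest="group", covariates=list(covs))
    fit = rs.fit_robust_lm(data, design)
    fit.table.to_csv(out / "casecontrol_terms.csv")
    a = data.loc[data.group == "control", "sn_vta_susceptibility"]
    b = data.loc[data.group == "patient", "sn_vta_susceptibility"]
    d, lo, hi = rs.cohens_d(a, b)
    group_term = fit.term("group[patient]")
    summary = {
        "seed": seed, "stage": "casecontrol", "n_control": int(len(a)),
        "n_patient": int(len(b)), "cohens_d": d, "d_ci": [lo, hi],
        "group_coef": float(group_term["coef"]), "group_t": float(group_term["t"]),
        "group_p": float(group_term["p"]),
    }
    _write_json(summary, out / "casecontrol.json", overwrite)
    return summary


def run_correlate(cohort_csv, out_dir, seed: int = 0, q: float = 0.05,
                  overwrite: bool = False):
    """ROI correlation battery: age, group-wise NM-CNR (Fisher comparison),
    patient susceptibility-Ki correlations with BH-FDR and Steiger tests."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = qio.read_cohort(cohort_csv)
    chi = data["sn_vta_susceptibility"]
    r_age, p_age = rs.pearson_with_p(data["age"], chi)
    grp = {}
    for g in ("control", "patient"):
        sel = data.group == g
        grp[g] = rs.pearson_with_p(chi[sel], data.loc[sel, "sn_vta_nm_cnr"])
    comp = rs.fisher_independent_comparison(
        grp["control"][0], int((data.group == "control").sum()),
        grp["patient"][0], int((data.group == "patient").sum()))
    pat = data[data.group == "patient"]
    ki_tests = {}
    pvals = []
    for sub in ("whole", "limbic", "associative", "sensorimotor", "sn_vta"):
        r, p = rs.pearson_with_p(pat["sn_vta_susceptibility"], pat[f"ki_{sub}"])
        ki_tests[sub] = {"r": r, "p": p}
        pvals.append(p)
    reject, p_adj = rs.bh_fdr(pvals, q=q)
    for (sub, t), rej, pa in zip(ki_tests.items(), reject, p_adj):
        t["p_fdr"] = float(pa)
        t["significant"] = bool(rej)
    summary = {
        "seed": seed, "stage": "correlate", "age_r": r_age, "age_p": p_age,
        "nmcnr_r_control": grp["control"][0], "nmcnr_r_patient": grp["patient"][0],
        "fisher_z": comp.z, "fisher_p": comp.p, "ki_correlations": ki_tests,
    }
    _write_json(summary, out / "correlate.json", overwrite)
    return summary


def _design_from_cohort(data: pd.DataFrame):
    X = np.column_stack([
        np.ones(len(data)),
        (data.group == "patient").astype(float),
        (data.smoking == "current").astype(float),
        (data.smoking == "past").astype(float),
        data.thc_positive.astype(float),
        (data.sex == "male").astype(float),
        data.age.astype(float),
    ])
    return X, 1  # term index of the group effect


def run_voxelwise(cohort_csv, stack_nii, mask_nii, out_dir, stat: str = "tfce",
                  n_perm: int = 1000, seed: int = 0, q: float = 0.05,
                  sigma_mm: float = 1.0, overwrite: bool = False):
    """Censor, smooth and run voxelwise case-control permutation inference."""
    from .volumes import VolumeStack

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = qio.read_cohort(cohort_csv)
    vol = qio.read_volume(stack_nii)
    mask_vol = qio.read_volume(mask_nii)
    qio.check_geometry_match(vol, mask_vol, "stack", "mask")
    stack_data = getattr(vol, "stack_data", vol.data[None])
    mask = mask_vol.data > 0.5
    if len(data) != stack_data.shape[0]:
        raise ValueError("cohort rows do not match stacked subjects")
    smoothed = np.stack([
        vw.gaussian_smooth(s, sigma_mm=sigma_mm, voxel_size=vol.voxel_size)
        for s in stack_data
    ])
    stack = VolumeStack(smoothed, mask, vol.voxel_size, vol.origin)
    censored, bounds = vw.censor_extremes(stack.matrix())
    stack = stack.with_matrix(censored)
    X, term = _design_from_cohort(data)
    if stat == "tfce":
        pmap, clusters, info = vw.permutation_tfce_inference(
            stack, X, term, n_perm=n_perm, seed=seed, q=q)
        qio.write_volume(np.nan_to_num(pmap, nan=1.0), out / "p_map.nii.gz",
                         overwrite=overwrite)
        n_sig = info["n_significant_voxels"]
    else:
        clusters, info = vw.spatial_extent_inference(
            stack, X, term, n_perm=n_perm, seed=seed)
        n_sig = int(clusters.table.query("corrected_p < 0.05")["n_voxels"].sum()) \
            if len(clusters.table) else 0
    clusters.table.to_csv(out / "clusters.csv", index=False)
    qio.write_volume(clusters.label_volume.astype(np.float32),
                     out / "cluster_labels.nii.gz", overwrite=overwrite)
    summary = {"seed": seed, "stage": "voxelwise", "stat": stat, "n_perm": n_perm,
               "censor_bounds_ppb": list(bounds), "n_significant_voxels": int(n_sig),
               "n_clusters": int(len(clusters.table))}
    _write_json(summary, out / "voxelwise.json", overwrite)
    return summary


def run_plsr(cohort_csv, x_stack_nii, x_mask_nii, y_stack_nii, y_mask_nii, out_dir,
             n_folds=10, n_repeats=20, n_perm=500, n_boot=200, seed=0,
             overwrite: bool = False, patients_only: bool = True):
    """One-pair PLS between SN-VTA susceptibility and striatal Ki voxels."""
    from .volumes import VolumeStack

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = qio.read_cohort(cohort_csv)
    blocks = []
    for stack_nii, mask_nii in ((x_stack_nii, x_mask_nii), (y_stack_nii, y_mask_nii)):
        vol = qio.read_volume(stack_nii)
        mask = qio.read_volume(mask_nii).data > 0.5
        stack_data = getattr(vol, "stack_data", vol.data[None])
        blocks.append(VolumeStack(stack_data, mask, vol.voxel_size, vol.origin).matrix())
    X, Y = blocks
    sel = (data.group == "patient").to_numpy() if patients_only else np.ones(len(data), bool)
    conf = np.column_stack([
        np.ones(int(sel.sum())),
        data.loc[sel, "age"].astype(float),
        (data.loc[sel, "sex"] == "male").astype(float),
        (data.loc[sel, "smoking"] == "current").astype(float),
        (data.loc[sel, "smoking"] == "past").astype(float),
        data.loc[sel, "thc_positive"].astype(float),
    ])
    est = pls.PLSBrainMapInference(n_folds=n_folds, n_repeats=n_repeats, n_perm=n_perm,
                                   n_boot=n_boot, seed=seed, confounders=conf)
    est.fit(X[sel], Y[sel])
    np.savetxt(out / "predictor_z.csv", est.predictor_z_, delimiter=",")
    np.savetxt(out / "response_z.csv", est.response_z_, delimiter=",")
    summary = {
        "seed": seed, "stage": "plsr", "mean_oos_r": est.mean_oos_r_,
        "perm_p": est.perm_p_, "n_perm": n_perm,
        "frac_negative_predictor_z": float(np.nanmean(est.predictor_z_ < 0)),
        "frac_negative_response_z": float(np.nanmean(est.response_z_ < 0)),
    }
    _write_json(summary, out / "plsr.json", overwrite)
    return summary


def run_patlak(tac_csv, out_dir, t_star: float = 20.0, seed: int = 0,
               weighted: bool = False, overwrite: bool = False):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tac = qio.read_tac(tac_csv)
    fit = patlak_fit(tac, t_star=t_star, weighted=weighted)
    summary = {"seed": seed, "stage": "patlak", "ki_per_min": fit.ki,
               "intercept": fit.intercept, "t_star_min": fit.t_star,
               "r_squared": fit.r_squared, "n_frames_used": fit.n_frames_used}
    _write_json(summary, out / "patlak.json", overwrite)
    return summary


def run_report(run_dir, overwrite: bool = False):
    """Collate per-stage JSON summaries into one report (JSON + text)."""
    run_dir = Path(run_dir)
    stages = {}
    for f in sorted(run_dir.glob("*.json")):
        if f.name in ("report.json", "simulate.json"):
            continue
        stages[f.stem] = json.loads(f.read_text())
    missing = [s for s in ("casecontrol",) if s not in stages]
    if missing:
        raise FileNotFoundError(
            f"missing upstream artifacts in {run_dir}: {', '.join(m + '.json' for m in missing)}"
        )
    report = {"generated": time.strftime("%Y-%m-%dT%H:%M:%S"), "stages": stages}
    _write_json(report, run_dir / "report.json", overwrite)
    lines = ["QSM-PET synthetic-cohort analysis report", "=" * 42]
    for name, s in stages.items():
        lines.append(f"\n[{name}]")
        for k, v in s.items():
            if k in ("stage",):
                continue
            lines.append(f"  {k}: {v}")
    (run_dir / "report.txt").write_text("\n".join(lines) + "\n")
    return report
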