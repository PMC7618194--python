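"""Seeded synthetic cohorts with the statistical structure of an early-course
schizophrenia QSM / [18F]-DOPA PET case-control study.

The generator produces, from an :class:`EffectConfig` alone:

* a covariate table (group, age, sex, smoking, THC urine screen, PANSS,
  chlorpromazine-equivalent dose) matching the study's marginal frequencies,
* per-subject ROI scalars (SN-VTA susceptibility in ppb, NM-CNR, mean
  diffusivity, striatal and nigral Ki in min^-1) with configured group
  effect size and within-group correlations,
* subject-stacked voxel maps on exact-size ellipsoidal SN-VTA and striatal
  phantom masks, with smooth spatial noise and focal effect topology,
* time-activity curves that satisfy the irreversible-uptake (Patlak) model
  exactly in the noiseless case.

Every routine is deterministic given the config seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import VolumeStack

__all__ = [
    "EffectConfig",
    "generate_subjects",
    "generate_roi_measures",
    "generate_voxel_maps",
    "generate_tacs",
    "generate_cluster_phantom",
    "generate_latent_pair_blocks",
    "build_ellipsoid_mask",
    "grow_contiguous_subset",
    "SN_VTA_VOXELS",
    "STRIATUM_VOXELS",
]

SN_VTA_VOXELS = 1790
STRIATUM_VOXELS = 2967

# Table-2-style marginal frequencies (control, patient)
_P_MALE = (0.70, 0.71)
_P_SMOKING = {"control": (0.15, 0.18, 0.67), "patient": (0.37, 0.11, 0.52)}  # current, past, never
_P_THC = (0.24, 0.25)
_AGE = ((31.9, 6.4), (31.2, 7.0))  # (mean, SD) per group
_PANSS = {"positive": (17.0, 5.4), "negative": (20.3, 5.7), "general": (36.0, 7.2)}
# shared severity loading chosen so the implied PANSS-total SD matches ~14.1
_PANSS_SHARED = 0.62
_UNMEDICATED_FRAC = 20 / 79
_CPZ_MEAN, _CPZ_SD = 233.7, 151.6


@dataclass
class EffectConfig:
    """Targets and scales for the synthetic cohort.

    Correlation targets are *within-group* correlations; the group shift is
    expressed as Cohen's d on the pooled within-group SD. The within-group
    susceptibility SD is not pinned down by the study tables and is exposed
    here (default 22 ppb, consistent with the reported coefficient scales).
    """

    n_control: int = 80
    n_patient: int = 79
    group_d: float = -0.66
    age_r: float = 0.19
    nmcnr_r_control: float = 0.25
    nmcnr_r_patient: float = -0.19
    ki_r_patient: float = -0.44
    cluster_fraction: float = 327 / 1790
    seed: int = 0
    # scales
    susceptibility_mean: float = 90.0
    susceptibility_sd: float = 22.0
    nmcnr_mean: float = 10.0
    nmcnr_sd: float = 3.0
    md_mean: float = 8.0e-4
    md_sd: float = 1.0e-4
    ki_mean: float = 0.013
    ki_sd: float = 0.0015
    # voxel-level structure
    voxel_noise_sd: float = 12.0
    ki_voxel_noise_sd: float = 0.002
    cluster_effect_sd: float = 1.2
    noise_smooth_sigma_vox: float = 2.0
    # subregion Ki correlation multipliers relative to ki_r_patient
    # (associative and sensorimotor carry the effect; limbic is weak)
    ki_subregion_scale: dict = field(
        default_factory=lambda: {
            "whole": 1.0,
            "limbic": 0.32,
            "associative": 1.02,
            "sensorimotor": 0.98,
            "sn_vta": 0.34,
        }
    )

    def __post_init__(self):
        if self.n_control <= 0 or self.n_patient <= 0:
            raise ValueError("group sizes must be positive")
        for name in ("age_r", "nmcnr_r_control", "nmcnr_r_patient", "ki_r_patient"):
            r = getattr(self, name)
            if not -1 < r < 1:
                raise ValueError(f"{name}={r} must lie in (-1, 1)")
        if not 0 <= self.cluster_fraction < 1:
            raise ValueError("cluster_fraction must lie in [0, 1)")
        if self.susceptibility_sd <= 0:
            raise ValueError("susceptibility_sd must be positive")
        # fail early if any implied within-group covariance is not PD
        for group in ("control", "patient"):
            self.correlation_matrix(group)

    # variable order used throughout: chi (susceptibility residual), nmcnr,
    # md, ki_whole, ki_limbic, ki_associative, ki_sensorimotor, ki_sn_vta
    _VARS = ("chi", "nmcnr", "md", "ki_whole", "ki_limbic", "ki_associative",
             "ki_sensorimotor", "ki_sn_vta")

    def correlation_matrix(self, group: str) -> np.ndarray:
        """Within-group latent correlation matrix, checked positive definite.

        The age share of the susceptibility variance dilutes any latent
        chi-X correlation by sqrt(1 - age_r^2); the latent targets are
        inflated accordingly so the *observed* within-group correlations
        land on the configured values.
        """
        dil = np.sqrt(1.0 - self.age_r**2)
        nm_r = {"control": self.nmcnr_r_control, "patient": self.nmcnr_r_patient}[group]
        ki_r = self.ki_r_patient if group == "patient" else 0.0
        k = self.ki_subregion_scale
        m = np.eye(8)
        names = self._VARS

        def set_r(a, b, r):
            i, j = names.index(a), names.index(b)
            m[i, j] = m[j, i] = r

        set_r("chi", "nmcnr", nm_r / dil)
        for sub in ("whole", "limbic", "associative", "sensorimotor", "sn_vta"):
            set_r("chi", f"ki_{sub}", np.clip(ki_r * k[sub] / dil, -0.99, 0.99))
        # Ki subregions cohere strongly with whole-striatal Ki
        ki_names = ["ki_whole", "ki_limbic", "ki_associative", "ki_sensorimotor"]
        for i, a in enumerate(ki_names):
            for b in ki_names[i + 1:]:
                set_r(a, b, 0.75)
        for a in ki_names:
            set_r(a, "ki_sn_vta", 0.35)
        set_r("chi", "md", -0.10 / dil)
        try:
            np.linalg.cholesky(m + 1e-12 * np.eye(8))
        except np.linalg.LinAlgError:
            raise ValueError(
                f"implied within-{group} correlation matrix is not positive definite:\n{m}"
            )
        return m


def _truncated_normal(rng, mean, sd, low, high, size):
    out = rng.normal(mean, sd, size)
    bad = (out < low) | (out > high)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < low) | (out > high)
    return out


def generate_subjects(config: EffectConfig) -> pd.DataFrame:
    """Draw the covariate table: one row per subject, controls first.

    Marginal frequencies follow the study's demographic table; PANSS
    subscales share a latent severity factor so the total-score SD is
    realistic, and ``panss_total`` is the exact subscale sum.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0]))
    rows = []
    for gi, (group, n) in enumerate(
        (("control", config.n_control), ("patient", config.n_patient))
    ):
        mu, sd = _AGE[gi]
        age = _truncated_normal(rng, mu, sd, 18, 45, n)
        sex = np.where(rng.random(n) < _P_MALE[gi], "male", "female")
        smoking = rng.choice(["current", "past", "never"], size=n, p=_P_SMOKING[group])
        thc = rng.random(n) < _P_THC[gi]
        for i in range(n):
            rec = {
                "subject_id": f"{'HC' if gi == 0 else 'SZ'}{i + 1:03d}",
                "group": group,
                "age": float(age[i]),
                "sex": sex[i],
                "smoking": smoking[i],
                "thc_positive": bool(thc[i]),
            }
            if group == "patient":
                sev = rng.normal()
                sub = {}
                for name, (mu, sd) in _PANSS.items():
                    lo, hi = (7, 49) if name != "general" else (16, 112)
                    val = mu + sd * (_PANSS_SHARED * sev
                                     + np.sqrt(1 - _PANSS_SHARED**2) * rng.normal())
                    sub[name] = int(np.clip(round(val), lo, hi))
                rec["panss_positive"] = sub["positive"]
                rec["panss_negative"] = sub["negative"]
                rec["panss_general"] = sub["general"]
                rec["panss_total"] = sum(sub.values())
                if rng.random() < _UNMEDICATED_FRAC:
                    rec["cpz_equiv"] = 0.0
                else:
                    shape = (_CPZ_MEAN / _CPZ_SD) ** 2
                    rec["cpz_equiv"] = float(rng.gamma(shape, _CPZ_MEAN / shape))
                rec["antipsychotic_free"] = rec["cpz_equiv"] == 0.0
            else:
                rec.update(
                    panss_positive=pd.NA, panss_negative=pd.NA, panss_general=pd.NA,
                    panss_total=pd.NA, cpz_equiv=np.nan, antipsychotic_free=pd.NA,
                )
            rows.append(rec)
    df = pd.DataFrame(rows)
    df["thc_positive"] = df["thc_positive"].astype(bool)
    return df


def generate_roi_measures(subjects: pd.DataFrame, config: EffectConfig) -> pd.DataFrame:
    """Sample ROI scalars with the configured effect size and correlations.

    Susceptibility decomposes as ``mean + sd*(age_r * z_age + sqrt(1-age_r^2)
    * u_chi) + sd * group_d * I(patient)`` where the latent block
    ``(u_chi, u_nmcnr, u_md, u_ki...)`` is multivariate normal with the
    group's (dilution-corrected) correlation matrix, so within-group
    observed correlations hit their targets in expectation.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xAB]))
    n = len(subjects)
    z_age = (subjects["age"].to_numpy(float) - 31.5) / 6.7
    is_patient = (subjects["group"] == "patient").to_numpy()
    out = np.empty((n, 8))
    for group, sel in (("control", ~is_patient), ("patient", is_patient)):
        corr = cfg.correlation_matrix(group)
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(8))
        out[sel] = rng.standard_normal((sel.sum(), 8)) @ chol.T
    u = dict(zip(EffectConfig._VARS, out.T))
    chi = cfg.susceptibility_mean + cfg.susceptibility_sd * (
        cfg.age_r * z_age + np.sqrt(1 - cfg.age_r**2) * u["chi"]
    )
    chi = chi + cfg.susceptibility_sd * cfg.group_d * is_patient
    meas = pd.DataFrame(
        {
            "subject_id": subjects["subject_id"].to_numpy(),
            "sn_vta_susceptibility": chi,
            "sn_vta_nm_cnr": cfg.nmcnr_mean + cfg.nmcnr_sd * u["nmcnr"],
            "sn_vta_md": np.maximum(cfg.md_mean + cfg.md_sd * u["md"], 1e-6),
        }
    )
    for sub in ("whole", "limbic", "associative", "sensorimotor", "sn_vta"):
        ki = cfg.ki_mean + cfg.ki_sd * u[f"ki_{sub}"]
        meas[f"ki_{sub}"] = np.clip(ki, 0.0, 0.0999)
    return meas


# ---------------------------------------------------------------------------
# voxel phantoms


def build_ellipsoid_mask(n_voxels: int, shape, centers_mm, semiaxes_mm,
                         voxel_size=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    """Boolean mask of exactly ``n_voxels`` sites: the lattice sites with the
    smallest ellipsoidal distance to any of the given centers.

    Exact counts make the phantom masks reproduce the study's reported mask
    sizes (1790 SN-VTA, 2967 striatal voxels) to the voxel.
    """
    idx = np.indices(shape, dtype=float)
    mm = [idx[a] * voxel_size[a] + origin[a] for a in range(3)]
    dist = np.full(shape, np.inf)
    for c in np.atleast_2d(centers_mm):
        d = sum(((mm[a] - c[a]) / semiaxes_mm[a]) ** 2 for a in range(3))
        dist = np.minimum(dist, d)
    flat = dist.ravel()
    if n_voxels > flat.size:
        raise ValueError("mask target exceeds lattice size")
    order = np.argsort(flat, kind="stable")
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:n_voxels]] = True
    return mask.reshape(shape)


def grow_contiguous_subset(mask: np.ndarray, n_voxels: int, pole: str = "ventral") -> np.ndarray:
    """A connected subset of ``mask`` grown breadth-first from a pole voxel.

    ``pole`` 'ventral' seeds at the minimum-z mask voxel, 'dorsal' at the
    maximum-z voxel; growth is 26-connected and deterministic (nearest
    voxels to the seed join first), mimicking a focal effect cluster.
    """
    if n_voxels == 0:
        return np.zeros_like(mask)
    sites = np.argwhere(mask)
    if n_voxels > len(sites):
        raise ValueError("subset larger than mask")
    z = sites[:, 2]
    cand = sites[z == (z.min() if pole == "ventral" else z.max())]
    seed = cand[np.lexsort((cand[:, 0], cand[:, 1]))][0]
    d2 = ((sites - seed) ** 2).sum(axis=1)
    order = np.argsort(d2, kind="stable")
    # BFS by distance rank, restricted to stay 26-connected to the seed
    chosen = np.zeros_like(mask)
    chosen[tuple(seed)] = True
    count = 1
    pending = [tuple(s) for s in sites[order[1:]]]
    struct = np.ones((3, 3, 3), bool)
    while count < n_voxels:
        progressed = False
        rest = []
        for s in pending:
            if count >= n_voxels:
                rest.append(s)
                continue
            lo = np.maximum(np.array(s) - 1, 0)
            hi = np.minimum(np.array(s) + 2, mask.shape)
            if chosen[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].any():
                chosen[s] = True
                count += 1
                progressed = True
            else:
                rest.append(s)
        pending = rest
        if not progressed:  # disconnected remainder: fall back to nearest
            s = pending.pop(0)
            chosen[s] = True
            count += 1
    assert ndimage.label(chosen, structure=struct)[1] >= 1
    return chosen


def _smooth_noise(rng, shape, mask, sigma_vox, n_subjects):
    """Per-subject smooth noise fields, standardized to mean 0 / SD 1 over the mask."""
    fields = rng.standard_normal((n_subjects,) + tuple(shape))
    if sigma_vox > 0:
        for i in range(n_subjects):
            fields[i] = ndimage.gaussian_filter(fields[i], sigma_vox, mode="constant")
    m = fields[:, mask]
    m = (m - m.mean(axis=1, keepdims=True)) / m.std(axis=1, keepdims=True)
    return m  # (n_subjects, n_mask_voxels)


def _zero_mean_focal_field(mask, subset):
    """Field = 1 on the focal subset, compensated outside so the mask mean is 0."""
    f = np.zeros(int(mask.sum()))
    sub = subset[mask]
    if sub.any() and (~sub).any():
        f[sub] = 1.0
        f[~sub] = -sub.sum() / (~sub).sum()
    return f


def sn_vta_mask(n_voxels: int = SN_VTA_VOXELS):
    """Bilateral SN-VTA phantom: two mirrored ellipsoids, exact voxel count."""
    shape, origin = (30, 28, 24), (-14.0, -30.0, -24.0)
    mask = build_ellipsoid_mask(
        n_voxels, shape, centers_mm=[(-9, -18, -14), (9, -18, -14)],
        semiaxes_mm=(5.0, 8.0, 7.0), origin=origin,
    )
    return mask, origin


def striatum_mask(n_voxels: int = STRIATUM_VOXELS):
    """Bilateral striatal phantom with exact voxel count."""
    shape, origin = (62, 40, 30), (-31.0, -18.0, -14.0)
    mask = build_ellipsoid_mask(
        n_voxels, shape, centers_mm=[(-24, 2, 4), (24, 2, 4)],
        semiaxes_mm=(6.0, 13.0, 7.0), origin=origin,
    )
    return mask, origin


def generate_voxel_maps(subjects: pd.DataFrame, roi_measures: pd.DataFrame,
                        config: EffectConfig) -> dict:
    """Subject-stacked SN-VTA susceptibility and striatal Ki voxel maps.

    Each subject's map is ``ROI scalar + smooth noise + focal field``, where
    noise and focal field both have zero mean over the mask, so the mask
    mean reproduces the tabulated ROI scalar exactly. The focal group
    effect occupies a contiguous ventral-pole subset of
    ``cluster_fraction * mask size`` SN-VTA voxels; the striatal maps
    concentrate the susceptibility-linked latent signal in a dorsal subset.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xF1]))
    n = len(subjects)
    is_patient = (subjects["group"] == "patient").to_numpy()

    sn_mask, sn_origin = sn_vta_mask()
    st_mask, st_origin = striatum_mask()
    n_cluster = int(round(cfg.cluster_fraction * sn_mask.sum()))
    sn_cluster = grow_contiguous_subset(sn_mask, n_cluster, pole="ventral")
    st_dorsal = grow_contiguous_subset(st_mask, int(round(0.4 * st_mask.sum())), pole="dorsal")

    # SN-VTA susceptibility maps
    noise = _smooth_noise(rng, sn_mask.shape, sn_mask, cfg.noise_smooth_sigma_vox, n)
    focal = _zero_mean_focal_field(sn_mask, sn_cluster)
    amp = np.sign(cfg.group_d or -1.0) * cfg.cluster_effect_sd * cfg.voxel_noise_sd
    chi = roi_measures["sn_vta_susceptibility"].to_numpy(float)
    y = chi[:, None] + cfg.voxel_noise_sd * noise + amp * is_patient[:, None] * focal[None, :]
    sn_stack = VolumeStack(
        np.full((n,) + sn_mask.shape, np.nan), sn_mask, origin=sn_origin
    ).with_matrix(y)

    # striatal Ki maps: latent susceptibility deviation modulates a dorsal field
    noise_k = _smooth_noise(rng, st_mask.shape, st_mask, cfg.noise_smooth_sigma_vox, n)
    dorsal = _zero_mean_focal_field(st_mask, st_dorsal)
    z_chi = (chi - chi.mean()) / (chi.std() or 1.0)
    ki = roi_measures["ki_whole"].to_numpy(float)
    yk = (
        ki[:, None]
        + cfg.ki_voxel_noise_sd * noise_k
        + 0.5 * cfg.ki_voxel_noise_sd * z_chi[:, None] * dorsal[None, :]
    )
    st_stack = VolumeStack(
        np.full((n,) + st_mask.shape, np.nan), st_mask, origin=st_origin
    ).with_matrix(yk)
    return {
        "sn_vta": sn_stack,
        "striatum": st_stack,
        "sn_vta_cluster": sn_cluster,
        "striatum_dorsal": st_dorsal,
    }


def generate_cluster_phantom(n_control, n_patient, n_voxels=500, cluster_voxels=300,
                             effect_sd=1.2, seed=0, smooth_sigma_vox=2.0, null=False):
    """Compact phantom for voxelwise-inference validation.

    A contiguous ``cluster_voxels`` subset of an ``n_voxels`` ellipsoidal
    mask carries an additive group effect of ``effect_sd`` within-voxel
    noise SDs (zero if ``null``); noise is smooth unit-SD Gaussian.
    Returns (stack, cluster_mask_bool_lattice, covariates DataFrame).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E]))
    shape = (14, 14, 12)
    mask = build_ellipsoid_mask(n_voxels, shape, centers_mm=[(6.5, 6.5, 5.5)],
                                semiaxes_mm=(5.0, 5.0, 4.5))
    cluster = grow_contiguous_subset(mask, cluster_voxels, pole="ventral")
    n = n_control + n_patient
    group = np.r_[np.zeros(n_control), np.ones(n_patient)]
    noise = _smooth_noise(rng, shape, mask, smooth_sigma_vox, n)
    y = noise.copy()
    if not null and effect_sd:
        y += effect_sd * group[:, None] * cluster[mask][None, :]
    covars = pd.DataFrame(
        {
            "group": group,
            "age": rng.normal(31.5, 6.7, n),
            "male": (rng.random(n) < 0.7).astype(float),
        }
    )
    stack = VolumeStack(np.full((n,) + shape, np.nan), mask).with_matrix(y)
    return stack, cluster, covars


def generate_latent_pair_blocks(n_subjects, n_predictors, n_responses, latent_r,
                                seed=0, signal_fraction=0.5, loading=1.0, noise_sd=1.0,
                                exact_sample_correlation=True):
    """Two voxel blocks linked through a single subject-level latent pair.

    ``latent_r`` is the correlation between the predictor-block factor and
    the response-block factor; a ``signal_fraction`` of the voxels in each
    block load on its factor with the given loading, the rest are pure
    noise. This is the structure a one-pair PLS model should recover.

    With ``exact_sample_correlation`` (default) the latent correlation is
    planted exactly in sample (the innovation is orthogonalized against the
    predictor factor), so every seed realizes the configured association.
    Null-hypothesis simulations should pass ``False`` so the cohort is a
    typical random draw rather than a constrained one.
    """
    if not -1 < latent_r < 1:
        raise ValueError("latent_r must lie in (-1, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9A]))
    f = rng.standard_normal(n_subjects)
    e = rng.standard_normal(n_subjects)
    if exact_sample_correlation:
        f = (f - f.mean()) / f.std()
        e = e - e.mean()
        e -= (e @ f) / (f @ f) * f
        e /= e.std()
    g = latent_r * f + np.sqrt(1 - latent_r**2) * e
    def block(factor, p):
        k = max(1, int(round(signal_fraction * p)))
        loads = np.zeros(p)
        loads[:k] = loading
        x = factor[:, None] * loads[None, :] + noise_sd * rng.standard_normal((n_subjects, p))
        return x
    return block(f, n_predictors), block(g, n_responses), f, g


# ---------------------------------------------------------------------------
# time-activity curves

_DEFAULT_FRAMES = np.r_[np.full(8, 0.25), np.full(3, 1.0), np.full(5, 2.0), np.full(16, 5.0)]


def default_frame_schedule():
    """95-min framing (8x15 s, 3x1 min, 5x2 min, 16x5 min): starts, durations."""
    durations = _DEFAULT_FRAMES.copy()
    starts = np.r_[0.0, np.cumsum(durations)[:-1]]
    return starts, durations


def _reference_curve(t, tau_uptake=2.0, tau_washout=60.0, amplitude=25.0):
    """Cerebellum-like reference TAC (kBq/mL): bi-exponential bolus shape,
    rising over ~tau_uptake minutes and washing out over ~tau_washout."""
    t = np.asarray(t, dtype=float)
    return amplitude * (np.exp(-t / tau_washout) - np.exp(-t / tau_uptake))


def generate_tacs(ki_true, blood_volume_frac=0.1, duration=95.0, frame_times=None,
                  noise_cv=0.0, seed=0):
    """Target/reference TAC pair satisfying the irreversible-uptake model.

    The target activity is built as ``Ki * cumint(C_ref) + V * C_ref`` using
    the same trapezoidal cumulative integral (zero-anchored at t=0) that the
    Patlak fit uses, so the noiseless construction is recovered exactly at
    any t*. Optional proportional Gaussian noise with coefficient of
    variation ``noise_cv`` is applied to the target curve.
    """
    from .patlak import Tac, cumulative_trapezoid_anchored

    if ki_true < 0:
        raise ValueError("ki_true must be non-negative")
    if blood_volume_frac < 0:
        raise ValueError("blood_volume_frac must be non-negative")
    if frame_times is None:
        starts, durations = default_frame_schedule()
        keep = starts + durations <= duration + 1e-9
        starts, durations = starts[keep], durations[keep]
    else:
        starts, durations = (np.asarray(a, dtype=float) for a in frame_times)
    mid = starts + durations / 2.0
    ref = _reference_curve(mid)
    target = ki_true * cumulative_trapezoid_anchored(ref, mid) + blood_volume_frac * ref
    if noise_cv:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7A]))
        target = target * (1.0 + noise_cv * rng.standard_normal(target.shape))
        target = np.maximum(target, 0.0)
    if (target < 0).any() or (ref < 0).any():
        raise ValueError("negative activities")
    return Tac(frame_mid_times=mid, frame_durations=durations,
               target_activity=target, reference_activity=ref)
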