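"""Patlak-Gjedde reference-region graphical analysis for irreversible
tracers ([18F]-DOPA with a cerebellar reference).

For late times the normalized tissue curve is linear in normalized
integrated reference activity:

    C_t(t) / C_ref(t) = Ki * (int_0^t C_ref dtau) / C_ref(t) + V

and the slope of the ordinary least-squares line over frames with mid-time
>= t* is the influx rate constant Ki (min^-1). Integration is trapezoidal
on frame mid-times with a zero-activity anchor at t = 0, the standard
convention for framed PET data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "Tac",
    "PatlakFit",
    "PatlakRegression",
    "patlak_fit",
    "parametric_ki_map",
    "cumulative_trapezoid_anchored",
]


def cumulative_trapezoid_anchored(values, times):
    """Cumulative trapezoidal integral with an implicit (0, 0) anchor."""
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    t = np.r_[0.0, times]
    v = np.vstack([np.zeros(values.shape[1:]), values]) if values.ndim > 1 else np.r_[0.0, values]
    dt = np.diff(t)
    mids = (v[1:] + v[:-1]) / 2.0
    return np.cumsum((mids.T * dt).T, axis=0)


@dataclass
class Tac:
    """Target/reference time-activity curve pair on a shared frame schedule.

    Times and durations in minutes, activities in kBq/mL.
    """

    frame_mid_times: np.ndarray
    frame_durations: np.ndarray
    target_activity: np.ndarray
    reference_activity: np.ndarray

    def __post_init__(self):
        for f in ("frame_mid_times", "frame_durations", "target_activity",
                  "reference_activity"):
            setattr(self, f, np.asarray(getattr(self, f), dtype=float))
        t = self.frame_mid_times
        if np.any(np.diff(t) <= 0):
            raise ValueError("frame mid-times must be strictly increasing")
        for f in (self.target_activity, self.reference_activity):
            if not np.isfinite(f).all():
                raise ValueError("activities must be finite")
        if (self.reference_activity[1:] <= 0).any():
            raise ValueError("reference activity must be positive after the first frame")


@dataclass
class PatlakFit:
    ki: float
    intercept: float
    t_star: float
    r_squared: float
    n_frames_used: int


class PatlakRegression(BaseEstimator):
    """Patlak graphical estimator (slope = Ki, intercept = apparent volume).

    Parameters
    ----------
    t_star : float
        Start of the linear phase, minutes (default 20).
    weighted : bool
        Weight the OLS by frame duration (default off; the usual choice for
        a late, roughly uniform framing).

    Fitted attributes: ``ki_``, ``intercept_``, ``r_squared_``,
    ``n_frames_used_``, ``linearity_deviation_`` (per-frame residual of the
    linear segment, a diagnostic for t* choice).
    """

    def __init__(self, t_star: float = 20.0, weighted: bool = False):
        self.t_star = t_star
        self.weighted = weighted

    def fit(self, tac: Tac):
        t = tac.frame_mid_times
        ref = tac.reference_activity
        use = t >= self.t_star
        if use.sum() < 3:
            raise ValueError(f"fewer than 3 frames at or after t* = {self.t_star} min")
        if (ref[use] <= 0).any():
            raise ValueError("zero or negative reference activity in the fit window")
        x_all = cumulative_trapezoid_anchored(ref, t) / ref
        y_all = tac.target_activity / ref
        x, y = x_all[use], y_all[use]
        w = tac.frame_durations[use] if self.weighted else np.ones(use.sum())
        W = w / w.sum()
        xm, ym = W @ x, W @ y
        sxx = W @ (x - xm) ** 2
        if sxx == 0:
            raise ValueError("degenerate Patlak abscissa (constant normalized integral)")
        self.ki_ = float(W @ ((x - xm) * (y - ym)) / sxx)
        self.intercept_ = float(ym - self.ki_ * xm)
        resid = y - (self.intercept_ + self.ki_ * x)
        syy = W @ (y - ym) ** 2
        self.r_squared_ = float(1.0 - (W @ resid**2) / syy) if syy > 0 else 1.0
        self.n_frames_used_ = int(use.sum())
        self.linearity_deviation_ = resid
        return self

    def result(self) -> PatlakFit:
        return PatlakFit(self.ki_, self.intercept_, self.t_star,
                         max(0.0, min(1.0, self.r_squared_)), self.n_frames_used_)


def patlak_fit(tac: Tac, t_star: float = 20.0, weighted: bool = False) -> PatlakFit:
    """OLS Patlak fit over frames with mid-time >= t_star; slope is Ki."""
    return PatlakRegression(t_star=t_star, weighted=weighted).fit(tac).result()


def parametric_ki_map(dynamic, reference_tac: Tac, t_star: float = 20.0,
                      sigma_mm: float = 1.0, voxel_size=(1.0, 1.0, 1.0),
                      mask=None, smooth: bool = True):
    """Voxelwise Patlak Ki map from a dynamic volume, then Gaussian smoothing.

    ``dynamic`` has shape (nx, ny, nz, n_frames) with a full TAC per voxel;
    all voxels share the reference curve. Voxels where the fit fails
    (non-positive target data producing a degenerate line) are set to NaN
    and counted.

    Returns (ki_volume, info dict with ``n_failed``).
    """
    from .voxelwise import gaussian_smooth

    dyn = np.asarray(dynamic, dtype=float)
    if dyn.ndim != 4:
        raise ValueError("dynamic volume must be 4D (x, y, z, frame)")
    t = reference_tac.frame_mid_times
    ref = reference_tac.reference_activity
    if dyn.shape[-1] != len(t):
        raise ValueError("frame count mismatch between dynamic volume and reference TAC")
    use = t >= t_star
    if use.sum() < 3:
        raise ValueError("fewer than 3 frames after t*")
    x = (cumulative_trapezoid_anchored(ref, t) / ref)[use]
    flat = dyn.reshape(-1, len(t))
    ok = np.isfinite(flat).all(axis=1)
    if mask is not None:
        ok &= np.asarray(mask, bool).ravel()
    y = flat[:, use] / ref[use]
    xm = x.mean()
    sxx = ((x - xm) ** 2).sum()
    ki = ((y - y.mean(axis=1, keepdims=True)) @ (x - xm)) / sxx
    ki[~ok] = np.nan
    n_failed = int(ok.sum() - np.isfinite(ki[ok]).sum())
    vol = ki.reshape(dyn.shape[:3])
    if smooth:
        vol = gaussian_smooth(vol, sigma_mm=sigma_mm, voxel_size=voxel_size)
    return vol, {"n_failed": n_failed, "t_star": t_star, "n_frames_used": int(use.sum())}
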