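"""Logan graphical analysis: VT per region / per voxel from a dynamic image
and an input function.

For a reversible tracer the late part of the transformed plot
(ordinate int_0^T C_T / C_T(T), abscissa int_0^T Cp / C_T(T)) is linear with
slope VT; points with frame midpoint >= t* enter an ordinary least-squares
fit.  A (0, 0) anchor is prepended to both integrals so they start at
injection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .core_io import DynamicImage, StaticImage
from .errors import StageError, ValidationError
from .idif import InputFunction

__all__ = ["LoganConfig", "LoganFit", "cumtrapz", "logan_fit", "vt_map"]


@dataclass(frozen=True)
class LoganConfig:
    t_star_s: float = 900.0
    min_points: int = 4


@dataclass(frozen=True)
class LoganFit:
    slope: float  # = VT
    intercept: float
    r_squared: float
    n_points: int

    @property
    def vt(self) -> float:
        return self.slope


def cumtrapz(times_s: np.ndarray, values: np.ndarray, anchor: bool = True) -> np.ndarray:
    """Trapezoidal running integral at each sample time.

    With ``anchor`` (default) a leading (0, 0) sample is prepended so the
    integral starts at injection; the returned array still has one value per
    input sample.
    """
    t = np.asarray(times_s, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValidationError("need at least 2 samples to integrate")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")
    if anchor and t[0] > 0:
        t = np.concatenate([[0.0], t])
        v = np.concatenate([np.zeros(v.shape[:-1] + (1,)), v], axis=-1) if v.ndim > 1 else np.concatenate([[0.0], v])
        return cumulative_trapezoid(v, t, axis=-1)
    return cumulative_trapezoid(v, t, axis=-1, initial=0.0)


def _resample_input(inp: InputFunction, times_s: np.ndarray) -> np.ndarray:
    if inp.times_s.shape == np.asarray(times_s).shape and np.allclose(inp.times_s, times_s):
        return inp.values
    return np.interp(times_s, inp.times_s, inp.values, left=0.0)


def logan_fit(
    tissue: np.ndarray,
    times_s: np.ndarray,
    inp: InputFunction,
    cfg: LoganConfig = LoganConfig(),
) -> LoganFit:
    """Fit the Logan plot for one tissue curve sampled at frame midpoints."""
    t = np.asarray(times_s, dtype=float)
    ct = np.asarray(tissue, dtype=float)
    if ct.shape != t.shape:
        raise ValidationError("tissue curve and times must have equal length")
    cp = _resample_input(inp, t)
    int_ct = cumtrapz(t, ct)
    int_cp = cumtrapz(t, cp)
    late = t >= cfg.t_star_s
    usable = late & (ct > 0)
    dropped = int(late.sum() - usable.sum())
    if dropped:
        warnings.warn(f"dropped {dropped} Logan points with non-positive tissue activity")
    if usable.sum() < cfg.min_points:
        raise ValidationError(
            f"only {int(usable.sum())} usable Logan points (need >= {cfg.min_points})"
        )
    x = int_cp[usable] / ct[usable]
    y = int_ct[usable] / ct[usable]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    if not np.isfinite(slope):
        raise ValidationError("Logan fit produced a non-finite slope")
    return LoganFit(float(slope), float(intercept), r2, int(usable.sum()))


def vt_map(
    img: DynamicImage,
    inp: InputFunction,
    cfg: LoganConfig = LoganConfig(),
    brain_mask: np.ndarray | None = None,
) -> StaticImage:
    """Voxel-wise Logan VT inside ``brain_mask`` (NaN sentinel for failures).

    Fully vectorized: integrals and the per-voxel OLS slope are computed with
    array reductions; voxels with fewer than ``min_points`` positive late
    samples are set to NaN.  More than 50% failed voxels raises StageError.
    """
    if brain_mask is None:
        brain_mask = np.ones(img.shape3, dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise ValidationError("brain mask is empty")
    t = img.schedule.midpoint_s
    cp = _resample_input(inp, t)
    late = t >= cfg.t_star_s
    if late.sum() < cfg.min_points:
        raise ValidationError("fewer than min_points frames beyond t*")

    Y = np.asarray(img.voxels[brain_mask], dtype=float)  # (V, F)
    t_anch = np.concatenate([[0.0], t]) if t[0] > 0 else t
    Y_anch = np.concatenate([np.zeros((Y.shape[0], 1)), Y], axis=1) if t[0] > 0 else Y
    int_ct = cumulative_trapezoid(Y_anch, t_anch, axis=1)[:, -img.schedule.n_frames :]
    int_cp = cumtrapz(t, cp)

    ok = (Y > 0) & late[None, :]
    n_ok = ok.sum(axis=1)
    good = n_ok >= cfg.min_points
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(ok, int_cp[None, :] / Y, 0.0)
        y = np.where(ok, int_ct / Y, 0.0)
    n = np.maximum(n_ok, 1)
    mx = x.sum(axis=1) / n
    my = y.sum(axis=1) / n
    sxx = (np.where(ok, (x - mx[:, None]) ** 2, 0.0)).sum(axis=1)
    sxy = (np.where(ok, (x - mx[:, None]) * (y - my[:, None]), 0.0)).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
    slope[~good | ~np.isfinite(slope)] = np.nan

    n_fail = int(np.isnan(slope).sum())
    if n_fail > 0.5 * slope.size:
        raise StageError(f"Logan failed in {n_fail}/{slope.size} voxels (> 50%)")
    out = np.full(img.shape3, np.nan)
    out[brain_mask] = slope
    return StaticImage(out, img.spacing_mm, quantity="VT")
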