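"""Image-derived input function extraction.

Spatial ICA parcellates the early dynamic frames; the component best
matching a carotid spatial prior is binarized, restricted to a vessel
segment mask, eroded to shed wall voxels, and the per-frame maximum inside
the surviving mask becomes the input-function proxy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .core_io import DynamicImage, erode_mask, frames_in_window
from .errors import ExtractionError, ValidationError

__all__ = [
    "ICAResult",
    "CarotidMask",
    "InputFunction",
    "run_spatial_ica",
    "select_carotid_component",
    "binarize_and_restrict",
    "extract_idif",
    "run_idif",
]


@dataclass
class InputFunction:
    """Sampled blood-activity proxy Cp(t) at frame midpoints."""

    times_s: np.ndarray
    values: np.ndarray
    source: str = "idif"  # idif | true_aif

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.shape != self.values.shape:
            raise ValidationError("times and values must have equal length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValidationError("input-function times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("input-function values must be finite")


@dataclass
class ICAResult:
    maps: np.ndarray  # (n_components, x, y, z), zero outside analysis mask
    timecourses: np.ndarray  # (n_frames_used, n_components)
    n_components: int
    frame_indices: np.ndarray
    analysis_mask: np.ndarray


@dataclass
class CarotidMask:
    pre_erosion: np.ndarray
    post_erosion: np.ndarray | None = None
    component_index: int = -1
    template_correlation: float = np.nan


def run_spatial_ica(
    img: DynamicImage,
    analysis_mask: np.ndarray,
    n_components: int = 10,
    seed: int = 0,
    early_window_s: tuple | None = (0.0, 300.0),
    max_iter: int = 1000,
    tol: float = 1e-4,
) -> ICAResult:
    """Spatial ICA of the frames-x-voxels matrix restricted to a mask.

    Frames are limited to an early window (default first 300 s) where vessel
    voxels carry a temporally coherent bolus signal.  Components are
    sign-aligned so the peak absolute loading is positive; loadings are
    unit-variance.  Deterministic given ``seed``.  If the data rank is below
    ``n_components`` the count is reduced with a warning.
    """
    analysis_mask = np.asarray(analysis_mask, dtype=bool)
    if not analysis_mask.any():
        raise ValidationError("analysis mask is empty")
    if early_window_s is None:
        frames = np.arange(img.schedule.n_frames)
    else:
        frames = frames_in_window(img.schedule, *early_window_s)
    if n_components >= frames.size:
        raise ValidationError(
            f"n_components ({n_components}) must be < number of frames used ({frames.size})"
        )
    X = np.asarray(img.voxels[analysis_mask][:, frames], dtype=float)  # (V, F)
    Xc = X - X.mean(axis=0, keepdims=True)
    sv = np.linalg.svd(Xc.T @ Xc, compute_uv=False)
    rank = int((sv > sv[0] * 1e-10).sum()) if sv[0] > 0 else 0
    k = n_components
    if rank < n_components:
        warnings.warn(f"data rank {rank} < {n_components} components; reducing")
        k = max(rank, 1)
    ica = FastICA(
        n_components=k,
        random_state=seed,
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        S = ica.fit_transform(X)  # (V, k): spatial loadings
    A = ica.mixing_  # (F, k): component timecourses
    flip = np.sign(S[np.abs(S).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    S = S * flip
    A = A * flip
    maps = np.zeros((k,) + img.shape3)
    maps[:, analysis_mask] = S.T
    return ICAResult(maps, A, k, frames, analysis_mask)


def select_carotid_component(ica: ICAResult, template_mask: np.ndarray, floor: float = 0.1):
    """Pick the component whose |loadings| best correlate with a binary prior.

    Returns ``(index, correlation)``; correlation below ``floor`` signals an
    extraction failure.
    """
    template_mask = np.asarray(template_mask, dtype=bool)
    if template_mask.shape != ica.analysis_mask.shape:
        raise ValidationError("template mask is not on the image grid")
    tmpl = template_mask[ica.analysis_mask].astype(float)
    if tmpl.std() == 0:
        raise ValidationError("template is constant inside the analysis mask")
    corrs = np.empty(ica.n_components)
    for i in range(ica.n_components):
        m = np.abs(ica.maps[i][ica.analysis_mask])
        corrs[i] = 0.0 if m.std() == 0 else float(np.corrcoef(m, tmpl)[0, 1])
    best = int(np.argmax(corrs))
    if corrs[best] < floor:
        raise ExtractionError(
            f"best template correlation {corrs[best]:.3f} below floor {floor}"
        )
    return best, float(corrs[best])


def binarize_and_restrict(
    map3d: np.ndarray,
    segment_mask: np.ndarray,
    z_thresh: float = 2.0,
    analysis_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Threshold standardized loadings at ``z_thresh`` and clip to the segment."""
    if not z_thresh > 0:
        raise ValidationError("z_thresh must be > 0")
    map3d = np.asarray(map3d, dtype=float)
    segment_mask = np.asarray(segment_mask, dtype=bool)
    if analysis_mask is None:
        analysis_mask = np.ones(map3d.shape, dtype=bool)
    vals = map3d[analysis_mask]
    sd = vals.std()
    if sd == 0:
        raise ExtractionError("component map is constant; cannot standardize")
    z = np.zeros_like(map3d)
    z[analysis_mask] = (vals - vals.mean()) / sd
    out = (z >= z_thresh) & segment_mask & analysis_mask
    if not out.any():
        raise ExtractionError("no voxel survives thresholding inside the segment")
    return out


def extract_idif(
    img: DynamicImage, mask: CarotidMask, erosion_voxels: int = 1
) -> InputFunction:
    """Per-frame maximum inside the eroded carotid mask, at frame midpoints.

    If erosion empties the mask, falls back to the pre-erosion mask with a
    warning; an empty pre-erosion mask is an extraction failure.
    """
    pre = np.asarray(mask.pre_erosion, dtype=bool)
    if not pre.any():
        raise ExtractionError("pre-erosion carotid mask is empty")
    if erosion_voxels > 0:
        radius = erosion_voxels * min(img.spacing_mm)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            eroded = erode_mask(pre, radius, img.spacing_mm)
        if not eroded.any():
            warnings.warn("erosion emptied the carotid mask; using pre-erosion mask")
            eroded = pre
    else:
        eroded = pre
    mask.post_erosion = eroded
    values = img.voxels[eroded].max(axis=0).astype(float)
    return InputFunction(img.schedule.midpoint_s, values, source="idif")


def run_idif(
    img: DynamicImage,
    segment_mask: np.ndarray,
    template_mask: np.ndarray,
    analysis_mask: np.ndarray | None = None,
    n_components: int = 10,
    seed: int = 0,
    z_thresh: float = 2.0,
    erosion_voxels: int = 1,
    early_window_s: tuple | None = (0.0, 300.0),
    correlation_floor: float = 0.1,
):
    """Full IDIF chain; returns ``(InputFunction, CarotidMask, qc_dict)``."""
    if analysis_mask is None:
        analysis_mask = img.voxels.max(axis=3) > 0
    ica = run_spatial_ica(
        img, analysis_mask, n_components=n_components, seed=seed, early_window_s=early_window_s
    )
    idx, corr = select_carotid_component(ica, template_mask, floor=correlation_floor)
    pre = binarize_and_restrict(ica.maps[idx], segment_mask, z_thresh, analysis_mask)
    cmask = CarotidMask(pre_erosion=pre, component_index=idx, template_correlation=corr)
    idif = extract_idif(img, cmask, erosion_voxels=erosion_voxels)
    qc = {
        "component_index": idx,
        "template_correlation": corr,
        "n_components": ica.n_components,
        "mask_voxels_pre": int(pre.sum()),
        "mask_voxels_post": int(cmask.post_erosion.sum()),
    }
    return idif, cmask, qc
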