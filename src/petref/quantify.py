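"""Reference-scaled readouts: static-window SUVr and VTr maps and ROI values."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    DynamicImage,
    LabelAtlas,
    StaticImage,
    frames_in_window,
    region_mean,
    time_weighted_mean_image,
)
from .errors import ValidationError

__all__ = [
    "suvr_map",
    "vtr_map",
    "bilateral_target_groups",
    "cohort_readouts",
    "DEFAULT_WINDOW_S",
]

DEFAULT_WINDOW_S = (1200.0, 2400.0)  # the 20-40 min static window


def _reference_scale(map3d: StaticImage, reference_mask: np.ndarray) -> float:
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if not reference_mask.any():
        raise ValidationError("reference mask is empty")
    vals = map3d.voxels[reference_mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValidationError("reference mask has no finite values")
    ref = float(vals.mean())
    if ref <= 0:
        raise ValidationError(f"reference mean is non-positive ({ref})")
    return ref


def suvr_map(
    img: DynamicImage,
    reference_mask: np.ndarray,
    window_s: tuple = DEFAULT_WINDOW_S,
) -> StaticImage:
    """Static-window SUV image divided by its mean over the reference mask."""
    frames = frames_in_window(img.schedule, *window_s)
    static = time_weighted_mean_image(img, frames)
    ref = _reference_scale(static, reference_mask)
    return StaticImage(static.voxels / ref, img.spacing_mm, quantity="SUVr")


def vtr_map(vt: StaticImage, reference_mask: np.ndarray) -> StaticImage:
    """VT map divided by its mean over the reference mask."""
    ref = _reference_scale(vt, reference_mask)
    return StaticImage(vt.voxels / ref, vt.spacing_mm, quantity="VTr")


def bilateral_target_groups(atlas: LabelAtlas, roles: Sequence[str] = ("target", "cortical_target")) -> dict:
    """Group atlas labels into named targets, merging ``_l``/``_r`` pairs.

    Returns ``{base_name: [labels]}``; bilateral regions are later averaged as
    the voxel-weighted mean over the union of both hemispheres' voxels.
    """
    groups: dict = {}
    for role in roles:
        for lbl in atlas.labels_with_role(role):
            name = atlas.name_of(lbl)
            base = name[:-2] if name.endswith(("_l", "_r")) else name
            groups.setdefault(base, []).append(lbl)
    return groups


def cohort_readouts(
    images: Mapping[str, DynamicImage],
    vt_maps: Mapping[str, StaticImage],
    atlas: LabelAtlas,
    references: Mapping[str, np.ndarray],
    targets: Mapping[str, Sequence[int]] | None = None,
    window_s: tuple = DEFAULT_WINDOW_S,
) -> pd.DataFrame:
    """All (target x reference x {suvr, vtr}) readouts, one row per subject.

    Column naming: ``{target}_{measure}_{reference}``.  Deterministic; a
    subject present in ``images`` but missing from ``vt_maps`` (or vice
    versa) raises ValidationError listing the offender.
    """
    if targets is None:
        targets = bilateral_target_groups(atlas)
    missing = sorted(set(images) ^ set(vt_maps))
    if missing:
        raise ValidationError(f"subjects missing an image or VT map: {missing}")
    rows = {}
    for sid in images:
        row = {}
        for ref_name, ref_mask in references.items():
            smap = suvr_map(images[sid], ref_mask, window_s)
            vmap = vtr_map(vt_maps[sid], ref_mask)
            for tgt_name, labels in targets.items():
                row[f"{tgt_name}_suvr_{ref_name}"] = region_mean(smap, atlas, labels)
                row[f"{tgt_name}_vtr_{ref_name}"] = region_mean(vmap, atlas, labels)
        rows[sid] = row
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)
    df.index.name = "id"
    return df
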