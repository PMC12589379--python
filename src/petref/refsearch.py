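"""Data-driven reference-region search.

Each candidate white-matter region is eroded, used to intensity-normalize
every discovery subject's VT map, and scored by the covariate-adjusted
patient-vs-control difference of the target-region VTr.  Candidates
surviving family-wise error correction are merged (union of eroded masks)
into a single optimized reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import CohortTable, LabelAtlas, StaticImage, erode_mask, region_mean
from .errors import ValidationError
from .quantify import vtr_map
from .stats import ancova

__all__ = ["CandidateResult", "ReferenceSearchReport", "score_candidate", "fwe_adjust", "search_reference"]


@dataclass
class CandidateResult:
    label: int
    name: str
    eroded_voxels: int
    usable: bool
    t: float = np.nan
    p: float = np.nan
    p_adjusted: float = np.nan
    selected: bool = False
    adjusted_means: dict = field(default_factory=dict)
    note: str = ""


@dataclass
class ReferenceSearchReport:
    candidates: list  # CandidateResult, ranked by p
    merged_mask: np.ndarray | None
    alpha: float
    erosion_mm: float
    fwe_method: str
    discovery_groups: tuple
    n_family: int
    success: bool

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "label": c.label,
                "name": c.name,
                "eroded_voxels": c.eroded_voxels,
                "usable": c.usable,
                "t": c.t,
                "p": c.p,
                "p_adjusted": c.p_adjusted,
                "selected": c.selected,
                "note": c.note,
            }
            for c in self.candidates
        ]
        return pd.DataFrame(rows)


def _discovery_arrays(cohort: CohortTable, patient_group: str, control_group: str):
    recs = [r for r in cohort.records if r.group in (patient_group, control_group)]
    if any(r.split == "validation" for r in recs):
        raise ValidationError(
            "refusing to run the reference search on subjects tagged 'validation'"
        )
    groups = np.asarray([r.group for r in recs])
    for gname in (patient_group, control_group):
        if (groups == gname).sum() < 3:
            raise ValidationError(f"discovery group {gname!r} needs n >= 3")
    return recs


def score_candidate(
    vt_maps: Mapping[str, StaticImage],
    atlas: LabelAtlas,
    target_labels: Sequence[int],
    candidate_label: int,
    cohort: CohortTable,
    patient_group: str = "PSP-RS",
    control_group: str = "HC",
    erosion_mm: float = 2.0,
    min_voxels: int = 10,
) -> CandidateResult:
    """Score one candidate reference by ANCOVA-adjusted group separation.

    The per-subject readout is the target-region mean of the VT map divided
    by the eroded-candidate mean (VTr).  Sign convention: positive t means
    patient above control.  A candidate whose eroded mask is smaller than
    ``min_voxels`` is marked unusable and excluded from the family.
    """
    name = atlas.name_of(candidate_label)
    cand_mask = atlas.mask(candidate_label)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        eroded = erode_mask(cand_mask, erosion_mm, atlas.spacing_mm)
    n_vox = int(eroded.sum())
    if n_vox < min_voxels:
        warnings.warn(f"candidate {name}: {n_vox} eroded voxels < {min_voxels}; excluded")
        return CandidateResult(candidate_label, name, n_vox, usable=False, note="eroded below min_voxels")

    recs = _discovery_arrays(cohort, patient_group, control_group)
    target_mask = atlas.mask(list(target_labels))
    if not target_mask.any():
        raise ValidationError("target labels cover no voxels")
    values, groups, ages, sexes = [], [], [], []
    for r in recs:
        if r.id not in vt_maps:
            raise ValidationError(f"no VT map for discovery subject {r.id}")
        vmap = vtr_map(vt_maps[r.id], eroded)
        vals = vmap.voxels[target_mask]
        values.append(float(vals[np.isfinite(vals)].mean()))
        groups.append(r.group)
        ages.append(r.age)
        sexes.append(r.sex)
    res = ancova(values, groups, age=ages, sex=sexes, reference=control_group)
    return CandidateResult(
        candidate_label,
        name,
        n_vox,
        usable=True,
        t=res.group_t,
        p=res.group_t_p,
        adjusted_means=res.adjusted_means,
    )


def fwe_adjust(p_values, method: str = "bonferroni") -> np.ndarray:
    """Family-wise error adjustment (Bonferroni default, Holm optional)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    if method == "holm":
        order = np.argsort(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(1.0, running)
        return adj
    raise ValidationError(f"unknown FWE method {method!r}")


def search_reference(
    vt_maps: Mapping[str, StaticImage],
    atlas: LabelAtlas,
    cohort: CohortTable,
    target_labels: Sequence[int] | None = None,
    patient_group: str = "PSP-RS",
    control_group: str = "HC",
    alpha: float = 0.05,
    erosion_mm: float = 2.0,
    min_voxels: int = 10,
    fwe_method: str = "bonferroni",
    require_positive: bool = False,
) -> ReferenceSearchReport:
    """Score all candidate references, FWE-correct, and merge the survivors.

    ``require_positive`` restricts selection to candidates with patient >
    control direction.  Deterministic given its inputs; zero survivors yields
    ``success=False`` with the ranked table still populated.
    """
    candidates = atlas.labels_with_role("candidate_reference")
    if len(candidates) < 2:
        raise ValidationError("atlas must flag >= 2 candidate_reference labels")
    if target_labels is None:
        target_labels = atlas.labels_with_role("target")
        if not target_labels:
            raise ValidationError("atlas flags no target labels")
    results = [
        score_candidate(
            vt_maps, atlas, target_labels, lbl, cohort,
            patient_group=patient_group, control_group=control_group,
            erosion_mm=erosion_mm, min_voxels=min_voxels,
        )
        for lbl in candidates
    ]
    usable = [c for c in results if c.usable]
    if usable:
        adj = fwe_adjust([c.p for c in usable], method=fwe_method)
        for c, pa in zip(usable, adj):
            c.p_adjusted = float(pa)
            c.selected = bool(pa < alpha) and (not require_positive or c.t > 0)
    selected = [c for c in results if c.selected]
    merged = None
    if selected:
        merged = np.zeros(atlas.labels.shape, dtype=bool)
        for c in selected:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                merged |= erode_mask(atlas.mask(c.label), erosion_mm, atlas.spacing_mm)
    ranked = sorted(results, key=lambda c: (not c.usable, c.p if np.isfinite(c.p) else 2.0))
    return ReferenceSearchReport(
        candidates=ranked,
        merged_mask=merged,
        alpha=alpha,
        erosion_mm=erosion_mm,
        fwe_method=fwe_method,
        discovery_groups=(patient_group, control_group),
        n_family=len(usable),
        success=merged is not None,
    )
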