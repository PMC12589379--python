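"""Synthetic dynamic-PET phantom cohorts with known kinetic ground truth.

The generator plants: a tri-exponential bolus input carried by a small
carotid-like tube, one-tissue-compartment tissue kinetics per region
(VT = K1/k2), group-dependent VT elevation in a pallidum-like target,
cortical elevation in an AD-like group, optional contamination of the
conventional cerebellar-like reference and of designated white-matter
candidate slabs, age/sex covariates, a severity score driven by true target
VT, and frame-duration-dependent Gaussian noise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .core_io import (
    CohortTable,
    DynamicImage,
    FrameSchedule,
    LabelAtlas,
    SubjectRecord,
    default_frame_schedule,
    read_atlas,
    read_cohort_table,
    read_dynamic_image,
    write_atlas,
    write_cohort_table,
    write_dynamic_image,
)
from .errors import ValidationError

__all__ = [
    "AIFParams",
    "KineticParams",
    "PhantomSpec",
    "Cohort",
    "aif",
    "tissue_tac",
    "frame_average",
    "build_atlas",
    "simulate_subject",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]


# ---------------------------------------------------------------------------
# input function and tissue kinetics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AIFParams:
    """Tri-exponential bolus input function.

    Cp(t) = ((A1*u - A2 - A3) e^{L1 u} + A2 e^{L2 u} + A3 e^{L3 u}) for
    u = t - delay_s >= 0, else 0.  Cp(delay) = 0 by construction.  Parameter
    sets producing a negative Cp anywhere on [0, 3600] s are rejected.
    """

    A1: float = 0.075  # amplitude rate, activity / s
    A2: float = 0.28
    A3: float = 0.15
    L1: float = -0.035  # s^-1, most negative (bolus peak decay)
    L2: float = -0.0032
    L3: float = -0.00012
    delay_s: float = 0.0

    def __post_init__(self):
        if not (self.L1 < self.L2 < 0 and self.L3 < 0):
            raise ValidationError("rate constants must be negative with L1 most negative")
        if self.delay_s < 0:
            raise ValidationError("delay_s must be >= 0")
        t = np.arange(0.0, 3600.0 + 0.5, 0.5)
        cp = aif(t, self)
        if np.any(cp < -1e-12):
            raise ValidationError("AIF parameters produce negative Cp on [0, 3600] s")


def aif(t_s, p: AIFParams) -> np.ndarray:
    """Evaluate the bolus input function at times ``t_s`` (seconds)."""
    t = np.asarray(t_s, dtype=float)
    u = t - p.delay_s
    cp = np.where(
        u < 0,
        0.0,
        (p.A1 * u - p.A2 - p.A3) * np.exp(p.L1 * np.clip(u, 0, None))
        + p.A2 * np.exp(p.L2 * np.clip(u, 0, None))
        + p.A3 * np.exp(p.L3 * np.clip(u, 0, None)),
    )
    return cp if cp.shape else float(cp)


@dataclass(frozen=True)
class KineticParams:
    """One-tissue-compartment parameters; implied VT = K1/k2."""

    K1: float  # s^-1
    k2: float  # s^-1

    def __post_init__(self):
        if self.K1 < 0:
            raise ValidationError("K1 must be >= 0")
        if not self.k2 > 0:
            raise ValidationError("k2 must be > 0")

    @property
    def vt(self) -> float:
        return self.K1 / self.k2


def tissue_tac(p: KineticParams, cp_fine: np.ndarray, t_grid: np.ndarray) -> np.ndarray:
    """One-tissue-compartment tissue curve by exact piecewise-linear convolution.

    C_T(t) = K1 * int_0^t e^{-k2 (t - tau)} Cp(tau) dtau, with Cp taken as
    piecewise linear between samples of the uniform fine grid (step <= 1 s).
    The recursion over grid intervals is exact for piecewise-linear Cp, so
    the only error is the (tiny) linear-interpolation error of Cp itself.
    """
    t = np.asarray(t_grid, dtype=float)
    cp = np.asarray(cp_fine, dtype=float)
    if t.ndim != 1 or t.size < 2 or cp.shape != t.shape:
        raise ValidationError("t_grid and cp must be 1-D arrays of equal length >= 2")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValidationError("t_grid must be strictly increasing")
    if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
        raise ValidationError("t_grid must be uniformly spaced")
    if dt[0] > 1.0 + 1e-9:
        raise ValidationError("t_grid step must be <= 1 s")
    if p.K1 == 0:
        return np.zeros_like(t)
    h = float(dt[0])
    e = np.exp(-p.k2 * h)
    alpha = (1.0 - e) / p.k2
    a = cp[:-1]
    b = (cp[1:] - cp[:-1]) / h
    # per-interval exact integral of e^{-k2 (h - tau)} (a + b tau) over [0, h]
    g = p.K1 * (a * alpha + b * (h - alpha) / p.k2)
    out = np.empty_like(t)
    out[0] = 0.0
    out[1:] = lfilter([1.0], [1.0, -e], g)
    return out


def frame_average(t_grid: np.ndarray, curve: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Duration-weighted average of a fine-grid curve over each frame interval.

    Exact for curves piecewise linear on the grid (trapezoid rule with
    interpolated frame-boundary values).
    """
    t = np.asarray(t_grid, dtype=float)
    y = np.asarray(curve, dtype=float)
    if t[0] > 0 or t[-1] < schedule.total_s - 1e-9:
        raise ValidationError("fine grid must cover [0, end of last frame]")
    out = np.empty(schedule.n_frames)
    for i, (t0, t1) in enumerate(zip(schedule.start_s, schedule.end_s)):
        lo = np.searchsorted(t, t0, side="right")
        hi = np.searchsorted(t, t1, side="left")
        tt = np.concatenate([[t0], t[lo:hi], [t1]])
        yy = np.concatenate([[np.interp(t0, t, y)], y[lo:hi], [np.interp(t1, t, y)]])
        out[i] = np.trapezoid(yy, tt) / (t1 - t0)
    return out


# ---------------------------------------------------------------------------
# phantom specification and geometry
# ---------------------------------------------------------------------------


def _default_cohort() -> dict:
    return {
        "discovery": {"PSP-RS": 8, "HC": 8},
        "validation": {"PSP-nonRS": 8, "HC": 8, "AD": 4, "alpha-syn": 4},
    }


def _default_baseline_vt() -> dict:
    return {
        "pallidum": 3.0,
        "temporal_meta": 2.6,
        "inferior_cerebellum": 2.2,
        "wm_candidate": 2.0,
        "background": 2.0,
    }


@dataclass
class PhantomSpec:
    """Full description of a simulated cohort; every knob is config-exposed."""

    shape: tuple = (32, 32, 20)
    spacing_mm: tuple = (2.0, 2.0, 2.0)
    n_candidates: int = 8
    contaminated_candidates: tuple = (6, 7)  # 0-based candidate indices
    cohort: dict = field(default_factory=_default_cohort)
    baseline_vt: dict = field(default_factory=_default_baseline_vt)
    k2_s: float = 0.002
    # group -> multiplicative VT factor on the pallidum-like target
    target_elevation: dict = field(default_factory=lambda: {"PSP-RS": 1.6, "PSP-nonRS": 1.6, "AD": 1.1})
    # group -> multiplicative VT factor on the cortical target
    cortical_elevation: dict = field(default_factory=lambda: {"AD": 1.8})
    # groups whose cerebellar-like reference and designated candidates are contaminated
    contamination_groups: tuple = ("PSP-RS", "PSP-nonRS")
    contamination_factor: float = 1.6
    between_subject_sd: float = 0.08  # lognormal sigma on per-region VT
    subject_scale_sd: float = 0.05  # lognormal sigma on global amplitude
    age_mean: float = 70.0
    age_sd: float = 8.0
    age_min: float = 40.0
    male_fraction: float = 0.5
    age_vt_slope: float = 0.0  # fractional VT change per year from age_mean
    severity_intercept: float = 20.0
    severity_slope: float = 5.0  # severity units per unit true target VT
    severity_sd: float = 0.8
    severity_groups: tuple = ("PSP-RS", "PSP-nonRS")
    sigma0: float = 0.02
    noise_floor: float = 1e-3  # epsilon in sqrt(max(value, eps) / duration)
    aif: AIFParams = field(default_factory=AIFParams)
    fine_dt_s: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if any(n < 2 for split in self.cohort.values() for n in split.values()):
            raise ValidationError("all group sizes must be >= 2")
        if any(i >= self.n_candidates for i in self.contaminated_candidates):
            raise ValidationError("contaminated candidate index out of range")

    @property
    def schedule(self) -> FrameSchedule:
        return default_frame_schedule()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["aif"] = dataclasses.asdict(self.aif)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PhantomSpec":
        d = dict(d)
        if "aif" in d and isinstance(d["aif"], Mapping):
            d["aif"] = AIFParams(**d["aif"])
        for key in ("shape", "spacing_mm", "contaminated_candidates", "contamination_groups", "severity_groups"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


# fixed label ids
LBL_PALLIDUM_L = 1
LBL_PALLIDUM_R = 2
LBL_TEMPORAL = 3
LBL_CEREBELLUM = 4
LBL_CANDIDATE0 = 10  # candidates occupy 10 .. 10 + n_candidates - 1
LBL_BACKGROUND = 100
LBL_CAROTID_TUBE = 200
LBL_CAROTID_SEGMENT = 201


def build_atlas(spec: PhantomSpec) -> tuple[LabelAtlas, dict]:
    """Construct the phantom parcellation and auxiliary masks.

    Returns the atlas plus a dict with 'carotid_template' (binary prior for
    component selection), 'carotid_pv' (partial-volume factor map for the
    tube) and 'brain_mask'.
    """
    nx, ny, nz = spec.shape
    if nx < 24 or ny < 20 or nz < 14:
        raise ValidationError("phantom grid must be at least 24 x 20 x 14")
    labels = np.zeros(spec.shape, dtype=np.int32)
    nz_neck = max(4, nz // 5)

    # --- neck: carotid tube (plus-shaped cross-section) and search segment
    cx, cy = nx // 2, ny // 4
    pv = np.zeros(spec.shape, dtype=float)
    for z in range(0, nz_neck):
        labels[cx, cy, z] = LBL_CAROTID_TUBE
        pv[cx, cy, z] = 1.0
        for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            labels[cx + dx, cy + dy, z] = LBL_CAROTID_TUBE
            pv[cx + dx, cy + dy, z] = 0.6
    segment = np.zeros(spec.shape, dtype=bool)
    segment[cx - 3 : cx + 4, cy - 3 : cy + 4, 1:nz_neck] = True
    seg_only = segment & (labels == 0)
    labels[seg_only] = LBL_CAROTID_SEGMENT

    # --- brain box above the neck
    zb0, zb1 = nz_neck, nz
    brain = np.zeros(spec.shape, dtype=bool)
    brain[2 : nx - 2, 2 : ny - 2, zb0:zb1] = True
    labels[brain] = LBL_BACKGROUND

    def place(lbl, x0, x1, y0, y1, z0, z1):
        block = np.zeros(spec.shape, dtype=bool)
        block[x0:x1, y0:y1, z0:z1] = True
        block &= labels == LBL_BACKGROUND
        labels[block] = lbl

    # cerebellum-like reference: central slab just above the neck
    place(LBL_CEREBELLUM, nx // 2 - 5, nx // 2 + 5, ny // 2 - 5, ny // 2 + 5, zb0, zb0 + 2)

    # candidate WM slabs: two rows of boxes
    zc0 = zb0 + 2
    zc1 = min(zc0 + 3, zb1 - 4)
    per_row = (spec.n_candidates + 1) // 2
    xw = max(5, (nx - 4) // per_row)
    for i in range(spec.n_candidates):
        row, col = divmod(i, per_row)
        x0 = 2 + col * xw
        x1 = min(x0 + xw - 1, nx - 2)
        y0 = 2 if row == 0 else ny // 2 + 1
        y1 = ny // 2 - 1 if row == 0 else ny - 2
        if x1 - x0 < 3 or y1 - y0 < 3:
            raise ValidationError("grid too small for requested candidate count")
        place(LBL_CANDIDATE0 + i, x0, x1, y0, y1, zc0, zc1)

    # targets in the upper slab
    zt0 = zc1 + 1
    zt1 = min(zt0 + 3, zb1)
    place(LBL_PALLIDUM_L, nx // 2 - 6, nx // 2 - 2, ny // 2 - 2, ny // 2 + 2, zt0, zt1)
    place(LBL_PALLIDUM_R, nx // 2 + 2, nx // 2 + 6, ny // 2 - 2, ny // 2 + 2, zt0, zt1)
    place(LBL_TEMPORAL, 3, nx - 3, ny - 7, ny - 3, zt0, zt1)

    rows = [
        (LBL_PALLIDUM_L, "pallidum_l", "target"),
        (LBL_PALLIDUM_R, "pallidum_r", "target"),
        (LBL_TEMPORAL, "temporal_meta", "cortical_target"),
        (LBL_CEREBELLUM, "inferior_cerebellum", "conventional_reference"),
        (LBL_BACKGROUND, "background", "other"),
        (LBL_CAROTID_TUBE, "carotid_tube", "other"),
        (LBL_CAROTID_SEGMENT, "carotid_segment", "carotid_segment"),
    ]
    for i in range(spec.n_candidates):
        rows.append((LBL_CANDIDATE0 + i, f"wm_candidate_{i:02d}", "candidate_reference"))
    table = pd.DataFrame(sorted(rows), columns=["label", "name", "role"])
    atlas = LabelAtlas(labels, table, spec.spacing_mm)
    aux = {
        "carotid_template": labels == LBL_CAROTID_TUBE,
        "carotid_pv": pv,
        "brain_mask": labels >= 1,
    }
    return atlas, aux


# ---------------------------------------------------------------------------
# subject- and cohort-level simulation
# ---------------------------------------------------------------------------


def _region_vt(spec: PhantomSpec, name: str, group: str) -> float:
    """Noise-free group-level VT for a named region."""
    if name.startswith("pallidum"):
        base = spec.baseline_vt["pallidum"]
        return base * spec.target_elevation.get(group, 1.0)
    if name == "temporal_meta":
        return spec.baseline_vt["temporal_meta"] * spec.cortical_elevation.get(group, 1.0)
    if name == "inferior_cerebellum":
        base = spec.baseline_vt["inferior_cerebellum"]
        if group in spec.contamination_groups:
            base *= spec.contamination_factor
        return base
    if name.startswith("wm_candidate"):
        base = spec.baseline_vt["wm_candidate"]
        idx = int(name.rsplit("_", 1)[1])
        if idx in spec.contaminated_candidates and group in spec.contamination_groups:
            base *= spec.contamination_factor
        return base
    if name == "background":
        return spec.baseline_vt["background"]
    raise ValidationError(f"no kinetic assignment for region {name!r}")


def simulate_subject(
    spec: PhantomSpec,
    record: SubjectRecord,
    rng: np.random.Generator,
    atlas: LabelAtlas | None = None,
    aux: dict | None = None,
) -> tuple[DynamicImage, dict]:
    """Simulate one subject's dynamic image; returns (image, ground-truth row).

    Ground truth holds the realized per-region VT (after group effects, age
    slope and between-subject jitter), the subject's global amplitude scale
    and the frame-averaged true input curve.
    """
    if atlas is None or aux is None:
        atlas, aux = build_atlas(spec)
    sched = spec.schedule
    t = np.arange(0.0, sched.total_s + spec.fine_dt_s / 2, spec.fine_dt_s)

    scale = float(np.exp(rng.normal(0.0, spec.subject_scale_sd))) if spec.subject_scale_sd else 1.0
    cp = aif(t, spec.aif) * scale
    cp_frames = frame_average(t, cp, sched)

    tissue_rows = atlas.table[~atlas.table["role"].isin(["carotid_segment"])]
    tissue_rows = tissue_rows[tissue_rows["name"] != "carotid_tube"]

    age_factor = 1.0 + spec.age_vt_slope * (record.age - spec.age_mean)
    shape4 = spec.shape + (sched.n_frames,)
    vol = np.zeros(shape4, dtype=float)
    truth: dict = {"id": record.id, "scale": scale}
    for _, row in tissue_rows.iterrows():
        name, lbl = str(row["name"]), int(row["label"])
        vt = _region_vt(spec, name, record.group) * age_factor
        vt *= float(np.exp(rng.normal(0.0, spec.between_subject_sd))) if spec.between_subject_sd else 1.0
        kin = KineticParams(K1=vt * spec.k2_s, k2=spec.k2_s)
        tac = frame_average(t, tissue_tac(kin, cp, t), sched)
        vol[atlas.mask(lbl)] = tac
        truth[f"vt_{name}"] = vt
    # carotid tube: partial-volume-scaled input curve, core factor 1.0
    tube = atlas.mask(LBL_CAROTID_TUBE)
    vol[tube] = aux["carotid_pv"][tube, None] * cp_frames[None, :]

    if spec.sigma0 > 0:
        active = atlas.labels > 0
        sd = spec.sigma0 * np.sqrt(
            np.maximum(vol[active], spec.noise_floor) / sched.duration_s[None, :]
        )
        vol[active] += rng.normal(0.0, 1.0, size=sd.shape) * sd
    truth["vt_target"] = 0.5 * (truth["vt_pallidum_l"] + truth["vt_pallidum_r"])
    truth["cp_frames"] = cp_frames
    img = DynamicImage(vol.astype(np.float32), spec.spacing_mm, sched)
    return img, truth


@dataclass
class Cohort:
    """In-memory simulated cohort: images, atlas, demographics, ground truth."""

    spec: PhantomSpec
    atlas: LabelAtlas
    aux: dict
    table: CohortTable
    images: dict  # id -> DynamicImage
    ground_truth: pd.DataFrame  # per-subject true VT etc.
    true_inputs: dict  # id -> frame-averaged true Cp

    @property
    def schedule(self) -> FrameSchedule:
        return self.spec.schedule


def _draw_records(spec: PhantomSpec, rng: np.random.Generator) -> list[SubjectRecord]:
    records = []
    i = 0
    for split in sorted(spec.cohort):
        for group in sorted(spec.cohort[split]):
            for _ in range(spec.cohort[split][group]):
                age = spec.age_min - 1.0
                while age < spec.age_min:
                    age = rng.normal(spec.age_mean, spec.age_sd)
                sex = "m" if rng.random() < spec.male_fraction else "f"
                records.append(
                    SubjectRecord(
                        id=f"sub-{i:03d}",
                        group=group,
                        age=round(float(age), 1),
                        sex=sex,
                        severity=None,  # filled after imaging (depends on true VT)
                        split=split,
                    )
                )
                i += 1
    return records


def simulate_cohort(spec: PhantomSpec, rng: np.random.Generator | None = None) -> Cohort:
    """Simulate a full cohort in memory; reproducible given ``spec.seed``."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    atlas, aux = build_atlas(spec)
    records = _draw_records(spec, rng)
    images, rows, true_inputs = {}, [], {}
    final_records = []
    for rec in records:
        img, truth = simulate_subject(spec, rec, rng, atlas, aux)
        images[rec.id] = img
        true_inputs[rec.id] = truth.pop("cp_frames")
        severity = None
        if rec.group in spec.severity_groups:
            severity = spec.severity_intercept + spec.severity_slope * truth["vt_target"]
            severity += rng.normal(0.0, spec.severity_sd)
            severity = max(0.0, float(severity))
        final_records.append(dataclasses.replace(rec, severity=severity))
        rows.append(truth)
    table = CohortTable(final_records)
    gt = pd.DataFrame(rows).set_index("id")
    return Cohort(spec, atlas, aux, table, images, gt, true_inputs)


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Persist a cohort in the standard on-disk layout (NIfTI + TSV + JSON)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_atlas(cohort.atlas, out / "atlas.nii", out / "atlas.tsv")
    write_cohort_table(cohort.table, out / "subjects.tsv")
    cohort.ground_truth.reset_index().to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    inputs = pd.DataFrame(cohort.true_inputs)
    inputs.insert(0, "time_s", cohort.schedule.midpoint_s)
    inputs.to_csv(out / "true_inputs.tsv", sep="\t", index=False)
    meta = {
        "phantom_spec": cohort.spec.to_dict(),
        "contaminated_candidates": list(cohort.spec.contaminated_candidates),
        "severity_coefficients": {
            "intercept": cohort.spec.severity_intercept,
            "slope": cohort.spec.severity_slope,
            "sd": cohort.spec.severity_sd,
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(meta, indent=1))
    for sid, img in cohort.images.items():
        write_dynamic_image(img, out / f"{sid}_pet.nii", out / f"{sid}_pet.json")


def read_cohort(indir: str | Path) -> Cohort:
    """Load a cohort written by :func:`write_cohort`."""
    ind = Path(indir)
    meta = json.loads((ind / "ground_truth.json").read_text())
    spec = PhantomSpec.from_dict(meta["phantom_spec"])
    atlas = read_atlas(ind / "atlas.nii", ind / "atlas.tsv")
    aux = {
        "carotid_template": atlas.labels == LBL_CAROTID_TUBE,
        "carotid_pv": None,
        "brain_mask": atlas.labels >= 1,
    }
    table = read_cohort_table(ind / "subjects.tsv")
    gt = pd.read_csv(ind / "ground_truth.tsv", sep="\t", dtype={"id": str}).set_index("id")
    inputs = pd.read_csv(ind / "true_inputs.tsv", sep="\t")
    true_inputs = {c: inputs[c].to_numpy() for c in inputs.columns if c != "time_s"}
    images = {}
    for rec in table.records:
        img_path = ind / f"{rec.id}_pet.nii"
        if not img_path.exists():
            raise ValidationError(f"missing image for subject {rec.id}")
        images[rec.id] = read_dynamic_image(img_path, ind / f"{rec.id}_pet.json")
    return Cohort(spec, atlas, aux, table, images, gt, true_inputs)
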