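"""Domain types, image/table I/O, frame-schedule arithmetic and mask morphology.

All images are assumed decay-corrected and on a single common grid; the only
physical geometry handled is the voxel spacing (affines are written as plain
diagonal scaling and are otherwise passed through).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import FormatError, ValidationError

__all__ = [
    "FrameSchedule",
    "DynamicImage",
    "StaticImage",
    "LabelAtlas",
    "SubjectRecord",
    "CohortTable",
    "default_frame_schedule",
    "frames_in_window",
    "time_weighted_mean_image",
    "erode_mask",
    "region_mean",
    "read_dynamic_image",
    "write_dynamic_image",
    "read_static_image",
    "write_static_image",
    "read_atlas",
    "write_atlas",
    "read_cohort_table",
    "write_cohort_table",
]

ROLES = (
    "target",
    "cortical_target",
    "candidate_reference",
    "conventional_reference",
    "carotid_segment",
    "other",
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping acquisition frames.

    Parameters
    ----------
    start_s, duration_s
        Per-frame start times and durations in seconds.  Frames must tile
        ``[0, total)`` without gaps: ``start[i+1] == start[i] + duration[i]``.
    """

    start_s: np.ndarray
    duration_s: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.start_s, dtype=float)
        dur = np.asarray(self.duration_s, dtype=float)
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "duration_s", dur)
        if start.ndim != 1 or dur.ndim != 1 or start.size != dur.size:
            raise ValidationError("start_s and duration_s must be 1-D and equal length")
        if start.size == 0:
            raise ValidationError("schedule must contain at least one frame")
        if not np.all(dur > 0):
            raise ValidationError("all frame durations must be positive")
        if start[0] != 0:
            raise ValidationError("first frame must start at t=0")
        if not np.allclose(start[1:], start[:-1] + dur[:-1], rtol=0, atol=1e-9):
            raise ValidationError("frames must be contiguous and non-overlapping")

    @property
    def n_frames(self) -> int:
        return int(self.start_s.size)

    @property
    def end_s(self) -> np.ndarray:
        return self.start_s + self.duration_s

    @property
    def midpoint_s(self) -> np.ndarray:
        return self.start_s + 0.5 * self.duration_s

    @property
    def total_s(self) -> float:
        return float(self.end_s[-1])

    def to_sidecar(self) -> dict:
        return {
            "FrameTimesStart": self.start_s.tolist(),
            "FrameDuration": self.duration_s.tolist(),
        }

    @classmethod
    def from_sidecar(cls, sidecar: Mapping) -> "FrameSchedule":
        try:
            start = sidecar["FrameTimesStart"]
            dur = sidecar["FrameDuration"]
        except KeyError as e:  # pragma: no cover - trivial
            raise FormatError(f"sidecar missing key {e}") from e
        if len(start) != len(dur):
            raise FormatError(
                f"FrameTimesStart ({len(start)}) and FrameDuration ({len(dur)}) "
                "have different lengths"
            )
        return cls(np.asarray(start, float), np.asarray(dur, float))


def default_frame_schedule() -> FrameSchedule:
    """The 35-frame, 60-min acquisition schedule used throughout.

    12 x 5 s, 6 x 10 s, 3 x 20 s, 7 x 60 s, 4 x 300 s, 3 x 600 s = 3600 s.
    """
    dur = np.concatenate(
        [
            np.full(12, 5.0),
            np.full(6, 10.0),
            np.full(3, 20.0),
            np.full(7, 60.0),
            np.full(4, 300.0),
            np.full(3, 600.0),
        ]
    )
    start = np.concatenate([[0.0], np.cumsum(dur)[:-1]])
    return FrameSchedule(start, dur)


@dataclass
class DynamicImage:
    """4-D voxel activity (x, y, z, frame) with frame schedule and spacing."""

    voxels: np.ndarray
    spacing_mm: tuple
    schedule: FrameSchedule

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if self.voxels.ndim != 4:
            raise ValidationError("DynamicImage voxels must be 4-D")
        if len(self.spacing_mm) != 3:
            raise ValidationError("spacing_mm must have 3 entries")
        if self.voxels.shape[3] != self.schedule.n_frames:
            raise FormatError(
                f"frame count mismatch: image has {self.voxels.shape[3]} frames, "
                f"schedule has {self.schedule.n_frames}"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise ValidationError("DynamicImage contains non-finite values")

    @property
    def shape3(self) -> tuple:
        return self.voxels.shape[:3]


@dataclass
class StaticImage:
    """3-D map on the image grid.  ``quantity`` tags the interpretation.

    Used both for plain static means (SUV) and parametric maps (VT, SUVr,
    VTr, tstat); parametric maps may contain NaN sentinels for failed voxels.
    """

    voxels: np.ndarray
    spacing_mm: tuple
    quantity: str = "SUV"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if self.voxels.ndim != 3:
            raise ValidationError("StaticImage voxels must be 3-D")


# A parametric map is structurally a StaticImage with a non-SUV quantity tag.
ParametricMap = StaticImage


@dataclass
class LabelAtlas:
    """Integer-labelled parcellation (0 = background) with a role table."""

    labels: np.ndarray
    table: pd.DataFrame  # columns: label, name, role
    spacing_mm: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if self.labels.ndim != 3:
            raise ValidationError("atlas labels must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("atlas labels must be integer-valued")
        required = {"label", "name", "role"}
        if not required.issubset(self.table.columns):
            raise FormatError(f"atlas table must have columns {sorted(required)}")
        bad_roles = set(self.table["role"]) - set(ROLES)
        if bad_roles:
            raise ValidationError(f"unknown atlas roles: {sorted(bad_roles)}")
        present = set(np.unique(self.labels)) - {0}
        known = set(int(v) for v in self.table["label"])
        missing = present - known
        if missing:
            raise ValidationError(f"labels present in image but not in table: {sorted(missing)}")

    def mask(self, labels: int | Iterable[int]) -> np.ndarray:
        if np.isscalar(labels):
            labels = [labels]
        return np.isin(self.labels, np.asarray(list(labels), dtype=self.labels.dtype))

    def labels_with_role(self, role: str) -> list[int]:
        return [int(v) for v in self.table.loc[self.table["role"] == role, "label"]]

    def name_of(self, label: int) -> str:
        row = self.table.loc[self.table["label"] == label]
        if row.empty:
            raise ValidationError(f"label {label} not in atlas table")
        return str(row["name"].iloc[0])

    def label_of(self, name: str) -> int:
        row = self.table.loc[self.table["name"] == name]
        if row.empty:
            raise ValidationError(f"region name {name!r} not in atlas table")
        return int(row["label"].iloc[0])


GROUPS = ("PSP-RS", "PSP-nonRS", "AD", "alpha-syn", "HC")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's demographics; ``severity`` may be missing (None)."""

    id: str
    group: str
    age: float
    sex: str
    severity: float | None = None
    split: str = "discovery"  # discovery | validation

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if not self.age > 0:
            raise ValidationError("age must be positive")
        if self.sex not in ("m", "f"):
            raise ValidationError("sex must be 'm' or 'f'")
        if self.severity is not None and self.severity < 0:
            raise ValidationError("severity must be non-negative")


@dataclass
class CohortTable:
    """Per-subject demographics plus named scalar readouts.

    Internally a DataFrame indexed by subject id with fixed demographic
    columns first; readout columns must be identical across subjects (a
    DataFrame guarantees this by construction).
    """

    records: list[SubjectRecord]
    readouts: pd.DataFrame | None = None  # index: subject id

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate subject ids in cohort")
        if self.readouts is None:
            self.readouts = pd.DataFrame(index=pd.Index(ids, name="id"))
        else:
            if list(self.readouts.index) != ids:
                self.readouts = self.readouts.reindex(ids)
                if self.readouts.isna().all(axis=None) and len(self.readouts.columns):
                    raise ValidationError("readout index does not match subject ids")
            self.readouts.index.name = "id"

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def record(self, sid: str) -> SubjectRecord:
        for r in self.records:
            if r.id == sid:
                return r
        raise ValidationError(f"no subject {sid!r}")

    def subset(self, ids: Sequence[str]) -> "CohortTable":
        keep = [r for r in self.records if r.id in set(ids)]
        return CohortTable(keep, self.readouts.loc[[r.id for r in keep]].copy())

    def to_frame(self) -> pd.DataFrame:
        demo = pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "group": [r.group for r in self.records],
                "age": [r.age for r in self.records],
                "sex": [r.sex for r in self.records],
                "severity": [r.severity for r in self.records],
                "split": [r.split for r in self.records],
            }
        ).set_index("id")
        return demo.join(self.readouts)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CohortTable":
        df = df.copy()
        if df.index.name != "id":
            df = df.set_index("id")
        records = []
        for sid, row in df.iterrows():
            sev = row.get("severity")
            if sev is not None and (sev == "" or (isinstance(sev, float) and np.isnan(sev))):
                sev = None
            records.append(
                SubjectRecord(
                    id=str(sid),
                    group=str(row["group"]),
                    age=float(row["age"]),
                    sex=str(row["sex"]),
                    severity=None if sev is None else float(sev),
                    split=str(row.get("split", "discovery")),
                )
            )
        readout_cols = [c for c in df.columns if c not in ("group", "age", "sex", "severity", "split")]
        return cls(records, df[readout_cols].astype(float) if readout_cols else None)


# ---------------------------------------------------------------------------
# schedule arithmetic and image reductions
# ---------------------------------------------------------------------------


def frames_in_window(schedule: FrameSchedule, t0_s: float, t1_s: float) -> np.ndarray:
    """Indices of frames whose midpoint lies in the half-open window [t0, t1).

    Raises ``ValidationError`` if the selection is empty.
    """
    if not t0_s < t1_s:
        raise ValidationError("window requires t0 < t1")
    mid = schedule.midpoint_s
    idx = np.nonzero((mid >= t0_s) & (mid < t1_s))[0]
    if idx.size == 0:
        raise ValidationError(f"no frame midpoint in window [{t0_s}, {t1_s}) s")
    return idx


def time_weighted_mean_image(img: DynamicImage, frames: Sequence[int]) -> StaticImage:
    """Duration-weighted mean over the selected frames (quantity 'SUV')."""
    frames = np.asarray(frames, dtype=int)
    if frames.size == 0:
        raise ValidationError("frame selection is empty")
    w = img.schedule.duration_s[frames]
    data = img.voxels[..., frames]
    mean = np.tensordot(data, w, axes=([3], [0])) / w.sum()
    return StaticImage(mean, img.spacing_mm, quantity="SUV")


def _sphere_structure(radius_mm: float, spacing_mm: Sequence[float]) -> np.ndarray:
    spacing = np.asarray(spacing_mm, dtype=float)
    r = np.maximum(np.floor(radius_mm / spacing + 1e-9).astype(int), 0)
    grids = np.meshgrid(
        *(np.arange(-n, n + 1) * s for n, s in zip(r, spacing)), indexing="ij"
    )
    dist2 = sum(g**2 for g in grids)
    return dist2 <= radius_mm**2 + 1e-9


def erode_mask(
    mask: np.ndarray, radius_mm: float, spacing_mm: Sequence[float]
) -> np.ndarray:
    """Binary erosion with a spherical structuring element of physical radius.

    Voxel offsets whose Euclidean physical distance is <= ``radius_mm`` form
    the structuring element; voxels outside the volume count as background.
    ``radius_mm == 0`` is the identity.  An empty result is allowed but
    triggers a warning.
    """
    if radius_mm < 0:
        raise ValidationError("erosion radius must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if radius_mm == 0:
        return mask.copy()
    structure = _sphere_structure(radius_mm, spacing_mm)
    out = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    if mask.any() and not out.any():
        warnings.warn("erosion produced an empty mask", stacklevel=2)
    return out


def region_mean(map3d: StaticImage, atlas: LabelAtlas, label: int | Iterable[int]) -> float:
    """Arithmetic mean of map values over the label's voxels (NaN-aware)."""
    m = atlas.mask(label)
    if not m.any():
        raise ValidationError(f"label {label} has no voxels")
    vals = map3d.voxels[m]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValidationError(f"label {label} has no finite map values")
    return float(vals.mean())


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def _affine(spacing_mm: Sequence[float]) -> np.ndarray:
    return np.diag(list(spacing_mm) + [1.0])


def write_dynamic_image(img: DynamicImage, image_path: str | Path, sidecar_path: str | Path) -> None:
    nii = nib.Nifti1Image(np.asarray(img.voxels, dtype=np.float32), _affine(img.spacing_mm))
    nii.to_filename(str(image_path))
    Path(sidecar_path).write_text(json.dumps(img.schedule.to_sidecar(), indent=1))


def read_dynamic_image(image_path: str | Path, sidecar_path: str | Path) -> DynamicImage:
    nii = nib.load(str(image_path))
    data = np.asarray(nii.dataobj, dtype=np.float32)
    if data.ndim != 4:
        raise FormatError(f"{image_path}: expected a 4-D image, got {data.ndim}-D")
    sidecar = json.loads(Path(sidecar_path).read_text())
    schedule = FrameSchedule.from_sidecar(sidecar)
    if schedule.n_frames != data.shape[3]:
        raise FormatError(
            f"{image_path}: {data.shape[3]} frames but sidecar lists {schedule.n_frames}"
        )
    spacing = tuple(float(z) for z in nii.header.get_zooms()[:3])
    return DynamicImage(data, spacing, schedule)


def write_static_image(img: StaticImage, path: str | Path) -> None:
    nii = nib.Nifti1Image(np.asarray(img.voxels, dtype=np.float32), _affine(img.spacing_mm))
    nii.header["descrip"] = img.quantity.encode()[:79]
    nii.to_filename(str(path))


def read_static_image(path: str | Path, quantity: str | None = None) -> StaticImage:
    nii = nib.load(str(path))
    data = np.asarray(nii.dataobj, dtype=np.float32)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D image, got {data.ndim}-D")
    if quantity is None:
        quantity = nii.header["descrip"].tobytes().split(b"\x00")[0].decode() or "SUV"
    spacing = tuple(float(z) for z in nii.header.get_zooms()[:3])
    return StaticImage(data, spacing, quantity)


def write_atlas(atlas: LabelAtlas, image_path: str | Path, table_path: str | Path) -> None:
    nii = nib.Nifti1Image(np.asarray(atlas.labels, dtype=np.int16), _affine(atlas.spacing_mm))
    nii.to_filename(str(image_path))
    atlas.table.to_csv(table_path, sep="\t", index=False)


def read_atlas(image_path: str | Path, table_path: str | Path) -> LabelAtlas:
    nii = nib.load(str(image_path))
    labels = np.asarray(nii.dataobj).astype(np.int32)
    table = pd.read_csv(table_path, sep="\t")
    spacing = tuple(float(z) for z in nii.header.get_zooms()[:3])
    return LabelAtlas(labels, table, spacing)


def write_cohort_table(table: CohortTable, path: str | Path) -> None:
    df = table.to_frame().reset_index()
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_cohort_table(path: str | Path) -> CohortTable:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    return CohortTable.from_frame(df)
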