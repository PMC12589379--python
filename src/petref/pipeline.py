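"""End-to-end orchestration: simulate -> IDIF -> Logan VT -> reference search
(discovery) -> SUVr/VTr quantification with both references -> validation
statistics -> report.

Stage outputs (VT maps) are cached on disk keyed by a content hash of the
subject image and the fit configuration, so partial reruns are cheap.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_io import LabelAtlas, StaticImage
from .errors import StageError, ValidationError
from .idif import InputFunction, run_idif
from .kinetics import LoganConfig, vt_map
from .phantom import Cohort, PhantomSpec, simulate_cohort
from .quantify import DEFAULT_WINDOW_S, bilateral_target_groups, cohort_readouts, suvr_map
from .refsearch import search_reference
from .stats import ancova, delong_compare, roc, severity_regression, voxelwise_cluster_test

__all__ = ["RunConfig", "RunReport", "run_discovery", "run_validation", "run_all"]


@dataclass
class RunConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    input_function: str = "idif"  # idif | true_aif
    t_star_s: float = 900.0
    min_points: int = 4
    window_s: tuple = DEFAULT_WINDOW_S
    erosion_mm: float = 2.0
    alpha: float = 0.05
    fwe_method: str = "bonferroni"
    min_voxels: int = 10
    n_components: int = 10
    z_thresh: float = 2.0
    erosion_voxels: int = 1
    early_window_s: tuple = (0.0, 300.0)
    correlation_floor: float = 0.1
    patient_group: str = "PSP-RS"
    control_group: str = "HC"
    validation_patient_group: str = "PSP-nonRS"
    n_perm: int = 200
    p_form: float = 0.001
    alpha_cluster: float = 0.05
    run_cluster_test: bool = True
    seed: int = 0
    out_dir: str | None = None

    @property
    def logan(self) -> LoganConfig:
        return LoganConfig(t_star_s=self.t_star_s, min_points=self.min_points)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom"] = self.phantom.to_dict()
        return d

    @classmethod
    def from_dict(cls, d) -> "RunConfig":
        d = dict(d)
        if "phantom" in d and not isinstance(d["phantom"], PhantomSpec):
            d["phantom"] = PhantomSpec.from_dict(d["phantom"])
        for key in ("window_s", "early_window_s"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def _json_default(o):
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


@dataclass
class RunReport:
    """Machine-readable run report; the text form is rendered from the same
    dict so both surfaces agree on every number."""

    data: dict

    def to_json(self) -> str:
        return json.dumps(self.data, indent=1, sort_keys=True, default=_json_default)

    def to_text(self) -> str:
        lines = []

        def walk(obj, prefix=""):
            if isinstance(obj, dict):
                for k in sorted(obj):
                    walk(obj[k], f"{prefix}{k}.")
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    walk(v, f"{prefix}{i}.")
            else:
                lines.append(f"{prefix[:-1]} = {json.dumps(obj, default=_json_default)}")

        walk(self.data)
        return "\n".join(lines) + "\n"


def _content_key(img, cfg: RunConfig, source: str, extra: str = "") -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(img.voxels).tobytes())
    h.update(repr((cfg.t_star_s, cfg.min_points, source, extra)).encode())
    return h.hexdigest()[:24]


def _derive_seeds(seed: int, ids):
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(ids))
    return {sid: int(c.generate_state(1)[0]) for sid, c in zip(sorted(ids), children)}


def compute_inputs_and_vt(cohort: Cohort, cfg: RunConfig, subject_ids=None):
    """Input function + Logan VT map per subject (with on-disk caching)."""
    ids = sorted(subject_ids if subject_ids is not None else cohort.images)
    seeds = _derive_seeds(cfg.seed, ids)
    cache_dir = None
    if cfg.out_dir:
        cache_dir = Path(cfg.out_dir) / "cache"
        cache_dir.mkdir(parents=True, exist_ok=True)
    atlas = cohort.atlas
    segment = atlas.mask(atlas.label_of("carotid_segment")) | cohort.aux["carotid_template"]
    template = cohort.aux["carotid_template"]
    brain = cohort.aux["brain_mask"] & (atlas.labels < 200)

    inputs, vt_maps, qc = {}, {}, {}
    for sid in ids:
        img = cohort.images[sid]
        if cfg.input_function == "true_aif":
            inp = InputFunction(cohort.schedule.midpoint_s, cohort.true_inputs[sid], source="true_aif")
            sqc = {"source": "true_aif"}
        elif cfg.input_function == "idif":
            inp, _, sqc = run_idif(
                img,
                segment_mask=segment,
                template_mask=template,
                n_components=cfg.n_components,
                seed=seeds[sid],
                z_thresh=cfg.z_thresh,
                erosion_voxels=cfg.erosion_voxels,
                early_window_s=cfg.early_window_s,
                correlation_floor=cfg.correlation_floor,
            )
            sqc = {"source": "idif", **sqc}
        else:
            raise ValidationError(f"unknown input_function {cfg.input_function!r}")

        key = None
        if cache_dir is not None:
            key = _content_key(img, cfg, cfg.input_function)
            cached = cache_dir / f"vt_{sid}_{key}.npz"
            if cached.exists():
                arr = np.load(cached)["vt"]
                vt_maps[sid] = StaticImage(arr, img.spacing_mm, quantity="VT")
                inputs[sid] = inp
                qc[sid] = {**sqc, "cached": True}
                continue
        vmap = vt_map(img, inp, cfg.logan, brain_mask=brain)
        if cache_dir is not None:
            np.savez_compressed(cache_dir / f"vt_{sid}_{key}.npz", vt=vmap.voxels)
        vt_maps[sid] = vmap
        inputs[sid] = inp
        nan_frac = float(np.isnan(vmap.voxels[brain]).mean())
        qc[sid] = {**sqc, "cached": False, "vt_nan_fraction": round(nan_frac, 6)}
    return inputs, vt_maps, qc


def run_discovery(cfg: RunConfig, cohort: Cohort | None = None):
    """Simulate (if needed), extract inputs, fit VT, run the reference search.

    Returns ``(report, cohort, vt_maps, merged_mask)``.
    """
    report: dict = {"stage_status": {}, "config": cfg.to_dict(), "version": __version__}
    try:
        if cohort is None:
            # master seed governs every stage, including simulation
            cohort = simulate_cohort(cfg.phantom, rng=np.random.default_rng(cfg.seed))
        report["stage_status"]["simulate"] = "ok"
    except Exception as e:
        report["stage_status"]["simulate"] = f"failed: {e}"
        raise StageError(f"simulate: {e}") from e

    disc_ids = [r.id for r in cohort.table.records if r.split == "discovery"]
    if not any(cohort.table.record(s).group == cfg.patient_group for s in disc_ids):
        raise StageError(f"discovery: no {cfg.patient_group!r} subjects in discovery split")
    try:
        inputs, vt_maps, qc = compute_inputs_and_vt(cohort, cfg, disc_ids)
        report["stage_status"]["idif_logan"] = "ok"
        report["idif_qc"] = qc
    except Exception as e:
        report["stage_status"]["idif_logan"] = f"failed: {e}"
        raise StageError(f"idif/logan: {e}") from e

    try:
        search = search_reference(
            vt_maps,
            cohort.atlas,
            cohort.table.subset(disc_ids),
            patient_group=cfg.patient_group,
            control_group=cfg.control_group,
            alpha=cfg.alpha,
            erosion_mm=cfg.erosion_mm,
            min_voxels=cfg.min_voxels,
            fwe_method=cfg.fwe_method,
        )
        report["stage_status"]["reference_search"] = "ok" if search.success else "no survivors"
        report["reference_search"] = {
            "candidates": search.table().to_dict(orient="records"),
            "n_family": search.n_family,
            "alpha": search.alpha,
            "fwe_method": search.fwe_method,
            "n_selected": int(sum(c.selected for c in search.candidates)),
            "merged_mask_voxels": int(search.merged_mask.sum()) if search.success else 0,
        }
    except Exception as e:
        report["stage_status"]["reference_search"] = f"failed: {e}"
        raise StageError(f"reference_search: {e}") from e

    if cfg.out_dir and search.success:
        from .core_io import write_static_image

        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_static_image(
            StaticImage(search.merged_mask.astype(float), cohort.atlas.spacing_mm, "mask"),
            out / "merged_reference.nii",
        )
    return RunReport(report), cohort, vt_maps, search.merged_mask


def run_validation(cfg: RunConfig, cohort: Cohort, merged_mask: np.ndarray):
    """Quantify both references on the validation split and compare them.

    Produces ANCOVA/Cohen's-d tables, ROC + paired DeLong per reference,
    the severity regression, and (optionally) the voxel-wise cluster test.
    """
    if merged_mask is None or not np.asarray(merged_mask).any():
        raise StageError("validation: merged reference mask is empty")
    report: dict = {"stage_status": {}}
    atlas = cohort.atlas
    conv_label = atlas.labels_with_role("conventional_reference")
    if not conv_label:
        raise StageError("validation: atlas has no conventional_reference label")
    references = {
        "wmref": np.asarray(merged_mask, dtype=bool),
        "cereb": atlas.mask(conv_label),
    }
    val_ids = [r.id for r in cohort.table.records if r.split == "validation"]
    all_ids = sorted(cohort.images)
    try:
        inputs, vt_maps, qc = compute_inputs_and_vt(cohort, cfg, all_ids)
        report["stage_status"]["idif_logan"] = "ok"
    except Exception as e:
        report["stage_status"]["idif_logan"] = f"failed: {e}"
        raise StageError(f"validation idif/logan: {e}") from e

    targets = bilateral_target_groups(atlas)
    readouts = cohort_readouts(
        {s: cohort.images[s] for s in all_ids}, vt_maps, atlas, references, targets, cfg.window_s
    )
    cohort.table.readouts = readouts.loc[cohort.table.ids]
    report["readout_columns"] = sorted(readouts.columns)

    val = cohort.table.subset(val_ids)
    vdf = val.to_frame()
    groups = vdf["group"].to_numpy()
    ages = vdf["age"].to_numpy(dtype=float)
    sexes = vdf["sex"].to_numpy()

    # --- ANCOVA + Tukey + Cohen's d per readout across all validation groups
    anc_tables = {}
    for col in readouts.columns:
        vals = vdf[col].to_numpy(dtype=float)
        try:
            res = ancova(vals, groups, age=ages, sex=sexes, reference=cfg.control_group)
        except ValidationError as e:
            anc_tables[col] = {"error": str(e)}
            continue
        anc_tables[col] = {
            "group_f": res.group_f,
            "group_p": res.group_p,
            "adjusted_means": res.adjusted_means,
            "tukey_p": res.tukey_p.round(10).to_dict(),
            "cohens_d": res.cohens_d.round(10).to_dict(),
        }
    report["ancova"] = anc_tables
    report["stage_status"]["ancova"] = "ok"

    # --- ROC per reference + paired DeLong, patient vs control
    roc_tables = {}
    pat, ctl = cfg.validation_patient_group, cfg.control_group
    sel = np.isin(groups, [pat, ctl])
    labels = groups[sel] == pat
    for tgt in targets:
        for measure in ("suvr", "vtr"):
            scores = {
                ref: vdf.loc[sel, f"{tgt}_{measure}_{ref}"].to_numpy(dtype=float)
                for ref in references
            }
            entry = {}
            for ref, sc in scores.items():
                r = roc(sc, labels)
                entry[ref] = {
                    "auc": r.auc,
                    "cutoff": r.cutoff,
                    "sensitivity": r.sensitivity,
                    "specificity": r.specificity,
                    "delong_variance": r.delong_variance,
                }
            try:
                z, p = delong_compare(scores["wmref"], scores["cereb"], labels)
                entry["delong"] = {"z": z, "p": p}
            except ValidationError as e:
                entry["delong"] = {"error": str(e)}
            roc_tables[f"{tgt}_{measure}"] = entry
    report["roc"] = roc_tables
    report["stage_status"]["roc"] = "ok"

    # --- severity regression on all subjects with a severity score
    full = cohort.table.to_frame()
    sev_tables = {}
    tgt0 = "pallidum" if "pallidum" in targets else sorted(targets)[0]
    for ref in references:
        for measure in ("suvr", "vtr"):
            col = f"{tgt0}_{measure}_{ref}"
            try:
                reg = severity_regression(
                    full["severity"].to_numpy(dtype=float),
                    full[col].to_numpy(dtype=float),
                    age=full["age"].to_numpy(dtype=float),
                    sex=full["sex"].to_numpy(),
                )
                sev_tables[col] = {"beta_std": reg.beta_std, "p": reg.p, "n": reg.n}
            except ValidationError as e:
                sev_tables[col] = {"error": str(e)}
    report["severity_regression"] = sev_tables
    report["stage_status"]["severity"] = "ok"

    # --- voxel-wise cluster test (validation patient vs control), per reference
    if cfg.run_cluster_test:
        brain = cohort.aux["brain_mask"] & (atlas.labels < 200)
        sel_ids = [r.id for r in val.records if r.group in (pat, ctl)]
        cgroups = [cohort.table.record(s).group for s in sel_ids]
        cages = [cohort.table.record(s).age for s in sel_ids]
        csexes = [cohort.table.record(s).sex for s in sel_ids]
        cluster_tables = {}
        for ref_name, ref_mask in references.items():
            maps = np.stack(
                [suvr_map(cohort.images[s], ref_mask, cfg.window_s).voxels for s in sel_ids]
            )
            cres = voxelwise_cluster_test(
                maps, cgroups, age=cages, sex=csexes, mask=brain,
                p_form=cfg.p_form, alpha_cluster=cfg.alpha_cluster,
                n_perm=cfg.n_perm, seed=cfg.seed + 7919,
            )
            cluster_tables[ref_name] = {
                "n_clusters": len(cres.cluster_extents),
                "n_surviving": int(cres.cluster_labels.max()),
                "extents": cres.cluster_extents,
                "p_fwe": cres.cluster_p_fwe,
                "forming_threshold": cres.forming_threshold,
            }
        report["cluster_test"] = cluster_tables
        report["stage_status"]["cluster_test"] = "ok"
    return RunReport(report), vt_maps


def run_all(cfg: RunConfig, cohort: Cohort | None = None) -> RunReport:
    """Full study replica; merges the discovery and validation reports."""
    disc_report, cohort, _, merged = run_discovery(cfg, cohort)
    val_report, _ = run_validation(cfg, cohort, merged)
    data = dict(disc_report.data)
    for k, v in val_report.data.items():
        if k == "stage_status":
            data["stage_status"].update(v)
        else:
            data[k] = v
    report = RunReport(data)
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        (out / "report.txt").write_text(report.to_text())
    return report
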