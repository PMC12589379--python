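# petref

Reusable pipeline for optimizing a dynamic-PET reference region for
subcortical tau quantification, exercised end-to-end on synthetic dynamic-PET
phantom cohorts with known kinetic ground truth.

Stages:

1. **Phantom simulation** (`petref.phantom`) — 60-min, 35-frame dynamic
   acquisitions with a tri-exponential bolus input carried by a carotid-like
   tube, one-tissue-compartment regional kinetics (VT = K1/k2),
   group-dependent target elevation, optional contamination of the
   conventional cerebellar-like reference, age/sex covariates, a severity
   score, and frame-duration-dependent noise.
2. **IDIF extraction** (`petref.idif`) — spatial ICA of the early frames,
   template-correlation component selection, segment masking, erosion, and
   per-frame maximum extraction of the blood-activity proxy.
3. **Logan VT mapping** (`petref.kinetics`) — vectorized voxel-wise Logan
   graphical analysis (t* = 900 s default).
4. **Quantification** (`petref.quantify`) — 20–40 min SUVr and VTr maps and
   ROI readouts against any reference mask.
5. **Reference search** (`petref.refsearch`) — every candidate white-matter
   region is eroded (2 mm spherical kernel), used to normalize each
   discovery subject's VT map, and scored by age/sex-adjusted
   patient-vs-control separation of the target VTr; Bonferroni/Holm
   FWE-corrected survivors are merged into one optimized reference mask.
6. **Validation statistics** (`petref.stats`) — ANCOVA with Tukey HSD and
   Cohen's d, ROC with Youden cut-offs and paired DeLong AUC comparison,
   covariate-adjusted severity regression, and permutation-based voxel-wise
   cluster-extent inference.
7. **Orchestration** (`petref.pipeline`, `petref.cli`) — discovery →
   validation replica with JSON + text reports and content-hash VT caching.

## CLI

```bash
petref simulate  --out cohort/ --seed 1                 # synthetic cohort
petref idif      --image sub_pet.nii --sidecar sub_pet.json \
                 --segment-mask seg.nii --template-mask tmpl.nii --out idif/
petref logan     --image sub_pet.nii --sidecar sub_pet.json \
                 --input-tsv idif/idif.tsv --out vt/
petref refsearch --cohort-dir cohort/ --out search/ --seed 1
petref run-all   --out run/ --seed 1                    # full replica
petref run-all   --config run.yaml --cohort-dir cohort/ --out run/
```

Configuration is a YAML rendering of `petref.pipeline.RunConfig`
(windows, t*, erosion radii, ICA settings, alphas, permutation counts,
phantom spec, seeds). Images are NIfTI-1 with BIDS-PET-style JSON frame
timing sidecars (`FrameTimesStart`, `FrameDuration`, seconds); atlases are
NIfTI label volumes plus a TSV role table; all tabular outputs are TSV.

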