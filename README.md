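# commissura

Virtual dissection and tractometry of commissural white matter tracts, with
synthetic diffusion phantoms and a complete structure–cognition statistics
layer.

## What problem this solves

The dorsal hippocampal commissure (DHC) is a small interhemispheric tract
connecting the parahippocampal regions of the two temporal lobes. Isolating
it in diffusion MRI is a gating problem: its fibres share the alveus with
the fornix, so streamlines seeded from the hippocampus must be filtered
with waypoint (AND) and exclusion (NOT) regions before any microstructure
measurement is meaningful. `commissura` implements that workflow end to
end, for researchers who want a reproducible, testable version of the
multiple-ROI dissection recipe:

* deterministic streamline tractography over a per-voxel peak field
  (supersampled seeding, fixed step, 60° angle threshold, no randomness);
* boolean SEED/AND/NOT gating with bilateral seeding and transverse-segment
  extraction between sagittal cut planes about the midline;
* vertex-weighted tractometry combining left- and right-seeded segments:

  `VWM = (N_L→R · m̄_L→R + N_R→L · m̄_R→L) / (N_L→R + N_R→L)`;

* cohort statistics: ICV-adjusted volumes, bootstrap Pearson correlations,
  Bonferroni–Holm families, Steiger Z / Cohen's q for dependent
  correlations, Spearman and outlier sensitivity analyses, and a default
  Bayes factor for a correlation (stretched-beta prior, numerical
  quadrature);
* a synthetic module that generates everything the pipeline consumes —
  multi-bundle DWI phantoms with ground truth (a commissural arc, a
  fornix-like decoy that the gates must remove, protocol ROI presets) and
  cohorts with planted effects — so the whole stack is testable without any
  external data.

## Worked example

Phantom → tracking → dissection → tractometry, all from the shell:

```bash
commissura simulate --layout dhc_default --flavor human --out-dir sim --cohort-n 95
commissura track --peaks-prefix sim/truth_field \
    --seed-mask sim/roi_left_hippocampus_SEED.nii.gz --out rawL.trk
commissura dissect --tractogram rawL.trk \
    --and-mask sim/roi_right_hippocampus_AND.nii.gz \
    --not-mask sim/roi_not_anterior_NOT.nii.gz \
    --not-mask sim/roi_not_posterior_NOT.nii.gz \
    --cut-mm 6.25 --out-segment segL.trk
# ... same with the right seed / left waypoint, then:
commissura tensor --dwi sim/phantom.nii.gz --bval sim/phantom.bval \
    --bvec sim/phantom.bvec --out-prefix maps
commissura tractometry --segment-left segL.trk --segment-right segR.trk \
    --fa-map maps_fa.nii.gz --md-map maps_md.nii.gz \
    --subject sub-0001 --tract dhc --out tractometry.csv
```

which prints

```
{"n_streamlines_in": 2304, "n_survivors": 1568, "n_segment_vertices": 40080}
 subject tract   n_L   n_R  fa_L  fa_R     md_L     md_R  fa_vw    md_vw
sub-0001   dhc 40080 48072 0.318 0.318 0.001478 0.001478  0.318 0.001478
```

Reading this: of 2304 raw streamlines seeded in the left blob, 1568 survive
the waypoint/exclusion gates (every decoy-following streamline is removed);
the transverse segments contribute 40 080 and 48 072 vertices from the two
seeding directions (the decoy clips only the left seed blob, hence the
asymmetry the vertex weighting absorbs); and the vertex-weighted mean
diffusivity, 1.478 × 10⁻³ mm²/s, recovers the phantom's assigned bundle MD
exactly on noise-free data.

The same pipeline is three calls in Python:

```python
import commissura as cm

dwi, field, truth = cm.build_phantom("dhc_default", flavor="human")
left, right = cm.run_bilateral_protocol(field, truth.protocol, cm.TrackingParams())
fa, md = cm.compute_fa_md(cm.fit_tensor_lls(dwi))
m = cm.segment_metrics(
    cm.cut_segment(left, truth.protocol.cut_planes, provenance="seeded-from-left"),
    cm.cut_segment(right, truth.protocol.cut_planes, provenance="seeded-from-right"),
    fa, md)
print(m.md_vw)            # 0.001478
```

Cohort statistics are exposed statsmodels-style:

```python
cohort = cm.make_cohort(cm.CohortSpec(n_subjects=95, true_corr_md_memory=-0.5, seed=42))
res = cm.StructureCognitionModel(cohort).fit(seed=0)
print(res.summary())      # correlation families, Holm adjustment,
                          # Steiger comparisons, sensitivity block
cm.correlation_bf10(-0.269, 95).bf10   # 3.924
```

## Layout

| Module | Role |
|---|---|
| `commissura.io` | NIfTI / bvals-bvecs / TRK / TCK I/O, world–voxel conventions |
| `commissura.config` | YAML run configuration with human / ex vivo flavors |
| `commissura.synthetic` | DWI phantoms with ground truth, ROI presets, cohorts |
| `commissura.tensor` | LLS tensor fit, FA/MD maps, orientation (peak) fields |
| `commissura.tracking` | deterministic bidirectional streamline propagation |
| `commissura.dissection` | SEED/AND/NOT gating, bilateral protocols, segment cuts |
| `commissura.metrics` | scalar sampling along segments, vertex-weighted means |
| `commissura.stats` | correlations, Holm, Steiger Z, Bayes factors, cohort model |

See `docs/methods.md` for the model details, parameter defaults and the
limitations of the synthetic experiments.
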