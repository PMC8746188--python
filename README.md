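# clsm — connectome-based lesion-symptom mapping

Mass-univariate, permutation-thresholded GLMs relating region-level lesion
damage, structural-connectome fiber counts and resting-state functional
connectivity to behavioral composite scores, plus the resting-state
preprocessing steps that feed them and a synthetic stroke-cohort generator
so every stage can be exercised without imaging data.

## What's in the box

| module | purpose |
| --- | --- |
| `clsm.parcellation` | dual-stream ROI bookkeeping (default 26 dorsal-left + 41 ventral per hemisphere = 108 ROIs) |
| `clsm.cohort` | behavioral composite scoring (Auditory Verbal Comprehension 0–10, Spontaneous Speech 0–20), the synthetic cohort generator with planted effects, plain-text cohort (de)serialization |
| `clsm.preprocess` | lesion-mask smoothing + 50% binarization, nuisance detrending, 0.01–0.1 Hz band-pass, lesion-overlap ICA-component filter (Jaccard > 5%), ROI averaging, Pearson connectome |
| `clsm.glm` | per-feature GLM t→z statistics, residualization, max-statistic permutation FWE thresholding (Freedman–Lane by default) |
| `clsm.analyses` | region lesion-symptom mapping (≥10-subject damage rule), structural-edge analysis, and the three functional-connectivity covariate modes (lesion volume; lesion volume + per-edge SC residualization; critical-area lesion load + SC) |
| `clsm.io` / `clsm.pipeline` / `clsm.cli` | labeled connectome CSV I/O, config-driven orchestration with a hashed run manifest, `clsm` command line |

## CLI

```bash
# generate a synthetic cohort as plain-text files
clsm simulate --n-subjects 97 --seed 1 --out cohort/

# Pearson connectomes from stored ROI time courses (optional band-pass)
clsm preprocess --cohort cohort/ --out fc/ --bandpass

# run configured analyses; writes z-tables, survivor lists and manifest.json
clsm analyze --config run.yaml
clsm report --results out/
```

A run config looks like:

```yaml
seed: 17
output_dir: out
cohort:
  source: synthetic        # or a cohort directory path
  n_subjects: 97
  n_dorsal_left: 8
  n_ventral_per_hemi: 11
analyses:
  - {name: lsm,  kind: region,     n_perm: 5000}
  - {name: sc,   kind: structural, n_perm: 5000}
  - {name: fc_a, kind: functional, covariate_mode: LESION_VOLUME, n_perm: 5000}
  - {name: fc_b, kind: functional, covariate_mode: LESION_VOLUME_PLUS_SC, n_perm: 5000}
```

Re-running an identical config reproduces every output hash bit-for-bit.

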