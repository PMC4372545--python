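# submem

A tested, fully synthetic re-implementation of a high-resolution fMRI
subsequent-memory analysis: three competing encoding models (sample-only,
sample+delay, inverse-square decay), voxel-wise first-level GLM, a weighted
least squares group model of memory strength, permutation max-|t| family-wise
error inference, and posterior-predictive model checking — driven end to end
by a synthetic BOLD + behavior generator so every stage is verifiable without
real scan data.

## Layout

| module | role |
| --- | --- |
| `submem.synthdata` | trial schedules (8 runs x 12 trials, balanced 6/10/14 s ITIs), ordinal-probit behavior, ground-truth effect maps, 4D BOLD simulation |
| `submem.designmat` | double-gamma HRF, encoding kernels (`sample_only`, `sample_plus_delay`, `decay` = n^-2), interest + nuisance regressors (run baselines, motion x run, cubic drift x run), rank-checked assembly |
| `submem.firstlevel` | vectorized voxel-wise OLS; per-category encoding coefficient tables |
| `submem.grouplevel` | memory-strength coding (1..R -> -2..+2), inverse-variance weighted least squares with subject intercept factors |
| `submem.inference` | two-tailed uncorrected thresholding, connected-component clusters, max-\|t\| permutation FWE |
| `submem.modelcheck` | sphere ROI extraction, z-scored trial-locked averages, posterior-predictive simulation, misfit-based model ranking |
| `submem.behavior` | DMS percent correct, subsequent-memory corrected accuracy (TPR - FPR) |
| `submem.config` / `io` / `pipeline` / `cli` | YAML config, NIfTI/TSV/JSON I/O, stage driver, CLI |

## CLI

The pipeline runs as one shot or as composable stages that communicate
through the output directory:

```bash
submem run --seed 1 --subjects 4 --out scratch/demo
# equivalently:
submem simulate --seed 1 --subjects 4 --out scratch/demo
submem design   --seed 1 --subjects 4 --out scratch/demo
submem fit      --seed 1 --subjects 4 --out scratch/demo
submem group    --seed 1 --subjects 4 --out scratch/demo
submem infer    --seed 1 --subjects 4 --out scratch/demo
submem ppc      --seed 1 --subjects 4 --out scratch/demo
submem behav    --seed 1 --subjects 4 --out scratch/demo
```

Options: `--config config.yaml` (see `submem.config.PipelineConfig` for the
schema), `--model {sample_only,sample_plus_delay,decay}`, `--perms INT`,
`--scheme {global,within_subject}`. Outputs include the synthetic dataset
(NIfTI + TSV), design matrices, group slope/t maps, a cluster table,
FWE-corrected p maps, a PPC model ranking, behavioral scores, and a markdown
report. Reruns with the same seed are byte-identical.

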