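# mrirepro

A multi-site MRI reproducibility pipeline:

* **Phantom QA** — deterministic signal / background / uniformity ROIs on an
  ACR-style cylinder phantom image, with SNR (mean signal / background SD) and
  percent integral uniformity (nearest-rank 5th/95th percentiles).
* **Diffusion tensor fitting** — per-voxel log-linear least squares with
  robust IRLS (Huber) reweighting; FA and MD maps from the eigenvalues.
* **STAPLE label fusion** — multilabel EM consensus of aligned candidate
  segmentations with per-rater confusion-matrix estimates, plus a
  majority-vote baseline.
* **ROI measurements** — label volumes and per-ROI scalar means, assembled
  into long-format scan panels.
* **Reproducibility reporting** — inter-scanner, intra-scanner, and
  intra-vendor coefficients of variation per label, across-label summaries,
  and inter:intra CV ratios.
* **Synthetic data** — generators for every input (cylinder phantoms under
  Rician noise with a controlled nonuniformity field, DW series forward
  simulated from known tensor fields, rater label maps drawn from known
  confusion matrices, geometric parcellations, multi-site measurement panels
  with controlled variance components), so the whole pipeline is testable
  with no acquired data.

All images are NIfTI-1; diffusion schemes use FSL-style `bval`/`bvec` text
files; panels and reports are CSV; configuration is YAML.

## Command line

One executable, `mrirepro`, with per-stage subcommands:

```sh
# synthetic inputs
mrirepro simulate phantom --out phantom.nii.gz --noise-sigma 2 --seed 1
mrirepro simulate dwi --out dwi.nii.gz --out-bval dwi.bval --out-bvec dwi.bvec
mrirepro simulate brain --out labels.nii.gz
mrirepro simulate raters --truth labels.nii.gz --out-dir raters/ --n-raters 4
mrirepro simulate panel --out panel.csv --seed 1

# analysis stages
mrirepro acr-qa --image phantom.nii.gz --out qa.csv --scanner-id A
mrirepro fit-dti --dwi dwi.nii.gz --bval dwi.bval --bvec dwi.bvec \
    --out-fa fa.nii.gz --out-md md.nii.gz --out-tensor tensor.nii.gz
mrirepro fuse --raters raters/rater_00.nii.gz --raters raters/rater_01.nii.gz \
    --labels 3 --out consensus.nii.gz --out-performance performance.csv
mrirepro roi-stats --labels consensus.nii.gz --scalar FA=fa.nii.gz \
    --scanner-id A --session-id s1 --out panel.csv
mrirepro report --panel panel.csv --out-dir reports/

# full synthetic pipeline, end to end (deterministic per seed)
mrirepro run --out-dir reports/ --seed 1
```

`mrirepro run` executes simulate → acr-qa → fit-dti → fuse → roi-stats →
report on a bundled synthetic configuration (override with `--config
config.yaml`) and writes `qa.csv`, `table_qa.csv`, `panel.csv`,
`table_intra.csv`, `table_labels.csv`, `summary.csv` and a `manifest.yaml`
with output hashes. Two runs with the same configuration are byte-identical.

## Conventions

* Sample SD (n − 1) everywhere; CV = 100 × SD / mean.
* Slice indices in ROI configuration are 1-based (ACR counting) and
  converted internally.
* Rescan sessions are ordinary sessions in every CV pool; the inter-scanner
  CV pools all scans directly; "mean intra-scanner" summaries are unweighted
  means over scanners.
* Rounding to one decimal happens only in the report layer (half-even).
* Scalars are reported unscaled (FA dimensionless, MD in mm²/s).
* All stages require pre-aligned inputs on identical grids; the only
  spatial operation provided is an integer-voxel centre-of-mass translation
  for phantom images.
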