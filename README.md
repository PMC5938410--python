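# mlsmap

Multiple-lesion symptom mapping for cohorts in which two lesion types
co-occur in the brain (e.g. acute ischemic lesions, "AIL", and white matter
hyperintensities, "WMH"). The package implements three voxelwise
lesion–symptom mapping methods on a shared reference grid:

- **VLSM** — mass-univariate pooled two-sample t per voxel with maxT
  (Westfall–Young) permutation familywise-error correction;
- **SVR-LSM** — one support vector regression over all voxels of a single
  lesion type (linear or RBF kernel), voxel weights tested by permutation;
- **SVR-MLSM** — the multi-lesion extension: each voxel contributes one
  indicator column per lesion type, so both lesion types are mapped in a
  single linear-kernel model and share one permutation stream.

Around the mapping core it provides behavior-score preparation
(covariate norm-correction, optional lesion-volume regression, deficit
transform), three volume-control strategies (`none`, `voxelwise` 1/sqrt
volume scaling, `regress_out`), LOOCV hyperparameter training with the
published power-of-two grids, cluster extraction with atlas overlap
reports, SVOI-based (significant-cluster volume of interest) behavior
prediction ladders, and a synthetic two-lesion-type cohort simulator with
planted strategic regions for validation.

## Inputs

- Per-subject binary lesion masks (NIfTI-1), one file per lesion type per
  subject, all co-registered to one grid. Masks must be strictly binary;
  probabilistic maps are rejected rather than thresholded.
- A TSV manifest with columns `id`, `lesion_type`, `path`.
- A cohort CSV with columns `id`, `age`, `sex` (0/1), `education`, and one
  or more score columns; per-type volume columns are recomputed from the
  masks.

## CLI

```sh
# synthetic cohort with known strategic regions
mlsmap simulate --config sim.yaml --out-dir sim/

# mass-univariate mapping
mlsmap vlsm --masks sim/manifest.tsv --table sim/cohort.csv \
    --score moca --perms 1000 --seed 7 --out-dir runs/vlsm

# multi-lesion mapping with voxelwise volume control
mlsmap svr-mlsm --masks sim/manifest.tsv --table sim/cohort.csv \
    --score moca --volume-control voxelwise --perms 1000 --seed 7 \
    --out-dir runs/mlsm

# SVOI-based nested prediction ladder from a run's significant clusters
mlsmap svoi-predict --clusters runs/mlsm --masks sim/manifest.tsv \
    --table sim/cohort.csv --score moca --models models.yaml --out ladder.tsv

# atlas overlap report
mlsmap report --run-dir runs/mlsm --atlas atlas.nii.gz --labels labels.tsv \
    --masks sim/manifest.tsv --table sim/cohort.csv --out atlas_report.tsv
```

Each analysis run writes `maps/` (beta, p, -log10 p, significance masks,
prevalence and lesion-size-topology volumes), `clusters/clusters.tsv`,
`reports/`, `logs/`, a resolved-config copy and a provenance manifest.
Re-running an identical config reproduces all outputs bit-identically.

## Python API

```python
from mlsmap.simcohort import SimulationConfig, LesionSpec, sample_cohort
from mlsmap.design_matrix import build_multilesion_design
from mlsmap.behavior_prep import prepare_scores
from mlsmap.svr_mapping import train_and_fit
from mlsmap.permutation_inference import permutation_p, threshold_and_cluster

cohort = sample_cohort(SimulationConfig(n_subjects=60, seed=1))
design = build_multilesion_design(cohort.ail, cohort.wmh, k=3,
                                  volume_mode="voxelwise")
prepared = prepare_scores(cohort.table, "moca")
report, model, betas = train_and_fit(design, prepared.deficit)
pmaps = permutation_p(design, prepared.deficit, C=report.best_C,
                      P=1000, seed=1)
clusters = threshold_and_cluster(pmaps, alpha=0.05)
```

## Tests and acceptance

```sh
python -m pytest -q tests/            # unit + property + acceptance suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance suite (`tests/test_acceptance.py`) is property-based:
method-reduction equivalence (SVR-MLSM with an empty second block equals
SVR-LSM), closed-form and exhaustive-permutation oracles for VLSM,
permutation-null calibration, planted-signal recovery (ROC AUC and peak
weight location), SVOI added predictive value, bookkeeping exactness, and
LOOCV sanity checks. `scripts/acceptance.py` runs a seeded end-to-end
smoke check and writes the (empty) numeric-target report; no external
numeric targets exist because the source study's numbers depend on
patient data that is not distributable.

## Notes

- Norm-correction is within-sample OLS on the configured covariates, not
  an external normative look-up.
- Volume control uses full-mask volumes (before prevalence filtering).
- Permutations reuse the hyperparameters selected on the unshuffled data.
- p values use (1 + count) / (P + 1) smoothing and are never zero; ties
  between pseudo and real weights count against significance.
- The multi-lesion model supports the linear kernel only; RBF is available
  for single-lesion SVR-LSM.
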