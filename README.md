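# voxelight

Voxel-wise morphometry, searchlight decoding, and longitudinal decline-rate
analysis for matched-cohort gray-matter studies.

`voxelight` implements, as a tested and reusable pipeline, the statistical
framework used to ask how a binary exposure — here the *digital divide*,
low versus regular use of computers and mobile devices in an aging cohort —
relates to brain structure and cognition:

1. **Propensity-score matching** of exposed (DD) and control (ODD) groups on
   age, gender, education, and comorbidity flags, with standardized-mean-
   difference balance diagnostics.
2. **Cognitive composites**: each domain's score is a weighted sum of its
   standardized tests, the weights being single-factor loadings (a
   one-test domain uses that test's z-score).
3. **Voxel-based morphometry**: per voxel, the group t statistic from
   `GMV ~ group + age + gender + education + TIV`, Benjamini–Hochberg FDR,
   and face-connected cluster tables with atlas peak labels.
4. **Searchlight decoding**: a 2 mm sphere slides over the brain; each
   sphere's subjects × voxels matrix is reduced by PCA (80% variance
   retained) and classified by a linear SVM (C = 1) under stratified
   10-fold cross-validation, giving a 3-D accuracy map.  FDR-significant
   voxels classifying above 0.6 form the **constrained region**; the rest
   are **excluded**.
5. **Cognitive representation**: at each constrained voxel, the sphere's
   PCA features predict each domain composite through a linear model;
   the predicted-vs-observed Pearson r is tested against a permutation
   null and FDR-corrected per domain.
6. **Longitudinal analysis**: per-subject annual decline rates
   `(V_t2 − V_t1) / (V_t1 Δt)` per voxel and per atlas region, group
   contrasts on rate maps, rate–cognition Pearson correlations,
   product-of-coefficients **mediation** (exposure → regional decline rate →
   cognitive change) with percentile bootstrap CIs, and the two-level
   **growth model**

       level 1:  score_ij = π0_i + π1_i · time_ij + e_ij
       level 2:  π0_i = β00 + β01·age_i + β02·gender_i + β03·edu_i + β04·group_i + r0_i
                 π1_i = β10 + β11·age_i + β12·gender_i + β13·edu_i + β14·group_i + r1_i

   fitted by maximum likelihood with correlated random intercepts and
   slopes (β14 is the exposure effect on the rate of cognitive aging).

Because no imaging cohort ships with the package, a first-class
**synthetic-cohort generator** produces volumes, phenotypes, and cognition
with known ground truth — planted spherical effect regions at chosen Cohen
d, cognitive domains wired to regional gray matter, and group-specific
annual decline rates — so that every stage has a recovery test.

## Worked example

```python
from voxelight.pipeline import load_config, run_pipeline

cfg = load_config(None)           # desk-scale defaults: 24^3 grid, 1.5 mm
cfg["seed"] = 7
cfg["synthetic"] = {"n_per_group": 80}
status = run_pipeline(cfg, "runs/demo")
print(status)
```

```
{'simulate': 'ran', 'match': 'ran', 'composite': 'ran', 'vbm': 'ran',
 'searchlight': 'ran', 'represent': 'ran', 'rates': 'ran', 'growth': 'ran'}
```

The run directory then holds `matched.csv` and `balance.tsv` (matching),
`tmap.nii.gz` / `qmap.nii.gz` / `clusters.tsv` (morphometry),
`accuracy.nii.gz` and `constrained.nii.gz` (searchlight),
`representation.tsv` / `coverage.tsv` (per-voxel r, permutation p, FDR q
per domain), `rates.nii.gz`, `region_rates.csv`, `mediation.json`, and one
`growth_<domain>.json` per composite.  `mediation.json`, for example,
reports the paths a (group → regional rate), b (rate → cognitive change),
the total and direct effects, and the proportion mediated with its
bootstrap CI.

The same stages are available from the shell:

```bash
voxelight run --seed 7 --out runs/demo          # full pipeline, resumable
voxelight searchlight --seed 7 --out runs/demo  # one stage (+ prerequisites)
```

Every invocation appends a record (stage, config hash, seed, outputs,
warnings) to `manifests.jsonl` in the run directory; re-running skips
stages whose outputs exist, so deleting one stage's outputs recomputes just
that stage.

## Layout

```
src/voxelight/
  synthetic.py       cohort generator + growth/mediation simulators
  matching.py        propensity scores, greedy caliper matching, balance
  composites.py      group assignment, factor loadings, composites
  voxelwise.py       mask, group t-maps, BH-FDR, clusters, Cohen d
  searchlight.py     neighborhoods, PCA features, CV-SVM accuracy maps
  representation.py  per-voxel GLM prediction + permutation significance
  longitudinal.py    decline rates, mediation, two-level growth model
  validation.py      recovery/calibration studies (drives scripts/acceptance.py)
  pipeline.py, cli.py, io.py, containers.py
```

See `docs/methods.md` for the modelling choices, parameter conventions, and
known limitations.
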