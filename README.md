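# gpadelta

Analysis toolkit for **polygenic-score achievement discrepancies**: given a
cohort with standardized school-achievement scores at several ages and a
precomputed polygenic score, the package builds discrepancy ("delta")
scores at the first assessment age, fits per-individual achievement slopes
across ages, quantifies how far individuals regress toward their
score-predicted level, classifies under/over-achiever groups, runs the
associated regression models, and decomposes trait variance with twin ACE
models. A calibrated synthetic twin-cohort generator is included so the
entire pipeline is testable without access to any restricted cohort data.

## What's inside

| Module | Purpose |
| --- | --- |
| `gpadelta.synthgen` | Synthetic twin cohorts: ACE structure, polygenic proxy with age-varying validity, SES, cognitive proxy, attrition; closed-form implied correlation matrix as its own oracle |
| `gpadelta.scores` | Z-scoring, achievement composites, difference / residualized delta scores |
| `gpadelta.slopes` | Per-individual OLS achievement slopes, raw-MAD outlier filter, slope standardization |
| `gpadelta.trajectories` | Regression-to-prediction percentages (trimmed-mean summary), relative/absolute achiever groups, decile and group trajectory tables |
| `gpadelta.models` | Pearson CIs, hierarchical regression with semi-partial R² and nested F, moderation, VIF, repeated-CV multi-score weighting, dependent-correlation comparison |
| `gpadelta.twin` | Twin intraclass correlations, Falconer estimates, maximum-likelihood ACE fit with profile-likelihood or bootstrap CIs |
| `gpadelta.pipeline` / `gpadelta.cli` | End-to-end orchestration, CSV I/O, manifest, text report |

## Command line

```bash
# generate a synthetic cohort
gpadelta simulate --n-pairs 2000 --seed 1 --out cohort.csv

# full pipeline (simulate -> score -> slopes -> trajectories -> models -> twin)
gpadelta run --out results/run1 --seed 1

# or with a config file
cat > run.yaml <<'YAML'
simulate:
  n_pairs: 5000
  n_gps: 5
  attrition: [0.05, 0.25, 0.10, 0.05]
seed: 7
YAML
gpadelta run --config run.yaml --out results/run7
```

`run` writes per-stage tidy CSVs (`scores.csv`, `slopes.csv`, `groups.csv`,
`group_trajectories.csv`, `group_regression.csv`, `decile_trajectories.csv`,
`hierarchical.csv`, `ace.csv`), a human-readable `report.txt`, and
`manifest.json` recording versions, the master seed, and row counts after
every filter. Reruns with the same seed are byte-identical.

Individual stages are also exposed (`gpadelta score`, `gpadelta slopes`,
`gpadelta trajectories`, `gpadelta models`, `gpadelta twin`); see
`gpadelta <cmd> --help`. Arbitrary cohort CSVs can be adapted via the
`columns:` mapping block in the run config.

## Key conventions

- Deltas are *achievement z minus predictor z*; negative = underachievement.
- The MAD outlier rule uses the **raw** MAD (no 1.4826 consistency
  constant) with removal only when strictly exceeding `k × MAD` (k = 3).
- The trimmed mean removes `floor(n·trim)` observations from *each* tail.
- Regression percentage per individual is `(1 − delta_last/delta_first) × 100`.
- Relative groups lie beyond ±1 SD of the delta mean; absolute groups are
  the subset additionally beyond ∓1 SD of standardized achievement.
- All regressions are complete-case; "semi-partial R²" is the increment to
  R² from adding the focal predictor to an otherwise identical model.
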