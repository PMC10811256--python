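# dyadpred

Data-driven prediction of psychotherapy process and outcome from baseline
therapist and client characteristics, for studies with clients nested in
therapists.

The pipeline:

1. **study_data** — three-table data model (therapists, clients, long
   session records), CSV I/O, Z-scoring of continuous predictors, ±0.5
   coding of binary predictors, and k-nearest-neighbour imputation.
2. **synthetic_study** — a seeded generator for nested dyadic studies
   (default design: 23 therapists × 2 clients, 7 weekly sessions, alliance
   rated by both parties at sessions 1/3/5/7, symptom outcome at
   pre / s1 / s3 / s5 / s7 / post) with full ground truth for recovery
   testing.
3. **target_derivation** — five client-level dependent variables: the
   conditional (shrunken) symptom-change slope, per-rater mean alliance
   (between-clients level), and per-rater conditional alliance slopes
   (within-client change), from jointly fitted random-intercept-and-slope
   growth models.
4. **mixed_model_engine** — fast maximum-likelihood fitting of two-level
   random-intercept linear mixed models via a profiled likelihood over the
   variance ratio; Wald-t inference, AIC (k = fixed effects + 2), ICC,
   Nakagawa–Schielzeth marginal R², BLUP-based prediction, and residual
   diagnostics (Shapiro–Wilk, Breusch–Pagan).
5. **model_search** — best-subset search over linear + quadratic +
   pairwise-interaction terms (≤ 9 per model), scored by AIC with a
   leave-one-client-out CV R² overfitting guard (selection requires the
   training-minus-CV R² drop ≤ 0.10); exhaustive when the subset count fits
   the budget, forward beam search otherwise.
6. **reporting / pipeline / cli** — coefficient tables (Estimates / CI /
   df / Statistic / p + random-effects block + training/CV R²), numeric
   effect grids for quadratics and interactions, and the end-to-end runner
   with manifest, hashes and structured logs.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalence, parameter and model recovery, diagnostics calibration, and the
deterministic five-model end-to-end run); the full suite takes roughly
10–15 minutes on one CPU.

## CLI

```bash
# generate a synthetic study (three CSVs + ground_truth.json)
dyadpred simulate --seed 7 --out-dir data/

# preprocess + derive the five DVs
dyadpred preprocess --in-dir data/ --out predictors.csv
dyadpred derive --in-dir data/ --out-dir derived/

# best-subset search for one outcome
dyadpred search --in-dir data/ --outcome outcome_slope --seed 7 --out-dir run/

# everything, all five outcome models
dyadpred run --seed 7 --out-dir run_all/
```

`dyadpred run` accepts a YAML config (`--config`) with optional blocks
`simulate` (generator settings), `inputs` (paths to the three CSVs —
mutually exclusive with `simulate`), `preprocess` (`knn_k`), `derive`
(`standardize`, `week_coding`, `prepost_only`) and `search` (`outcomes`,
`max_terms`, `drop_threshold`, `drop_mode`, `cv_pool_size`, `budget`,
`beam_width`, heredity flags, `rescale_per_fold`).

The same functionality is available as a library:

```python
from dyadpred import SyntheticConfig, generate_study, derive_targets, \
    preprocess_predictors, build_universe, select_model, Predictor

dataset, truth = generate_study(SyntheticConfig(seed=7))
frame, meta = preprocess_predictors(dataset)
targets, log = derive_targets(dataset)
merged = frame.merge(targets.reset_index(), on="client_id")
universe = build_universe([Predictor(p["name"], p["kind"], p["level"])
                           for p in meta["predictors"]])
result = select_model(merged, universe, "outcome_slope", seed=7)
print(result.selected.describe(), result.selection_note)
```

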