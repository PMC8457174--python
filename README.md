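# transdx

Transdiagnostic symptom dimensions and bandit decision-making: a tested
analysis pipeline covering

- **bandit_env** — 3-option task schedules (bounded drifting success
  probabilities with occasional best-option switches), choice sessions in
  reward and loss framings, correct-option labelling, and performance.
- **rl_models** — eight reinforcement-learning models (`RL1a`–`RL4b`):
  Q-learning, value forgetting, choice-trace perseveration, asymmetric
  learning rates, and a hybrid Pearce-Hall learner; numba-accelerated
  per-trial likelihoods and agent simulators.
- **fitting** — per-participant maximum-likelihood estimation (multi-start
  L-BFGS-B on transformed parameters) and −BIC/2 model evidence.
- **bms** — random-effects Bayesian model selection (variational Dirichlet
  updates; Monte-Carlo exceedance probabilities).
- **history_regression** — lagged reward/choice history design with ±1/0
  coding, two-stage hierarchical logistic estimation, total effects,
  Benjamini-Hochberg FDR, and a pooled two-task model with task
  interactions.
- **factors** — polychoric correlations (batched two-step estimator),
  CNG scree test, minres extraction with promax rotation, Harman factor
  scores, and a low-loading item filter.
- **dimension_stats** — random-intercept performance model (adaptive
  Gauss-Hermite), CIT~parameter regressions with one-tailed tests,
  leave-one-out cross-validated prediction, and permutation testing.
- **synthetic_cohort** — end-to-end synthetic studies with planted ground
  truth: latent factors → RL parameters → bandit sessions, and latent
  factors → 154-item ordinal questionnaires (5 instrument blocks).

All analyses run on synthetic cohorts; every estimator is validated
against planted ground truth or independent oracles in the test suite.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (likelihood
oracles, parameter/model recovery, history-design exactness, planted-sign
recovery, factor-pipeline recovery, statistical calibration, CLI
determinism). The full suite takes several minutes; the heavy recovery
studies live in the acceptance file.

## CLI

```sh
transdx simulate --scenario paper_like --seed 11 --out run/
transdx fit      --sessions run/sessions_reward.csv --out run/fits.csv
transdx bms      --fits run/fits.csv --out run/bms.json
transdx history  --sessions run/sessions_reward.csv \
                 --participants run/ground_truth.csv --out run/history.csv
transdx factors  --responses run/questionnaire.csv \
                 --items run/item_map.json --out-dir run/
transdx analyze  --summaries run/summaries_reward.csv --out run/report.json
```

Scenarios: `paper_like` (planted CIT links: lower learning rate in both
arms, higher choice-trace weight in the reward arm only), `null`,
`strong_effects`, `small_n_smoke`. Every stage is deterministic for a
fixed `--seed`; custom cohorts can be described in YAML
(`--config cfg.yaml`, fields of `synthetic_cohort.CohortConfig`).

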