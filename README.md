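# palpkit

Objective skill assessment for simulator-based vascular palpation: per-trial
kinematic metrics from fingertip motion capture, mixed-effects models of
haptic-factor effects, and calibrated synthetic study generation so the whole
pipeline is testable end to end without any recorded data.

## What's inside

| module | purpose |
| --- | --- |
| `palpkit.trajectory` | Domain types (conditions, targets, frames, trials), coordinate conventions, CSV/JSON serialization |
| `palpkit.metrics` | The five per-trial metrics: endpoint accuracy (+ bands / binary), duration, total path length, ratio of correct movement, error rate |
| `palpkit.models` | Random-intercept LMM per metric (REML, via statsmodels) and a random-intercept logistic GLMM for binary accuracy (adaptive Gauss–Hermite quadrature), with Wald CIs and odds ratios |
| `palpkit.synth` | Synthetic studies at metric fidelity (direct generative draws) and trajectory fidelity (biased-random-walk kinematics), plus parameter-recovery harness |
| `palpkit.cli` | `palpkit generate / metrics / analyze / recover` |

Conventions: millimeters and seconds throughout; x–y is the skin plane with
the origin at the workspace center; accuracy/error-rate/velocity-projection
distances are in-plane, path length and the movement-frame speed test are 3D.
Accuracy bands: ≤ 10 mm accurate, (10, 30] marginal, > 30 mm error.

## CLI

```sh
# synthesize a full 12-participant study with per-frame trajectories
palpkit generate --participants 12 --seed 7 --fidelity trajectory --out study/

# derive the per-trial metric table from the bundle
palpkit metrics --bundle study/ --out study/metrics_rederived.csv

# fit the accuracy GLMM + per-metric LMMs; prints a factor-by-metric table
palpkit analyze --metrics study/metrics.csv --out study/results.json

# simulate-then-fit parameter recovery (bias, Monte-Carlo SE, CI coverage)
palpkit recover --replicates 100 --seed 1 --out recovery.json
```

Exit codes: 0 success, 1 usage error, 2 data error, 3 model-fit failure.
Generator constants live in a JSON config (`GeneratorParams`); pass
`--config my_params.json` to override the documented defaults, which are
calibrated so a 12×32 study reproduces the published effect sizes and
accuracy distribution.

Results JSON layout: `{"metrics": {<metric>: {<factor>: {estimate, se,
ci_low, ci_high, significant}}}, "accuracy": {<factor>: {log_odds, se, or,
or_ci_low, or_ci_high, significant}}, "variances": ..., "n": ...,
"failures": ...}`.

## File formats

- **Frame CSV** — header `t_s,ix,iy,iz,mx,my,mz`; strictly increasing
  timestamps; full round-trip float precision.
- **Study manifest** — JSON array of
  `{trial_id, participant_id, vibration_type, vibration_intensity,
  skin_thickness_mm, location_index, target_x_mm, target_y_mm, frame_file}`.
- **Metrics CSV** — one row per trial: ids, condition columns, and
  `accuracy_mm, accuracy_band, accurate_binary, duration_s, tpl_mm, rcm_pct,
  error_rate` (empty cells where a frame-ratio metric is undefined).
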