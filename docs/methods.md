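# Methods

## Model and procedure

The pipeline treats each experimental arm (fasted FS, carbohydrate
pre-fed CPF) separately and assumes the post-hemorrhage dynamics of a
*controlled* metabolite are approximately linear in the measured
concentration panel:

    dx_j/dt = f_j(x_1, …, x_M) ≈ β_0 + Σ_m β_jm x_m ,   sparse in m.

Stages:

1. **Baseline shift.**  For every animal and metabolite, the
   pre-hemorrhage baseline (BS) value is subtracted from all later
   measurements; BS rows are retained at 0.  Animals without a BS sample
   are excluded (warning, not an error).  Shifted values may be negative.
2. **Normalization.**  Each metabolite column is divided by the standard
   deviation (ddof = 1) of its shifted values pooled over all animals and
   post-baseline timepoints of the arm, so that one penalty level is
   meaningful across all regressors.  Columns with pooled SD below 1e-12
   are flagged degenerate and left unscaled.  Whether the original study
   normalized before or after shifting, or by SD at all, is not stated in
   its main text; pooled-SD-after-shift is this package's documented
   choice, and every support/acceptance decision is invariant to the units
   of the raw columns (tested).
3. **Rates.**  First differences over the schedule-consecutive
   post-hemorrhage pairs (0.75–3, 3–5, 5–9, 9–17, 17–21 h).  The
   baseline-to-45-min interval is excluded: the hemorrhage lies inside it,
   so that difference is a treatment effect, not network dynamics.  An
   interval exists only when both endpoint samples exist (dropout drops
   intervals, not animals).  The regressor row is the concentration vector
   at the interval start (explicit-Euler alignment; a midpoint option
   exists as a sensitivity).
4. **Sparse prediction.**  Per target, a lasso path over 50 log-spaced
   penalties from λ_max (smallest penalty zeroing all coefficients) down
   to 1e-4·λ_max.  Candidate supports are every support visited on the
   path (size ≤ 8) plus the greedy backward-elimination chain of each —
   the path can step over a small qualifying subset, and pruning the
   weakest member recovers it; this makes the selection agree with the
   exhaustive best-subset oracle on essentially all noiseless test
   instances.  Each candidate is refit by unpenalized least squares
   (intercept always included and unpenalized) and the **sparsest**
   candidate with mean |error| < 0.5 · mean |rate| is selected; ties by
   smaller error, then lexicographic support.  If none qualifies the
   best-error fit is returned unaccepted.  Errors are mean *absolute*
   (matching a "mean magnitude" reading, not squared), in-sample: the
   procedure describes one pooled fit, and the null-calibration test
   guards against overfitting pathologies.  Targets with mean |rate|
   ≤ 1e-10 are "no-signal".  Self-edges are allowed by default (the
   predictor ranges over *all* measured concentrations, including the
   target's own); a flag disables them for table-style replication.
5. **Assembly.**  Accepted fits become signed edges
   controlling → controlled with the fitted coefficients as weights;
   feedback nodes are the controlled ∩ controlling intersection; each
   controlling node is annotated with its correlated signals: other
   metabolites whose pooled Pearson R², on the shifted+normalized
   post-baseline trajectories, strictly exceeds 0.8 (pairs evaluated on
   jointly observed entries).

No multiple-testing correction is applied across targets, no
cross-validation, and no smoothing or spline derivatives — first
differences only, with the long inter-sample gaps understood as a
limitation of the design being emulated.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `error_ratio_threshold` | 0.5 | acceptance bound on mean abs error / mean abs rate |
| `max_support` | 8 | largest candidate support ("low order") |
| `n_lambdas`, `lambda_min_ratio` | 50, 1e-4 | penalty grid |
| `min_intervals_per_metabolite` | 10 | eligibility floor for controlled-node candidates |
| `r2_threshold` | 0.8 | strict lower bound for correlated signals |

With unit-SD regressors and roughly Gaussian zero-mean rates, an error
ratio of 0.5 corresponds to explaining about 75 % of rate variance, which
bounded-support fits on pure noise essentially never reach at ~160 pooled
intervals; the null-calibration experiment (200 replicates of 48-metabolite
noise cohorts) measures an acceptance fraction of zero.

## Synthetic cohorts

The simulator generates what the inference assumes, plus the nuisance
structure of the emulated study: 32 animals per arm, the fixed 7-point
schedule, lognormal baselines (median 1 mM, σ = 0.5 — high inter-animal
variation), a randomized hemorrhage deviation at 45 min (SD = 50 % of each
metabolite's baseline), linear relaxation dynamics on deviations
dx/dt = rate_scale·A·(x − baseline) integrated by Euler–Maruyama at
0.05 h, process noise 0.02 mM/√h, measurement noise 0.02 mM, negative
measurements clipped at zero (counted), and exponential mortality with
hazard 0.0156/h (≈ 28 % cumulative over 21 h, matching the fasted arm's
printed mortality).  Dropout is uninformative right-truncation.

Two ground-truth flavours:

- `make_truth` (ODE truth): each controlled row gets 0–2 signed drivers
  with magnitudes in [0.5, 1] plus a dominating negative self-coefficient
  (Gershgorin ⇒ all eigenvalue real parts ≤ 0).  The stability margin is
  drawn from the same magnitude range so every non-zero coefficient
  honors the 0.5 floor.  `rate_scale` = 0.12/h sets relaxation times of
  roughly 4–10 h, comparable to the sampling gaps; acceptance decisions
  are invariant to uniform rate scaling, so this choice governs only how
  much the long-gap first differences depart from instantaneous rates.
- `make_regression_truth` (panel truth): off-diagonal-only rows with 1–3
  drivers, used by `make_rate_panel`, which emits the regression problem
  directly (i.i.d. unit-SD regressor rows, additive rate noise SD 0.2).
  This isolates the selection rule from integration error and is the
  basis of the signed-edge recovery and null-calibration experiments.

What the simulator deliberately does *not* model: physiological
mechanisms (no glucose kinetics, no resuscitation-fluid effects),
nonlinear or time-varying regulation, informative dropout, and NMR
quantification error structure beyond additive Gaussian noise.  Passing
recovery tests therefore demonstrate that the inference machinery recovers
the generative structure it assumes at realistic noise — not that the
linear-sparse assumption holds in real serum data.

## Numerical choices and degenerate inputs

- Pooled SDs use ddof = 1; columns under 1e-12 SD are degenerate (kept,
  flagged, excluded from eligibility).
- All tie-breaks are deterministic (error, then lexicographic metabolite
  order), so repeated runs produce byte-identical edge lists and reports.
- Rate-panel rows are used for a target when the target's rate and the
  full regressor vector are finite; regressor columns observed in < 80 %
  of a target's usable rows are dropped from that target's candidate pool.
- OLS refits use `numpy.linalg.lstsq` (minimum-norm under rank
  deficiency); the lasso path itself tolerates rank-deficient designs.
- The `best_subset_oracle` refuses panels wider than 12 regressors
  (exhaustive enumeration only); it is a test oracle, not a user surface.
- Problem sizes in the validation experiments: 100 noiseless 10-regressor
  instances for oracle agreement, 200 pure-noise 48-metabolite cohorts for
  null calibration, 20 seeds for signed-edge recovery, 10 seeds for
  end-to-end recovery through the simulator.

## Known limitations

- The selection rule legitimately drops a weak driver whenever the
  remaining support already meets the 50 % criterion (e.g. a driver at
  |β| = 0.3 beside one at 0.8); table-exact edge recovery is therefore
  only expected when generating coefficients are reasonably balanced, and
  controlled nodes with ≥ 5 equal-strength drivers cannot be recovered
  edge-exactly under this criterion by *any* subset-selection rule.
- In-sample acceptance with no multiple-testing correction mirrors the
  emulated procedure; on 48 simultaneous targets a small false-acceptance
  rate is possible in principle even though the null experiments measure
  zero at these sizes.
- First differences over 2–8 h gaps estimate interval-averaged, not
  instantaneous, rates; with mixed gap lengths this leaves a
  model-mismatch floor in the error ratio that grows with |A|·gap.
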