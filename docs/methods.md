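# Methods

## Model and assumptions

`il6kin` models plasma IL-6 during and after a single exercise bout as a
linear three-state cascade. Suprabasal oxygen consumption `PVO2max(t)`
(percent of VO2max; the ~8% basal consumption is excluded, capping the
target at 92%) follows first-order kinetics with rate 0.8 min⁻¹ toward the
piecewise-constant exercise target, so it reaches 99% of the target in
ln(100)/0.8 ≈ 5.76 min — the "within 5–6 minutes" behaviour the single
rate constant is meant to encode. Muscle-compartment IL-6 is produced
proportionally to `PVO2max` (secretion rate `SR_ex`) and transferred to
plasma with rate `k_m`; plasma IL-6 is cleared with turnover `k_e`
(half-life ln 2/k_e) and topped up by a constant adipose-tissue production
`Ra_IL6/V`.

Assumptions worth keeping in mind:

* a single intensity input — no dependence on exercise modality or engaged
  muscle mass;
* one-component oxygen-uptake kinetics, an acknowledged simplification for
  heavy exercise where a slow component exists;
* adipose production constant throughout, fixed by the resting steady state
  `Ra_IL6 = k_e·IL6_b·V`, so it is derived from the estimate, never fitted;
* the baseline `IL6_b` is pinned to the fasting pre-exercise value and is
  not a free parameter.

## Units

Intensities carry the numeric percent value (67, not 0.67); `SR_ex` is
therefore pg·ml⁻¹·min⁻¹ per percent of suprabasal VO2max. This is the only
convention under which the shipped parameter sets, protocol intensities and
observed plasma IL-6 magnitudes are mutually consistent. The distribution
volume is stored in millilitres (default 14,000 ml = 14 l) so
`k_e·IL6_b·V` is a pg·min⁻¹ production rate directly; config readers accept
`V_l` (litres) and convert on read, making a litres/millilitres mix-up
impossible downstream.

## Analytic solution and numerical integration

Because the cascade is linear with a piecewise-constant input, the exact
solution is a sum of exponentials per segment, propagated across the input
breakpoints (`model.closed_form_state`). It requires pairwise-distinct
rates: if two of (ramp_rate, k_m, k_e) coincide within 1e-10 relative, a
`DegenerateRatesError` is raised rather than silently losing precision —
the numerical integrator is the fallback there (secular terms would be
needed, and no shipped parameter set is near-degenerate).

The integrator (`simulate`) uses an adaptive explicit Runge–Kutta method
(DOP853) with rtol 1e-9 / atol 1e-12 defaults. The input discontinuities
are the only numerical hazard, so integration is split at `t_ex_start` and
`t_ex_end` and the solver never steps across them; observation times are
solver evaluation points, never interpolated. The suite verifies < 1e-6
relative agreement with the analytic solution on all four preset protocols
and < 1e-8 change under tolerance refinement. The default output grid is
1-minute spacing to `t_ex_end + 6·ln2/k_e`, which captures recovery to
within ~2% of baseline.

## Estimation

`wnls_fit` minimises `Σ_j w_j (y_j − y*_j)²` with Levenberg–Marquardt,
weights `w_j = 1/(cv·y_j)²` from a constant fractional assay CV (default
0.069, the mean intra-assay CV of the source studies) applied to the
*observed* values — the weight matrix is fixed, not iterated on model
predictions. Positivity of the rates is guaranteed by optimising
log-parameters internally (LM is unconstrained); the reported minimiser
agrees with a natural-space fit to 1e-3 relative on well-conditioned data
(tested). Default initial guess (0.05, 0.005, 0.05) is the order of
magnitude of the reference estimates; an optional seeded multi-start
(log-uniform ±1 decade) adds robustness. Stopping tolerances are
ftol = xtol = gtol = 1e-12 so that noiseless fits recover generating
parameters to ~1e-5 relative.

Precision: the Fisher information `J^T W J` is built from central finite
differences of the predictions with respect to the log-parameters (step
1e-6). On the log scale the standard deviations are fractional, so
CV% = 100·SD_log, identical to first order with the natural-space
CV% = 100·SD_p/p; natural SDs are reported as p·SD_log. A singular
information matrix (eigenvalues ≤ 1e-12 of the largest) triggers a
non-identifiability report: the undetermined log-parameter directions are
returned, the affected CV% are infinite, and the fit is flagged with a
warning rather than failing — a flat (no-exercise) series, where none of
the three parameters moves the prediction, exercises this path. Finite CV%
above 1000% are likewise flagged as practically non-identifiable.

Monte-Carlo behaviour under the reference conditions (below): the
linearised FIM standard deviations track the empirical sampling spread
within ~10% for all three parameters, and nominal 95% intervals
(estimate ± 1.96·SD) cover the truth in 91–93% of replicates. The
`SR_ex`–`k_e` pair is strongly correlated (both scale the response
amplitude), which is why their individual CVs (~17%) are much larger than
`k_m`'s (~6%).

## Cross-validation

`kfold` runs the dataset-level scheme: each series takes one turn as
training set; the fitted parameters are then used to predict *every*
series under its own protocol and baseline, with `Ra_IL6` re-derived per
dataset from the steady-state relation. Per-dataset mean squared prediction
errors (MSPE, pg²·ml⁻²) pool into the observation-count-weighted CVPEE,
which algebraically equals the plain mean of pooled per-observation squared
errors (asserted exactly in tests). The training dataset's own fit error is
included by default — that is what the pooled-count normalisation implies —
with an `include_training=False` option. The best set is the stage with
minimal CVPEE; exact ties break toward the lowest summed parameter CV%.
A stage whose fit fails is recorded with its error, excluded from
selection, and the run continues. MSPE is implemented in its squared form,
as the name implies.

## Synthetic data

`generate_series` corrupts noiseless model trajectories with multiplicative
zero-mean Gaussian noise at constant CV — exactly the error model the
estimator's weights assume — and floors observations at 1e-3 pg·ml⁻¹ so CV
weighting stays defined (at 6.9% CV the floor is effectively never hit).
Consequences verified in the suite: the empirical SD/mean at a fixed time
over 1000 replicates lands in [0.064, 0.074], and the mean weighted
residual variance of refits is ≈ 0.8, inside [0.5, 1.5].

The benchmark suite emulates the four published protocols from a single
ground truth (default: the cross-validation-winning set
SR_ex = 0.045, k_m = 0.004, k_e = 0.053). Sampling schedules: the two-leg
knee-extensor study prints its ten instants (0–1380 min) and is used
verbatim; hourly-during-exercise (one-leg study) and 30-min-during-exercise
(cycling study) follow the studies' descriptions; the treadmill study's
exact instants are not printed, so the stand-in is a uniform 30-min
schedule over [0, 480] min — 17 samples spanning the 150-min bout and
~5.5 h of recovery, consistent with its "before, during and 6-h recovery"
design. All schedules are overridable. Master-seed splitting is
`seed + dataset_index`, documented and platform-independent.

What the synthetic data do *not* emulate: between-subject variability and
repeated-measures correlation (the estimator fits group means with
independent errors), assay drift, and any model misspecification. Passing
recovery tests therefore demonstrates the estimator's correctness under its
own assumptions, not robustness to violations of them on real data.

## Reference study conditions and problem sizes

The parameter-recovery study uses 100 seeded replicates of the
17-sample treadmill-protocol series at 6.9% CV, fitted from the default
initial guess; summaries are median absolute relative error, bias, RMSE and
95%-interval coverage per parameter. The residual-randomness check (runs
test at α = 0.05) uses 50 seeds; the noise-calibration check 1000
single-point replicates. The noiseless cross-validation self-consistency
suite uses the four preset schedules (N = 38 observations). Noiseless
fixtures are generated with zero noise CV and the 6.9% weighting CV
restored afterwards, since a zero CV cannot define reciprocal-variance
weights.

## Known limitations

* The analytic oracle rejects (near-)equal rate constants instead of
  switching to limit formulas; only the integrator covers that measure-zero
  set.
* FIM-based intervals are linearised; along the correlated `SR_ex`–`k_e`
  ridge they are mildly optimistic (coverage 91–93% at nominal 95% under
  the reference conditions).
* Published per-study CV% and CVPEE values depend on the original
  digitised time courses, which are third-party figure data and not
  redistributed; the cross-validation machinery reproduces the *structure*
  and selection logic on synthetic suites instead.
* No population/mixed-effects fitting, no Bayesian posteriors, no
  leave-one-observation-out variants.
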