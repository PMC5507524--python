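# il6kin — exercise-induced plasma interleukin-6 kinetics

Interleukin-6 (IL-6) is produced mainly by adipose tissue at rest and, during
exercise, in large additional amounts by contracting skeletal muscle; the
hepatosplanchnic viscera clear it from plasma. `il6kin` implements a
two-compartment linear kinetic model of this balance, for exercise
physiologists and modellers who want to simulate plasma IL-6 responses to an
exercise bout, fit the model's kinetic parameters to measured IL-6 time
courses, and compare candidate parameter sets across studies — entirely
reproducible on synthetic data.

## The model

Exercise intensity enters as suprabasal oxygen consumption
$PVO_{2max}(t)$ (percent of maximal oxygen uptake, basal ≈ 8% excluded),
which relaxes toward the piecewise-constant target $u(t)$ ($T_v$ during the
bout, 0 otherwise):

$$\dot P = -0.8\,P + 0.8\,u(t), \qquad P(0)=0$$
$$\dot{IL6}_m = SR_{ex}\,P - k_m\,IL6_m, \qquad IL6_m(0)=0$$
$$\dot{IL6}_p = k_m\,IL6_m - k_e\,IL6_p + \frac{Ra_{IL6}}{V}, \qquad IL6_p(0)=IL6_b$$

with $SR_{ex}$ the muscular secretion rate, $k_m$ the muscle→plasma transfer
rate, $k_e$ the plasma turnover rate and $V$ the distribution volume (14 l).
The adipose production $Ra_{IL6}$ is pinned by the resting steady state
$Ra_{IL6} = k_e\,IL6_b\,V$, so it is derived, never fitted.

The three free parameters $(SR_{ex}, k_m, k_e)$ are estimated by weighted
nonlinear least squares (Levenberg–Marquardt on log-parameters) with weights
$1/(cv\cdot y_j)^2$ from a constant 6.9% assay coefficient of variation.
Precision comes from the Fisher information matrix $J^\top W J$, reported as
percent CV per parameter. Candidate parameter sets are compared by a
dataset-level K-fold cross-validation: each dataset takes a turn as training
set and the observation-count-weighted mean squared prediction error (CVPEE)
over all datasets selects the best set.

## Worked example

```python
from il6kin import (PROTOCOLS, PARAMETER_SETS, simulate, half_life,
                    wnls_fit, generate_series)
from il6kin.synth import DEFAULT_SCHEDULES

protocol = PROTOCOLS["d1_ostrowski"]        # 150 min treadmill run at 67% VO2max
params = PARAMETER_SETS["d1_ostrowski"]     # SR_ex=0.045, k_m=0.004, k_e=0.053

traj = simulate(protocol, params)
print(f"Ra_IL6 = {traj.Ra_IL6:.1f} pg/min")
print(f"half-life = {half_life(params.k_e):.1f} min")
print(f"plasma IL-6 at end of exercise = {traj.il6_plasma[150]:.2f} pg/ml")

series = generate_series(protocol, params, DEFAULT_SCHEDULES["d1_ostrowski"],
                         assay_cv=0.069, seed=42)
fit = wnls_fit(series)
for name, value, cv in zip(("SR_ex", "k_m", "k_e"),
                           fit.params.free_values, fit.cv_percent):
    print(f"{name:6s} = {value:.4g}  (CV {cv:.0f}%)")
```

prints

```
Ra_IL6 = 1261.4 pg/min
half-life = 13.1 min
plasma IL-6 at end of exercise = 24.65 pg/ml
SR_ex  = 0.0434  (CV 18%)
k_m    = 0.003826  (CV 7%)
k_e    = 0.05088  (CV 17%)
```

The first three lines are deterministic model properties: the adipose tissue
must produce ≈1261 pg of IL-6 per minute to sustain a 1.7 pg/ml baseline
against a turnover of 0.053 min⁻¹ (13-min half-life), and the 2.5-h run
raises plasma IL-6 roughly 15-fold to ≈24.7 pg/ml. The fit lines show the
estimator recovering the generating parameters from one noisy synthetic
series, each with its Fisher-information percent CV.

The same pipeline is scriptable from the shell:

```sh
il6kin synth --seed 1 --out-dir suite/            # 4-protocol synthetic suite
il6kin crossval --manifest suite/manifest.json --out report.tsv -v
il6kin recover --seed 1 --n-replicates 100 --out recovery.json
il6kin simulate --preset d1_ostrowski --params-preset d1_ostrowski --out traj.tsv
```

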