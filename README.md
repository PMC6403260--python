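# tempattn

Modelling how visual attention is allocated in *time* around an expected
event.  When a brief, near-threshold target appears at a random delay after
a temporal cue, contrast sensitivity traces out the observer's attention as
a function of elapsed time.  `tempattn` implements a subjective predictive
hazard-rate account of that curve together with the full estimation and
statistics chain needed to fit it to trial-level psychophysics data — and a
synthetic-observer generator so every stage can be exercised end to end
without any data.

It is written for computational psychophysicists and cognitive modellers:
scikit-learn-style estimators over pandas trial tables, with a thin CLI.

## The model

For cue–target intervals drawn uniformly from `[t_min, t_max]` with density
`f` and CDF `F`:

* miss-corrected hazard: `h(t) = f(t) / (1 − k F(t))`, with
  `k = 1 − P(ND|A) = 0.5` for threshold-level targets that go unnoticed on
  about half the presentations;
* scalar timing noise: elapsed time is known through a measurement
  `m ~ N(t, (w t)²)` (Weber fraction `w`), giving the subjective hazard
  `ĥ(m) = ∫ f p(m|t) dt / ∫ (1 − kF) p(m|t) dt`;
* predictive look-ahead: attention reflects target probability now *and* in
  the near future, exponentially weighted with time constant `mu` — the
  numerator `f` is replaced by `(1/mu)∫_t^∞ f(τ) e^{−(τ−t)/mu} dτ`;
* threshold read-out: `y(t) = β0 + β1 ∫ ĥ(m) p(m|t) dm`, fitted jointly to
  a narrow-range (700–1300 ms) and a wide-range (500–3000 ms) threshold
  curve with shared `w` (and `mu`), and compared against the no-look-ahead
  reduction with an extra-sum-of-squares F test on df (1, 12).

Estimation tools: shared-slope 2AFC psychometric MLE (per-interval
thresholds at 75% correct), a subject-resampling bootstrap for group
thresholds, a hierarchical Bayesian Metropolis–Hastings fit of
shorter/longer-than-one-second duration judgments (population PSE mode and
95% credible interval), a permutation test for short-term threshold
fluctuation, window-3 smoothing, subject centering, repeated-measures ANOVA
and Fisher-LSD comparisons.  See `docs/methods.md` for assumptions,
numerics and limitations.

## Worked example

Simulate a 15-subject narrow-range study, run the analysis chain, and fit
both model variants:

```python
import numpy as np
import tempattn as ta

trials, truth = ta.simulate_study(ta.design("1"), n_subjects=15, seed=0)

from tempattn.pipeline import analyze_narrow_range
res = analyze_narrow_range(trials, n_perm=2000, seed=0)
a = res["anova"]
print(f"F({a.df1},{a.df2}) = {a.F:.2f}, p = {a.p:.2e}, eta_p^2 = {a.partial_eta_sq:.2f}")

# model curves on the two analysis grids, perturbed with residual noise
rng = np.random.default_rng(1)
curves = []
for c in ta.true_threshold_curves():
    noise = 0.05 * np.ptp(c.thresholds) * rng.standard_normal(c.thresholds.size)
    curves.append(ta.ThresholdCurve(c.intervals, c.thresholds + noise, c.dist, c.label))

red  = ta.AttentionModelRegression("classical",  seed=0).fit(curves)
full = ta.AttentionModelRegression("predictive", seed=0).fit(curves)
cmp_ = ta.compare_models(red, full)
print(f"w = {full.w_:.3f}, mu = {full.mu_*1e3:.0f} ms, "
      f"F({cmp_.df_extra},{cmp_.df_resid}) = {cmp_.F:.1f}, p = {cmp_.p:.1e}")
```

Output:

```
F(6,84) = 56.47, p = 2.03e-27, eta_p^2 = 0.80
w = 0.115, mu = 96 ms, F(1,12) = 465.2, p = 5.8e-11
```

The ANOVA confirms that simulated thresholds vary systematically with the
cue–target interval.  The joint fit recovers the generating Weber fraction
(w = 0.11) and look-ahead constant (106 ms) from the noisy curves, and the
nested comparison strongly prefers the predictive variant over the
no-look-ahead reduction.

The same stages are available from the shell:

```bash
tempattn simulate --experiment 1 --n-subjects 15 --seed 0 --out trials.csv
tempattn fit-thresholds --trials trials.csv --out thresholds.csv
tempattn stats --trials trials.csv --n-perm 2000 --seed 0 --out stats/
tempattn recover --study attention --n-replicates 20 --seed 0 --out recover.json
tempattn run --config examples/demo_config.json
```

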