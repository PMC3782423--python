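# trajbayes

Behavioural modelling of **occluded-trajectory endpoint prediction** under a
non-stationary statistical environment.

An observer watches a target fall along a noisy parabolic path, loses sight
of it behind an occluder, and must predict the horizontal coordinate where it
will land.  Two sources of information constrain that prediction:

* a **dynamic forward model** — extrapolation of the current trajectory,
  summarized here by an ordinary-least-squares quadratic fit to the observed
  samples, giving an endpoint estimate μ_d with standard error σ_d;
* a **statistical model** — the distribution of landing points across trials,
  which is Gaussian but whose mean and variance jump to new values at
  unsignalled change-points every 20–40 trials, so it must be tracked by a
  Bayesian ideal observer that returns the belief (μ_s, σ_s) in force at the
  start of each trial.

Bayes-optimal behaviour fuses the two by **precision weighting**.  With
precisions P_s = M/σ_s² and P_d = (2−M)/σ_d² (mixing factor M, spatial bias
b), the package implements and compares three response models:

| model | predicted response μ_sd |
|---|---|
| weighted combination | b + (P_s μ_s + P_d μ_d)/(P_s + P_d), M ∈ [0, 2] |
| unweighted combination | b + M μ_s + (1−M) μ_d, M ∈ [0, 1] |
| weighted, no combination | b + (μ_s if P_s ≥ P_d else μ_d) |

Responses are modelled as r ~ N(μ_sd, k²); the per-participant parameters
(M, k, b) are fit by maximum likelihood and the models compared by log
likelihood ratios and BIC.  The package also produces the trial-wise
parametric regressors used in event-related neuroimaging designs — log
precisions of both predictions, Gaussian KL divergences KL(statistical ‖
combined) and KL(statistical_i ‖ statistical_{i+1}), unsigned mean change,
and response accuracy in % screen width — without any GLM fitting.

It is aimed at computational cognitive neuroscientists who want a tested,
fully synthetic re-implementation of this task and model family for
simulation studies, parameter/model recovery, and regressor design.

## Worked example

```python
import numpy as np
import trajbayes as tb
from trajbayes.behavior import BeliefArrays

config = tb.EnvironmentConfig(seed=11)        # 220 trials, 20 warmup
session = tb.generate_session(config)
print(f"analysis trials: {session.analysis_mask.sum()}")
print(f"noise calibration ratio: {tb.noise_calibration_ratio(session):.2f}")

stat = tb.run_filter(session)                 # ideal observer (mu_s, sigma_s)
dyn = tb.run_dynamic(session)                 # quadratic fit (mu_d, sigma_d)
beliefs = BeliefArrays.from_beliefs(stat, dyn, session.analysis_mask)

truth = tb.CombinationParams(M=1.0, k=0.02, b=0.0, model_kind="weighted")
responses = tb.simulate_responses(beliefs, truth, np.random.default_rng(0))

fits = [tb.fit_mle(responses, beliefs, kind)
        for kind in ("weighted", "unweighted", "select")]
for f in fits:
    print(f"{f.model_kind:<10} logL={f.log_lik:8.2f}  M={f.M:.3f}  "
          f"k={f.k:.4f}  b={f.b:+.4f}")
print(tb.compare_models(fits).to_string(index=False))
```

prints

```
analysis trials: 200
noise calibration ratio: 0.67
weighted   logL=  506.54  M=1.001  k=0.0192  b=+0.0003
unweighted logL=  388.02  M=0.394  k=0.0348  b=+0.0041
select     logL=  347.05  M=1.045  k=0.0427  b=-0.0044
   model_a    model_b      loglr   delta_bic
  weighted unweighted 118.518602 -237.037203
  weighted     select 159.490830 -318.981660
unweighted     select  40.972229  -81.944457
```

The calibration ratio confirms that the average per-sample trajectory noise
SD is 0.67 of the average generative endpoint SD, which keeps the two
information sources comparably reliable.  Fitting recovers the generating
parameters (M ≈ 1: optimal weighting; k ≈ 0.02 screen widths of response
noise; b ≈ 0) and the weighted-combination model beats both alternatives by
a wide log-likelihood margin, as it should when responses really do combine
both cues by precision.

The attraction-slope analysis summarizes the same behaviour without model
fitting: regressing the response's displacement toward the statistical mean
on the endpoint's displacement from it, within terciles of trajectory noise
σ_d, yields slopes that rise with noise (here 0.11 → 0.31 → 0.35, tracking
the optimal-observer reference slopes 0.09 → 0.29 → 0.40): the noisier the
trajectory, the more the responses lean on the statistical prior.

A `trajbayes` command-line tool exposes the same pipeline
(`simulate`, `observe`, `dynamic`, `fit`, `recover-models`,
`recover-params`, `equivalence`); see `trajbayes --help`.

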