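# effortddm

Drift-diffusion modelling of effort-based decision making for reward, with
synthetic clinical cohorts, hierarchical Bayesian estimation and the
downstream choice-model and covariate-association analyses. The package is
aimed at computational-psychiatry researchers who study motivational
deficits (apathy, depression) with reward/effort trade-off tasks and want a
tested, reproducible pipeline they can point at their own trial tables — or
use to run parameter-recovery experiments before collecting data.

## The model

On each trial a participant accepts or rejects an offer of reward (1–15
virtual apples) in exchange for squeezing at 10–80% of their own maximum
grip force. The decision is modelled as a Wiener process with noise scale
c = 1 drifting between a reject boundary at 0 and an accept boundary at
*a*, starting at *z·a*, with non-decision time *t*; the drift rate depends
on the offer:

    V = v0 + vr·r − ve·e − vre·r·e

where *r* is reward scaled to (0, 1] and *e* is the squared force fraction
(quadratic effort cost). For an unbiased start the acceptance rate and mean
decision time have closed forms, AR = 1/(1+e^(−2Va/c²)) and
DT = (a/V)·tanh(Va/c²) (with *a* the distance from start to boundary), which
the package verifies against its own first-passage simulator. Trial
likelihoods use the Wiener first-passage density with a 5% uniform outlier
mixture; subjects are pooled hierarchically with adaptive
Metropolis-within-Gibbs MCMC. Downstream, choices are analysed with a
random-intercept logistic model (reward × effort² × apathy), and subject
parameters are related to apathy (AES), depression (BDI), age and cognition
with HC3-robust regressions.

Because the motivating clinical dataset is not public, the package includes
a first-class synthetic-cohort generator that emulates its structure
(82 participants, 180 trials on a 6 × 6 reward-by-effort grid, 25%
force-exempt accepted trials, AES–BDI correlation ≈ 0.38, apathy lowering
baseline drift and depression raising the boundary), so every stage is
verifiable by parameter recovery. See `docs/methods.md` for modelling
details and design choices.

## Worked example

```python
from effortddm.synthetic_cohort import CohortSpec, simulate_cohort
from effortddm.preprocessing import exclude_trials
from effortddm.hierarchical_fit import (FitConfig, fit_hierarchical,
                                        extract_subject_means, rhat,
                                        posterior_probability)

trials, covariates = simulate_cohort(CohortSpec(n_participants=30, seed=501))
flagged, report = exclude_trials(trials)
print(f"excluded {report.fraction_excluded:.1%} of {report.n_total} trials")

cfg = FitConfig(n_chains=3, n_samples=3000, n_burn_in=500, seed=501)
samples = fit_hierarchical(flagged, cfg)
print(rhat(samples).table.head(3).to_string(index=False))

means = extract_subject_means(samples)
print(means.head(3).round(3).to_string(index=False))
```

prints (about six minutes on one CPU):

```
excluded 3.8% of 5400 trials
parameter     rhat    ess_bulk  flagged
     mu_a 1.000827 4893.544328    False
  sigma_a 1.001680 1057.848506    False
     mu_z 1.008802  436.961124    False
participant_id     a     z     t    v0    vr    ve   vre
          p001 1.844 0.505 0.331 0.475 1.871 2.242 0.334
          p002 2.088 0.499 0.314 0.371 1.915 2.571 0.424
          p003 1.791 0.460 0.349 0.267 1.813 2.930 0.454
```

Here `excluded 0.5%` is the fraction of trials removed by the fast (< 0.4 s)
and slow (> mean + 3 SD) rules; each subsequent row gives one subject's
posterior-mean boundary separation, starting bias, non-decision time and
drift weights. `posterior_probability(samples, "vr > ve", scales=...)`
turns group-level hypotheses ("reward influences the drift more than
effort") into posterior probabilities.

The same pipeline is scriptable from the shell:

```bash
effort-ddm pipeline --seed 1 --out-dir runs/demo     # simulate ... report
effort-ddm recover --seed 1 --replicates 20 --out-dir runs/recovery
```

which writes tables, convergence and posterior-predictive reports, figures
(6 × 6 acceptance/RT heat maps, parameter-covariate scatter plots, traces)
and a manifest sufficient to reproduce every output byte-for-byte.

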