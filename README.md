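# msdemog

Bayesian multi-state capture-recapture demography for long-lived,
biennially breeding seabirds.

Long-lived seabirds such as the great albatrosses breed every second year
when successful, spend their first years entirely at sea, and may be alive
but away from the colony in any given season. Estimating their demographic
rates therefore requires a model that separates *survival* from *presence*.
`msdemog` implements a hidden-Markov multi-state model for per-individual
encounter histories from a fully banded colony with near-perfect detection
of birds that attend. It is aimed at population ecologists working with
long-term banding studies who want stage-specific survival, recruitment
schedules, and population size from a single joint model.

## The model

Each bird occupies one latent state per breeding season: juvenile at sea
(J), pre-breeder attending the colony (PB), breeder (B, with the current
attempt's outcome recorded as data), non-breeder (NB, distinguishing the
season right after a success), or dead (D). Annual transitions compose
stage survival φ with movement:

- P(PB_t | J_{t−1}) = R_a φ_J, with R_a the probability of first return at
  age *a* (zero below 3, free for ages 3–7, one shared value for ≥ 8);
- P(B_t | PB_{t−1}) = B_a φ_PB, with B_a the probability of first breeding
  at age *a* (zero below 6, free for 6–10, shared for ≥ 11);
- adults breed again with probabilities conditioned on last season's
  outcome, all scaled by φ_A; every live state dies with 1 − φ; D is
  absorbing.

Adult survival may senesce on the logit scale,
logit(φ_a) = logit(φ_6) + α_A (a−6) + β_A (a−6)², may differ by sex
(logit offset β_M), and may vary between years either freely or as random
effects ε_t ~ N(0, τ⁻¹). Ten model variants combine these effects per life
stage. Detection at the colony is perfect, so observation reduces to
attendance: breeders are always present, juveniles and dead birds never,
pre-breeders and non-breeders attend with probabilities γ_PB,
γ_NB|success, γ_NB|fail.

The likelihood of an encounter history is the exact marginal probability of
the observation sequence, summing over all latent paths with the forward
algorithm (dead recoveries pin the path to D). The posterior is sampled
with an adaptive Metropolis sampler launched from a Laplace approximation;
models are compared by DIC = mean deviance + half its variance. Derived
quantities — expected ages at first return and first breeding
E(α) = Σ i π⁽ⁱ⁾ / Σ π⁽ⁱ⁾, age-weighted overall adult survival, lifespan
quantiles — come from deterministic cohort projection, and the total
population size is reconstructed by forward–backward sampling of each
bird's latent states.

A full individual-based simulator generates synthetic colonies with the
exact generative structure the model assumes, plus ground-truth logs for
recovery testing.

## Worked example

```python
from msdemog import (make_fixture, fit_model, compare_models,
                     propagate_cohort, expected_age_first_event)
from msdemog.inference_engine import PRESETS

data, truth = make_fixture("senescent", seed=601)   # 300-bird colony
runs = [fit_model(data, model_id, PRESETS["test"].with_seed(model_id))
        for model_id in (0, 1)]                     # constant vs senescent
print(compare_models(runs)[["model_id", "dic", "delta_dic"]])

best = runs[1]
traj = propagate_cohort(best.posterior_mean_params(), max_age=110, spec=best.spec)
print(f"age at first return:   {expected_age_first_event(traj, 'return'):.1f}")
print(f"age at first breeding: {expected_age_first_event(traj, 'breed'):.1f}")
```

prints

```
   model_id          dic  delta_dic
0         1  2962.602032   0.000000
1         0  2993.288176  30.686145
age at first return:   5.2
age at first breeding: 9.0
```

The senescence model is preferred by ~31 DIC units (the colony was
simulated with senescent adult survival), and the fitted recruitment
schedule puts mean first return at about five years and mean first
breeding at about nine.

The same pipeline runs from the shell:

```bash
msdemog simulate --preset paper_like --seed 1 -o colony/
msdemog fit --model 1 --data colony/encounters.csv --preset test -o fits/
msdemog run config.yaml -o out/ && msdemog report out/
```

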