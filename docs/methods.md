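# Methods

## Model

`msdemog` estimates stage-specific annual survival of a fully banded,
intensively monitored seabird colony from per-season encounter histories,
jointly with recruitment schedules, breeding-cycle transition
probabilities, colony-attendance probabilities, and derived demographic
quantities. The season is the observation unit: a season labelled *Y*
runs from November of year *Y* to October of *Y*+1, with the census at
the start, so a chick fledging in season *Y* first counts as a population
member in season *Y*+1.

### Latent states

The classical multi-state formulation for this life history uses five
states (juvenile, pre-breeder, breeder, non-breeder, dead) with breeding
outcome carried as a covariate. We expand to seven states — splitting
breeders into B_SUCCESS/B_FAIL by the current attempt's outcome and
non-breeders into NB_POST_SUCCESS (the season immediately after a
success) and NB_OTHER — so that outcome-conditioned transitions and
attendance become first-order Markov. The two formulations are
equivalent because breeders always attend and are always detected, so
the outcome is observed whenever it is needed.

Breeding success is *not* modelled (colony management manipulates it);
the observed outcome is a covariate. In the likelihood, mass entering
the breeding state is routed entirely to the outcome recorded in that
season's observation; when the observation is not a breeder code, latent
breeder states receive emission probability zero, so the routing is
immaterial (it is filled with the simulator's success probability to
keep rows summing to one). In simulation and cohort projection the
outcome is drawn from `outcome_success_prob`.

### Transitions, ages, recruitment

A transition step is indexed by the age the bird *attains* at the
destination season (age = season − fledge season) and by the starting
season of the interval (for year effects). First return R(a) is zero
below age 3, free at ages 3–7, and one shared plateau value for ≥ 8;
first breeding B(a) is zero below 6, free at 6–10, shared for ≥ 11. The
plateaus capture the long observed tails of both distributions with a
single parameter each.

### Survival effects

All survival effects compose additively on the logit scale:

- stage intercepts φ_J, φ_PB, and the age-six adult survival φ_6;
- senescence: α_A (a−6) + β_A (a−6)² for adults aged ≥ 6 (younger adults
  keep φ_6); α_A is constrained non-positive;
- sex: a male offset β_M on adult survival;
- year: either free per-season survival (wider uniform support) or
  random per-season logit offsets ε_t with stage-specific precision τ.

Logit-scale sums are clipped to ±20 before the inverse logit so extreme
quadratic terms cannot overflow; at the parameter magnitudes the priors
support, the clip is inactive in practice.

Ten model variants assign subsets of these effects per stage, from the
base model (all constant) through combinations of senescence, sex, free
year effects and random year effects.

### Observation layer

Detection of birds present at the colony is assumed perfect, so emission
reduces to attendance: P(seen as own status | state) equals the state's
attendance probability (γ_PB; γ_NB|success for the season after a
success; γ_NB|fail otherwise; 1 for breeders) and P(not seen) is the
complement (1 for juveniles and the dead). A dead recovery is a hard
constraint fixing the latent state to dead in the recovery season, not
an emission. Adults never seen in a season are thereby inferred to be
non-breeders or dead — never unobserved breeders.

### Likelihood

The likelihood of one history is the exact marginal probability of its
observation sequence given its entry state (a chick enters as a juvenile
in its fledge season; a bird already alive when the study window opens
enters in the observed state of its first resighting), computed by the
forward algorithm over the seven-state space with per-step
renormalization. Trailing not-seen seasons up to the end of the study
are data. Unknown-sex birds are marginalized with equal prior odds
inside the likelihood when the model has a sex effect, which keeps the
posterior density a deterministic function of the parameters. The
dataset log-likelihood is the sum over birds; a vectorized evaluator
(one 7-vector per bird, stepped season by season) is the hot path and is
tested to agree with the scalar reference and with brute-force path
enumeration to 1e-9.

The original formulation of such models augments the latent states and
samples them by Gibbs steps; marginalizing instead changes nothing about
the posterior of the shared parameters and makes the likelihood an
exactly testable contract. One consequence: our deviance is the
observed-data (marginal) deviance, so absolute deviance and DIC values
are not comparable to a latent-state-conditioned sampler's output on the
same data — only DIC arithmetic and within-implementation model ordering
are.

## Priors

Uniform(0, 1) for juvenile and pre-breeder survival, all recruitment,
breeding and attendance probabilities; uniform(0.7, 1) for the adult
intercept (adult survival is known to be high in this guild); under free
year effects the adult annual survivals get uniform(0.3, 1) so single
bad years can be accommodated. β_M ~ N(0, 100); α_A half-normal(sd 0.1)
on the non-positive half-line (the decline orientation is the scientific
hypothesis; the magnitude is weakly informative); β_A ~ N(0, 0.01);
ε_t ~ N(0, τ⁻¹) with τ ~ Gamma(0.001, 0.001) independently per stage
(the weakest assumption absent information about shared year effects
across stages).

## Sampling

The sampler is adaptive random-walk Metropolis on a transformed space:
interval-supported parameters through a scaled logit, precisions through
log, α_A on its natural scale with the boundary enforced by the prior
(a log transform creates a pathological flat direction as α→0).
Each fit first computes a Laplace approximation — bounded L-BFGS to the
posterior mode (precision parameters capped so hierarchical modes cannot
run away) and a finite-difference Hessian — that supplies the starting
points and the initial proposal covariance. Burn-in then adapts a
Haario-style proposal (running covariance, Robbins–Monro scale tuning
toward 23% acceptance) and everything is frozen afterwards, so retained
draws target the exact posterior. Two protocol presets are shipped: the
full protocol (2 chains, 50 000 burn-in, 250 000 iterations thinned by
100) and a reduced `test` preset (2 chains, 2 000 burn-in, 5 000
iterations thinned by 5) used throughout the test suite and the
acceptance script; at the ~300-bird, 20-season problem sizes used there
it recovers all survival parameters and passes split-R̂ < 1.1 on the
well-identified parameters, with weakly identified recruitment plateaus
occasionally marginal. Convergence is summarized by split R̂ and an
autocorrelation-based effective sample size per scalar parameter;
failures are flagged, never silent. Per-draw marginal deviance is
recorded for model comparison.

## Model comparison

DIC = mean posterior deviance + half its variance, with the n−1 variance
estimator. Models more than 3 DIC units above the best are annotated as
weakly supported. The DIC arithmetic is verified against a published
ten-model comparison table to ±0.01 (two table rows differ from exact
arithmetic by one unit in the last printed decimal, consistent with
round-half-up at two decimals).

## Derived quantities

Deterministic cohort projection propagates a fledgling cohort through
the mean transition kernel (year effects dropped, outcomes split by the
expected success rate), recording first-passage masses into the
pre-breeder and breeder states. Expected ages at first return and first
breeding are the first moment over the mass of those first-passage
sequences — i.e. the mean age among birds that ever experience the
event, which is what the individual-based oracle measures empirically.
Sums are truncated at age 90 by default (residual live mass below 1e-6
for senescent parameterizations; a warning is raised otherwise) and
results are invariant to the truncation point beyond that. Overall adult
survival averages φ_a over ages weighted by the probability of being
alive and adult at each age. Lifespan quantiles come from the cohort
survivorship curve. Uncertainty for any of these is obtained by
repeating the calculation over retained posterior draws.

Population size is reconstructed per posterior draw by forward–backward
sampling of each bird's latent path given its history; live birds are
counted from the season after fledging (chick entrants) or from first
resighting (birds entering as adults), matching the census convention.
Breeding pairs are observed breeders divided by two — outcome data, not
latent. Ratios N/N_BP and N/N_A are computed per season and pooled
across seasons per draw, with seasons lacking breeding pairs excluded
and reported.

## Synthetic data

The simulator draws each bird's latent trajectory from the same
transition kernel, attendance from the same γ's, and emits codes by the
same deterministic seen-identity rules, so it is the exact generative
inverse of the likelihood. It emulates a small managed colony: fledgling
cohorts every season, an optional pool of birds banded (as chicks)
before the window that enter at first resighting — these supply the old
ages that identify senescence, as in the real study design — rare dead
recoveries (3% of deaths), and ~10% unknown-sex birds. Chick production
can be exogenous (fixed cohort sizes, the default, for controlled
recovery tests) or linked one-chick-per-successful-nest. Named presets:
`tiny` (16 birds, 8 seasons, smoke tests), `paper_like` (23 seasons,
~350 birds, the reported point estimates as truth, recruitment schedules
chosen so the cohort's expected ages at first return/breeding are ~4.8
and ~8.9 years, breeding success probability 0.74 as under management),
`senescent` (α_A = −0.05 truth) and `sexed` (β_M = 0.5 truth).

What the simulator does *not* emulate: pair formation (birds are
independent, so "pairs" are breeder counts halved), environmental
covariates driving shared year effects, immigration, emigration
(apparent survival equals true survival in simulation), and management
interventions. Passing recovery tests therefore demonstrates the
estimator is correct under the model's own assumptions, not that those
assumptions hold for any particular field dataset.

## Problem sizes and numerical choices

The test suite and acceptance script use reduced problem sizes chosen to
exercise every stage meaningfully: recovery experiments use 300-bird,
20-season colonies with 3 replicates; the senescence model-selection
experiment uses ten 300-bird replicates at a single-chain reduced
protocol; the cohort-projection oracle uses 100 000 simulated individual
fates; population reconstruction uses 150 posterior draws. Transition
rows are validated to sum to 1 within 1e-12; cohort occupancy is
conserved to the same tolerance; the forward algorithm renormalizes per
step and flags non-finite likelihoods with the offending bird. Ties in
the backward sampling of latent paths cannot occur (probabilities are
continuous); degenerate all-zero filtering distributions indicate an
impossible history and surface as −inf log-likelihood upstream.

## Known limitations

- Free-year-effect models (one survival per season per stage) are the
  hardest to sample at reduced scale; their deviance variance — and
  hence DIC — is noisy, exactly as in the published comparison where
  that model ranks last by a wide margin.
- The adaptive Metropolis sampler is serial; very high-dimensional
  random-effect models would benefit from a gradient-based sampler,
  which the pluggable design admits but does not ship.
- P(breed | non-breeder) is shared between the two non-breeder states,
  and breeding-cycle probabilities are constant over time, age and sex.
- Unknown-age birds are excluded from analysis (they lack the age index
  the recruitment and senescence structures require); the reader flags
  them rather than dropping them silently.
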