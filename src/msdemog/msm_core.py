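"""Multi-state hidden-process model for biennially breeding seabirds.

The latent annual state of a bird is one of seven values: juvenile at sea
(``J``), pre-breeder attending the colony (``PB``), breeder whose current
attempt succeeded (``B_SUCCESS``) or failed (``B_FAIL``), non-breeder in
the season immediately after a successful attempt (``NB_POST_SUCCESS``),
any other non-breeder (``NB_OTHER``), and dead (``D``).  The classical
five-state formulation (J, PB, B, NB, D) conditions breeding-state
transitions and colony attendance on the outcome of the previous attempt;
splitting B and NB by outcome makes the chain first-order Markov, which
is exactly equivalent because breeders are always observed.

Transitions compose stage survival with conditional movement:

* ``J -> PB`` with ``R(a) * phi_J`` and ``J -> J`` with the complement,
  where ``R(a)`` is the probability of first return at age ``a`` (zero
  below age 3, free for ages 3-7, one shared plateau value for >= 8);
* ``PB -> B`` with ``B(a) * phi_PB`` (first breeding; zero below age 6,
  free for 6-10, plateau >= 11);
* adults move between breeding and non-breeding with probabilities
  conditioned on the previous attempt's outcome, all scaled by ``phi_A``;
* every live state moves to ``D`` with one minus its stage survival and
  ``D`` is absorbing.

Adult survival may senesce: on the logit scale it is a quadratic in years
since age six (the minimum age at first breeding), anchored at ``phi6``.
Sex enters as a logit offset ``beta_M`` for males and year enters either
as a free annual survival or as a random logit offset ``eps_t``.

Detection at the colony is perfect, so the emission layer is attendance:
juveniles and dead birds are never at the colony, breeders always are,
and pre-breeders / non-breeders attend with probabilities ``gamma_PB``,
``gamma_NB_success`` (season after a success) and ``gamma_NB_fail``.
The marginal likelihood of an encounter history sums over all latent
paths with the forward algorithm.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np
from scipy.special import expit, logit

from .encounter_data import (
    CHICK_ENTRY,
    IndividualHistory,
    ObservationCode,
    StudyDataset,
)

__all__ = [
    "LatentState",
    "ParameterSet",
    "ModelSpec",
    "MODEL_TABLE",
    "TransitionRow",
    "ConfigurationError",
    "survival_at",
    "transition_row",
    "transition_matrix",
    "presence_probability",
    "emission_probability",
    "forward_log_likelihood",
    "dataset_log_likelihood",
    "LikelihoodEvaluator",
    "LOGIT_CLIP",
]

#: logit-scale overflow guard: quantities are clipped to +-20 before the
#: inverse-logit so that extreme senescence terms cannot overflow
LOGIT_CLIP = 20.0

MIN_AGE_FIRST_RETURN = 3
AGE_RETURN_PLATEAU = 8
MIN_AGE_FIRST_BREEDING = 6
AGE_BREED_PLATEAU = 11


class ConfigurationError(ValueError):
    """A stage/effect combination not defined by the model family."""


class LatentState(IntEnum):
    J = 0
    PB = 1
    B_SUCCESS = 2
    B_FAIL = 3
    NB_POST_SUCCESS = 4
    NB_OTHER = 5
    D = 6


N_STATES = len(LatentState)

LIVE_STATES = (
    LatentState.J,
    LatentState.PB,
    LatentState.B_SUCCESS,
    LatentState.B_FAIL,
    LatentState.NB_POST_SUCCESS,
    LatentState.NB_OTHER,
)
ADULT_STATES = (
    LatentState.B_SUCCESS,
    LatentState.B_FAIL,
    LatentState.NB_POST_SUCCESS,
    LatentState.NB_OTHER,
)


# ---------------------------------------------------------------------------
# model family (which effects act on which stage's survival)
# ---------------------------------------------------------------------------

VALID_EFFECTS = frozenset({"constant", "sex", "age", "year", "year_re"})


@dataclass(frozen=True)
class ModelSpec:
    """One row of the ten-model family.

    Each life-history stage's survival carries a subset of effects:
    ``sex`` (adult male logit offset), ``age`` (quadratic senescence),
    ``year`` (free independent annual survival) or ``year_re`` (random
    annual logit offsets); the empty set means constant survival.
    """

    model_id: int
    juvenile_effects: frozenset = frozenset()
    prebreeder_effects: frozenset = frozenset()
    adult_effects: frozenset = frozenset()

    def __post_init__(self) -> None:
        for effs in (
            self.juvenile_effects,
            self.prebreeder_effects,
            self.adult_effects,
        ):
            if not effs <= VALID_EFFECTS:
                raise ConfigurationError(f"unknown effects {set(effs) - VALID_EFFECTS}")
            if {"year", "year_re"} <= effs:
                raise ConfigurationError("'year' and 'year_re' are exclusive")

    def effects(self, stage: str) -> frozenset:
        try:
            return {
                "J": self.juvenile_effects,
                "PB": self.prebreeder_effects,
                "A": self.adult_effects,
            }[stage]
        except KeyError:
            raise ConfigurationError(f"unknown stage {stage!r}") from None

    @classmethod
    def from_id(cls, model_id: int) -> "ModelSpec":
        try:
            return MODEL_TABLE[model_id]
        except KeyError:
            raise ConfigurationError(
                f"model_id must be 0..9, got {model_id}"
            ) from None


def _ms(model_id, juv, pb, adult):
    return ModelSpec(model_id, frozenset(juv), frozenset(pb), frozenset(adult))


MODEL_TABLE: dict[int, ModelSpec] = {
    0: _ms(0, (), (), ()),
    1: _ms(1, (), (), ("age",)),
    2: _ms(2, (), (), ("sex", "age")),
    3: _ms(3, (), (), ("age", "year_re")),
    4: _ms(4, (), (), ("sex", "age", "year_re")),
    5: _ms(5, ("year_re",), ("year_re",), ("age", "year_re")),
    6: _ms(6, ("year_re",), ("year_re",), ("sex", "age", "year_re")),
    7: _ms(7, ("year",), ("year",), ("age", "year")),
    8: _ms(8, ("year_re",), ("year_re",), ("year_re",)),
    9: _ms(9, (), (), ("year_re",)),
}


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name}={value} outside [0, 1]")


@dataclass
class ParameterSet:
    """All model parameters.

    ``r_first_return`` holds the six free values of R(a) for ages 3..7
    plus the shared plateau for ages >= 8; ``b_first_breed`` the values
    of B(a) for ages 6..10 plus the plateau for >= 11.  ``year_effects``
    maps a stage ('J', 'PB', 'A') to per-season logit offsets (the
    random-year formulation) and ``year_survival`` maps a stage to free
    per-season survival probabilities (the independent-year formulation);
    a season key is the label of the interval's starting season.
    ``outcome_success_prob`` is used only when generating data or
    propagating cohorts: breeding success is a covariate, not a fitted
    parameter.
    """

    phi_J: float = 0.93
    phi_PB: float = 0.96
    phi6: float = 0.97
    alpha_A: float = 0.0
    beta_A: float = 0.0
    beta_M: float = 0.0
    r_first_return: tuple = (0.25, 0.35, 0.40, 0.40, 0.40, 0.40)
    b_first_breed: tuple = (0.20, 0.30, 0.35, 0.35, 0.35, 0.35)
    p_breed_given_nonbreeder: float = 0.79
    p_breed_again_given_success: float = 0.006
    p_breed_again_given_fail: float = 0.83
    gamma_PB: float = 0.99
    gamma_NB_success: float = 0.16
    gamma_NB_fail: float = 0.95
    year_effects: dict = field(default_factory=dict)
    tau: dict = field(default_factory=dict)
    year_survival: dict = field(default_factory=dict)
    outcome_success_prob: float = 0.74

    def validate(self) -> None:
        for name in (
            "phi_J",
            "phi_PB",
            "phi6",
            "p_breed_given_nonbreeder",
            "p_breed_again_given_success",
            "p_breed_again_given_fail",
            "gamma_PB",
            "gamma_NB_success",
            "gamma_NB_fail",
            "outcome_success_prob",
        ):
            _check_prob(name, getattr(self, name))
        if len(self.r_first_return) != 6 or len(self.b_first_breed) != 6:
            raise ValueError("r_first_return and b_first_breed need 6 values each")
        for i, v in enumerate(self.r_first_return):
            _check_prob(f"r_first_return[{i}]", v)
        for i, v in enumerate(self.b_first_breed):
            _check_prob(f"b_first_breed[{i}]", v)
        if self.alpha_A > 0:
            raise ValueError("alpha_A must be <= 0 (survival declines with age)")
        for stage, tab in self.year_survival.items():
            for season, v in tab.items():
                _check_prob(f"year_survival[{stage}][{season}]", v)

    def R_at(self, age: int) -> float:
        """Probability of first return at age ``age`` (Eq. 14 structure)."""
        if age < MIN_AGE_FIRST_RETURN:
            return 0.0
        if age >= AGE_RETURN_PLATEAU:
            return float(self.r_first_return[-1])
        return float(self.r_first_return[age - MIN_AGE_FIRST_RETURN])

    def B_at(self, age: int) -> float:
        """Probability of first breeding at age ``age`` (Eq. 15 structure)."""
        if age < MIN_AGE_FIRST_BREEDING:
            return 0.0
        if age >= AGE_BREED_PLATEAU:
            return float(self.b_first_breed[-1])
        return float(self.b_first_breed[age - MIN_AGE_FIRST_BREEDING])

    # -- serialization (flat JSON; fixtures and manifests) ------------------

    def to_json(self) -> str:
        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ParameterSet":
        d = json.loads(text)
        for key in ("r_first_return", "b_first_breed"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("year_effects", "year_survival"):
            if key in d:
                d[key] = {
                    stage: {int(s): float(v) for s, v in tab.items()}
                    for stage, tab in d[key].items()
                }
        return cls(**d)

    def replace(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def _clip_logit(x: float) -> float:
    return float(np.clip(x, -LOGIT_CLIP, LOGIT_CLIP))


def survival_at(
    stage: str,
    age: int,
    season: int | None,
    sex: str | None,
    params: ParameterSet,
    spec: ModelSpec = MODEL_TABLE[0],
) -> float:
    """Annual survival for a bird of ``stage`` ('J', 'PB' or 'A').

    All effects compose additively on the logit scale: the stage
    intercept, the adult male offset ``beta_M`` when the sex effect is
    active, the senescence terms ``alpha_A*(a-6) + beta_A*(a-6)**2`` for
    adults aged six or more when the age effect is active (younger adults
    keep the age-six survival), and the annual offset ``eps_t`` under
    random year effects.  Under free year effects the per-season survival
    replaces the intercept.  ``season`` is the label of the interval's
    starting season; ``None`` (projections) drops year terms.
    """
    effects = spec.effects(stage)
    if "sex" in effects and stage != "A":
        raise ConfigurationError("sex effect is defined for adults only")
    if "age" in effects and stage != "A":
        raise ConfigurationError("age effect is defined for adults only")
    if age < 0:
        raise ValueError(f"negative age {age}")

    if "year" in effects:
        if season is None:
            raise ConfigurationError("free year effects need a season label")
        try:
            intercept = params.year_survival[stage][season]
        except KeyError:
            raise ConfigurationError(
                f"no year_survival entry for stage {stage}, season {season}"
            ) from None
    else:
        intercept = {"J": params.phi_J, "PB": params.phi_PB, "A": params.phi6}[stage]

    offset = 0.0
    if stage == "A":
        if "sex" in effects and sex == "M":
            offset += params.beta_M
        if "age" in effects and age >= MIN_AGE_FIRST_BREEDING:
            d = age - MIN_AGE_FIRST_BREEDING
            offset += params.alpha_A * d + params.beta_A * d * d
    if "year_re" in effects and season is not None:
        offset += params.year_effects.get(stage, {}).get(season, 0.0)
    if offset == 0.0:
        # no logit-scale modification: return the intercept exactly (the
        # logit round trip would perturb boundary values like 1.0)
        return float(intercept)
    return float(expit(_clip_logit(logit(intercept) + offset)))


# ---------------------------------------------------------------------------
# transitions
# ---------------------------------------------------------------------------


@dataclass
class TransitionRow:
    source: LatentState
    probs: dict
    age: int
    season: int | None = None
    outcome: str | None = None

    def as_array(self) -> np.ndarray:
        out = np.zeros(N_STATES)
        for state, p in self.probs.items():
            out[state] = p
        return out


def _split_b_entry(mass: float, outcome: str | None, params: ParameterSet):
    """Distribute probability of entering the breeding state over outcomes.

    When the current attempt's outcome is known (likelihood use: outcome
    is a covariate carried by the observation) the full mass goes to the
    matching state; otherwise it is split by ``outcome_success_prob``
    (simulation / cohort-propagation use).
    """
    if outcome == "success":
        return mass, 0.0
    if outcome == "fail":
        return 0.0, mass
    if outcome is None:
        p = params.outcome_success_prob
        return mass * p, mass * (1.0 - p)
    raise ValueError(f"outcome must be 'success', 'fail' or None, got {outcome!r}")


def transition_row(
    source: LatentState,
    age: int,
    season: int | None = None,
    sex: str | None = None,
    params: ParameterSet = None,
    spec: ModelSpec = MODEL_TABLE[0],
    outcome: str | None = None,
) -> TransitionRow:
    """One row of the annual transition kernel.

    ``age`` is the age the bird attains at the destination season (the
    bird moves from age-1 to age over the interval); ``season`` labels
    the interval's starting season.  ``outcome`` resolves how mass
    entering the breeding state is split between success and failure.
    Ages beyond the recruitment plateaus use the plateau values; a
    negative age is an error.
    """
    if params is None:
        raise ValueError("params is required")
    if age < 0:
        raise ValueError(f"negative age {age}")
    S = LatentState
    probs: dict[LatentState, float] = {}
    if source == S.D:
        probs[S.D] = 1.0
    elif source == S.J:
        sJ = survival_at("J", age, season, sex, params, spec)
        r = params.R_at(age)
        probs[S.PB] = r * sJ
        probs[S.J] = (1.0 - r) * sJ
        probs[S.D] = 1.0 - sJ
    elif source == S.PB:
        sPB = survival_at("PB", age, season, sex, params, spec)
        b = params.B_at(age)
        bs, bf = _split_b_entry(b * sPB, outcome, params)
        probs[S.B_SUCCESS] = bs
        probs[S.B_FAIL] = bf
        probs[S.PB] = (1.0 - b) * sPB
        probs[S.D] = 1.0 - sPB
    else:
        sA = survival_at("A", age, season, sex, params, spec)
        if source == S.B_SUCCESS:
            p_again = params.p_breed_again_given_success
            stay_nb = S.NB_POST_SUCCESS
        elif source == S.B_FAIL:
            p_again = params.p_breed_again_given_fail
            stay_nb = S.NB_OTHER
        else:  # NB_POST_SUCCESS or NB_OTHER
            p_again = params.p_breed_given_nonbreeder
            stay_nb = S.NB_OTHER
        bs, bf = _split_b_entry(p_again * sA, outcome, params)
        probs[S.B_SUCCESS] = bs
        probs[S.B_FAIL] = bf
        probs[stay_nb] = probs.get(stay_nb, 0.0) + (1.0 - p_again) * sA
        probs[S.D] = 1.0 - sA
    probs = {s: p for s, p in probs.items()}
    return TransitionRow(source, probs, age, season, outcome)


def transition_matrix(
    age: int,
    season: int | None = None,
    sex: str | None = None,
    params: ParameterSet = None,
    spec: ModelSpec = MODEL_TABLE[0],
    outcome: str | None = None,
) -> np.ndarray:
    """Full 7x7 kernel: row ``i`` is ``transition_row`` from state ``i``."""
    out = np.zeros((N_STATES, N_STATES))
    for source in LatentState:
        out[source] = transition_row(
            source, age, season, sex, params, spec, outcome
        ).as_array()
    return out


# ---------------------------------------------------------------------------
# presence and emission
# ---------------------------------------------------------------------------


def presence_probability(state: LatentState, params: ParameterSet) -> float:
    """Probability of being at the colony given the latent state."""
    S = LatentState
    return {
        S.J: 0.0,
        S.PB: params.gamma_PB,
        S.B_SUCCESS: 1.0,
        S.B_FAIL: 1.0,
        S.NB_POST_SUCCESS: params.gamma_NB_success,
        S.NB_OTHER: params.gamma_NB_fail,
        S.D: 0.0,
    }[state]


#: seen-identity of each latent state (None = never seen)
_SEEN_CODE = {
    LatentState.J: None,
    LatentState.PB: ObservationCode.SEEN_PREBREEDER,
    LatentState.B_SUCCESS: ObservationCode.SEEN_BREEDER_SUCCESS,
    LatentState.B_FAIL: ObservationCode.SEEN_BREEDER_FAIL,
    LatentState.NB_POST_SUCCESS: ObservationCode.SEEN_NONBREEDER,
    LatentState.NB_OTHER: ObservationCode.SEEN_NONBREEDER,
    LatentState.D: None,
}


def emission_probability(
    state: LatentState, obs: ObservationCode, params: ParameterSet
) -> float:
    """P(observation code | latent state), with perfect detection at the colony.

    A state's seen-identity code has probability equal to its attendance
    probability; ``NOT_SEEN`` has the complement; any mismatched seen
    code has probability 0.  ``RECOVERED_DEAD`` is a hard state
    constraint handled by the likelihood, not an emission, and is not
    part of the emission alphabet.
    """
    if obs is ObservationCode.RECOVERED_DEAD:
        raise ValueError("RECOVERED_DEAD is a state constraint, not an emission")
    gamma = presence_probability(state, params)
    if obs is ObservationCode.NOT_SEEN:
        return 1.0 - gamma
    return gamma if _SEEN_CODE[state] is obs else 0.0


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

_ENTRY_STATE = {
    CHICK_ENTRY: LatentState.J,
    "PB": LatentState.PB,
    "BS": LatentState.B_SUCCESS,
    "BF": LatentState.B_FAIL,
    "NB": LatentState.NB_OTHER,
}

_OUTCOME_OF_OBS = {
    ObservationCode.SEEN_BREEDER_SUCCESS: "success",
    ObservationCode.SEEN_BREEDER_FAIL: "fail",
}


def _forward_one_sex(
    history: IndividualHistory,
    params: ParameterSet,
    spec: ModelSpec,
    last_season: int,
    sex: str,
) -> float:
    """Reference (scalar) forward recursion for a single sex assignment."""
    entry = history.entry_season
    alpha = np.zeros(N_STATES)
    alpha[_ENTRY_STATE[history.entry_state]] = 1.0
    loglik = 0.0
    for season in range(entry + 1, last_season + 1):
        age = history.age_at(season)
        obs = history.observations.get(season, ObservationCode.NOT_SEEN)
        outcome = _OUTCOME_OF_OBS.get(obs)
        T = transition_matrix(age, season - 1, sex, params, spec, outcome)
        pred = alpha @ T
        if obs is ObservationCode.RECOVERED_DEAD:
            new = np.zeros(N_STATES)
            new[LatentState.D] = pred[LatentState.D]
        else:
            e = np.array(
                [
                    emission_probability(s, obs, params)
                    for s in LatentState
                ]
            )
            new = pred * e
        norm = new.sum()
        if norm <= 0.0:
            return -np.inf
        loglik += math.log(norm)
        alpha = new / norm
    return loglik


def forward_log_likelihood(
    history: IndividualHistory,
    params: ParameterSet,
    spec: ModelSpec = MODEL_TABLE[0],
    last_season: int | None = None,
) -> float:
    """Exact marginal log-probability of one encounter history.

    Sums over all latent-state paths with the forward recursion,
    conditioning on the entry state (chick: juvenile at age 0 in the
    fledge season; pre-study bird: the observed state at first
    resighting).  Seasons where the bird was recovered dead constrain
    the path to the dead state from then on.  Trailing not-seen seasons
    up to ``last_season`` (default: the last observed season) are data
    and contribute to the likelihood.  Unknown-sex birds are marginalized
    with equal prior odds when the model has a sex effect.
    """
    if not history.known_age:
        raise ValueError(f"{history.band_id}: unknown-age bird in likelihood")
    if last_season is None:
        last_season = max(history.observations, default=history.entry_season)
    if last_season < history.entry_season:
        raise ValueError("observation window before entry")
    needs_sex = "sex" in spec.adult_effects
    if needs_sex and history.sex == "U":
        lm = _forward_one_sex(history, params, spec, last_season, "M")
        lf = _forward_one_sex(history, params, spec, last_season, "F")
        val = float(np.logaddexp(lm, lf) - math.log(2.0))
    else:
        val = _forward_one_sex(history, params, spec, last_season, history.sex)
    if not np.isfinite(val) and val != -np.inf:
        raise ValueError(f"{history.band_id}: non-finite log-likelihood")
    return val


# ---------------------------------------------------------------------------
# vectorized dataset likelihood
# ---------------------------------------------------------------------------

# observation-code indices used by the evaluator
_OBS_IDX = {
    ObservationCode.NOT_SEEN: 0,
    ObservationCode.SEEN_PREBREEDER: 1,
    ObservationCode.SEEN_BREEDER_SUCCESS: 2,
    ObservationCode.SEEN_BREEDER_FAIL: 3,
    ObservationCode.SEEN_NONBREEDER: 4,
    ObservationCode.RECOVERED_DEAD: 5,
}


class LikelihoodEvaluator:
    """Precompiled dataset for repeated likelihood evaluation.

    Flattens a :class:`~msdemog.encounter_data.StudyDataset` into integer
    arrays once, then evaluates the exact marginal log-likelihood of the
    whole dataset for any :class:`ParameterSet` with vectorized forward
    recursions (one 7-vector per bird, stepped season by season).  This
    is the hot path used by the MCMC engine; the scalar
    :func:`forward_log_likelihood` is the readable reference it must
    agree with.
    """

    def __init__(self, data: StudyDataset, spec: ModelSpec = MODEL_TABLE[0]):
        data.validate()
        if data.unknown_age_ids:
            raise ValueError(
                "unknown-age birds must be excluded before analysis: "
                + ", ".join(data.unknown_age_ids)
            )
        self.spec = spec
        self.seasons = sorted(data.seasons)
        self.band_ids = [ind.band_id for ind in data.individuals]
        n = len(data.individuals)
        T = len(self.seasons)
        s0 = self.seasons[0]
        self.n, self.T = n, T
        self.entry_t = np.array(
            [ind.entry_season - s0 for ind in data.individuals], dtype=int
        )
        self.entry_state = np.array(
            [_ENTRY_STATE[ind.entry_state] for ind in data.individuals], dtype=int
        )
        self.fledge = np.array(
            [ind.fledge_season for ind in data.individuals], dtype=int
        )
        self.sex_is_unknown = np.array(
            [ind.sex == "U" for ind in data.individuals], dtype=bool
        )
        self.sex_is_male = np.array(
            [ind.sex == "M" for ind in data.individuals], dtype=bool
        )
        self.obs = np.zeros((n, T), dtype=int)
        for i, ind in enumerate(data.individuals):
            for season, code in ind.observations.items():
                self.obs[i, season - s0] = _OBS_IDX[code]
        # age attained at each season index
        self.ages = np.array(self.seasons)[None, :] - self.fledge[:, None]
        self.max_age = int(self.ages.max()) if n else 0

    # -- per-season parameter tables ----------------------------------------

    def _survival_tables(self, params: ParameterSet, male: np.ndarray):
        """Per (bird, interval) stage survivals; interval t is seasons[t]->t+1."""
        spec = self.spec
        seasons = self.seasons
        Tm1 = self.T - 1
        ages_dest = self.ages[:, 1:]  # age attained at destination season

        def stage_probs(stage, intercept):
            """Per-interval survival on the probability scale; the logit
            round trip is skipped when no offsets apply, matching the
            scalar :func:`survival_at` exactly."""
            effs = spec.effects(stage)
            if "year" in effs:
                tab = params.year_survival.get(stage, {})
                try:
                    probs = np.array([tab[seasons[t]] for t in range(Tm1)])
                except KeyError as exc:
                    raise ConfigurationError(
                        f"missing year_survival for stage {stage}: {exc}"
                    ) from None
            else:
                probs = np.full(Tm1, intercept)
            if "year_re" in effs:
                eps = params.year_effects.get(stage, {})
                eps_arr = np.array([eps.get(seasons[t], 0.0) for t in range(Tm1)])
                shifted = np.clip(
                    logit(probs) + eps_arr, -LOGIT_CLIP, LOGIT_CLIP
                )
                probs = np.where(eps_arr == 0.0, probs, expit(shifted))
            return probs  # (Tm1,)

        sJ = stage_probs("J", params.phi_J)
        sPB = stage_probs("PB", params.phi_PB)
        baseA = stage_probs("A", params.phi6)  # (Tm1,)
        effs = spec.effects("A")
        offset = np.zeros(ages_dest.shape)
        if "age" in effs:
            d = np.maximum(ages_dest - MIN_AGE_FIRST_BREEDING, 0)
            offset = offset + params.alpha_A * d + params.beta_A * d * d
        if "sex" in effs:
            offset = offset + params.beta_M * male[:, None]
        x = np.clip(logit(baseA)[None, :] + offset, -LOGIT_CLIP, LOGIT_CLIP)
        sA = np.where(
            offset == 0.0, np.broadcast_to(baseA, ages_dest.shape), expit(x)
        )  # (n, Tm1)
        return sJ, sPB, sA

    def _recruit_tables(self, params: ParameterSet):
        ages = np.arange(self.max_age + 1)
        R = np.array([params.R_at(a) for a in ages])
        B = np.array([params.B_at(a) for a in ages])
        return R, B

    def _emission_table(self, params: ParameterSet) -> np.ndarray:
        """E[obs_idx, state]; RECOVERED_DEAD row is the hard D constraint."""
        E = np.zeros((6, N_STATES))
        for code, idx in _OBS_IDX.items():
            if code is ObservationCode.RECOVERED_DEAD:
                E[idx, LatentState.D] = 1.0
            else:
                for s in LatentState:
                    E[idx, s] = emission_probability(s, code, params)
        return E

    # -- forward pass --------------------------------------------------------

    def _forward(self, params: ParameterSet, male: np.ndarray, keep_alpha=False):
        n, T = self.n, self.T
        S = LatentState
        sJ, sPB, sA = self._survival_tables(params, male)
        Rtab, Btab = self._recruit_tables(params)
        E = self._emission_table(params)
        p_succ = params.outcome_success_prob
        alpha = np.zeros((n, N_STATES))
        loglik = np.zeros(n)
        entered = self.entry_t == 0
        alpha[entered, self.entry_state[entered]] = 1.0
        alphas = [alpha.copy()] if keep_alpha else None
        for t in range(1, T):
            active = self.entry_t < t
            a = alpha
            age = np.clip(self.ages[:, t], 0, self.max_age)
            R = Rtab[age]
            B = Btab[age]
            vJ, vPB = sJ[t - 1], sPB[t - 1]
            vA = sA[:, t - 1]
            new = np.zeros_like(a)
            new[:, S.J] = a[:, S.J] * (1.0 - R) * vJ
            new[:, S.PB] = a[:, S.PB] * (1.0 - B) * vPB + a[:, S.J] * R * vJ
            b_entry = (
                a[:, S.PB] * B * vPB
                + a[:, S.B_SUCCESS] * params.p_breed_again_given_success * vA
                + a[:, S.B_FAIL] * params.p_breed_again_given_fail * vA
                + (a[:, S.NB_POST_SUCCESS] + a[:, S.NB_OTHER])
                * params.p_breed_given_nonbreeder
                * vA
            )
            obs_t = self.obs[:, t]
            frac_succ = np.where(
                obs_t == _OBS_IDX[ObservationCode.SEEN_BREEDER_SUCCESS],
                1.0,
                np.where(
                    obs_t == _OBS_IDX[ObservationCode.SEEN_BREEDER_FAIL],
                    0.0,
                    p_succ,
                ),
            )
            new[:, S.B_SUCCESS] = b_entry * frac_succ
            new[:, S.B_FAIL] = b_entry * (1.0 - frac_succ)
            new[:, S.NB_POST_SUCCESS] = (
                a[:, S.B_SUCCESS] * (1.0 - params.p_breed_again_given_success) * vA
            )
            new[:, S.NB_OTHER] = a[:, S.B_FAIL] * (
                1.0 - params.p_breed_again_given_fail
            ) * vA + (a[:, S.NB_POST_SUCCESS] + a[:, S.NB_OTHER]) * (
                1.0 - params.p_breed_given_nonbreeder
            ) * vA
            new[:, S.D] = (
                a[:, S.J] * (1.0 - vJ)
                + a[:, S.PB] * (1.0 - vPB)
                + (
                    a[:, S.B_SUCCESS]
                    + a[:, S.B_FAIL]
                    + a[:, S.NB_POST_SUCCESS]
                    + a[:, S.NB_OTHER]
                )
                * (1.0 - vA)
                + a[:, S.D]
            )
            new *= E[obs_t]
            norm = new.sum(axis=1)
            step = active & (norm > 0.0)
            dead_end = active & (norm <= 0.0)
            loglik[step] += np.log(norm[step])
            loglik[dead_end] = -np.inf
            alpha = np.where(
                (active & (norm > 0.0))[:, None], new / np.maximum(norm, 1e-300)[:, None], alpha
            )
            entering = self.entry_t == t
            if entering.any():
                alpha[entering] = 0.0
                alpha[entering, self.entry_state[entering]] = 1.0
            if keep_alpha:
                alphas.append(alpha.copy())
        return (loglik, alphas) if keep_alpha else loglik

    def step_matrices(self, params: ParameterSet, male: np.ndarray) -> list:
        """Per-bird transition matrices for every step, as used by the
        forward pass (outcome split resolved by the destination-season
        observation).  Entry ``t-1`` of the list is the (n, 7, 7) kernel
        from season index ``t-1`` to ``t``.  Used by the forward-backward
        path sampler; must stay consistent with :meth:`_forward`."""
        S = LatentState
        sJ, sPB, sA = self._survival_tables(params, male)
        Rtab, Btab = self._recruit_tables(params)
        p_succ = params.outcome_success_prob
        mats = []
        for t in range(1, self.T):
            age = np.clip(self.ages[:, t], 0, self.max_age)
            R, B = Rtab[age], Btab[age]
            vJ, vPB, vA = sJ[t - 1], sPB[t - 1], sA[:, t - 1]
            obs_t = self.obs[:, t]
            frac = np.where(
                obs_t == _OBS_IDX[ObservationCode.SEEN_BREEDER_SUCCESS],
                1.0,
                np.where(
                    obs_t == _OBS_IDX[ObservationCode.SEEN_BREEDER_FAIL], 0.0, p_succ
                ),
            )
            T = np.zeros((self.n, N_STATES, N_STATES))
            T[:, S.J, S.PB] = R * vJ
            T[:, S.J, S.J] = (1.0 - R) * vJ
            T[:, S.J, S.D] = 1.0 - vJ
            b = B * vPB
            T[:, S.PB, S.B_SUCCESS] = b * frac
            T[:, S.PB, S.B_FAIL] = b * (1.0 - frac)
            T[:, S.PB, S.PB] = (1.0 - B) * vPB
            T[:, S.PB, S.D] = 1.0 - vPB
            for src, p_again, stay in (
                (S.B_SUCCESS, params.p_breed_again_given_success, S.NB_POST_SUCCESS),
                (S.B_FAIL, params.p_breed_again_given_fail, S.NB_OTHER),
                (S.NB_POST_SUCCESS, params.p_breed_given_nonbreeder, S.NB_OTHER),
                (S.NB_OTHER, params.p_breed_given_nonbreeder, S.NB_OTHER),
            ):
                T[:, src, S.B_SUCCESS] = p_again * vA * frac
                T[:, src, S.B_FAIL] = p_again * vA * (1.0 - frac)
                T[:, src, stay] += (1.0 - p_again) * vA
                T[:, src, S.D] = 1.0 - vA
            T[:, S.D, S.D] = 1.0
            mats.append(T)
        return mats

    def per_individual(self, params: ParameterSet) -> np.ndarray:
        """Log-likelihood vector, one entry per bird."""
        needs_sex = "sex" in self.spec.effects("A")
        if needs_sex and self.sex_is_unknown.any():
            as_f = self._forward(params, self.sex_is_male & ~self.sex_is_unknown)
            as_m = self._forward(params, self.sex_is_male | self.sex_is_unknown)
            mixed = np.logaddexp(as_f, as_m) - math.log(2.0)
            return np.where(self.sex_is_unknown, mixed, as_f)
        return self._forward(params, self.sex_is_male)

    def __call__(self, params: ParameterSet) -> float:
        return float(self.per_individual(params).sum())


def dataset_log_likelihood(
    data: StudyDataset,
    params: ParameterSet,
    spec: ModelSpec = MODEL_TABLE[0],
) -> tuple[float, np.ndarray]:
    """Total log-likelihood and the per-individual vector.

    The deviance of the dataset is minus twice the returned total.
    """
    ev = LikelihoodEvaluator(data, spec)
    try:
        vec = ev.per_individual(params)
    except Exception as exc:
        raise type(exc)(f"dataset likelihood failed: {exc}") from exc
    return float(vec.sum()), vec
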