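"""The hidden-process model: transitions, emissions and the forward
likelihood, checked against closed forms and a brute-force path
enumeration oracle."""

import itertools
import math

import numpy as np
import pytest
from scipy.special import expit, logit

from msdemog import (
    MODEL_TABLE,
    IndividualHistory,
    LatentState,
    LikelihoodEvaluator,
    ModelSpec,
    ParameterSet,
    StudyDataset,
    dataset_log_likelihood,
    emission_probability,
    forward_log_likelihood,
    presence_probability,
    survival_at,
    transition_matrix,
    transition_row,
)
from msdemog.encounter_data import ObservationCode as OC
from msdemog.msm_core import (
    _ENTRY_STATE,
    _OUTCOME_OF_OBS,
    ConfigurationError,
    N_STATES,
)

from conftest import random_history, random_parameter_set

S = LatentState


def enumeration_log_likelihood(hist, params, spec, last_season):
    """Independent oracle: explicit sum over every latent-state path.

    Per-season kernels and emission vectors are precomputed once; the
    probability of every one of the 7^L paths is then accumulated by
    plain elementwise gathers, with no forward recursion involved.
    """
    entry = hist.entry_season
    steps = list(range(entry + 1, last_season + 1))
    start = _ENTRY_STATE[hist.entry_state]
    kernels, emissions = [], []
    for season in steps:
        obs = hist.observations.get(season, OC.NOT_SEEN)
        kernels.append(
            transition_matrix(
                hist.age_at(season),
                season - 1,
                hist.sex,
                params,
                spec,
                _OUTCOME_OF_OBS.get(obs),
            )
        )
        if obs is OC.RECOVERED_DEAD:
            e = np.zeros(N_STATES)
            e[int(S.D)] = 1.0  # hard state constraint, no emission factor
        else:
            e = np.array(
                [emission_probability(S(j), obs, params) for j in range(N_STATES)]
            )
        emissions.append(e)
    paths = np.array(
        list(itertools.product(range(N_STATES), repeat=len(steps))), dtype=int
    )
    prob = kernels[0][start, paths[:, 0]] * emissions[0][paths[:, 0]]
    for k in range(1, len(steps)):
        prob = prob * kernels[k][paths[:, k - 1], paths[:, k]]
        prob = prob * emissions[k][paths[:, k]]
    total = float(prob.sum())
    return math.log(total) if total > 0 else -math.inf


class TestSurvival:
    def test_adult_below_six_keeps_age_six_survival(self):
        p = ParameterSet(phi6=0.976, alpha_A=-0.05, beta_A=-0.002)
        assert survival_at("A", 5, None, "F", p, MODEL_TABLE[1]) == pytest.approx(
            0.976
        )

    def test_no_senescence_terms_means_constant_in_age(self):
        p = ParameterSet(phi6=0.95, alpha_A=0.0, beta_A=0.0)
        vals = [survival_at("A", a, None, "F", p, MODEL_TABLE[1]) for a in range(6, 60)]
        assert vals == pytest.approx([0.95] * len(vals))

    def test_senescent_point_evaluation(self):
        # inverse-logit(logit(0.976) - 0.032*34 - 0.001*34^2) at age 40
        p = ParameterSet(phi6=0.976, alpha_A=-0.032, beta_A=-0.001)
        expected = expit(logit(0.976) - 0.032 * 34 - 0.001 * 34**2)
        got = survival_at("A", 40, None, "F", p, MODEL_TABLE[1])
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.812, abs=5e-3)

    def test_sex_offset_applies_to_males_only(self):
        p = ParameterSet(phi6=0.9, beta_M=0.5)
        spec = MODEL_TABLE[2]
        female = survival_at("A", 10, None, "F", p, spec)
        male = survival_at("A", 10, None, "M", p, spec)
        assert male > female
        assert logit(male) - logit(female) == pytest.approx(0.5, abs=1e-9)

    def test_effect_outside_model_family_raises(self):
        p = ParameterSet()
        bad = ModelSpec(0, juvenile_effects=frozenset({"sex"}))
        with pytest.raises(ConfigurationError):
            survival_at("J", 3, None, "M", p, bad)

    def test_extreme_senescence_is_clipped_not_overflowing(self):
        p = ParameterSet(phi6=0.976, alpha_A=-0.1, beta_A=-0.01)
        val = survival_at("A", 80, None, "F", p, MODEL_TABLE[1])
        assert 0.0 < val < 1.0


class TestTransitions:
    def test_dead_is_absorbing(self):
        row = transition_row(S.D, 10, None, "F", ParameterSet())
        assert row.probs == {S.D: 1.0}

    def test_no_return_below_age_three(self):
        p = ParameterSet()
        row = transition_row(S.J, 2, None, "F", p)
        assert row.probs.get(S.PB, 0.0) == 0.0
        assert row.probs[S.J] == pytest.approx(p.phi_J)
        assert row.probs[S.D] == pytest.approx(1 - p.phi_J)

    def test_juvenile_split_arithmetic(self):
        p = ParameterSet(phi_J=0.9, r_first_return=(0.3, 0.5, 0.4, 0.4, 0.4, 0.4))
        row = transition_row(S.J, 4, None, "F", p)
        assert row.probs[S.PB] == pytest.approx(0.45)
        assert row.probs[S.J] == pytest.approx(0.45)
        assert row.probs[S.D] == pytest.approx(0.10)

    def test_no_first_breeding_below_age_six(self):
        p = ParameterSet()
        row = transition_row(S.PB, 5, None, "F", p)
        assert row.probs[S.B_SUCCESS] + row.probs[S.B_FAIL] == 0.0

    def test_observed_outcome_routes_all_entry_mass(self):
        p = ParameterSet()
        row = transition_row(S.PB, 8, None, "F", p, outcome="fail")
        assert row.probs[S.B_SUCCESS] == 0.0
        assert row.probs[S.B_FAIL] == pytest.approx(p.B_at(8) * p.phi_PB)

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError, match="negative age"):
            transition_row(S.J, -1, None, "F", ParameterSet())

    @pytest.mark.parametrize("seed", range(10))
    def test_rows_sum_to_one_over_ages_and_states(self, seed):
        rng = np.random.default_rng(seed)
        params = random_parameter_set(rng)
        for age in range(0, 81, 5):
            T = transition_matrix(age, None, "M", params, MODEL_TABLE[2])
            np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)


class TestPresenceEmission:
    def test_presence_by_state(self):
        p = ParameterSet(gamma_PB=0.991, gamma_NB_success=0.162, gamma_NB_fail=0.954)
        assert presence_probability(S.J, p) == 0.0
        assert presence_probability(S.D, p) == 0.0
        assert presence_probability(S.B_FAIL, p) == 1.0
        assert presence_probability(S.PB, p) == 0.991
        assert presence_probability(S.NB_POST_SUCCESS, p) == 0.162
        assert presence_probability(S.NB_OTHER, p) == 0.954

    def test_emission_examples(self):
        p = ParameterSet(gamma_NB_fail=0.954)
        assert emission_probability(S.J, OC.NOT_SEEN, p) == 1.0
        assert emission_probability(S.B_SUCCESS, OC.NOT_SEEN, p) == 0.0
        assert emission_probability(S.NB_OTHER, OC.SEEN_NONBREEDER, p) == 0.954
        # mismatched seen code is probability zero, not an error
        assert emission_probability(S.PB, OC.SEEN_NONBREEDER, p) == 0.0

    def test_emission_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        params = random_parameter_set(rng)
        alphabet = [
            OC.NOT_SEEN,
            OC.SEEN_PREBREEDER,
            OC.SEEN_BREEDER_SUCCESS,
            OC.SEEN_BREEDER_FAIL,
            OC.SEEN_NONBREEDER,
        ]
        for state in S:
            total = sum(emission_probability(state, o, params) for o in alphabet)
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_dead_recovery_is_not_an_emission(self):
        with pytest.raises(ValueError):
            emission_probability(S.D, OC.RECOVERED_DEAD, ParameterSet())


class TestForwardLikelihood:
    def test_never_seen_again_has_unit_total_probability(self):
        hist = IndividualHistory("R1", "F", 2000, 2000, "chick", {})
        ll = forward_log_likelihood(hist, ParameterSet(), last_season=2001)
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_single_path_step_is_transition_product(self):
        # failed breeder seen breeding again next season: phi_A * p(breed|fail)
        p = ParameterSet()
        hist = IndividualHistory(
            "R1",
            "F",
            1980,
            1990,
            "BF",
            {1990: OC.SEEN_BREEDER_FAIL, 1991: OC.SEEN_BREEDER_SUCCESS},
        )
        ll = forward_log_likelihood(hist, p, last_season=1991)
        expected = math.log(p.phi6 * p.p_breed_again_given_fail)
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_forward_equals_enumeration_on_random_histories(self):
        rng = np.random.default_rng(7)
        spec = MODEL_TABLE[1]
        for _ in range(25):
            params = random_parameter_set(rng)
            hist = random_history(rng, length=4)
            last = 2000 + 4
            a = forward_log_likelihood(hist, params, spec, last_season=last)
            b = enumeration_log_likelihood(hist, params, spec, last)
            if math.isinf(a) or math.isinf(b):
                assert a == b
            else:
                assert a == pytest.approx(b, abs=1e-9)

    def test_fully_observed_history_is_product_of_transitions(self):
        # all attendance probabilities 1: the latent path is determined
        p = ParameterSet(gamma_PB=1.0, gamma_NB_success=1.0, gamma_NB_fail=1.0)
        hist = IndividualHistory(
            "R1",
            "F",
            1984,
            1990,
            "BS",
            {
                1990: OC.SEEN_BREEDER_SUCCESS,
                1991: OC.SEEN_NONBREEDER,
                1992: OC.SEEN_BREEDER_FAIL,
            },
        )
        ll = forward_log_likelihood(hist, p, last_season=1992)
        expected = math.log(
            (1 - p.p_breed_again_given_success) * p.phi6
        ) + math.log(p.p_breed_given_nonbreeder * p.phi6)
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_likelihood_increases_with_adult_survival(self):
        obs = {y: OC.SEEN_BREEDER_FAIL for y in range(1991, 1996)}
        obs[1990] = OC.SEEN_BREEDER_FAIL
        hist = IndividualHistory("R1", "F", 1980, 1990, "BF", obs)
        lls = [
            forward_log_likelihood(
                hist, ParameterSet(phi6=phi), last_season=1995
            )
            for phi in (0.80, 0.90, 0.99)
        ]
        assert lls[0] < lls[1] < lls[2]

    def test_unknown_age_bird_rejected(self):
        hist = IndividualHistory("R1", "F", None, 1990, "NB", {1990: OC.SEEN_NONBREEDER})
        with pytest.raises(ValueError, match="unknown-age"):
            forward_log_likelihood(hist, ParameterSet())


class TestDatasetLikelihood:
    def test_two_identical_birds_double_the_loglik(self):
        obs = {2001: OC.SEEN_PREBREEDER, 2003: OC.SEEN_PREBREEDER}
        birds = [
            IndividualHistory(f"R{i}", "F", 1998, 1998, "chick", dict(obs))
            for i in range(2)
        ]
        seasons = list(range(1998, 2004))
        one, _ = dataset_log_likelihood(
            StudyDataset(birds[:1], seasons), ParameterSet()
        )
        both, vec = dataset_log_likelihood(StudyDataset(birds, seasons), ParameterSet())
        assert both == pytest.approx(2 * one, rel=1e-12)
        assert vec[0] == pytest.approx(vec[1], rel=1e-12)

    def test_empty_dataset_loglik_zero(self):
        total, vec = dataset_log_likelihood(
            StudyDataset([], [2000, 2001]), ParameterSet()
        )
        assert total == 0.0
        assert vec.size == 0

    def test_order_invariance(self, tiny_dataset):
        params = ParameterSet()
        fwd, _ = dataset_log_likelihood(tiny_dataset, params)
        reversed_data = StudyDataset(
            list(reversed(tiny_dataset.individuals)), tiny_dataset.seasons
        )
        rev, _ = dataset_log_likelihood(reversed_data, params)
        assert fwd == pytest.approx(rev, rel=1e-12)

    def test_evaluator_matches_scalar_reference(self, tiny_dataset):
        rng = np.random.default_rng(11)
        for spec_id in (0, 1, 2):
            spec = MODEL_TABLE[spec_id]
            params = random_parameter_set(rng)
            ev = LikelihoodEvaluator(tiny_dataset, spec)
            vec = ev.per_individual(params)
            last = max(tiny_dataset.seasons)
            ref = np.array(
                [
                    forward_log_likelihood(ind, params, spec, last_season=last)
                    for ind in tiny_dataset.individuals
                ]
            )
            np.testing.assert_allclose(vec, ref, atol=1e-10)

    def test_step_matrices_consistent_with_forward(self, tiny_dataset):
        """The path-sampler's per-bird kernels reproduce the forward pass."""
        rng = np.random.default_rng(13)
        params = random_parameter_set(rng)
        ev = LikelihoodEvaluator(tiny_dataset, MODEL_TABLE[0])
        male = ev.sex_is_male
        mats = ev.step_matrices(params, male)
        E = ev._emission_table(params)
        n = ev.n
        alpha = np.zeros((n, N_STATES))
        entered = ev.entry_t == 0
        alpha[entered, ev.entry_state[entered]] = 1.0
        loglik = np.zeros(n)
        for t in range(1, ev.T):
            active = ev.entry_t < t
            new = np.einsum("ni,nij->nj", alpha, mats[t - 1]) * E[ev.obs[:, t]]
            norm = new.sum(axis=1)
            step = active & (norm > 0)
            loglik[step] += np.log(norm[step])
            alpha = np.where(
                step[:, None], new / np.maximum(norm, 1e-300)[:, None], alpha
            )
            entering = ev.entry_t == t
            alpha[entering] = 0.0
            alpha[entering, ev.entry_state[entering]] = 1.0
        np.testing.assert_allclose(loglik, ev.per_individual(params), atol=1e-10)

    def test_unknown_sex_marginalized_under_sex_model(self):
        obs = {2001: OC.SEEN_PREBREEDER}
        seasons = list(range(1998, 2003))
        mk = lambda sex: StudyDataset(
            [IndividualHistory("R1", sex, 1998, 1998, "chick", dict(obs))], seasons
        )
        params = ParameterSet(beta_M=1.0)
        spec = MODEL_TABLE[2]
        lm, _ = dataset_log_likelihood(mk("M"), params, spec)
        lf, _ = dataset_log_likelihood(mk("F"), params, spec)
        lu, _ = dataset_log_likelihood(mk("U"), params, spec)
        assert lu == pytest.approx(np.logaddexp(lm, lf) - math.log(2), abs=1e-12)


class TestParameterSet:
    def test_recruitment_age_structure(self):
        p = ParameterSet(r_first_return=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6))
        assert p.R_at(2) == 0.0
        assert p.R_at(3) == 0.1
        assert p.R_at(7) == 0.5
        assert p.R_at(8) == 0.6
        assert p.R_at(60) == 0.6
        assert p.B_at(5) == 0.0
        assert p.B_at(11) == p.B_at(50)

    def test_json_round_trip(self):
        p = ParameterSet(year_effects={"A": {1990: 0.1}}, tau={"A": 2.0})
        q = ParameterSet.from_json(p.to_json())
        assert q == p

    def test_validation_catches_bad_probability(self):
        with pytest.raises(ValueError):
            ParameterSet(phi_J=1.2).validate()
        with pytest.raises(ValueError, match="alpha_A"):
            ParameterSet(alpha_A=0.1).validate()
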