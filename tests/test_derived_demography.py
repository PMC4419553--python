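"""Cohort propagation, derived ages, lifespans and population series."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msdemog import (
    MODEL_TABLE,
    CohortTrajectory,
    IndividualHistory,
    McmcConfig,
    ParameterSet,
    StudyDataset,
    expected_age_first_event,
    fit_model,
    lifespan_quantile,
    overall_adult_survival,
    population_ratios,
    population_size_series,
    propagate_cohort,
)
from msdemog.encounter_data import ObservationCode as OC

from conftest import random_parameter_set

CERTAIN = ParameterSet(
    phi_J=1.0,
    phi_PB=1.0,
    phi6=1.0,
    r_first_return=(1.0, 1.0, 1.0, 1.0, 1.0, 1.0),
    b_first_breed=(1.0, 1.0, 1.0, 1.0, 1.0, 1.0),
)


class TestPropagateCohort:
    def test_certain_schedule_concentrates_first_passages(self):
        with np.errstate(divide="ignore"):
            traj = propagate_cohort(CERTAIN, max_age=20)
        assert traj.pi_R[3] == pytest.approx(1.0)
        assert traj.pi_R.sum() == pytest.approx(1.0)
        assert traj.pi_B[6] == pytest.approx(1.0)
        assert expected_age_first_event(traj, "return") == pytest.approx(3.0)
        assert expected_age_first_event(traj, "breed") == pytest.approx(6.0)

    def test_occupancy_mass_conserved(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            traj = propagate_cohort(random_parameter_set(rng), max_age=60)
            np.testing.assert_allclose(traj.occupancy.sum(axis=1), 1.0, atol=1e-12)

    def test_warns_when_live_mass_remains(self):
        with pytest.warns(UserWarning, match="live cohort mass"):
            propagate_cohort(CERTAIN, max_age=30)

    def test_truncation_invariance_once_mass_extinct(self):
        p = ParameterSet()
        t1 = propagate_cohort(p, max_age=90)
        t2 = propagate_cohort(p, max_age=140)
        for event in ("return", "breed"):
            assert expected_age_first_event(t1, event) == pytest.approx(
                expected_age_first_event(t2, event), abs=1e-9
            )

    def test_matches_individual_based_simulation(self):
        """First-passage distributions agree with a Monte-Carlo cohort."""
        from msdemog.msm_core import transition_matrix

        rng = np.random.default_rng(8)
        params = random_parameter_set(rng)
        traj = propagate_cohort(params, max_age=90)
        n = 30_000
        state = np.zeros(n, dtype=int)
        first_ret = np.full(n, -1)
        first_breed = np.full(n, -1)
        for age in range(1, 91):
            cum = transition_matrix(age, None, None, params, outcome=None).cumsum(
                axis=1
            )
            new = (rng.random(n)[:, None] > cum[state]).sum(axis=1)
            ret = (state == 0) & (new == 1) & (first_ret < 0)
            first_ret[ret] = age
            breed = (state == 1) & ((new == 2) | (new == 3)) & (first_breed < 0)
            first_breed[breed] = age
            state = new
        for event, hits in (("return", first_ret), ("breed", first_breed)):
            ages = hits[hits > 0]
            mc_mean = ages.mean()
            mc_se = ages.std(ddof=1) / math.sqrt(ages.size)
            assert expected_age_first_event(traj, event) == pytest.approx(
                mc_mean, abs=3 * mc_se
            )


class TestExpectedAge:
    @staticmethod
    def _traj_with(pi_R=None, pi_B=None, max_age=10):
        occ = np.zeros((max_age + 1, 7))
        occ[:, 6] = 1.0
        z = np.zeros(max_age + 1)
        pr, pb = z.copy(), z.copy()
        for a, v in (pi_R or {}).items():
            pr[a] = v
        for a, v in (pi_B or {}).items():
            pb[a] = v
        return CohortTrajectory(occ, pr, pb)

    def test_point_mass(self):
        traj = self._traj_with(pi_R={3: 1.0})
        assert expected_age_first_event(traj, "return") == 3.0

    def test_symmetric_mass_averages(self):
        traj = self._traj_with(pi_B={6: 0.5, 8: 0.5})
        assert expected_age_first_event(traj, "breed") == 7.0

    def test_zero_mass_is_explicit_error(self):
        traj = self._traj_with()
        with pytest.raises(ValueError, match="zero probability"):
            expected_age_first_event(traj, "breed")

    def test_unknown_event_rejected(self):
        traj = self._traj_with(pi_R={3: 1.0})
        with pytest.raises(ValueError):
            expected_age_first_event(traj, "fledge")


class TestOverallAdultSurvival:
    def test_reduces_to_intercept_without_senescence(self):
        p = ParameterSet(phi6=0.93, alpha_A=0.0, beta_A=0.0)
        assert overall_adult_survival(p, MODEL_TABLE[1]) == pytest.approx(
            0.93, abs=1e-12
        )

    def test_senescence_pulls_average_below_age_six_value(self):
        p = ParameterSet(phi6=0.976, alpha_A=-0.032, beta_A=-0.001)
        avg = overall_adult_survival(p, MODEL_TABLE[1])
        assert avg < 0.976
        assert avg > 0.90

    def test_cohort_never_breeding_is_an_error(self):
        p = ParameterSet(b_first_breed=(0.0,) * 6)
        with pytest.raises(ValueError, match="adult"):
            overall_adult_survival(p, MODEL_TABLE[1])


class TestLifespanQuantile:
    def test_constant_half_survival(self):
        p = ParameterSet(phi_J=0.5, phi_PB=0.5, phi6=0.5)
        with np.errstate(all="ignore"):
            traj = propagate_cohort(p, max_age=60)
        assert lifespan_quantile(traj, 0.5) == 1

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        s=st.floats(0.3, 0.9),
        p=st.floats(0.01, 0.5),
    )
    def test_constant_survival_closed_form(self, s, p):
        params = ParameterSet(phi_J=s, phi_PB=s, phi6=s)
        traj = propagate_cohort(params, max_age=120)
        expected = math.ceil(math.log(p) / math.log(s))
        assert lifespan_quantile(traj, p) == expected

    def test_out_of_range_quantile_rejected(self):
        traj = propagate_cohort(ParameterSet(), max_age=200)
        for bad in (0.0, 1.0, -0.1, 2.0):
            with pytest.raises(ValueError):
                lifespan_quantile(traj, bad)


def _adult_only_dataset(seasons, n=12, seen=True):
    """Birds entering as adults; with full attendance everything is seen."""
    birds = []
    for i in range(n):
        obs = {}
        for t in seasons:
            obs[t] = OC.SEEN_BREEDER_FAIL if (t + i) % 2 else OC.SEEN_NONBREEDER
        birds.append(
            IndividualHistory(f"A{i}", "F", seasons[0] - 10 - i, seasons[0], "BF", obs)
        )
    return StudyDataset(birds, seasons)


@pytest.fixture(scope="module")
def fitted():
    seasons = list(range(2000, 2008))
    data = _adult_only_dataset(seasons)
    config = McmcConfig(n_chains=1, n_burnin=400, n_iter=800, thin=8, seed=2)
    return data, fit_model(data, 0, config)


class TestPopulationSeries:

    def test_fully_observed_counts_are_exact(self, fitted):
        data, chains = fitted
        series = population_size_series(data, chains, n_sample_draws=40, seed=1)
        # every bird is seen alive every season: no latent uncertainty
        np.testing.assert_allclose(series.table["N_mean"], len(data))
        np.testing.assert_allclose(series.table["N_lo"], len(data))
        np.testing.assert_allclose(series.table["N_hi"], len(data))

    def test_dead_recovery_zeroes_the_bird_out(self, fitted):
        data, chains = fitted
        seasons = data.seasons
        birds = list(data.individuals)
        obs = {seasons[0]: OC.SEEN_BREEDER_FAIL, seasons[2]: OC.RECOVERED_DEAD}
        birds[0] = IndividualHistory(
            "A0", "F", seasons[0] - 10, seasons[0], "BF", obs
        )
        data2 = StudyDataset(birds, seasons)
        series = population_size_series(data2, chains, n_sample_draws=40, seed=1)
        # from the recovery season on, the bird can never be counted
        assert series.table["N_hi"].iloc[2:].max() <= len(birds) - 1

    def test_ratio_arithmetic(self, fitted):
        data, chains = fitted
        series = population_size_series(data, chains, n_sample_draws=40, seed=1)
        ratios = population_ratios(series)
        n = len(data)
        nbp = series.table["N_BP"].iloc[0]
        assert ratios["pooled_N_over_NBP"] == pytest.approx(n / nbp, rel=1e-9)
        assert ratios["pooled_N_over_NA"] == pytest.approx(1.0, rel=1e-9)

    def test_all_zero_breeding_pairs_rejected(self, fitted):
        data, chains = fitted
        seasons = data.seasons
        birds = [
            IndividualHistory(
                f"N{i}",
                "F",
                seasons[0] - 10 - i,
                seasons[0],
                "NB",
                {t: OC.SEEN_NONBREEDER for t in seasons},
            )
            for i in range(5)
        ]
        nb_only = StudyDataset(birds, seasons)
        series = population_size_series(nb_only, chains, n_sample_draws=20, seed=1)
        with pytest.raises(ValueError, match="breeding pairs"):
            population_ratios(series)
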