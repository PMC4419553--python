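import io

import numpy as np
import pytest

from msdemog import (
    IndividualHistory,
    ParameterSet,
    StudyDataset,
    make_fixture,
)
from msdemog.encounter_data import ObservationCode as OC


def random_parameter_set(rng: np.random.Generator) -> ParameterSet:
    """A valid, well-separated-from-boundary random parameter set."""
    return ParameterSet(
        phi_J=rng.uniform(0.5, 0.99),
        phi_PB=rng.uniform(0.5, 0.99),
        phi6=rng.uniform(0.7, 0.99),
        alpha_A=-rng.uniform(0.0, 0.1),
        beta_A=rng.normal(0.0, 0.004),
        beta_M=rng.normal(0.0, 0.3),
        r_first_return=tuple(rng.uniform(0.05, 0.9, 6)),
        b_first_breed=tuple(rng.uniform(0.05, 0.9, 6)),
        p_breed_given_nonbreeder=rng.uniform(0.1, 0.95),
        p_breed_again_given_success=rng.uniform(0.0, 0.3),
        p_breed_again_given_fail=rng.uniform(0.3, 0.95),
        gamma_PB=rng.uniform(0.5, 1.0),
        gamma_NB_success=rng.uniform(0.0, 0.5),
        gamma_NB_fail=rng.uniform(0.5, 1.0),
        outcome_success_prob=rng.uniform(0.3, 0.9),
    )


def random_history(rng, fledge=2000, length=5, band="X1") -> IndividualHistory:
    """A random chick-entry encounter history over ``length`` seasons."""
    codes = [
        OC.NOT_SEEN,
        OC.SEEN_PREBREEDER,
        OC.SEEN_BREEDER_SUCCESS,
        OC.SEEN_BREEDER_FAIL,
        OC.SEEN_NONBREEDER,
    ]
    obs = {}
    for t in range(fledge + 1, fledge + 1 + length):
        if rng.random() < 0.08:
            obs[t] = OC.RECOVERED_DEAD
            break
        code = codes[rng.integers(len(codes))]
        if code is not OC.NOT_SEEN:
            obs[t] = code
    return IndividualHistory(band, "F", fledge, fledge, "chick", obs)


@pytest.fixture(scope="session")
def tiny_fixture():
    return make_fixture("tiny")


@pytest.fixture()
def tiny_dataset(tiny_fixture):
    return tiny_fixture[0]


@pytest.fixture()
def wide_csv():
    """A hand-written two-bird encounter table."""
    return io.StringIO(
        "band_id,sex,fledge_season,1989,1990,1991,1992,1993\n"
        "R100,F,1989,C,,,,PB\n"
        "R200,M,1985,,,BS,,NB\n"
    )
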