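"""Derived demographic quantities.

Post-inference summaries built on the fitted model: deterministic cohort
propagation (ages at first return / first breeding, lifespan quantiles,
age-weighted overall adult survival) and latent-state population
reconstruction (total population size, adult numbers, and their ratios
to the annual number of breeding pairs).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encounter_data import ObservationCode, StudyDataset, summarize_dataset
from .inference_engine import PosteriorChains
from .msm_core import (
    ADULT_STATES,
    MODEL_TABLE,
    CHICK_ENTRY,
    LatentState,
    LikelihoodEvaluator,
    MIN_AGE_FIRST_BREEDING,
    ModelSpec,
    N_STATES,
    ParameterSet,
    survival_at,
    transition_matrix,
)

__all__ = [
    "CohortTrajectory",
    "PopulationSeries",
    "propagate_cohort",
    "expected_age_first_event",
    "overall_adult_survival",
    "lifespan_quantile",
    "population_size_series",
    "population_ratios",
]

logger = logging.getLogger("msdemog")

LIVE_IDX = [int(s) for s in LatentState if s != LatentState.D]
ADULT_IDX = [int(s) for s in ADULT_STATES]

#: residual live cohort mass above which propagation warns
RESIDUAL_TOL = 1e-6


@dataclass
class CohortTrajectory:
    """Deterministic fate of a fledgling cohort.

    ``occupancy[a]`` is the distribution over the seven latent states at
    age ``a`` (row sums are exactly 1, the dead state absorbing the lost
    mass); ``pi_R[a]`` / ``pi_B[a]`` are the unconditional probabilities
    that a fledgling first returns / first breeds at age ``a``.
    """

    occupancy: np.ndarray  # (max_age + 1, 7)
    pi_R: np.ndarray
    pi_B: np.ndarray

    @property
    def max_age(self) -> int:
        return self.occupancy.shape[0] - 1

    def alive(self) -> np.ndarray:
        """P(alive at age a), the cohort's survivorship curve."""
        return self.occupancy[:, LIVE_IDX].sum(axis=1)

    def adult_mass(self) -> np.ndarray:
        return self.occupancy[:, ADULT_IDX].sum(axis=1)


def propagate_cohort(
    params: ParameterSet,
    max_age: int = 90,
    spec: ModelSpec = MODEL_TABLE[0],
    sex: str | None = None,
) -> CohortTrajectory:
    """Propagate a fledgling cohort through the mean transition kernel.

    Uses time-constant parameters: year effects are dropped (the mean
    annual survival is used) and breeding outcomes are split
    deterministically by ``outcome_success_prob``.  ``sex=None`` applies
    no sex offset; pass ``'M'``/``'F'`` to project a sexed cohort.
    Warns when live mass above ``RESIDUAL_TOL`` remains at ``max_age``.
    """
    occ = np.zeros((max_age + 1, N_STATES))
    occ[0, LatentState.J] = 1.0
    pi_R = np.zeros(max_age + 1)
    pi_B = np.zeros(max_age + 1)
    for a in range(1, max_age + 1):
        T = transition_matrix(a, None, sex, params, spec, outcome=None)
        occ[a] = occ[a - 1] @ T
        sJ = survival_at("J", a, None, sex, params, spec)
        sPB = survival_at("PB", a, None, sex, params, spec)
        pi_R[a] = occ[a - 1, LatentState.J] * params.R_at(a) * sJ
        pi_B[a] = occ[a - 1, LatentState.PB] * params.B_at(a) * sPB
    traj = CohortTrajectory(occ, pi_R, pi_B)
    residual = traj.alive()[-1]
    if residual > RESIDUAL_TOL:
        warnings.warn(
            f"live cohort mass {residual:.2e} remains at age {max_age}; "
            "increase max_age",
            stacklevel=2,
        )
    return traj


def expected_age_first_event(traj: CohortTrajectory, event: str) -> float:
    """Expected age at first return ('return') or first breeding ('breed').

    The ratio of the first moment to the mass of the first-passage
    probabilities: the mean age at the event among birds that ever
    experience it.
    """
    if event == "return":
        pi = traj.pi_R
    elif event == "breed":
        pi = traj.pi_B
    else:
        raise ValueError(f"event must be 'return' or 'breed', got {event!r}")
    mass = pi.sum()
    if mass <= 0.0:
        raise ValueError(f"zero probability of ever experiencing {event!r}")
    ages = np.arange(traj.max_age + 1)
    return float((ages * pi).sum() / mass)


def overall_adult_survival(
    params: ParameterSet,
    spec: ModelSpec = MODEL_TABLE[1],
    max_age: int = 90,
    sex: str | None = None,
) -> float:
    """Age-weighted mean annual adult survival.

    Averages the (possibly senescent) adult survival across ages,
    weighting each age by the probability that a fledgling is alive and
    adult at that age under the cohort trajectory.  With no senescence
    this equals the age-six survival exactly.
    """
    traj = propagate_cohort(params, max_age, spec, sex)
    w = traj.adult_mass()
    total = w.sum()
    if total <= 0.0:
        raise ValueError("cohort never reaches the adult stage")
    phis = np.array(
        [survival_at("A", a, None, sex, params, spec) for a in range(max_age + 1)]
    )
    return float((w * phis).sum() / total)


def lifespan_quantile(traj: CohortTrajectory, p: float) -> int:
    """Smallest age at which the proportion of the cohort still alive
    drops to ``p`` or below."""
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must be in (0, 1), got {p}")
    alive = traj.alive()
    below = np.nonzero(alive <= p)[0]
    if below.size == 0:
        raise ValueError(
            f"cohort survivorship never drops to {p}; increase max_age"
        )
    return int(below[0])


# ---------------------------------------------------------------------------
# population reconstruction
# ---------------------------------------------------------------------------


@dataclass
class PopulationSeries:
    """Per-season population sizes with credible intervals.

    ``table`` has one row per season: posterior mean and 95% interval of
    the total population ``N`` (juveniles + pre-breeders + adults among
    banded birds, counted from the season after fledging) and of the
    adult count ``N_A``, plus the observed breeding-pair count ``N_BP``
    (breeding outcome is data, not latent).  ``n_draws_*`` hold the
    per-draw counts used for ratio summaries.
    """

    table: pd.DataFrame
    n_draws: np.ndarray = field(repr=False, default=None)  # (draws, seasons)
    na_draws: np.ndarray = field(repr=False, default=None)

    @property
    def seasons(self) -> np.ndarray:
        return self.table.index.to_numpy()


def _ffbs_paths(ev: LikelihoodEvaluator, params: ParameterSet, rng) -> np.ndarray:
    """Sample one latent path per bird from the smoothing distribution.

    Forward-filter with the evaluator then backward-sample.  Returns an
    (n, T) integer state array; seasons before a bird's entry are -1.
    """
    male = ev.sex_is_male.copy()
    if "sex" in ev.spec.effects("A") and ev.sex_is_unknown.any():
        # resolve unknown sexes with equal odds for this draw
        male = male | (ev.sex_is_unknown & (rng.random(ev.n) < 0.5))
    _, alphas = ev._forward(params, male, keep_alpha=True)
    mats = ev.step_matrices(params, male)  # list of (n,7,7), step t-1 -> t
    n, T = ev.n, ev.T
    paths = np.full((n, T), -1, dtype=int)

    def sample_rows(probs):
        totals = probs.sum(axis=1, keepdims=True)
        safe = np.where(totals > 0, probs / np.maximum(totals, 1e-300), 0.0)
        c = np.cumsum(safe, axis=1)
        u = rng.random((len(probs), 1))
        return (u > c).sum(axis=1).clip(0, N_STATES - 1)

    active_last = ev.entry_t <= T - 1
    paths[active_last, T - 1] = sample_rows(alphas[T - 1][active_last])
    for t in range(T - 2, -1, -1):
        active = ev.entry_t <= t
        if not active.any():
            break
        nxt = paths[:, t + 1]
        Tmat = mats[t]  # step t -> t+1
        w = alphas[t] * Tmat[np.arange(n), :, nxt.clip(0)]
        paths[active, t] = sample_rows(w[active])
    return paths


def population_size_series(
    data: StudyDataset,
    chains: PosteriorChains,
    n_sample_draws: int = 200,
    seed: int = 0,
) -> PopulationSeries:
    """Reconstruct annual population sizes from the fitted model.

    For each retained posterior draw, each bird's latent path is sampled
    from the forward-backward smoothing distribution given its encounter
    history, and live birds are counted per season.  Chick entrants are
    counted from the season after fledging (chicks are not population
    members at the start-of-season census); birds entering as adults or
    pre-breeders are counted from their first resighting.
    """
    data = data.known_age()
    ev = LikelihoodEvaluator(data, chains.spec)
    if ev.seasons != sorted(chains.seasons):
        raise ValueError("chains were fitted on a different season range")
    rng = np.random.default_rng(seed)
    start_count = ev.entry_t + np.array(
        [1 if ind.entry_state == CHICK_ENTRY else 0 for ind in data.individuals]
    )
    countable = np.arange(ev.T)[None, :] >= start_count[:, None]  # (n, T)

    n_counts, na_counts = [], []
    for params in chains.parameter_sets(max_draws=n_sample_draws, rng=rng):
        paths = _ffbs_paths(ev, params, rng)
        live = np.isin(paths, LIVE_IDX) & countable
        adult = np.isin(paths, ADULT_IDX) & countable
        n_counts.append(live.sum(axis=0))
        na_counts.append(adult.sum(axis=0))
    n_counts = np.array(n_counts)
    na_counts = np.array(na_counts)

    summary = summarize_dataset(data)
    idx = pd.Index(ev.seasons, name="season")
    table = pd.DataFrame(
        {
            "N_mean": n_counts.mean(axis=0),
            "N_lo": np.quantile(n_counts, 0.025, axis=0),
            "N_hi": np.quantile(n_counts, 0.975, axis=0),
            "N_A_mean": na_counts.mean(axis=0),
            "N_A_lo": np.quantile(na_counts, 0.025, axis=0),
            "N_A_hi": np.quantile(na_counts, 0.975, axis=0),
            "N_BP": summary.loc[idx, "breeding_pairs"].to_numpy(),
        },
        index=idx,
    )
    return PopulationSeries(table, n_counts, na_counts)


def population_ratios(series: PopulationSeries) -> dict:
    """Ratios of total population size to breeding pairs and to adults.

    Returns per-season ratio tables and pooled across-season means with
    95% credible intervals.  Seasons with zero breeding pairs are
    excluded from N/N_BP (and reported); an all-zero breeding-pair
    series is an error.
    """
    tab = series.table
    nbp = tab["N_BP"].to_numpy()
    usable = nbp > 0
    if not usable.any():
        raise ValueError("no season has a positive number of breeding pairs")
    excluded = list(tab.index[~usable])
    if excluded:
        logger.info("seasons excluded from N/N_BP (no breeding pairs): %s", excluded)

    ratio_bp_draws = series.n_draws[:, usable] / nbp[usable]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_na_draws = np.where(
            series.na_draws > 0, series.n_draws / np.maximum(series.na_draws, 1), np.nan
        )
    per_season = pd.DataFrame(
        {
            "N_over_NBP": np.where(usable, tab["N_mean"] / np.where(usable, nbp, 1), np.nan),
            "N_over_NA": tab["N_mean"] / tab["N_A_mean"].replace(0, np.nan),
        },
        index=tab.index,
    )
    pooled_bp = ratio_bp_draws.mean(axis=1)
    pooled_na = np.nanmean(ratio_na_draws, axis=1)
    return {
        "per_season": per_season,
        "pooled_N_over_NBP": float(pooled_bp.mean()),
        "pooled_N_over_NBP_ci": (
            float(np.quantile(pooled_bp, 0.025)),
            float(np.quantile(pooled_bp, 0.975)),
        ),
        "pooled_N_over_NA": float(np.nanmean(pooled_na)),
        "pooled_N_over_NA_ci": (
            float(np.nanquantile(pooled_na, 0.025)),
            float(np.nanquantile(pooled_na, 0.975)),
        ),
        "excluded_seasons": excluded,
    }
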