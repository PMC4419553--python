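"""Model comparison by the Deviance Information Criterion.

DIC is approximated from the posterior sample of the deviance theta as
``DIC = mean(theta) + var(theta) / 2`` — the half-variance form of the
effective-parameter penalty.  The sample variance uses the n-1
denominator.  Models whose DIC exceeds the best model's by three units
or more are conventionally considered to have substantially less
support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference_engine import PosteriorChains

__all__ = [
    "DevianceSamples",
    "compute_dic",
    "dic_from_moments",
    "compare_models",
    "SUPPORT_THRESHOLD",
]

#: Delta-DIC at or above which a model is flagged as clearly weaker
SUPPORT_THRESHOLD = 3.0


@dataclass
class DevianceSamples:
    values: np.ndarray
    model_id: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        if self.values.size < 2:
            raise ValueError("need at least two deviance samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("deviance samples must be finite")


def compute_dic(dev: DevianceSamples | np.ndarray) -> float:
    """DIC from a posterior deviance sample: mean plus half the variance."""
    if not isinstance(dev, DevianceSamples):
        dev = DevianceSamples(np.asarray(dev), model_id=-1)
    v = dev.values
    return float(v.mean() + 0.5 * v.var(ddof=1))


def dic_from_moments(mean: float, variance: float) -> float:
    """DIC from precomputed deviance moments."""
    if variance < 0:
        raise ValueError(f"negative deviance variance {variance}")
    return float(mean + 0.5 * variance)


def compare_models(runs: list[PosteriorChains]) -> pd.DataFrame:
    """Comparison table across fitted models, sorted by DIC.

    Columns: model_id, mean_deviance, var_deviance, dic, delta_dic and a
    ``support`` annotation (empty for the best model and anything within
    three DIC units of it, ``'weak'`` beyond that).
    """
    if not runs:
        raise ValueError("no runs to compare")
    ids = [r.spec.model_id for r in runs]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate model ids in comparison: {ids}")
    rows = []
    for run in runs:
        v = run.deviance.reshape(-1)
        rows.append(
            {
                "model_id": run.spec.model_id,
                "mean_deviance": float(v.mean()),
                "var_deviance": float(v.var(ddof=1)),
                "dic": compute_dic(DevianceSamples(v, run.spec.model_id)),
            }
        )
    table = pd.DataFrame(rows).sort_values("dic").reset_index(drop=True)
    table["delta_dic"] = table["dic"] - table["dic"].iloc[0]
    table["support"] = np.where(
        table["delta_dic"] >= SUPPORT_THRESHOLD, "weak", ""
    )
    return table
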