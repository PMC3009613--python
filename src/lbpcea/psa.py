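"""Probabilistic sensitivity analysis (PSA) and acceptability curves.

Parameter uncertainty is propagated by Monte-Carlo: each draw samples one
joint parameter set (transition probabilities, utilities, per-cycle chronic
costs and the recovery risk ratio), evaluates BOTH strategies on that shared
draw, and records the per-strategy cost/QALY pair.  The cost-effectiveness
acceptability curve (CEAC) then reports, per willingness-to-pay threshold,
the fraction of draws in which the collaborative strategy's net monetary
benefit exceeds usual care's (pairwise definition; ties count toward the
reference strategy, so the two curves sum to one exactly).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .cost_model import CycleCosts
from .markov_engine import Conventions, evaluate_strategy
from .parameters import (
    ConfigurationError,
    DistributionSpec,
    ModelSettings,
    sample_parameter_set,
)

__all__ = ["CEACCurve", "CEACCrossing", "run_psa", "compute_ceac", "ceac_crossing"]

_PARAM_COLUMNS = [
    "tATC", "tWTC", "tCTW", "uALBP", "uCLBPUC", "uCLBPACUC", "uWell", "cUC", "cACUC", "tRR",
]


def run_psa(
    specs: Mapping[str, DistributionSpec],
    mortality: np.ndarray,
    settings: ModelSettings,
    conventions: Conventions = Conventions(),
    n_draws: int = 10_000,
    seed: int = 0,
    indirect_per_cycle: float = 0.0,
) -> pd.DataFrame:
    """Run the Monte-Carlo PSA and return one row per draw.

    Columns: the sampled parameter values, per-strategy ``cost_*`` and
    ``qaly_*``, and the incremental ``delta_cost`` / ``delta_qaly``
    (collaborative minus usual care).  ``indirect_per_cycle`` adds an equal
    per-cycle indirect cost to the sampled chronic-state cost of both
    strategies (zero in the base case).  Identical seeds give identical
    frames.
    """
    if n_draws < 1:
        raise ConfigurationError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    records = np.empty((n_draws, len(_PARAM_COLUMNS) + 6))
    for i in range(n_draws):
        draw = sample_parameter_set(specs, rng, mortality=mortality)
        per_strategy = {}
        for strategy in ("usual_care", "collaborative"):
            costs = CycleCosts(
                direct_medical=draw.chronic_cost[strategy],
                direct_nonmedical=0.0,
                indirect_nonmedical=indirect_per_cycle,
                include_indirect=indirect_per_cycle > 0,
            )
            per_strategy[strategy] = evaluate_strategy(
                strategy, draw.transitions, draw.utilities, costs, settings, conventions
            )
        uc, ac = per_strategy["usual_care"], per_strategy["collaborative"]
        t = draw.transitions
        u = draw.utilities
        records[i] = [
            t.t_atc, t.t_wtc, t.t_ctw,
            u.acute, u.chronic_usual_care, u.chronic_collaborative, u.well,
            draw.chronic_cost["usual_care"], draw.chronic_cost["collaborative"], t.t_rr,
            uc.cost, uc.qaly, ac.cost, ac.qaly,
            ac.cost - uc.cost, ac.qaly - uc.qaly,
        ]
    frame = pd.DataFrame(
        records,
        columns=_PARAM_COLUMNS
        + [
            "cost_usual_care", "qaly_usual_care",
            "cost_collaborative", "qaly_collaborative",
            "delta_cost", "delta_qaly",
        ],
    )
    frame.insert(0, "draw", np.arange(n_draws))
    return frame


@dataclass(frozen=True)
class CEACCurve:
    """Acceptance probabilities per willingness-to-pay threshold."""

    lambdas: np.ndarray
    p_collaborative: np.ndarray
    p_usual_care: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lambda": self.lambdas,
                "p_collaborative": self.p_collaborative,
                "p_usual_care": self.p_usual_care,
            }
        )


def compute_ceac(samples: pd.DataFrame, lambda_grid: np.ndarray) -> CEACCurve:
    """Pairwise CEAC: P(NMB difference > 0) per threshold, ties to reference."""
    lambdas = np.asarray(lambda_grid, dtype=float)
    if lambdas.size == 0:
        raise ConfigurationError("lambda grid must be non-empty")
    if samples.empty:
        raise ConfigurationError("PSA samples must be non-empty")
    dq = samples["delta_qaly"].to_numpy()
    dc = samples["delta_cost"].to_numpy()
    # incremental NMB per (draw, lambda); strict inequality sends ties to usual care
    wins = (np.outer(dq, lambdas) - dc[:, None]) > 0.0
    p_collab = wins.mean(axis=0)
    return CEACCurve(
        lambdas=lambdas, p_collaborative=p_collab, p_usual_care=1.0 - p_collab
    )


@dataclass(frozen=True)
class CEACCrossing:
    """Where the acceptability curve first reaches a probability level."""

    grid_lambda: float
    interpolated_lambda: float
    reached: bool


def ceac_crossing(curve: CEACCurve, level: float = 0.5) -> CEACCrossing:
    """Smallest grid threshold whose acceptance probability reaches ``level``.

    Also reports a linear interpolation between the bracketing grid points.
    If the curve never reaches the level, ``reached`` is False and the
    thresholds are NaN.
    """
    idx = np.nonzero(curve.p_collaborative >= level)[0]
    if idx.size == 0:
        return CEACCrossing(np.nan, np.nan, reached=False)
    i = int(idx[0])
    grid_lambda = float(curve.lambdas[i])
    if i == 0:
        return CEACCrossing(grid_lambda, grid_lambda, reached=True)
    lam0, lam1 = curve.lambdas[i - 1], curve.lambdas[i]
    p0, p1 = curve.p_collaborative[i - 1], curve.p_collaborative[i]
    interp = lam1 if p1 == p0 else lam0 + (level - p0) * (lam1 - lam0) / (p1 - p0)
    return CEACCrossing(grid_lambda, float(interp), reached=True)
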