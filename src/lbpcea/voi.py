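"""Value-of-information analysis: per-decision and population EVPI.

The expected value of perfect information (EVPI) at a willingness-to-pay
threshold is the expected net-benefit gain from resolving all parameter
uncertainty before deciding: ``E[max_s NMB_s] - max_s E[NMB_s]`` over the
PSA draws.  It is non-negative by Jensen's inequality and zero when the
parameters are certain.  The population EVPI scales the per-person value by
the discounted number of incident cases the decision affects over a fixed
horizon.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .parameters import ParameterError

__all__ = ["evpi_at_threshold", "population_evpi", "population_multiplier", "evpi_curve"]


def _nmb_matrix(samples: pd.DataFrame, lam: float) -> np.ndarray:
    """Per-draw, per-strategy net monetary benefit (columns: usual care, collaborative)."""
    return np.column_stack(
        [
            lam * samples["qaly_usual_care"].to_numpy() - samples["cost_usual_care"].to_numpy(),
            lam * samples["qaly_collaborative"].to_numpy()
            - samples["cost_collaborative"].to_numpy(),
        ]
    )


def evpi_at_threshold(samples: pd.DataFrame, lam: float) -> float:
    """Per-person EVPI at one threshold, from PSA draws.

    ``samples`` is the frame returned by :func:`lbpcea.psa.run_psa` (it must
    carry the per-strategy cost and QALY columns).
    """
    if samples.empty:
        raise ParameterError("PSA samples must be non-empty")
    if lam < 0:
        raise ParameterError("threshold must be >= 0")
    nmb = _nmb_matrix(samples, lam)
    return float(nmb.max(axis=1).mean() - nmb.mean(axis=0).max())


def population_multiplier(
    annual_incidence: float,
    horizon_years: int,
    discount_rate: float,
    cohort_timing: str = "start",
) -> float:
    """Discounted number of incident cases the decision affects.

    Annual cohorts of ``annual_incidence`` new cases arrive for
    ``horizon_years`` years; with ``start`` timing the first cohort is
    undiscounted (arrives at decision time), with ``end`` every cohort is
    discounted one extra year.
    """
    if annual_incidence < 0 or horizon_years < 0 or discount_rate < 0:
        raise ParameterError("population-EVPI inputs must be >= 0")
    offset = 0 if cohort_timing == "start" else 1
    years = np.arange(horizon_years) + offset
    return float(annual_incidence * np.sum((1.0 + discount_rate) ** (-years)))


def population_evpi(
    evpi_per_person: float,
    annual_incidence: float,
    horizon_years: int,
    discount_rate: float,
    cohort_timing: str = "start",
) -> float:
    """Per-person EVPI scaled to the affected population."""
    if evpi_per_person < 0:
        raise ParameterError("per-person EVPI must be >= 0")
    return evpi_per_person * population_multiplier(
        annual_incidence, horizon_years, discount_rate, cohort_timing
    )


def evpi_curve(
    samples: pd.DataFrame,
    lambda_grid: np.ndarray,
    annual_incidence: float = 57_400,
    horizon_years: int = 5,
    discount_rate: float = 0.05,
    cohort_timing: str = "start",
) -> pd.DataFrame:
    """EVPI across thresholds: columns lambda, evpi_per_person, population_evpi."""
    lambdas = np.asarray(lambda_grid, dtype=float)
    multiplier = population_multiplier(
        annual_incidence, horizon_years, discount_rate, cohort_timing
    )
    per_person = np.array([evpi_at_threshold(samples, lam) for lam in lambdas])
    return pd.DataFrame(
        {
            "lambda": lambdas,
            "evpi_per_person": per_person,
            "population_evpi": per_person * multiplier,
            "annual_incidence": annual_incidence,
            "horizon_years": horizon_years,
            "discount_rate": discount_rate,
        }
    )
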