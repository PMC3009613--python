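"""Random-effects meta-analysis of recovery risk ratios.

The treatment-effect parameter of the decision model — the risk ratio (RR)
for recovery from chronic low back pain under collaborative treatment — is
pooled from study-level 2x2 recovery counts with the DerSimonian-Laird (DL)
moment estimator, which inflates study variances by a between-study variance
tau^2 estimated from Cochran's Q.  The pooled log-RR and its standard error
map directly onto the lognormal sampling distribution the PSA draws from.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .parameters import DistributionSpec, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "StudyArmData",
    "PooledEffect",
    "NonInformativeStudyError",
    "log_rr_and_se",
    "dersimonian_laird_pool",
    "pooled_to_lognormal",
    "read_studies_csv",
]


class NonInformativeStudyError(ValueError):
    """Raised for a study with zero events in both arms (log-RR undefined)."""


@dataclass(frozen=True)
class StudyArmData:
    """Recovery counts for one two-arm study."""

    label: str
    events_treatment: int
    total_treatment: int
    events_control: int
    total_control: int

    def __post_init__(self) -> None:
        for arm in ("treatment", "control"):
            events = getattr(self, f"events_{arm}")
            total = getattr(self, f"total_{arm}")
            if total <= 0:
                raise ParameterError(f"{self.label}: {arm} arm size must be positive")
            if not 0 <= events <= total:
                raise ParameterError(f"{self.label}: {arm} events must lie in [0, total]")


@dataclass(frozen=True)
class PooledEffect:
    """Pooled log risk ratio with its SE and between-study variance."""

    log_rr: float
    se_log_rr: float
    tau_squared: float
    k: int
    q_statistic: float = math.nan

    @property
    def rr_point(self) -> float:
        return math.exp(self.log_rr)


def log_rr_and_se(study: StudyArmData, continuity: float = 0.5) -> tuple[float, float]:
    """Per-study log risk ratio and its large-sample standard error.

    ``log RR = ln[(eT/nT) / (eC/nC)]`` with
    ``SE = sqrt(1/eT - 1/nT + 1/eC - 1/nC)``.  When either arm has zero
    events the continuity correction is added to all four cells (events and
    non-events), the conventional fix for empty cells.  A study with zero
    events in both arms carries no information about the ratio and raises
    :class:`NonInformativeStudyError`.
    """
    et, nt = float(study.events_treatment), float(study.total_treatment)
    ec, nc = float(study.events_control), float(study.total_control)
    if et == 0 and ec == 0:
        raise NonInformativeStudyError(f"{study.label}: zero events in both arms")
    if et == 0 or ec == 0:
        et += continuity
        ec += continuity
        nt += 2 * continuity
        nc += 2 * continuity
    log_rr = math.log((et / nt) / (ec / nc))
    se = math.sqrt(1.0 / et - 1.0 / nt + 1.0 / ec - 1.0 / nc)
    return log_rr, se


def dersimonian_laird_pool(studies: Sequence[StudyArmData]) -> PooledEffect:
    """DerSimonian-Laird random-effects pooling of study risk ratios.

    Fixed-effect inverse-variance weights give Cochran's
    ``Q = sum w_i (y_i - y_FE)^2``; the moment estimator
    ``tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))`` inflates each
    study variance, and the pooled effect is the tau^2-adjusted
    inverse-variance average.  Non-informative studies (zero events in both
    arms) are dropped with a warning.
    """
    effects, variances = [], []
    for study in studies:
        try:
            y, se = log_rr_and_se(study)
        except NonInformativeStudyError:
            logger.warning("dropping non-informative study %s", study.label)
            continue
        effects.append(y)
        variances.append(se**2)
    k = len(effects)
    if k == 0:
        raise ParameterError("no informative studies to pool")
    y = np.asarray(effects)
    v = np.asarray(variances)
    w = 1.0 / v
    y_fe = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - y_fe) ** 2))
    if k == 1:
        return PooledEffect(log_rr=y_fe, se_log_rr=math.sqrt(v[0]), tau_squared=0.0, k=1, q_statistic=0.0)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom)
    w_re = 1.0 / (v + tau2)
    pooled = float(np.sum(w_re * y) / np.sum(w_re))
    se_pooled = float(math.sqrt(1.0 / np.sum(w_re)))
    return PooledEffect(log_rr=pooled, se_log_rr=se_pooled, tau_squared=tau2, k=k, q_statistic=q)


def pooled_to_lognormal(pooled: PooledEffect) -> DistributionSpec:
    """Express a pooled effect as the PSA's lognormal risk-ratio distribution."""
    return DistributionSpec(family="lognormal", param_a=pooled.log_rr, param_b=pooled.se_log_rr)


def read_studies_csv(path) -> list[StudyArmData]:
    """Read a study table (columns: study, events_t, total_t, events_c, total_c)."""
    frame = pd.read_csv(path)
    required = {"study", "events_t", "total_t", "events_c", "total_c"}
    missing = required - set(frame.columns)
    if missing:
        raise ParameterError(f"studies CSV missing columns: {sorted(missing)}")
    return [
        StudyArmData(
            label=str(row.study),
            events_treatment=int(row.events_t),
            total_treatment=int(row.total_t),
            events_control=int(row.events_c),
            total_control=int(row.total_c),
        )
        for row in frame.itertuples()
    ]
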