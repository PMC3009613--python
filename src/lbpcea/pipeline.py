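"""End-to-end analysis pipeline: base case, sensitivity analyses, VOI, outputs.

`run_full_analysis` reproduces the complete analysis sequence from one
configuration: the deterministic base case and its incremental comparison,
the univariate sensitivity analysis that toggles indirect (productivity)
costs on, the Monte-Carlo PSA with its acceptability curve, the
value-of-information curve, and the calibration summary — writing each
result to a documented text file plus a run manifest that suffices to
regenerate everything.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .cea import incremental_analysis
from .config import AnalysisConfig, config_sha256
from .markov_engine import evaluate_strategy, validation_summary
from .parameters import TransitionParameters, UtilitySet
from .psa import ceac_crossing, compute_ceac, run_psa
from .voi import evpi_curve

logger = logging.getLogger(__name__)

__all__ = ["base_case", "run_full_analysis"]


def _point_inputs(config: AnalysisConfig):
    points = config.point_values()
    transitions = TransitionParameters(
        t_atc=points["tATC"],
        t_wtc=points["tWTC"],
        t_ctw=points["tCTW"],
        t_rr=points["tRR"],
        mortality=config.mortality_schedule(),
    )
    utilities = UtilitySet(
        acute=points["uALBP"],
        chronic_usual_care=points["uCLBPUC"],
        chronic_collaborative=points["uCLBPACUC"],
        well=points["uWell"],
    )
    return transitions, utilities


def base_case(config: AnalysisConfig, include_indirect: bool | None = None) -> dict:
    """Deterministic run of both strategies at the point values.

    Returns the per-strategy outcomes, the incremental comparison and the
    calibration summary of the usual-care arm.
    """
    settings = config.model_settings()
    conventions = config.engine_conventions()
    transitions, utilities = _point_inputs(config)
    outcomes = {}
    for strategy in ("usual_care", "collaborative"):
        costs = config.cycle_costs(strategy, include_indirect)
        outcomes[strategy] = evaluate_strategy(
            strategy, transitions, utilities, costs, settings, conventions
        )
    incremental = incremental_analysis(outcomes["usual_care"], outcomes["collaborative"])
    validation = validation_summary(outcomes["usual_care"].trace, settings.cohort_size)
    return {"outcomes": outcomes, "incremental": incremental, "validation": validation}


def _outcome_dict(outcome) -> dict:
    return {
        "cost": outcome.cost,
        "qaly": outcome.qaly,
        "cost_discounted": outcome.cost_discounted,
        "qaly_discounted": outcome.qaly_discounted,
        "cost_undiscounted": outcome.cost_undiscounted,
        "qaly_undiscounted": outcome.qaly_undiscounted,
    }


def run_full_analysis(
    config: AnalysisConfig,
    out_dir,
    seed: int | None = None,
    n_draws: int | None = None,
) -> dict:
    """Run every stage and write summary.json, trace.csv, ce_plane.csv,
    ceac.csv, evpi.csv and manifest.json under ``out_dir``.

    ``seed`` and ``n_draws`` override the configuration's PSA block.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.psa.seed if seed is None else int(seed)
    n_draws = config.psa.n_draws if n_draws is None else int(n_draws)
    settings = config.model_settings()
    conventions = config.engine_conventions()

    logger.info("deterministic base case (%d cycles)", settings.n_cycles)
    base = base_case(config)
    logger.info("univariate sensitivity: indirect costs included")
    univariate = base_case(config, include_indirect=True)

    logger.info("PSA: %d draws, seed %d", n_draws, seed)
    samples = run_psa(
        config.distribution_specs(),
        config.mortality_schedule(),
        settings,
        conventions,
        n_draws=n_draws,
        seed=seed,
        indirect_per_cycle=(
            config.costs.indirect_nonmedical_per_cycle if config.costs.include_indirect else 0.0
        ),
    )
    curve = compute_ceac(samples, settings.lambda_grid)
    crossing = ceac_crossing(curve, 0.5)
    logger.info("value-of-information curve")
    evpi = evpi_curve(
        samples,
        settings.lambda_grid,
        annual_incidence=config.voi.annual_incidence,
        horizon_years=config.voi.horizon_years,
        discount_rate=config.voi.discount_rate,
        cohort_timing=config.conventions.cohort_timing,
    )

    # ---- outputs ----------------------------------------------------------
    traces = [base["outcomes"][s].trace.to_dataframe() for s in base["outcomes"]]
    pd.concat(traces, ignore_index=True).to_csv(out / "trace.csv", index=False)
    samples[["draw", "delta_cost", "delta_qaly"]].to_csv(out / "ce_plane.csv", index=False)
    curve.to_dataframe().to_csv(out / "ceac.csv", index=False)
    evpi.to_csv(out / "evpi.csv", index=False)

    summary = {
        "base_case": {
            "strategies": {s: _outcome_dict(o) for s, o in base["outcomes"].items()},
            "incremental": asdict(base["incremental"]),
            "validation": base["validation"],
        },
        "univariate_indirect": {
            "strategies": {s: _outcome_dict(o) for s, o in univariate["outcomes"].items()},
            "incremental": asdict(univariate["incremental"]),
        },
        "psa": {
            "n_draws": n_draws,
            "seed": seed,
            "mean_delta_cost": float(samples["delta_cost"].mean()),
            "mean_delta_qaly": float(samples["delta_qaly"].mean()),
            "p_collaborative_at_max_lambda": float(curve.p_collaborative[-1]),
            "ceac_50pct_crossing": asdict(crossing),
        },
        "evpi": {
            "per_person_at_max_lambda": float(evpi["evpi_per_person"].iloc[-1]),
            "population_peak": float(evpi["population_evpi"].max()),
            "population_peak_lambda": float(
                evpi.loc[evpi["population_evpi"].idxmax(), "lambda"]
            ),
        },
    }
    with open(out / "summary.json", "w", encoding="utf-8") as handle:
        json.dump(summary, handle, indent=2)

    manifest = {
        "package": "lbpcea",
        "version": __version__,
        "seed": seed,
        "n_draws": n_draws,
        "config_sha256": config_sha256(config),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=2)
    logger.info("wrote outputs to %s", out)
    return {
        "base_case": base,
        "univariate_indirect": univariate,
        "samples": samples,
        "ceac": curve,
        "crossing": crossing,
        "evpi": evpi,
        "summary": summary,
    }
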