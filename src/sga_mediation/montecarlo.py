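"""Replicated simulation runs and their summary statistics.

Each (scenario, model) cell of the study's tables is the mean of the ICS
coefficient over replicated cohorts, together with its Monte-Carlo standard
error sd(estimates)/sqrt(reps) and a flag for whether the normal 95%
interval mean ± 1.96·se covers zero. Defaults match the full study scale
(1000 replicates of 20,000 babies); both knobs are first-class so reduced
runs are exact subsets of the same machinery.

Reproducibility: the master seed feeds a ``numpy.random.SeedSequence`` whose
spawn key is (scenario-index, replicate-index), so every scenario and every
replicate gets an independent, documented substream; results for a given
master seed do not depend on execution order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import ModelSpec, fit_model, model_battery
from .scenarios import SCENARIOS, ScenarioSpec, Variant, get_scenario, simulate_cohort

__all__ = ["MCSummary", "run_replicates", "summarize", "interpretation_of", "summarize_run"]

#: Failure budget: more than this fraction of failed fits aborts the summary.
MAX_FAILURE_RATE = 0.01

_SCENARIO_INDEX = {name: i for i, name in enumerate(SCENARIOS)}


@dataclass(frozen=True)
class MCSummary:
    """Monte-Carlo summary of one (scenario, model) cell."""

    scenario: str
    model: str
    interpretation: str  # total | direct
    mean_estimate: float
    mc_se: float
    null_flag: bool  # True when 0 is inside mean ± 1.96·se
    n_reps_used: int
    confounded_flag: bool | None = None


def interpretation_of(model: str, scenario: str | None = None) -> str:
    """Which causal effect a model's ICS coefficient targets.

    The GA-unadjusted models of BW and LBW (M1, M3 and their V-adjusted
    forms) estimate the total effect; the GA-adjusted BW models (M2, M2*)
    and the SGA models (M4), which are internally GA-adjusted, target the
    direct effect.
    """
    base = model.replace(",V", "").replace("V*", "*")
    if base in ("M1", "M3"):
        return "total"
    if base in ("M2", "M2*", "M4"):
        return "direct"
    raise ValueError(f"unknown model name {model!r}")


def replicate_seed(master_seed: int, scenario: ScenarioSpec, replicate: int) -> np.random.SeedSequence:
    """Documented substream layout: spawn key (scenario index, replicate)."""
    return np.random.SeedSequence(
        entropy=master_seed, spawn_key=(_SCENARIO_INDEX[scenario.name], replicate)
    )


def run_replicates(
    spec: ScenarioSpec | str,
    variant: Variant | None = None,
    n: int = 20_000,
    reps: int = 1000,
    seed: int = 0,
    models: list[ModelSpec] | None = None,
    estimates_csv: str | Path | None = None,
) -> dict[str, np.ndarray]:
    """Simulate ``reps`` cohorts and fit the model battery on each.

    Returns {model name: array of reps ICS estimates} (NaN for a failed
    fit). Optionally streams per-replicate estimates to a CSV for audit.
    """
    if isinstance(spec, str):
        spec = get_scenario(spec)
    if reps < 2:
        raise ValueError("at least 2 replicates are needed for a Monte-Carlo SE")
    variant = variant or Variant()
    if models is None:
        models = model_battery(spec, variant)

    estimates = {m.name: np.full(reps, np.nan) for m in models}
    for r in range(reps):
        cohort = simulate_cohort(spec, variant, n=n, seed=replicate_seed(seed, spec, r))
        for m in models:
            fit = fit_model(cohort, m)
            if fit.converged:
                estimates[m.name][r] = fit.beta_ics

    if estimates_csv is not None:
        rows = pd.DataFrame(
            [
                (r, spec.name, name, est[r])
                for name, est in estimates.items()
                for r in range(reps)
            ],
            columns=["replicate", "scenario", "model", "estimate"],
        )
        rows.to_csv(estimates_csv, index=False)
    return estimates


def summarize(
    estimates: np.ndarray,
    interpretation: str,
    scenario: str = "",
    model: str = "",
    confounded_flag: bool | None = None,
) -> MCSummary:
    """Mean, Monte-Carlo SE and null flag for one vector of estimates.

    Failed (NaN) replicates are dropped with a warning; a failure rate above
    ``MAX_FAILURE_RATE`` raises instead of silently biasing the mean.
    """
    estimates = np.asarray(estimates, dtype=float)
    ok = np.isfinite(estimates)
    n_used = int(ok.sum())
    if n_used < 2:
        raise ValueError("fewer than 2 successful replicates; cannot summarize")
    n_failed = estimates.size - n_used
    if n_failed:
        if n_failed / estimates.size > MAX_FAILURE_RATE:
            raise RuntimeError(
                f"{model or 'model'}: {n_failed}/{estimates.size} fits failed "
                f"(> {MAX_FAILURE_RATE:.0%} budget)"
            )
        warnings.warn(
            f"{model or 'model'}: dropped {n_failed} failed fit(s) of {estimates.size}",
            stacklevel=2,
        )
    values = estimates[ok]
    mean = float(values.mean())
    se = float(values.std(ddof=1) / np.sqrt(n_used))
    null_flag = bool(mean - 1.96 * se <= 0.0 <= mean + 1.96 * se)
    return MCSummary(
        scenario=scenario,
        model=model,
        interpretation=interpretation,
        mean_estimate=mean,
        mc_se=se,
        null_flag=null_flag,
        n_reps_used=n_used,
        confounded_flag=confounded_flag,
    )


def summarize_run(
    spec: ScenarioSpec | str,
    variant: Variant | None = None,
    n: int = 20_000,
    reps: int = 1000,
    seed: int = 0,
    estimates_csv: str | Path | None = None,
    with_bias_flags: bool = False,
) -> list[MCSummary]:
    """run_replicates + summarize for every model in the battery."""
    from .oracle import bias_flag  # deferred: oracle imports scenarios too

    if isinstance(spec, str):
        spec = get_scenario(spec)
    variant = variant or Variant()
    estimates = run_replicates(
        spec, variant, n=n, reps=reps, seed=seed, estimates_csv=estimates_csv
    )
    summaries = []
    for name, values in estimates.items():
        flag = bias_flag(spec, name) == "biased" if with_bias_flags else None
        summaries.append(
            summarize(
                values,
                interpretation_of(name),
                scenario=spec.name,
                model=name,
                confounded_flag=flag,
            )
        )
    return summaries
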