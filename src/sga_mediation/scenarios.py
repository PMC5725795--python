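"""Causal-DAG scenarios and cohort generation.

Eight scenarios over the nodes {V, ICS, GA, BW}:

* ``basic1``..``basic4`` (three nodes, no confounder): ICS effect on BW is
  respectively null, fully mediated through GA, direct only, or both. The
  GA -> BW edge is present in every scenario.
* ``conf1``..``conf4`` (four nodes): the ICS effect on BW is fully mediated
  through GA, and a binary confounder V points at {ICS, GA}, {GA, BW},
  {ICS, BW} or {ICS, GA, BW} respectively.

Effect sizes: any V->GA or ICS->GA edge subtracts 2 weeks of gestation; any
ICS->BW or V->BW edge shifts mean BW by −100 g; a V->ICS edge sets
P(ICS=1 | V) to 0.7 / 0.3 (otherwise 0.5 for everyone).

A generated cohort is a pandas DataFrame with one row per baby and columns
``v, ics, ga, bw, lbw, sga`` (metadata in ``DataFrame.attrs``). LBW is
BW < 2500 g; SGA is BW strictly below the 10th-percentile reference
threshold at the baby's (shifted) GA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .ga_reference import (
    GA_SHIFTED_MIN,
    GA_SUPPORT_MAX,
    BWMeanModel,
    ErrorModel,
    GADistribution,
    make_default_ga_distribution,
    mean_bw,
    sd_bw,
    sga_threshold,
)

__all__ = [
    "EDGES",
    "LBW_CUTOFF",
    "ScenarioSpec",
    "Variant",
    "SCENARIOS",
    "get_scenario",
    "sample_confounder",
    "sample_exposure",
    "sample_base_ga",
    "apply_ga_shifts",
    "generate_bw",
    "simulate_cohort",
    "save_cohort",
    "load_cohort",
]

#: All possible causal edges besides the always-present GA->BW.
EDGES = ("V->ICS", "V->GA", "V->BW", "ICS->GA", "ICS->BW")

LBW_CUTOFF = 2500.0
GA_SHIFT = -2  # weeks, applied per V->GA / ICS->GA edge
DIRECT_EFFECT = -100.0  # grams, applied per V->BW / ICS->BW edge


@dataclass(frozen=True)
class ScenarioSpec:
    """One causal scenario: an edge set plus the implied effect sizes."""

    name: str
    edges: frozenset[str]
    #: Optional override of (P(ICS=1 | V=1), P(ICS=1 | V=0)); study values
    #: are implied by the edge set and need not be given.
    exposure_probs: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        unknown = self.edges - set(EDGES)
        if unknown:
            raise ValueError(f"unknown edges {sorted(unknown)}")
        object.__setattr__(self, "edges", frozenset(self.edges))
        if self.exposure_probs is not None and not all(
            0.0 <= p <= 1.0 for p in self.exposure_probs
        ):
            raise ValueError("exposure probabilities must lie in [0, 1]")

    @property
    def has_confounder(self) -> bool:
        return any(edge.startswith("V->") for edge in self.edges)

    @property
    def ga_shift_ics(self) -> int:
        return GA_SHIFT if "ICS->GA" in self.edges else 0

    @property
    def ga_shift_v(self) -> int:
        return GA_SHIFT if "V->GA" in self.edges else 0

    @property
    def beta_ics(self) -> float:
        return DIRECT_EFFECT if "ICS->BW" in self.edges else 0.0

    @property
    def beta_v(self) -> float:
        return DIRECT_EFFECT if "V->BW" in self.edges else 0.0

    @property
    def p_exposure_given_v(self) -> tuple[float, float]:
        """(P(ICS=1 | V=1), P(ICS=1 | V=0))."""
        if self.exposure_probs is not None:
            return self.exposure_probs
        if "V->ICS" in self.edges:
            return (0.7, 0.3)
        return (0.5, 0.5)


def _spec(name: str, edges: Iterable[str]) -> ScenarioSpec:
    return ScenarioSpec(name=name, edges=frozenset(edges))


#: Registry of the eight study scenarios, addressable by name.
SCENARIOS: dict[str, ScenarioSpec] = {
    "basic1": _spec("basic1", []),
    "basic2": _spec("basic2", ["ICS->GA"]),
    "basic3": _spec("basic3", ["ICS->BW"]),
    "basic4": _spec("basic4", ["ICS->GA", "ICS->BW"]),
    "conf1": _spec("conf1", ["V->ICS", "V->GA", "ICS->GA"]),
    "conf2": _spec("conf2", ["V->GA", "V->BW", "ICS->GA"]),
    "conf3": _spec("conf3", ["V->ICS", "V->BW", "ICS->GA"]),
    "conf4": _spec("conf4", ["V->ICS", "V->GA", "V->BW", "ICS->GA"]),
}


def get_scenario(name: str) -> ScenarioSpec:
    try:
        return SCENARIOS[name]
    except KeyError:
        valid = ", ".join(SCENARIOS)
        raise KeyError(f"unknown scenario {name!r}; valid names: {valid}") from None


@dataclass(frozen=True)
class Variant:
    """Which reference model generates BW: mean form x error structure."""

    mean_form: str = "linear"  # linear | cubic
    error_kind: str = "homoskedastic"  # homoskedastic | ga_specific
    ga_dist: GADistribution = field(default_factory=make_default_ga_distribution)

    def __post_init__(self) -> None:
        if self.mean_form not in ("linear", "cubic"):
            raise ValueError(f"unknown mean form {self.mean_form!r}")
        if self.error_kind not in ("homoskedastic", "ga_specific"):
            raise ValueError(f"unknown error kind {self.error_kind!r}")

    @property
    def label(self) -> str:
        return f"{self.mean_form}+{'homo' if self.error_kind == 'homoskedastic' else 'het'}"

    def mean_model(self, beta_ics: float = 0.0, beta_v: float = 0.0) -> BWMeanModel:
        if self.mean_form == "linear":
            return BWMeanModel.linear_default(beta_ics, beta_v)
        return BWMeanModel.cubic_default(beta_ics, beta_v)

    def error_model(self) -> ErrorModel:
        if self.error_kind == "homoskedastic":
            return ErrorModel.homoskedastic()
        return ErrorModel.ga_specific()


def sample_confounder(n: int) -> np.ndarray:
    """Deterministic half/half confounder assignment: first n/2 have V=0."""
    if n % 2 != 0:
        raise ValueError(f"confounding scenarios need an even sample size, got {n}")
    return np.repeat([0, 1], n // 2).astype(np.int8)


def sample_exposure(v: np.ndarray, spec: ScenarioSpec, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli exposure draws at the V-conditional probability."""
    p1, p0 = spec.p_exposure_given_v
    p = np.where(np.asarray(v) == 1, p1, p0)
    return (rng.random(len(p)) < p).astype(np.int8)


def sample_base_ga(
    n: int,
    dist: GADistribution,
    rng: np.random.Generator,
    v: np.ndarray | None = None,
) -> np.ndarray:
    """Base GA draws before any shift.

    Without a confounder, n i.i.d. draws. With one, only the V=0 half is
    drawn and the V=1 half receives copies of those draws — a shared-base
    variance-reduction pairing that leaves expectations untouched. Requires
    the half/half V layout produced by :func:`sample_confounder`.
    """
    if v is None:
        return rng.choice(dist.weeks, size=n, p=dist.probs).astype(np.int16)
    v = np.asarray(v)
    half = n // 2
    if n % 2 or not (np.all(v[:half] == 0) and np.all(v[half:] == 1)):
        raise ValueError("paired base-GA sampling requires the half/half V layout")
    base_half = rng.choice(dist.weeks, size=half, p=dist.probs).astype(np.int16)
    return np.concatenate([base_half, base_half])


def apply_ga_shifts(
    base_ga: np.ndarray, v: np.ndarray, ics: np.ndarray, spec: ScenarioSpec
) -> np.ndarray:
    """Final GA = base + shift_v * v + shift_ics * ics (no clipping)."""
    return (
        np.asarray(base_ga)
        + spec.ga_shift_v * np.asarray(v)
        + spec.ga_shift_ics * np.asarray(ics)
    ).astype(np.int16)


def generate_bw(
    ga: np.ndarray,
    ics: np.ndarray,
    v: np.ndarray,
    model: BWMeanModel,
    err: ErrorModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Independent Normal(mean_bw, sd_bw) birth-weight draws in grams."""
    mu = mean_bw(ga, ics, v, model)
    sigma = sd_bw(ga, err)
    return mu + sigma * rng.standard_normal(len(np.asarray(ga)))


def _threshold_lookup(model: BWMeanModel, err: ErrorModel) -> np.ndarray:
    """SGA thresholds for every reachable week, indexed by week - 22."""
    weeks = np.arange(GA_SHIFTED_MIN, GA_SUPPORT_MAX + 1)
    return np.asarray(sga_threshold(weeks, model, err))


def simulate_cohort(
    spec: ScenarioSpec | str,
    variant: Variant | None = None,
    n: int = 20_000,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Simulate one cohort of ``n`` babies under a scenario.

    Composes the generation steps in causal order — V, ICS, base GA, GA
    shifts, BW, then the derived LBW/SGA indicators — and is reproducible
    for a fixed seed.
    """
    if isinstance(spec, str):
        spec = get_scenario(spec)
    variant = variant or Variant()
    seed_seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(seed_seq)

    if spec.has_confounder:
        v = sample_confounder(n)
        ics = sample_exposure(v, spec, rng)
        base_ga = sample_base_ga(n, variant.ga_dist, rng, v=v)
    else:
        v = np.zeros(n, dtype=np.int8)
        ics = sample_exposure(v, spec, rng)
        base_ga = sample_base_ga(n, variant.ga_dist, rng)

    ga = apply_ga_shifts(base_ga, v, ics, spec)
    model = variant.mean_model(spec.beta_ics, spec.beta_v)
    err = variant.error_model()
    bw = generate_bw(ga, ics, v, model, err, rng)

    thresholds = _threshold_lookup(model, err)[ga - GA_SHIFTED_MIN]
    cohort = pd.DataFrame(
        {
            "v": v,
            "ics": ics,
            "ga": ga,
            "bw": bw,
            "lbw": (bw < LBW_CUTOFF).astype(np.int8),
            "sga": (bw < thresholds).astype(np.int8),
        }
    )
    cohort.attrs.update(
        scenario=spec.name, variant=variant.label, n=n, seed=repr(seed_seq)
    )
    return cohort


def save_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Dump a cohort to a flat CSV (header: v,ics,ga,bw,lbw,sga)."""
    cohort.to_csv(path, index=False)


def load_cohort(path: str | Path) -> pd.DataFrame:
    cohort = pd.read_csv(path)
    expected = ["v", "ics", "ga", "bw", "lbw", "sga"]
    if list(cohort.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(cohort.columns)}")
    return cohort
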