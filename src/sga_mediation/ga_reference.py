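"""Reference birth-weight-given-gestational-age model.

This module holds the three ingredients shared by every simulation scenario:

* the base distribution of gestational age (GA) at delivery, a multinomial
  over integer weeks 26..43;
* the reference mean birth weight (BW) as a function of GA — linear by
  default, with an optional cubic form for the nonlinearity sensitivity
  analyses — plus direct-effect terms for the exposure (ICS) and the
  confounder (V);
* the error model for BW around that mean — a constant SD by default, with
  an optional GA-specific SD for the heteroskedasticity sensitivity analyses.

The same reference model is used twice: to *generate* BW, and to *construct*
the small-for-gestational-age (SGA) indicator, defined as BW below the 10th
percentile of the reference BW distribution conditional on GA (with the
direct-effect terms zeroed, so a common threshold applies to every baby born
at the same GA).

The published study drew its GA probabilities and per-week SDs from an
external perinatal reference table that is not reproduced here; this module
ships documented synthetic stand-ins (a discretized normal over 26..43, and
a linear-in-GA SD through the two published anchor weeks) that can be
overridden from a JSON/YAML file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "GA_SUPPORT_MIN",
    "GA_SUPPORT_MAX",
    "GA_SHIFTED_MIN",
    "SGA_QUANTILE",
    "Z_SGA",
    "GADistribution",
    "BWMeanModel",
    "ErrorModel",
    "make_default_ga_distribution",
    "load_ga_distribution",
    "load_error_model",
    "mean_bw",
    "sd_bw",
    "sga_threshold",
]

#: Support of the base GA distribution (integer weeks, inclusive).
GA_SUPPORT_MIN = 26
GA_SUPPORT_MAX = 43
#: Lowest GA reachable after the two −2-week shifts (no clipping is applied).
GA_SHIFTED_MIN = 22

#: SGA is defined at the 10th percentile of the conditional BW distribution.
SGA_QUANTILE = 0.10
#: Standard-normal 0.10 quantile, z ≈ −1.2815516.
Z_SGA = float(stats.norm.ppf(SGA_QUANTILE))

# Defaults of the published reference fits (grams / grams-per-week-power).
LINEAR_COEFFS = (-3703.3, 183.25)
CUBIC_COEFFS = (29415.0, -2922.4, 94.46, -0.9378)
SIGMA_CONST = 333.82
# Published GA-specific SD anchors: (week, grams).
SD_ANCHORS = ((28, 241.00), (40, 447.00))


@dataclass(frozen=True)
class GADistribution:
    """Multinomial distribution of GA at delivery over integer weeks 26..43."""

    weeks: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        weeks = np.asarray(self.weeks, dtype=int)
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "weeks", weeks)
        object.__setattr__(self, "probs", probs)
        expected = np.arange(GA_SUPPORT_MIN, GA_SUPPORT_MAX + 1)
        if not np.array_equal(weeks, expected):
            raise ValueError(
                f"GA support must be the integers {GA_SUPPORT_MIN}..{GA_SUPPORT_MAX}"
            )
        if np.any(probs < 0):
            raise ValueError("GA probabilities must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("GA probabilities must sum to 1 within 1e-12")

    @classmethod
    def from_mapping(cls, mapping: Mapping[int | str, float]) -> "GADistribution":
        """Build from a {week: probability} mapping; renormalizes weights."""
        weeks = np.arange(GA_SUPPORT_MIN, GA_SUPPORT_MAX + 1)
        probs = np.zeros_like(weeks, dtype=float)
        for key, value in mapping.items():
            week = int(key)
            if not GA_SUPPORT_MIN <= week <= GA_SUPPORT_MAX:
                raise ValueError(f"week {week} outside support 26..43")
            probs[week - GA_SUPPORT_MIN] = float(value)
        total = probs.sum()
        if total <= 0:
            raise ValueError("GA weights must have a positive sum")
        return cls(weeks=weeks, probs=probs / total)


def make_default_ga_distribution() -> GADistribution:
    """Default stand-in for the (unpublished) reference GA distribution.

    Probabilities are proportional to a Normal(39.5, 2.0^2) density evaluated
    at integer weeks 26..43, renormalized — a unimodal, term-heavy shape with
    mode at 40 weeks. Override with :func:`load_ga_distribution` to use an
    empirical table.
    """
    weeks = np.arange(GA_SUPPORT_MIN, GA_SUPPORT_MAX + 1)
    density = stats.norm.pdf(weeks, loc=39.5, scale=2.0)
    return GADistribution(weeks=weeks, probs=density / density.sum())


def load_ga_distribution(path: str | Path) -> GADistribution:
    """Load a GA distribution from a JSON or YAML file.

    The file must contain a top-level ``ga_probs`` mapping week -> weight
    (weights are renormalized), e.g. ``{"ga_probs": {"26": 0.001, ...}}``.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict) or "ga_probs" not in data:
        raise ValueError(f"{path}: expected a mapping with a 'ga_probs' key")
    return GADistribution.from_mapping(data["ga_probs"])


def load_error_model(path: str | Path) -> "ErrorModel":
    """Load a GA-specific error model from a JSON/YAML ``sigma_by_week`` table."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict) or "sigma_by_week" not in data:
        raise ValueError(f"{path}: expected a mapping with a 'sigma_by_week' key")
    return ErrorModel.ga_specific(
        {int(k): float(v) for k, v in data["sigma_by_week"].items()}
    )


@dataclass(frozen=True)
class BWMeanModel:
    """Polynomial-in-GA mean birth weight plus direct-effect terms.

    mu_BW(GA, ICS, V) = poly(GA) + beta_ics * ICS + beta_v * V, with poly
    either the linear or the cubic reference fit. beta_ics / beta_v are the
    direct effects on BW in grams (0 or −100 in the study scenarios).
    """

    form: str = "linear"
    coefficients: tuple[float, ...] = LINEAR_COEFFS
    beta_ics: float = 0.0
    beta_v: float = 0.0

    def __post_init__(self) -> None:
        if self.form not in ("linear", "cubic"):
            raise ValueError(f"unknown mean form {self.form!r}")
        expected_len = 2 if self.form == "linear" else 4
        if len(self.coefficients) != expected_len:
            raise ValueError(
                f"{self.form} mean model needs {expected_len} coefficients, "
                f"got {len(self.coefficients)}"
            )

    @classmethod
    def linear_default(cls, beta_ics: float = 0.0, beta_v: float = 0.0) -> "BWMeanModel":
        return cls("linear", LINEAR_COEFFS, beta_ics, beta_v)

    @classmethod
    def cubic_default(cls, beta_ics: float = 0.0, beta_v: float = 0.0) -> "BWMeanModel":
        return cls("cubic", CUBIC_COEFFS, beta_ics, beta_v)

    def reference_mean(self, ga) -> np.ndarray | float:
        """Polynomial part of the mean (ICS and V terms zeroed)."""
        ga = np.asarray(ga, dtype=float)
        # np.polynomial convention: coefficients in increasing powers of GA
        return np.polynomial.polynomial.polyval(ga, self.coefficients)


def _check_binary(name: str, value) -> None:
    arr = np.asarray(value)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary 0/1, got {value!r}")


def mean_bw(ga, ics, v, model: BWMeanModel) -> np.ndarray | float:
    """Mean BW in grams at GA (weeks) for exposure ics and confounder v."""
    _check_binary("ics", ics)
    _check_binary("v", v)
    ga_arr = np.asarray(ga)
    if np.any(ga_arr < GA_SHIFTED_MIN) or np.any(ga_arr > GA_SUPPORT_MAX):
        raise ValueError(f"GA outside supported range {GA_SHIFTED_MIN}..{GA_SUPPORT_MAX}")
    out = (
        model.reference_mean(ga)
        + model.beta_ics * np.asarray(ics, dtype=float)
        + model.beta_v * np.asarray(v, dtype=float)
    )
    return float(out) if np.isscalar(ga) and out.ndim == 0 else out


def _interpolate_sd(weeks: np.ndarray, anchors) -> np.ndarray:
    """Linear-in-GA SD through the anchor weeks, extrapolated to 22..43."""
    xs = np.array([a[0] for a in anchors], dtype=float)
    ys = np.array([a[1] for a in anchors], dtype=float)
    slope = (ys[-1] - ys[0]) / (xs[-1] - xs[0])
    return ys[0] + slope * (weeks - xs[0])


@dataclass(frozen=True)
class ErrorModel:
    """BW error model: constant SD, or a GA-specific SD per integer week.

    The GA-specific table defaults to a linear interpolation through the two
    published anchor weeks (28 -> 241.00 g, 40 -> 447.00 g), extrapolated
    over the full reachable range 22..43 — a documented stand-in for the
    unpublished per-week reference values.
    """

    kind: str = "homoskedastic"
    sigma_const: float = SIGMA_CONST
    sigma_by_week: Mapping[int, float] | None = None
    _table: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ("homoskedastic", "ga_specific"):
            raise ValueError(f"unknown error model kind {self.kind!r}")
        if self.kind == "homoskedastic":
            if self.sigma_const <= 0:
                raise ValueError("sigma_const must be strictly positive")
            object.__setattr__(self, "_table", {})
            return
        if self.sigma_by_week is None:
            weeks = np.arange(GA_SHIFTED_MIN, GA_SUPPORT_MAX + 1)
            table = dict(zip(weeks.tolist(), _interpolate_sd(weeks, SD_ANCHORS)))
        else:
            table = {int(k): float(val) for k, val in self.sigma_by_week.items()}
        if any(s <= 0 for s in table.values()):
            raise ValueError("all GA-specific SDs must be strictly positive")
        object.__setattr__(self, "_table", table)

    @classmethod
    def homoskedastic(cls, sigma: float = SIGMA_CONST) -> "ErrorModel":
        return cls(kind="homoskedastic", sigma_const=sigma)

    @classmethod
    def ga_specific(cls, sigma_by_week: Mapping[int, float] | None = None) -> "ErrorModel":
        return cls(kind="ga_specific", sigma_by_week=sigma_by_week)


def sd_bw(ga, err: ErrorModel) -> np.ndarray | float:
    """BW error SD in grams at GA (weeks)."""
    ga_arr = np.asarray(ga)
    if np.any(ga_arr < GA_SHIFTED_MIN) or np.any(ga_arr > GA_SUPPORT_MAX):
        raise ValueError(f"GA outside supported range {GA_SHIFTED_MIN}..{GA_SUPPORT_MAX}")
    if err.kind == "homoskedastic":
        return err.sigma_const if np.isscalar(ga) else np.full(ga_arr.shape, err.sigma_const)
    try:
        if np.isscalar(ga):
            return err._table[int(ga)]
        return np.array([err._table[int(g)] for g in ga_arr.ravel()]).reshape(ga_arr.shape)
    except KeyError as exc:
        raise ValueError(f"no SD configured for GA week {exc.args[0]}") from exc


def sga_threshold(ga, model: BWMeanModel, err: ErrorModel) -> np.ndarray | float:
    """BW cut-off below which a baby born at ``ga`` weeks is SGA.

    The 0.10 quantile of Normal(reference mean at ga, sd at ga), computed
    from the *reference* (unexposed, V = 0) mean so the same threshold
    applies to exposed and unexposed babies at the same GA. The comparison
    convention is strict: BW exactly equal to the threshold is not SGA.
    """
    mu = mean_bw(ga, 0, 0, model)
    return mu + Z_SGA * sd_bw(ga, err)
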