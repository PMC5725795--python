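"""Closed-form expectations and graph-based bias flags.

Under the linear homoskedastic data-generating process every regression in
the battery has a closed-form large-sample ICS coefficient, obtainable by
linear projection of the structural equations

    GA = G0 + a_V V + a_I ICS,      BW = c + b_G GA + b_I ICS + b_V V + eps

onto the model's covariates. The projection is solved *symbolically* with
the base-GA variance Var(G0) left as a free symbol: if the symbol cancels,
the expectation is independent of the (unpublished) reference GA
distribution and the oracle emits a number; if it survives, the quantity is
distribution-dependent and the oracle refuses to guess. The same logic
applies to the SGA log odds ratios, which are GA-distribution-free because
the SGA indicator depends only on the BW residual about the GA-specific
reference mean: P(SGA=1 | ICS, V) = Phi(z_0.10 − (b_I ICS + b_V V)/sigma).

The bias flags are derived from the scenario DAG by d-separation
(networkx): a total-effect model is unbiased iff the adjustment set blocks
every back-door path; a GA-adjusted direct-effect model is checked with GA
in the conditioning set, which correctly *opens* the collider
ICS -> GA <- V -> BW; an SGA model is checked against a derived SGA node
whose parents are the direct (non-GA) determinants of BW, reflecting the
residual construction above — this is why SGA is immune to the GA collider.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import sympy
from scipy import stats

from .ga_reference import SIGMA_CONST, Z_SGA
from .scenarios import DIRECT_EFFECT, GA_SHIFT, SCENARIOS, ScenarioSpec, get_scenario
from .estimators import MODEL_SPECS

__all__ = [
    "OracleResult",
    "VMixing",
    "confounding_weight",
    "expected_bw_coefficient",
    "expected_sga_log_or",
    "expected_coefficient",
    "bias_flag",
    "oracle_table",
]

BETA_GA = 183.25  # grams per week, linear reference slope
P_V = 0.5  # confounder prevalence (deterministic half/half)


@dataclass(frozen=True)
class OracleResult:
    """A closed-form expectation, or an explicit refusal to provide one."""

    quantity: str
    value: float | None
    assumptions: str
    distribution_independent: bool

    def __post_init__(self) -> None:
        if self.distribution_independent and self.value is None:
            raise ValueError("a distribution-independent result must carry a value")


def confounding_weight(p1: float, p0: float, pv: float = P_V) -> float:
    """OLS coefficient of V regressed on ICS: cov(V, ICS) / var(ICS).

    This is the weight with which V's association with the outcome leaks
    into an ICS coefficient that fails to adjust for V.
    """
    for name, p in (("p1", p1), ("p0", p0), ("pv", pv)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be a probability, got {p}")
    m = pv * p1 + (1 - pv) * p0
    var_ics = m * (1 - m)
    if var_ics == 0:
        raise ValueError("degenerate exposure: var(ICS) = 0")
    cov = pv * (1 - pv) * (p1 - p0)
    return cov / var_ics


def _rat(x: float) -> sympy.Rational:
    return sympy.Rational(str(x))


def _projection_beta_ics(spec: ScenarioSpec, covariates: tuple[str, ...]) -> sympy.Expr:
    """Symbolic large-sample ICS coefficient of BW on the covariates."""
    s2 = sympy.Symbol("s2", positive=True)  # Var(G0), unknown
    p1, p0 = (_rat(p) for p in spec.p_exposure_given_v)
    pv = _rat(P_V) if spec.has_confounder else sympy.Integer(0)
    a_v, a_i = sympy.Integer(spec.ga_shift_v), sympy.Integer(spec.ga_shift_ics)
    b_g, b_i, b_v = _rat(BETA_GA), _rat(spec.beta_ics), _rat(spec.beta_v)

    m = pv * p1 + (1 - pv) * p0
    var_v = pv * (1 - pv)
    var_i = m * (1 - m)
    cov_vi = pv * (1 - pv) * (p1 - p0)

    cov = {
        ("v", "v"): var_v,
        ("v", "ics"): cov_vi,
        ("ics", "ics"): var_i,
        ("ga", "ics"): a_v * cov_vi + a_i * var_i,
        ("ga", "v"): a_v * var_v + a_i * cov_vi,
        ("ga", "ga"): s2 + a_v**2 * var_v + a_i**2 * var_i + 2 * a_v * a_i * cov_vi,
    }

    def c(x: str, y: str) -> sympy.Expr:
        return cov.get((x, y), cov.get((y, x)))

    def c_bw(x: str) -> sympy.Expr:
        return b_g * c("ga", x) + b_i * c("ics", x) + b_v * c("v", x)

    sigma = sympy.Matrix([[c(a, b) for b in covariates] for a in covariates])
    rhs = sympy.Matrix([c_bw(a) for a in covariates])
    beta = sigma.solve(rhs)
    return sympy.simplify(beta[covariates.index("ics")])


def expected_bw_coefficient(spec: ScenarioSpec | str, model: str) -> OracleResult:
    """Large-sample ICS coefficient of a linear BW model (grams).

    Valid for the linear-mean, homoskedastic variant. Returns a flagged
    non-numeric result when the value depends on the base GA distribution's
    variance (e.g. the collider bias of M2 in the GA–BW confounding
    scenario), rather than guessing.
    """
    if isinstance(spec, str):
        spec = get_scenario(spec)
    mspec = MODEL_SPECS[model]
    if mspec.family != "linear":
        raise ValueError(f"{model} is not a linear BW model")
    if "v" in mspec.covariates and not spec.has_confounder:
        raise ValueError(f"{model} adjusts for V but scenario {spec.name} has no V node")
    covariates = tuple(cov for cov in mspec.covariates if cov in ("ics", "ga", "v"))
    if covariates != mspec.covariates:
        raise ValueError(f"{model}: polynomial GA terms are outside the linear oracle")
    expr = _projection_beta_ics(spec, covariates)
    assumptions = "linear mean, homoskedastic errors, scenario edges"
    if expr.free_symbols:
        return OracleResult(
            quantity=f"{spec.name}:{model}",
            value=None,
            assumptions=assumptions + "; depends on Var(GA)",
            distribution_independent=False,
        )
    return OracleResult(
        quantity=f"{spec.name}:{model}",
        value=float(expr),
        assumptions=assumptions,
        distribution_independent=True,
    )


@dataclass(frozen=True)
class VMixing:
    """V's direct BW effect and its exposure-conditional distribution."""

    beta_v: float
    p_v_given_exposed: float
    p_v_given_unexposed: float


def _p_sga(direct_bw_effect: float, beta_v: float, v: int, sigma: float) -> float:
    # BW < mu_ref(GA) + z*sigma  <=>  eps/sigma < z - (effects)/sigma
    return float(stats.norm.cdf(Z_SGA - (direct_bw_effect + beta_v * v) / sigma))


def expected_sga_log_or(
    direct_bw_effect: float,
    sigma: float = SIGMA_CONST,
    mixing: VMixing | None = None,
) -> float:
    """Large-sample ICS log odds ratio of the marginal SGA model.

    Per (ICS, V) stratum, P(SGA=1) = Phi(z_0.10 − (b_I ICS + b_V V)/sigma);
    when V directly affects BW the stratum probabilities are mixed over the
    exposure-conditional V distribution. Valid under homoskedastic errors —
    with GA-specific SDs the quantity depends on the GA distribution and is
    not offered here.
    """
    if sigma <= 0:
        raise ValueError("sigma must be strictly positive")
    if mixing is None:
        p_exposed = _p_sga(direct_bw_effect, 0.0, 0, sigma)
        p_unexposed = _p_sga(0.0, 0.0, 0, sigma)
    else:
        w1, w0 = mixing.p_v_given_exposed, mixing.p_v_given_unexposed
        p_exposed = w1 * _p_sga(direct_bw_effect, mixing.beta_v, 1, sigma) + (
            1 - w1
        ) * _p_sga(direct_bw_effect, mixing.beta_v, 0, sigma)
        p_unexposed = w0 * _p_sga(0.0, mixing.beta_v, 1, sigma) + (1 - w0) * _p_sga(
            0.0, mixing.beta_v, 0, sigma
        )
    logit = lambda p: np.log(p / (1 - p))  # noqa: E731
    return float(logit(p_exposed) - logit(p_unexposed))


def _scenario_mixing(spec: ScenarioSpec) -> VMixing | None:
    if spec.beta_v == 0.0:
        return None
    p1, p0 = spec.p_exposure_given_v
    m = P_V * p1 + (1 - P_V) * p0
    return VMixing(
        beta_v=spec.beta_v,
        p_v_given_exposed=P_V * p1 / m,
        p_v_given_unexposed=P_V * (1 - p1) / (1 - m),
    )


def expected_coefficient(spec: ScenarioSpec | str, model: str) -> OracleResult:
    """Oracle expectation for any model of the battery (or a flagged refusal).

    Linear BW models go through the symbolic projection; SGA models through
    the normal-CDF closed form (V-adjusted SGA models in the fully mediated
    confounding scenarios have a zero conditional effect); LBW models are
    always GA-distribution-dependent and are refused.
    """
    if isinstance(spec, str):
        spec = get_scenario(spec)
    mspec = MODEL_SPECS[model]
    assumptions = "linear mean, homoskedastic errors, scenario edges"
    if mspec.family == "linear":
        return expected_bw_coefficient(spec, model)
    if mspec.outcome == "lbw":
        return OracleResult(
            quantity=f"{spec.name}:{model}",
            value=None,
            assumptions=assumptions + "; LBW rates depend on the GA distribution",
            distribution_independent=False,
        )
    # SGA models
    if "v" in mspec.covariates:
        if spec.beta_ics != 0.0:
            raise ValueError("V-adjusted SGA oracle only covers fully mediated scenarios")
        value = 0.0
    else:
        value = expected_sga_log_or(spec.beta_ics, SIGMA_CONST, _scenario_mixing(spec))
    return OracleResult(
        quantity=f"{spec.name}:{model}",
        value=value,
        assumptions=assumptions,
        distribution_independent=True,
    )


def _scenario_graph(spec: ScenarioSpec) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(["ICS", "GA", "BW"])
    g.add_edge("GA", "BW")
    for edge in spec.edges:
        src, dst = edge.split("->")
        g.add_edge(src, dst)
    return g


def bias_flag(spec: ScenarioSpec | str, model: str) -> str:
    """'biased' or 'unbiased': does the model identify its target effect?

    Total-effect models (M1/M3 classes): biased iff the adjustment set fails
    to d-separate ICS from BW once ICS's outgoing edges are removed (an open
    back-door path). Direct-effect BW models (M2 class): biased iff ICS and
    BW remain d-connected given {GA} ∪ adjustments after deleting the direct
    ICS -> BW edge — conditioning on GA is part of the model, so the GA
    collider is correctly opened. SGA models (M4 class): checked against a
    derived SGA node whose parents are BW's direct non-GA determinants.
    """
    if isinstance(spec, str):
        spec = get_scenario(spec)
    if model not in MODEL_SPECS:
        raise ValueError(f"unknown model name {model!r}")
    mspec = MODEL_SPECS[model]
    g = _scenario_graph(spec)
    adjust = {"V"} if "v" in mspec.covariates else set()
    if adjust and "V" not in g:
        raise ValueError(f"{model} adjusts for V but scenario {spec.name} has no V node")

    if mspec.outcome in ("bw", "lbw"):
        target = "total" if "ga" not in mspec.covariates else "direct"
        if target == "total":
            back_door = g.copy()
            back_door.remove_edges_from(list(g.out_edges("ICS")))
            separated = nx.is_d_separator(back_door, {"ICS"}, {"BW"}, adjust)
        else:
            direct = g.copy()
            if direct.has_edge("ICS", "BW"):
                direct.remove_edge("ICS", "BW")
            separated = nx.is_d_separator(direct, {"ICS"}, {"BW"}, adjust | {"GA"})
        return "unbiased" if separated else "biased"

    # SGA: a function of the BW residual about the GA-specific reference
    # mean, so its structural parents are BW's direct non-GA parents.
    g_sga = g.copy()
    g_sga.add_node("SGA")
    for parent in g.predecessors("BW"):
        if parent != "GA":
            g_sga.add_edge(parent, "SGA")
    if g_sga.has_edge("ICS", "SGA"):
        g_sga.remove_edge("ICS", "SGA")
    separated = nx.is_d_separator(g_sga, {"ICS"}, {"SGA"}, adjust)
    return "unbiased" if separated else "biased"


def oracle_table(scenario_names: list[str] | None = None) -> pd.DataFrame:
    """Expected-coefficient table for side-by-side comparison with MC output."""
    from .estimators import model_battery  # battery order matches the tables

    names = scenario_names or list(SCENARIOS)
    rows = []
    for name in names:
        spec = get_scenario(name)
        for mspec in model_battery(spec):
            result = expected_coefficient(spec, mspec.name)
            rows.append(
                {
                    "scenario": name,
                    "model": mspec.name,
                    "expected": result.value,
                    "distribution_independent": result.distribution_independent,
                    "bias_flag": bias_flag(spec, mspec.name),
                }
            )
    return pd.DataFrame(rows)
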