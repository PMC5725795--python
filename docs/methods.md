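# Methods

## Data-generating processes

Every scenario is a DAG over {V, ICS, GA, BW} with GA → BW always present,
translated literally into a structural simulation executed in causal order:

1. **Confounder.** In the confounding scenarios, V is assigned
   deterministically: the first n/2 records get V = 0, the last n/2 get
   V = 1 (not Bernoulli draws — the V margin is exact by design).
2. **Exposure.** ICS is Bernoulli with P(ICS=1|V=1) = 0.7 and
   P(ICS=1|V=0) = 0.3 when the V → ICS edge exists; 0.5 for everyone
   otherwise.
3. **Base GA.** Integer weeks drawn i.i.d. from the base multinomial on
   26..43. In confounding scenarios only the V = 0 half is drawn; the V = 1
   half receives copies of those draws. This pairing is a common-random-
   numbers variance-reduction device: the base-GA margin is identical across
   V strata by construction, and expectations are unaffected.
4. **GA shifts.** Final GA = base + (−2)·V·[V→GA] + (−2)·ICS·[ICS→GA]. No
   clipping is applied; the reachable support is therefore 22..43 and the
   reference mean/SD functions are simply evaluated at the shifted week.
5. **BW.** Independent draws from Normal(μ(GA) + β_ICS·ICS + β_V·V, σ(GA)²),
   with β_ICS, β_V ∈ {0, −100} g per the scenario's direct edges.
6. **Derived outcomes.** LBW = 1{BW < 2500 g}. SGA = 1{BW < t(GA)}, where
   t(g) is the exact normal 10th percentile of the *reference* conditional
   distribution: t(g) = μ(g) + z₀.₁₀·σ(g) with the ICS and V terms zeroed,
   z₀.₁₀ = Φ⁻¹(0.10) ≈ −1.281552. One threshold per GA week applies to every
   baby; the comparison is strict, so BW exactly at the threshold is not SGA.

Two sensitivity variants swap the reference ingredients while keeping
everything else (including the SGA construction, which always uses the same
mean/SD as generation): a **cubic mean**
μ(GA) = 29415 − 2922.4·GA + 94.46·GA² − 0.9378·GA³, and **GA-specific
error SDs** (below).

## Reference stand-ins and what they imply

The study's base GA distribution and its per-week SD vector come from an
external perinatal reference table that is not published with it. This
package uses documented synthetic stand-ins:

* **Base GA distribution** — probabilities proportional to a
  Normal(39.5, 2.0²) density at integer weeks 26..43, renormalized. The
  shape is unimodal and term-heavy, which is all the qualitative results
  need. Any other distribution can be supplied as a JSON/YAML
  `{"ga_probs": {week: weight}}` file (weights renormalized).
* **GA-specific SDs** — linear in GA through the two anchor values the study
  states (241.00 g at 28 weeks, 447.00 g at 40 weeks), extrapolated over
  22..43. Monotone increasing and strictly positive over the whole range.

Consequences, verified by the symbolic oracle below: every *basic*-scenario
BW expectation, the V-adjusted and correctly-GA-adjusted confounding cells,
the back-door-inflated M1 means, and all homoskedastic SGA log odds ratios
are independent of the base GA distribution — the package reproduces those
numerically. Cells whose value involves Var(GA) — all LBW odds ratios, the
GA-collider bias magnitude in the GA–BW confounding scenario, the residual
bias of a linear-GA adjustment under the cubic mean, and the small
heteroskedastic SGA deviations — differ under the stand-in and are checked
only for sign, significance, and elimination by the appropriate adjustment.
Passing tests therefore demonstrate the causal-structure conclusions, not
agreement with any particular perinatal reference population.

## Estimation

OLS for the BW models and Newton maximum-likelihood logistic regression for
LBW/SGA (statsmodels; score tolerance 1e-8, at most 100 iterations). The
polynomial models use raw GA powers, not an orthogonal basis — conditioning
is unproblematic with GA ≤ 43. A rank-deficient design (e.g. an all-exposed
cohort) raises immediately; logistic separation or non-convergence is
surfaced as a failed fit, dropped from the Monte-Carlo summary with its
count reported, and a failure rate above 1% aborts the summary rather than
bias the mean. At the study scale (n = 20,000, event rates ≥ 5%) failures do
not occur in practice.

## Monte-Carlo summaries

Per (scenario, model): mean of the replicate ICS coefficients, Monte-Carlo
SE = sd(estimates, unbiased denominator)/√reps, and a null flag set exactly
when 0 ∈ mean ± 1.96·SE. Defaults are the full study scale — 1000 replicates
of n = 20,000 — which runs in minutes on one CPU; reduced scales are
first-class parameters, and the acceptance tests use 200 replicates of
n = 20,000 (100–300 for the qualitative patterns) with tolerances widened to
the correspondingly larger Monte-Carlo SE.

Reproducibility: the master seed feeds `numpy.random.SeedSequence` with
spawn key (scenario index, replicate index), so each replicate of each
scenario has an independent documented substream and results are
bit-identical for a given master seed regardless of which subsets run.

## The analytic oracle

For the linear homoskedastic variant the large-sample ICS coefficient of any
BW model is a linear projection of the structural equations onto the model's
covariates. The projection is solved symbolically (sympy) with Var(GA₀) kept
as a free symbol: if it cancels, the cell is distribution-independent and the
oracle emits the number; if it survives, the oracle returns an explicitly
flagged non-result instead of a guess. Worked consequences: the fully
mediated total effect is (−2)(183.25) = −366.50 g; an unadjusted model adds
the confounding weight cov(V,ICS)/var(ICS) = 0.4 times V's non-ICS
association with BW (e.g. −366.5·1.4 = −513.1 g when V shifts GA, or
−366.5 − 40 = −406.5 g when V shifts BW); and the V-coefficient projection in
BW ~ ICS + GA under an ICS–BW confounder is (0.4, 0) whatever Var(GA₀), which
is why that collider-free direct-effect bias is exactly −40 g.

SGA cells have a separate closed form. Under homoskedastic errors,
SGA = 1{ε < z₀.₁₀σ − β_ICS·ICS − β_V·V}: the indicator depends only on the
BW residual, never on GA. Hence P(SGA=1|ICS,V) = Φ(z₀.₁₀ − (β_ICS·ICS +
β_V·V)/σ) per stratum, mixed over the exposure-conditional V distribution
for the marginal model. This yields exp(log OR) ≈ 1.7534 for a −100 g direct
effect and 0.2214 on the log scale for the exposure–BW confounding scenario.
Under GA-specific SDs the stratum probabilities vary with GA and the
quantity becomes distribution-dependent; the oracle refuses it.

## Bias flags

The "is this association confounded?" column is computed by d-separation
(networkx) on the scenario DAG:

* total-effect models (M1/M3 classes): biased iff the adjustment set fails
  to d-separate ICS from BW in the graph with ICS's outgoing edges removed
  (an open back-door path);
* direct-effect BW models (M2 class): GA joins the conditioning set and the
  direct ICS → BW edge is removed; conditioning on GA correctly *opens* the
  collider ICS → GA ← V → BW, which is what flags the GA–BW confounding
  scenario's M2;
* SGA models (M4 class): checked against a derived SGA node whose parents
  are BW's direct non-GA determinants — the graph encoding of the residual
  construction above. This is the structural reason SGA is immune to the GA
  collider while remaining susceptible to exposure–BW confounders, and it
  reproduces the full 32-entry published flag column.

The checker is written against the edge-list abstraction but is only
exercised (and only claimed correct) for this 3–4 node scenario family.

## Numerical and design choices

* Exact normal quantiles/CDF from scipy; z₀.₁₀ at full double precision.
* SGA thresholds are precomputed per integer week (22..43) and applied by
  lookup; generation is fully vectorized per cohort.
* Exposure probabilities, shifts and direct effects are derived from the
  scenario's edge set rather than stored, so a scenario cannot be internally
  inconsistent; an explicit override exists for exposure probabilities
  (used for limiting-case tests).
* Cohorts persist as flat CSV (`v,ics,ga,bw,lbw,sga`) — trivially auditable,
  and LBW/SGA are recomputable from (GA, BW) with zero mismatches.
* Table rendering mimics the study's mixed precision (two decimals for
  gram-scale means, four for log odds ratios); CSV output keeps full
  precision.

## Known limitations

* GA is integer-valued and sex-normalization of SGA is out of scope, as in
  the study design.
* Results involving the base GA distribution are stand-in-specific (see
  above); the package makes no claim of numerical agreement for them.
* The oracle covers the linear homoskedastic variant; cubic and
  heteroskedastic variants are validated by qualitative patterns only.
* Logistic "failure surfacing" is designed for transparency, not for
  small-sample work: at n in the hundreds with rare events, separation will
  be frequent and summaries will abort by design.
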