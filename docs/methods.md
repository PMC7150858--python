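# Methods

`dcewtp` analyzes forced-choice data from a discrete choice experiment (DCE)
on solid oral drug forms and estimates willingness to pay (WTP) for the
physical attributes of a medication. This note documents the model, the
synthetic data-generating process, the numerical choices, and the known
limitations.

## The choice model

Respondent *i* faces task *t* with two alternatives; alternative *j* is a
profile with dummy-coded attributes `X_ijt` (seven contrasts: long tablet,
capsule; medium, large; yellow, blue, red — against the base profile of a
small white round tablet) and a weekly copayment `c_ijt` in EUR (PLN × 0.25).
Utility is money-metric ("WTP space"):

    U_ijt = alpha_i * (X_ijt · beta_i − c_ijt) + eps_ijt

with i.i.d. standard Gumbel errors, so the choice probability is the logit

    P(j) = exp(alpha_i (X_ijt·beta_i − c_ijt)) / Σ_k exp(alpha_i (X_ikt·beta_i − c_ikt)).

`beta_i` is the individual's WTP vector in EUR per unit contrast;
`alpha_i > 0` converts EUR into utility. The population model is a mixed
(random-parameters) logit: `beta_i ~ Normal(wtp_mean, diag(wtp_sd²))` with
independent components, and `alpha_i ~ LogNormal(scale_mu, scale_sigma)` —
equivalently, the negative of the preference-space cost coefficient is
lognormal, guaranteeing cost lowers utility for every individual. WTP-space
and preference-space parameterizations of a fixed-coefficient model are
behaviorally equivalent (`b = alpha·beta`, `a = −alpha`), and the package
exposes both directions of that translation.

Simulating the mixing distribution directly in WTP space (normal WTPs,
lognormal scale) avoids the heavy-tailed ratio distributions that arise when
normal preference-space coefficients are divided by a normal cost
coefficient.

## Maximum simulated likelihood

The panel likelihood integrates over `(beta_i, alpha_i)`; there is no closed
form. Per respondent the integral is simulated:

    logL = Σ_i log (1/D) Σ_d Π_t P_it(beta_i^d, alpha_i^d)

with the product over the respondent's tasks *inside* the draw average
(coefficients are constant within person). Draws are scrambled Sobol points
mapped through the standard-normal inverse CDF — randomized quasi-Monte
Carlo, scrambling keyed by a seed; each respondent receives a distinct
contiguous block, aligned to the sorted respondent ids so the likelihood is
invariant to row order. A pseudo-random scheme is available as an
independent cross-check. The production default is D = 10,000 draws; desk
runs and the bundled experiments use D = 500, which on the fixtures agrees
with a 64-node Gauss–Hermite quadrature of the 1-D mixing integral to well
under 1e-3 at D = 10,000.

All probabilities are computed in log space with max-shift, the task product
as a sum of log probabilities, and the draw average via log-sum-exp, so the
T-fold product cannot underflow. The exponent of the lognormal scale is
clipped at ±40 to keep extreme optimizer trial points finite.

Estimation maximizes the simulated log-likelihood (scaled per respondent)
by L-BFGS-B with an analytic gradient (verified against finite differences
in the test suite); draws are fixed across iterations, making the objective
smooth and deterministic. Mixing SDs and `scale_sigma` are unconstrained
and reported as absolute values. Start values come from a conditional-logit
fit translated to WTP space: means `b/(-a)`, `scale_mu = log(-a)` (the
information is free, and starting the scale at its fixed-coefficient value
conditions the first iterations noticeably better than a neutral zero),
SDs at `0.1·|mean| + 0.05`, `scale_sigma = 0.1`. If the start-value logit
is singular (tiny or separated samples) the start falls back to zeros with
unit scale. Standard errors are the inverse of a central-finite-difference
Hessian of the analytic gradient at the optimum; a singular or indefinite
Hessian yields flagged (NaN) SEs rather than numbers. The convergence flag
is the optimizer's own success status, and the achieved gradient norm is
reported alongside.

The conditional logit itself — the SDs-equal-zero special case, also used as
an oracle — is fitted as a binary logit on attribute differences (exact for
two-alternative tasks) via statsmodels. The interaction model drops random
coefficients and instead interacts every contrast with female, centered age
in decades, and chronic-medication status, again as a plain logit on the
differenced design; it reports preference-space coefficients and translates
to WTP at chosen covariate values.

## Synthetic data generator

The generator emulates the survey conditions the analysis was designed for:
200 respondents; 16 forced binary tasks each (8 framed as chronic treatment,
8 as short-term treatment, presented interleaved in randomly ordered pairs);
profiles drawn from the full 3 × 3 × 4 × 4 factorial of form, size, color
and copayment (5/10/15/20 PLN); no opt-out. Ground-truth WTP distributions
default to the published per-scenario estimates (means and SDs of the seven
contrasts), with chronic and short-term parameters drawn independently,
mirroring the separately estimated per-scenario models. The published cost
row does not identify the scale distribution's parameters unambiguously, so
the default `scale_mu = 0, scale_sigma = 0.5` (median alpha of 1 utility/EUR)
is this package's neutral convention. Covariates match the reported sample:
female ~ Bernoulli(0.51), chronic medication ~ Bernoulli(0.515), and age
18 + LogNormal with median 48.8 years; the age spread is not reported, so
the shifted part uses a coefficient of variation of 0.3 — covariates only
feed the interaction model, and any 18+ distribution with the right median
serves that purpose. An optional covariate-effects hook shifts individual
WTP means linearly in the covariates, giving the interaction model a
recoverable ground truth.

Two deliberate design choices:

* **Per-respondent task sets.** The original survey showed everyone one
  fixed 16-task design, which is not printed and not recoverable. By default
  each synthetic respondent gets an independently randomized task set (all
  seeded); this is better for identification — with a single shared design
  the 16 parameters of the mixed logit lean on just 8 choice-situation
  contrasts per scenario — and the estimator must work for any valid design
  anyway. `shared_design=True` reproduces the single-design survey shape.
* **Diagonal heterogeneity.** WTP components are drawn independently; this
  is the minimal reading of "individual parameters follow specific
  distributions", and correlated mixing is out of scope for the estimator.

What the generator does **not** emulate: lexicographic or inattentive
responders, straight-lining, ordering/anchoring effects, opt-out behavior,
or a D-efficient experimental design. Passing recovery tests therefore show
that the estimator inverts its own data-generating process at realistic
sizes — not that the published survey estimates are correct, nor that real
respondents behave this cleanly.

## Scaled experiments and frozen sizes

The parameter-recovery experiment simulates 2,000 respondents × 8 chronic
tasks from the published chronic truth and fits with D = 500 scrambled Sobol
draws; every recovered mean is required to lie within 3 estimated SEs of its
generating value. The mean SEs at that size are ≈ 0.05–0.12 EUR, so the
experiment genuinely distinguishes the published means from zero and from
each other. Worked examples on the printed table (preferred configuration,
attribute importance, currency conversion) are exact arithmetic and run in
milliseconds.

## Result surface conventions

* **Preferred configuration**: exhaustive search over the 36 form × size ×
  color combinations, maximizing summed contrast means (base levels 0);
  ties break toward base levels. The total is a premium over the small
  white round tablet at equal copayment. For the chronic column this gives
  the small yellow capsule at 0.96 + 0.67 = 1.63 EUR (6.52 PLN). For the
  short-term column it gives the small yellow long tablet at 2.41 + 1.40 =
  3.81 EUR; the originally reported short-term headline total (3.61 EUR /
  14.44 PLN) cannot be reproduced from the printed coefficient table, and
  the package reports the table-derived 3.81 rather than forcing the
  headline number. Reported WTP is per week; no rescaling to per-month or
  per-course units is attempted.
* **Attribute importance**: the within-attribute range of mean WTP across
  levels (base at 0). No importance measure was published; under the range
  measure the short-term order is size > form > color, while the chronic
  order is size > color > form — the ranking object carries an explicit
  note whenever the blanket "size, form, color" ordering fails, rather than
  hiding the discrepancy.
* **Significance stars**: two-sided normal test of mean/SE at the 1% (***),
  5% (**) and 10% (*) levels.

## Degenerate inputs and numerical edges

* Exact utility ties in simulation resolve to the lower alternative index
  (Gumbel noise makes them measure-zero).
* A design column with no variation across alternatives makes the
  conditional logit singular and is rejected with the offending contrast
  named; degenerate covariates are rejected by the interaction model.
* `simulated_loglik` raises, naming the respondent, if any per-respondent
  likelihood is non-finite.
* Tiny samples (the 5-respondent fixture, the n=5 pipeline path) run end to
  end; their SEs are flagged unavailable when the Hessian is singular.
* The bundled fixture is generated with a low scale (`scale_mu = −0.7`) so
  its 20 observations do not separate the 8-parameter start-value logit.

## Limitations

* Correlated random parameters, latent-class and Bayesian variants are out
  of scope; so are D-efficient designs, blocking, and opt-out alternatives.
* Estimated mixing SDs near zero sit on a boundary: their SEs and stars
  should be read cautiously (the zero-heterogeneity tests assert a small
  likelihood-ratio against the conditional logit instead).
* With D draws fixed during optimization, results carry a small simulation
  bias of order 1/D; D = 500 is adequate at the bundled experiment sizes,
  and D = 10,000 is the production default.
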