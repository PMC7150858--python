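"""WTP-space mixed logit estimation by maximum simulated likelihood.

The model: respondent *i* chooses among the alternatives of task *t* with

    P(j) = exp(v_ijt) / sum_k exp(v_ikt),
    v_ijt = alpha_i * (X_ijt . beta_i - c_ijt),

where ``beta_i`` (EUR per contrast) is multivariate normal with independent
components and ``alpha_i`` (utility per EUR) is lognormal, so the negative
of the preference-space cost coefficient is lognormal.  The likelihood
integral over ``(beta_i, alpha_i)`` has no closed form; it is simulated by
averaging, per respondent, the product over that respondent's tasks of the
chosen alternative's probability across D draws — scrambled Sobol points
mapped through the standard-normal inverse CDF by default (pseudo-random
draws available as a cross-check).  The simulated log-likelihood

    logL = sum_i log (1/D) sum_d prod_t P_it(beta_i^d, alpha_i^d)

is maximized by L-BFGS-B with an analytic gradient; draws are held fixed
across iterations.  Mixing standard deviations and the lognormal sigma are
estimated unconstrained and reported as absolute values.  Standard errors
come from the inverse numerical Hessian at the optimum (finite differences
of the analytic gradient).

The fixed-coefficient conditional logit — the all-SDs-zero special case —
is fitted on the differenced two-alternative design via a binary logit
(statsmodels), and supplies start values and the degenerate-mixing oracle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy.special import logsumexp, ndtri
from scipy.stats import qmc

from .design import AttributeScheme, ChoiceDataset, PanelGroup, build_attribute_scheme

_ALPHA_EXP_CLIP = 40.0      # cap on |scale_mu + scale_sigma * w| before exp
_UNIF_EPS = 1e-12           # keep Sobol uniforms strictly inside (0, 1)


# ---------------------------------------------------------------------------
# Specs and results
# ---------------------------------------------------------------------------

@dataclass
class MXLSpec:
    """Estimation settings.

    ``random_attrs`` lists the contrasts with estimated mixing SDs (default:
    all seven); the scale is always random unless ``random_attrs`` is empty,
    in which case the model collapses to a reparameterized conditional logit.
    ``n_draws`` defaults to the survey analysis setting of 10,000 scrambled
    Sobol draws; desk-scale runs typically use 500.
    """

    random_attrs: tuple[str, ...] | None = None
    n_draws: int = 10_000
    draw_scheme: str = "scrambled_sobol"
    scramble_seed: int = 0
    maxiter: int = 1000
    gtol: float = 1e-6
    start_values: np.ndarray | None = None

    def __post_init__(self):
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.draw_scheme not in ("scrambled_sobol", "pseudo_random"):
            raise ValueError(f"unknown draw scheme {self.draw_scheme!r}")

    def resolve_random(self, scheme: AttributeScheme) -> tuple[str, ...]:
        if self.random_attrs is None:
            return scheme.contrast_names
        unknown = set(self.random_attrs) - set(scheme.contrast_names)
        if unknown:
            raise ValueError(f"unknown contrasts: {sorted(unknown)}")
        # preserve scheme column order
        return tuple(c for c in scheme.contrast_names if c in self.random_attrs)


@dataclass
class MXLParams:
    """Population hyperparameters of the WTP-space mixed logit."""

    wtp_mean: np.ndarray          # (K,)
    wtp_sd: np.ndarray            # (K,), zero for non-random contrasts
    scale_mu: float
    scale_sigma: float

    def __post_init__(self):
        self.wtp_mean = np.asarray(self.wtp_mean, dtype=float)
        self.wtp_sd = np.asarray(self.wtp_sd, dtype=float)


@dataclass
class MXLEstimate:
    """Fitted WTP-space mixed logit with uncertainty and fit metadata."""

    contrasts: tuple[str, ...]
    wtp_mean: np.ndarray
    wtp_mean_se: np.ndarray
    wtp_sd: np.ndarray            # absolute values; NaN SE for non-random
    wtp_sd_se: np.ndarray
    scale_mu: float
    scale_mu_se: float
    scale_sigma: float
    scale_sigma_se: float
    loglik: float
    start_loglik: float
    converged: bool
    message: str
    grad_norm: float
    n_respondents: int
    n_tasks_min: int
    n_tasks_max: int
    n_alternatives: int
    n_draws: int
    draw_scheme: str
    random_attrs: tuple[str, ...]

    def params(self) -> MXLParams:
        return MXLParams(self.wtp_mean.copy(), self.wtp_sd.copy(),
                         self.scale_mu, self.scale_sigma)

    def to_json(self, path=None) -> str:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
            elif isinstance(v, tuple):
                d[k] = list(v)
            elif isinstance(v, (np.floating, np.integer)):
                d[k] = v.item()
        s = json.dumps(d, indent=2, allow_nan=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_json(cls, path) -> "MXLEstimate":
        with open(path) as fh:
            d = json.load(fh)
        for k in ("wtp_mean", "wtp_mean_se", "wtp_sd", "wtp_sd_se"):
            d[k] = np.asarray(d[k], dtype=float)
        for k in ("contrasts", "random_attrs"):
            d[k] = tuple(d[k])
        return cls(**d)


# ---------------------------------------------------------------------------
# Probabilities and draws
# ---------------------------------------------------------------------------

def choice_probability(v: np.ndarray) -> np.ndarray:
    """Overflow-safe softmax over the last axis of a utility-index array."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] < 2:
        raise ValueError("need at least two alternatives")
    if not np.all(np.isfinite(v)):
        raise ValueError("utilities must be finite")
    shifted = v - v.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def make_draws(spec: MXLSpec, n_respondents: int,
               scheme: AttributeScheme | None = None) -> np.ndarray:
    """Standard-normal simulation draws, one block per respondent.

    Returns an ``(N, D, R + 1)`` array: R columns for the random WTP
    contrasts (in scheme column order) and a final column for the lognormal
    scale.  Scrambled Sobol points (one long sequence cut into contiguous
    per-respondent blocks, scrambling keyed by ``scramble_seed``) are mapped
    through the standard-normal inverse CDF; ``pseudo_random`` substitutes
    an ordinary generator for oracle comparisons.
    """
    scheme = scheme or build_attribute_scheme()
    dims = len(spec.resolve_random(scheme)) + 1
    D = spec.n_draws
    if spec.draw_scheme == "scrambled_sobol":
        engine = qmc.Sobol(d=dims, scramble=True, seed=spec.scramble_seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # non-power-of-two n
            u = engine.random(n_respondents * D)
        u = np.clip(u, _UNIF_EPS, 1 - _UNIF_EPS)
        z = ndtri(u)
    else:
        rng = np.random.default_rng(spec.scramble_seed)
        z = rng.standard_normal((n_respondents * D, dims))
    return z.reshape(n_respondents, D, dims)


# ---------------------------------------------------------------------------
# Simulated log-likelihood (with analytic gradient)
# ---------------------------------------------------------------------------

def _group_loglik(
    group: PanelGroup,
    draws: np.ndarray,
    mean: np.ndarray,
    sd_full: np.ndarray,
    mu: float,
    sig: float,
    random_idx: np.ndarray,
    want_grad: bool,
    chunk_cells: int = 4_000_000,
):
    """Sum of per-respondent simulated log-likelihoods for one panel group.

    Returns ``(loglik_vec, grad)`` where ``loglik_vec`` has one entry per
    respondent and ``grad`` (if requested) stacks derivatives with respect
    to ``(mean[K], sd[random], mu, sig)``.
    """
    n_all, T, A, K = group.X.shape
    D = draws.shape[1]
    R = len(random_idx)
    logD = np.log(D)

    ll = np.empty(n_all)
    grad = np.zeros(K + R + 2) if want_grad else None

    chunk = max(1, int(chunk_cells // max(D * T * A, 1)))
    for lo in range(0, n_all, chunk):
        hi = min(lo + chunk, n_all)
        n = hi - lo
        X = group.X[lo:hi]                       # (n,T,A,K)
        cost = group.cost_eur[lo:hi]             # (n,T,A)
        ch = group.chosen[lo:hi]                 # (n,T)
        Z = draws[group.draw_rows[lo:hi]]        # (n,D,R+1)

        beta = np.broadcast_to(mean, (n, D, K)).copy()
        if R:
            beta[:, :, random_idx] += sd_full[random_idx] * Z[:, :, :R]
        w = Z[:, :, R]                           # (n,D)
        ae = np.clip(mu + sig * w, -_ALPHA_EXP_CLIP, _ALPHA_EXP_CLIP)
        alpha = np.exp(ae)                       # (n,D)

        X2 = X.reshape(n, T * A, K)
        V0 = (X2 @ beta.transpose(0, 2, 1)).transpose(0, 2, 1)  # (n,D,TA)
        V0 = V0.reshape(n, D, T, A) - cost[:, None, :, :]
        v = alpha[:, :, None, None] * V0

        lse = logsumexp(v, axis=-1)              # (n,D,T)
        chb = np.broadcast_to(ch[:, None, :, None], (n, D, T, 1))
        vy = np.take_along_axis(v, chb, axis=3)[..., 0]
        logP = (vy - lse).sum(axis=2)            # (n,D)
        Li = logsumexp(logP, axis=1) - logD      # (n,)
        ll[lo:hi] = Li

        if want_grad:
            wts = np.exp(logP - Li[:, None] - logD)          # (n,D), rows sum to 1
            p = np.exp(v - lse[..., None])                   # (n,D,T,A)
            r = -p
            np.put_along_axis(r, chb, np.take_along_axis(r, chb, axis=3) + 1.0, axis=3)
            G_beta = alpha[:, :, None] * (r.reshape(n, D, T * A) @ X2)   # (n,D,K)
            G_alpha = (r * V0).sum(axis=(2, 3))                          # (n,D)
            wb = wts[:, :, None] * G_beta
            grad[:K] += wb.sum(axis=(0, 1))
            if R:
                grad[K:K + R] += (wb[:, :, random_idx] * Z[:, :, :R]).sum(axis=(0, 1))
            ga = wts * G_alpha * alpha
            grad[K + R] += ga.sum()
            grad[K + R + 1] += (ga * w).sum()

    return ll, grad


def _panel_loglik(groups, draws, params: MXLParams, random_idx, want_grad=False,
                  return_per_respondent=False):
    mean, sd, mu, sig = (params.wtp_mean, params.wtp_sd,
                         params.scale_mu, params.scale_sigma)
    total = 0.0
    K = mean.shape[0]
    R = len(random_idx)
    grad = np.zeros(K + R + 2) if want_grad else None
    per = []
    for g in groups:
        ll, gr = _group_loglik(g, draws, mean, sd, mu, sig, random_idx, want_grad)
        total += ll.sum()
        if want_grad:
            grad += gr
        if return_per_respondent:
            per.append((g.respondent_ids, ll))
    if return_per_respondent:
        return total, grad, per
    return total, grad


def simulated_loglik(
    dataset: ChoiceDataset,
    params: MXLParams,
    draws: np.ndarray,
    random_attrs: tuple[str, ...] | None = None,
    scenario: str | None = None,
) -> float:
    """Simulated panel log-likelihood of ``params`` given per-respondent draws.

    ``draws`` must be an ``(N, D, R + 1)`` block array aligned with the
    dataset's sorted respondent ids (see :func:`make_draws`).  A non-finite
    result raises, naming the offending respondent.
    """
    scheme = dataset.scheme
    random = (tuple(c for c in scheme.contrast_names if c in random_attrs)
              if random_attrs is not None else scheme.contrast_names)
    random_idx = np.array([scheme.contrast_names.index(c) for c in random], dtype=int)
    if draws.shape[0] != dataset.n_respondents:
        raise ValueError("draws must have one block per respondent")
    if draws.shape[2] != len(random_idx) + 1:
        raise ValueError("draw dimension must equal |random attrs| + 1")
    groups = dataset.to_panel(scenario)
    total, _, per = _panel_loglik(groups, draws, params, random_idx,
                                  return_per_respondent=True)
    if not np.isfinite(total):
        for rids, ll in per:
            bad = rids[~np.isfinite(ll)]
            if len(bad):
                raise FloatingPointError(
                    f"non-finite simulated likelihood for respondent {bad[0]!r}"
                )
        raise FloatingPointError("non-finite simulated log-likelihood")
    return float(total)


# ---------------------------------------------------------------------------
# Conditional logit (fixed coefficients)
# ---------------------------------------------------------------------------

@dataclass
class CLogitEstimate:
    """Preference-space conditional logit fit: 7 contrasts + cost."""

    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool


def _differenced_design(dataset: ChoiceDataset, scenario: str | None = None):
    groups = dataset.to_panel(scenario)
    Xd, cd, y = [], [], []
    for g in groups:
        Xd.append((g.X[:, :, 0, :] - g.X[:, :, 1, :]).reshape(-1, g.X.shape[-1]))
        cd.append((g.cost_eur[:, :, 0] - g.cost_eur[:, :, 1]).ravel())
        y.append((g.chosen == 0).astype(float).ravel())
    return np.vstack(Xd), np.concatenate(cd), np.concatenate(y)


def fit_conditional_logit(
    dataset: ChoiceDataset, scenario: str | None = None
) -> CLogitEstimate:
    """Fixed-coefficient multinomial logit on the dummy contrasts + cost.

    With two alternatives per task the conditional logit is exactly a binary
    logit on attribute-level differences, which is how it is fitted here.
    """
    scheme = dataset.scheme
    Xd, cd, y = _differenced_design(dataset, scenario)
    design = np.column_stack([Xd, cd])
    names = scheme.contrast_names + ("cost_eur",)
    degenerate = [names[j] for j in range(design.shape[1])
                  if np.ptp(design[:, j]) == 0]
    if degenerate:
        raise ValueError(
            f"singular design: no variation in {degenerate} across alternatives"
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as e:
        raise ValueError(f"conditional logit failed: {e}") from e
    return CLogitEstimate(
        names=names,
        coef=np.asarray(res.params, float),
        se=np.asarray(res.bse, float),
        loglik=float(res.llf),
        converged=bool(res.mle_retvals.get("converged", False)),
    )


def conditional_logit_loglik(
    dataset: ChoiceDataset, coef: np.ndarray, scenario: str | None = None
) -> float:
    """Analytic conditional-logit log-likelihood at ``coef`` (7 contrasts + cost)."""
    coef = np.asarray(coef, float)
    total = 0.0
    for g in dataset.to_panel(scenario):
        v = g.X @ coef[:-1] + coef[-1] * g.cost_eur          # (n,T,A)
        lse = logsumexp(v, axis=-1)
        vy = np.take_along_axis(v, g.chosen[:, :, None], axis=2)[..., 0]
        total += (vy - lse).sum()
    return float(total)


def preference_to_wtp(b: np.ndarray, a: float) -> tuple[np.ndarray, float]:
    """Translate preference-space ``(b, a)`` to WTP-space ``(beta, alpha)``.

    ``a`` is the utility-per-EUR cost coefficient and must be negative;
    ``alpha = -a`` and ``beta = b / alpha``.
    """
    if not a < 0:
        raise ValueError("cost coefficient must be negative (WTP undefined)")
    alpha = -float(a)
    return np.asarray(b, float) / alpha, alpha


def wtp_to_preference(beta: np.ndarray, alpha: float) -> tuple[np.ndarray, float]:
    """Inverse of :func:`preference_to_wtp`."""
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    return np.asarray(beta, float) * alpha, -float(alpha)


# ---------------------------------------------------------------------------
# Maximum simulated likelihood
# ---------------------------------------------------------------------------

def _pack(mean, sd_random, mu, sig):
    return np.concatenate([mean, sd_random, [mu, sig]])


def _unpack(theta, K, random_idx):
    R = len(random_idx)
    sd_full = np.zeros(K)
    sd_full[random_idx] = theta[K:K + R]
    return MXLParams(theta[:K].copy(), sd_full, float(theta[K + R]),
                     float(theta[K + R + 1]))


def estimate_mxl(
    dataset: ChoiceDataset,
    spec: MXLSpec,
    scenario: str | None = None,
) -> MXLEstimate:
    """Fit the WTP-space mixed logit by maximum simulated likelihood.

    Start values come from the conditional logit translated to WTP space
    (means = b/-a, scale_mu = log(-a)), with mixing SDs at 0.1·|mean| + 0.05
    and scale_sigma at 0.1.  Draws are generated once and held fixed; the
    scaled negative log-likelihood is minimized by L-BFGS-B with the analytic
    gradient.  SDs are reported as absolute values.
    """
    scheme = dataset.scheme
    random = spec.resolve_random(scheme)
    random_idx = np.array([scheme.contrast_names.index(c) for c in random], dtype=int)
    K = scheme.n_dummies
    R = len(random_idx)

    work = dataset if scenario is None else dataset.subset(scenario)
    groups = work.to_panel()
    N = sum(len(g.respondent_ids) for g in groups)
    Ts = [g.X.shape[1] for g in groups]

    draws = make_draws(spec, N, scheme)
    # key draw rows to the working subset's own sorted respondent ordering
    all_ids = np.sort(np.concatenate([g.respondent_ids for g in groups]))
    pos = {rid: i for i, rid in enumerate(all_ids)}
    groups = [
        PanelGroup(g.respondent_ids, np.array([pos[r] for r in g.respondent_ids]),
                   g.X, g.cost_eur, g.chosen)
        for g in groups
    ]

    if spec.start_values is not None:
        theta0 = np.asarray(spec.start_values, float)
        if theta0.shape != (K + R + 2,):
            raise ValueError(f"start_values must have shape ({K + R + 2},)")
    else:
        try:
            cl = fit_conditional_logit(work)
            a = cl.coef[-1]
            if a < -1e-8:
                beta0, alpha0 = preference_to_wtp(cl.coef[:-1], a)
            else:
                beta0, alpha0 = cl.coef[:-1], 1.0
        except ValueError:
            # degenerate start-value fit (tiny/separated sample): neutral start
            beta0, alpha0 = np.zeros(K), 1.0
        sd0 = 0.1 * np.abs(beta0[random_idx]) + 0.05
        theta0 = _pack(beta0, sd0, np.log(alpha0), 0.1 if R else 0.0)

    estimate_sigma = R > 0  # with no random WTP contrast, fix the scale spread at 0
    if not estimate_sigma:
        theta0[-1] = 0.0

    def objective(theta):
        params = _unpack(theta, K, random_idx)
        ll, grad = _panel_loglik(groups, draws, params, random_idx, want_grad=True)
        if not estimate_sigma:
            grad[-1] = 0.0
        if not np.isfinite(ll):
            return np.inf, np.zeros_like(theta)
        return -ll / N, -grad / N

    bounds = ([(-100.0, 100.0)] * K + [(-50.0, 50.0)] * R
              + [(-8.0, 8.0)] + [(0.0, 0.0) if not estimate_sigma else (-5.0, 5.0)])

    f0 = objective(theta0)[0]
    res = optimize.minimize(
        objective, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": spec.maxiter, "ftol": 1e-10, "gtol": spec.gtol},
    )
    theta_hat = res.x
    params_hat = _unpack(theta_hat, K, random_idx)
    loglik = -res.fun * N
    start_loglik = -f0 * N

    # --- standard errors from the numerical Hessian of the total -loglik ---
    free = np.ones(len(theta_hat), bool)
    if not estimate_sigma:
        free[-1] = False
    se = np.full(len(theta_hat), np.nan)
    try:
        H = _numeric_hessian(lambda th: objective(th)[1] * N, theta_hat, free)
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        if np.all(d > 0):
            se_free = np.sqrt(d)
            se[free] = se_free
        # else leave NaN (singular/indefinite Hessian)
    except np.linalg.LinAlgError:
        pass

    sd_se = np.full(K, np.nan)
    sd_se[random_idx] = se[K:K + R]
    grad_norm = float(np.max(np.abs(res.jac)))
    return MXLEstimate(
        contrasts=scheme.contrast_names,
        wtp_mean=params_hat.wtp_mean,
        wtp_mean_se=se[:K],
        wtp_sd=np.abs(params_hat.wtp_sd),
        wtp_sd_se=sd_se,
        scale_mu=params_hat.scale_mu,
        scale_mu_se=se[K + R],
        scale_sigma=abs(params_hat.scale_sigma),
        scale_sigma_se=se[K + R + 1] if estimate_sigma else np.nan,
        loglik=float(loglik),
        start_loglik=float(start_loglik),
        converged=bool(res.success),
        message=str(res.message),
        grad_norm=grad_norm,
        n_respondents=N,
        n_tasks_min=int(min(Ts)),
        n_tasks_max=int(max(Ts)),
        n_alternatives=2,
        n_draws=spec.n_draws,
        draw_scheme=spec.draw_scheme,
        random_attrs=random,
    )


def _numeric_hessian(grad_fn, theta, free_mask, rel_step=1e-5):
    """Central-difference Hessian of a scalar objective from its gradient."""
    idx = np.flatnonzero(free_mask)
    H = np.zeros((len(idx), len(idx)))
    for r, j in enumerate(idx):
        h = rel_step * (1.0 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        gp, gm = grad_fn(tp), grad_fn(tm)
        H[r, :] = (gp[idx] - gm[idx]) / (2 * h)
    return 0.5 * (H + H.T)
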