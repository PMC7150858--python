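"""Synthetic respondents and forced choices under a WTP-space mixed logit.

The data-generating process mirrors the random-utility model the estimator
targets: respondent *i* values profile *j* in task *t* as

    U_ijt = alpha_i * (X_ijt . beta_i - c_ijt) + eps_ijt

with individual WTP vector ``beta_i ~ Normal(wtp_mean, diag(wtp_sd^2))``
(EUR per unit contrast), positive scale ``alpha_i ~ LogNormal(scale_mu,
scale_sigma)`` (utility per EUR), and i.i.d. standard Gumbel errors, the
standard logit normalization.  Choices are the utility argmax — forced,
no opt-out.

Defaults reproduce the study conditions being emulated: 200 respondents,
8 chronic + 8 short-term binary tasks each, profiles from the canonical
attribute scheme, ground-truth WTP distributions from the published
per-scenario coefficient table, covariates matched to the reported sample
(51% female, median age 48.8 years, 51.5% on chronic medication).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference
from .design import (
    SCENARIOS,
    AttributeScheme,
    ChoiceDataset,
    ChoiceTask,
    build_attribute_scheme,
    build_task_set,
    encode_profile,
)


@dataclass
class PopulationTruth:
    """Hyperparameters of the simulated WTP distribution (one scenario)."""

    wtp_mean: np.ndarray          # (K,) EUR
    wtp_sd: np.ndarray            # (K,) EUR, >= 0
    scale_mu: float               # lognormal location of alpha_i
    scale_sigma: float            # lognormal spread of alpha_i, >= 0

    def __post_init__(self):
        self.wtp_mean = np.asarray(self.wtp_mean, dtype=float)
        self.wtp_sd = np.asarray(self.wtp_sd, dtype=float)
        if self.wtp_mean.shape != self.wtp_sd.shape:
            raise ValueError("wtp_mean and wtp_sd must have the same shape")
        if np.any(self.wtp_sd < 0):
            raise ValueError("wtp_sd must be nonnegative")
        if self.scale_sigma < 0:
            raise ValueError("scale_sigma must be nonnegative")


@dataclass
class RespondentParams:
    """One individual's latent WTP vector and positive scale."""

    beta: np.ndarray              # (K,) EUR per unit contrast
    alpha: float                  # utility per EUR, > 0

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")


@dataclass
class CovariateModel:
    """Socio-demographic marginals matched to the emulated sample.

    Age is 18 + LogNormal with median ``age_median - 18`` and coefficient of
    variation ``age_cv`` on the shifted part, so the overall median matches
    while respecting the 18+ inclusion criterion.
    """

    p_female: float = 0.51
    age_median: float = 48.8
    age_cv: float = 0.3
    p_chronic: float = 0.515

    def __post_init__(self):
        for p in (self.p_female, self.p_chronic):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.age_median <= 18:
            raise ValueError("age_median must exceed 18")

    def draw(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        female = rng.binomial(1, self.p_female, size=n)
        chronic = rng.binomial(1, self.p_chronic, size=n)
        sigma = np.sqrt(np.log1p(self.age_cv ** 2))
        age = 18.0 + np.exp(rng.normal(np.log(self.age_median - 18.0), sigma, size=n))
        return pd.DataFrame({
            "female": female,
            "age": np.round(age, 1),
            "chronic_meds": chronic,
        })


def draw_respondents(
    truth: PopulationTruth,
    n: int,
    seed: int,
    mean_shift: np.ndarray | None = None,
) -> list[RespondentParams]:
    """Draw ``n`` respondents' ``(beta_i, alpha_i)`` from the population truth.

    ``mean_shift`` (n, K), if given, shifts each respondent's WTP mean —
    used to inject observed (covariate-driven) preference heterogeneity on
    top of the unobserved normal heterogeneity.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    K = truth.wtp_mean.shape[0]
    means = np.broadcast_to(truth.wtp_mean, (n, K)).copy()
    if mean_shift is not None:
        means = means + np.asarray(mean_shift, dtype=float)
    betas = means + truth.wtp_sd * rng.standard_normal((n, K))
    alphas = np.exp(truth.scale_mu + truth.scale_sigma * rng.standard_normal(n))
    return [RespondentParams(beta=b, alpha=float(a)) for b, a in zip(betas, alphas)]


def simulate_choices(
    tasks: list[ChoiceTask],
    respondents: list[RespondentParams],
    scheme: AttributeScheme,
    seed: int,
    covariates: pd.DataFrame | None = None,
    respondent_ids: np.ndarray | None = None,
) -> ChoiceDataset:
    """Simulate every respondent's forced choice on every task.

    Utility = ``alpha_i * (X . beta_i - cost_eur) + Gumbel(0, 1)``; the
    chosen alternative is the argmax (ties, measure zero, go to the lower
    alternative index).  All respondents face the same ``tasks`` list.
    """
    if not tasks or not respondents:
        raise ValueError("tasks and respondents must be nonempty")
    rng = np.random.default_rng(seed)
    n = len(respondents)
    T = len(tasks)

    X = np.zeros((T, 2, scheme.n_dummies))
    cost = np.zeros((T, 2))
    for t, task in enumerate(tasks):
        for a, prof in enumerate(task.alternatives):
            X[t, a], cost[t, a] = encode_profile(prof, scheme)

    betas = np.stack([r.beta for r in respondents])          # (n, K)
    alphas = np.array([r.alpha for r in respondents])        # (n,)
    v = alphas[:, None, None] * (betas @ X.reshape(T * 2, -1).T - cost.ravel()).reshape(n, T, 2)
    u = v + rng.gumbel(size=(n, T, 2))
    chosen_idx = u.argmax(axis=2)                            # (n, T)

    if respondent_ids is None:
        respondent_ids = np.arange(1, n + 1)
    if covariates is None:
        covariates = pd.DataFrame({
            "female": np.zeros(n, dtype=int),
            "age": np.full(n, 18.0),
            "chronic_meds": np.zeros(n, dtype=int),
        })

    rows = {
        "respondent_id": np.repeat(respondent_ids, T * 2),
        "scenario": np.tile([t.scenario for t in tasks for _ in range(2)], n),
        "task": np.tile([t.task_index for t in tasks for _ in range(2)], n),
        "alt": np.tile([1, 2], n * T),
        "form": np.tile([p.form for t in tasks for p in t.alternatives], n),
        "size": np.tile([p.size for t in tasks for p in t.alternatives], n),
        "color": np.tile([p.color for t in tasks for p in t.alternatives], n),
        "copay_pln": np.tile([p.copayment_pln for t in tasks for p in t.alternatives], n),
    }
    chosen = np.zeros((n, T, 2), dtype=int)
    np.put_along_axis(chosen, chosen_idx[:, :, None], 1, axis=2)
    rows["chosen"] = chosen.ravel()
    for cov in ("female", "age", "chronic_meds"):
        rows[cov] = np.repeat(covariates[cov].to_numpy(), T * 2)
    df = pd.DataFrame(rows)
    return ChoiceDataset(df, scheme=scheme, validate=False)


def generate_study(
    n_respondents: int = 200,
    tasks_per_scenario: int = 8,
    truth_chronic: PopulationTruth | None = None,
    truth_short: PopulationTruth | None = None,
    covariates: CovariateModel | None = None,
    seed: int = 0,
    scheme: AttributeScheme | None = None,
    shared_design: bool = False,
    covariate_effects: dict[str, np.ndarray] | None = None,
) -> ChoiceDataset:
    """Simulate a full two-scenario study.

    Each scenario has its own population truth (defaults: the published
    per-scenario WTP tables with the neutral scale convention) and its own
    independent respondent draws, mirroring the separately estimated
    per-scenario models.  By default every respondent faces an independently
    randomized task set; ``shared_design=True`` gives all respondents one
    common task set, the shape of the original single-design survey.

    ``covariate_effects`` maps covariate name (``female``, ``age_decades``
    — age centered at the median, in decades — or ``chronic_meds``) to a
    (K,) shift of the WTP mean per unit covariate, applied in both scenarios.
    """
    scheme = scheme or build_attribute_scheme()
    truth_chronic = truth_chronic or reference.reference_truth("chronic")
    truth_short = truth_short or reference.reference_truth("short_term")
    covariates = covariates or CovariateModel()

    root = np.random.SeedSequence(seed)
    s_cov, s_design, s_resp_c, s_resp_s, s_gumbel = [
        int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(5)
    ]

    cov_df = covariates.draw(n_respondents, np.random.default_rng(s_cov))

    mean_shift = None
    if covariate_effects:
        z = {
            "female": cov_df["female"].to_numpy(float),
            "age_decades": (cov_df["age"].to_numpy(float) - covariates.age_median) / 10.0,
            "chronic_meds": cov_df["chronic_meds"].to_numpy(float),
        }
        K = scheme.n_dummies
        mean_shift = np.zeros((n_respondents, K))
        for name, gamma in covariate_effects.items():
            if name not in z:
                raise ValueError(f"unknown covariate {name!r}")
            mean_shift += z[name][:, None] * np.asarray(gamma, float)[None, :]

    resp = {
        "chronic": draw_respondents(truth_chronic, n_respondents, s_resp_c, mean_shift),
        "short_term": draw_respondents(truth_short, n_respondents, s_resp_s, mean_shift),
    }

    design_rng = np.random.default_rng(s_design)
    gumbel_rng = np.random.default_rng(s_gumbel)
    if shared_design:
        shared_tasks = build_task_set(scheme, tasks_per_scenario,
                                      seed=int(design_rng.integers(2 ** 31)))

    frames = []
    for i in range(n_respondents):
        tasks = shared_tasks if shared_design else build_task_set(
            scheme, tasks_per_scenario, seed=int(design_rng.integers(2 ** 31))
        )
        for scenario in SCENARIOS:
            sc_tasks = [t for t in tasks if t.scenario == scenario]
            ds = simulate_choices(
                sc_tasks, [resp[scenario][i]], scheme,
                seed=int(gumbel_rng.integers(2 ** 31)),
                covariates=cov_df.iloc[[i]].reset_index(drop=True),
                respondent_ids=np.array([i + 1]),
            )
            frames.append(ds.df)
    df = pd.concat(frames, ignore_index=True)
    df = df.sort_values(["respondent_id", "scenario", "task", "alt"],
                        kind="mergesort").reset_index(drop=True)
    return ChoiceDataset(df, scheme=scheme, validate=False)
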