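"""Willingness-to-pay summaries and downstream results.

Turns fitted (or published) per-scenario coefficient tables into the result
surface of the analysis: a significance-starred summary table, the preferred
drug configuration (the form × size × color combination maximizing summed
mean WTP relative to the small white round tablet), EUR↔PLN conversion,
attribute-importance ordering, and a socio-demographic interaction model
that replaces unobserved heterogeneity with observed covariate interactions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .design import AttributeScheme, ChoiceDataset, build_attribute_scheme
from .mxl import MXLEstimate, preference_to_wtp

#: two-sided normal critical values for 1% / 5% / 10% significance stars
_STAR_LEVELS = (("***", norm.ppf(0.995)), ("**", norm.ppf(0.975)), ("*", norm.ppf(0.95)))


def significance_stars(mean: float, se: float) -> str:
    """Stars from a two-sided normal test of ``mean == 0`` given its SE."""
    if not np.isfinite(se) or se <= 0 or mean == 0:
        return ""
    z = abs(mean) / se
    for stars, crit in _STAR_LEVELS:
        if z >= crit:
            return stars
    return ""


@dataclass
class WTPSummary:
    """Per-scenario WTP table plus scale row and provenance metadata.

    ``tables[scenario]`` is a DataFrame indexed by contrast with columns
    ``mean, se_mean, sd, se_sd, stars_mean, stars_sd`` (EUR per week).
    """

    tables: dict[str, pd.DataFrame]
    scale: dict[str, dict] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)
    scheme: AttributeScheme = field(default_factory=build_attribute_scheme)

    def scenarios(self) -> tuple[str, ...]:
        return tuple(self.tables)

    def means(self, scenario: str) -> pd.Series:
        return self.tables[scenario]["mean"]


@dataclass
class PreferredConfiguration:
    """Argmax form × size × color combination and its total WTP premium."""

    scenario: str
    form: str
    size: str
    color: str
    total_wtp_eur: float


@dataclass
class ImportanceRanking:
    """Attributes ordered by importance, with the measure documented."""

    scenario: str
    items: list[tuple[str, float]]
    measure: str = ("within-attribute range of mean WTP across levels, "
                    "base level contributing 0 EUR")
    notes: tuple[str, ...] = ()


def _build_table(scheme, mean, se_mean, sd, se_sd) -> pd.DataFrame:
    df = pd.DataFrame(
        {"mean": mean, "se_mean": se_mean, "sd": sd, "se_sd": se_sd},
        index=pd.Index(scheme.contrast_names, name="contrast"),
    )
    df["stars_mean"] = [significance_stars(m, s) for m, s in zip(df["mean"], df["se_mean"])]
    df["stars_sd"] = [significance_stars(m, s) for m, s in zip(df["sd"], df["se_sd"])]
    return df


def summarize(estimates: dict[str, MXLEstimate],
              scheme: AttributeScheme | None = None) -> WTPSummary:
    """Build the WTP summary table from fitted per-scenario estimates."""
    if not estimates:
        raise ValueError("at least one scenario estimate is required")
    scheme = scheme or build_attribute_scheme()
    tables, scale = {}, {}
    for scenario, est in estimates.items():
        if tuple(est.contrasts) != scheme.contrast_names:
            raise ValueError("estimate contrasts do not match the attribute scheme")
        tables[scenario] = _build_table(
            scheme, est.wtp_mean, est.wtp_mean_se, est.wtp_sd, est.wtp_sd_se
        )
        scale[scenario] = {
            "scale_mu": est.scale_mu, "scale_mu_se": est.scale_mu_se,
            "scale_sigma": est.scale_sigma, "scale_sigma_se": est.scale_sigma_se,
            "loglik": est.loglik, "n_respondents": est.n_respondents,
            "converged": est.converged,
        }
    return WTPSummary(tables=tables, scale=scale, scheme=scheme,
                      metadata={"source": "fitted mixed logit estimates"})


def summary_from_table(per_scenario: dict[str, dict],
                       scheme: AttributeScheme | None = None) -> WTPSummary:
    """Build a WTPSummary directly from a coefficient table.

    ``per_scenario[scenario]`` must hold arrays ``mean, se_mean, sd, se_sd``
    in scheme contrast order — e.g. the published estimates.
    """
    scheme = scheme or build_attribute_scheme()
    tables = {
        sc: _build_table(scheme, d["mean"], d["se_mean"], d["sd"], d["se_sd"])
        for sc, d in per_scenario.items()
    }
    return WTPSummary(tables=tables, scheme=scheme,
                      metadata={"source": "coefficient table"})


def preferred_configuration(summary: WTPSummary, scenario: str) -> PreferredConfiguration:
    """Exhaustively search form × size × color for the maximal summed mean WTP.

    Base levels contribute 0 EUR; ties break toward base levels (levels are
    scanned base-first and only a strictly larger total displaces the
    incumbent).  The copayment attribute is held fixed: the total is the
    premium over the base profile at equal cost.
    """
    scheme = summary.scheme
    means = summary.means(scenario)

    def level_value(attr: str, level: str) -> float:
        return 0.0 if level == scheme.base_level(attr) else float(means[level])

    best, best_total = None, -np.inf
    for form, size, color in itertools.product(
        scheme.levels("form"), scheme.levels("size"), scheme.levels("color")
    ):
        total = (level_value("form", form) + level_value("size", size)
                 + level_value("color", color))
        if total > best_total:
            best, best_total = (form, size, color), total
    return PreferredConfiguration(scenario, *best, total_wtp_eur=float(best_total))


def convert_eur_to_pln(amount_eur: float, rate: float = 0.25) -> float:
    """EUR → PLN at ``rate`` EUR per PLN, rounded to grosze (2 decimals)."""
    if not rate > 0:
        raise ValueError("rate must be positive")
    return round(amount_eur / rate, 2)


def convert_pln_to_eur(amount_pln: float, rate: float = 0.25) -> float:
    if not rate > 0:
        raise ValueError("rate must be positive")
    return round(amount_pln * rate, 2)


def attribute_importance(summary: WTPSummary, scenario: str) -> ImportanceRanking:
    """Attributes ranked by the range of mean WTP across their levels.

    The base level enters each range at 0 EUR.  Range is one of several
    defensible importance measures; it is stated in the result so downstream
    reports are explicit about what was ranked.
    """
    scheme = summary.scheme
    means = summary.means(scenario)
    items = []
    for attr, levels in scheme.attributes:
        vals = [0.0] + [float(means[lv]) for lv in levels[1:]]
        items.append((attr, max(vals) - min(vals)))
    items.sort(key=lambda kv: -kv[1])
    notes = []
    order = [a for a, _ in items]
    if order != ["size", "form", "color"]:
        notes.append(
            "importance order under the range measure is "
            + " > ".join(order)
            + "; a blanket size > form > color ordering does not hold here"
        )
    return ImportanceRanking(scenario=scenario, items=items, notes=tuple(notes))


def largest_effect(summary: WTPSummary, scenario: str) -> tuple[str, float]:
    """The contrast with the largest absolute mean WTP and its (signed) mean."""
    means = summary.means(scenario)
    name = means.abs().idxmax()
    return name, float(means[name])


# ---------------------------------------------------------------------------
# Socio-demographic interaction model
# ---------------------------------------------------------------------------

@dataclass
class InteractionEstimate:
    """Conditional logit with attribute × covariate interactions.

    Preference-space coefficients: 7 contrasts + cost, plus each contrast
    interacted with female, age (centered, decades) and chronic_meds.
    """

    names: tuple[str, ...]
    coef: pd.Series
    se: pd.Series
    loglik: float
    converged: bool
    age_center: float

    def wtp_at(self, female: float = 0.0, age: float | None = None,
               chronic_meds: float = 0.0) -> pd.Series:
        """Contrast WTPs (EUR) at given covariate values via b(z) / -a."""
        age_dec = 0.0 if age is None else (age - self.age_center) / 10.0
        z = {"female": female, "age_dec": age_dec, "chronic_meds": chronic_meds}
        base_names = [n for n in self.names if ":" not in n and n != "cost_eur"]
        b = self.coef[base_names].copy()
        for contrast in base_names:
            for cov, val in z.items():
                b[contrast] += self.coef[f"{contrast}:{cov}"] * val
        beta, _ = preference_to_wtp(b.to_numpy(), self.coef["cost_eur"])
        return pd.Series(beta, index=base_names)


def fit_interaction_model(
    dataset: ChoiceDataset, scenario: str | None = None
) -> InteractionEstimate:
    """Fixed-coefficient logit with all attribute × covariate interactions.

    Drops unobserved heterogeneity and instead interacts every contrast with
    female, centered age in decades, and chronic-medication status.  Age is
    centered at the sample mean so main effects read as the average
    respondent's preferences; signs of interactions are unaffected.
    """
    scheme = dataset.scheme
    work = dataset if scenario is None else dataset.subset(scenario)
    cov = work.covariates()
    for c in ("female", "age", "chronic_meds"):
        if np.ptp(cov[c].to_numpy(float)) == 0:
            raise ValueError(f"covariate {c!r} is degenerate (no variation)")

    groups = work.to_panel()
    age_center = float(cov["age"].mean())
    zmap = pd.DataFrame({
        "female": cov["female"].astype(float),
        "age_dec": (cov["age"].astype(float) - age_center) / 10.0,
        "chronic_meds": cov["chronic_meds"].astype(float),
    })

    Xrows, yrows = [], []
    names = list(scheme.contrast_names) + ["cost_eur"]
    cov_names = ["female", "age_dec", "chronic_meds"]
    names += [f"{c}:{z}" for c in scheme.contrast_names for z in cov_names]
    for g in groups:
        n, T, _, K = g.X.shape
        Xd = (g.X[:, :, 0, :] - g.X[:, :, 1, :])             # (n,T,K)
        cd = (g.cost_eur[:, :, 0] - g.cost_eur[:, :, 1])     # (n,T)
        zg = zmap.loc[g.respondent_ids].to_numpy(float)      # (n,3)
        inter = (Xd[:, :, :, None] * zg[:, None, None, :])   # (n,T,K,3)
        block = np.concatenate(
            [Xd.reshape(n * T, K), cd.reshape(n * T, 1),
             inter.reshape(n * T, K * 3)], axis=1,
        )
        Xrows.append(block)
        yrows.append((g.chosen == 0).astype(float).ravel())
    design = np.vstack(Xrows)
    y = np.concatenate(yrows)

    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError("collinear interaction design (rank deficient)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, design).fit(disp=0, maxiter=200)
    return InteractionEstimate(
        names=tuple(names),
        coef=pd.Series(np.asarray(res.params, float), index=names),
        se=pd.Series(np.asarray(res.bse, float), index=names),
        loglik=float(res.llf),
        converged=bool(res.mle_retvals.get("converged", False)),
        age_center=age_center,
    )
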