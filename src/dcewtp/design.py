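"""Experimental design for a solid-oral-drug-form discrete choice experiment.

The design universe is the attribute scheme used in the Polish outpatient
survey this package emulates: three medication forms (round tablet, long
tablet, capsule — tablet shape and form collapse into one attribute because
shape is undefined for capsules), three sizes (5/10/15 mm), four colors, and
four weekly copayment levels in Polish zloty (PLN), converted to EUR at 0.25.
Respondents face forced binary choices: two profiles per task, no opt-out,
eight tasks framed as chronic treatment and eight as short-term treatment.

Profiles are dummy-coded against the base profile (round tablet, small,
white): seven contrast columns in the fixed order

    long_tablet, capsule, medium, large, yellow, blue, red

so that estimated coefficients line up one-to-one with the reported
willingness-to-pay contrasts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

SCENARIOS = ("chronic", "short_term")

#: canonical CSV header for long-format choice data
CSV_COLUMNS = [
    "respondent_id", "scenario", "task", "alt",
    "form", "size", "color", "copay_pln", "chosen",
    "female", "age", "chronic_meds",
]

DESIGN_CSV_COLUMNS = ["scenario", "task", "alt", "form", "size", "color", "copay_pln"]


@dataclass(frozen=True)
class AttributeScheme:
    """Attribute/level universe plus its dummy-coding contract.

    ``attributes`` is an ordered tuple of ``(name, levels)`` pairs; the first
    level of each attribute is its base level and encodes to all zeros.
    """

    attributes: tuple[tuple[str, tuple[str, ...]], ...]
    cost_levels_pln: tuple[float, ...]
    pln_to_eur: float
    # derived below; excluded from equality/repr
    coding: dict = field(default=None, compare=False, repr=False)

    def __post_init__(self):
        coding: dict[tuple[str, str], int] = {}
        col = 0
        for name, levels in self.attributes:
            if len(levels) != len(set(levels)):
                raise ValueError(f"duplicate levels in attribute {name!r}")
            for level in levels[1:]:
                coding[(name, level)] = col
                col += 1
        object.__setattr__(self, "coding", coding)

    # -- convenience views -------------------------------------------------
    @property
    def n_dummies(self) -> int:
        return len(self.coding)

    @property
    def attribute_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.attributes)

    @property
    def contrast_names(self) -> tuple[str, ...]:
        """Non-base level names in dummy-column order."""
        out = []
        for name, levels in self.attributes:
            out.extend(levels[1:])
        return tuple(out)

    @property
    def contrast_attributes(self) -> tuple[str, ...]:
        """Attribute owning each dummy column."""
        out = []
        for name, levels in self.attributes:
            out.extend([name] * (len(levels) - 1))
        return tuple(out)

    def levels(self, attribute: str) -> tuple[str, ...]:
        for name, lv in self.attributes:
            if name == attribute:
                return lv
        raise KeyError(attribute)

    def base_level(self, attribute: str) -> str:
        return self.levels(attribute)[0]

    def contrast_label(self, contrast: str) -> str:
        """Human-readable row label, e.g. ``Form—capsule (vs. round tablet)``."""
        for name, levels in self.attributes:
            if contrast in levels[1:]:
                pretty = lambda s: s.replace("_", " ")
                return f"{name.capitalize()}—{pretty(contrast)} (vs. {pretty(levels[0])})"
        raise KeyError(contrast)

    def cost_levels_eur(self) -> tuple[float, ...]:
        return tuple(c * self.pln_to_eur for c in self.cost_levels_pln)


@dataclass(frozen=True)
class ChoiceProfile:
    """One hypothetical medication: form, size, color and weekly copayment."""

    form: str
    size: str
    color: str
    copayment_pln: float


@dataclass(frozen=True)
class ChoiceTask:
    """A forced binary choice between two distinct profiles."""

    scenario: str
    task_index: int
    alternatives: tuple[ChoiceProfile, ChoiceProfile]

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if len(self.alternatives) != 2:
            raise ValueError("a choice task holds exactly two alternatives")
        if self.alternatives[0] == self.alternatives[1]:
            raise ValueError("the two alternatives must differ in at least one attribute")


def build_attribute_scheme() -> AttributeScheme:
    """Return the canonical drug-form scheme (7 dummy columns, PLN costs)."""
    return AttributeScheme(
        attributes=(
            ("form", ("round_tablet", "long_tablet", "capsule")),
            ("size", ("small", "medium", "large")),
            ("color", ("white", "yellow", "blue", "red")),
        ),
        cost_levels_pln=(5.0, 10.0, 15.0, 20.0),
        pln_to_eur=0.25,
    )


def enumerate_profiles(scheme: AttributeScheme) -> list[ChoiceProfile]:
    """Full factorial over form × size × color × copayment."""
    names = scheme.attribute_names
    if names != ("form", "size", "color"):
        raise ValueError("scheme must define exactly the attributes form, size, color")
    combos = itertools.product(
        scheme.levels("form"), scheme.levels("size"), scheme.levels("color"),
        scheme.cost_levels_pln,
    )
    return [ChoiceProfile(f, s, c, p) for f, s, c, p in combos]


def encode_profile(profile: ChoiceProfile, scheme: AttributeScheme) -> tuple[np.ndarray, float]:
    """Dummy-code a profile; returns ``(X, cost_eur)``.

    Base levels map to zero columns; cost is converted from PLN to EUR.
    """
    x = np.zeros(scheme.n_dummies)
    for attr in ("form", "size", "color"):
        level = getattr(profile, attr)
        if level not in scheme.levels(attr):
            raise ValueError(f"unknown level {level!r} for attribute {attr!r}")
        if level != scheme.base_level(attr):
            x[scheme.coding[(attr, level)]] = 1.0
    if profile.copayment_pln not in scheme.cost_levels_pln:
        raise ValueError(
            f"unknown level {profile.copayment_pln!r} for attribute 'copayment_pln'"
        )
    return x, profile.copayment_pln * scheme.pln_to_eur


def build_task_set(
    scheme: AttributeScheme, n_tasks_per_scenario: int = 8, seed: int = 0
) -> list[ChoiceTask]:
    """Randomized task set: ``n`` chronic plus ``n`` short-term binary tasks.

    Profile pairs are drawn uniformly without replacement from the full
    factorial (so the two alternatives always differ).  Presentation order
    interleaves the scenarios in randomly ordered pairs, mirroring a survey
    that rotates chronic/short-term questions two at a time.
    """
    if n_tasks_per_scenario < 1:
        raise ValueError("n_tasks_per_scenario must be >= 1")
    rng = np.random.default_rng(seed)
    profiles = enumerate_profiles(scheme)
    per_scenario: dict[str, list[ChoiceTask]] = {}
    for scenario in SCENARIOS:
        tasks = []
        for t in range(1, n_tasks_per_scenario + 1):
            i, j = rng.choice(len(profiles), size=2, replace=False)
            tasks.append(ChoiceTask(scenario, t, (profiles[i], profiles[j])))
        per_scenario[scenario] = tasks
    ordered: list[ChoiceTask] = []
    for k in range(n_tasks_per_scenario):
        pair = [per_scenario["chronic"][k], per_scenario["short_term"][k]]
        if rng.random() < 0.5:
            pair.reverse()
        ordered.extend(pair)
    return ordered


def write_design(tasks: Sequence[ChoiceTask], path) -> None:
    rows = []
    for task in tasks:
        for a, prof in enumerate(task.alternatives, start=1):
            rows.append(
                (task.scenario, task.task_index, a,
                 prof.form, prof.size, prof.color, prof.copayment_pln)
            )
    pd.DataFrame(rows, columns=DESIGN_CSV_COLUMNS).to_csv(path, index=False)


def read_design(path, scheme: AttributeScheme) -> list[ChoiceTask]:
    df = pd.read_csv(path)
    missing = set(DESIGN_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"design file missing columns: {sorted(missing)}")
    tasks = []
    for (scenario, t), grp in df.groupby(["scenario", "task"], sort=False):
        grp = grp.sort_values("alt")
        if list(grp["alt"]) != [1, 2]:
            raise ValueError(f"task {t} in scenario {scenario!r} must have alternatives 1 and 2")
        profs = tuple(
            ChoiceProfile(r.form, r.size, r.color, float(r.copay_pln))
            for r in grp.itertuples()
        )
        tasks.append(ChoiceTask(scenario, int(t), profs))
    for task in tasks:
        for prof in task.alternatives:
            encode_profile(prof, scheme)  # validates levels
    return tasks


# ---------------------------------------------------------------------------
# Choice data container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelGroup:
    """Respondents sharing a common number of tasks, as dense arrays.

    ``X``: (n, T, 2, K) dummy codes; ``cost_eur``: (n, T, 2);
    ``chosen``: (n, T) index in {0, 1} of the chosen alternative;
    ``draw_rows``: positions of these respondents in the dataset-wide
    sorted respondent order (used to align simulation draw blocks).
    """

    respondent_ids: np.ndarray
    draw_rows: np.ndarray
    X: np.ndarray
    cost_eur: np.ndarray
    chosen: np.ndarray


class ChoiceDataset:
    """Long-format panel of forced binary choices plus respondent covariates.

    Wraps a :class:`pandas.DataFrame` with columns :data:`CSV_COLUMNS`.  One
    row per respondent × scenario × task × alternative; exactly one
    ``chosen == 1`` row per task.
    """

    def __init__(self, df: pd.DataFrame, scheme: AttributeScheme | None = None,
                 validate: bool = True):
        self.df = df.reset_index(drop=True)
        self.scheme = scheme or build_attribute_scheme()
        if validate:
            self.validate()

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        df, scheme = self.df, self.scheme
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")

        def bad_rows(mask: pd.Series) -> str:
            rows = (df.index[mask] + 2).tolist()[:5]  # +2: header + 1-based
            return f"rows {rows}"

        m = ~df["scenario"].isin(SCENARIOS)
        if m.any():
            raise ValueError(f"unknown scenario value ({bad_rows(m)})")
        for attr in ("form", "size", "color"):
            m = ~df[attr].isin(scheme.levels(attr))
            if m.any():
                lvl = df.loc[m, attr].iloc[0]
                raise ValueError(f"unknown level {lvl!r} for attribute {attr!r} ({bad_rows(m)})")
        m = ~df["copay_pln"].astype(float).isin(scheme.cost_levels_pln)
        if m.any():
            lvl = df.loc[m, "copay_pln"].iloc[0]
            raise ValueError(f"unknown copayment level {lvl!r} ({bad_rows(m)})")
        m = ~df["chosen"].isin([0, 1])
        if m.any():
            raise ValueError(f"chosen must be 0 or 1 ({bad_rows(m)})")
        for cov, ok in (("female", (0, 1)), ("chronic_meds", (0, 1))):
            m = ~df[cov].isin(ok)
            if m.any():
                raise ValueError(f"{cov} must be in {ok} ({bad_rows(m)})")
        m = df["age"].astype(float) < 18
        if m.any():
            raise ValueError(f"age must be >= 18 ({bad_rows(m)})")

        g = df.groupby(["respondent_id", "scenario", "task"], sort=False)
        sizes = g.size()
        if (sizes != 2).any():
            key = sizes.index[sizes != 2][0]
            raise ValueError(f"task {key} must have exactly 2 alternative rows")
        n_chosen = g["chosen"].sum()
        if (n_chosen != 1).any():
            key = n_chosen.index[n_chosen != 1][0]
            first = df.index[
                (df["respondent_id"] == key[0]) & (df["scenario"] == key[1])
                & (df["task"] == key[2])
            ][0] + 2
            raise ValueError(
                f"task {key} must have exactly one chosen alternative (near row {first})"
            )
        alts = g["alt"].agg(lambda s: sorted(s.tolist()))
        if (alts.apply(lambda a: a != [1, 2])).any():
            key = alts.index[alts.apply(lambda a: a != [1, 2])][0]
            raise ValueError(f"task {key} must have alternatives 1 and 2")
        # covariates constant within respondent
        for cov in ("female", "age", "chronic_meds"):
            if (df.groupby("respondent_id")[cov].nunique() > 1).any():
                raise ValueError(f"covariate {cov!r} varies within a respondent")

    # -- views -------------------------------------------------------------
    @property
    def respondent_ids(self) -> np.ndarray:
        """Sorted unique respondent ids."""
        return np.unique(self.df["respondent_id"].to_numpy())

    @property
    def n_respondents(self) -> int:
        return len(self.respondent_ids)

    def subset(self, scenario: str) -> "ChoiceDataset":
        if scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {scenario!r}")
        return ChoiceDataset(
            self.df[self.df["scenario"] == scenario].reset_index(drop=True),
            self.scheme, validate=False,
        )

    def covariates(self) -> pd.DataFrame:
        """One row per respondent (sorted by id): female, age, chronic_meds."""
        cov = (
            self.df.groupby("respondent_id", sort=True)[["female", "age", "chronic_meds"]]
            .first()
        )
        return cov

    def to_panel(self, scenario: str | None = None) -> list[PanelGroup]:
        """Dense per-respondent arrays, grouped by common task count.

        Respondent order inside and across groups follows the sorted unique
        respondent ids of the *full* dataset, so draw blocks keyed to that
        order are invariant to row permutations and scenario subsetting.
        """
        scheme = self.scheme
        df = self.df
        if scenario is not None:
            df = df[df["scenario"] == scenario]
        if df.empty:
            raise ValueError("no rows to build a panel from")
        df = df.sort_values(
            ["respondent_id", "scenario", "task", "alt"], kind="mergesort"
        ).reset_index(drop=True)

        K = scheme.n_dummies
        X = np.zeros((len(df), K))
        for attr in ("form", "size", "color"):
            for level in scheme.levels(attr)[1:]:
                col = scheme.coding[(attr, level)]
                X[:, col] = (df[attr] == level).to_numpy(float)
        cost = df["copay_pln"].to_numpy(float) * scheme.pln_to_eur
        chosen = df["chosen"].to_numpy(int)

        all_ids = self.respondent_ids
        pos = {rid: i for i, rid in enumerate(all_ids)}
        rids = df["respondent_id"].to_numpy()
        uniq, counts = np.unique(rids, return_counts=True)
        n_tasks = counts // 2

        groups = []
        for T in np.unique(n_tasks):
            sel_ids = uniq[n_tasks == T]
            mask = np.isin(rids, sel_ids)
            n = len(sel_ids)
            Xg = X[mask].reshape(n, T, 2, K)
            cg = cost[mask].reshape(n, T, 2)
            ch = chosen[mask].reshape(n, T, 2).argmax(axis=2)
            groups.append(PanelGroup(
                respondent_ids=sel_ids,
                draw_rows=np.array([pos[r] for r in sel_ids]),
                X=Xg, cost_eur=cg, chosen=ch,
            ))
        return groups

    # -- equality / io -----------------------------------------------------
    def __eq__(self, other) -> bool:
        if not isinstance(other, ChoiceDataset):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(
                self.df[CSV_COLUMNS], other.df[CSV_COLUMNS], check_exact=True
            )
        except AssertionError:
            return False
        return True

    def __len__(self) -> int:
        return len(self.df)


def write_choice_data(dataset: ChoiceDataset, path) -> None:
    dataset.df[CSV_COLUMNS].to_csv(path, index=False)


def read_choice_data(path, scheme: AttributeScheme | None = None) -> ChoiceDataset:
    df = pd.read_csv(path)
    return ChoiceDataset(df, scheme=scheme, validate=True)
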