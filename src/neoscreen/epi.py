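"""Epidemiological arithmetic over confirmed-case count tables.

Incidences follow the screening convention "one case per N births" with
``N = population / cases`` rounded half-up.  Sub-population sizes for the
ethnic groups were not published; where a group anchors on a disorder (or a
disease class) observed only in that group together with its printed
group-specific incidence, the screened sub-population is inferred as
``anchor cases × printed denominator``.  The Dong group has no such anchor
and its population must be supplied explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .rounding import format_one_in_n, percent, round_half_up

__all__ = [
    "CaseRow",
    "CaseCountTable",
    "CannotInferError",
    "TestResult",
    "load_cases",
    "load_default_cases",
    "load_yearly",
    "load_default_yearly",
    "incidence_denominator",
    "per_disorder_incidence",
    "class_incidence",
    "share_within_class",
    "infer_population",
    "group_incidence",
    "minority_implied_population",
    "yearly_frequencies",
    "rate_percent",
    "compare_groups",
    "GROUP_ANCHORS",
    "ETHNIC_GROUPS",
    "TOTAL_POPULATION",
]

ETHNIC_GROUPS = ("Han", "Miao", "Dong", "Tujia", "Yao")
TOTAL_POPULATION = 206_977

#: Printed group-specific incidence anchors used to infer sub-populations:
#: the anchor is a disorder (or disease class) observed only in that group,
#: with the denominator of its published group-specific "1:N" incidence.
GROUP_ANCHORS: dict[str, tuple[str, int]] = {
    "Han": ("MCADD", 128_004),
    "Miao": ("BKD", 32_237),
    "Tujia": ("AAMD", 6_015),
    "Yao": ("AAMD", 3_538),
}


class CannotInferError(ValueError):
    """No anchoring row allows inferring this group's screened population."""


@dataclass(frozen=True)
class CaseRow:
    disorder: str
    disease_class: str
    counts: Mapping[str, int]  # per ethnic group
    total: int

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError(f"{self.disorder}: negative case count")
        if sum(self.counts.values()) != self.total:
            raise ValueError(f"{self.disorder}: ethnic counts do not sum to total")


@dataclass(frozen=True)
class CaseCountTable:
    rows: tuple[CaseRow, ...]
    populations: dict[str, int] = field(default_factory=dict)

    @property
    def total_cases(self) -> int:
        return sum(r.total for r in self.rows)

    def row(self, disorder: str) -> CaseRow:
        for r in self.rows:
            if r.disorder == disorder:
                return r
        raise KeyError(f"unknown disorder {disorder!r}")

    def class_cases(self, disease_class: str) -> int:
        rows = [r for r in self.rows if r.disease_class == disease_class]
        if not rows:
            raise KeyError(f"unknown disease class {disease_class!r}")
        return sum(r.total for r in rows)

    def group_cases(self, group: str, disease_class: str | None = None) -> int:
        return sum(r.counts.get(group, 0) for r in self.rows
                   if disease_class is None or r.disease_class == disease_class)


def load_cases(path: str | Path, population: int = TOTAL_POPULATION) -> CaseCountTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    rows = tuple(
        CaseRow(
            disorder=str(r["disorder"]),
            disease_class=str(r["class"]),
            counts={g: int(r[g]) for g in ETHNIC_GROUPS},
            total=int(r["total"]),
        )
        for _, r in df.iterrows()
    )
    return CaseCountTable(rows, {"overall": population})


def load_default_cases() -> CaseCountTable:
    with resources.as_file(resources.files("neoscreen.data") / "cases_huaihua.tsv") as p:
        return load_cases(p)


def load_yearly(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def load_default_yearly() -> pd.DataFrame:
    with resources.as_file(resources.files("neoscreen.data") / "yearly_huaihua.tsv") as p:
        return load_yearly(p)


# --- incidence arithmetic ----------------------------------------------------

def incidence_denominator(population: int, cases: int) -> int | None:
    """N of the "1:N" incidence: population/cases, rounded half-up.

    Returns ``None`` (undefined incidence) when there are no cases.
    """
    if cases == 0:
        return None
    if cases < 0 or population < cases:
        raise ValueError("need population >= cases >= 1")
    return int(round_half_up(population / cases))


def per_disorder_incidence(table: CaseCountTable,
                           population: int = TOTAL_POPULATION) -> dict[str, int]:
    return {r.disorder: incidence_denominator(population, r.total) for r in table.rows}


def class_incidence(table: CaseCountTable,
                    population: int = TOTAL_POPULATION) -> dict[str, int]:
    classes = []
    for r in table.rows:  # preserve first-appearance order
        if r.disease_class not in classes:
            classes.append(r.disease_class)
    return {c: incidence_denominator(population, table.class_cases(c)) for c in classes}


def share_within_class(table: CaseCountTable, disorder: str) -> float | None:
    """Disorder's percentage share of its disease class's cases (2 dp)."""
    row = table.row(disorder)
    class_total = table.class_cases(row.disease_class)
    if class_total == 0:
        return None
    return percent(row.total, class_total)


def infer_population(table: CaseCountTable, group: str,
                     anchors: Mapping[str, tuple[str, int]] = GROUP_ANCHORS) -> int:
    """Screened sub-population from the group's anchor and printed incidence."""
    if group not in anchors:
        raise CannotInferError(
            f"no single-group anchor disorder for {group!r}; supply its population")
    anchor, denominator = anchors[group]
    try:
        row = table.row(anchor)
        if any(row.counts.get(g, 0) for g in row.counts if g != group):
            raise CannotInferError(f"anchor {anchor!r} has cases outside {group!r}")
        cases = row.counts.get(group, 0)
    except KeyError:
        cases = table.group_cases(group, disease_class=anchor)  # class-level anchor
    if cases == 0:
        raise CannotInferError(f"anchor {anchor!r} has no cases in {group!r}")
    return cases * denominator


def group_incidence(table: CaseCountTable, group: str,
                    population: int | None = None) -> int | None:
    """Group-specific overall incidence denominator (population inferred if needed)."""
    if population is None:
        population = table.populations.get(group) or infer_population(table, group)
    return incidence_denominator(population, table.group_cases(group))


def minority_implied_population(table: CaseCountTable,
                                printed_denominator: int = 1_852) -> int:
    """Combined non-Han screened population implied by the printed minority
    incidence; the residual groups it covers were not itemised."""
    minority_cases = sum(table.group_cases(g) for g in ETHNIC_GROUPS if g != "Han")
    return minority_cases * printed_denominator


def yearly_frequencies(yearly: pd.DataFrame) -> dict[int, int | None]:
    return {int(r["year"]): incidence_denominator(int(r["screened"]), int(r["confirmed"]))
            for _, r in yearly.iterrows()}


def rate_percent(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """100 × numerator/denominator, half-up (e.g. the 2.69% positive rate)."""
    if denominator < 1:
        raise ValueError("denominator must be >= 1")
    return percent(numerator, denominator, ndigits)


# --- group comparisons -------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    statistic: float | None
    p_value: float | None
    method: str


def compare_groups(data, kind: str | None = None) -> TestResult:
    """Pearson chi-square (no continuity correction) on a 2-way count table,
    or one-way ANOVA when given per-group samples of a continuous outcome.

    ``kind`` forces the interpretation ("counts" or "samples"); by default a
    rectangular 2-D numeric array is read as a contingency table.  A
    degenerate table (any zero row/column margin) yields an undefined result
    (``None`` fields) rather than an error.
    """
    if kind is None:
        try:
            arr = np.asarray(data, dtype=float)
            kind = "counts" if arr.ndim == 2 else "samples"
        except ValueError:
            kind = "samples"
    if kind == "counts":
        counts = np.asarray(data, dtype=float)
        if counts.ndim != 2:
            raise ValueError("count table must be 2-dimensional")
        if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
            return TestResult(None, None, "chi-square (degenerate table)")
        res = sps.chi2_contingency(counts, correction=False)
        return TestResult(float(res.statistic), float(res.pvalue), "chi-square")
    if kind != "samples":
        raise ValueError(f"kind must be 'counts' or 'samples', got {kind!r}")
    samples = [np.asarray(s, dtype=float) for s in data]
    stat, p = sps.f_oneway(*samples)
    return TestResult(float(stat), float(p), "one-way ANOVA")
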