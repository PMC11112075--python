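"""Evaluate newborn analyte profiles against a screening panel.

Ratios are always recomputed from the 43 measured base analytes, so a
profile and its derived ratios can never disagree.  Comparisons are exact
floating-point comparisons with the comparator as written in the panel:
``PHE>120`` is not satisfied by PHE = 120.  A zero denominator is mapped to
``+inf`` (above any finite threshold, below none) and recorded as a
diagnostic rather than raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .panel import Condition, DisorderDef, Panel, RatioExpr

__all__ = [
    "AnalyteProfile",
    "OutOfRange",
    "ScreenResult",
    "MissingAnalyteError",
    "compute_ratios",
    "evaluate_condition",
    "screen_profile",
    "screen_many",
    "read_profiles",
    "write_profiles",
    "write_results",
]


class MissingAnalyteError(KeyError):
    """A profile lacks an analyte required for evaluation."""


#: A profile is a plain mapping analyte abbreviation -> concentration (μmol/L).
AnalyteProfile = Mapping[str, float]


@dataclass(frozen=True)
class OutOfRange:
    indicator: str
    value: float
    lower: float
    upper: float
    side: str  # "low" | "high"


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of screening one profile.

    ``flagged`` maps each positive disorder's abbreviation to the lowest
    satisfied rule tier; ``out_of_range`` annotates every indicator outside
    its reference interval (annotation only -- positivity is defined solely
    by the rules).
    """

    flagged: Mapping[str, int]
    out_of_range: tuple[OutOfRange, ...]
    ratios: Mapping[str, float]
    diagnostics: tuple[str, ...] = ()

    @property
    def is_positive(self) -> bool:
        return bool(self.flagged)


def _profile_value(profile: AnalyteProfile, abbr: str) -> float:
    try:
        return float(profile[abbr])
    except KeyError as exc:
        raise MissingAnalyteError(f"profile is missing analyte {abbr!r}") from exc


def _eval_expr(expr: RatioExpr, profile: AnalyteProfile, diagnostics: list[str] | None = None) -> float:
    num = sum(_profile_value(profile, a) for a in expr.numerator)
    den = sum(_profile_value(profile, a) for a in expr.denominator)
    if den == 0.0:
        if diagnostics is not None:
            diagnostics.append(f"zero denominator in {expr.to_text()}; ratio treated as +inf")
        return math.inf
    return num / den


def compute_ratios(
    profile: AnalyteProfile, panel: Panel, diagnostics: list[str] | None = None
) -> dict[str, float]:
    """Recompute every ratio indicator of the panel from the base analytes."""
    return {abbr: _eval_expr(expr, profile, diagnostics) for abbr, expr in panel.ratio_exprs.items()}


_COMPARE = {
    "<": lambda v, t: v < t,
    "<=": lambda v, t: v <= t,
    ">": lambda v, t: v > t,
    ">=": lambda v, t: v >= t,
}


def evaluate_condition(
    cond: Condition,
    profile: AnalyteProfile,
    ratios: Mapping[str, float] | None = None,
    diagnostics: list[str] | None = None,
) -> bool:
    """Evaluate one resolved condition on a profile (ratios recomputed inline)."""
    if isinstance(cond.operand, str):
        value = _profile_value(profile, cond.operand)
    else:
        value = _eval_expr(cond.operand, profile, diagnostics)
    return _COMPARE[cond.comparator](value, cond.threshold)


def satisfied_tier(
    disorder: DisorderDef,
    profile: AnalyteProfile,
    diagnostics: list[str] | None = None,
) -> int | None:
    """Lowest rule tier fully satisfied by the profile, or None."""
    for rule in sorted(disorder.rules, key=lambda r: r.tier):
        if all(evaluate_condition(c, profile, diagnostics=diagnostics) for c in rule.conditions):
            return rule.tier
    return None


def screen_profile(profile: AnalyteProfile, panel: Panel) -> ScreenResult:
    """Screen one complete profile: rule flags plus out-of-range annotation."""
    diagnostics: list[str] = []
    for abbr in panel.analyte_abbrs():  # fail fast on incomplete profiles
        _profile_value(profile, abbr)
    ratios = compute_ratios(profile, panel, diagnostics)

    flagged: dict[str, int] = {}
    for disorder in panel.disorders:
        tier = satisfied_tier(disorder, profile, diagnostics)
        if tier is not None:
            flagged[disorder.abbr] = tier

    out_of_range: list[OutOfRange] = []
    for ind in panel.indicators:
        value = profile[ind.abbr] if ind.kind == "analyte" else ratios[ind.abbr]
        if value < ind.lower:
            out_of_range.append(OutOfRange(ind.abbr, value, ind.lower, ind.upper, "low"))
        elif value > ind.upper:
            out_of_range.append(OutOfRange(ind.abbr, value, ind.lower, ind.upper, "high"))

    return ScreenResult(flagged, tuple(out_of_range), ratios, tuple(diagnostics))


def screen_many(profiles: Mapping[str, AnalyteProfile], panel: Panel) -> dict[str, ScreenResult]:
    return {pid: screen_profile(p, panel) for pid, p in profiles.items()}


# --- tabular I/O -------------------------------------------------------------

def read_profiles(path: str | Path, panel: Panel) -> dict[str, dict[str, float]]:
    """Read a profiles table (TSV/CSV: id column + one column per analyte).

    The header must match the panel's analyte abbreviations exactly.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    id_col = df.columns[0]
    missing = [a for a in panel.analyte_abbrs() if a not in df.columns]
    if missing:
        raise MissingAnalyteError(f"profile table is missing analyte columns {missing}")
    return {
        str(row[id_col]): {a: float(row[a]) for a in panel.analyte_abbrs()}
        for _, row in df.iterrows()
    }


def write_profiles(
    profiles: Mapping[str, AnalyteProfile], panel: Panel, path: str | Path
) -> None:
    cols = list(panel.analyte_abbrs())
    df = pd.DataFrame(
        [[pid] + [profile[a] for a in cols] for pid, profile in profiles.items()],
        columns=["id"] + cols,
    )
    df.to_csv(path, sep="\t", index=False)


def write_results(results: Mapping[str, ScreenResult], path: str | Path) -> None:
    rows = []
    for pid, res in results.items():
        flags = ";".join(f"{abbr}:{tier}" for abbr, tier in sorted(res.flagged.items()))
        rows.append({"id": pid, "flagged": flags, "n_out_of_range": len(res.out_of_range)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
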