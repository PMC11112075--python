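"""Screening-panel data model: indicators, reference intervals and positive rules.

A panel document has two sections: ``indicators`` (43 measured MS/MS analyte
channels plus 43 derived ratios, each with the 0.5th-99.5th-percentile
reference interval used for out-of-range annotation) and ``disorders`` (tiered
positive rules).  Conditions follow the grammar::

    expr  (">" | "<" | ">=" | "<=" | "≥" | "≤")  number  ["μmol/L"]
    expr := term | term "/" term
    term := ABBR | "(" ABBR {"+" ABBR} ")"

Compound channels such as ``C4DC+C5OH`` are single measured analytes; the
resolver therefore prefers to read ``(C4DC + C5OH)`` as one channel and only
falls back to a sum of separate analytes.  Tiers of one disorder are
disjunctive alternatives; the conditions inside a tier are a conjunction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import yaml

__all__ = [
    "Indicator",
    "RatioExpr",
    "Condition",
    "PositiveRule",
    "DisorderDef",
    "Panel",
    "PanelError",
    "ConditionParseError",
    "PanelReferenceError",
    "PanelValidationError",
    "LintDiagnostic",
    "parse_condition",
    "parse_panel",
    "serialize_panel",
    "lint_panel",
    "load_default_panel",
]

DISEASE_CLASSES = ("AAMD", "OAMD", "FAOD", "UCD")


class PanelError(Exception):
    """Base class for panel document errors."""


class ConditionParseError(PanelError):
    """A condition string does not match the grammar."""


class PanelReferenceError(PanelError):
    """A condition references an abbreviation that is not a panel analyte."""


class PanelValidationError(PanelError):
    """A structurally parsed panel violates an invariant."""


def _canon(text: str) -> str:
    """Canonical spelling of an abbreviation/expression: no whitespace."""
    return re.sub(r"\s+", "", text)


@dataclass(frozen=True)
class Indicator:
    """One screening indicator with its healthy reference interval.

    ``lower``/``upper`` are the 0.5th/99.5th percentiles of healthy newborns,
    in μmol/L for ``kind="analyte"`` and dimensionless for ``kind="ratio"``.
    """

    abbr: str
    name: str
    kind: str  # "analyte" | "ratio"
    lower: float
    upper: float

    @property
    def units(self) -> str:
        return "μmol/L" if self.kind == "analyte" else ""

    def __post_init__(self) -> None:
        if self.kind not in ("analyte", "ratio"):
            raise PanelValidationError(f"{self.abbr}: unknown indicator kind {self.kind!r}")
        if self.lower < 0:
            raise PanelValidationError(f"{self.abbr}: lower bound must be >= 0")
        if not self.upper > self.lower:
            raise PanelValidationError(f"{self.abbr}: upper bound must exceed lower bound")


@dataclass(frozen=True)
class RatioExpr:
    """A quotient of analyte sums, e.g. ``(C16 + C18:1)/C2``."""

    numerator: tuple[str, ...]
    denominator: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.numerator or not self.denominator:
            raise PanelValidationError("ratio expression needs a numerator and a denominator")

    def to_text(self) -> str:
        def side(terms: tuple[str, ...]) -> str:
            return terms[0] if len(terms) == 1 else "(" + "+".join(terms) + ")"

        return f"{side(self.numerator)}/{side(self.denominator)}"


Operand = Union[str, RatioExpr]


@dataclass(frozen=True)
class Condition:
    """A single threshold comparison on an analyte or a ratio expression."""

    operand: Operand
    comparator: str  # one of "<", "<=", ">", ">="
    threshold: float

    def __post_init__(self) -> None:
        if self.comparator not in ("<", "<=", ">", ">="):
            raise ConditionParseError(f"unknown comparator {self.comparator!r}")
        if not (self.threshold >= 0 and self.threshold == self.threshold):
            raise ConditionParseError("threshold must be finite and >= 0")

    def to_text(self) -> str:
        lhs = self.operand if isinstance(self.operand, str) else self.operand.to_text()
        return f"{lhs}{self.comparator}{self.threshold:g}"


@dataclass(frozen=True)
class PositiveRule:
    """One disjunctive tier: a conjunction of conditions that flags a disorder."""

    tier: int
    conditions: tuple[Condition, ...]

    def __post_init__(self) -> None:
        if not 1 <= self.tier <= 4:
            raise PanelValidationError(f"rule tier must be 1-4, got {self.tier}")
        if not self.conditions:
            raise PanelValidationError(f"tier {self.tier} has no conditions")


@dataclass(frozen=True)
class DisorderDef:
    """A screening target: one rule row, possibly covering several OMIM conditions.

    Rows that cannot be distinguished at the screen (e.g. isovaleric acidemia
    vs 2-methylbutyryl glycinuria, both flagged on C5) are one definition with
    a slash-joined abbreviation; :meth:`aliases` exposes the individual names.
    """

    name: str
    abbr: str
    omim_codes: tuple[str, ...]
    disease_class: str
    rules: tuple[PositiveRule, ...]

    def __post_init__(self) -> None:
        if self.disease_class not in DISEASE_CLASSES:
            raise PanelValidationError(
                f"{self.abbr}: disease class must be one of {DISEASE_CLASSES}"
            )
        if not self.rules:
            raise PanelValidationError(f"{self.abbr}: at least one positive rule required")
        tiers = [r.tier for r in self.rules]
        if len(set(tiers)) != len(tiers):
            raise PanelValidationError(f"{self.abbr}: duplicate rule tier")

    def aliases(self) -> tuple[str, ...]:
        return tuple(self.abbr.split("/"))


@dataclass(frozen=True)
class Panel:
    """A validated screening panel: indicators plus disorder rule sets."""

    indicators: tuple[Indicator, ...]
    disorders: tuple[DisorderDef, ...]
    ratio_exprs: Mapping[str, RatioExpr] = field(default_factory=dict, compare=False)

    @property
    def analytes(self) -> tuple[Indicator, ...]:
        return tuple(i for i in self.indicators if i.kind == "analyte")

    @property
    def ratios(self) -> tuple[Indicator, ...]:
        return tuple(i for i in self.indicators if i.kind == "ratio")

    def analyte_abbrs(self) -> tuple[str, ...]:
        return tuple(i.abbr for i in self.analytes)

    def indicator(self, abbr: str) -> Indicator:
        key = _canon(abbr)
        for ind in self.indicators:
            if ind.abbr == key:
                return ind
        raise PanelReferenceError(f"unknown indicator {abbr!r}")

    def disorder(self, abbr: str) -> DisorderDef:
        """Look up a disorder by its abbreviation or any slash-alias of it."""
        for d in self.disorders:
            if d.abbr == abbr or abbr in d.aliases():
                return d
        raise PanelReferenceError(f"unknown disorder {abbr!r}")


# --- condition parsing -------------------------------------------------------

_COMPARATOR_RE = re.compile(r"(>=|<=|≥|≤|>|<)")
_UNIT_RE = re.compile(r"(μmol/L|umol/L)\s*$")
_ABBR_RE = re.compile(r"^[A-Za-z0-9:\-]+$")
_NORMALIZE = {"≥": ">=", "≤": "<="}


def _split_top_level_slash(expr: str) -> list[str]:
    parts, depth, start = [], 0, 0
    for i, ch in enumerate(expr):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ConditionParseError(f"unbalanced parentheses in {expr!r} at position {i}")
        elif ch == "/" and depth == 0:
            parts.append(expr[start:i])
            start = i + 1
    if depth != 0:
        raise ConditionParseError(f"unbalanced parentheses in {expr!r}")
    parts.append(expr[start:])
    return parts


def _parse_term(term: str) -> tuple[str, ...]:
    """Split one side of a quotient into '+'-separated abbreviation parts."""
    term = term.strip()
    if term.startswith("(") and term.endswith(")"):
        term = term[1:-1]
    parts = tuple(p for p in term.split("+") if p)
    if not parts:
        raise ConditionParseError(f"empty term in {term!r}")
    for p in parts:
        if not _ABBR_RE.match(p):
            raise ConditionParseError(f"malformed abbreviation {p!r}")
    return parts


def parse_condition(text: str) -> Condition:
    """Parse one condition string, e.g. ``"(C16 + C18:1)/C2>0.5"``.

    The μmol/L unit suffix is tolerated and stripped.  The operand is returned
    as a plain abbreviation string when it has no quotient, otherwise as a
    syntactic :class:`RatioExpr`; compound-channel regrouping (``C4DC+C5OH``
    as one analyte) happens later, against a concrete panel.
    """
    m = _COMPARATOR_RE.search(text)
    if m is None:
        raise ConditionParseError(f"no comparator in condition {text!r}")
    comparator = _NORMALIZE.get(m.group(1), m.group(1))
    lhs = _canon(text[: m.start()])
    rhs = _UNIT_RE.sub("", text[m.end() :].strip()).strip()
    if not lhs:
        raise ConditionParseError(f"empty operand in condition {text!r}")
    try:
        threshold = float(rhs)
    except ValueError as exc:
        raise ConditionParseError(
            f"malformed threshold {rhs!r} in condition {text!r} at position {m.end()}"
        ) from exc

    sides = _split_top_level_slash(lhs)
    operand: Operand
    if len(sides) == 1:
        operand = _canon("+".join(_parse_term(sides[0])))
    elif len(sides) == 2:
        operand = RatioExpr(_parse_term(sides[0]), _parse_term(sides[1]))
    else:
        raise ConditionParseError(f"more than one '/' in condition {text!r}")
    return Condition(operand, comparator, threshold)


def _resolve_terms(parts: Sequence[str], analytes: set[str], context: str) -> tuple[str, ...]:
    """Regroup '+'-separated parts into panel analytes, greedily merging
    consecutive parts into compound channels (longest match first)."""
    resolved: list[str] = []
    i = 0
    n = len(parts)
    while i < n:
        for j in range(n, i, -1):
            candidate = "+".join(parts[i:j])
            if candidate in analytes:
                resolved.append(candidate)
                i = j
                break
        else:
            raise PanelReferenceError(f"unknown analyte {parts[i]!r} in {context}")
    return tuple(resolved)


def _resolve_condition(cond: Condition, analytes: set[str], context: str) -> Condition:
    if isinstance(cond.operand, str):
        merged = _resolve_terms(cond.operand.split("+"), analytes, context)
        if len(merged) != 1:
            raise PanelReferenceError(
                f"operand {cond.operand!r} in {context} is not a single analyte"
            )
        return replace(cond, operand=merged[0])
    expr = RatioExpr(
        _resolve_terms(cond.operand.numerator, analytes, context),
        _resolve_terms(cond.operand.denominator, analytes, context),
    )
    return replace(cond, operand=expr)


# --- panel document I/O ------------------------------------------------------

def parse_panel(source: Union[str, Path, Mapping]) -> Panel:
    """Parse and validate a panel document (YAML text, path, or mapping)."""
    if isinstance(source, Mapping):
        doc = source
    else:
        text = Path(source).read_text(encoding="utf-8") if isinstance(source, Path) else source
        if isinstance(source, str) and "\n" not in source and source.endswith((".yaml", ".yml")):
            text = Path(source).read_text(encoding="utf-8")
        doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping) or "indicators" not in doc or "disorders" not in doc:
        raise PanelValidationError("panel document needs 'indicators' and 'disorders' sections")

    indicators = tuple(
        Indicator(
            abbr=_canon(str(row["abbr"])),
            name=str(row.get("name", row["abbr"])),
            kind=str(row["kind"]),
            lower=float(row["lower"]),
            upper=float(row["upper"]),
        )
        for row in doc["indicators"]
    )
    abbrs = [i.abbr for i in indicators]
    if len(set(abbrs)) != len(abbrs):
        dupes = sorted({a for a in abbrs if abbrs.count(a) > 1})
        raise PanelValidationError(f"duplicate indicator abbreviations: {dupes}")
    analytes = {i.abbr for i in indicators if i.kind == "analyte"}

    disorders = []
    for row in doc["disorders"]:
        abbr = str(row["abbr"])
        rules_doc = row["rules"]
        tiers = sorted(int(t) for t in rules_doc)
        rules = []
        for tier in tiers:
            conds = tuple(
                _resolve_condition(parse_condition(c), analytes, f"{abbr} tier {tier}")
                for c in rules_doc[tier if tier in rules_doc else str(tier)]
            )
            rules.append(PositiveRule(tier, conds))
        disorders.append(
            DisorderDef(
                name=str(row["name"]),
                abbr=abbr,
                omim_codes=tuple(str(c) for c in row.get("omim", ())),
                disease_class=str(row["class"]),
                rules=tuple(rules),
            )
        )
    disorder_abbrs = [d.abbr for d in disorders]
    if len(set(disorder_abbrs)) != len(disorder_abbrs):
        raise PanelValidationError("duplicate disorder abbreviations")

    ratio_exprs = {}
    for ind in indicators:
        if ind.kind != "ratio":
            continue
        cond = _resolve_condition(
            parse_condition(f"{ind.abbr}>0"), analytes, f"ratio indicator {ind.abbr}"
        )
        if not isinstance(cond.operand, RatioExpr):
            raise PanelValidationError(f"ratio indicator {ind.abbr} is not a quotient")
        ratio_exprs[ind.abbr] = cond.operand

    return Panel(indicators, tuple(disorders), ratio_exprs)


def serialize_panel(panel: Panel) -> str:
    """Serialize a panel back to the document format (round-trips on structure)."""
    doc = {
        "indicators": [
            {"abbr": i.abbr, "name": i.name, "kind": i.kind, "lower": i.lower, "upper": i.upper}
            for i in panel.indicators
        ],
        "disorders": [
            {
                "name": d.name,
                "abbr": d.abbr,
                "omim": list(d.omim_codes),
                "class": d.disease_class,
                "rules": {r.tier: [c.to_text() for c in r.conditions] for r in d.rules},
            }
            for d in panel.disorders
        ],
    }
    return yaml.safe_dump(doc, allow_unicode=True, sort_keys=False)


def load_default_panel() -> Panel:
    """Load the shipped Huaihua 2015-2021 panel fixture."""
    text = resources.files("neoscreen.data").joinpath("panel_huaihua.yaml").read_text("utf-8")
    return parse_panel(text)


# --- lint --------------------------------------------------------------------

@dataclass(frozen=True)
class LintDiagnostic:
    code: str  # "threshold-inside-interval" | "threshold-on-boundary" | "unreferenced-analyte"
    message: str
    disorder: str = ""
    indicator: str = ""


def _condition_indicator(panel: Panel, cond: Condition) -> Indicator | None:
    """Indicator carrying a reference interval for this condition's operand."""
    if isinstance(cond.operand, str):
        try:
            return panel.indicator(cond.operand)
        except PanelReferenceError:
            return None
    for abbr, expr in panel.ratio_exprs.items():
        if expr == cond.operand:
            return panel.indicator(abbr)
    return None


def lint_panel(panel: Panel) -> list[LintDiagnostic]:
    """Non-fatal cross-checks of rule thresholds against reference intervals.

    Reports rule thresholds that sit strictly inside the indicator's healthy
    interval (they alone would flag in-range newborns), thresholds equal to an
    interval bound, and analytes never referenced by any rule.
    """
    out: list[LintDiagnostic] = []
    referenced: set[str] = set()
    for d in panel.disorders:
        for rule in d.rules:
            for cond in rule.conditions:
                if isinstance(cond.operand, str):
                    referenced.add(cond.operand)
                else:
                    referenced.update(cond.operand.numerator)
                    referenced.update(cond.operand.denominator)
                ind = _condition_indicator(panel, cond)
                if ind is None:
                    continue
                if ind.lower < cond.threshold < ind.upper:
                    out.append(
                        LintDiagnostic(
                            "threshold-inside-interval",
                            f"{d.abbr} tier {rule.tier}: threshold {cond.to_text()} lies inside"
                            f" the reference interval {ind.lower:g}-{ind.upper:g} of {ind.abbr}",
                            disorder=d.abbr,
                            indicator=ind.abbr,
                        )
                    )
                elif cond.threshold in (ind.lower, ind.upper):
                    out.append(
                        LintDiagnostic(
                            "threshold-on-boundary",
                            f"{d.abbr} tier {rule.tier}: threshold {cond.to_text()} equals an"
                            f" interval bound of {ind.abbr} ({ind.lower:g}-{ind.upper:g})",
                            disorder=d.abbr,
                            indicator=ind.abbr,
                        )
                    )
    for ind in panel.analytes:
        if ind.abbr not in referenced:
            out.append(
                LintDiagnostic(
                    "unreferenced-analyte",
                    f"analyte {ind.abbr} is not referenced by any positive rule",
                    indicator=ind.abbr,
                )
            )
    return out
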