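"""Synthetic newborn cohorts with the statistical structure the screen assumes.

Healthy analyte concentrations are drawn independently per analyte from
two-parameter families exactly identified by the panel's reference interval,
which is defined as the 0.5th-99.5th percentile range of healthy newborns:

* lower bound L > 0: log-normal with ``μ = (ln L + ln U)/2`` and
  ``σ = (ln U − ln L)/(2 z)`` (z the normal quantile at the upper percentile),
  so the fitted percentiles equal (L, U) analytically;
* L = 0: half-normal scaled so its upper percentile equals U.

Disease cases are injected mechanically: each disorder has a signature that
pins the analytes of one targeted rule tier to ``threshold × (1 ± δ)`` and
then repairs any ratio conditions of that tier, guaranteeing the tier fires
on every draw.  Signatures emulate a clearly positive case, not the clinical
severity distribution.  Demographics follow the screened population's
marginal proportions and are independent of disease status.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .engine import evaluate_condition, satisfied_tier
from .panel import Condition, DisorderDef, Indicator, Panel, PanelError, RatioExpr

__all__ = [
    "GeneratorConfig",
    "NewbornRecord",
    "DiseaseSignature",
    "SignatureError",
    "calibrate_healthy_distribution",
    "sample_analyte",
    "sample_healthy",
    "median_healthy_profile",
    "build_signature",
    "apply_signature",
    "sample_affected",
    "self_test_signatures",
    "generate_cohort",
    "huaihua_disease_rates",
    "HUAIHUA_ETHNICITY_WEIGHTS",
    "HUAIHUA_DEMOGRAPHIC_MARGINS",
]

_POPULATION = 206_977  # screened newborns behind the default margins

# Ethnic-group weights inferred from the screened-population denominators
# (Han 128,004; Miao 32,237; Tujia 6,015; Yao 3,538; Dong the remainder).
HUAIHUA_ETHNICITY_WEIGHTS: dict[str, float] = {
    "Han": 128_004 / _POPULATION,
    "Miao": 32_237 / _POPULATION,
    "Dong": 37_183 / _POPULATION,
    "Tujia": 6_015 / _POPULATION,
    "Yao": 3_538 / _POPULATION,
}

# Marginal demographic proportions of the screened population (combined
# normal + patient columns; preterm 4.25%, low birth weight 3.33%).
HUAIHUA_DEMOGRAPHIC_MARGINS: dict[str, dict[str, float]] = {
    "sex": {"male": 110_749 / _POPULATION, "female": 96_136 / _POPULATION,
            "unrecorded": 92 / _POPULATION},
    "gestational_band": {"<32": 458 / _POPULATION, "32-36": 8_351 / _POPULATION,
                         ">=37": 184_330 / _POPULATION, "unrecorded": 13_838 / _POPULATION},
    "birthweight_band": {"<1500": 366 / _POPULATION, "1500-1999": 1_118 / _POPULATION,
                         "2000-2499": 5_411 / _POPULATION, ">=2500": 190_521 / _POPULATION,
                         "unrecorded": 9_561 / _POPULATION},
    "fetus_count": {"1": 205_783 / _POPULATION, "2": 1_185 / _POPULATION,
                    "3": 9 / _POPULATION},
}


class SignatureError(PanelError):
    """A disease signature cannot satisfy its targeted rule tier."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-generation settings; defaults emulate the screened population."""

    seed: int = 0
    n_newborns: int = 10_000
    lower_percentile: float = 0.005
    upper_percentile: float = 0.995
    disease_rates: Mapping[str, float] = field(default_factory=dict)
    elevation_factor: float = 0.5  # δ: signature margin beyond the threshold
    ethnicity_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(HUAIHUA_ETHNICITY_WEIGHTS))
    demographic_margins: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in HUAIHUA_DEMOGRAPHIC_MARGINS.items()})

    def __post_init__(self) -> None:
        if not (0 < self.lower_percentile < self.upper_percentile < 1):
            raise ValueError("percentiles must satisfy 0 < lower < upper < 1")
        if any(not 0 <= r <= 1 for r in self.disease_rates.values()):
            raise ValueError("disease rates must lie in [0, 1]")
        if sum(self.disease_rates.values()) >= 1:
            raise ValueError("disease rates must sum to < 1")
        total = sum(self.ethnicity_weights.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError(f"ethnicity weights must sum to 1 (got {total})")


@dataclass(frozen=True)
class NewbornRecord:
    id: str
    sex: str
    ethnicity: str
    gestational_band: str
    birthweight_band: str
    fetus_count: int
    true_disorder: str | None
    profile: dict[str, float]


def huaihua_disease_rates(cases: Mapping[str, int] | None = None,
                          population: int = _POPULATION) -> dict[str, float]:
    """Per-birth disorder probabilities from confirmed-case counts.

    Defaults to the shipped case-count table (69 cases / 206,977 births).
    """
    if cases is None:
        from .epi import load_default_cases
        table = load_default_cases()
        cases = {row.disorder: row.total for row in table.rows}
    return {d: n / population for d, n in cases.items()}


# --- healthy-distribution calibration ---------------------------------------

def calibrate_healthy_distribution(indicator: Indicator,
                                   config: GeneratorConfig | None = None) -> tuple:
    """Distribution parameters whose percentiles equal the reference interval.

    Returns ``("lognormal", mu, sigma)`` for indicators with a positive lower
    bound, ``("halfnormal", scale)`` for zero-lower-bound indicators.
    """
    config = config or GeneratorConfig()
    lower, upper = indicator.lower, indicator.upper
    if upper <= lower:
        raise ValueError(f"{indicator.abbr}: upper bound must exceed lower bound")
    if lower > 0:
        z_lo = stats.norm.ppf(config.lower_percentile)
        z_hi = stats.norm.ppf(config.upper_percentile)
        log_l, log_u = math.log(lower), math.log(upper)
        sigma = (log_u - log_l) / (z_hi - z_lo)
        mu = (z_hi * log_l - z_lo * log_u) / (z_hi - z_lo)
        return ("lognormal", mu, sigma)
    scale = upper / stats.norm.ppf((1 + config.upper_percentile) / 2)
    return ("halfnormal", scale)


def sample_analyte(indicator: Indicator, config: GeneratorConfig, n: int,
                   rng: np.random.Generator) -> np.ndarray:
    params = calibrate_healthy_distribution(indicator, config)
    if params[0] == "lognormal":
        _, mu, sigma = params
        return np.exp(rng.normal(mu, sigma, size=n))
    return np.abs(rng.normal(0.0, params[1], size=n))


def sample_healthy(panel: Panel, config: GeneratorConfig, n: int,
                   rng: np.random.Generator | None = None) -> list[dict[str, float]]:
    """Draw ``n`` complete healthy profiles (independent analytes, seeded)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    columns = {ind.abbr: sample_analyte(ind, config, n, rng) for ind in panel.analytes}
    abbrs = list(columns)
    return [dict(zip(abbrs, values)) for values in zip(*(columns[a] for a in abbrs))]


def median_healthy_profile(panel: Panel, config: GeneratorConfig | None = None) -> dict[str, float]:
    """The analytic median of every healthy analyte distribution."""
    config = config or GeneratorConfig()
    profile = {}
    for ind in panel.analytes:
        params = calibrate_healthy_distribution(ind, config)
        if params[0] == "lognormal":
            profile[ind.abbr] = math.exp(params[1])
        else:
            profile[ind.abbr] = params[1] * stats.norm.ppf(0.75)  # half-normal median
    return profile


# --- disease signatures ------------------------------------------------------

@dataclass(frozen=True)
class DiseaseSignature:
    """Mechanical perturbation recipe targeting one rule tier of a disorder."""

    disorder: str
    target_tier: int
    perturbations: tuple[tuple[str, str], ...]  # (analyte, "up"|"down")


def _target_tier(disorder: DisorderDef) -> int:
    """Tier a signature aims at: prefer tiers made only of single-analyte
    thresholds (fewest conditions, then lowest tier); else the lowest tier,
    whose ratio conditions are repaired per draw."""
    plain = [r for r in disorder.rules
             if all(isinstance(c.operand, str) for c in r.conditions)]
    if plain:
        return min(plain, key=lambda r: (len(r.conditions), r.tier)).tier
    return min(r.tier for r in disorder.rules)


def build_signature(disorder: DisorderDef) -> DiseaseSignature:
    tier = _target_tier(disorder)
    rule = next(r for r in disorder.rules if r.tier == tier)
    perturbations = tuple(
        (c.operand, "up" if c.comparator in (">", ">=") else "down")
        for c in rule.conditions if isinstance(c.operand, str)
    )
    return DiseaseSignature(disorder.abbr, tier, perturbations)


def _repair_ratio(profile: dict[str, float], cond: Condition, pinned: set[str],
                  delta: float) -> None:
    """Adjust one free analyte so a ratio condition holds with margin δ."""
    expr = cond.operand
    assert isinstance(expr, RatioExpr)
    num = sum(profile[a] for a in expr.numerator)
    den = sum(profile[a] for a in expr.denominator)
    upward = cond.comparator in (">", ">=")
    target = cond.threshold * (1 + delta) if upward else cond.threshold * (1 - delta)

    free_num = [a for a in expr.numerator if a not in pinned]
    free_den = [a for a in expr.denominator if a not in pinned]
    if upward:
        if free_num:
            a = free_num[0]
            profile[a] = max(0.0, profile[a] + target * den - num)
        elif free_den:
            a = free_den[0]
            if target > 0:
                profile[a] = max(0.0, profile[a] + num / target - den)
        else:
            raise SignatureError(f"no adjustable analyte in {expr.to_text()}")
    else:
        if free_num:
            a = free_num[0]
            profile[a] = max(0.0, profile[a] + target * den - num)
        elif free_den:
            a = free_den[0]
            if target <= 0:
                raise SignatureError(f"cannot repair {cond.to_text()} via denominator")
            profile[a] = max(0.0, profile[a] + num / target - den)
        else:
            raise SignatureError(f"no adjustable analyte in {expr.to_text()}")
    pinned.update(expr.numerator if free_num else expr.denominator)


def apply_signature(profile: Mapping[str, float], disorder: DisorderDef,
                    delta: float = 0.5) -> dict[str, float]:
    """Perturb a healthy profile so the disorder's targeted tier is satisfied."""
    out = dict(profile)
    signature = build_signature(disorder)
    rule = next(r for r in disorder.rules if r.tier == signature.target_tier)

    pinned: set[str] = set()
    for analyte, direction in signature.perturbations:
        cond = next(c for c in rule.conditions if c.operand == analyte)
        factor = 1 + delta if direction == "up" else 1 - delta
        out[analyte] = max(0.0, cond.threshold * factor)
        pinned.add(analyte)
    for cond in rule.conditions:
        if isinstance(cond.operand, RatioExpr):
            if not evaluate_condition(cond, out):
                _repair_ratio(out, cond, pinned, delta)

    if satisfied_tier(disorder, out) is None:
        raise SignatureError(
            f"signature for {disorder.abbr} failed to satisfy tier {signature.target_tier}")
    return out


def sample_affected(disorder: str, panel: Panel, config: GeneratorConfig,
                    rng: np.random.Generator | None = None) -> dict[str, float]:
    """One affected profile: a healthy draw pushed over the disorder's rules."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    d = panel.disorder(disorder)
    healthy = sample_healthy(panel, config, 1, rng)[0]
    return apply_signature(healthy, d, config.elevation_factor)


def self_test_signatures(panel: Panel, config: GeneratorConfig | None = None) -> None:
    """Start-up check: every disorder's signature flags it on the median profile."""
    config = config or GeneratorConfig()
    median = median_healthy_profile(panel, config)
    for d in panel.disorders:
        perturbed = apply_signature(median, d, config.elevation_factor)
        if satisfied_tier(d, perturbed) is None:  # pragma: no cover - guarded upstream
            raise SignatureError(f"signature self-test failed for {d.abbr}")


# --- whole-cohort generation -------------------------------------------------

def _draw_categorical(rng: np.random.Generator, margins: Mapping[str, float], n: int) -> list[str]:
    labels = list(margins)
    probs = np.asarray([margins[k] for k in labels], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(labels), size=n, p=probs)
    return [labels[i] for i in idx]


def generate_cohort(config: GeneratorConfig, panel: Panel) -> list[NewbornRecord]:
    """Generate ``config.n_newborns`` records: demographics, disease labels
    drawn per ``disease_rates``, signature profiles for the affected."""
    self_test_signatures(panel, config)
    rng = np.random.default_rng(config.seed)
    n = config.n_newborns

    disorders = list(config.disease_rates)
    rates = np.asarray([config.disease_rates[d] for d in disorders], dtype=float)
    labels: list[str | None] = [None] * n
    if disorders:
        u = rng.random(n)
        edges = np.concatenate([[0.0], np.cumsum(rates)])
        for i, ui in enumerate(u):
            j = np.searchsorted(edges, ui, side="right") - 1
            if j < len(disorders):
                labels[i] = disorders[j]

    ethnicities = _draw_categorical(rng, config.ethnicity_weights, n)
    sexes = _draw_categorical(rng, config.demographic_margins["sex"], n)
    gest = _draw_categorical(rng, config.demographic_margins["gestational_band"], n)
    weight = _draw_categorical(rng, config.demographic_margins["birthweight_band"], n)
    fetus = _draw_categorical(rng, config.demographic_margins["fetus_count"], n)

    healthy = sample_healthy(panel, config, n, rng)
    records = []
    for i in range(n):
        profile = healthy[i]
        if labels[i] is not None:
            profile = apply_signature(profile, panel.disorder(labels[i]),
                                      config.elevation_factor)
        records.append(NewbornRecord(
            id=f"NB{i + 1:06d}",
            sex=sexes[i],
            ethnicity=ethnicities[i],
            gestational_band=gest[i],
            birthweight_band=weight[i],
            fetus_count=int(fetus[i]),
            true_disorder=labels[i],
            profile=profile,
        ))
    return records
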