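#!/usr/bin/env python
"""Incidence and rate arithmetic from the confirmed-case fixtures.

Reproduces, from case counts alone: the overall 1:3,000 incidence, the four
disease-class incidences, every per-disorder denominator, within-class
shares, the yearly frequencies, the cascade rates, and the ethnic-group
incidences built on inferred sub-populations.
"""

from pathlib import Path

import pandas as pd

from neoscreen.epi import (
    TOTAL_POPULATION,
    CannotInferError,
    class_incidence,
    group_incidence,
    incidence_denominator,
    infer_population,
    load_default_cases,
    load_default_yearly,
    minority_implied_population,
    per_disorder_incidence,
    rate_percent,
    share_within_class,
    yearly_frequencies,
    ETHNIC_GROUPS,
)
from neoscreen.rounding import format_one_in_n

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cases = load_default_cases()
    yearly = load_default_yearly()

    overall = incidence_denominator(TOTAL_POPULATION, cases.total_cases)
    print(f"{cases.total_cases} confirmed cases in {TOTAL_POPULATION:,} newborns: "
          f"overall incidence {format_one_in_n(overall)}")

    rows = []
    for row in cases.rows:
        denom = incidence_denominator(TOTAL_POPULATION, row.total)
        rows.append({"disorder": row.disorder, "class": row.disease_class,
                     "cases": row.total, "incidence": format_one_in_n(denom),
                     "share_within_class_pct": share_within_class(cases, row.disorder)})
    per_disorder = pd.DataFrame(rows)
    per_disorder.to_csv(RESULTS / "incidence_per_disorder.tsv", sep="\t", index=False)

    print("\nclass incidences:")
    for cls, denom in class_incidence(cases).items():
        print(f"  {cls}: {cases.class_cases(cls)} cases, {format_one_in_n(denom)}")
    lead = per_disorder.sort_values("cases", ascending=False).head(3)
    print("\nmost common disorders:")
    for _, r in lead.iterrows():
        print(f"  {r.disorder}: {r.incidence} ({r.share_within_class_pct}% of {r['class']}s)")

    print("\nethnic stratification (populations inferred from anchor disorders):")
    group_rows = []
    for group in ETHNIC_GROUPS:
        try:
            pop = cases.populations.get(group) or infer_population(cases, group)
            denom = group_incidence(cases, group)
            note = "inferred"
        except CannotInferError:
            pop, denom, note = None, None, "no anchor; population not inferable"
        group_rows.append({"group": group, "population": pop,
                           "cases": cases.group_cases(group),
                           "incidence": format_one_in_n(denom) if denom else "",
                           "note": note})
        shown = format_one_in_n(denom) if denom else "-"
        print(f"  {group}: {cases.group_cases(group)} cases, population "
              f"{pop if pop else '?'}, incidence {shown} ({note})")
    pd.DataFrame(group_rows).to_csv(RESULTS / "incidence_by_ethnic_group.tsv",
                                    sep="\t", index=False)
    minority = minority_implied_population(cases)
    print(f"  combined minority groups: 42 cases; published 1:1,852 implies "
          f"~{minority:,} screened (residual for Dong stays positive)")

    yf = yearly_frequencies(yearly)
    pd.DataFrame([{"year": y, "frequency": format_one_in_n(n)} for y, n in yf.items()]
                 ).to_csv(RESULTS / "yearly_frequency.tsv", sep="\t", index=False)
    suspected = int(yearly["suspected_positive"].sum())
    print(f"\ncascade rates: initial-positive {rate_percent(suspected, TOTAL_POPULATION)}%, "
          f"recall {rate_percent(4_085, suspected)}%, referral PPV {rate_percent(69, 297)}%")
    print("specificity recomputed from counts: "
          f"{rate_percent(206_908 - 228, 206_908)}% (published as 99.90%)")
    print(f"\ntables -> {RESULTS}")


if __name__ == "__main__":
    main()
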