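#!/usr/bin/env python
"""Generate a synthetic screening cohort emulating the Huaihua population.

Draws 50,000 newborns with demographics matching the screened population's
margins, healthy analyte profiles calibrated to the panel's 0.5/99.5
percentile reference intervals, and disease cases injected at the observed
per-disorder rates (about 1 case per 3,000 births overall).  Full profiles
are bulky and go to scratch/; a small summary lands in results/.
"""

import json
from collections import Counter
from pathlib import Path

import pandas as pd

from neoscreen.cohort import GeneratorConfig, generate_cohort, huaihua_disease_rates
from neoscreen.engine import write_profiles
from neoscreen.panel import load_default_panel

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
N = 50_000
SEED = 20150101


def main() -> None:
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    panel = load_default_panel()
    cfg = GeneratorConfig(seed=SEED, n_newborns=N, disease_rates=huaihua_disease_rates())
    cohort = generate_cohort(cfg, panel)

    write_profiles({r.id: r.profile for r in cohort}, panel, SCRATCH / "cohort_profiles.tsv")
    pd.DataFrame([
        {"id": r.id, "ethnicity": r.ethnicity, "true_disorder": r.true_disorder or "",
         "sex": r.sex, "gestational_band": r.gestational_band,
         "birthweight_band": r.birthweight_band, "fetus_count": r.fetus_count}
        for r in cohort
    ]).to_csv(SCRATCH / "cohort_labels.tsv", sep="\t", index=False)

    affected = Counter(r.true_disorder for r in cohort if r.true_disorder)
    ethnicity = Counter(r.ethnicity for r in cohort)
    summary = {
        "n_newborns": N,
        "seed": SEED,
        "n_affected": sum(affected.values()),
        "affected_by_disorder": dict(sorted(affected.items())),
        "ethnicity_counts": dict(sorted(ethnicity.items())),
    }
    (RESULTS / "cohort_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"generated {N} newborns (seed {SEED}): {summary['n_affected']} affected "
          f"({sum(affected.values()) / N:.5%} ~ expected 1:3,000)")
    print("disorders injected:", dict(sorted(affected.items())))
    print(f"profiles -> {SCRATCH / 'cohort_profiles.tsv'}")


if __name__ == "__main__":
    main()
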