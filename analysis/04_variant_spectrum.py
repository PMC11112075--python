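#!/usr/bin/env python
"""Variant-spectrum statistics: per-gene frequencies, total shares, the
variant × ethnic-group allele matrix, and zygosity summaries.

Writes the spectrum and matrix as TSVs under results/ and a convenience
heatmap (allele counts by ethnic group) under scratch/.
"""

from pathlib import Path

from neoscreen.variants import (
    ethnicity_matrix,
    load_default_genotypes,
    load_default_variants,
    relative_frequency,
    spectrum_table,
    total_share,
    zygosity_summary,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    records = load_default_variants()
    genotypes = load_default_genotypes()

    table = spectrum_table(records)
    table.to_csv(RESULTS / "variant_spectrum.tsv", sep="\t", index=False)
    matrix = ethnicity_matrix(records)
    matrix.to_csv(RESULTS / "variant_ethnicity_matrix.tsv", sep="\t")

    total = int(table["total"].sum())
    print(f"{len(records)} distinct variants, {total} alleles across "
          f"{table['gene'].nunique()} genes")
    print(f"ACADSB c.1165A>G: {relative_frequency('ACADSB', 'c.1165A>G', records)}% of "
          f"ACADSB alleles, {total_share('c.1165A>G', records, gene='ACADSB')}% of all alleles")
    print(f"SLC25A13 c.852_855del: {relative_frequency('SLC25A13', 'c.852_855del', records)}% "
          "of SLC25A13 alleles")
    z = zygosity_summary(genotypes, "2MBG")
    print(f"2MBG zygosity over 29 cases: {z['homozygous']}% homozygous, "
          f"{z['compound-heterozygous']}% compound het, {z['single-detected']}% single allele")
    shared = matrix.gt(0).all(axis=1).sum()
    print(f"variants detected in all five ethnic groups: {shared}")

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 14))
        im = ax.imshow(matrix.values, aspect="auto", cmap="viridis")
        ax.set_xticks(range(matrix.shape[1]), matrix.columns)
        ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=4)
        fig.colorbar(im, label="allele count")
        fig.tight_layout()
        fig.savefig(SCRATCH / "variant_heatmap.png", dpi=150)
        print(f"heatmap -> {SCRATCH / 'variant_heatmap.png'}")
    except Exception as exc:  # plotting is convenience output only
        print(f"heatmap skipped: {exc}")
    print(f"tables -> {RESULTS}")


if __name__ == "__main__":
    main()
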