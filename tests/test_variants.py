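"""Variant-spectrum statistics: frequencies, matrix marginals, zygosity, HGVS."""

from fractions import Fraction

import pandas as pd
import pytest

from neoscreen.variants import (
    CaseGenotype,
    ethnicity_matrix,
    relative_frequency,
    spectrum_table,
    total_share,
    validate_hgvs_table,
    zygosity_summary,
)


class TestFrequencies:
    @pytest.mark.parametrize("gene, variant, expected", [
        ("ACADSB", "c.1165A>G", 85.96),
        ("SLC25A13", "c.852_855del", 58.33),
        ("PAH", "c.728G>A", 27.78),
        ("SLC22A5", "c.51C>G", 38.46),
        ("MAT1A", "c.791G>A", 100.00),
    ])
    def test_relative_frequency(self, variant_records, gene, variant, expected):
        assert relative_frequency(gene, variant, variant_records) == expected

    @pytest.mark.parametrize("gene, variant, expected", [
        ("ACADSB", "c.1165A>G", 35.77),
        ("SLC25A13", "c.852_855del", 5.11),
        ("PAH", "c.728G>A", 3.65),
        ("BCKDHA", "c.632C>T", 0.73),  # any single allele is 1/137
    ])
    def test_total_share(self, variant_records, gene, variant, expected):
        assert total_share(variant, variant_records, gene=gene) == expected

    def test_unknown_gene_raises(self, variant_records):
        with pytest.raises(KeyError):
            relative_frequency("NOTAGENE", "c.1A>G", variant_records)

    def test_exact_shares_sum_to_one(self, variant_records):
        """Before rounding, total shares are exact fractions summing to 1."""
        grand = sum(r.total for r in variant_records)
        assert sum(Fraction(r.total, grand) for r in variant_records) == 1

    def test_full_table_regression(self, variant_records):
        """Every relative-frequency and total-share cell recomputes from the
        allele counts (62 variants, 137 alleles)."""
        df = spectrum_table(variant_records)
        assert len(df) == 62
        assert df["total"].sum() == 137
        by_gene = df.groupby("gene")
        for gene, sub in by_gene:
            gene_total = sub["total"].sum()
            for _, row in sub.iterrows():
                expected = round(100 * row["total"] / gene_total + 1e-12, 2)
                assert row["relative_frequency_pct"] == pytest.approx(expected, abs=0.005)
        # spot-check printed per-gene header shares
        gene_share = {g: round(100 * s["total"].sum() / 137, 2) for g, s in by_gene}
        assert gene_share["ACADSB"] == pytest.approx(41.61, abs=0.005)
        assert gene_share["PAH"] == pytest.approx(13.14, abs=0.005)


class TestEthnicityMatrix:
    def test_pah_hotspot_row(self, variant_records):
        m = ethnicity_matrix(variant_records)
        assert m.loc["PAH NM_000277.1:c.728G>A"].tolist() == [1, 2, 1, 0, 1]

    def test_marginals(self, variant_records):
        m = ethnicity_matrix(variant_records)
        assert int(m.values.sum()) == 137
        totals = {r.cdna_hgvs: r.total for r in variant_records}
        for r in variant_records:
            assert m.loc[f"{r.gene} {r.cdna_hgvs}"].sum() == totals[r.cdna_hgvs]

    def test_per_gene_subtotals(self, variant_records):
        expected = {"PAH": 18, "ACADSB": 57, "SLC22A5": 13, "SLC25A13": 12,
                    "ACADS": 8, "ACADVL": 4, "PTS": 4, "MMUT": 4}
        for gene, total in expected.items():
            assert sum(r.total for r in variant_records if r.gene == gene) == total

    def test_zero_columns_preserved(self, variant_records):
        pah_only = [r for r in variant_records if r.gene == "BCKDHA"]
        m = ethnicity_matrix(pah_only)
        assert list(m.columns) == ["Han", "Miao", "Dong", "Tujia", "Yao"]
        assert (m["Tujia"] == 0).all()

    def test_row_normalization(self, variant_records):
        m = ethnicity_matrix(variant_records, normalize=True)
        assert m.sum(axis=1).round(9).eq(1.0).all()


class TestZygosity:
    def test_2mbg_homozygote_share(self, genotypes):
        summary = zygosity_summary(genotypes, "2MBG")
        assert summary["homozygous"] == 72.41  # 21 of 29
        assert summary["single-detected"] == 3.45  # exactly one case

    def test_cd_homozygotes(self, genotypes):
        cd = [g for g in genotypes if g.disorder == "CD"]
        hom = [g for g in cd if g.zygosity == "homozygous"]
        assert len(hom) == 3
        assert all(g.alleles[0].endswith("c.852_855del") for g in hom)

    def test_no_cases_is_undefined(self, genotypes):
        assert zygosity_summary(genotypes, "NOPE") is None

    def test_all_single_detected(self):
        g = [CaseGenotype("a", "X", "Han", ("G:c.1A>G",), "single-detected")]
        summary = zygosity_summary(g, "X")
        assert summary == {"homozygous": 0.0, "compound-heterozygous": 0.0,
                           "single-detected": 100.0}

    def test_zygosity_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            CaseGenotype("a", "X", "Han", ("G:c.1A>G", "G:c.1A>G"), "compound-heterozygous")

    def test_case_allele_accounting(self, variant_records, genotypes):
        """Per disorder: alleles = 2×cases − single-detected cases.  Holds for
        every gene table except SLC22A5, whose printed total (13 alleles for
        6 cases) exceeds what two alleles per case allow."""
        disorders = {g.disorder for g in genotypes}
        for disorder in disorders:
            cases = [g for g in genotypes if g.disorder == disorder]
            singles = sum(g.zygosity == "single-detected" for g in cases)
            genotype_alleles = sum(len(g.alleles) for g in cases)
            assert genotype_alleles == 2 * len(cases) - singles
            table_alleles = sum(r.total for r in variant_records if r.disorder == disorder)
            if disorder != "PCD":
                assert table_alleles == genotype_alleles
            else:
                assert table_alleles == genotype_alleles + 1  # documented excess

    def test_2mbg_allele_count_implies_one_single(self, variant_records, genotypes):
        acadsb = sum(r.total for r in variant_records if r.gene == "ACADSB")
        cases = [g for g in genotypes if g.disorder == "2MBG"]
        assert acadsb == 57 and len(cases) == 29
        assert 2 * 29 - acadsb == 1  # exactly one single-detected case


class TestHgvsValidation:
    def _row(self, hgvs, classification="P"):
        return {"disorder": "X", "gene": "G", "cdna_hgvs": hgvs, "protein_hgvs": "-",
                "classification": classification,
                "Han": 1, "Miao": 0, "Dong": 0, "Tujia": 0, "Yao": 0, "total": 1}

    def test_standard_substitution_accepted(self):
        records, diags = validate_hgvs_table(pd.DataFrame([self._row("NM_000017.4:c.79A>C")]))
        assert len(records) == 1 and not diags

    @pytest.mark.parametrize("hgvs", [
        "NM_000277.1:c.47_48del", "NM_014251.2:c.1638_1660dup",
        "NM_000255.4:c.753+3A>G", "NM_000018.4:c.1605+1G>T"])
    def test_standard_forms(self, hgvs):
        records, diags = validate_hgvs_table(pd.DataFrame([self._row(hgvs)]))
        assert len(records) == 1 and not diags

    def test_nonstandard_insertion_kept_with_diagnostic(self):
        records, diags = validate_hgvs_table(
            pd.DataFrame([self._row("NM_014251.2:c.1751-4_1751-5ins3kb")]))
        assert len(records) == 1
        assert any("nonstandard" in d for d in diags)

    def test_missing_transcript_rejected(self):
        records, diags = validate_hgvs_table(pd.DataFrame([self._row("c.100A>G")]))
        assert not records
        assert any("rejected" in d for d in diags)

    def test_bad_classification_rejected(self):
        records, diags = validate_hgvs_table(
            pd.DataFrame([self._row("NM_000017.4:c.79A>C", classification="BENIGN")]))
        assert not records and any("classification" in d for d in diags)

    def test_shipped_table_fully_valid(self, variant_records):
        assert len(variant_records) == 62
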