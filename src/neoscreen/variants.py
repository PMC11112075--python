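"""Variant-spectrum statistics from per-gene allele counts and case genotypes.

Frequencies are allele-based: a variant's *relative frequency* divides its
allele count by the total detected alleles of its gene, and its *total
share* divides by the detected alleles across all genes; both are reported
as half-up percentages at two decimals.  Zygosity summaries are case-based.
HGVS validation is purely syntactic (transcript-anchored ``c.`` description);
no sequence lookup is performed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .rounding import percent

__all__ = [
    "VariantRecord",
    "CaseGenotype",
    "load_variants",
    "load_default_variants",
    "load_genotypes",
    "load_default_genotypes",
    "relative_frequency",
    "total_share",
    "ethnicity_matrix",
    "zygosity_summary",
    "validate_hgvs_table",
    "spectrum_table",
    "ETHNIC_GROUPS",
]

ETHNIC_GROUPS = ("Han", "Miao", "Dong", "Tujia", "Yao")

_TRANSCRIPT_RE = re.compile(r"^(N[MR]_\d+\.\d+):c\.(.+)$")
_POS = r"\d+([+-]\d+)?"
_STANDARD_DESC_RE = re.compile(
    rf"^({_POS})(_{_POS})?"
    r"([ACGT]+>[ACGT]+|del[ACGT]*|dup[ACGT]*|ins[ACGT]+|delins[ACGT]+)$"
)
_LENIENT_DESC_RE = re.compile(rf"^({_POS})(_{_POS})?[A-Za-z0-9>]+$")
CLASSIFICATIONS = ("P", "LP", "VUS")


@dataclass(frozen=True)
class VariantRecord:
    disorder: str
    gene: str
    cdna_hgvs: str
    protein_hgvs: str | None
    classification: str  # P | LP | VUS
    counts: Mapping[str, int]  # alleles per ethnic group
    total: int

    def __post_init__(self) -> None:
        if self.classification not in CLASSIFICATIONS:
            raise ValueError(f"{self.cdna_hgvs}: classification must be one of "
                             f"{CLASSIFICATIONS}, got {self.classification!r}")
        if sum(self.counts.values()) != self.total:
            raise ValueError(f"{self.cdna_hgvs}: ethnic allele counts do not sum to total")
        if not _TRANSCRIPT_RE.match(self.cdna_hgvs):
            raise ValueError(f"{self.cdna_hgvs!r} lacks a versioned transcript ':c.' anchor")


@dataclass(frozen=True)
class CaseGenotype:
    case_id: str
    disorder: str
    ethnicity: str
    alleles: tuple[str, ...]  # 1 or 2 "GENE:c.x" references
    zygosity: str  # homozygous | compound-heterozygous | single-detected

    def __post_init__(self) -> None:
        if len(self.alleles) not in (1, 2):
            raise ValueError(f"{self.case_id}: a case carries 1 or 2 detected alleles")
        expected = (
            "single-detected" if len(self.alleles) == 1
            else "homozygous" if self.alleles[0] == self.alleles[1]
            else "compound-heterozygous"
        )
        if self.zygosity != expected:
            raise ValueError(f"{self.case_id}: zygosity {self.zygosity!r} inconsistent "
                             f"with alleles {self.alleles}")


# --- loading and validation --------------------------------------------------

def validate_hgvs_table(rows: pd.DataFrame) -> tuple[list[VariantRecord], list[str]]:
    """Validate a variant table; returns valid records plus diagnostics.

    Rows without a versioned transcript anchor are rejected; syntactically
    unusual descriptions (e.g. ``ins3kb`` with descending positions) are kept
    with a nonstandard-description diagnostic.
    """
    records: list[VariantRecord] = []
    diagnostics: list[str] = []
    for _, row in rows.iterrows():
        hgvs = str(row["cdna_hgvs"]).strip()
        m = _TRANSCRIPT_RE.match(hgvs)
        if m is None:
            diagnostics.append(f"rejected {hgvs!r}: no versioned transcript ':c.' anchor")
            continue
        desc = m.group(2)
        if not _STANDARD_DESC_RE.match(desc):
            if _LENIENT_DESC_RE.match(desc):
                diagnostics.append(f"nonstandard description in {hgvs!r}")
            else:
                diagnostics.append(f"rejected {hgvs!r}: unparseable description {desc!r}")
                continue
        classification = str(row["classification"]).strip()
        if classification not in CLASSIFICATIONS:
            diagnostics.append(f"rejected {hgvs!r}: classification {classification!r}")
            continue
        protein = str(row.get("protein_hgvs", "") or "").strip()
        records.append(VariantRecord(
            disorder=str(row["disorder"]),
            gene=str(row["gene"]),
            cdna_hgvs=hgvs,
            protein_hgvs=None if protein in ("", "-") else protein,
            classification=classification,
            counts={g: int(row[g]) for g in ETHNIC_GROUPS},
            total=int(row["total"]),
        ))
    return records, diagnostics


def load_variants(path: str | Path) -> list[VariantRecord]:
    records, diagnostics = validate_hgvs_table(pd.read_csv(path, sep="\t", comment="#"))
    rejected = [d for d in diagnostics if d.startswith("rejected")]
    if rejected:
        raise ValueError("variant table has invalid rows: " + "; ".join(rejected))
    return records


def load_default_variants() -> list[VariantRecord]:
    with resources.as_file(resources.files("neoscreen.data") / "variants_huaihua.tsv") as p:
        return load_variants(p)


def load_genotypes(path: str | Path) -> list[CaseGenotype]:
    df = pd.read_csv(path, sep="\t", comment="#")
    genotypes = []
    for _, row in df.iterrows():
        alleles = [str(row["allele1"])]
        second = str(row["allele2"]).strip()
        if second and second != "-":
            alleles.append(second)
        genotypes.append(CaseGenotype(
            case_id=str(row["case_id"]),
            disorder=str(row["disorder"]),
            ethnicity=str(row["ethnicity"]),
            alleles=tuple(alleles),
            zygosity=str(row["zygosity"]),
        ))
    return genotypes


def load_default_genotypes() -> list[CaseGenotype]:
    """Shipped case-level genotypes (a synthetic reconstruction; see fixture)."""
    with resources.as_file(resources.files("neoscreen.data") / "genotypes_huaihua.tsv") as p:
        return load_genotypes(p)


# --- spectrum statistics -----------------------------------------------------

def _find(records: Sequence[VariantRecord], gene: str, variant: str) -> VariantRecord:
    for r in records:
        if r.gene == gene and (r.cdna_hgvs == variant or r.cdna_hgvs.endswith(":" + variant)):
            return r
    raise KeyError(f"variant {variant!r} not found in gene {gene!r}")


def relative_frequency(gene: str, variant: str, records: Sequence[VariantRecord]) -> float:
    """Variant alleles as a half-up percentage of the gene's detected alleles."""
    gene_records = [r for r in records if r.gene == gene]
    if not gene_records:
        raise KeyError(f"no records for gene {gene!r}")
    target = _find(gene_records, gene, variant)
    return percent(target.total, sum(r.total for r in gene_records))


def total_share(variant: str, records: Sequence[VariantRecord], gene: str | None = None) -> float:
    """Variant alleles as a half-up percentage of all detected alleles."""
    candidates = [r for r in records if gene is None or r.gene == gene]
    target = next(
        (r for r in candidates
         if r.cdna_hgvs == variant or r.cdna_hgvs.endswith(":" + variant)), None)
    if target is None:
        raise KeyError(f"variant {variant!r} not found")
    return percent(target.total, sum(r.total for r in records))


def ethnicity_matrix(records: Sequence[VariantRecord], normalize: bool = False) -> pd.DataFrame:
    """Variant × ethnic-group allele-count matrix (heatmap input).

    Rows are indexed by ``gene cdna_hgvs``; all-zero columns are preserved.
    With ``normalize=True`` rows are scaled to frequencies summing to 1.
    """
    index = [f"{r.gene} {r.cdna_hgvs}" for r in records]
    data = [[r.counts.get(g, 0) for g in ETHNIC_GROUPS] for r in records]
    df = pd.DataFrame(data, index=index, columns=list(ETHNIC_GROUPS), dtype=int)
    if normalize:
        return df.div(df.sum(axis=1).replace(0, 1), axis=0)
    return df


def zygosity_summary(genotypes: Sequence[CaseGenotype], disorder: str) -> dict[str, float] | None:
    """Case-based zygosity percentages for one disorder (half-up, 2 dp)."""
    cases = [g for g in genotypes if g.disorder == disorder]
    if not cases:
        return None
    n = len(cases)
    return {
        z: percent(sum(g.zygosity == z for g in cases), n)
        for z in ("homozygous", "compound-heterozygous", "single-detected")
    }


def spectrum_table(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Per-variant report: allele counts, relative frequency and total share."""
    grand_total = sum(r.total for r in records)
    gene_totals: dict[str, int] = {}
    for r in records:
        gene_totals[r.gene] = gene_totals.get(r.gene, 0) + r.total
    rows = []
    for r in records:
        rows.append({
            "disorder": r.disorder, "gene": r.gene, "cdna_hgvs": r.cdna_hgvs,
            "classification": r.classification,
            **{g: r.counts.get(g, 0) for g in ETHNIC_GROUPS},
            "total": r.total,
            "relative_frequency_pct": percent(r.total, gene_totals[r.gene]),
            "total_share_pct": percent(r.total, grand_total),
        })
    return pd.DataFrame(rows)
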