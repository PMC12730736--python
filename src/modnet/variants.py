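"""Annotated-variant parsing and the rare/high-impact filter cascade.

The genomic arm of the analysis starts from per-subject VCFs plus a
VEP-style annotation table (gene symbol, consequence, gnomAD allele
frequency, CADD PHRED, pLI, ...).  Variants are joined to their
annotations, QC-filtered, then pushed through the filter cascade:

* ``rare_filter`` — keep alleles with population AF < 0.01 or absent
  from gnomAD (rare or private variants),
* ``high_impact_filter`` — keep alleles with CADD PHRED >= a cutoff
  (30 for highly deleterious, 15 for moderate impact),
* ``pli_prioritize`` — keep genes intolerant to loss of function
  (pLI >= 0.9).

All filters operate on :class:`SubjectVariantSet`, a thin wrapper around
a pandas DataFrame with one row per (variant, gene) annotation, and every
filter returns a new set plus a per-reason removal report so the funnel
is auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "SubjectVariantSet",
    "FilterReport",
    "VennSummary",
    "parse_annotated_variants",
    "qc_filter",
    "rare_filter",
    "high_impact_filter",
    "pli_prioritize",
    "partition_by_subject",
]

#: canonical column order of the record table
RECORD_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene_symbol",
    "biotype",
    "hgvsc",
    "hgvsp",
    "allele_frequency",
    "cadd_phred",
    "pli",
    "zygosity",
    "subject_id",
]


@dataclass(frozen=True)
class VariantRecord:
    """One annotated allele observation in one subject.

    ``allele_frequency`` and ``pli`` may be ``None`` (absent from gnomAD);
    CADD PHRED scores are non-negative; zygosity is ``het`` or ``hom``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_symbol: str
    subject_id: str
    biotype: str = "protein_coding"
    hgvsc: str | None = None
    hgvsp: str | None = None
    allele_frequency: float | None = None
    cadd_phred: float = 0.0
    pli: float | None = None
    zygosity: str = "het"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.allele_frequency is not None and not (
            0.0 <= self.allele_frequency <= 1.0
        ):
            raise ValueError(f"AF out of [0,1]: {self.allele_frequency}")
        if self.cadd_phred < 0:
            raise ValueError(f"negative CADD score: {self.cadd_phred}")
        if self.pli is not None and not (0.0 <= self.pli <= 1.0):
            raise ValueError(f"pLI out of [0,1]: {self.pli}")
        if self.zygosity not in ("het", "hom"):
            raise ValueError(f"zygosity must be het|hom, got {self.zygosity!r}")


@dataclass
class FilterReport:
    """Row-count bookkeeping for one filter application."""

    name: str
    n_in: int
    n_out: int
    removed: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.n_in == self.n_out + sum(self.removed.values())


class SubjectVariantSet:
    """All annotated variant records of one subject.

    Wraps a DataFrame with :data:`RECORD_COLUMNS`; ``gene_index`` is the
    partition of row indices by gene symbol.
    """

    def __init__(self, subject_id: str, records: pd.DataFrame,
                 reports: list[FilterReport] | None = None):
        missing = [c for c in ("gene_symbol",) if c not in records.columns]
        if missing:
            raise ValueError(f"record table lacks columns: {missing}")
        table = records.copy()
        for col in RECORD_COLUMNS:
            if col not in table.columns:
                table[col] = np.nan
        table["subject_id"] = subject_id
        self.subject_id = subject_id
        self.records = table.reset_index(drop=True)
        self.reports: list[FilterReport] = list(reports or [])

    def __len__(self) -> int:
        return len(self.records)

    @property
    def gene_index(self) -> dict[str, list[int]]:
        idx: dict[str, list[int]] = {}
        for i, g in enumerate(self.records["gene_symbol"]):
            if isinstance(g, str) and g:
                idx.setdefault(g, []).append(i)
        return idx

    @property
    def genes(self) -> set[str]:
        vals = self.records["gene_symbol"].dropna()
        return {g for g in vals if isinstance(g, str) and g}

    def variant_keys(self) -> set[tuple]:
        """Distinct (chrom, pos, ref, alt) keys."""
        cols = self.records[["chrom", "pos", "ref", "alt"]]
        return {tuple(r) for r in cols.itertuples(index=False) if pd.notna(r[0])}

    def iter_records(self) -> Iterable[VariantRecord]:
        for row in self.records.itertuples(index=False):
            yield VariantRecord(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                gene_symbol=str(row.gene_symbol),
                subject_id=self.subject_id,
                biotype=str(row.biotype),
                hgvsc=None if pd.isna(row.hgvsc) else str(row.hgvsc),
                hgvsp=None if pd.isna(row.hgvsp) else str(row.hgvsp),
                allele_frequency=None
                if pd.isna(row.allele_frequency)
                else float(row.allele_frequency),
                cadd_phred=float(row.cadd_phred),
                pli=None if pd.isna(row.pli) else float(row.pli),
                zygosity=str(row.zygosity),
            )

    def _derive(self, mask: pd.Series, report: FilterReport) -> "SubjectVariantSet":
        out = SubjectVariantSet(
            self.subject_id,
            self.records.loc[mask],
            reports=self.reports + [report],
        )
        return out

    def report_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.reports:
            for reason, n in sorted(r.removed.items()):
                rows.append({"filter": r.name, "reason": reason, "removed": n})
            rows.append({"filter": r.name, "reason": "<retained>", "removed": r.n_out})
        return pd.DataFrame(rows, columns=["filter", "reason", "removed"])


def _zygosity_from_gt(gt_alleles: Iterable[int], alt_index: int) -> str | None:
    """Map a genotype allele tuple to het/hom for the alt_index-th ALT.

    1-based ``alt_index`` into the site's ALT list.  Returns None when the
    genotype does not carry that ALT allele at all.
    """
    n_alt = sum(1 for a in gt_alleles if a == alt_index)
    if n_alt == 0:
        return None
    return "hom" if n_alt >= 2 else "het"


def parse_annotated_variants(
    vcf_path: str,
    annotation_table_path: str,
    subject_id: str,
    header_map: Mapping[str, str] | None = None,
) -> SubjectVariantSet:
    """Join a VCF with a VEP-style annotation TSV into a variant set.

    One output record per (variant, gene) annotation row; multi-allelic
    sites are split into biallelic records; zygosity is derived from the
    GT field (two copies of the ALT allele -> hom, one -> het).

    Annotation rows that cannot be joined to any VCF record by
    (chrom, pos, ref, alt) are collected — their count is exposed via the
    parse report — never silently dropped.  ``header_map`` renames
    annotation columns onto the canonical names in :data:`RECORD_COLUMNS`.
    """
    from cyvcf2 import VCF

    # genotype per (chrom,pos,ref,alt) key, multi-allelics split
    zygosity: dict[tuple, str] = {}
    for v in VCF(vcf_path):
        alleles = [a for a in (v.genotypes[0][:-1] if v.genotypes else []) if a >= 0]
        for ai, alt in enumerate(v.ALT, start=1):
            z = _zygosity_from_gt(alleles, ai)
            if z is not None:
                zygosity[(str(v.CHROM), int(v.POS), str(v.REF), str(alt))] = z

    ann = pd.read_csv(annotation_table_path, sep="\t", dtype={"chrom": str})
    if header_map:
        ann = ann.rename(columns=dict(header_map))
    required = {"chrom", "pos", "ref", "alt", "gene_symbol"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation table lacks columns: {sorted(missing)}")

    keys = list(zip(ann["chrom"].astype(str), ann["pos"].astype(int),
                    ann["ref"].astype(str), ann["alt"].astype(str)))
    joined = [k in zygosity for k in keys]
    n_unjoined = len(ann) - sum(joined) + max(
        0, len(zygosity) - len({k for k, j in zip(keys, joined) if j})
    ) * 0  # annotation-side orphans only; VCF-side orphans counted below
    table = ann.loc[joined].copy()
    table["zygosity"] = [zygosity[k] for k, j in zip(keys, joined) if j]

    out = SubjectVariantSet(subject_id, table)
    n_vcf_orphans = len(set(zygosity) - set(keys))
    out.reports.append(
        FilterReport(
            "parse",
            n_in=len(ann) + n_vcf_orphans,
            n_out=len(out),
            removed={
                "unjoined_annotation_rows": int(len(ann) - sum(joined)),
                "vcf_records_without_annotation": int(n_vcf_orphans),
            },
        )
    )
    return out


def qc_filter(s: SubjectVariantSet, max_alt_len: int = 25) -> SubjectVariantSet:
    """Remove records failing basic QC.

    Dropped: missing chromosome or gene symbol; ALT alleles longer than
    ``max_alt_len`` bp (likely artifacts — a 25 bp ALT is kept, 26 bp is
    not); non-protein-coding biotype.
    """
    r = s.records
    chrom_ok = r["chrom"].notna() & (r["chrom"].astype(str).str.len() > 0)
    gene_ok = r["gene_symbol"].notna() & (r["gene_symbol"].astype(str).str.len() > 0)
    alt_len = r["alt"].fillna("").astype(str).str.len()
    alt_ok = alt_len <= max_alt_len
    bio = r["biotype"].fillna("protein_coding").astype(str)
    bio_ok = bio.isin(["protein_coding", "LoF", ""])
    keep = chrom_ok & gene_ok & alt_ok & bio_ok
    removed = {
        "missing_chrom": int((~chrom_ok).sum()),
        "missing_gene_symbol": int((chrom_ok & ~gene_ok).sum()),
        "long_alt_allele": int((chrom_ok & gene_ok & ~alt_ok).sum()),
        "non_protein_coding": int((chrom_ok & gene_ok & alt_ok & ~bio_ok).sum()),
    }
    return s._derive(keep, FilterReport("qc", len(r), int(keep.sum()), removed))


def rare_filter(s: SubjectVariantSet, af_max: float = 0.01) -> SubjectVariantSet:
    """Keep rare or unobserved alleles: AF strictly below ``af_max``, or AF
    absent from the population database."""
    if not (0.0 < af_max <= 1.0):
        raise ValueError(f"af_max must be in (0, 1], got {af_max}")
    af = pd.to_numeric(s.records["allele_frequency"], errors="coerce")
    keep = af.isna() | (af < af_max)
    return s._derive(
        keep,
        FilterReport("rare", len(s.records), int(keep.sum()),
                     {"common_af": int((~keep).sum())}),
    )


def high_impact_filter(s: SubjectVariantSet, cadd_min: float) -> SubjectVariantSet:
    """Keep alleles with CADD PHRED >= ``cadd_min`` (inclusive)."""
    if cadd_min < 0:
        raise ValueError("cadd_min must be >= 0")
    cadd = pd.to_numeric(s.records["cadd_phred"], errors="coerce")
    keep = cadd.notna() & (cadd >= cadd_min)
    return s._derive(
        keep,
        FilterReport("high_impact", len(s.records), int(keep.sum()),
                     {"low_cadd": int((~keep).sum())}),
    )


def pli_prioritize(s: SubjectVariantSet, pli_min: float = 0.9) -> SubjectVariantSet:
    """Keep records in loss-of-function-intolerant genes (pLI >= ``pli_min``).

    A missing pLI fails prioritization (pLI is a prioritization criterion,
    not a QC one, so it is only consulted here).
    """
    pli = pd.to_numeric(s.records["pli"], errors="coerce")
    keep = pli.notna() & (pli >= pli_min)
    return s._derive(
        keep,
        FilterReport("pli", len(s.records), int(keep.sum()),
                     {"low_or_missing_pli": int((~keep).sum())}),
    )


@dataclass
class VennSummary:
    """Two-subject overlap at variant-key and gene level."""

    shared_keys: set
    unique_a_keys: set
    unique_b_keys: set
    shared_genes: set
    unique_a_genes: set
    unique_b_genes: set

    def counts(self) -> dict[str, int]:
        return {
            "shared_variants": len(self.shared_keys),
            "unique_a_variants": len(self.unique_a_keys),
            "unique_b_variants": len(self.unique_b_keys),
            "shared_genes": len(self.shared_genes),
            "unique_a_genes": len(self.unique_a_genes),
            "unique_b_genes": len(self.unique_b_genes),
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.counts(), fh, indent=2)


def partition_by_subject(a: SubjectVariantSet, b: SubjectVariantSet) -> VennSummary:
    """Partition two subjects' variants into shared / unique-to-a /
    unique-to-b, at the (chrom, pos, ref, alt) key level and at gene level."""
    ka, kb = a.variant_keys(), b.variant_keys()
    ga, gb = a.genes, b.genes
    return VennSummary(
        shared_keys=ka & kb,
        unique_a_keys=ka - kb,
        unique_b_keys=kb - ka,
        shared_genes=ga & gb,
        unique_a_genes=ga - gb,
        unique_b_genes=gb - ga,
    )
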