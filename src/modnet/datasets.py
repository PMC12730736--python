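"""Curated data tables from the two-sibling TANGO2-deficiency case study.

Three small tables ship with the package:

* the 48 rare (gnomAD AF < 0.01 or unannotated), high-impact
  (CADD >= 30) variants found across the two siblings, with pLI;
* the seven core hub genes of the functional-interaction network with
  their edge counts and in-/out-degrees;
* the variants of uncertain significance or predicted pathogenic
  (CADD >= 15) mapped to the giant components of the personalized
  integrated networks, with per-subject zygosity.

They serve as ground-truth fixtures for the filter cascade and the
integration stage, and as worked-example inputs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .variants import SubjectVariantSet

__all__ = [
    "load_rare_high_impact_variants",
    "load_fi_core_genes",
    "load_integrated_variants",
    "case_variant_set",
    "integrated_variant_sets",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("modnet.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_rare_high_impact_variants() -> pd.DataFrame:
    """The 48 rare high-CADD sibling variants.

    Columns: gene_symbol, hgvsc, hgvsp, existing_variation,
    allele_frequency (may be missing: unobserved in gnomAD), cadd_phred,
    pli (may be missing), subjects ("1", "2" or "1-2").
    """
    return _read("tdd_rare_high_impact_variants.tsv")


def load_fi_core_genes() -> pd.DataFrame:
    """The seven-hub core of the functional-interaction network
    (edge_count, in_degree, out_degree per gene)."""
    return _read("tdd_fi_core_genes.tsv")


def load_integrated_variants() -> pd.DataFrame:
    """CADD >= 15 variants in the giant components of the personalized
    integrated networks, with per-subject zygosity (het/hom/absent).

    One source row prints a pLI above 1 (an artifact in the published
    table); it is loaded as missing.
    """
    df = _read("tdd_integrated_variants.tsv")
    df.loc[df["pli"] > 1.0, "pli"] = pd.NA
    return df


def _subject_mask(subjects: pd.Series, subject: str) -> pd.Series:
    want = subject.removeprefix("subject")
    return subjects.astype(str).str.split("-").apply(lambda parts: want in parts)


def case_variant_set(subject: str) -> SubjectVariantSet:
    """The rare high-impact table as one subject's variant set.

    ``subject`` is "subject1" or "subject2"; rows marked "1-2" belong to
    both.  Positional fields are synthetic placeholders (the published
    table is gene-level), which the filter cascade does not consult.
    """
    df = load_rare_high_impact_variants()
    sub = df[_subject_mask(df["subjects"], subject)].copy()
    return _as_variant_set(sub, subject, zygosity="het")


def _as_variant_set(df: pd.DataFrame, subject: str,
                    zygosity: str | pd.Series = "het") -> SubjectVariantSet:
    table = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": range(1, len(df) + 1),
            "ref": "N",
            "alt": "N",
            "gene_symbol": df["gene_symbol"].to_numpy(),
            "biotype": "protein_coding",
            "hgvsc": df["hgvsc"].to_numpy() if "hgvsc" in df else None,
            "hgvsp": df["hgvsp"].to_numpy() if "hgvsp" in df else None,
            "allele_frequency": df["allele_frequency"].to_numpy(),
            "cadd_phred": df["cadd_phred"].to_numpy(),
            "pli": df["pli"].to_numpy(),
            "zygosity": zygosity if isinstance(zygosity, str)
            else zygosity.to_numpy(),
        }
    )
    return SubjectVariantSet(subject, table)


def integrated_variant_sets() -> dict[str, SubjectVariantSet]:
    """The integrated-network variant table as per-subject variant sets,
    zygosity taken from the per-subject columns."""
    df = load_integrated_variants()
    out: dict[str, SubjectVariantSet] = {}
    for sid, col in (("subject1", "subject1"), ("subject2", "subject2")):
        sub = df[df[col].notna() & (df[col] != "")].copy()
        out[sid] = _as_variant_set(sub, sid, zygosity=sub[col])
    return out
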