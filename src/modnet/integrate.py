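"""Phenotype-ontology integration and the candidate-modifier shortlist.

A virtual gene panel is assembled from Human Phenotype Ontology
annotations of the disease's clinical terms; the interactome induced on
that panel is the disease-phenotype network.  Its giant component is
intersected with the functional-interaction network (DEGs + linkers,
keeping FI edges), every node is overlaid with per-subject variant
annotations (HGVS, zygosity, AF, CADD, pLI), and subject-specific
subnetworks are cut at a CADD >= 15 threshold.  Population frequency is
deliberately *not* re-applied at this stage: common polymorphisms can
act as genetic modifiers, so the integration filter looks at predicted
impact only.  Candidates are the giant-component genes of each
subject-specific subnetwork, reported with their evidence flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .netbuild import ComponentDecomposition, giant_component
from .variants import SubjectVariantSet

__all__ = [
    "PhenotypePanel",
    "CandidateModifier",
    "read_hpo_annotations",
    "write_hpo_annotations",
    "build_phenotype_panel",
    "overlay_variants",
    "cadd_subnetwork",
    "shortlist_candidates",
]


@dataclass
class PhenotypePanel:
    """A virtual gene panel: the union of genes annotated to the
    disease-linked phenotype terms."""

    disease: str
    hpo_terms: list[str]
    genes: set[str]
    per_term_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class CandidateModifier:
    gene: str
    subject: str
    rare: bool
    high_cadd: bool
    homozygous_burden: bool
    differentially_expressed: bool
    phenotype_panel_member: bool
    giant_component_member: bool
    max_cadd: float = 0.0

    @property
    def n_flags(self) -> int:
        return sum(
            [self.rare, self.high_cadd, self.homozygous_burden,
             self.differentially_expressed, self.phenotype_panel_member,
             self.giant_component_member]
        )


def read_hpo_annotations(
    path: str,
    term_col: str = "hpo_id",
    name_col: str = "hpo_name",
    gene_col: str = "gene_symbol",
) -> pd.DataFrame:
    """Read a genes_to_phenotype-style TSV (term id, term name, gene
    symbol; column names configurable)."""
    df = pd.read_csv(path, sep="\t")
    missing = {term_col, gene_col} - set(df.columns)
    if missing:
        raise ValueError(f"HPO annotation table lacks columns: {sorted(missing)}")
    out = df.rename(columns={term_col: "hpo_id", gene_col: "gene_symbol"})
    if name_col in df.columns:
        out = out.rename(columns={name_col: "hpo_name"})
    else:
        out["hpo_name"] = ""
    return out[["hpo_id", "hpo_name", "gene_symbol"]]


def write_hpo_annotations(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False)


def build_phenotype_panel(
    hpo_annotations: pd.DataFrame,
    query_terms: list[str],
    disease: str = "",
) -> PhenotypePanel:
    """Union the gene annotations of ``query_terms`` into a panel.

    Unknown terms fail loudly, listing the offending ids.
    """
    known = set(hpo_annotations["hpo_id"])
    unknown = [t for t in query_terms if t not in known]
    if unknown:
        raise KeyError(f"HPO terms absent from the annotation table: {unknown}")
    sub = hpo_annotations[hpo_annotations["hpo_id"].isin(query_terms)]
    per_term = sub.groupby("hpo_id")["gene_symbol"].nunique().to_dict()
    return PhenotypePanel(
        disease=disease,
        hpo_terms=list(query_terms),
        genes=set(sub["gene_symbol"]),
        per_term_counts={t: int(per_term.get(t, 0)) for t in query_terms},
    )


def overlay_variants(
    n: nx.Graph,
    a: SubjectVariantSet,
    b: SubjectVariantSet,
) -> nx.Graph:
    """Annotate every node with per-subject variant entries.

    Topology is untouched; each node gains a ``variants`` attribute
    mapping subject id -> list of dicts (hgvsc, zygosity, AF, CADD, pLI).
    Nodes without variants carry empty lists.
    """
    g = n.copy()
    per_subject: dict[str, dict[str, list[dict]]] = {}
    for svs in (a, b):
        by_gene: dict[str, list[dict]] = {}
        for gene, rows in svs.gene_index.items():
            recs = svs.records.iloc[rows]
            by_gene[gene] = [
                {
                    "hgvsc": None if pd.isna(r.hgvsc) else str(r.hgvsc),
                    "zygosity": str(r.zygosity),
                    "allele_frequency": None
                    if pd.isna(r.allele_frequency) else float(r.allele_frequency),
                    "cadd_phred": float(r.cadd_phred)
                    if pd.notna(r.cadd_phred) else 0.0,
                    "pli": None if pd.isna(r.pli) else float(r.pli),
                }
                for r in recs.itertuples(index=False)
            ]
        per_subject[svs.subject_id] = by_gene
    for node in g.nodes:
        g.nodes[node]["variants"] = {
            sid: list(by_gene.get(node, [])) for sid, by_gene in per_subject.items()
        }
    return g


def cadd_subnetwork(
    n: nx.Graph,
    subject: str,
    cadd_min: float = 15.0,
) -> ComponentDecomposition:
    """Subject-specific subnetwork of nodes carrying an impactful variant.

    Keeps nodes with at least one variant of CADD >= ``cadd_min`` for
    ``subject`` (population frequency is intentionally ignored here),
    induces the edges, and decomposes into giant component, secondary
    clusters, triads, pairs and singletons.
    """
    keep = []
    for node, data in n.nodes(data=True):
        entries = data.get("variants", {}).get(subject, [])
        if any(e.get("cadd_phred", 0.0) >= cadd_min for e in entries):
            keep.append(node)
    return giant_component(n.subgraph(keep).copy())


def shortlist_candidates(
    decomp: ComponentDecomposition,
    panel: PhenotypePanel,
    de: pd.DataFrame,
    subject: str,
    alpha: float = 0.05,
    af_max: float = 0.01,
    cadd_mid: float = 15.0,
) -> pd.DataFrame:
    """Candidate genetic modifiers from a subject's giant component.

    Every giant-component gene is emitted with its evidence flags:
    ``rare`` (any variant with AF < ``af_max`` or unobserved),
    ``high_cadd`` (any variant with CADD >= ``cadd_mid``),
    ``homozygous_burden`` (any homozygous variant),
    ``differentially_expressed`` (BH-adjusted p < ``alpha``),
    ``phenotype_panel_member`` and ``giant_component_member``.  The
    required conjunction (high_cadd & panel member & giant component)
    holds by construction for every emitted row.  Sorted by flag count
    desc, max CADD desc, gene asc.
    """
    import warnings

    rows: list[CandidateModifier] = []
    if decomp.giant.number_of_nodes() == 0:
        warnings.warn("empty giant component; no candidates")
    sig = de[de["padj"].notna() & (de["padj"] < alpha)] if len(de) else de
    sig_genes = set(map(str, sig.index)) if len(de) else set()

    for node, data in decomp.giant.nodes(data=True):
        entries = data.get("variants", {}).get(subject, [])
        rare = any(
            e.get("allele_frequency") is None or e["allele_frequency"] < af_max
            for e in entries
        )
        high = any(e.get("cadd_phred", 0.0) >= cadd_mid for e in entries)
        hom = any(e.get("zygosity") == "hom" for e in entries)
        cadds = [e.get("cadd_phred", 0.0) for e in entries]
        rows.append(
            CandidateModifier(
                gene=str(node),
                subject=subject,
                rare=rare,
                high_cadd=high,
                homozygous_burden=hom,
                differentially_expressed=str(node) in sig_genes,
                phenotype_panel_member=str(node) in panel.genes,
                giant_component_member=True,
                max_cadd=max(cadds) if cadds else 0.0,
            )
        )
    rows = [r for r in rows
            if r.high_cadd and r.phenotype_panel_member and r.giant_component_member]
    rows.sort(key=lambda r: (-r.n_flags, -r.max_cadd, r.gene))
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "subject": r.subject,
                "rare": r.rare,
                "high_cadd": r.high_cadd,
                "homozygous_burden": r.homozygous_burden,
                "differentially_expressed": r.differentially_expressed,
                "phenotype_panel_member": r.phenotype_panel_member,
                "giant_component_member": r.giant_component_member,
                "max_cadd": r.max_cadd,
                "n_flags": r.n_flags,
            }
            for r in rows
        ],
        columns=[
            "gene", "subject", "rare", "high_cadd", "homozygous_burden",
            "differentially_expressed", "phenotype_panel_member",
            "giant_component_member", "max_cadd", "n_flags",
        ],
    )
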