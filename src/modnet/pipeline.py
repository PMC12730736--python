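"""Workflow orchestration: configuration, the three analysis arms, and
run manifests.

The three workflows mirror the study design:

* **genomic** — parse and QC per-subject variants, apply the rare
  (AF < 0.01 or unobserved) and high-impact (CADD >= 30) filters,
  prioritize LoF-intolerant genes, build subject PPI networks on the
  rare-variant genes, extract giant components and run ORA on them;
* **transcriptomic** — CPM filtering, HLA removal, the NB Wald test,
  sPLS-DA + RFE, the univariate/multivariate DEG intersection, and the
  FI network with linkers plus its topology table;
* **integration** — phenotype panel, disease-phenotype network,
  intersection with the FI network, per-subject variant overlay,
  CADD >= 15 subnetworks, and the candidate-modifier shortlist.

Every run writes its outputs plus a manifest (inputs, seed, sha256 of
each artifact) so a rerun with the same config is byte-identical for the
deterministic stages.  A 1-vs-1 analysis lives or dies by provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import enrich, integrate, mvsel, netbuild, rnaseq, variants

log = logging.getLogger("modnet")

__all__ = ["RunConfig", "run_genomic", "run_transcriptomic",
           "run_integration", "run_all", "write_manifest"]


@dataclass
class RunConfig:
    """All inputs, thresholds and the seed of one pipeline run.

    Thresholds default to the published cascade: AF < 0.01, CADD >= 30
    (high impact) / >= 15 (integration), pLI >= 0.9, CPM >= 0.5 in >= 2
    samples, BH-adjusted alpha 0.05, RFE retention 10%.
    """

    outdir: str = "results/run"
    seed: int = 0
    # inputs
    vcf_subject1: str = ""
    annotations_subject1: str = ""
    vcf_subject2: str = ""
    annotations_subject2: str = ""
    interactome_mitab: str = ""
    fi_database: str = ""
    counts: str = ""
    hpo_annotations: str = ""
    gene_sets_gmt: str = ""
    groups: dict[str, str] = field(default_factory=dict)
    hpo_query_terms: list[str] = field(default_factory=list)
    # thresholds
    af_max: float = 0.01
    cadd_high: float = 30.0
    cadd_mid: float = 15.0
    pli_min: float = 0.9
    cpm_min: float = 0.5
    min_samples: int = 2
    alpha: float = 0.05
    retain_fraction: float = 0.10

    def __post_init__(self) -> None:
        checks = [
            (0 < self.af_max <= 1, "af_max"),
            (self.cadd_high >= 0, "cadd_high"),
            (self.cadd_mid >= 0, "cadd_mid"),
            (0 <= self.pli_min <= 1, "pli_min"),
            (self.cpm_min >= 0, "cpm_min"),
            (self.min_samples >= 1, "min_samples"),
            (0 < self.alpha < 1, "alpha"),
            (0 < self.retain_fraction < 1, "retain_fraction"),
        ]
        bad = [name for ok, name in checks if not ok]
        if bad:
            raise ValueError(f"config thresholds out of range: {bad}")

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def require(self, *fields: str) -> None:
        missing = [f for f in fields if not getattr(self, f)]
        if missing:
            raise FileNotFoundError(f"config inputs not set: {missing}")
        absent = [getattr(self, f) for f in fields
                  if not Path(getattr(self, f)).exists()]
        if absent:
            raise FileNotFoundError(f"input files not found: {absent}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(outdir: Path, cfg: RunConfig, stage: str,
                   outputs: list[Path]) -> Path:
    manifest = {
        "stage": stage,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
    }
    path = outdir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def _funnel(stage: str, name: str, n_in: int, n_out: int) -> None:
    log.info("%s: %s %d -> %d", stage, name, n_in, n_out)


@dataclass
class GenomicArtifacts:
    subject_sets: dict[str, variants.SubjectVariantSet]
    rare_sets: dict[str, variants.SubjectVariantSet]
    high_impact_sets: dict[str, variants.SubjectVariantSet]
    venn: variants.VennSummary
    networks: dict[str, object]
    decompositions: dict[str, netbuild.ComponentDecomposition]
    ora_tables: dict[str, pd.DataFrame]


def run_genomic(cfg: RunConfig) -> GenomicArtifacts:
    cfg.require("vcf_subject1", "annotations_subject1", "vcf_subject2",
                "annotations_subject2", "interactome_mitab", "gene_sets_gmt")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    edges = netbuild.read_mitab(cfg.interactome_mitab)
    universe = {e.source for e in edges} | {e.target for e in edges}
    collection = enrich.read_gmt(cfg.gene_sets_gmt)

    subject_sets, rare_sets, high_sets = {}, {}, {}
    networks, decomps, oras = {}, {}, {}
    for sid, vcf, ann in (("subject1", cfg.vcf_subject1, cfg.annotations_subject1),
                          ("subject2", cfg.vcf_subject2, cfg.annotations_subject2)):
        parsed = variants.parse_annotated_variants(vcf, ann, sid)
        clean = variants.qc_filter(parsed)
        _funnel("genomic", f"{sid} qc", len(parsed), len(clean))
        rare = variants.rare_filter(clean, cfg.af_max)
        _funnel("genomic", f"{sid} rare", len(clean), len(rare))
        high = variants.high_impact_filter(rare, cfg.cadd_high)
        _funnel("genomic", f"{sid} high-impact", len(rare), len(high))
        subject_sets[sid], rare_sets[sid], high_sets[sid] = clean, rare, high

        net = netbuild.build_subject_ppi(rare.genes, edges)
        decomp = netbuild.giant_component(net)
        networks[sid], decomps[sid] = net, decomp
        giant_genes = set(decomp.giant.nodes)
        oras[sid] = enrich.enrichment_table(
            enrich.ora(giant_genes, collection, universe | giant_genes,
                       alpha=cfg.alpha)
        )

        p = outdir / f"{sid}_filtered_variants.tsv"
        rare.records.to_csv(p, sep="\t", index=False)
        outputs.append(p)
        p = outdir / f"{sid}_funnel.tsv"
        rare.report_frame().to_csv(p, sep="\t", index=False)
        outputs.append(p)
        p = outdir / f"{sid}_ppi.sif"
        netbuild.export_sif(net, str(p))
        outputs.append(p)
        p = outdir / f"{sid}_ora.tsv"
        oras[sid].to_csv(p, sep="\t", index=False)
        outputs.append(p)

    venn = variants.partition_by_subject(subject_sets["subject1"],
                                         subject_sets["subject2"])
    p = outdir / "venn.json"
    venn.to_json(str(p))
    outputs.append(p)
    p = outdir / "giant_components.json"
    p.write_text(json.dumps({s: d.counts() for s, d in decomps.items()},
                            indent=2))
    outputs.append(p)
    write_manifest(outdir, cfg, "genomic", outputs)
    return GenomicArtifacts(subject_sets, rare_sets, high_sets, venn,
                            networks, decomps, oras)


@dataclass
class TranscriptomicArtifacts:
    matrix: rnaseq.CountMatrix
    de_table: pd.DataFrame
    qc: rnaseq.QCSummary
    rfe: mvsel.RfeResult
    degs: dict[str, str]
    fi_network: object
    topology: pd.DataFrame
    gsea: list


def run_transcriptomic(cfg: RunConfig) -> TranscriptomicArtifacts:
    cfg.require("counts", "fi_database", "gene_sets_gmt")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    raw = pd.read_csv(cfg.counts, sep="\t", index_col=0)
    groups = cfg.groups or {s: s.rsplit("_", 1)[0] for s in raw.columns}
    m = rnaseq.CountMatrix(raw, groups)
    filt = rnaseq.filter_low_expression(m, cfg.cpm_min, cfg.min_samples)
    _funnel("transcriptomic", "low-expression", len(m.genes), len(filt.genes))
    final, removed_hla = rnaseq.remove_hla(filt)
    _funnel("transcriptomic", "HLA removal", len(filt.genes), len(final.genes))

    qc = rnaseq.qc_summary(final)
    de = rnaseq.nb_wald_test(final, alpha=cfg.alpha)
    n_sig = int((de["padj"] < cfg.alpha).sum())
    _funnel("transcriptomic", "DE (univariate)", len(final.genes), n_sig)
    rfe = mvsel.rfe_select(final.log2cpm, final.groups,
                           retain_fraction=cfg.retain_fraction)
    degs = mvsel.intersect_selections(de, rfe, alpha=cfg.alpha)
    _funnel("transcriptomic", "DEG intersection",
            min(n_sig, len(rfe.final_genes)), len(degs))

    fi_edges = netbuild.read_fi_table(cfg.fi_database)
    fi = netbuild.build_fi_network(degs, fi_edges, add_linkers=True)
    topo = netbuild.topology(fi)

    collection = enrich.read_gmt(cfg.gene_sets_gmt)
    gsea = enrich.gsea_preranked(de["log2fc"].dropna(), collection,
                                 n_perm=1000, seed=cfg.seed)

    p = outdir / "de_results.tsv"
    de.rename_axis("gene").to_csv(p, sep="\t")
    outputs.append(p)
    p = outdir / "deg_intersection.tsv"
    pd.DataFrame(sorted(degs.items()), columns=["gene", "direction"]).to_csv(
        p, sep="\t", index=False)
    outputs.append(p)
    p = outdir / "rfe_diagnostics.json"
    p.write_text(json.dumps({
        "retain_fraction": rfe.retain_fraction,
        "trace_sizes": [len(t) for t in rfe.trace],
        "n_final": len(rfe.final_genes),
        "pca_variance_fractions": list(qc.pca_variance_fractions),
        "removed_hla": removed_hla,
    }, indent=2))
    outputs.append(p)
    p = outdir / "fi_topology.tsv"
    topo.to_csv(p, sep="\t", index=False)
    outputs.append(p)
    p = outdir / "fi_network.sif"
    netbuild.export_sif(fi, str(p))
    outputs.append(p)
    p = outdir / "gsea.tsv"
    pd.DataFrame([dataclasses.asdict(r) for r in gsea]).to_csv(
        p, sep="\t", index=False)
    outputs.append(p)
    write_manifest(outdir, cfg, "transcriptomic", outputs)
    return TranscriptomicArtifacts(final, de, qc, rfe, degs, fi, topo, gsea)


@dataclass
class IntegrationArtifacts:
    panel: integrate.PhenotypePanel
    integrated: object
    decompositions: dict[str, netbuild.ComponentDecomposition]
    shortlists: dict[str, pd.DataFrame]
    enrichment: dict[str, pd.DataFrame]


def run_integration(
    cfg: RunConfig,
    genomic: GenomicArtifacts | None = None,
    transcriptomic: TranscriptomicArtifacts | None = None,
) -> IntegrationArtifacts:
    cfg.require("hpo_annotations", "interactome_mitab", "gene_sets_gmt")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    if genomic is None:
        genomic = run_genomic(cfg)
    if transcriptomic is None:
        transcriptomic = run_transcriptomic(cfg)

    hpo = integrate.read_hpo_annotations(cfg.hpo_annotations)
    terms = cfg.hpo_query_terms or sorted(set(hpo["hpo_id"]))
    panel = integrate.build_phenotype_panel(hpo, terms)

    edges = netbuild.read_mitab(cfg.interactome_mitab)
    pheno_net = netbuild.build_subject_ppi(panel.genes, edges)
    pheno_giant = netbuild.giant_component(pheno_net).giant
    _funnel("integration", "phenotype network giant",
            pheno_net.number_of_nodes(), pheno_giant.number_of_nodes())

    fi = transcriptomic.fi_network
    integrated = netbuild.intersect_networks(fi, pheno_giant, edge_source="a")
    _funnel("integration", "FI x phenotype intersection",
            fi.number_of_nodes(), integrated.number_of_nodes())

    overlaid = integrate.overlay_variants(
        integrated,
        genomic.subject_sets["subject1"],
        genomic.subject_sets["subject2"],
    )

    collection = enrich.read_gmt(cfg.gene_sets_gmt)
    universe = {e.source for e in edges} | {e.target for e in edges}
    decomps, shortlists, enr = {}, {}, {}
    for sid in ("subject1", "subject2"):
        decomp = integrate.cadd_subnetwork(overlaid, sid, cfg.cadd_mid)
        decomps[sid] = decomp
        shortlists[sid] = integrate.shortlist_candidates(
            decomp, panel, transcriptomic.de_table, sid,
            alpha=cfg.alpha, af_max=cfg.af_max, cadd_mid=cfg.cadd_mid,
        )
        giant_genes = set(decomp.giant.nodes)
        terms_enr = enrich.ora(giant_genes, collection,
                               universe | giant_genes, alpha=cfg.alpha) \
            if giant_genes else []
        reduced = enrich.weighted_set_cover(
            [t for t in terms_enr if t.fdr < cfg.alpha])
        enr[sid] = enrich.enrichment_table(reduced)

        p = outdir / f"{sid}_candidates.tsv"
        shortlists[sid].to_csv(p, sep="\t", index=False)
        outputs.append(p)
        p = outdir / f"{sid}_cadd_subnetwork.json"
        p.write_text(json.dumps(decomp.counts(), indent=2))
        outputs.append(p)
        p = outdir / f"{sid}_integrated_enrichment.tsv"
        enr[sid].to_csv(p, sep="\t", index=False)
        outputs.append(p)

    p = outdir / "panel.json"
    p.write_text(json.dumps({
        "disease": panel.disease,
        "n_terms": len(panel.hpo_terms),
        "n_genes": len(panel.genes),
        "per_term_counts": panel.per_term_counts,
    }, indent=2))
    outputs.append(p)
    write_manifest(outdir, cfg, "integration", outputs)
    return IntegrationArtifacts(panel, overlaid, decomps, shortlists, enr)


def analyze_bundle(bundle, cfg: RunConfig | None = None) -> dict[str, object]:
    """Run the whole analysis on an in-memory synthetic study bundle.

    File-free twin of :func:`run_all` for simulation experiments (e.g.
    planted-modifier recovery): same stages, same thresholds, no
    artifacts written.  Returns the per-stage objects keyed by name.
    """
    from .variants import SubjectVariantSet

    cfg = cfg or RunConfig()
    m = rnaseq.filter_low_expression(bundle.counts, cfg.cpm_min, cfg.min_samples)
    m, _ = rnaseq.remove_hla(m)
    de = rnaseq.nb_wald_test(m, alpha=cfg.alpha)
    rfe = mvsel.rfe_select(m.log2cpm, m.groups,
                           retain_fraction=cfg.retain_fraction)
    degs = mvsel.intersect_selections(de, rfe, alpha=cfg.alpha)
    fi = netbuild.build_fi_network(degs, bundle.fi_db)

    panel = integrate.build_phenotype_panel(
        bundle.hpo_annotations, sorted(set(bundle.hpo_annotations["hpo_id"])))
    pheno = netbuild.build_subject_ppi(panel.genes, bundle.interactome)
    pheno_giant = netbuild.giant_component(pheno).giant
    integrated = netbuild.intersect_networks(fi, pheno_giant, edge_source="a")

    s1 = SubjectVariantSet("subject1", bundle.variants_subject1)
    s2 = SubjectVariantSet("subject2", bundle.variants_subject2)
    overlaid = integrate.overlay_variants(integrated, s1, s2)
    decomps, shortlists = {}, {}
    for sid in ("subject1", "subject2"):
        decomps[sid] = integrate.cadd_subnetwork(overlaid, sid, cfg.cadd_mid)
        shortlists[sid] = integrate.shortlist_candidates(
            decomps[sid], panel, de, sid, alpha=cfg.alpha,
            af_max=cfg.af_max, cadd_mid=cfg.cadd_mid)
    return {
        "matrix": m, "de_table": de, "rfe": rfe, "degs": degs,
        "fi_network": fi, "panel": panel, "phenotype_giant": pheno_giant,
        "integrated": overlaid, "decompositions": decomps,
        "shortlists": shortlists,
    }


def run_all(cfg: RunConfig) -> dict[str, object]:
    genomic = run_genomic(cfg)
    transcriptomic = run_transcriptomic(cfg)
    integration = run_integration(cfg, genomic, transcriptomic)
    return {"genomic": genomic, "transcriptomic": transcriptomic,
            "integration": integration}
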