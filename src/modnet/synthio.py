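"""Synthetic study generator with planted ground truth.

Every downstream stage of the pipeline is exercised against data drawn
here, with the statistical structure the analysis assumes:

* two subjects sharing most exome variants, plus subject-unique
  variants; a handful of *planted modifier genes* appear only in
  subject 1 as rare (AF < 0.01 or unobserved), homozygous, high-CADD
  (>= 30) alleles;
* an undirected physical interactome and a directed functional-
  interaction (FI) database, both scale-free (preferential attachment),
  with a denser functional module over the differentially expressed
  genes — differential expression is modelled as the readout of a
  perturbed functional module, so FI edges are enriched among DE genes
  and the planted modifiers;
* a 2-group x 3-replicate negative-binomial count matrix with planted
  DE genes (the modifiers among them, upregulated in subject 1);
* a phenotype-term gene panel whose terms preferentially annotate the
  disease module and always cover the planted modifiers.

All generators are fully deterministic under a fixed seed, and every
table round-trips through the corresponding reader.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .netbuild import InteractionEdge, HUMAN_TAXON
from .rnaseq import CountMatrix

__all__ = [
    "AFModel",
    "CaddModel",
    "LibsizeModel",
    "SimTruth",
    "StudyBundle",
    "simulate_variant_tables",
    "simulate_interactome",
    "simulate_fi_database",
    "simulate_counts",
    "simulate_phenotype_panel",
    "simulate_gene_sets",
    "simulate_study",
    "write_vcf",
]

_BASES = np.array(list("ACGT"))


@dataclass
class AFModel:
    """Population allele-frequency model: Beta(a, b) with a fraction of
    records missing AF entirely (never observed in the population)."""

    beta_a: float = 0.2
    beta_b: float = 5.0
    missing_fraction: float = 0.1


@dataclass
class CaddModel:
    """CADD PHRED model: background uniform, planted records uniform on a
    clearly deleterious range."""

    background_low: float = 0.0
    background_high: float = 25.0
    planted_low: float = 30.0
    planted_high: float = 50.0


@dataclass
class LibsizeModel:
    """Log-normal library sizes."""

    mean: float = 1.5e6
    sigma: float = 0.2


@dataclass
class SimTruth:
    """Planted ground truth of one simulated study."""

    modifier_genes: list[str] = field(default_factory=list)
    de_genes: list[tuple[str, float]] = field(default_factory=list)
    panel_genes: list[str] = field(default_factory=list)
    seed: int = 0


def default_gene_universe(n_genes: int, n_hla: int = 3) -> list[str]:
    """Synthetic gene symbols, including a few HLA-prefixed genes so the
    HLA-removal step has work to do."""
    hla = ["HLA-A", "HLA-B", "HLA-DRB1", "HLA-C", "HLA-DQA1"][:n_hla]
    if n_genes <= n_hla:
        return hla[:n_genes]
    return [f"G{i:05d}" for i in range(n_genes - len(hla))] + hla


def _gene_pli(genes: list[str], rng: np.random.Generator) -> dict[str, float | None]:
    """Per-gene pLI: ~20% of genes LoF-intolerant, 5% unannotated."""
    pli: dict[str, float | None] = {}
    for g in genes:
        u = rng.random()
        if u < 0.05:
            pli[g] = None
        elif u < 0.25:
            pli[g] = float(rng.uniform(0.8, 1.0))
        else:
            pli[g] = float(np.clip(rng.beta(0.5, 8.0), 0.0, 1.0))
    return pli


def _draw_variants(
    n: int,
    genes: list[str],
    rng: np.random.Generator,
    af_model: AFModel,
    cadd_model: CaddModel,
    pli: dict[str, float | None],
    used_keys: set[tuple],
    planted: bool = False,
    gene_choices: list[str] | None = None,
) -> pd.DataFrame:
    rows = []
    pool = gene_choices if gene_choices is not None else genes
    for i in range(n):
        gene = pool[i] if planted else pool[int(rng.integers(len(pool)))]
        while True:
            chrom = f"chr{int(rng.integers(1, 23))}"
            pos = int(rng.integers(1, 5_000_000))
            key = (chrom, pos)
            if key not in used_keys:
                used_keys.add(key)
                break
        ref = str(rng.choice(_BASES))
        alt = str(rng.choice([b for b in _BASES if b != ref]))
        if planted:
            af = None if rng.random() < af_model.missing_fraction \
                else float(rng.uniform(0.0, 0.009))
            cadd = float(rng.uniform(cadd_model.planted_low, cadd_model.planted_high))
        else:
            af = None if rng.random() < af_model.missing_fraction \
                else float(np.clip(rng.beta(af_model.beta_a, af_model.beta_b), 0, 1))
            cadd = float(rng.uniform(cadd_model.background_low,
                                     cadd_model.background_high))
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "gene_symbol": gene,
                "biotype": "protein_coding",
                "hgvsc": f"c.{pos % 999 + 1}{ref}>{alt}",
                "hgvsp": None,
                "allele_frequency": af,
                "cadd_phred": cadd,
                "pli": pli.get(gene),
            }
        )
    return pd.DataFrame(rows)


def simulate_variant_tables(
    n_genes: int = 1500,
    n_shared: int = 2500,
    n_unique_per_subject: int = 400,
    n_planted: int = 5,
    af_model: AFModel | None = None,
    cadd_model: CaddModel | None = None,
    seed: int = 0,
    genes: list[str] | None = None,
    planted_genes: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Two per-subject annotated variant tables with planted modifiers.

    The subjects share exactly ``n_shared`` variant keys; each carries
    ``n_unique_per_subject`` additional private variants, the first
    ``n_planted`` of subject 1's being the planted modifiers: rare or
    unobserved, CADD in the planted (>= 30) range, homozygous, in
    distinct genes.  Zygosity elsewhere is Bernoulli(0.1) homozygous.
    """
    if min(n_genes, n_shared, n_unique_per_subject) <= 0 and n_planted > 0:
        raise ValueError("counts must be positive")
    if n_genes <= 0 or n_shared < 0 or n_unique_per_subject < 0:
        raise ValueError("counts must be positive")
    if n_planted > n_unique_per_subject:
        raise ValueError("n_planted exceeds n_unique_per_subject")
    if n_shared + 2 * n_unique_per_subject > n_genes * 3000:
        raise ValueError("variant count exceeds the positional capacity "
                         f"of {n_genes} genes")
    af_model = af_model or AFModel()
    cadd_model = cadd_model or CaddModel()
    rng = np.random.default_rng(seed)
    genes = genes if genes is not None else default_gene_universe(n_genes)
    if n_planted > len(genes):
        raise ValueError("more planted modifiers than genes")
    pli = _gene_pli(genes, rng)
    used: set[tuple] = set()

    if planted_genes is None:
        planted_genes = [genes[i] for i in
                         rng.choice(len(genes), size=n_planted, replace=False)]
    elif len(planted_genes) != n_planted:
        raise ValueError("planted_genes length must equal n_planted")

    shared = _draw_variants(n_shared, genes, rng, af_model, cadd_model, pli, used)
    uniq1_planted = _draw_variants(
        n_planted, genes, rng, af_model, cadd_model, pli, used,
        planted=True, gene_choices=planted_genes,
    )
    uniq1_bg = _draw_variants(
        n_unique_per_subject - n_planted, genes, rng, af_model, cadd_model,
        pli, used,
    )
    uniq2 = _draw_variants(
        n_unique_per_subject, genes, rng, af_model, cadd_model, pli, used,
    )

    def with_zygosity(df: pd.DataFrame, forced: str | None = None) -> pd.DataFrame:
        out = df.copy()
        if forced:
            out["zygosity"] = forced
        else:
            out["zygosity"] = np.where(rng.random(len(out)) < 0.1, "hom", "het")
        return out

    t1 = pd.concat(
        [with_zygosity(shared), with_zygosity(uniq1_planted, forced="hom"),
         with_zygosity(uniq1_bg)],
        ignore_index=True,
    )
    t2 = pd.concat([with_zygosity(shared), with_zygosity(uniq2)],
                   ignore_index=True)
    truth = SimTruth(modifier_genes=list(planted_genes), seed=seed)
    return t1, t2, truth


def simulate_interactome(
    n_nodes: int = 1500,
    degree_model: int = 5,
    taxon: int = HUMAN_TAXON,
    seed: int = 0,
    genes: list[str] | None = None,
) -> list[InteractionEdge]:
    """Scale-free undirected interactome via preferential attachment.

    ``degree_model`` is the number of edges each arriving node attaches
    with; the resulting graph is connected (the giant component is the
    whole graph), with no self-loops or duplicate unordered pairs.
    """
    if n_nodes < 2:
        raise ValueError("need >= 2 nodes")
    if degree_model < 1:
        raise ValueError("degree_model must be >= 1")
    m = min(degree_model, n_nodes - 1)
    g = nx.barabasi_albert_graph(n_nodes, m, seed=int(seed))
    names = genes if genes is not None else default_gene_universe(n_nodes)
    if len(names) < n_nodes:
        raise ValueError("gene list shorter than n_nodes")
    return [
        InteractionEdge(names[u], names[v], directed=False, taxon=taxon,
                        provenance=f"intact:EBI-SYN{u:05d}{v:05d}")
        for u, v in sorted(g.edges())
    ]


def simulate_fi_database(
    n_nodes: int = 1500,
    degree_model: int = 3,
    module_genes: list[str] | None = None,
    p_module: float = 0.12,
    seed: int = 0,
    genes: list[str] | None = None,
) -> list[InteractionEdge]:
    """Directed functional-interaction database.

    A preferential-attachment skeleton with random edge orientations,
    plus extra directed edges among ``module_genes`` (each unordered pair
    with probability ``p_module``): functionally related genes — the
    perturbed disease module — are densely interconnected, which is the
    structure the FI-linker analysis presumes.
    """
    if degree_model < 1:
        raise ValueError("degree_model must be >= 1")
    rng = np.random.default_rng(seed)
    names = genes if genes is not None else default_gene_universe(n_nodes)
    m = min(degree_model, n_nodes - 1)
    g = nx.barabasi_albert_graph(n_nodes, m, seed=int(seed))
    pairs: set[tuple[str, str]] = set()
    for u, v in sorted(g.edges()):
        a, b = names[u], names[v]
        pairs.add((a, b) if rng.random() < 0.5 else (b, a))
    if module_genes:
        mod = sorted(set(module_genes) & set(names))
        for i in range(len(mod)):
            for j in range(i + 1, len(mod)):
                if rng.random() < p_module:
                    a, b = mod[i], mod[j]
                    pairs.add((a, b) if rng.random() < 0.5 else (b, a))
    return [
        InteractionEdge(a, b, directed=True, provenance="reactome-fi-syn")
        for a, b in sorted(pairs)
    ]


def simulate_counts(
    n_genes: int = 1500,
    n_reps: int = 3,
    de_fraction: float = 0.08,
    effect_log2fc: float = 2.0,
    dispersion: float = 0.05,
    libsize_model: LibsizeModel | None = None,
    seed: int = 0,
    genes: list[str] | None = None,
    forced_de: list[str] | None = None,
) -> tuple[CountMatrix, SimTruth]:
    """Two-group negative-binomial count matrix with planted DE genes.

    Counts for gene g in sample j are NB with mean
    ``libsize_j * p_g * 2^(+-log2fc_g / 2)`` (+ for group subject1, - for
    subject2) and the given dispersion.  A ``de_fraction`` of genes get
    ``effect_log2fc`` with random sign; genes in ``forced_de`` are always
    DE with positive sign (up in subject 1).  Genes in ``forced_de`` are
    given baselines at or above the median expression, as candidate
    modifier genes are assumed expressed in the assayed tissue.
    """
    if n_reps < 2:
        raise ValueError("need >= 2 replicates per group")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if not (0.0 <= de_fraction <= 1.0):
        raise ValueError("de_fraction must be in [0, 1]")
    libsize_model = libsize_model or LibsizeModel()
    rng = np.random.default_rng(seed)
    genes = genes if genes is not None else default_gene_universe(n_genes)
    if len(genes) != n_genes:
        n_genes = len(genes)

    base = np.exp(rng.normal(math.log(200.0), 1.2, size=n_genes))
    forced_de = list(forced_de or [])
    gene_pos = {g: i for i, g in enumerate(genes)}
    med = float(np.median(base))
    for g in forced_de:
        i = gene_pos[g]
        base[i] = max(base[i], med * float(np.exp(rng.uniform(0.5, 1.5))))

    lfc = np.zeros(n_genes)
    n_de = int(round(de_fraction * n_genes))
    forced_idx = [gene_pos[g] for g in forced_de]
    free = np.array([i for i in range(n_genes) if i not in set(forced_idx)])
    n_extra = max(0, n_de - len(forced_idx))
    extra = rng.choice(free, size=min(n_extra, len(free)), replace=False) \
        if n_extra else np.array([], dtype=int)
    lfc[forced_idx] = abs(effect_log2fc)
    lfc[extra] = np.where(rng.random(len(extra)) < 0.5, 1.0, -1.0) * effect_log2fc

    p = base / base.sum()
    samples = [f"subject1_r{i+1}" for i in range(n_reps)] + \
              [f"subject2_r{i+1}" for i in range(n_reps)]
    groups = {s: ("subject1" if s.startswith("subject1") else "subject2")
              for s in samples}
    lib = np.exp(rng.normal(math.log(libsize_model.mean), libsize_model.sigma,
                            size=2 * n_reps))
    counts = np.zeros((n_genes, 2 * n_reps), dtype=np.int64)
    for j, s in enumerate(samples):
        sign = +0.5 if groups[s] == "subject1" else -0.5
        mu = lib[j] * p * np.exp2(sign * lfc)
        if dispersion < 1e-8:
            counts[:, j] = rng.poisson(mu)
        else:
            r = 1.0 / dispersion
            counts[:, j] = rng.negative_binomial(r, r / (r + mu))
    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=samples), groups)
    de = [(genes[i], float(lfc[i])) for i in np.flatnonzero(lfc)]
    return cm, SimTruth(de_genes=de, seed=seed)


def simulate_phenotype_panel(
    genes: list[str],
    n_terms: int = 12,
    genes_per_term: tuple[int, int] = (20, 60),
    include: list[str] | None = None,
    seed: int = 0,
    favored: list[str] | None = None,
    favored_weight: float = 0.5,
    disease: str = "synthetic metabolic encephalomyopathy",
) -> pd.DataFrame:
    """HPO-style term -> gene annotation table.

    Terms annotate ``genes_per_term`` genes drawn from the universe; a
    ``favored`` subset (the disease module) receives ``favored_weight``
    of each term's probability mass, mirroring how phenotype terms
    preferentially annotate genes of the disease process.  Every gene in
    ``include`` is guaranteed at least one annotation.  Round-trips
    through the genes_to_phenotype reader.
    """
    if not genes:
        raise ValueError("empty gene universe")
    include = list(include or [])
    if not set(include) <= set(genes):
        raise ValueError("include genes must be a subset of the universe")
    rng = np.random.default_rng(seed)
    lo, hi = genes_per_term
    favored = sorted(set(favored or []) & set(genes))
    others = sorted(set(genes) - set(favored))

    rows = []
    term_ids = [f"HP:9{i:06d}" for i in range(n_terms)]
    for t, tid in enumerate(term_ids):
        k = int(rng.integers(lo, hi + 1))
        chosen: set[str] = set()
        while len(chosen) < min(k, len(genes)):
            if favored and rng.random() < favored_weight:
                chosen.add(favored[int(rng.integers(len(favored)))])
            elif others:
                chosen.add(others[int(rng.integers(len(others)))])
            else:
                chosen.add(favored[int(rng.integers(len(favored)))])
        for g in sorted(chosen):
            rows.append({"hpo_id": tid, "hpo_name": f"{disease} feature {t}",
                         "gene_symbol": g})
    for g in include:
        tid = term_ids[int(rng.integers(n_terms))]
        rows.append({"hpo_id": tid,
                     "hpo_name": f"{disease} feature {term_ids.index(tid)}",
                     "gene_symbol": g})
    df = pd.DataFrame(rows).drop_duplicates().reset_index(drop=True)
    return df.sort_values(["hpo_id", "gene_symbol"]).reset_index(drop=True)


def simulate_gene_sets(
    genes: list[str],
    n_sets: int = 30,
    size_range: tuple[int, int] = (10, 80),
    seed: int = 0,
    database: str = "synthetic-pathways",
):
    """Random GMT-style gene-set collection over the universe."""
    from .enrich import GeneSetCollection

    rng = np.random.default_rng(seed)
    lo, hi = size_range
    sets = {}
    for i in range(n_sets):
        k = int(rng.integers(lo, min(hi, len(genes)) + 1))
        idx = rng.choice(len(genes), size=k, replace=False)
        sets[f"SYNPATH_{i:03d}"] = sorted(genes[j] for j in idx)
    return GeneSetCollection(sets, database=database)


# ---------------------------------------------------------------------------
# study bundle
# ---------------------------------------------------------------------------

@dataclass
class StudyBundle:
    """Everything one simulated two-subject study comprises."""

    genes: list[str]
    variants_subject1: pd.DataFrame
    variants_subject2: pd.DataFrame
    interactome: list[InteractionEdge]
    fi_db: list[InteractionEdge]
    counts: CountMatrix
    hpo_annotations: pd.DataFrame
    gene_sets: object
    truth: SimTruth

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Materialize the bundle as the on-disk formats the readers
        consume; returns a name -> path map."""
        from .netbuild import write_mitab, write_fi_table
        from .enrich import write_gmt
        from .integrate import write_hpo_annotations

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, str] = {}
        for sid, table in (("subject1", self.variants_subject1),
                           ("subject2", self.variants_subject2)):
            vcf = out / f"{sid}.vcf"
            ann = out / f"{sid}.annotations.tsv"
            write_vcf(table, str(vcf), sample=sid)
            table.drop(columns=["zygosity"]).to_csv(ann, sep="\t", index=False)
            paths[f"{sid}_vcf"] = str(vcf)
            paths[f"{sid}_annotations"] = str(ann)
        write_mitab(self.interactome, str(out / "interactome.mitab"))
        paths["interactome"] = str(out / "interactome.mitab")
        write_fi_table(self.fi_db, str(out / "fi_database.tsv"))
        paths["fi_database"] = str(out / "fi_database.tsv")
        self.counts.to_tsv(str(out / "counts.tsv"))
        paths["counts"] = str(out / "counts.tsv")
        write_hpo_annotations(self.hpo_annotations, str(out / "hpo_annotations.tsv"))
        paths["hpo_annotations"] = str(out / "hpo_annotations.tsv")
        write_gmt(self.gene_sets, str(out / "gene_sets.gmt"))
        paths["gene_sets"] = str(out / "gene_sets.gmt")
        (out / "truth.json").write_text(_truth_json(self.truth))
        paths["truth"] = str(out / "truth.json")
        return paths


def _truth_json(truth: SimTruth) -> str:
    import json

    return json.dumps(asdict(truth), indent=2)


def simulate_study(
    n_genes: int = 1500,
    n_planted: int = 5,
    effect_log2fc: float = 2.0,
    dispersion: float = 0.05,
    de_fraction: float = 0.08,
    n_reps: int = 3,
    n_shared: int = 2500,
    n_unique_per_subject: int = 400,
    seed: int = 0,
) -> StudyBundle:
    """One coherent simulated study with planted modifiers.

    The planted modifier genes are (a) reasonably connected in both the
    interactome and the FI database, (b) differentially expressed
    (upregulated in subject 1), (c) carriers of subject-1-unique rare
    homozygous high-CADD variants, and (d) phenotype-panel members — the
    signature the pipeline is designed to recover.
    """
    rng = np.random.default_rng(seed)
    genes = default_gene_universe(n_genes)
    hla = [g for g in genes if g.startswith("HLA-")]

    # degree-aware modifier choice: candidate modifiers must sit inside
    # both networks, like real disease genes do
    inter_skel = nx.barabasi_albert_graph(n_genes, 5, seed=int(seed))
    fi_skel = nx.barabasi_albert_graph(n_genes, 3, seed=int(seed) + 1)
    eligible = [
        i for i in range(n_genes)
        if inter_skel.degree(i) >= 5 and fi_skel.degree(i) >= 3
        and genes[i] not in hla
    ]
    mod_idx = rng.choice(len(eligible), size=n_planted, replace=False)
    modifiers = sorted(genes[eligible[i]] for i in mod_idx)

    counts, counts_truth = simulate_counts(
        n_genes=n_genes,
        n_reps=n_reps,
        de_fraction=de_fraction,
        effect_log2fc=effect_log2fc,
        dispersion=dispersion,
        seed=int(rng.integers(2**31 - 1)),
        genes=genes,
        forced_de=modifiers,
    )
    de_gene_names = [g for g, _ in counts_truth.de_genes if not g.startswith("HLA-")]
    module = sorted(set(de_gene_names) | set(modifiers))

    interactome = [
        InteractionEdge(genes[u], genes[v], directed=False,
                        provenance=f"intact:EBI-SYN{u:05d}{v:05d}")
        for u, v in sorted(inter_skel.edges())
    ]
    fi_db = simulate_fi_database(
        n_nodes=n_genes, degree_model=3, module_genes=module,
        p_module=0.12, seed=int(seed) + 1, genes=genes,
    )

    t1, t2, var_truth = simulate_variant_tables(
        n_genes=n_genes,
        n_shared=n_shared,
        n_unique_per_subject=n_unique_per_subject,
        n_planted=n_planted,
        seed=int(rng.integers(2**31 - 1)),
        genes=genes,
        planted_genes=modifiers,
    )

    # phenotype terms annotate the disease module preferentially and the
    # interactome neighbourhood of the modifiers, covering all modifiers
    neighborhood = set(module)
    name_pos = {g: i for i, g in enumerate(genes)}
    for g in modifiers:
        neighborhood |= {genes[nb] for nb in inter_skel.neighbors(name_pos[g])}
    hpo = simulate_phenotype_panel(
        genes=genes,
        n_terms=12,
        genes_per_term=(20, 60),
        include=modifiers,
        favored=sorted(neighborhood),
        favored_weight=0.5,
        seed=int(rng.integers(2**31 - 1)),
    )
    gene_sets = simulate_gene_sets(genes, seed=int(rng.integers(2**31 - 1)))

    truth = SimTruth(
        modifier_genes=modifiers,
        de_genes=counts_truth.de_genes,
        panel_genes=sorted(set(hpo["gene_symbol"])),
        seed=seed,
    )
    return StudyBundle(
        genes=genes,
        variants_subject1=t1,
        variants_subject2=t2,
        interactome=interactome,
        fi_db=fi_db,
        counts=counts,
        hpo_annotations=hpo,
        gene_sets=gene_sets,
        truth=truth,
    )


def write_vcf(table: pd.DataFrame, path: str, sample: str) -> None:
    """Write a variant table as a minimal single-sample VCF 4.2 with GT."""
    df = table.copy()

    def chrom_key(c: str) -> tuple:
        c = str(c).removeprefix("chr")
        return (0, int(c)) if c.isdigit() else (1, c)

    # one VCF row per (chrom,pos,ref,alt) key — annotation rows may repeat keys
    seen: set[tuple] = set()
    rows = []
    for r in df.itertuples(index=False):
        key = (str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        if key in seen:
            continue
        seen.add(key)
        gt = "1/1" if r.zygosity == "hom" else "0/1"
        rows.append((key[0], key[1], key[2], key[3], gt))
    rows.sort(key=lambda r: (chrom_key(r[0]), r[1], r[2], r[3]))

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted({r[0] for r in rows}, key=chrom_key):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample}\n")
        for chrom, pos, ref, alt, gt in rows:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt}\n")
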