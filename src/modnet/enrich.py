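"""Over-representation analysis, redundancy reduction and preranked GSEA.

ORA scores each gene set by the hypergeometric upper tail of its overlap
with the query against a protein-coding reference universe, with
Benjamini-Hochberg adjustment per collection (KEGG, Reactome, GO-CC, or
a custom GMT).  A greedy weighted set cover then prunes redundant
significant terms.  Preranked GSEA uses the weighted Kolmogorov-Smirnov
running sum on a gene -> log2 fold change ranking with a gene-label
permutation null (sample permutation is impossible at n = 3 + 3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "EnrichmentTerm",
    "GseaResult",
    "read_gmt",
    "write_gmt",
    "ora",
    "weighted_set_cover",
    "gsea_preranked",
]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT rows) from one database."""

    sets: dict[str, list[str]]
    database: str = "custom"

    def __post_init__(self) -> None:
        clean = {}
        for name, genes in self.sets.items():
            dedup = list(dict.fromkeys(genes))
            if not dedup:
                raise ValueError(f"empty gene set: {name}")
            clean[name] = dedup
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class EnrichmentTerm:
    term: str
    database: str
    overlap: int
    set_size: int
    expected: float
    enrichment_ratio: float
    pvalue: float
    fdr: float
    members: list[str] = field(default_factory=list)


@dataclass
class GseaResult:
    term: str
    es: float
    nes: float
    pvalue: float
    fdr: float


def read_gmt(path: str, database: str = "custom") -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *genes = parts
            sets[name] = [g for g in genes if g]
    return GeneSetCollection(sets, database=database)


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, collection.database, *genes]) + "\n")


def ora(
    query: set[str],
    collection: GeneSetCollection,
    universe: set[str],
    alpha: float = 0.05,
) -> list[EnrichmentTerm]:
    """Hypergeometric over-representation of each term in the query.

    Per term: overlap k of the n query genes with the K-gene set inside
    the N-gene universe; p = P(X >= k) for X ~ Hypergeom(N, K, n).  BH is
    applied across all terms of the collection; significance is
    fdr < ``alpha``.  Query genes outside the universe are dropped with a
    warning; set members outside the universe do not count toward K.
    """
    if not universe:
        raise ValueError("empty universe")
    stray = query - universe
    if stray:
        warnings.warn(f"{len(stray)} query genes outside the universe dropped")
    q = query & universe
    N, n = len(universe), len(q)

    rows = []
    for name, genes in collection.sets.items():
        members_in_universe = [g for g in genes if g in universe]
        K = len(members_in_universe)
        if K == 0:
            continue
        hits = sorted(q.intersection(members_in_universe))
        k = len(hits)
        expected = n * K / N
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, K, k, expected, hits, min(p, 1.0)))

    pvals = np.array([r[5] for r in rows]) if rows else np.array([])
    fdrs = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else []
    out = []
    for (name, K, k, expected, hits, p), fdr in zip(rows, fdrs):
        out.append(
            EnrichmentTerm(
                term=name,
                database=collection.database,
                overlap=k,
                set_size=K,
                expected=expected,
                enrichment_ratio=(k / expected) if expected > 0 else np.nan,
                pvalue=p,
                fdr=float(fdr),
                members=hits,
            )
        )
    out.sort(key=lambda t: (t.fdr, t.pvalue, t.term))
    return out


def enrichment_table(terms: list[EnrichmentTerm]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": t.term,
                "database": t.database,
                "overlap": t.overlap,
                "set_size": t.set_size,
                "expected": t.expected,
                "enrichment_ratio": t.enrichment_ratio,
                "pvalue": t.pvalue,
                "fdr": t.fdr,
                "members": ";".join(t.members),
            }
            for t in terms
        ]
    )


def weighted_set_cover(
    significant: list[EnrichmentTerm],
    top_k: int | None = None,
    eps: float = 1e-300,
) -> list[EnrichmentTerm]:
    """Greedy weighted set cover over the members of significant terms.

    Each step picks the term maximizing newly-covered genes divided by
    its weight, weight = 1 / (-log10(fdr) + ``eps``) — i.e. more
    significant terms are cheaper.  Ties break by (fdr, term name).
    Stops when every member gene is covered or ``top_k`` terms are
    chosen.
    """
    all_genes: set[str] = set()
    for t in significant:
        all_genes |= set(t.members)
    covered: set[str] = set()
    remaining = list(significant)
    chosen: list[EnrichmentTerm] = []
    limit = top_k if top_k is not None else len(significant)

    def gain_per_weight(t: EnrichmentTerm) -> float:
        new = len(set(t.members) - covered)
        score = -np.log10(max(t.fdr, 1e-320)) + eps
        return new * score

    while covered != all_genes and len(chosen) < limit and remaining:
        best = max(
            remaining,
            key=lambda t: (gain_per_weight(t), -t.fdr,
                           tuple(-ord(c) for c in t.term)),
        )
        if len(set(best.members) - covered) == 0:
            break
        chosen.append(best)
        covered |= set(best.members)
        remaining.remove(best)
    return chosen


def _running_es(ranked_weights: np.ndarray, hit_mask: np.ndarray) -> float:
    """Signed maximum deviation of the weighted KS running sum.

    ``ranked_weights`` are |score|^p in ranking order; ``hit_mask`` marks
    set members.  Hits step up proportionally to their weight, misses
    step down by 1/(N - Nh).
    """
    nh = int(hit_mask.sum())
    n = len(hit_mask)
    if nh == 0 or nh == n:
        return 0.0
    wsum = ranked_weights[hit_mask].sum()
    if wsum == 0:
        return 0.0
    steps = np.where(hit_mask, ranked_weights / wsum, -1.0 / (n - nh))
    run = np.cumsum(steps)
    i = int(np.argmax(np.abs(run)))
    return float(run[i])


def gsea_preranked(
    ranking: dict[str, float] | pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    weight_p: float = 1.0,
    seed: int = 0,
    min_set_size: int = 3,
) -> list[GseaResult]:
    """Preranked GSEA with a gene-label permutation null.

    ``ranking`` maps genes to scores (log2 fold changes); duplicates are
    rejected.  ES is the weighted KS statistic (weights |score|^p);
    the null redistributes set labels uniformly over ranked genes;
    NES = ES / mean(|null ES| of matching sign); p-values are the
    matching-sign null exceedance rate, BH-adjusted across terms.
    Terms with fewer than ``min_set_size`` ranked genes are skipped.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if isinstance(ranking, pd.Series):
        if ranking.index.duplicated().any():
            raise ValueError("duplicate genes in ranking")
        items = list(ranking.items())
    else:
        items = list(ranking.items())
    # sort by score descending, gene ascending for determinism
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    genes = [g for g, _ in items]
    scores = np.array([s for _, s in items], dtype=float)
    weights = np.abs(scores) ** weight_p
    pos = {g: i for i, g in enumerate(genes)}
    N = len(genes)
    rng = np.random.default_rng(seed)

    results: list[GseaResult] = []
    null_cache: dict[int, np.ndarray] = {}
    for name, members in collection.sets.items():
        idx = [pos[g] for g in members if g in pos]
        if len(idx) < min_set_size:
            warnings.warn(f"term {name!r} has <{min_set_size} ranked genes; skipped")
            continue
        nh = len(idx)
        mask = np.zeros(N, dtype=bool)
        mask[idx] = True
        es = _running_es(weights, mask)

        if nh not in null_cache:
            null = np.empty(n_perm)
            m = np.zeros(N, dtype=bool)
            for b in range(n_perm):
                m[:] = False
                m[rng.choice(N, size=nh, replace=False)] = True
                null[b] = _running_es(weights, m)
            null_cache[nh] = null
        null = null_cache[nh]

        if es >= 0:
            same = null[null >= 0]
            p = (1 + (same >= es).sum()) / (1 + len(same)) if len(same) else 1.0
        else:
            same = null[null < 0]
            p = (1 + (same <= es).sum()) / (1 + len(same)) if len(same) else 1.0
        denom = np.abs(same).mean() if len(same) else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else 0.0
        results.append(GseaResult(term=name, es=es, nes=float(nes),
                                  pvalue=float(p), fdr=np.nan))

    if results:
        fdrs = multipletests([r.pvalue for r in results], method="fdr_bh")[1]
        for r, f in zip(results, fdrs):
            r.fdr = float(f)
    results.sort(key=lambda r: (r.pvalue, r.term))
    return results
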