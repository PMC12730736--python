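"""Gene-network construction, refinement and topology.

Three network classes are handled:

* subject PPI networks — the undirected interactome restricted to a
  subject's mutated genes (induced subgraph; equivalent to building the
  first-degree neighbourhood and then pruning non-mutated interactors,
  self-loops and duplicate edges),
* the functional-interaction (FI) network — a directed network over the
  differentially expressed genes plus greedily chosen *linker* genes that
  join disconnected DEG components,
* the disease-phenotype network — the interactome induced on a phenotype
  gene panel (built with the same primitives).

Connected components are binned into the giant component, secondary
clusters (size >= 4), triads, pairs and singletons, matching how these
networks are summarised downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = [
    "InteractionEdge",
    "NodeTopology",
    "ComponentDecomposition",
    "read_mitab",
    "write_mitab",
    "read_fi_table",
    "write_fi_table",
    "build_subject_ppi",
    "giant_component",
    "build_fi_network",
    "topology",
    "intersect_networks",
    "export_sif",
]

HUMAN_TAXON = 9606


@dataclass(frozen=True)
class InteractionEdge:
    """One interaction between two gene products."""

    source: str
    target: str
    directed: bool = False
    taxon: int = HUMAN_TAXON
    provenance: str = ""


@dataclass
class NodeTopology:
    gene: str
    edge_count: int
    in_degree: int | None = None
    out_degree: int | None = None


@dataclass
class ComponentDecomposition:
    """Connected components binned by size class.

    ``giant`` is a largest component; ``secondary_clusters`` are the
    non-giant components of size >= 4; component node counts always sum
    to the parent network's node count.
    """

    giant: nx.Graph
    secondary_clusters: list[nx.Graph] = field(default_factory=list)
    n_triads: int = 0
    n_pairs: int = 0
    n_singletons: int = 0

    def counts(self) -> dict[str, int]:
        return {
            "giant_nodes": self.giant.number_of_nodes(),
            "giant_edges": self.giant.number_of_edges(),
            "n_secondary_clusters": len(self.secondary_clusters),
            "n_triads": self.n_triads,
            "n_pairs": self.n_pairs,
            "n_singletons": self.n_singletons,
        }


# ---------------------------------------------------------------------------
# PSI-MITAB and FI-table I/O
# ---------------------------------------------------------------------------

def _mitab_taxon(fieldval: str) -> int | None:
    # e.g. "taxid:9606(Homo sapiens)"
    for part in fieldval.split("|"):
        part = part.strip()
        if part.startswith("taxid:"):
            tax = part[len("taxid:"):].split("(")[0]
            try:
                return int(tax)
            except ValueError:
                return None
    return None


def _mitab_symbol(alias_field: str, id_field: str) -> str | None:
    """Resolve a gene symbol from a MITAB alias column.

    Precedence: ``uniprotkb:SYMBOL(gene name)`` alias, then the display
    short label, then the bare primary identifier value.
    """
    display = None
    for part in alias_field.split("|"):
        part = part.strip()
        if not part or part == "-":
            continue
        if part.startswith("uniprotkb:") and "(gene name)" in part:
            return part[len("uniprotkb:"):].split("(")[0]
        if "(display_short)" in part:
            display = part.split(":", 1)[-1].split("(")[0]
    if display:
        return display
    if id_field and id_field != "-":
        return id_field.split(":", 1)[-1]
    return None


def read_mitab(path: str, taxon_filter: int = HUMAN_TAXON,
               max_bad_fraction: float = 0.2) -> list[InteractionEdge]:
    """Read a PSI-MITAB 2.5/2.7 file into undirected interaction edges.

    Only pairs where *both* interactors carry ``taxon_filter`` are kept.
    Duplicate unordered pairs collapse to one edge; malformed lines are
    counted and skipped (a warning is raised above ``max_bad_fraction``).
    """
    import warnings

    edges: dict[frozenset, InteractionEdge] = {}
    n_bad = n_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            n_lines += 1
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 11:
                n_bad += 1
                continue
            tax_a, tax_b = _mitab_taxon(cols[9]), _mitab_taxon(cols[10])
            if tax_a != taxon_filter or tax_b != taxon_filter:
                continue
            sym_a = _mitab_symbol(cols[4], cols[0])
            sym_b = _mitab_symbol(cols[5], cols[1])
            if not sym_a or not sym_b:
                n_bad += 1
                continue
            prov = cols[13] if len(cols) > 13 else ""
            key = frozenset((sym_a, sym_b))
            if key not in edges:
                edges[key] = InteractionEdge(sym_a, sym_b, directed=False,
                                             taxon=taxon_filter, provenance=prov)
    if n_lines and n_bad / n_lines > max_bad_fraction:
        warnings.warn(f"{n_bad}/{n_lines} malformed MITAB lines in {path}")
    return list(edges.values())


def write_mitab(edges: list[InteractionEdge], path: str) -> None:
    """Write edges as minimal PSI-MITAB 2.7 (15 columns)."""
    with open(path, "w") as fh:
        for i, e in enumerate(edges):
            tax = f"taxid:{e.taxon}(Homo sapiens)" if e.taxon == HUMAN_TAXON \
                else f"taxid:{e.taxon}(-)"
            cols = [
                f"uniprotkb:{e.source}_HUMAN", f"uniprotkb:{e.target}_HUMAN",
                "-", "-",
                f"uniprotkb:{e.source}(gene name)",
                f"uniprotkb:{e.target}(gene name)",
                'psi-mi:"MI:0018"(two hybrid)',
                "-", "pubmed:00000000",
                tax, tax,
                'psi-mi:"MI:0915"(physical association)',
                'psi-mi:"MI:0469"(IntAct)',
                e.provenance or f"intact:EBI-SYN{i:07d}",
                "-",
            ]
            fh.write("\t".join(cols) + "\n")


def read_fi_table(path: str) -> list[InteractionEdge]:
    """Read a functional-interaction TSV (source, target, directed flag,
    annotation) into directed edges.  Undirected rows expand to both
    orientations."""
    df = pd.read_csv(path, sep="\t")
    out: list[InteractionEdge] = []
    for row in df.itertuples(index=False):
        directed = bool(row.directed)
        out.append(InteractionEdge(str(row.source), str(row.target),
                                   directed=True, provenance=str(getattr(row, "annotation", ""))))
        if not directed:
            out.append(InteractionEdge(str(row.target), str(row.source),
                                       directed=True, provenance=str(getattr(row, "annotation", ""))))
    return out


def write_fi_table(edges: list[InteractionEdge], path: str) -> None:
    rows = [{"source": e.source, "target": e.target,
             "directed": True, "annotation": e.provenance} for e in edges]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def _interactome_graph(edges: list[InteractionEdge]) -> nx.Graph:
    g = nx.Graph()
    for e in edges:
        if e.source != e.target:
            g.add_edge(e.source, e.target)
    return g


def build_subject_ppi(genes: set[str], edges: list[InteractionEdge]) -> nx.Graph:
    """Subject PPI network: the interactome induced on ``genes``.

    Equivalent to taking first-degree interactors of the mutated genes and
    then removing non-mutated interactors, self-loops and duplicate edges.
    Input genes absent from the interactome stay as singleton nodes.
    """
    if not genes:
        raise ValueError("empty gene set")
    inter = _interactome_graph(edges)
    g = nx.Graph()
    g.add_nodes_from(genes)
    members = genes & set(inter.nodes)
    g.add_edges_from(
        (u, v) for u, v in inter.subgraph(members).edges()
    )
    return g


def giant_component(n: nx.Graph) -> ComponentDecomposition:
    """Bin connected components (on the undirected skeleton) by size.

    The giant component is a largest component; ties break on the
    lexicographically smallest member so the decomposition is
    deterministic.
    """
    skel = n.to_undirected(as_view=False) if n.is_directed() else n
    if skel.number_of_nodes() == 0:
        return ComponentDecomposition(giant=n.__class__())
    comps = sorted(
        (sorted(c) for c in nx.connected_components(skel)),
        key=lambda c: (-len(c), c[0]),
    )
    giant_nodes = comps[0]
    decomp = ComponentDecomposition(giant=n.subgraph(giant_nodes).copy())
    for c in comps[1:]:
        if len(c) >= 4:
            decomp.secondary_clusters.append(n.subgraph(c).copy())
        elif len(c) == 3:
            decomp.n_triads += 1
        elif len(c) == 2:
            decomp.n_pairs += 1
        else:
            decomp.n_singletons += 1
    return decomp


def build_fi_network(
    degs: dict[str, str],
    fi_db: list[InteractionEdge],
    add_linkers: bool = True,
) -> nx.DiGraph:
    """Functional-interaction network over DEGs, optionally with linkers.

    ``degs`` maps gene -> direction ("up"/"down").  Nodes are the DEGs
    present in the FI database plus, when ``add_linkers``, greedily chosen
    linker genes: non-DEG genes adjacent (in either direction) to >= 2
    DEGs lying in *different* connected components of the DEG-induced
    subgraph.  Linkers are added by descending DEG-neighbour count (ties
    lexicographic) until no further components can be merged.  Node
    attributes: ``role`` (deg|linker) and ``direction`` (up|down|ns).
    """
    db = nx.DiGraph()
    for e in fi_db:
        if e.source != e.target:
            db.add_edge(e.source, e.target)
    db_und = db.to_undirected(as_view=True)

    members = set(degs) & set(db.nodes)
    chosen_linkers: set[str] = set()

    if add_linkers and members:
        # union-find over DEG components of the induced subgraph
        parent: dict[str, str] = {}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(x: str, y: str) -> bool:
            rx, ry = find(x), find(y)
            if rx == ry:
                return False
            parent[ry] = rx
            return True

        for g in members:
            parent[g] = g
        for u, v in db_und.subgraph(members).edges():
            union(u, v)

        # candidate linkers: non-DEG neighbours of >=2 DEGs
        cand: dict[str, set[str]] = {}
        for g in members:
            for nb in db_und.neighbors(g):
                if nb not in degs:
                    cand.setdefault(nb, set()).add(g)
        order = sorted(
            (c for c, nbs in cand.items() if len(nbs) >= 2),
            key=lambda c: (-len(cand[c]), c),
        )
        for c in order:
            roots = {find(g) for g in cand[c]}
            if len(roots) >= 2:
                chosen_linkers.add(c)
                gs = sorted(cand[c])
                for other in gs[1:]:
                    union(gs[0], other)

    nodes = members | chosen_linkers
    g = nx.DiGraph()
    for node in nodes:
        role = "deg" if node in degs else "linker"
        g.add_node(node, role=role, direction=degs.get(node, "ns"))
    g.add_edges_from(
        (u, v) for u, v in db.subgraph(nodes).edges()
    )
    return g


def topology(n: nx.Graph | nx.DiGraph, top_k: int | None = None) -> pd.DataFrame:
    """Per-node edge count and, for directed networks, in-/out-degree.

    Ranked by edge count descending, ties broken lexicographically;
    ``top_k`` truncates for hub reporting.
    """
    rows = []
    if n.is_directed():
        for node in n.nodes:
            ind, outd = n.in_degree(node), n.out_degree(node)
            rows.append({"gene": node, "edge_count": ind + outd,
                         "in_degree": ind, "out_degree": outd})
    else:
        for node in n.nodes:
            rows.append({"gene": node, "edge_count": n.degree(node),
                         "in_degree": pd.NA, "out_degree": pd.NA})
    df = pd.DataFrame(rows, columns=["gene", "edge_count", "in_degree", "out_degree"])
    df = df.sort_values(["edge_count", "gene"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    return df.head(top_k) if top_k else df


def intersect_networks(a: nx.Graph, b: nx.Graph, edge_source: str = "a") -> nx.Graph:
    """Intersect two networks on nodes, taking edges from one of them.

    Nodes = nodes(a) & nodes(b); edges are those of the ``edge_source``
    network ("a" or "b") with both endpoints retained.  Node attributes
    are merged with ``edge_source`` taking precedence on collisions.
    """
    import warnings

    if edge_source not in ("a", "b"):
        raise ValueError("edge_source must be 'a' or 'b'")
    src, other = (a, b) if edge_source == "a" else (b, a)
    common = set(a.nodes) & set(b.nodes)
    if not common:
        warnings.warn("network intersection is empty")
    g = src.__class__()
    for node in common:
        attrs = dict(other.nodes[node]) if node in other else {}
        attrs.update(src.nodes[node])
        g.add_node(node, **attrs)
    g.add_edges_from(
        (u, v, dict(d)) for u, v, d in src.subgraph(common).edges(data=True)
    )
    return g


def export_sif(n: nx.Graph, path: str, relation: str = "int") -> None:
    """Write a network in simple interaction format (SIF)."""
    with open(path, "w") as fh:
        for u, v in n.edges():
            fh.write(f"{u}\t{relation}\t{v}\n")
        for node in n.nodes:
            if n.degree(node) == 0:
                fh.write(f"{node}\n")
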