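"""Heterogeneous network construction, degree screening, PPI summaries.

The central object is a typed undirected graph over five node kinds —
prescription, compound, disease, gene, pathway — with four permitted edge
kinds. Quality markers are the active compounds whose degree (counting only
compound–gene edges, i.e. the size of the compound's common-target set)
strictly exceeds a threshold: either the network's mean degree 2E/N or a
fixed value.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, TYPE_CHECKING

import networkx as nx

from .symbols import GeneSymbol

if TYPE_CHECKING:  # pragma: no cover
    from .model import GeneSetCollection
    from .screening import ScreenResult

NODE_TYPES = ("prescription", "compound", "disease", "gene", "pathway")

#: Permitted edge types, keyed by the unordered pair of endpoint node types.
EDGE_TYPES = {
    frozenset({"prescription", "compound"}): "prescription-compound",
    frozenset({"compound", "gene"}): "compound-gene",
    frozenset({"disease", "gene"}): "disease-gene",
    frozenset({"pathway", "gene"}): "pathway-gene",
}


class HeteroNetwork:
    """Typed undirected graph with no self-edges and no duplicate edges.

    Thin validation layer over :class:`networkx.Graph`; nodes carry an
    ``ntype`` attribute and edges an ``etype`` attribute drawn from the
    fixed vocabularies above.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()

    # -- construction ------------------------------------------------------
    def add_node(self, node_id: str, ntype: str) -> None:
        if ntype not in NODE_TYPES:
            raise ValueError(f"unknown node type {ntype!r}")
        if node_id in self.graph:
            if self.graph.nodes[node_id]["ntype"] != ntype:
                raise ValueError(
                    f"node {node_id!r} already present with a different type"
                )
            return
        self.graph.add_node(node_id, ntype=ntype)

    def add_edge(self, u: str, v: str, etype: str | None = None) -> None:
        if u == v:
            raise ValueError(f"self-edge on {u!r} not permitted")
        for n in (u, v):
            if n not in self.graph:
                raise ValueError(f"edge endpoint {n!r} is not a declared node")
        pair = frozenset(
            {self.graph.nodes[u]["ntype"], self.graph.nodes[v]["ntype"]}
        )
        expected = EDGE_TYPES.get(pair)
        if expected is None:
            raise ValueError(f"no edge type permitted between {sorted(pair)}")
        if etype is not None and etype != expected:
            raise ValueError(f"edge type {etype!r} inconsistent with endpoints")
        self.graph.add_edge(u, v, etype=expected)

    def has_node(self, node_id: str) -> bool:
        return node_id in self.graph

    # -- inspection --------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[tuple[str, str]]:
        """All (node_id, node_type) pairs."""
        return [(n, d["ntype"]) for n, d in self.graph.nodes(data=True)]

    def edges(self) -> list[tuple[str, str, str]]:
        """All (u, v, edge_type) triples with u < v lexicographically."""
        return [
            (min(u, v), max(u, v), d["etype"])
            for u, v, d in self.graph.edges(data=True)
        ]

    def nodes_of_type(self, ntype: str) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["ntype"] == ntype]

    def node_type_counts(self) -> dict[str, int]:
        return dict(Counter(d["ntype"] for _, d in self.graph.nodes(data=True)))

    def degree(self, node_id: str) -> int:
        return self.graph.degree[node_id]

    def mean_degree(self) -> float:
        """2E/N over the full network (0 for an empty network)."""
        return 2 * self.n_edges / self.n_nodes if self.n_nodes else 0.0


def build_network(
    screen: "ScreenResult",
    pathways: "GeneSetCollection",
    prescription_name: str = "prescription",
    disease_name: str = "disease",
) -> HeteroNetwork:
    """Assemble the prescription–compound–disease–gene–pathway network.

    Nodes: one prescription, every active compound, one disease, the union
    of the compounds' common target genes, and one node per pathway set.
    Edges: prescription–compound for every active compound; compound–gene
    for every (compound, common target) pair; disease–gene for every common
    gene; pathway–gene for every membership. Pathway sets must already be
    restricted to the common gene set.

    A compound with an empty common set is a contract violation here — such
    compounds are excluded upstream by the screening stage.
    """
    for cid in screen.active_compounds:
        if not screen.common_targets.entries.get(cid):
            raise ValueError(
                f"active compound {cid!r} has an empty common target set; "
                "filter excluded compounds before building the network"
            )
    common_union = screen.common_union()
    stray = pathways.union() - common_union
    if stray:
        raise ValueError(
            "pathway sets must be restricted to the common gene set; "
            f"found {len(stray)} foreign genes (e.g. {sorted(stray)[:3]})"
        )

    net = HeteroNetwork()
    net.add_node(prescription_name, "prescription")
    net.add_node(disease_name, "disease")
    for cid in screen.active_compounds:
        net.add_node(cid, "compound")
    for gene in sorted(common_union):
        net.add_node(gene, "gene")
    for sid in pathways.sets:
        net.add_node(sid, "pathway")

    for cid in screen.active_compounds:
        net.add_edge(prescription_name, cid)
        for gene in screen.common_targets.entries[cid]:
            net.add_edge(cid, gene)
    for gene in common_union:
        net.add_edge(disease_name, gene)
    for sid, (_, members) in pathways.sets.items():
        for gene in members:
            net.add_edge(sid, gene)
    return net


def compound_degrees(net: HeteroNetwork) -> dict[str, int]:
    """Degree of each compound node counting compound–gene edges only.

    The single prescription–compound edge is deliberately excluded, so a
    compound's screening degree equals the size of its common target set —
    the convention under which recomputed degrees match published
    interaction tables.
    """
    out: dict[str, int] = {}
    for cid in net.nodes_of_type("compound"):
        out[cid] = sum(
            1
            for nbr in net.graph.neighbors(cid)
            if net.graph.nodes[nbr]["ntype"] == "gene"
        )
    return out


@dataclass
class MarkerSelection:
    """Result of the degree-above-threshold quality-marker screen."""

    threshold_used: float
    mode: str
    per_compound_degree: dict[str, int]
    selected: list[str] = field(default_factory=list)
    rejected: list[str] = field(default_factory=list)


def select_markers(
    degrees: dict[str, int],
    threshold_mode: str = "computed_mean",
    fixed_value: float | None = None,
    net: HeteroNetwork | None = None,
) -> MarkerSelection:
    """Select compounds whose degree strictly exceeds a threshold.

    ``computed_mean`` mode takes the threshold from the full network's mean
    degree 2E/N (requires ``net``); ``fixed`` mode uses ``fixed_value``.
    Output lists are ordered by degree descending, ties alphabetical.
    """
    from .errors import ConfigError

    if not degrees:
        raise ValueError("degrees mapping is empty")
    if threshold_mode == "computed_mean":
        if net is None:
            raise ConfigError("computed_mean mode requires the network")
        threshold = net.mean_degree()
    elif threshold_mode == "fixed":
        if fixed_value is None:
            raise ConfigError("fixed mode requires fixed_value")
        threshold = float(fixed_value)
    else:
        raise ConfigError(f"unknown threshold mode {threshold_mode!r}")

    ordered = sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0]))
    selected = [cid for cid, d in ordered if d > threshold]
    rejected = [cid for cid, d in ordered if d <= threshold]
    return MarkerSelection(
        threshold_used=threshold,
        mode=threshold_mode,
        per_compound_degree=dict(degrees),
        selected=selected,
        rejected=rejected,
    )


@dataclass
class PpiSummary:
    """Node/edge counts and top-frequency genes of a PPI edge list."""

    n_nodes: int
    n_edges: int
    top_genes: list[tuple[GeneSymbol, int]] = field(default_factory=list)


def ppi_summary(
    edges: Iterable[tuple[GeneSymbol, GeneSymbol]], top_k: int = 30
) -> PpiSummary:
    """Summarize an undirected PPI edge list.

    Reversed duplicates (A–B vs B–A) collapse to one edge; self-loops are
    dropped with a warning. ``top_genes`` lists the ``top_k``
    highest-frequency (degree) genes, frequency descending, ties
    alphabetical; frequencies over all nodes sum to twice the edge count.
    """
    dedup: set[frozenset[GeneSymbol]] = set()
    for a, b in edges:
        if a == b:
            warnings.warn(f"dropping self-loop on {a!r}", stacklevel=2)
            continue
        dedup.add(frozenset((a, b)))
    freq: Counter[GeneSymbol] = Counter()
    for pair in dedup:
        for g in pair:
            freq[g] += 1
    top = sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    return PpiSummary(n_nodes=len(freq), n_edges=len(dedup), top_genes=top)
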