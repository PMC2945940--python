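"""Weighted undirected gene association networks and their matrix forms.

A :class:`Network` wraps a weighted undirected :class:`networkx.Graph` with a
stable node ordering (first appearance in the input), so every matrix and
vector in the package can be indexed consistently.  Edge weights are
association confidences in ``(0, 1]`` — STRING-style integer scores (0-1000)
are rescaled at load time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp

log = logging.getLogger(__name__)

__all__ = [
    "Network",
    "NetworkMatrices",
    "EdgeListError",
    "load_edge_list",
    "threshold_edges",
    "augment_with_isolated_nodes",
    "build_matrices",
    "network_stats",
    "network_overlap",
]


class EdgeListError(ValueError):
    """Raised for malformed edge-list input, with the offending line number."""


@dataclass
class Network:
    """Undirected weighted gene/protein association network.

    Parameters
    ----------
    node_ids
        Gene identifiers in a fixed order; index ``i`` of every derived
        matrix/vector refers to ``node_ids[i]``.
    graph
        Undirected graph whose edge attribute ``weight`` lies in ``(0, 1]``.
        No self-loops; each undirected edge is stored once.
    name
        Free-text label carried through to reports.
    """

    node_ids: tuple[str, ...]
    graph: nx.Graph
    name: str = ""
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.node_ids) != self.graph.number_of_nodes():
            raise ValueError("node_ids and graph disagree on the node set")
        self._index = {g: i for i, g in enumerate(self.node_ids)}
        if len(self._index) != len(self.node_ids):
            raise ValueError("duplicate node identifiers")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def edge_weight(self, a: str, b: str) -> float:
        return float(self.graph[a][b]["weight"])


@dataclass
class NetworkMatrices:
    """Shared matrix forms of a network.

    ``adjacency`` is the symmetric weighted adjacency A, ``degrees`` the row
    sums of A, ``laplacian`` the combinatorial Laplacian ``L = D - A`` and
    ``transition`` the row-stochastic random-walk matrix ``W = D^{-1} A``.
    Degree-zero nodes get a unit self-row in W (absorbing state), so an
    isolated gene retains its own signal under diffusion and W rows always
    sum to one.
    """

    node_ids: tuple[str, ...]
    adjacency: sp.csr_array
    degrees: np.ndarray
    laplacian: sp.csr_array
    transition: sp.csr_array
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.node_ids)}

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def index_of(self, gene: str) -> int:
        return self._index[gene]


def load_edge_list(path, dialect: str = "unit", name: str | None = None) -> Network:
    """Read a TSV edge list (``node_a<TAB>node_b<TAB>weight``).

    ``dialect="string1000"`` interprets weights as integer confidence scores
    on 0-1000 and divides by 1000.  A header row is auto-detected (third
    field non-numeric).  Duplicate pairs are collapsed to the maximum weight,
    self-loops and zero-weight records are dropped with a logged count, and
    malformed rows raise :class:`EdgeListError` naming the line.
    """
    if dialect not in ("unit", "string1000"):
        raise ValueError(f"unknown dialect {dialect!r}")
    graph = nx.Graph()
    order: list[str] = []
    seen: set[str] = set()
    n_self = n_zero = n_conflict = 0

    def register(gene: str) -> None:
        if gene not in seen:
            seen.add(gene)
            order.append(gene)

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise EdgeListError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields"
                )
            a, b, w_raw = parts[0].strip(), parts[1].strip(), parts[2].strip()
            try:
                w = float(w_raw)
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise EdgeListError(
                    f"{path}: line {lineno}: non-numeric weight {w_raw!r}"
                ) from None
            if not a or not b:
                raise EdgeListError(f"{path}: line {lineno}: empty node identifier")
            if dialect == "string1000":
                w = w / 1000.0
            if not np.isfinite(w) or w < 0 or w > 1:
                raise EdgeListError(
                    f"{path}: line {lineno}: weight {w!r} outside [0, 1] after scaling"
                )
            register(a)
            register(b)
            if a == b:
                n_self += 1
                continue
            if w == 0:
                n_zero += 1
                continue
            if graph.has_edge(a, b):
                old = graph[a][b]["weight"]
                if old != w:
                    n_conflict += 1
                w = max(old, w)
            graph.add_edge(a, b, weight=w)
    graph.add_nodes_from(order)
    if n_self:
        log.warning("%s: dropped %d self-loop record(s)", path, n_self)
    if n_zero:
        log.info("%s: dropped %d zero-weight record(s)", path, n_zero)
    if n_conflict:
        log.info("%s: resolved %d conflicting duplicate weight(s) by max", path, n_conflict)
    return Network(tuple(order), graph, name=name or str(path))


def threshold_edges(net: Network, eps: float) -> Network:
    """Keep edges with weight strictly above ``eps``; the node set is unchanged.

    Nodes whose every edge falls below the threshold become isolated rather
    than being removed, so node indexing stays stable.
    """
    if not 0 <= eps < 1:
        raise ValueError(f"eps must lie in [0, 1), got {eps}")
    g = nx.Graph()
    g.add_nodes_from(net.node_ids)
    for a, b, w in net.graph.edges(data="weight"):
        if w > eps:
            g.add_edge(a, b, weight=w)
    return Network(net.node_ids, g, name=net.name)


def augment_with_isolated_nodes(net: Network, genes) -> Network:
    """Ensure every listed gene is a node; new genes are added isolated.

    Mirrors the handling of benchmark genes absent from a sparse interaction
    database: they join the graph with degree zero so their own expression
    signal can still be ranked.
    """
    new = [g for g in genes if g not in net]
    # preserve first-appearance order among the additions, dropping dups
    uniq: list[str] = []
    seen: set[str] = set()
    for g in new:
        if g not in seen:
            seen.add(g)
            uniq.append(g)
    if not uniq:
        return net
    g2 = net.graph.copy()
    g2.add_nodes_from(uniq)
    return Network(net.node_ids + tuple(uniq), g2, name=net.name)


def build_matrices(net: Network) -> NetworkMatrices:
    """Derive A, degree vector, Laplacian L = D - A and transition W = D^{-1}A."""
    if net.n_nodes < 1:
        raise ValueError("network must contain at least one node")
    A = nx.to_scipy_sparse_array(
        net.graph, nodelist=list(net.node_ids), weight="weight", format="csr"
    ).astype(float)
    deg = np.asarray(A.sum(axis=1)).ravel()
    L = (sp.diags_array(deg) - A).tocsr()
    inv = np.zeros_like(deg)
    pos = deg > 0
    inv[pos] = 1.0 / deg[pos]
    W = (sp.diags_array(inv) @ A).tocsr()
    if (~pos).any():
        # absorbing unit self-row for isolated nodes keeps W row-stochastic
        W = (W + sp.diags_array((~pos).astype(float))).tocsr()
    return NetworkMatrices(net.node_ids, A, deg, L, W)


def network_stats(net: Network) -> dict:
    """Global network properties in database-report convention.

    ``n_interaction_records`` counts directed records, i.e. twice the stored
    undirected edges, matching how interaction databases report their sizes;
    ``avg_node_degree`` is records per gene.
    """
    n_genes = net.n_nodes
    records = 2 * net.n_edges
    return {
        "n_genes": n_genes,
        "n_interaction_records": records,
        "avg_node_degree": records / n_genes if n_genes else 0.0,
    }


def network_overlap(a: Network, b: Network) -> dict:
    """Interaction records shared by two networks (weights ignored).

    Returns the shared record count (directed convention, as in
    :func:`network_stats`) and the fraction of each network it represents.
    """
    ea = {frozenset(e) for e in a.graph.edges()}
    eb = {frozenset(e) for e in b.graph.edges()}
    shared = 2 * len(ea & eb)
    rec_a = 2 * len(ea)
    rec_b = 2 * len(eb)
    return {
        "shared_records": shared,
        "frac_of_a": shared / rec_a if rec_a else 0.0,
        "frac_of_b": shared / rec_b if rec_b else 0.0,
    }
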