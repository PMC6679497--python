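"""Background interaction network, disease subnetworks and node centrality.

The screen works on an undirected, unweighted protein-protein interaction
(PPI) graph. Disease genes induce a signaling subnetwork (isolated nodes
dropped), and each node gets a centrality score

    CS(v) = Bn(v) + Cn(v) + Pr(v)

the sum of pair-normalized betweenness, component-scaled (Wasserman-Faust)
closeness, and PageRank. Three correlated measures are summed to obtain a
robust notion of "hubness" on the disease network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .errors import (DegenerateNetworkError, DomainError, InputFormatError,
                     InputIOError)

logger = logging.getLogger(__name__)

PAGERANK_TOL = 1e-10
PAGERANK_MAXITER = 10_000


@dataclass
class InteractionNetwork:
    """Undirected simple graph of protein/gene nodes.

    Node identifiers are opaque, case-sensitive strings; self-loops and
    duplicate edges are never stored. ``graph`` is the underlying
    :class:`networkx.Graph` and may be used directly for algorithms.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "InteractionNetwork":
        g = nx.Graph()
        for a, b in edges:
            if a != b:
                g.add_edge(str(a), str(b))
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, b in self.graph.edges}

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def __eq__(self, other) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class GeneSet:
    """A named set of node identifiers (e.g. disease driver genes)."""

    ids: frozenset[str]
    label: str = ""

    @classmethod
    def from_file(cls, path: str | Path, label: str | None = None) -> "GeneSet":
        path = Path(path)
        try:
            lines = path.read_text().splitlines()
        except OSError as exc:
            raise InputIOError(f"cannot read gene list {path}: {exc}") from exc
        ids = frozenset(
            ln.strip() for ln in lines
            if ln.strip() and not ln.lstrip().startswith("#"))
        return cls(ids, label if label is not None else path.stem)

    def __len__(self) -> int:
        return len(self.ids)


def load_edge_list(path: str | Path) -> InteractionNetwork:
    """Read a two-column whitespace/TSV edge list into an undirected network.

    Lines starting with ``#`` are comments. Duplicate edges (in either
    orientation) collapse to one; self-loops are dropped and counted.
    Node identifiers are taken verbatim, with no case folding.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise InputIOError(f"cannot read edge list {path}: {exc}") from exc
    g = nx.Graph()
    n_selfloops = 0
    n_parsed = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        cols = stripped.split()
        if len(cols) < 2:
            raise InputFormatError(
                f"{path}:{lineno}: expected >=2 whitespace-separated "
                f"columns (node_a, node_b), got {stripped!r}")
        a, b = cols[0], cols[1]
        n_parsed += 1
        if a == b:
            n_selfloops += 1
            continue
        g.add_edge(a, b)
    if n_parsed == 0:
        raise InputFormatError(
            f"{path}: no edges parsed; expected lines of the form "
            "'node_a<TAB>node_b' with optional '#' comments")
    if n_selfloops:
        logger.info("%s: dropped %d self-loop(s)", path, n_selfloops)
    logger.info("%s: %d nodes, %d edges", path,
                g.number_of_nodes(), g.number_of_edges())
    return InteractionNetwork(g)


def induce_subnetwork(net: InteractionNetwork, genes: GeneSet) -> InteractionNetwork:
    """Induce the subgraph on ``genes`` and drop isolated nodes.

    Genes absent from the background network are ignored (counted in the
    log); nodes left without any edge after induction are removed, so the
    result contains only interacting members of the gene set.
    """
    if len(genes) == 0:
        raise DomainError("gene set for subnetwork induction is empty")
    mapped = genes.ids & net.nodes
    n_unmapped = len(genes.ids) - len(mapped)
    sub = net.graph.subgraph(mapped).copy()
    isolates = list(nx.isolates(sub))
    sub.remove_nodes_from(isolates)
    if sub.number_of_edges() == 0:
        raise DegenerateNetworkError(
            f"gene set {genes.label!r} induces no edges on the network "
            f"({n_unmapped} unmapped, {len(isolates)} isolated)")
    logger.info("induced %r: %d nodes, %d edges (%d unmapped, %d isolates removed)",
                genes.label, sub.number_of_nodes(), sub.number_of_edges(),
                n_unmapped, len(isolates))
    return InteractionNetwork(sub)


def pagerank(net: InteractionNetwork, damping: float = 0.85,
             tol: float = PAGERANK_TOL) -> dict[str, float]:
    """PageRank by power iteration with uniform teleport.

    Iterates x <- d * x A D^-1 + (1-d)/N until the L1 change drops below
    ``tol``. On an undirected graph with isolates removed there are no
    dangling nodes, so the scores sum to one exactly (up to float error).
    """
    nodes = sorted(net.graph.nodes)
    n = len(nodes)
    if n == 0:
        raise DomainError("PageRank on an empty network")
    index = {v: i for i, v in enumerate(nodes)}
    a = nx.to_scipy_sparse_array(net.graph, nodelist=nodes, dtype=float)
    deg = np.asarray(a.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0  # isolates cannot occur upstream; keep div safe
    x = np.full(n, 1.0 / n)
    teleport = (1.0 - damping) / n
    for _ in range(PAGERANK_MAXITER):
        x_new = damping * (a.T @ (x / deg)) + teleport
        if np.abs(x_new - x).sum() < tol:
            x = x_new
            break
        x = x_new
    return {v: float(x[index[v]]) for v in nodes}


def compute_centralities(net: InteractionNetwork,
                         damping: float = 0.85) -> pd.DataFrame:
    """Per-node betweenness, closeness, PageRank and their sum CS.

    Returns a DataFrame indexed by node with columns ``betweenness``
    (pair-normalized, in [0, 1]), ``closeness`` (Wasserman-Faust
    component-scaled), ``pagerank`` (sums to 1) and ``cs`` (their sum).
    """
    if net.n_nodes() < 2 or net.n_edges() < 1:
        raise DegenerateNetworkError(
            "centralities need a network with >=2 nodes and >=1 edge")
    g = net.graph
    bn = nx.betweenness_centrality(g, normalized=True)
    cn = nx.closeness_centrality(g, wf_improved=True)
    pr = pagerank(net, damping=damping)
    nodes = sorted(g.nodes)
    df = pd.DataFrame({
        "betweenness": [bn[v] for v in nodes],
        "closeness": [cn[v] for v in nodes],
        "pagerank": [pr[v] for v in nodes],
    }, index=pd.Index(nodes, name="node"))
    df["cs"] = df["betweenness"] + df["closeness"] + df["pagerank"]
    return df


def write_centrality_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a centrality table as TSV with a ``node`` column first."""
    out = df.reset_index()
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_centrality_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.set_index("node")
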