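"""Community detection on the extended network and Newman modularity.

Two methods are provided, matching the two the tool exposes:

``edge_betweenness``
    Girvan-Newman: iteratively remove the edge of maximal betweenness,
    score the connected-component partition at every level with modularity
    Q, and return the partition maximizing Q. Ties in betweenness are
    broken by the lexicographically smallest endpoint pair so the result
    is deterministic.

``leading_eigenvector``
    Newman's spectral method: recursive bisection by the sign of the
    leading eigenvector of the (generalized) modularity matrix, stopping
    when no split increases Q. Recommended for larger networks where the
    cubic-ish Girvan-Newman loop becomes slow.

Modularity is Q = sum_c (e_cc - a_c^2) with e_cc the fraction of edges
inside module c and a_c the fraction of edge ends in c; Q is in
[-1/2, 1] for a simple undirected graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network_io import InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = ["ModulePartition", "modularity", "detect_communities"]

#: above this node count Girvan-Newman becomes slow; we advise (but do not
#: force) switching to the spectral method
LARGE_NETWORK_NODES = 2000

_TIE_TOL = 1e-12


@dataclass
class ModulePartition:
    """Assignment of every node to exactly one module.

    Module ids are contiguous integers 0..m-1, ordered by descending
    module size, ties broken by the lexicographically smallest member, so
    identical groupings always yield identical ids.
    """

    assignment: dict[str, int]
    modularity: float
    method: str

    @property
    def n_modules(self) -> int:
        return max(self.assignment.values()) + 1 if self.assignment else 0

    def modules(self) -> list[set[str]]:
        out: list[set[str]] = [set() for _ in range(self.n_modules)]
        for node, mid in self.assignment.items():
            out[mid].add(node)
        return out

    @classmethod
    def from_groups(cls, groups, Q: float, method: str) -> "ModulePartition":
        ordered = sorted((sorted(g) for g in groups if g), key=lambda g: (-len(g), g[0]))
        assignment = {n: i for i, g in enumerate(ordered) for n in g}
        return cls(assignment, float(Q), method)


def modularity(network: InteractionNetwork, assignment: dict[str, int]) -> float:
    """Newman modularity Q of a node->module assignment.

    Raises if any network node is missing from the assignment or the
    network has no edges (Q is undefined without edges).
    """
    g = network.graph
    missing = set(g.nodes) - set(assignment)
    if missing:
        raise ValueError(f"assignment does not cover nodes: {sorted(missing)[:5]}")
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("modularity is undefined for an edgeless network")
    intra: dict[int, int] = {}
    deg_sum: dict[int, int] = {}
    for u, v in g.edges:
        if assignment[u] == assignment[v]:
            intra[assignment[u]] = intra.get(assignment[u], 0) + 1
    for n in g.nodes:
        c = assignment[n]
        deg_sum[c] = deg_sum.get(c, 0) + g.degree[n]
    q = 0.0
    for c in deg_sum:
        e_cc = intra.get(c, 0) / m
        a_c = deg_sum[c] / (2 * m)
        q += e_cc - a_c * a_c
    return q


def detect_communities(network: InteractionNetwork, method: str = "edge_betweenness") -> ModulePartition:
    """Partition a network into modules maximizing modularity.

    See the module docstring for the two methods. For an edgeless network
    every node is its own module and Q is reported as 0.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("cannot detect communities in an empty network")
    if network.number_of_edges() == 0:
        return ModulePartition.from_groups([{n} for n in network.nodes], 0.0, method)
    if method == "edge_betweenness":
        if network.number_of_nodes() > LARGE_NETWORK_NODES:
            logger.warning(
                "edge-betweenness community detection on %d nodes will be slow; "
                "consider method='leading_eigenvector'",
                network.number_of_nodes(),
            )
        groups, q = _girvan_newman(network)
    elif method == "leading_eigenvector":
        groups, q = _leading_eigenvector(network)
    else:
        raise ValueError(f"unknown community method: {method!r}")
    return ModulePartition.from_groups(groups, q, method)


# ----------------------------------------------------------------------
# Girvan-Newman


def _components(g: nx.Graph) -> list[set[str]]:
    return [set(c) for c in nx.connected_components(g)]


def _girvan_newman(network: InteractionNetwork) -> tuple[list[set[str]], float]:
    g = network.graph
    work = g.copy()
    best_groups = _components(work)
    best_q = modularity(network, _groups_to_assignment(best_groups))
    while work.number_of_edges() > 0:
        bc = nx.edge_betweenness_centrality(work)
        top = max(bc.values())
        # lexicographically smallest endpoint pair among (near-)ties
        tied = [tuple(sorted(e)) for e, v in bc.items() if v >= top - _TIE_TOL * max(1.0, top)]
        work.remove_edge(*min(tied))
        groups = _components(work)
        q = modularity(network, _groups_to_assignment(groups))
        if q > best_q + _TIE_TOL:
            best_q, best_groups = q, groups
    return best_groups, best_q


def _groups_to_assignment(groups) -> dict[str, int]:
    return {n: i for i, grp in enumerate(groups) for n in grp}


# ----------------------------------------------------------------------
# leading eigenvector


def _leading_eigenvector(network: InteractionNetwork) -> tuple[list[set[str]], float]:
    g = network.graph
    nodes = sorted(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    A = nx.to_numpy_array(g, nodelist=nodes)
    k = A.sum(axis=1)
    two_m = k.sum()
    B = A - np.outer(k, k) / two_m

    final: list[set[str]] = []
    # start from connected components; the spectral step only ever splits
    # within a connected group
    stack = [sorted(index[n] for n in comp) for comp in nx.connected_components(g)]
    while stack:
        group = stack.pop()
        split = _spectral_bisect(B, group)
        if split is None:
            final.append({nodes[i] for i in group})
        else:
            stack.extend(split)
    q = modularity(network, _groups_to_assignment(final))
    return final, q


def _spectral_bisect(B: np.ndarray, group: list[int]):
    """One bisection step on the generalized modularity matrix.

    Returns the two index groups, or None if the group is indivisible:
    no positive leading eigenvalue, a (near-)degenerate leading eigenpair
    (splitting would depend on an arbitrary eigenbasis rotation), a trivial
    split, or a split that does not increase Q.
    """
    if len(group) < 2:
        return None
    Bg = B[np.ix_(group, group)].copy()
    Bg[np.diag_indices_from(Bg)] -= Bg.sum(axis=1)
    vals, vecs = np.linalg.eigh(Bg)
    scale = max(1.0, float(np.abs(vals).max()))
    tol = 1e-10 * scale
    if vals[-1] <= tol:
        return None
    if len(vals) > 1 and vals[-1] - vals[-2] <= tol:
        return None  # degenerate leading eigenvalue: arbitrary rotation
    v = vecs[:, -1]
    s = np.where(v >= 0, 1.0, -1.0)
    dq = s @ Bg @ s  # proportional to the modularity change of the split
    if dq <= tol:
        return None
    left = [g for g, si in zip(group, s) if si > 0]
    right = [g for g, si in zip(group, s) if si < 0]
    if not left or not right:
        return None
    return [left, right]
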