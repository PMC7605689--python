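"""Linker-gene inference: hypergeometric tail test, FDR, extended network.

A *candidate linker* is an unaltered gene that is a direct neighbor of at
least one altered gene. For a candidate of global degree ``k`` with ``x``
altered neighbors, the null model treats the candidate's neighbor set as a
uniform draw of ``k`` nodes from the other ``N`` nodes of the prior
network, of which ``A`` are altered. The p-value is the hypergeometric
upper tail Pr(X >= x); an alternative ``legacy_point`` mode reports the
point probability Pr(X = x) as used by the original NetBox implementation.
Raw p-values over all candidates are Benjamini-Hochberg adjusted and
candidates with adjusted p <= cutoff (inclusive) are accepted as linkers.

The *extended network* is the induced subgraph on the mapped altered genes
plus the accepted linkers, with isolated nodes removed; it is the substrate
for community detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network_io import AlteredGeneSet, InteractionNetwork

__all__ = [
    "LinkerResult",
    "ExtendedNetwork",
    "find_candidate_linkers",
    "linker_pvalue",
    "adjust_pvalues",
    "build_extended_network",
    "linker_table",
]

DEFAULT_CUTOFF = 0.05

ALTERED = "altered"
LINKER = "linker"


@dataclass(frozen=True)
class LinkerResult:
    """Per-candidate linker statistics."""

    gene: str
    degree: int            # global degree k in the prior network
    altered_neighbors: int  # x, neighbors in the mapped altered set
    p_raw: float
    p_adjusted: float
    accepted: bool


@dataclass
class ExtendedNetwork:
    """Connected altered genes + accepted linkers, with node roles.

    ``dropped_altered`` lists mapped altered genes that ended up isolated
    within the extended node set and were therefore excluded.
    """

    network: InteractionNetwork
    node_role: dict[str, str]  # node -> "altered" | "linker"
    dropped_altered: list[str]

    @property
    def altered_nodes(self) -> set[str]:
        return {n for n, r in self.node_role.items() if r == ALTERED}

    @property
    def linker_nodes(self) -> set[str]:
        return {n for n, r in self.node_role.items() if r == LINKER}


def find_candidate_linkers(network: InteractionNetwork, altered: AlteredGeneSet) -> list[str]:
    """Unaltered nodes with at least one altered neighbor, sorted."""
    if not altered.mapped:
        raise ValueError("no altered genes map into the network")
    g = network.graph
    candidates = set()
    for a in altered.mapped:
        candidates.update(g.neighbors(a))
    return sorted(candidates - altered.mapped)


def linker_pvalue(N: int, A: int, k: int, x: int, mode: str = "tail") -> float:
    """Hypergeometric linker p-value.

    Parameters
    ----------
    N : population size (nodes the candidate's neighbors are drawn from).
    A : number of altered genes in the population.
    k : candidate's degree (number of draws).
    x : observed altered neighbors.
    mode : ``"tail"`` for Pr(X >= x) (the default test), ``"legacy_point"``
        for Pr(X = x) (original NetBox behavior).
    """
    if not (0 <= x <= k <= N and 0 <= A <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, A={A}, k={k}, x={x}")
    if mode == "tail":
        if x == 0:
            return 1.0
        return float(stats.hypergeom.sf(x - 1, N, A, k))
    if mode == "legacy_point":
        return float(stats.hypergeom.pmf(x, N, A, k))
    raise ValueError(f"unknown linker p-value mode: {mode!r}")


def adjust_pvalues(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _population_size(network: InteractionNetwork) -> int:
    # urn: the candidate's k neighbors are drawn from the other N-1 nodes
    return network.number_of_nodes() - 1


def build_extended_network(
    network: InteractionNetwork,
    altered: AlteredGeneSet,
    cutoff: float = DEFAULT_CUTOFF,
    mode: str = "tail",
) -> tuple[ExtendedNetwork, list[LinkerResult]]:
    """Score all candidate linkers and assemble the extended network.

    Returns the extended network and the full linker table (accepted and
    rejected candidates) sorted by raw p-value, then gene identifier.
    Acceptance is inclusive: adjusted p exactly equal to ``cutoff`` passes.
    """
    if not 0 < cutoff <= 1:
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    g = network.graph
    candidates = find_candidate_linkers(network, altered)
    N = _population_size(network)
    A = len(altered.mapped)

    p_raw = []
    degrees = []
    xs = []
    for c in candidates:
        k = g.degree[c]
        x = sum(1 for nb in g.neighbors(c) if nb in altered.mapped)
        degrees.append(k)
        xs.append(x)
        p_raw.append(linker_pvalue(N, A, k, x, mode=mode))
    p_adj = adjust_pvalues(p_raw)

    results = [
        LinkerResult(gene=c, degree=k, altered_neighbors=x, p_raw=pr, p_adjusted=float(pa),
                     accepted=bool(pa <= cutoff))
        for c, k, x, pr, pa in zip(candidates, degrees, xs, p_raw, p_adj)
    ]
    results.sort(key=lambda r: (r.p_raw, r.gene))

    accepted = {r.gene for r in results if r.accepted}
    keep = altered.mapped | accepted
    sub = network.subgraph(keep)
    connected = {n for n in sub.nodes if sub.degree(n) > 0}
    if not connected:
        raise ValueError("no connected altered genes: extended network is empty")
    dropped = sorted((altered.mapped - connected))
    ext_net = sub.subgraph(connected)
    node_role = {n: (ALTERED if n in altered.mapped else LINKER) for n in ext_net.nodes}
    return ExtendedNetwork(ext_net, node_role, dropped), results


def linker_table(results: list[LinkerResult]) -> pd.DataFrame:
    """Linker results as a tidy DataFrame (one row per candidate)."""
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "degree": r.degree,
                "altered_neighbors": r.altered_neighbors,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "accepted": r.accepted,
            }
            for r in results
        ],
        columns=["gene", "degree", "altered_neighbors", "p_raw", "p_adjusted", "accepted"],
    )
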