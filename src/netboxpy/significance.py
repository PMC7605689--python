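"""Statistical assessment of a discovered network: two permutation tests.

1. **Global connectivity (LCC) test.** The observed statistic is the size
   of the largest connected component of the subgraph induced by the
   mapped altered genes on the full prior network. The null draws the same
   number of genes uniformly at random (without replacement) from all
   network nodes; the empirical p-value is ``(r + 1) / (trials + 1)``
   where ``r`` counts trials whose LCC equals or exceeds the observed one
   (pseudocount so p is never zero).

2. **Modularity significance.** The observed statistic is the modularity Q
   of the detected partition of the extended network. The null ensemble is
   degree-preserving rewirings (double-edge swaps) of that network;
   community detection is re-run on every rewired network, and the
   observed Q is converted to a z-score against the null mean/SD and
   reported as a one-sided upper-tail normal p-value.

Both tests are exactly reproducible given a seed; per-trial seeds are
derived from the master seed via numpy's SeedSequence spawning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .community import detect_communities
from .network_io import AlteredGeneSet, InteractionNetwork

__all__ = [
    "SignificanceReport",
    "global_connectivity_test",
    "rewire_network",
    "modularity_significance",
    "assess_significance",
]

DEFAULT_LCC_TRIALS = 1000
DEFAULT_MOD_TRIALS = 100
DEFAULT_SWAP_FACTOR = 10.0


@dataclass
class SignificanceReport:
    """Results of both significance tests for one run."""

    observed_lcc: int
    lcc_null_sizes: list[int]
    lcc_p: float
    observed_Q: float
    Q_null_mean: float
    Q_null_sd: float
    Q_z: float  # NaN when the null SD is zero
    Q_p: float
    lcc_trials: int
    mod_trials: int
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def _induced_lcc(graph, nodes) -> int:
    """Size of the largest connected component induced by ``nodes``."""
    nodes = set(nodes)
    seen: set = set()
    best = 0
    for start in nodes:
        if start in seen:
            continue
        size = 0
        queue = [start]
        seen.add(start)
        while queue:
            u = queue.pop()
            size += 1
            for v in graph.adj[u]:
                if v in nodes and v not in seen:
                    seen.add(v)
                    queue.append(v)
        best = max(best, size)
    return best


def global_connectivity_test(
    network: InteractionNetwork,
    altered: AlteredGeneSet,
    trials: int = DEFAULT_LCC_TRIALS,
    seed: int | np.random.Generator = 0,
) -> tuple[int, list[int], float]:
    """Empirical LCC test of the altered-gene list against random lists.

    Returns ``(observed_lcc, null_sizes, p)`` with
    ``p = (r + 1) / (trials + 1)`` and ``r`` the number of null draws whose
    induced-subgraph LCC equals or exceeds the observed one.
    """
    if trials < 1:
        raise ValueError(f"trials must be >= 1, got {trials}")
    if not altered.mapped:
        raise ValueError("no altered genes map into the network")
    g = network.graph
    observed = _induced_lcc(g, altered.mapped)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    all_nodes = sorted(g.nodes)
    n_draw = len(altered.mapped)
    null_sizes = []
    for _ in range(trials):
        draw = rng.choice(len(all_nodes), size=n_draw, replace=False)
        null_sizes.append(_induced_lcc(g, (all_nodes[i] for i in draw)))
    r = sum(1 for s in null_sizes if s >= observed)
    p = (r + 1) / (trials + 1)
    return observed, null_sizes, p


def rewire_network(
    network: InteractionNetwork,
    swap_factor: float = DEFAULT_SWAP_FACTOR,
    seed: int | np.random.Generator = 0,
) -> InteractionNetwork:
    """Degree-preserving randomization by double-edge swaps.

    Attempts ``ceil(swap_factor * |E|)`` swaps. Each attempt picks two
    distinct edges (a, b) and (c, d) uniformly and proposes replacing them
    with (a, d) and (c, b); the proposal is rejected if it would create a
    self-loop or a duplicate edge. The node set and every node's degree
    are preserved exactly. Edge labels are not carried over (the null
    model concerns topology only).
    """
    m = network.number_of_edges()
    if m < 2:
        raise ValueError("rewiring requires at least 2 edges")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edges = [tuple(sorted(e)) for e in network.graph.edges]
    edges.sort()
    edge_set = set(edges)
    n_attempts = math.ceil(swap_factor * m)
    for _ in range(n_attempts):
        i, j = rng.choice(m, size=2, replace=False)
        a, b = edges[i]
        c, d = edges[j]
        new1 = (a, d) if a < d else (d, a)
        new2 = (c, b) if c < b else (b, c)
        if a == d or c == b:
            continue  # self-loop
        if new1 in edge_set or new2 in edge_set or new1 == new2:
            continue  # duplicate edge
        edge_set.discard((a, b) if a < b else (b, a))
        edge_set.discard((c, d) if c < d else (d, c))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[i] = new1
        edges[j] = new2
    out = InteractionNetwork()
    for n in network.nodes:
        out.add_node(n)
    for u, v in sorted(edge_set):
        out.add_edge(u, v)
    return out


def modularity_significance(
    network: InteractionNetwork,
    partition_method: str = "edge_betweenness",
    trials: int = DEFAULT_MOD_TRIALS,
    swap_factor: float = DEFAULT_SWAP_FACTOR,
    seed: int = 0,
) -> tuple[float, float, float, float, float]:
    """Modularity z-score versus a degree-preserving rewired null ensemble.

    Community detection is re-run from scratch on every rewired network so
    each null draw gets its own best partition. Returns
    ``(observed_Q, null_mean, null_sd, z, p)`` with p the one-sided
    upper-tail standard-normal probability. If the null SD is zero the
    z-score is reported as NaN and p falls back to the empirical fraction
    of null Q values >= the observed Q (with the same +1 pseudocount as
    the LCC test).
    """
    if trials < 2:
        raise ValueError(f"modularity null needs trials >= 2, got {trials}")
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    observed_q = detect_communities(network, method=partition_method).modularity
    seeds = np.random.SeedSequence(seed).spawn(trials)
    null_q = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        rewired = rewire_network(network, swap_factor=swap_factor, seed=rng)
        null_q.append(detect_communities(rewired, method=partition_method).modularity)
    null_q = np.asarray(null_q)
    mean = float(null_q.mean())
    sd = float(null_q.std(ddof=1))
    if sd > 0:
        z = (observed_q - mean) / sd
        p = float(stats.norm.sf(z))
    else:
        z = float("nan")
        r = int(np.sum(null_q >= observed_q))
        p = (r + 1) / (trials + 1)
    return observed_q, mean, sd, z, p


def assess_significance(
    prior_network: InteractionNetwork,
    altered: AlteredGeneSet,
    extended_network: InteractionNetwork,
    partition_method: str = "edge_betweenness",
    lcc_trials: int = DEFAULT_LCC_TRIALS,
    mod_trials: int = DEFAULT_MOD_TRIALS,
    swap_factor: float = DEFAULT_SWAP_FACTOR,
    seed: int = 0,
) -> SignificanceReport:
    """Run both tests and bundle the results.

    The LCC test samples from the *full prior network* (the frame the
    observed altered genes were mapped onto); the modularity null rewires
    the *extended network* that was actually partitioned.
    """
    lcc_seed, mod_seed = np.random.SeedSequence(seed).spawn(2)
    observed_lcc, null_sizes, lcc_p = global_connectivity_test(
        prior_network, altered, trials=lcc_trials, seed=np.random.default_rng(lcc_seed)
    )
    mod_master = int(mod_seed.generate_state(1)[0] % (2**31))
    observed_q, mean, sd, z, q_p = modularity_significance(
        extended_network,
        partition_method=partition_method,
        trials=mod_trials,
        swap_factor=swap_factor,
        seed=mod_master,
    )
    return SignificanceReport(
        observed_lcc=observed_lcc,
        lcc_null_sizes=null_sizes,
        lcc_p=lcc_p,
        observed_Q=observed_q,
        Q_null_mean=mean,
        Q_null_sd=sd,
        Q_z=z,
        Q_p=q_p,
        lcc_trials=lcc_trials,
        mod_trials=mod_trials,
        seed=seed,
    )
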