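"""Planted-module benchmark: generate networks with known modules and
altered-gene lists with controlled signal, then score recovery.

The generator is a stochastic block model. Module members are wired
densely (``p_intra``), different modules sparsely (``p_inter``), and a
pool of background nodes — standing in for the bulk of a prior-knowledge
interactome that carries no signal — connects to everything with
``p_background``. The altered list takes a fraction of each module's nodes
plus a few random background nodes (noise). The module members *not*
selected as altered are recorded as ``withheld_linkers``: they are exactly
the genes the linker test should recover, operationalizing the premise
that unaltered genes embedded in an altered neighborhood are part of the
process.

Recovery is scored by (a) adjusted Rand index between planted and inferred
module assignments, (b) withheld-linker recall, and (c) the count of
background nodes falsely accepted as linkers.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .community import ModulePartition
from .linker_stats import LinkerResult
from .network_io import AlteredGeneSet, InteractionNetwork

__all__ = [
    "PlantedConfig",
    "PlantedTruth",
    "RecoveryMetrics",
    "generate_planted",
    "score_recovery",
    "DEFAULT_PLANTED_CONFIG",
]


@dataclass(frozen=True)
class PlantedConfig:
    """Parameters of the planted-module generator."""

    n_modules: int = 3
    module_sizes: tuple[int, ...] = (12, 12, 12)
    p_intra: float = 0.6
    p_inter: float = 0.02
    background_nodes: int = 40
    p_background: float = 0.02
    altered_fraction_in_modules: float = 0.7
    altered_background: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_modules != len(self.module_sizes):
            raise ValueError("n_modules must equal len(module_sizes)")
        if any(s < 2 for s in self.module_sizes):
            raise ValueError("module sizes must be >= 2")
        if not (0 <= self.p_inter < self.p_intra <= 1):
            raise ValueError("require 0 <= p_inter < p_intra <= 1")
        if not 0 <= self.p_background <= 1:
            raise ValueError("p_background must be a probability")
        if not 0 <= self.altered_fraction_in_modules <= 1:
            raise ValueError("altered_fraction_in_modules must be a probability")
        if self.altered_background < 0 or self.background_nodes < 0:
            raise ValueError("counts must be non-negative")
        if self.altered_background > self.background_nodes:
            raise ValueError("altered_background exceeds background_nodes")


@dataclass
class PlantedTruth:
    """A generated network with its ground truth."""

    network: InteractionNetwork
    true_assignment: dict[str, int]  # module members only; background absent
    altered: AlteredGeneSet
    withheld_linkers: set[str]
    config: PlantedConfig


@dataclass
class RecoveryMetrics:
    ari: float
    linker_recall: float
    linker_false_positives: int
    n_withheld: int
    n_module_nodes_in_result: int

    def to_dict(self) -> dict:
        return asdict(self)


#: the benchmark's reference conditions: 3 planted modules of 12 genes in a
#: 76-node network with a weak-noise altered list
DEFAULT_PLANTED_CONFIG = PlantedConfig()


def _node_names(config: PlantedConfig) -> tuple[list[list[str]], list[str]]:
    modules = []
    for m, size in enumerate(config.module_sizes):
        modules.append([f"M{m}_{i:02d}" for i in range(size)])
    background = [f"BG_{i:03d}" for i in range(config.background_nodes)]
    return modules, background


def generate_planted(config: PlantedConfig = DEFAULT_PLANTED_CONFIG) -> PlantedTruth:
    """Draw one planted-module network and altered-gene list.

    Deterministic given ``config.seed``. Any edge touching a background
    node appears with ``p_background``; edges between two modules with
    ``p_inter``; edges within a module with ``p_intra``.
    """
    rng = np.random.default_rng(config.seed)
    modules, background = _node_names(config)
    all_nodes = [n for mod in modules for n in mod] + background
    block_of = {}
    for m, mod in enumerate(modules):
        for n in mod:
            block_of[n] = m
    bg_block = config.n_modules

    net = InteractionNetwork()
    for n in all_nodes:
        net.add_node(n)
    for i, u in enumerate(all_nodes):
        bu = block_of.get(u, bg_block)
        for v in all_nodes[i + 1:]:
            bv = block_of.get(v, bg_block)
            if bu == bg_block or bv == bg_block:
                p = config.p_background
            elif bu == bv:
                p = config.p_intra
            else:
                p = config.p_inter
            if p > 0 and rng.random() < p:
                net.add_edge(u, v)

    altered_genes: list[str] = []
    withheld: set[str] = set()
    for mod in modules:
        n_alt = int(round(config.altered_fraction_in_modules * len(mod)))
        picked = set(rng.choice(len(mod), size=n_alt, replace=False).tolist())
        for i, n in enumerate(mod):
            if i in picked:
                altered_genes.append(n)
            else:
                withheld.add(n)
    if config.altered_background:
        picked = rng.choice(len(background), size=config.altered_background, replace=False)
        altered_genes.extend(background[i] for i in sorted(picked.tolist()))

    altered = AlteredGeneSet.from_genes(altered_genes, net)
    # keep only withheld genes that are actual linker candidates
    g = net.graph
    withheld = {
        w for w in withheld if any(nb in altered.mapped for nb in g.neighbors(w))
    }
    true_assignment = {n: block_of[n] for n in block_of}
    return PlantedTruth(net, true_assignment, altered, withheld, config)


def score_recovery(
    truth: PlantedTruth,
    partition: ModulePartition,
    linker_results: list[LinkerResult],
) -> RecoveryMetrics:
    """Score an inference result against the planted ground truth.

    ARI is computed on the true module members that appear in the inferred
    partition (background nodes carry no planted label and are excluded).
    """
    common = [n for n in sorted(truth.true_assignment) if n in partition.assignment]
    if not common and not linker_results:
        raise ValueError("result shares no nodes with the planted truth")
    if common:
        true_labels = [truth.true_assignment[n] for n in common]
        pred_labels = [partition.assignment[n] for n in common]
        ari = float(adjusted_rand_score(true_labels, pred_labels))
    else:
        ari = float("nan")

    accepted = {r.gene for r in linker_results if r.accepted}
    n_withheld = len(truth.withheld_linkers)
    recall = len(accepted & truth.withheld_linkers) / n_withheld if n_withheld else float("nan")
    background = truth.network.nodes - set(truth.true_assignment)
    fp = len(accepted & background)
    return RecoveryMetrics(
        ari=ari,
        linker_recall=recall,
        linker_false_positives=fp,
        n_withheld=n_withheld,
        n_module_nodes_in_result=len(common),
    )
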