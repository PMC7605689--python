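"""Model/Results interface over the module-discovery pipeline.

:class:`NetBoxModel` is built from a prior-knowledge interaction network
and an altered-gene list; ``fit()`` runs linker inference and community
detection and returns a :class:`NetBoxResults` carrying the linker table,
the extended network, the module partition, and (on request) the two
significance tests, with a ``summary()`` in the spirit of statsmodels
results objects.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

from . import community as _community
from . import linker_stats as _linker
from . import significance as _significance
from .network_io import AlteredGeneSet, InteractionNetwork, load_gene_list, load_sif


class NetBoxModel:
    """Module discovery on a prior network from an altered-gene list.

    Parameters
    ----------
    network : InteractionNetwork
        The prior-knowledge interactome (undirected, simple).
    altered : AlteredGeneSet or iterable of str
        The altered genes; a plain iterable is mapped onto the network.
    """

    def __init__(self, network: InteractionNetwork, altered):
        self.network = network
        if not isinstance(altered, AlteredGeneSet):
            altered = AlteredGeneSet.from_genes(altered, network)
        if not altered.mapped:
            raise ValueError("no altered genes map into the network")
        self.altered = altered

    @classmethod
    def from_files(cls, network_path, gene_list_path) -> "NetBoxModel":
        """Build from a SIF network file and a one-gene-per-line list."""
        network = load_sif(network_path)
        altered = load_gene_list(gene_list_path, network)
        return cls(network, altered)

    def fit(
        self,
        cutoff: float = _linker.DEFAULT_CUTOFF,
        linker_mode: str = "tail",
        community_method: str = "edge_betweenness",
    ) -> "NetBoxResults":
        """Run linker inference and community detection.

        ``linker_mode`` is ``"tail"`` (Pr(X >= x), default) or
        ``"legacy_point"`` (Pr(X = x), matching the original NetBox raw
        p-values). ``community_method`` is ``"edge_betweenness"`` or
        ``"leading_eigenvector"``.
        """
        extended, linker_results = _linker.build_extended_network(
            self.network, self.altered, cutoff=cutoff, mode=linker_mode
        )
        partition = _community.detect_communities(extended.network, method=community_method)
        return NetBoxResults(self, extended, linker_results, partition, cutoff, linker_mode)


class NetBoxResults:
    """Fitted module-discovery results.

    Attributes
    ----------
    extended : ExtendedNetwork
        Connected altered genes plus accepted linkers.
    linker_results : list of LinkerResult
        All candidates, accepted and rejected, sorted by raw p-value.
    partition : ModulePartition
        Module assignment of the extended network with its modularity Q.
    significance : SignificanceReport or None
        Filled by :meth:`assess_significance`.
    """

    def __init__(self, model, extended, linker_results, partition, cutoff, linker_mode):
        self.model = model
        self.extended = extended
        self.linker_results = linker_results
        self.partition = partition
        self.cutoff = cutoff
        self.linker_mode = linker_mode
        self.significance = None

    # -- tables -------------------------------------------------------

    @property
    def linker_table(self) -> pd.DataFrame:
        return _linker.linker_table(self.linker_results)

    @property
    def module_table(self) -> pd.DataFrame:
        rows = [
            {"gene": n, "module_id": mid, "role": self.extended.node_role[n]}
            for n, mid in sorted(self.partition.assignment.items(), key=lambda kv: (kv[1], kv[0]))
        ]
        return pd.DataFrame(rows, columns=["gene", "module_id", "role"])

    # -- significance -------------------------------------------------

    def assess_significance(
        self,
        lcc_trials: int = _significance.DEFAULT_LCC_TRIALS,
        mod_trials: int = _significance.DEFAULT_MOD_TRIALS,
        swap_factor: float = _significance.DEFAULT_SWAP_FACTOR,
        seed: int = 0,
    ) -> "_significance.SignificanceReport":
        """Run the LCC permutation test and the modularity-null z-test."""
        self.significance = _significance.assess_significance(
            self.model.network,
            self.model.altered,
            self.extended.network,
            partition_method=self.partition.method,
            lcc_trials=lcc_trials,
            mod_trials=mod_trials,
            swap_factor=swap_factor,
            seed=seed,
        )
        return self.significance

    # -- reporting ----------------------------------------------------

    def summary(self) -> str:
        """Human-readable run summary."""
        alt = self.model.altered
        n_acc = sum(r.accepted for r in self.linker_results)
        buf = StringIO()
        w = buf.write
        w("Network module discovery results\n")
        w("=" * 46 + "\n")
        w(f"Prior network          {self.model.network.number_of_nodes()} nodes, "
          f"{self.model.network.number_of_edges()} edges\n")
        w(f"Altered genes          {len(alt.requested)} requested, {len(alt.mapped)} mapped, "
          f"{len(alt.unmapped)} unmapped\n")
        w(f"Linker candidates      {len(self.linker_results)} tested, {n_acc} accepted "
          f"(BH-adjusted p <= {self.cutoff:g}, mode={self.linker_mode})\n")
        w(f"Extended network       {self.extended.network.number_of_nodes()} nodes, "
          f"{self.extended.network.number_of_edges()} edges"
          f" ({len(self.extended.dropped_altered)} isolated altered genes dropped)\n")
        w(f"Modules                {self.partition.n_modules} "
          f"({self.partition.method}), modularity Q = {self.partition.modularity:.4f}\n")
        if self.significance is not None:
            s = self.significance
            w("-" * 46 + "\n")
            w(f"LCC test               observed {s.observed_lcc}, "
              f"p = {s.lcc_p:.4g} ({s.lcc_trials} trials)\n")
            w(f"Modularity null        mean {s.Q_null_mean:.4f}, sd {s.Q_null_sd:.4f}, "
              f"z = {s.Q_z:.2f}, p = {s.Q_p:.4g} ({s.mod_trials} rewired networks)\n")
        return buf.getvalue()

    def __repr__(self) -> str:
        return (f"<NetBoxResults: {self.partition.n_modules} modules, "
                f"Q={self.partition.modularity:.3f}>")
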