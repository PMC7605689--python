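"""Reading, normalizing, and writing interaction networks and gene lists.

The interchange formats are the plain-text ones used around Cytoscape and
Pathway Commons: SIF (three whitespace-separated columns: source,
interaction-type, target), two/three-column TSV edge tables, GraphML for
visualization tools, and one-identifier-per-line gene lists.

Normalization contract: identifiers are stripped of surrounding whitespace
but otherwise preserved byte-for-byte (no case folding, no aliasing);
self-loops are dropped; duplicate undirected edges are merged keeping the
first-seen interaction label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "AlteredGeneSet",
    "NetworkParseError",
    "load_sif",
    "load_edge_table",
    "load_gene_list",
    "write_network",
]

#: placeholder interaction type for unlabeled edges written to SIF
SIF_PLACEHOLDER_LABEL = "interacts"


class NetworkParseError(ValueError):
    """Malformed network or gene-list input file."""


class InteractionNetwork:
    """Undirected simple graph of gene identifiers with optional edge labels.

    Thin wrapper over a :class:`networkx.Graph` that enforces the
    normalization invariants (no self-loops, no duplicate undirected edges,
    every endpoint in the node set). The underlying graph is exposed as
    :attr:`graph` for algorithms; edge labels live in the ``label`` edge
    attribute.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self._g = nx.Graph()
        if graph is not None:
            # canonical (sorted) insertion order so downstream iteration --
            # and hence floating-point summation order -- never depends on
            # set/hash ordering of the source graph
            for n in sorted(graph.nodes):
                self._g.add_node(str(n))
            for u, v in sorted(tuple(sorted((str(u), str(v)))) for u, v in graph.edges):
                self.add_edge(u, v, graph.edges[u, v].get("label"))

    # -- construction -------------------------------------------------

    def add_node(self, node: str) -> None:
        self._g.add_node(node)

    def add_edge(self, u: str, v: str, label: str | None = None) -> None:
        """Add an undirected edge; self-loops are silently dropped and a
        duplicate edge keeps the first-seen label (conflicts are logged)."""
        if u == v:
            return
        if self._g.has_edge(u, v):
            old = self._g.edges[u, v].get("label")
            if label is not None and old is not None and old != label:
                logger.debug("conflicting labels for edge (%s, %s): keeping %r, ignoring %r", u, v, old, label)
            return
        self._g.add_edge(u, v, label=label)

    # -- views --------------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self._g.edges}

    def edge_label(self, u: str, v: str) -> str | None:
        return self._g.edges[u, v].get("label")

    def degree(self, node: str) -> int:
        return self._g.degree[node]

    def number_of_nodes(self) -> int:
        return self._g.number_of_nodes()

    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def subgraph(self, nodes) -> "InteractionNetwork":
        """Induced subgraph on ``nodes`` (unknown identifiers ignored)."""
        keep = set(nodes) & self.nodes
        return InteractionNetwork(self._g.subgraph(keep))

    def copy(self) -> "InteractionNetwork":
        return InteractionNetwork(self._g)

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def __eq__(self, other) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return f"InteractionNetwork({self.number_of_nodes()} nodes, {self.number_of_edges()} edges)"


@dataclass
class AlteredGeneSet:
    """An input altered-gene list with its mapping onto a network.

    ``requested`` preserves the de-duplicated input order; ``mapped`` and
    ``unmapped`` partition the unique identifiers by presence in the
    network node set.
    """

    requested: list[str]
    mapped: set[str]
    unmapped: set[str]
    n_duplicates: int = 0

    def __post_init__(self):
        assert self.mapped | self.unmapped == set(self.requested)
        assert not (self.mapped & self.unmapped)

    @classmethod
    def from_genes(cls, genes, network: InteractionNetwork) -> "AlteredGeneSet":
        seen: dict[str, None] = {}
        dups = 0
        for g in genes:
            g = str(g).strip()
            if not g:
                continue
            if g in seen:
                dups += 1
            else:
                seen[g] = None
        requested = list(seen)
        nodes = network.nodes
        mapped = {g for g in requested if g in nodes}
        return cls(requested, mapped, set(requested) - mapped, dups)


# ----------------------------------------------------------------------
# readers


def _iter_lines(path):
    text = Path(path).read_text(encoding="utf-8")
    for i, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            yield i, line


def load_sif(path) -> InteractionNetwork:
    """Load a SIF file (``source interaction-type target``, whitespace-split).

    Raises :class:`NetworkParseError` naming the line number for any
    non-empty line that does not have exactly three fields, and for an
    empty file.
    """
    net = InteractionNetwork()
    n_lines = 0
    for lineno, line in _iter_lines(path):
        fields = line.split()
        if len(fields) != 3:
            raise NetworkParseError(
                f"{path}: line {lineno}: expected 3 fields (source, type, target), got {len(fields)}"
            )
        src, kind, dst = (f.strip() for f in fields)
        net.add_node(src)
        net.add_node(dst)
        net.add_edge(src, dst, kind)
        n_lines += 1
    if n_lines == 0:
        raise NetworkParseError(f"{path}: empty network file")
    return net


def load_edge_table(path, has_header: bool = False) -> InteractionNetwork:
    """Load a 2- or 3-column tab-separated edge table.

    Column order is ``source<TAB>target`` (unlabeled) or
    ``source<TAB>type<TAB>target``. The column count must be consistent
    across all data lines.
    """
    net = InteractionNetwork()
    ncols = None
    n_lines = 0
    for lineno, line in _iter_lines(path):
        if has_header and n_lines == 0 and ncols is None:
            ncols = len(line.split("\t"))
            if ncols not in (2, 3):
                raise NetworkParseError(f"{path}: line {lineno}: expected 2 or 3 columns, got {ncols}")
            has_header = False  # consumed
            continue
        fields = [f.strip() for f in line.split("\t")]
        if ncols is None:
            ncols = len(fields)
            if ncols not in (2, 3):
                raise NetworkParseError(f"{path}: line {lineno}: expected 2 or 3 columns, got {ncols}")
        elif len(fields) != ncols:
            raise NetworkParseError(
                f"{path}: line {lineno}: inconsistent column count ({len(fields)} vs {ncols})"
            )
        if ncols == 2:
            src, dst, kind = fields[0], fields[1], None
        else:
            src, kind, dst = fields
        net.add_node(src)
        net.add_node(dst)
        net.add_edge(src, dst, kind)
        n_lines += 1
    if n_lines == 0:
        raise NetworkParseError(f"{path}: empty network file")
    return net


def load_gene_list(path, network: InteractionNetwork) -> AlteredGeneSet:
    """Load a one-identifier-per-line gene list and map it onto ``network``.

    Blank lines are ignored; duplicates are collapsed (count kept in
    ``n_duplicates`` and logged). Raises :class:`NetworkParseError` if no
    gene maps into the network — there is nothing to analyze.
    """
    genes = [line for _, line in _iter_lines(path)]
    altered = AlteredGeneSet.from_genes(genes, network)
    if altered.n_duplicates:
        logger.warning("%s: collapsed %d duplicate identifiers", path, altered.n_duplicates)
    if not altered.requested:
        raise NetworkParseError(f"{path}: empty gene list")
    if not altered.mapped:
        raise NetworkParseError(f"{path}: none of the {len(altered.requested)} genes map into the network")
    return altered


# ----------------------------------------------------------------------
# writers


def write_network(network: InteractionNetwork, path, format: str = "sif") -> None:
    """Write a network as ``sif``, ``edge-table``, or ``graphml``.

    Round-trip guarantee: loading the written file reproduces the node and
    edge sets. Isolated nodes cannot be represented in SIF/edge-table and
    are only preserved by GraphML.
    """
    path = Path(path)
    g = network.graph
    if format == "sif":
        lines = []
        for u, v in sorted((sorted((u, v)) for u, v in g.edges), key=tuple):
            label = g.edges[u, v].get("label") or SIF_PLACEHOLDER_LABEL
            lines.append(f"{u}\t{label}\t{v}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "edge-table":
        # column count must be uniform for the reader; placeholder-fill if
        # any edge carries a label
        any_label = any(d.get("label") is not None for _, _, d in g.edges(data=True))
        lines = []
        for u, v in sorted((sorted((u, v)) for u, v in g.edges), key=tuple):
            label = g.edges[u, v].get("label")
            if any_label:
                lines.append(f"{u}\t{label or SIF_PLACEHOLDER_LABEL}\t{v}")
            else:
                lines.append(f"{u}\t{v}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "graphml":
        out = nx.Graph()
        out.add_nodes_from(sorted(g.nodes))
        for u, v in g.edges:
            label = g.edges[u, v].get("label")
            if label is not None:
                out.add_edge(u, v, label=label)
            else:
                out.add_edge(u, v)
        nx.write_graphml(out, path, encoding="utf-8")
    else:
        raise ValueError(f"unknown network format: {format!r} (expected sif, edge-table, or graphml)")
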