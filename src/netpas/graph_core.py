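"""Interaction-network and gene-set containers.

The interactome is modelled as a simple undirected graph: nodes are gene
identifiers (opaque, case-sensitive strings; typically HUGO symbols), edges
are physical interactions.  The loader enforces the simple-graph contract
that every downstream statistic assumes: no self-loops, no multi-edges,
orientation-independent edge identity.

Gene sets are plain named sets of identifiers, read from GMT files (one set
per line: name, description, members) or one-identifier-per-line lists.
Genes absent from the network never enter edge counting, but are always
surfaced in a :class:`FilterReport` so nothing is dropped silently.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Network",
    "GeneSet",
    "GeneSetCollection",
    "FilterReport",
    "NetworkError",
    "EmptySetError",
    "load_network",
    "write_edgelist",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "restrict_to_network",
]


class NetworkError(ValueError):
    """Raised when an input graph violates the simple-graph contract."""


class EmptySetError(ValueError):
    """Raised when a gene set is empty after restriction to the network."""


class Network:
    """Simple undirected graph with string node labels.

    Edges are stored once, as canonically ordered integer index pairs into
    the node label table; ``{u, v}`` and ``{v, u}`` are the same edge.

    Parameters
    ----------
    labels
        Node labels, unique strings.
    edges
        ``(m, 2)`` integer array of node indices.  Self-loops and duplicate
        edges (in either orientation) raise :class:`NetworkError`.
    """

    __slots__ = ("_labels", "_index", "_edges", "_degrees")

    def __init__(self, labels: Sequence[str], edges: np.ndarray):
        self._labels: tuple[str, ...] = tuple(labels)
        if len(set(self._labels)) != len(self._labels):
            raise NetworkError("duplicate node labels")
        self._index: dict[str, int] = {lab: i for i, lab in enumerate(self._labels)}
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        if edges.size and (edges.min() < 0 or edges.max() >= len(self._labels)):
            raise NetworkError("edge index out of range")
        if np.any(edges[:, 0] == edges[:, 1]):
            raise NetworkError("self-loop in edge array")
        canon = np.sort(edges, axis=1)
        order = np.lexsort((canon[:, 1], canon[:, 0]))
        canon = canon[order]
        if len(canon) > 1 and np.any(np.all(canon[1:] == canon[:-1], axis=1)):
            raise NetworkError("duplicate edge in edge array")
        self._edges = canon
        self._edges.setflags(write=False)
        deg = np.zeros(len(self._labels), dtype=np.int64)
        np.add.at(deg, self._edges.ravel(), 1)
        self._degrees = deg
        self._degrees.setflags(write=False)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edge_labels(cls, pairs: Iterable[tuple[str, str]]) -> "Network":
        pairs = list(pairs)
        labels = sorted({g for pair in pairs for g in pair})
        index = {lab: i for i, lab in enumerate(labels)}
        edges = np.array([[index[u], index[v]] for u, v in pairs], dtype=np.int64)
        return cls(labels, edges.reshape(-1, 2))

    def replace_edges(self, edges: np.ndarray) -> "Network":
        """New Network over the same node table with a different edge array."""
        return Network(self._labels, edges)

    # -- basic queries -----------------------------------------------------

    @property
    def labels(self) -> tuple[str, ...]:
        return self._labels

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._labels)

    @property
    def edge_array(self) -> np.ndarray:
        """Read-only ``(m, 2)`` canonical integer edge array."""
        return self._edges

    @property
    def n_nodes(self) -> int:
        return len(self._labels)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    @property
    def degree(self) -> dict[str, int]:
        return {lab: int(d) for lab, d in zip(self._labels, self._degrees)}

    @property
    def degree_array(self) -> np.ndarray:
        return self._degrees

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def edge_set(self) -> frozenset[frozenset[str]]:
        return frozenset(
            frozenset((self._labels[u], self._labels[v])) for u, v in self._edges
        )

    def has_edge(self, u: str, v: str) -> bool:
        if u not in self._index or v not in self._index:
            return False
        a, b = sorted((self._index[u], self._index[v]))
        idx = np.searchsorted(
            self._edges[:, 0] * self.n_nodes + self._edges[:, 1], a * self.n_nodes + b
        )
        return idx < self.n_edges and tuple(self._edges[idx]) == (a, b)

    def membership(self, genes: Iterable[str]) -> np.ndarray:
        """Boolean node-indexed mask of the genes present in the network."""
        mask = np.zeros(self.n_nodes, dtype=bool)
        for g in genes:
            i = self._index.get(g)
            if i is not None:
                mask[i] = True
        return mask

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self._labels)
        g.add_edges_from(
            (self._labels[u], self._labels[v]) for u, v in self._edges
        )
        return g

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Network(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers."""

    name: str
    genes: frozenset[str]

    def __init__(self, name: str, genes: Iterable[str]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "genes", frozenset(genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)


class GeneSetCollection:
    """Ordered, uniquely named collection of :class:`GeneSet`."""

    def __init__(
        self,
        sets: Iterable[GeneSet] = (),
        descriptions: Mapping[str, str] | None = None,
    ):
        self._sets: dict[str, GeneSet] = {}
        self.descriptions: dict[str, str] = dict(descriptions or {})
        for gs in sets:
            self.add(gs)

    def add(self, gs: GeneSet, description: str = "") -> None:
        if gs.name in self._sets:
            raise ValueError(f"duplicate gene-set name: {gs.name!r}")
        self._sets[gs.name] = gs
        if description:
            self.descriptions[gs.name] = description

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __len__(self) -> int:
        return len(self._sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.names == other.names and all(
            self[n].genes == other[n].genes for n in self.names
        )


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping for the network restriction of one gene set."""

    name: str
    n_input: int
    n_in_network: int
    dropped: tuple[str, ...]

    def __post_init__(self):
        if self.n_in_network > self.n_input:
            raise ValueError("n_in_network exceeds n_input")


# -- I/O -------------------------------------------------------------------


def load_network(
    path: str | Path,
    dedupe: bool = True,
    keep_isolated: bool = False,
    header: bool = False,
) -> Network:
    """Read an undirected simple graph from a two-column edge-list file.

    Lines starting with ``#`` are comments; extra columns beyond the first
    two are ignored.  Self-loops are dropped and duplicate edges (either
    orientation) collapsed; the counts of dropped records are reported via
    warnings.  Nodes left with no edge after cleaning are dropped unless
    ``keep_isolated`` — degree-zero nodes are invisible to degree-preserving
    permutation and to edge counting alike.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    n_self = 0
    n_dup = 0
    isolated: set[str] = set()
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        first_data = True
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if header and first_data:
                first_data = False
                continue
            first_data = False
            cols = line.split()
            if len(cols) < 2:
                raise NetworkError(f"{path}: malformed line {line!r}")
            u, v = cols[0], cols[1]
            if u == v:
                n_self += 1
                isolated.add(u)
                continue
            key = (u, v) if u < v else (v, u)
            if key in seen:
                n_dup += 1
                if not dedupe:
                    raise NetworkError(f"{path}: duplicate edge {key}")
                continue
            seen.add(key)
            pairs.append(key)
    if not pairs:
        raise NetworkError(f"{path}: no edges after cleaning")
    if n_self or n_dup:
        warnings.warn(
            f"{path.name}: dropped {n_self} self-loop(s) and {n_dup} duplicate edge(s)"
        )
    net = Network.from_edge_labels(pairs)
    if keep_isolated:
        extra = sorted(isolated - net.nodes)
        if extra:
            labels = list(net.labels) + extra
            net = Network(labels, net.edge_array)
    return net


def write_edgelist(net: Network, path: str | Path) -> None:
    """Write the network as a deterministic tab-separated edge list."""
    labels = net.labels
    with open(path, "w") as fh:
        for u, v in net.edge_array:
            fh.write(f"{labels[u]}\t{labels[v]}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a Broad-style GMT file: name TAB description TAB gene1 TAB ...

    Duplicate genes within a line are deduplicated with a warning; a line
    with no genes or a repeated set name raises.
    """
    path = Path(path)
    coll = GeneSetCollection()
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has no genes")
            name, desc, genes = cols[0], cols[1], [g for g in cols[2:] if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: GMT line has no genes")
            if len(set(genes)) != len(genes):
                warnings.warn(f"{path.name}:{lineno}: duplicate genes in set {name!r}")
            coll.add(GeneSet(name, genes), description=desc)
    if n_lines == 0:
        warnings.warn(f"{path.name}: empty GMT file")
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in coll:
            desc = coll.descriptions.get(gs.name, "")
            fh.write("\t".join([gs.name, desc, *sorted(gs.genes)]) + "\n")


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a single gene set from a one-identifier-per-line file."""
    path = Path(path)
    genes = []
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                genes.append(g)
    if not genes:
        raise ValueError(f"{path}: no gene identifiers")
    return GeneSet(name or path.stem, genes)


def restrict_to_network(gs: GeneSet, net: Network) -> tuple[GeneSet, FilterReport]:
    """Intersect a gene set with the network's node set.

    Returns the restricted set together with a :class:`FilterReport` listing
    every dropped identifier.  An empty restricted set is returned as-is;
    operations that need network members refuse it with
    :class:`EmptySetError`.
    """
    kept = frozenset(g for g in gs.genes if g in net)
    dropped = tuple(sorted(gs.genes - kept))
    report = FilterReport(
        name=gs.name,
        n_input=len(gs.genes),
        n_in_network=len(kept),
        dropped=dropped,
    )
    return GeneSet(gs.name, kept), report
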