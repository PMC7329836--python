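"""Synthetic networks, random gene sets, and calibration machinery.

Two jobs live here.  First, the calibration experiments that justify the
``|Z| > 2`` working cutoff: background Z distributions over randomly
constructed gene sets, and the affiliation bootstrap that re-partitions a
pooled pair of sets to show the observed Z is typical of chance
partitions.  Second, desk-scale fixtures — preferential-attachment
networks with optional pendant (degree-1) nodes and planted inter-set edge
surpluses — that stand in for a real interactome so the whole pipeline is
testable offline, with exact ground-truth bookkeeping for oracle tests.

Everything is seed-deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .association import (
    AssociationResult,
    GeneSetAssociation,
    _count_between_masks,
    associate_all_pairs,
    z_score,
)
from .graph_core import (
    EmptySetError,
    GeneSet,
    GeneSetCollection,
    Network,
    restrict_to_network,
)
from .ms02 import MS02Config, null_edge_arrays

__all__ = [
    "RandomSetSpec",
    "FixtureSpec",
    "CalibrationResult",
    "BootstrapResult",
    "make_random_sets",
    "background_calibration",
    "bootstrap_affiliation",
    "make_fixture",
    "make_synthetic_variants",
]


@dataclass(frozen=True)
class RandomSetSpec:
    """Random gene-set construction rule.

    ``size`` is either a fixed integer or an inclusive ``(lo, hi)`` range
    sampled uniformly per set.  Genes are drawn uniformly without
    replacement from the network's node universe.
    """

    n_sets: int
    size: int | tuple[int, int]
    seed: int

    def __post_init__(self):
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        lo, hi = self.size_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid size range")

    @property
    def size_range(self) -> tuple[int, int]:
        if isinstance(self.size, int):
            return self.size, self.size
        lo, hi = self.size
        return int(lo), int(hi)


def make_random_sets(net: Network, spec: RandomSetSpec) -> GeneSetCollection:
    """Sample ``spec.n_sets`` random gene sets from the network's nodes."""
    lo, hi = spec.size_range
    if hi > net.n_nodes:
        raise ValueError("set size exceeds node universe")
    rng = np.random.default_rng(int(spec.seed))
    labels = np.array(net.labels)
    width = len(str(spec.n_sets))
    coll = GeneSetCollection()
    for i in range(spec.n_sets):
        k = int(rng.integers(lo, hi + 1))
        members = rng.choice(labels, size=k, replace=False)
        coll.add(GeneSet(f"rand{i + 1:0{width}d}", members.tolist()))
    return coll


@dataclass
class CalibrationResult:
    """Background Z distribution over random gene-set pairs.

    ``z_values`` holds all defined non-self pairwise Z-scores;
    ``tail_counts`` / ``tail_fractions`` report, per threshold t, the
    number/fraction of pairs with Z > t and Z < -t.
    """

    z_values: np.ndarray
    n_pairs: int
    thresholds: tuple[float, ...]
    tail_counts: dict[float, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        self.z_values = np.asarray(self.z_values, dtype=float)
        if not self.tail_counts:
            for t in self.thresholds:
                self.tail_counts[t] = (
                    int(np.sum(self.z_values > t)),
                    int(np.sum(self.z_values < -t)),
                )

    @classmethod
    def from_counts(
        cls, n_above: int, n_below: int, n_pairs: int, threshold: float = 2.0
    ) -> "CalibrationResult":
        """Summarizer from pre-tabulated tail counts (no Z vector kept)."""
        out = cls(
            z_values=np.empty(0),
            n_pairs=n_pairs,
            thresholds=(threshold,),
            tail_counts={threshold: (n_above, n_below)},
        )
        return out

    @property
    def tail_fractions(self) -> dict[float, tuple[float, float]]:
        return {
            t: (above / self.n_pairs, below / self.n_pairs)
            for t, (above, below) in self.tail_counts.items()
        }

    def combined_fraction(self, threshold: float = 2.0) -> float:
        above, below = self.tail_counts[threshold]
        return (above + below) / self.n_pairs

    def summary(self) -> str:
        lines = [
            f"Background calibration over {self.n_pairs} non-self pairs",
        ]
        for t, (above, below) in sorted(self.tail_counts.items()):
            fa, fb = self.tail_fractions[t]
            lines.append(
                f"  Z > {t:g}: {above} (p = {fa:.3f});  "
                f"Z < -{t:g}: {below} (p = {fb:.3f})"
            )
        return "\n".join(lines)


def background_calibration(
    net: Network,
    spec: RandomSetSpec,
    config: MS02Config,
    thresholds: tuple[float, ...] = (2.0,),
) -> CalibrationResult:
    """Pairwise Z-scores among random gene sets (shared null ensemble).

    Random sets carry no signal, so their Z distribution is the genetic
    background; the tail fractions beyond each threshold estimate the false
    positive rate of that cutoff.  Self-associations are excluded.
    """
    if spec.n_sets < 2:
        raise ValueError("need at least 2 random sets")
    coll = make_random_sets(net, spec)
    matrix = associate_all_pairs(net, coll, config)
    z = matrix.offdiag_values("z")
    n_pairs = matrix.n_unique_pairs()
    return CalibrationResult(z_values=z, n_pairs=n_pairs, thresholds=thresholds)


@dataclass
class BootstrapResult:
    """Affiliation bootstrap of one pair of gene sets."""

    original_z: float
    z_values: np.ndarray
    n_boot: int

    def fraction_beyond(self, threshold: float = 2.0) -> float:
        return float(np.mean(np.abs(self.z_values) > threshold))

    def covers_original(self) -> bool:
        return (
            float(self.z_values.min())
            <= self.original_z
            <= float(self.z_values.max())
        )


def bootstrap_affiliation(
    net: Network,
    a: GeneSet,
    b: GeneSet,
    n_boot: int,
    config: MS02Config,
    seed: int | None = None,
) -> BootstrapResult:
    """Re-partition the pooled genes of A and B and recompute Z each time.

    The pooled membership A ∪ B is randomly split back into sizes |A| and
    |B| (overlapping genes, if any, are pooled once and land on one side),
    and the association Z of each chance partition is computed against the
    *same* shared null ensemble as the original pair.  On exchangeable
    no-signal pairs the original Z should be an ordinary draw from this
    distribution.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    ra, _ = restrict_to_network(a, net)
    rb, _ = restrict_to_network(b, net)
    if not ra.genes or not rb.genes:
        raise EmptySetError("a gene set has no members in the network")
    pool = sorted(ra.genes | rb.genes)
    n_a = len(ra.genes - rb.genes) + len(ra.genes & rb.genes)
    pool_idx = np.array([net.index_of(g) for g in pool], dtype=np.int64)

    rng = np.random.default_rng(int(seed if seed is not None else config.seed))
    n_nodes = net.n_nodes
    # side-A membership per bootstrap partition, node-indexed
    amemb = np.zeros((n_nodes, n_boot), dtype=bool)
    for j in range(n_boot):
        pick = rng.choice(pool_idx, size=n_a, replace=False)
        amemb[pick, j] = True
    pool_mask = np.zeros(n_nodes, dtype=bool)
    pool_mask[pool_idx] = True
    bmemb = pool_mask[:, None] & ~amemb

    orig_a = net.membership(ra.genes)
    orig_b = net.membership(rb.genes)

    def counts_on(edges: np.ndarray) -> tuple[np.ndarray, int]:
        u, v = edges[:, 0], edges[:, 1]
        boots = (
            (amemb[u] & bmemb[v]).sum(axis=0) + (amemb[v] & bmemb[u]).sum(axis=0)
        )
        orig = _count_between_masks(edges, orig_a, orig_b)
        return boots.astype(np.int64), orig

    obs_boot, obs_orig = counts_on(net.edge_array)
    null_boot = np.empty((config.n_models, n_boot), dtype=np.int64)
    null_orig = np.empty(config.n_models, dtype=np.int64)
    for i, edges in enumerate(null_edge_arrays(net, config)):
        null_boot[i], null_orig[i] = counts_on(edges)

    mean = null_boot.mean(axis=0)
    sd = null_boot.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (obs_boot - mean) / sd, np.nan)
    original_z = z_score(
        obs_orig, float(null_orig.mean()), float(null_orig.std(ddof=1))
    )
    return BootstrapResult(original_z=original_z, z_values=z, n_boot=n_boot)


# -- fixtures --------------------------------------------------------------


@dataclass(frozen=True)
class FixtureSpec:
    """Desk-scale synthetic interactome specification.

    A preferential-attachment backbone (``attachment`` edges per new node)
    is optionally decorated with ``n_pendant`` degree-1 nodes attached to
    existing nodes proportionally to degree, so the fixture reproduces the
    hub-attached single-interaction proteins of real interactomes.  Random
    gene sets are drawn from the nodes, and ``planted`` blocks add a
    surplus of edges between named set pairs, drawn uniformly over the
    non-existing inter-set node pairs.
    """

    n_nodes: int = 2000
    attachment: int = 3
    n_pendant: int = 0
    n_sets: int = 0
    set_size: int | tuple[int, int] = (15, 200)
    planted: tuple[tuple[str, str, int], ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < self.attachment + 1:
            raise ValueError("n_nodes too small for attachment parameter")
        if self.n_pendant < 0:
            raise ValueError("n_pendant must be >= 0")


def _backbone_edges(spec: FixtureSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    import networkx as nx

    n_core = spec.n_nodes - spec.n_pendant
    if n_core < spec.attachment + 1:
        raise ValueError("too many pendant nodes for the core size")
    g = nx.barabasi_albert_graph(
        n_core, spec.attachment, seed=int(rng.integers(0, 2**31 - 1))
    )
    edges = [tuple(sorted(e)) for e in g.edges()]
    # pendant degree-1 nodes, attached preferentially (degree-proportional)
    deg = np.zeros(spec.n_nodes, dtype=np.int64)
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    for p in range(n_core, spec.n_nodes):
        probs = deg[:p] / deg[:p].sum()
        target = int(rng.choice(p, p=probs))
        edges.append((target, p))
        deg[target] += 1
        deg[p] = 1
    return edges


def make_fixture(
    spec: FixtureSpec,
) -> tuple[Network, GeneSetCollection, dict]:
    """Generate (network, gene-set collection, ground-truth record).

    The ground truth records node/edge counts, per-set memberships, the
    empirical isolated-pair count, and for every planted block the number
    of surplus edges added and the final inter-set count — exact numbers
    for oracle tests.
    """
    from .ms02 import isolated_pair_count

    rng = np.random.default_rng(int(spec.seed))
    edges = _backbone_edges(spec, rng)
    width = max(4, len(str(spec.n_nodes)))
    labels = [f"g{i:0{width}d}" for i in range(spec.n_nodes)]

    set_rng = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
    coll = GeneSetCollection()
    membership: dict[str, list[str]] = {}
    lo, hi = RandomSetSpec(
        n_sets=max(spec.n_sets, 1), size=spec.set_size, seed=0
    ).size_range
    for i in range(spec.n_sets):
        k = int(set_rng.integers(lo, hi + 1))
        members = set_rng.choice(spec.n_nodes, size=k, replace=False)
        name = f"set{i + 1:02d}"
        genes = [labels[j] for j in members]
        coll.add(GeneSet(name, genes))
        membership[name] = sorted(genes)

    edge_set = set(edges)
    label_index = {lab: i for i, lab in enumerate(labels)}
    planted_record = []
    for name_a, name_b, surplus in spec.planted:
        ia = np.array([label_index[g] for g in coll[name_a].genes])
        ib = np.array([label_index[g] for g in coll[name_b].genes])
        candidates = [
            (int(u), int(v)) if u < v else (int(v), int(u))
            for u in ia
            for v in ib
            if u != v
        ]
        candidates = sorted(set(c for c in candidates if c not in edge_set))
        if surplus > len(candidates):
            raise ValueError(
                f"planted surplus {surplus} exceeds free bipartite capacity "
                f"{len(candidates)} for ({name_a}, {name_b})"
            )
        pick = rng.choice(len(candidates), size=surplus, replace=False)
        for idx in pick:
            edge_set.add(candidates[int(idx)])
        planted_record.append(
            {"set_a": name_a, "set_b": name_b, "surplus": int(surplus)}
        )

    net = Network(labels, np.array(sorted(edge_set), dtype=np.int64))
    truth = {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "n_pendant": spec.n_pendant,
        "memberships": membership,
        "isolated_pairs": isolated_pair_count(net),
        "planted": planted_record,
        "seed": spec.seed,
    }
    return net, coll, truth


def make_synthetic_variants(
    base: GeneSet, net: Network, mode: str
) -> GeneSet:
    """Topology-contrasted variants of a gene set.

    ``dense_clique`` keeps the members with at least one within-set
    interaction (the mutually connected core); ``isolated_nodes`` keeps the
    members with none.  Both operations are idempotent.
    """
    restricted, _ = restrict_to_network(base, net)
    if not restricted.genes:
        raise EmptySetError(f"set {base.name!r} has no members in the network")
    mask = net.membership(restricted.genes)
    e = net.edge_array
    within = np.zeros(net.n_nodes, dtype=np.int64)
    inside = mask[e[:, 0]] & mask[e[:, 1]]
    np.add.at(within, e[inside].ravel(), 1)
    if mode == "dense_clique":
        keep = [g for g in restricted.genes if within[net.index_of(g)] > 0]
    elif mode == "isolated_nodes":
        keep = [g for g in restricted.genes if within[net.index_of(g)] == 0]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not keep:
        raise EmptySetError(f"mode {mode!r} yields an empty set for {base.name!r}")
    return GeneSet(f"{base.name}_{mode}", keep)
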