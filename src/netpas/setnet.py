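"""Weighted association networks over gene-set collections.

Gene sets become nodes; a pair is connected when its association statistic
passes a cutoff.  Three flavours mirror the three statistics: a signed
Z-score network (enriched vs suppressed edges), a uniform-weight p-value
network, and a Jaccard overlap network (``J > 0`` reproduces the classic
shared-gene disease-network rule).  Isolated nodes are kept explicitly —
a set with no passing association is itself informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .association import AssociationMatrix

__all__ = ["SetNetwork", "build_znet", "build_pnet", "build_jnet"]

_EDGE_COLUMNS = ["set_a", "set_b", "weight", "sign"]


@dataclass
class SetNetwork:
    """Gene sets as nodes, passing associations as weighted signed edges."""

    nodes: tuple[str, ...]
    edges: pd.DataFrame  # columns: set_a, set_b, weight, sign
    statistic: str
    cutoff: dict = field(default_factory=dict)

    def __post_init__(self):
        if list(self.edges.columns) != _EDGE_COLUMNS:
            raise ValueError(f"edge table must have columns {_EDGE_COLUMNS}")
        if np.any(self.edges["set_a"] == self.edges["set_b"]):
            raise ValueError("self-edge in set network")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def isolated_nodes(self) -> tuple[str, ...]:
        used = set(self.edges["set_a"]) | set(self.edges["set_b"])
        return tuple(n for n in self.nodes if n not in used)

    def edge_count(self, sign: str | None = None) -> int:
        if sign is None:
            return len(self.edges)
        return int((self.edges["sign"] == sign).sum())

    def to_tsv(self, path: str | Path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    def to_graphml(self, path: str | Path) -> None:
        import networkx as nx

        g = nx.Graph(statistic=self.statistic)
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.set_a, row.set_b, weight=float(row.weight), sign=row.sign)
        nx.write_graphml(g, path)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.set_a, row.set_b, weight=float(row.weight), sign=row.sign)
        return g


def _upper_pairs(mat: pd.DataFrame):
    names = list(mat.index)
    arr = mat.to_numpy(dtype=float)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            yield names[i], names[j], arr[i, j]


def _edges_frame(rows: list[tuple]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=_EDGE_COLUMNS)


def _z_frame(matrix) -> pd.DataFrame:
    return matrix.z if isinstance(matrix, AssociationMatrix) else matrix


def build_znet(
    matrix: AssociationMatrix | pd.DataFrame,
    mode: str = "abs_cutoff",
    threshold: float = 2.0,
) -> SetNetwork:
    """Signed Z-score network.

    ``abs_cutoff`` keeps pairs with ``Z >= +threshold`` (enriched) or
    ``Z <= -threshold`` (suppressed).  ``top_fraction`` keeps the top
    ``threshold`` quantile of off-diagonal Z values as enriched and the
    bottom quantile as suppressed; quantile ties are all included, so the
    edge count may slightly exceed the nominal fraction (deterministic,
    seed-free tie rule).  NA statistics never form edges; the diagonal is
    always excluded; isolated nodes are retained.
    """
    zmat = _z_frame(matrix)
    names = tuple(zmat.index)
    pairs = [(a, b, z) for a, b, z in _upper_pairs(zmat) if not np.isnan(z)]
    if not pairs:
        vals_all = zmat.to_numpy(dtype=float)
        iu = np.triu_indices(len(names), k=1)
        if np.all(np.isnan(vals_all[iu])):
            raise ValueError("all-NA Z matrix")
    if mode == "abs_cutoff":
        hi, lo = threshold, -threshold
        meta = {"mode": mode, "threshold": threshold}
    elif mode == "top_fraction":
        if not 0 < threshold < 1:
            raise ValueError("top_fraction threshold must be in (0, 1)")
        vals = np.array([z for _, _, z in pairs])
        hi = float(np.quantile(vals, 1 - threshold))
        lo = float(np.quantile(vals, threshold))
        meta = {"mode": mode, "fraction": threshold, "z_hi": hi, "z_lo": lo}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for a, b, z in pairs:
        if z >= hi:
            rows.append((a, b, z, "enriched"))
        elif z <= lo:
            rows.append((a, b, z, "suppressed"))
    return SetNetwork(nodes=names, edges=_edges_frame(rows), statistic="z", cutoff=meta)


def build_pnet(
    matrix: AssociationMatrix | pd.DataFrame,
    alpha: float = 1e-4,
    p_floor: pd.DataFrame | None = None,
) -> SetNetwork:
    """Uniform-weight network of pairs with empirical ``p < alpha``.

    Floored p-values (no null model reached the observation) always pass —
    they are below any resolvable alpha.  The comparison is strict, so
    ``p == alpha`` is excluded.
    """
    if isinstance(matrix, AssociationMatrix):
        pmat, floor = matrix.p, matrix.p_floor
    else:
        pmat = matrix
        floor = (
            p_floor
            if p_floor is not None
            else pd.DataFrame(False, index=pmat.index, columns=pmat.columns)
        )
    names = tuple(pmat.index)
    rows = []
    for a, b, p in _upper_pairs(pmat):
        if bool(floor.loc[a, b]) or (not np.isnan(p) and p < alpha):
            rows.append((a, b, 1.0, "enriched"))
    return SetNetwork(
        nodes=names,
        edges=_edges_frame(rows),
        statistic="p",
        cutoff={"alpha": alpha},
    )


def build_jnet(
    matrix: AssociationMatrix | pd.DataFrame, min_j: float = 0.0
) -> SetNetwork:
    """Jaccard overlap network: edges where ``J > min_j``, weight ``J``.

    The default ``min_j = 0`` connects any two sets sharing at least one
    gene.
    """
    jmat = matrix.jaccard if isinstance(matrix, AssociationMatrix) else matrix
    names = tuple(jmat.index)
    rows = [
        (a, b, j, "enriched")
        for a, b, j in _upper_pairs(jmat)
        if not np.isnan(j) and j > min_j
    ]
    return SetNetwork(
        nodes=names,
        edges=_edges_frame(rows),
        statistic="jaccard",
        cutoff={"min_j": min_j},
    )
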