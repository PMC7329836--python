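"""Permutation association statistics between gene sets on a network.

The observed number of interactions between two gene sets A and B,
``E_pin``, is compared with the distribution of the same count over an
ensemble of degree-preserving null networks:

    Z  = (E_pin - mean(E_null)) / sd(E_null)
    Z' = (E_pin - median(E_null)) / IQR(E_null)

with a one-tailed empirical p-value ``p = n / n_models`` where ``n`` is the
number of null models whose count reaches the observation (ties count
toward the null).  When no null model reaches it, only ``p < 1/n_models``
can be inferred: the p-value is floored, never reported as zero.  The
membership-only Jaccard index ``|A ∩ B| / |A ∪ B|`` is reported alongside
as a topology-blind baseline.

A positive Z means the two sets interact more than degree structure alone
explains (enriched association); a negative Z means they avoid each other
(suppressed association).

The model/results surface follows the statsmodels convention:
:class:`GeneSetAssociation` is constructed from data and ``fit()`` returns
an :class:`AssociationResult` with the estimates, null summary and a
``summary()`` table.  Functional wrappers (:func:`associate`,
:func:`associate_all_pairs`) cover script use.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .graph_core import (
    EmptySetError,
    FilterReport,
    GeneSet,
    GeneSetCollection,
    Network,
    restrict_to_network,
)
from .ms02 import MS02Config, normality_check, null_edge_arrays

__all__ = [
    "AssociationResult",
    "AssociationMatrix",
    "GeneSetAssociation",
    "count_between",
    "compute_z",
    "compute_zprime",
    "compute_p",
    "compute_jaccard",
    "z_score",
    "zprime_score",
    "normal_equivalent_z",
    "normal_tail_probability",
    "associate",
    "associate_all_pairs",
    "adjust_fdr",
]


# -- elementary statistics -------------------------------------------------


def n_unique_pairs(n_sets: int, include_self: bool = False) -> int:
    """Number of unique non-self pairs in an ``n_sets`` collection."""
    pairs = n_sets * (n_sets - 1) // 2
    return pairs + n_sets if include_self else pairs


def z_score(e_pin: float, null_mean: float, null_sd: float) -> float:
    """Association Z from an observed count and null mean/sd.

    Returns NaN (undefined, not an error) when the null sd is zero.
    """
    if null_sd == 0:
        return float("nan")
    return (e_pin - null_mean) / null_sd


def zprime_score(e_pin: float, null_median: float, null_iqr: float) -> float:
    """Robust Z' from an observed count and null median/IQR.

    Returns NaN when the IQR is zero (a known pathology for sparsely
    interacting sets, where a finite value would be misleading).
    """
    if null_iqr == 0:
        return float("nan")
    return (e_pin - null_median) / null_iqr


def compute_z(e_pin: int, null_counts: np.ndarray) -> float:
    """Z against an ensemble count vector; sample sd (ddof=1)."""
    counts = np.asarray(null_counts, dtype=float)
    if len(counts) < 2:
        raise ValueError("need at least 2 null counts")
    return z_score(float(e_pin), float(counts.mean()), float(counts.std(ddof=1)))


def compute_zprime(e_pin: int, null_counts: np.ndarray) -> float:
    """Z' against an ensemble count vector; type-7 (linear) quantiles."""
    counts = np.asarray(null_counts, dtype=float)
    if len(counts) < 4:
        raise ValueError("need at least 4 null counts")
    q1, med, q3 = np.percentile(counts, [25, 50, 75])
    return zprime_score(float(e_pin), float(med), float(q3 - q1))


def compute_p(
    e_pin: int, null_counts: np.ndarray, strict: bool = False
) -> tuple[float, bool]:
    """One-tailed empirical p-value for an enriched association.

    ``p = n / n_models`` with ``n`` the number of null models whose count is
    ``>= e_pin`` (ties count toward the null; pass ``strict=True`` for the
    ``>`` variant).  Returns ``(nan, True)`` when ``n == 0``: the p-value is
    then only bounded above by ``1/n_models``.
    """
    counts = np.asarray(null_counts)
    if len(counts) == 0:
        raise ValueError("empty null count vector")
    n = int(np.sum(counts > e_pin) if strict else np.sum(counts >= e_pin))
    if n == 0:
        return float("nan"), True
    return n / len(counts), False


def compute_jaccard(a: GeneSet | frozenset, b: GeneSet | frozenset) -> float:
    """Jaccard index |A ∩ B| / |A ∪ B| on the raw (unrestricted) sets."""
    ga = a.genes if isinstance(a, GeneSet) else frozenset(a)
    gb = b.genes if isinstance(b, GeneSet) else frozenset(b)
    union = ga | gb
    if not union:
        raise ValueError("both gene sets are empty")
    return len(ga & gb) / len(union)


def normal_equivalent_z(p: float) -> float:
    """One-tailed standard-normal quantile for a p-value (e.g. 1e-4 -> 3.72)."""
    return float(scipy.stats.norm.isf(p))


def normal_tail_probability(z: float) -> float:
    """One-tailed standard-normal tail probability (e.g. Z=2 -> 0.023)."""
    return float(scipy.stats.norm.sf(z))


def adjust_fdr(p_values: np.ndarray, floor_value: float | None = None) -> np.ndarray:
    """Benjamini–Hochberg q-values.

    NaN entries (floored empirical p-values) must be substituted first;
    ``floor_value`` does that in one step when given.
    """
    p = np.asarray(p_values, dtype=float).copy()
    if floor_value is not None:
        p[np.isnan(p)] = floor_value
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-values; supply floor_value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# -- edge counting ---------------------------------------------------------


def count_between(net: Network, a: GeneSet, b: GeneSet) -> int:
    """Number of network edges joining set A and set B.

    An edge ``{u, v}`` counts once when one endpoint lies in A and the
    other in B (in either orientation); an edge with both endpoints in
    ``A ∩ B`` therefore also counts exactly once.  With ``a is b`` this is
    the number of edges inside the set.
    """
    return _count_between_masks(
        net.edge_array, net.membership(a.genes), net.membership(b.genes)
    )


def _count_between_masks(edges: np.ndarray, am: np.ndarray, bm: np.ndarray) -> int:
    if not len(edges):
        return 0
    u, v = edges[:, 0], edges[:, 1]
    hit = (am[u] & bm[v]) | (bm[u] & am[v])
    return int(hit.sum())


def _pair_count_matrix(edges: np.ndarray, memb: np.ndarray) -> np.ndarray:
    """Between-set edge counts for every pair of sets at once.

    ``memb`` is a (n_nodes, n_sets) boolean membership matrix.  Returns the
    symmetric (n_sets, n_sets) integer matrix whose (a, b) entry counts each
    qualifying edge once — including edges inside the overlap, corrected so
    they are not double-counted — and whose diagonal counts within-set
    edges.
    """
    u, v = edges[:, 0], edges[:, 1]
    mu = memb[u].astype(np.int64)
    mv = memb[v].astype(np.int64)
    c = mu.T @ mv
    both = (memb[u] & memb[v]).astype(np.int64)
    overlap = both.T @ both
    return c + c.T - overlap


# -- results objects -------------------------------------------------------


@dataclass
class AssociationResult:
    """Fitted association between two gene sets.

    Carries the observed count, the null-ensemble summary, the Z, Z' and
    empirical-p estimates with their degeneracy flags, and the restriction
    bookkeeping for both sets.
    """

    set_a: str
    set_b: str
    e_pin: int
    null_mean: float
    null_sd: float
    null_median: float
    null_iqr: float
    z: float
    zprime: float
    p: float
    p_floor: bool
    jaccard: float
    n_models: int
    filter_a: FilterReport | None = None
    filter_b: FilterReport | None = None
    null_counts: np.ndarray | None = None

    @property
    def z_undefined(self) -> bool:
        return math.isnan(self.z)

    @property
    def zprime_undefined(self) -> bool:
        return math.isnan(self.zprime)

    @property
    def p_display(self) -> str:
        if self.p_floor:
            return f"< {1.0 / self.n_models:g}"
        return f"{self.p:g}"

    def p_for_fdr(self, floor_value: float | None = None) -> float:
        """Numeric p with the floor substituted (default ``1/n_models``)."""
        if self.p_floor:
            return floor_value if floor_value is not None else 1.0 / self.n_models
        return self.p

    def neg_log10_p(self, floor_substitute: float = 1e-5) -> float:
        """-log10 p with floored values substituted (default 1e-5, i.e. 5)."""
        p = floor_substitute if self.p_floor else self.p
        return -math.log10(p)

    def normality(self):
        if self.null_counts is None:
            raise ValueError("null counts were not retained")
        return normality_check(self.null_counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "set_a": self.set_a,
                    "set_b": self.set_b,
                    "e_pin": self.e_pin,
                    "null_mean": self.null_mean,
                    "null_sd": self.null_sd,
                    "null_median": self.null_median,
                    "null_iqr": self.null_iqr,
                    "z": self.z,
                    "zprime": self.zprime,
                    "p": self.p,
                    "p_floor": self.p_floor,
                    "jaccard": self.jaccard,
                    "n_models": self.n_models,
                }
            ]
        )

    def summary(self, round_z: int | None = None) -> str:
        def fmt(x: float) -> str:
            if math.isnan(x):
                return "NA (degenerate null)"
            return f"{x:.{round_z}f}" if round_z is not None else f"{x:.6g}"

        lines = [
            "Gene-set association (degree-preserving permutation test)",
            "=" * 58,
            f"set A: {self.set_a}    set B: {self.set_b}",
            f"observed inter-set edges E_pin : {self.e_pin}",
            f"null models                    : {self.n_models}",
            f"null mean ± sd                 : {self.null_mean:.4g} ± {self.null_sd:.4g}",
            f"null median (IQR)              : {self.null_median:.4g} ({self.null_iqr:.4g})",
            f"Z-score                        : {fmt(self.z)}",
            f"Z'-score                       : {fmt(self.zprime)}",
            f"empirical one-tailed p         : {self.p_display}",
            f"Jaccard index                  : {self.jaccard:.4g}",
        ]
        for rep in (self.filter_a, self.filter_b):
            if rep is not None and rep.dropped:
                lines.append(
                    f"note: {rep.name}: {len(rep.dropped)}/{rep.n_input} genes "
                    "absent from the network"
                )
        return "\n".join(lines)


@dataclass
class AssociationMatrix:
    """All-pairs association statistics over a gene-set collection.

    Symmetric DataFrames indexed by set name; the diagonal holds
    self-associations (edges inside each set).  Floored p-values are NaN in
    ``p`` with the corresponding ``p_floor`` entry set.
    """

    names: tuple[str, ...]
    e_pin: pd.DataFrame
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    z: pd.DataFrame
    zprime: pd.DataFrame
    p: pd.DataFrame
    p_floor: pd.DataFrame
    jaccard: pd.DataFrame
    n_models: int
    filter_reports: dict[str, FilterReport] = field(default_factory=dict)

    def statistic(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def n_unique_pairs(self, include_self: bool = False) -> int:
        n = len(self.names)
        pairs = n * (n - 1) // 2
        return pairs + n if include_self else pairs

    def offdiag_values(self, stat: str = "z") -> np.ndarray:
        """Upper-triangle (non-self) values of a statistic, NaN dropped."""
        mat = self.statistic(stat).to_numpy(dtype=float)
        iu = np.triu_indices(len(self.names), k=1)
        vals = mat[iu]
        return vals[~np.isnan(vals)]

    def to_tsv(self, directory: str | Path, prefix: str = "assoc") -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for stat in ("e_pin", "z", "zprime", "p", "p_floor", "jaccard"):
            path = directory / f"{prefix}_{stat}.tsv"
            self.statistic(stat).to_csv(path, sep="\t", na_rep="NA")
            written.append(path)
        return written


# -- model classes ---------------------------------------------------------


def _null_summary(counts: np.ndarray) -> tuple[float, float, float, float]:
    q1, med, q3 = np.percentile(counts.astype(float), [25, 50, 75])
    return (
        float(counts.mean()),
        float(counts.std(ddof=1)) if len(counts) > 1 else 0.0,
        float(med),
        float(q3 - q1),
    )


class GeneSetAssociation:
    """Permutation association model for one pair of gene sets.

    Parameters
    ----------
    network
        The empirical interaction network.
    set_a, set_b
        Raw gene sets; they are restricted to the network's nodes on
        construction (Jaccard always uses the raw memberships).

    ``fit`` generates the null ensemble and returns an
    :class:`AssociationResult`.
    """

    def __init__(self, network: Network, set_a: GeneSet, set_b: GeneSet):
        self.network = network
        self.raw_a, self.raw_b = set_a, set_b
        self.set_a, self.filter_a = restrict_to_network(set_a, network)
        self.set_b, self.filter_b = restrict_to_network(set_b, network)
        for gs in (self.set_a, self.set_b):
            if not gs.genes:
                raise EmptySetError(
                    f"gene set {gs.name!r} has no members in the network"
                )

    @classmethod
    def from_files(cls, network_path, set_a_path, set_b_path) -> "GeneSetAssociation":
        from .graph_core import load_network, read_gene_list

        return cls(
            load_network(network_path),
            read_gene_list(set_a_path),
            read_gene_list(set_b_path),
        )

    def observed_count(self) -> int:
        return count_between(self.network, self.set_a, self.set_b)

    def fit(
        self,
        config: MS02Config | None = None,
        *,
        seed: int | None = None,
        n_models: int = 10_000,
        swap_multiplier: float = 10.0,
        keep_null_counts: bool = True,
    ) -> AssociationResult:
        if config is None:
            if seed is None:
                raise ValueError("a seed (or an MS02Config) is required")
            config = MS02Config(
                seed=seed, n_models=n_models, swap_multiplier=swap_multiplier
            )
        if config.n_models < 2:
            raise ValueError("association needs n_models >= 2")
        am = self.network.membership(self.set_a.genes)
        bm = self.network.membership(self.set_b.genes)
        e_pin = _count_between_masks(self.network.edge_array, am, bm)
        counts = np.empty(config.n_models, dtype=np.int64)
        for i, edges in enumerate(null_edge_arrays(self.network, config)):
            counts[i] = _count_between_masks(edges, am, bm)
        return self._result_from_counts(e_pin, counts, config, keep_null_counts)

    def _result_from_counts(
        self, e_pin, counts, config, keep_null_counts
    ) -> AssociationResult:
        mean, sd, med, iqr = _null_summary(counts)
        if sd == 0:
            warnings.warn(
                f"degenerate null (sd = 0) for pair "
                f"({self.set_a.name}, {self.set_b.name}); Z undefined"
            )
        p, floor = compute_p(e_pin, counts)
        return AssociationResult(
            set_a=self.set_a.name,
            set_b=self.set_b.name,
            e_pin=int(e_pin),
            null_mean=mean,
            null_sd=sd,
            null_median=med,
            null_iqr=iqr,
            z=z_score(e_pin, mean, sd),
            zprime=zprime_score(e_pin, med, iqr),
            p=p,
            p_floor=floor,
            jaccard=compute_jaccard(self.raw_a, self.raw_b),
            n_models=config.n_models,
            filter_a=self.filter_a,
            filter_b=self.filter_b,
            null_counts=counts if keep_null_counts else None,
        )


def associate(
    net: Network, a: GeneSet, b: GeneSet, config: MS02Config
) -> AssociationResult:
    """One-pair association with its own null ensemble."""
    return GeneSetAssociation(net, a, b).fit(config)


def associate_all_pairs(
    net: Network,
    coll: GeneSetCollection,
    config: MS02Config,
    include_self: bool = True,
) -> AssociationMatrix:
    """All-pairs association matrices over a collection.

    One *shared* null ensemble is used: each null model is generated once
    and the between-set counts for every pair are taken on it.  Per-pair
    statistics are unaffected marginally; counts are correlated across
    pairs (documented trade-off that makes large collections tractable).
    Sets with no member in the network are dropped with a warning.
    """
    usable: list[GeneSet] = []
    reports: dict[str, FilterReport] = {}
    raw: dict[str, GeneSet] = {}
    for gs in coll:
        restricted, rep = restrict_to_network(gs, net)
        reports[gs.name] = rep
        if restricted.genes:
            usable.append(restricted)
            raw[gs.name] = gs
        else:
            warnings.warn(f"dropping set {gs.name!r}: no members in network")
    if len(usable) < 2:
        raise EmptySetError("fewer than 2 usable gene sets")
    names = tuple(gs.name for gs in usable)
    s = len(names)
    memb = np.zeros((net.n_nodes, s), dtype=bool)
    for j, gs in enumerate(usable):
        memb[:, j] = net.membership(gs.genes)

    observed = _pair_count_matrix(net.edge_array, memb)
    null_stack = np.empty((config.n_models, s, s), dtype=np.int32)
    for i, edges in enumerate(null_edge_arrays(net, config)):
        null_stack[i] = _pair_count_matrix(edges, memb)

    mean = null_stack.mean(axis=0)
    sd = null_stack.std(axis=0, ddof=1)
    q1, med, q3 = np.percentile(null_stack.astype(float), [25, 50, 75], axis=0)
    iqr = q3 - q1
    with np.errstate(divide="ignore", invalid="ignore"):
        zmat = np.where(sd > 0, (observed - mean) / sd, np.nan)
        zpmat = np.where(iqr > 0, (observed - med) / iqr, np.nan)
    ge = (null_stack >= observed[None, :, :]).sum(axis=0)
    floor = ge == 0
    pmat = np.where(floor, np.nan, ge / config.n_models)

    jac = np.empty((s, s))
    for i in range(s):
        for j in range(i, s):
            jac[i, j] = jac[j, i] = compute_jaccard(raw[names[i]], raw[names[j]])

    if not include_self:
        for arr in (zmat, zpmat, pmat):
            np.fill_diagonal(arr, np.nan)

    def df(arr, dtype=None):
        frame = pd.DataFrame(arr, index=list(names), columns=list(names))
        return frame.astype(dtype) if dtype else frame

    return AssociationMatrix(
        names=names,
        e_pin=df(observed),
        null_mean=df(mean),
        null_sd=df(sd),
        z=df(zmat),
        zprime=df(zpmat),
        p=df(pmat),
        p_floor=df(floor, dtype=bool),
        jaccard=df(jac),
        n_models=config.n_models,
        filter_reports=reports,
    )
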