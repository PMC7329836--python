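"""Functional-term enrichment by network permutation.

A GO term or pathway is just a gene set; the association Z-score of a
target set against every term in a collection, ranked, yields an
enrichment analysis driven by *interactions* rather than membership
overlap: a term is enriched when the target's genes interact with the
term's genes far more than degree-preserving null networks allow, and
suppressed when far less.  One shared null ensemble serves every term
(re-randomizing per term is needless for the marginal per-term statistics
and intractable for genome-scale term collections).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .association import (
    adjust_fdr,
    compute_jaccard,
    z_score,
    zprime_score,
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
    "EnrichmentTable",
    "GeneSetEnrichment",
    "enrich",
    "top_terms",
    "compare_tables",
]


@dataclass
class EnrichmentTable:
    """Ranked per-term association results for one target set.

    ``table`` columns: term, term_size, restricted_size, overlap, e_pin,
    null_mean, null_sd, z, zprime, p, p_floor, q, rank.  Sorted by Z
    descending (NA last), ties broken by term name; ``rank`` is 1-based.
    """

    target: str
    table: pd.DataFrame
    n_models: int
    skipped_terms: tuple[str, ...] = ()
    min_term_size: int = 3

    @property
    def n_terms(self) -> int:
        return len(self.table)

    def top_terms(self, k: int, direction: str = "enriched") -> pd.DataFrame:
        """Top-k terms by Z: descending for enriched, ascending for suppressed."""
        if k < 1:
            raise ValueError("k must be >= 1")
        tab = self.table.dropna(subset=["z"])
        ascending = {"enriched": False, "suppressed": True}[direction]
        tab = tab.sort_values(["z", "term"], ascending=[ascending, True])
        return tab.head(k).reset_index(drop=True)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")

    def summary(self, k: int = 10) -> str:
        top = self.top_terms(min(k, max(self.n_terms, 1)))
        lines = [
            f"Network-permutation enrichment of {self.target!r}",
            f"{self.n_terms} terms scored against {self.n_models} null models"
            f" ({len(self.skipped_terms)} skipped below size {self.min_term_size})",
            "",
            top[["rank", "term", "e_pin", "null_mean", "z", "p", "q"]].to_string(
                index=False
            ),
        ]
        return "\n".join(lines)


class GeneSetEnrichment:
    """Enrichment model: one target set against a term collection.

    Terms whose network-restricted size falls below ``min_term_size`` are
    skipped (tiny terms are the main source of degenerate IQR = 0 nulls);
    set it to 1 to score every term.  ``fit`` runs the shared-ensemble
    permutation test and returns an :class:`EnrichmentTable`.
    """

    def __init__(
        self,
        network: Network,
        target: GeneSet,
        terms: GeneSetCollection,
        min_term_size: int = 3,
    ):
        self.network = network
        self.raw_target = target
        self.target, self.filter_target = restrict_to_network(target, network)
        if not self.target.genes:
            raise EmptySetError(
                f"target set {target.name!r} has no members in the network"
            )
        self.min_term_size = min_term_size
        self.terms = terms
        self._kept: list[GeneSet] = []
        self._raw_sizes: dict[str, int] = {}
        skipped = []
        for gs in terms:
            restricted, _ = restrict_to_network(gs, network)
            if len(restricted) >= min_term_size:
                self._kept.append(restricted)
                self._raw_sizes[gs.name] = len(gs)
            else:
                skipped.append(gs.name)
        self.skipped_terms = tuple(skipped)
        if not self._kept:
            raise EmptySetError("no terms left after size filtering")

    def fit(self, config: MS02Config) -> EnrichmentTable:
        net = self.network
        tmask = net.membership(self.target.genes)
        # sort terms by name for a deterministic compute order
        kept = sorted(self._kept, key=lambda gs: gs.name)
        names = [gs.name for gs in kept]
        memb = np.zeros((net.n_nodes, len(kept)), dtype=bool)
        for j, gs in enumerate(kept):
            memb[:, j] = net.membership(gs.genes)

        def counts_on(edges: np.ndarray) -> np.ndarray:
            u, v = edges[:, 0], edges[:, 1]
            a_u, a_v = tmask[u], tmask[v]
            c = a_u.astype(np.int64) @ memb[v] + a_v.astype(np.int64) @ memb[u]
            # edges inside target ∩ term are hit by both orientations: count once
            both = a_u & a_v
            dup = both.astype(np.int64) @ (memb[u] & memb[v])
            return c - dup

        observed = counts_on(net.edge_array)
        null = np.empty((config.n_models, len(kept)), dtype=np.int32)
        for i, edges in enumerate(null_edge_arrays(net, config)):
            null[i] = counts_on(edges)

        mean = null.mean(axis=0)
        sd = null.std(axis=0, ddof=1)
        q1, med, q3 = np.percentile(null.astype(float), [25, 50, 75], axis=0)
        iqr = q3 - q1
        ge = (null >= observed[None, :]).sum(axis=0)
        floor = ge == 0
        p = np.where(floor, np.nan, ge / config.n_models)
        q = adjust_fdr(p, floor_value=1.0 / config.n_models)

        rows = []
        for j, gs in enumerate(kept):
            rows.append(
                {
                    "term": gs.name,
                    "term_size": self._raw_sizes[gs.name],
                    "restricted_size": len(gs),
                    "overlap": len(gs.genes & self.target.genes),
                    "e_pin": int(observed[j]),
                    "null_mean": mean[j],
                    "null_sd": sd[j],
                    "z": z_score(observed[j], mean[j], sd[j]),
                    "zprime": zprime_score(observed[j], med[j], iqr[j]),
                    "p": p[j],
                    "p_floor": bool(floor[j]),
                    "q": q[j],
                }
            )
        tab = pd.DataFrame(rows)
        # Z descending, NA last, term-name tie-break
        tab = tab.sort_values(
            ["z", "term"], ascending=[False, True], na_position="last"
        ).reset_index(drop=True)
        tab["rank"] = np.arange(1, len(tab) + 1)
        n_degen = int(tab["zprime"].isna().sum())
        if n_degen:
            warnings.warn(f"{n_degen} term(s) with degenerate (IQR = 0) null")
        return EnrichmentTable(
            target=self.target.name,
            table=tab,
            n_models=config.n_models,
            skipped_terms=self.skipped_terms,
            min_term_size=self.min_term_size,
        )


def enrich(
    net: Network,
    target: GeneSet,
    terms: GeneSetCollection,
    config: MS02Config,
    min_term_size: int = 3,
) -> EnrichmentTable:
    """Functional wrapper around :class:`GeneSetEnrichment`."""
    return GeneSetEnrichment(net, target, terms, min_term_size=min_term_size).fit(
        config
    )


def top_terms(table: EnrichmentTable, k: int, direction: str = "enriched"):
    return table.top_terms(k, direction=direction)


def compare_tables(a, b, c=None) -> dict:
    """Overlap summary of two or three ranked term lists.

    Accepts iterables of term names (or EnrichmentTable top rows).  Returns
    counts and identities of shared/unique terms; with three lists, the
    seven Venn regions.
    """

    def as_set(x) -> set[str]:
        if isinstance(x, pd.DataFrame):
            return set(x["term"])
        return set(x)

    sa, sb = as_set(a), as_set(b)
    if c is None:
        return {
            "n_shared": len(sa & sb),
            "shared": sorted(sa & sb),
            "only_a": sorted(sa - sb),
            "only_b": sorted(sb - sa),
        }
    sc = as_set(c)
    return {
        "abc": sorted(sa & sb & sc),
        "ab_only": sorted((sa & sb) - sc),
        "ac_only": sorted((sa & sc) - sb),
        "bc_only": sorted((sb & sc) - sa),
        "a_only": sorted(sa - sb - sc),
        "b_only": sorted(sb - sa - sc),
        "c_only": sorted(sc - sa - sb),
        "counts": {
            "abc": len(sa & sb & sc),
            "ab": len(sa & sb),
            "ac": len(sa & sc),
            "bc": len(sb & sc),
            "a": len(sa),
            "b": len(sb),
            "c": len(sc),
        },
    }
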