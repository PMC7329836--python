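# Methods

## Model

`netpas` treats the interactome as a simple undirected graph
`G = (V, E)`: nodes are gene identifiers, edges are physical
interactions, no self-loops or multi-edges. For two gene sets `A`, `B`
(intersected with `V` before any counting), the observed statistic is
the between-set edge count `E_pin`: the number of edges with one
endpoint in `A` and the other in `B`, each edge counted once. An edge
whose endpoints both lie in `A ∩ B` connects a member of `A` to a member
of `B` and therefore counts exactly once as well; with `A = B` the
statistic is the number of edges inside the set. This convention is a
deliberate choice — alternatives (counting overlap edges twice, or
excluding them) are defensible but break the `A = B` special case.

The null distribution of `E_pin` comes from an ensemble of
degree-preserving randomizations: each null network keeps the node set
and the exact degree of every node. Degree preservation is the binding
assumption — interactomes are scale-free, and an Erdős–Rényi null would
attribute ordinary hub structure to biology. Higher-order features
(clustering, connectedness) are deliberately *not* preserved; their
divergence between data and ensemble is signal, not artefact (see the
isolated-pair diagnostic below).

From the ensemble counts `E_null`:

* `Z = (E_pin − mean)/sd`, sample sd (n−1). Undefined (reported `NA`
  with a reason, never ±inf) when `sd = 0`, e.g. when `A = B = V`.
* `Z' = (E_pin − median)/IQR`, robust to null outliers. IQR uses
  linear-interpolation (type-7) quantiles; on integer-valued counts at
  ensemble sizes of interest the common conventions agree. `IQR = 0`
  (typical for tiny term sets) again gives `NA`, not infinity.
* one-tailed empirical `p = #{E_null ≥ E_pin}/n_models`. Ties count
  toward the null (conservative); a strict-inequality variant is a flag.
  `#{} = 0` sets a floor flag: the value is reported as `< 1/n_models`
  and stored as `NA`, with `1/n_models` (or the conventional `1e-5`
  substitution for `−log10` displays) substituted only where arithmetic
  requires a number.
* Jaccard `J = |A ∩ B|/|A ∪ B|` is computed on the *raw* input sets,
  before network restriction — it is a membership statistic and should
  not silently change with the network.

The Z-score reads the null as approximately normal;
`normality_check` (Shapiro–Wilk, at most 5,000 values, deterministic
subsample) is attached as a diagnostic and never gates results.
Benjamini–Hochberg FDR (via statsmodels) converts p-values to q-values;
it is deterministic and assumption-light, which we prefer over
Storey-type estimators for ensembles this small.

## The MS02 sampler

Each null model is produced by double-edge swaps:
pick edges `{a,b}`, `{c,d}`, rewire to `{a,d}`, `{c,b}` (a random
orientation bit covers both pairings), reject any proposal creating a
self-loop or duplicate edge. The swap budget is `ceil(Q·|E|)` attempts
with `Q = 10` by default — at ~50% acceptance this gives every edge ~5
expected rewirings, comfortably past the empirical mixing point for the
sparse graphs this package targets; `Q` is exposed for users who want to
verify insensitivity. Each model is an *independent* chain started from
the original network (seeded `SeedSequence(master, model_index)`), so
ensembles are reproducible, parallelizable and free of inter-model
autocorrelation. Degree sequences admitting no legal swap (stars) are
returned unchanged with a "frozen" warning; the degenerate `sd = 0`
path then reports `Z = NA` downstream.

Edge-swap chains are known not to be perfectly uniform over the simple
graphs realizing a degree sequence. `realization_uniformity` quantifies
this on tiny instances (`|E| ≤ 8`) against brute-force enumeration; at
the instance sizes we test, sampled frequencies sit within 3 binomial
standard deviations of uniform, and any deviation is *reported*, not
silently accepted.

A cheap fingerprint of what degree preservation does **not** preserve:
the isolated-pair count, the number of edges joining two degree-1
nodes. Empirical interactomes have almost none (single-interaction
proteins attach to hubs); null ensembles have many. The package exposes
this as a per-model diagnostic.

## Ensembles shared across pairs

`associate_all_pairs` and `GeneSetEnrichment` generate each null model
once and take every pair/term count on it. Marginally, each pair's
statistics are identical to a dedicated ensemble; jointly, counts are
positively correlated across pairs, so joint statements ("326 pairs
passed the floor simultaneously") inherit that correlation. This is the
documented cost of making genome-scale term collections tractable —
re-randomizing per term multiplies runtime by the number of terms for no
marginal gain.

## Synthetic data

The fixture generator emulates the two features of real interactomes
the method is sensitive to: a heavy-tailed degree distribution
(Barabási–Albert preferential attachment, `attachment = 3` by default,
matching the sparse density of curated PINs) and an abundance of
degree-1 nodes attached preferentially to hubs (`n_pendant` extra
leaves). Gene sets are sampled uniformly from network nodes — the
natural universe here, since genes outside the network cannot
contribute edges. Planted signal adds a fixed surplus of edges drawn
uniformly over the free `A × B` node pairs; infeasible requests error
rather than truncate. Every generator is seed-deterministic and returns
exact ground-truth records (memberships, planted counts, isolated
pairs) for oracle tests.

What the fixtures do *not* emulate: the empirical size (~6 × 10⁵ edges),
the precise degree exponent, modular/community structure, and
tissue-specific wiring. Passing tests therefore demonstrate the
statistical machinery — degree preservation, calibration of the
background tails, recovery of planted signal — not biological
conclusions about any real interactome.

Random-set calibration defaults mirror the benchmark design: groups of
50 sets with sizes fixed (15, 50, 100, 200) or uniform on [15, 200],
giving 1,225 unique non-self pairs per group. The affiliation bootstrap
pools `A ∪ B` once per gene (overlapping genes land on one side — the
reference construction uses disjoint 100+100 sets, where this is moot)
and re-partitions into the original sizes, recomputing Z against the
same shared ensemble.

## Problem sizes used in the test suite

The suite runs at desk scale, chosen once as representative: the
ensemble-contract and isolated-pair checks use 1,200-node fixtures with
300–400 pendant leaves (100–250 models); background calibration uses a
2,000-node fixture, 50 random sets on [15, 200] and 1,000 null models;
the bootstrap uses a 1,000-node fixture, a 100+100 no-signal pair,
300 models and 1,000 re-partitions; planted-signal recovery uses ten
independent 300-node fixtures. Full-scale runs (10,000 models — chosen
as the default because it sets the p-value floor at 1e-4) go through
the same code paths with only `n_models` changed.

## Cutoffs and interpretation

* `|Z| > 2` for a single association test: on random gene sets the
  combined background tail beyond ±2 is a few percent, and a
  no-signal affiliation bootstrap keeps `|Z| > 2` below 5%.
* Z-score networks: either an absolute cutoff (edges at `Z ≥ +t` /
  `Z ≤ −t`) or per-sign top-fraction quantiles of the off-diagonal
  upper triangle; quantile ties are all retained (deterministic,
  seed-free), so edge counts may slightly exceed the nominal fraction.
* p-value networks use strict `p < α` with floored entries always
  passing; Jaccard networks use `J > j₀`, where `j₀ = 0` reproduces the
  classic "share at least one gene" disease-network rule.
* Enrichment tables rank by Z descending (NA last, term-name
  tie-break); suppressed terms are read from the same Z vector with the
  sign flipped — no separate lower-tail empirical p is computed.
  `min_term_size = 3` (restricted size) by default, because tiny terms
  are the dominant source of `IQR = 0` degeneracies; set 1 to score
  every term.

## Numerical and degenerate-input choices

* All undefined statistics are `NA` plus a machine-readable flag —
  never infinities, never exceptions, except where the input itself is
  unusable (a set with no network members raises explicitly).
* Gene identifiers are opaque case-sensitive strings; no aliasing.
* Edge lists: `#` comments tolerated, extra columns ignored, an
  optional single header line is skipped via an explicit flag;
  self-loops dropped and duplicates collapsed with a logged count.
  Nodes appearing only in dropped self-loops are omitted unless
  `keep_isolated` is set — degree-0 nodes are invisible to both the
  permutation and the counting.
* Any interaction-confidence scores in extra edge-list columns are
  ignored: every listed pair is an edge.

## Known limitations

* Edge-swap sampling is only approximately uniform; deviations are
  flagged by the small-instance diagnostic but not corrected (no
  stub-matching/configuration-model sampler in this version).
* The empirical p-value resolution is `1/n_models`; ranking within the
  floored set requires the Z-score.
* Shared ensembles correlate statistics across pairs (above).
* One-tailed only: enrichment and suppression are read from opposite
  tails of Z, not from a two-sided test.
* No GO DAG propagation — terms are flat gene sets; no identifier
  translation; results inherit the incompleteness of whatever
  interactome and annotations the user supplies.
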