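"""Association statistics: worked examples, oracles, matrix consistency."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netpas import (
    EmptySetError,
    GeneSet,
    GeneSetCollection,
    GeneSetAssociation,
    MS02Config,
    Network,
    adjust_fdr,
    associate,
    associate_all_pairs,
    compute_jaccard,
    compute_p,
    compute_z,
    compute_zprime,
    count_between,
    z_score,
    zprime_score,
)
from netpas.association import n_unique_pairs


class TestElementaryScores:
    def test_worked_z_example(self):
        # observed 51 vs null 25.4 ± 4.8 over 10,000 models
        assert round(z_score(51, 25.4, 4.8), 1) == 5.3

    def test_worked_zprime_example(self):
        assert round(zprime_score(51, 25, 6), 1) == 4.3

    def test_hallmark_pair_z(self):
        assert round(z_score(344, 204.5, 13.5), 1) == 10.3

    def test_z_at_null_mean_is_zero(self):
        counts = np.array([3, 4, 5, 6])
        assert compute_z(float(counts.mean()), counts) == 0.0

    def test_zprime_at_median_is_zero(self):
        counts = np.array([1, 2, 3, 4, 5])
        assert compute_zprime(3, counts) == 0.0

    def test_degenerate_null_gives_nan_not_error(self):
        constant = np.full(10, 5)
        assert math.isnan(compute_z(7, constant))
        assert math.isnan(compute_zprime(7, constant))

    def test_sample_sd_convention(self):
        counts = np.array([1, 2, 3, 4])
        expected = (5 - counts.mean()) / counts.std(ddof=1)
        assert compute_z(5, counts) == pytest.approx(expected)

    @given(
        st.lists(st.integers(0, 50), min_size=4, max_size=60),
        st.integers(0, 60),
        st.integers(0, 60),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_observed_count(self, counts, e1, e2):
        counts = np.array(counts)
        lo, hi = min(e1, e2), max(e1, e2)
        z_lo, z_hi = compute_z(lo, counts), compute_z(hi, counts)
        if not (math.isnan(z_lo) or math.isnan(z_hi)):
            assert z_lo <= z_hi
        # a floored p is below any resolvable value: substitute 1/(2n)
        def as_value(p, floor):
            return 0.5 / len(counts) if floor else p

        assert as_value(*compute_p(lo, counts)) >= as_value(*compute_p(hi, counts))


class TestEmpiricalP:
    def test_direct_count(self):
        p, floor = compute_p(3, np.array([1, 2, 3, 4]))
        assert (p, floor) == (0.5, False)

    def test_min_gives_one(self):
        counts = np.array([2, 3, 4, 5])
        assert compute_p(2, counts) == (1.0, False)

    def test_floor_flag(self):
        counts = np.arange(100)
        p, floor = compute_p(1000, counts)
        assert floor and math.isnan(p)

    def test_strict_variant(self):
        counts = np.array([1, 2, 3, 4])
        assert compute_p(3, counts, strict=True) == (0.25, False)


class TestJaccard:
    def test_venn_example(self):
        a = GeneSet("A", [f"a{i}" for i in range(23)] + ["s1", "s2", "s3"])
        b = GeneSet("B", [f"b{i}" for i in range(19)] + ["s1", "s2", "s3"])
        assert (len(a), len(b)) == (26, 22)
        assert compute_jaccard(a, b) == pytest.approx(3 / 45)
        assert round(compute_jaccard(a, b), 4) == 0.0667

    def test_identical_and_disjoint(self):
        a = GeneSet("A", ["x", "y"])
        assert compute_jaccard(a, a) == 1.0
        assert compute_jaccard(a, GeneSet("B", ["z"])) == 0.0

    def test_symmetric(self):
        a, b = GeneSet("A", ["x", "y"]), GeneSet("B", ["y", "z"])
        assert compute_jaccard(a, b) == compute_jaccard(b, a)

    def test_both_empty_error(self):
        with pytest.raises(ValueError):
            compute_jaccard(frozenset(), frozenset())


class TestCountBetween:
    def test_triangle(self, triangle_net):
        assert count_between(triangle_net, GeneSet("A", ["a"]),
                             GeneSet("B", ["b", "c"])) == 2

    def test_all_nodes_gives_edge_total(self, small_fixture):
        net, _, _ = small_fixture
        everything = GeneSet("all", net.labels)
        assert count_between(net, everything, everything) == net.n_edges

    def test_symmetry(self, small_fixture):
        net, coll, _ = small_fixture
        a, b = coll[coll.names[0]], coll[coll.names[1]]
        assert count_between(net, a, b) == count_between(net, b, a)

    def test_overlap_edge_counted_once(self):
        net = Network.from_edge_labels([("x", "y"), ("y", "z")])
        a = GeneSet("A", ["x", "y"])
        b = GeneSet("B", ["x", "y", "z"])
        # edge {x,y} lies inside A ∩ B: counted once, plus {y,z}
        assert count_between(net, a, b) == 2
        shared = GeneSet("S", ["x", "y"])
        assert count_between(net, shared, shared) == 1

    def test_brute_force_oracle(self, small_fixture):
        net, _, _ = small_fixture
        rng = np.random.default_rng(99)
        labels = np.array(net.labels)
        edge_sets = [set(e) for e in net.edge_set()]
        for _ in range(10):
            a = set(rng.choice(labels, size=40, replace=False))
            b = set(rng.choice(labels, size=55, replace=False))
            brute = sum(
                1
                for e in edge_sets
                for (u, v) in [tuple(e)]
                if (u in a and v in b) or (u in b and v in a)
            )
            got = count_between(net, GeneSet("A", a), GeneSet("B", b))
            assert got == brute


class TestAssociationModel:
    def test_planted_block_recovered(self, planted_fixture, quick_config):
        net, coll, _ = planted_fixture
        res = associate(net, coll["set01"], coll["set02"], quick_config)
        assert res.z > 2
        assert res.p_floor or res.p < 0.05

    def test_result_fields_consistent(self, planted_fixture, quick_config):
        net, coll, _ = planted_fixture
        res = GeneSetAssociation(net, coll["set01"], coll["set03"]).fit(quick_config)
        assert res.n_models == quick_config.n_models
        assert len(res.null_counts) == quick_config.n_models
        assert res.null_mean == pytest.approx(res.null_counts.mean())
        assert res.e_pin >= 0 and res.null_sd >= 0
        assert 0 <= res.jaccard <= 1
        assert "Z-score" in res.summary()

    def test_full_node_set_degenerate(self, small_fixture, quick_config):
        net, _, _ = small_fixture
        everything = GeneSet("all", net.labels)
        with pytest.warns(UserWarning, match="degenerate"):
            res = associate(net, everything, everything, quick_config)
        assert res.z_undefined and res.zprime_undefined
        assert res.e_pin == net.n_edges

    def test_empty_restricted_set_refused(self, small_fixture, quick_config):
        net, _, _ = small_fixture
        ghost = GeneSet("ghost", ["nope1", "nope2"])
        with pytest.raises(EmptySetError):
            GeneSetAssociation(net, ghost, GeneSet("ok", [net.labels[0]]))

    def test_seed_determinism(self, planted_fixture):
        net, coll, _ = planted_fixture
        cfg = MS02Config(seed=55, n_models=50)
        r1 = associate(net, coll["set03"], coll["set04"], cfg)
        r2 = associate(net, coll["set03"], coll["set04"], cfg)
        assert np.array_equal(r1.null_counts, r2.null_counts)
        assert r1.z == r2.z

    def test_neg_log10_floor_substitution(self, planted_fixture, quick_config):
        net, coll, _ = planted_fixture
        res = associate(net, coll["set01"], coll["set02"], quick_config)
        if res.p_floor:
            assert res.neg_log10_p(1e-5) == pytest.approx(5.0)
            assert res.p_display.startswith("<")


class TestAllPairs:
    def test_pair_combinatorics(self):
        assert n_unique_pairs(50) == 1225
        assert n_unique_pairs(50, include_self=True) == 1275

    def test_matrices_symmetric_and_consistent(self, small_fixture, quick_config):
        net, coll, _ = small_fixture
        mat = associate_all_pairs(net, coll, quick_config)
        for stat in ("e_pin", "z", "jaccard", "p"):
            arr = mat.statistic(stat).to_numpy(dtype=float)
            assert np.allclose(arr, arr.T, equal_nan=True)
        assert np.all(np.diag(mat.jaccard.to_numpy()) == 1.0)
        assert mat.n_unique_pairs() == n_unique_pairs(len(mat.names))

    def test_duplicate_set_rows_identical(self, small_fixture, quick_config):
        net, coll, _ = small_fixture
        dup = GeneSetCollection(
            [coll["set01"], coll["set02"],
             GeneSet("set01_copy", coll["set01"].genes)]
        )
        mat = associate_all_pairs(net, dup, quick_config)
        z = mat.z
        pair_cols = ["set02"]
        assert z.loc["set01", pair_cols].equals(z.loc["set01_copy", pair_cols])
        assert mat.e_pin.loc["set01", "set02"] == mat.e_pin.loc["set01_copy", "set02"]

    def test_matches_single_pair_run_with_shared_seed(self, small_fixture):
        """The matrix entry must equal a one-pair fit computed on the same
        ensemble (same master seed => identical null models)."""
        net, coll, _ = small_fixture
        cfg = MS02Config(seed=77, n_models=60)
        mat = associate_all_pairs(net, coll, cfg)
        a, b = coll["set01"], coll["set02"]
        single = associate(net, a, b, cfg)
        assert single.e_pin == mat.e_pin.loc["set01", "set02"]
        assert single.z == pytest.approx(mat.z.loc["set01", "set02"])
        p_mat = mat.p.loc["set01", "set02"]
        if single.p_floor:
            assert bool(mat.p_floor.loc["set01", "set02"])
        else:
            assert single.p == pytest.approx(p_mat)

    def test_unusable_sets_dropped_with_warning(self, small_fixture, quick_config):
        net, coll, _ = small_fixture
        bad = GeneSetCollection(
            [coll["set01"], coll["set02"], GeneSet("ghost", ["nope"])]
        )
        with pytest.warns(UserWarning, match="ghost"):
            mat = associate_all_pairs(net, bad, quick_config)
        assert "ghost" not in mat.names
        assert mat.filter_reports["ghost"].n_in_network == 0


class TestNormalApproximation:
    def test_empirical_p_tracks_normal_tail_of_z(self, small_fixture):
        """On ensembles that pass the normality diagnostic, the empirical
        one-tailed p and the normal tail probability implied by Z agree
        within a factor of 3 for moderate p."""
        from netpas import GeneSetAssociation, normal_tail_probability

        net, coll, _ = small_fixture
        cfg = MS02Config(seed=314, n_models=400)
        checked = 0
        for i, name_a in enumerate(coll.names):
            for name_b in coll.names[i + 1:]:
                res = GeneSetAssociation(net, coll[name_a], coll[name_b]).fit(cfg)
                if res.p_floor or not (0.01 <= res.p <= 0.5) or res.z_undefined:
                    continue
                ratio = res.p / normal_tail_probability(res.z)
                assert 1 / 3 <= ratio <= 3
                checked += 1
        assert checked >= 3  # the fixture must actually exercise the range


class TestFdr:
    def test_all_equal_p_unchanged(self):
        p = np.array([0.2, 0.2, 0.2])
        assert np.allclose(adjust_fdr(p), p)

    def test_hand_bh_example(self):
        q = adjust_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert adjust_fdr(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_floor_substitution_and_validation(self):
        q = adjust_fdr(np.array([np.nan, 0.5]), floor_value=1e-4)
        assert q[0] == pytest.approx(2e-4)
        with pytest.raises(ValueError):
            adjust_fdr(np.array([np.nan, 0.5]))
        with pytest.raises(ValueError):
            adjust_fdr(np.array([1.5]))

    def test_monotone_in_p(self):
        rng = np.random.default_rng(0)
        p = np.sort(rng.uniform(size=30))
        q = adjust_fdr(p)
        assert np.all(np.diff(q) >= -1e-12)
        assert np.all((q >= 0) & (q <= 1))
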