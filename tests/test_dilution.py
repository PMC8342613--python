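"""Single-linkage dilution, silhouettes and representative selection."""

import numpy as np
import pytest

from acaritax.dilution import (
    dilute,
    dilute_series,
    select_representatives,
    silhouette_scores,
    single_linkage_clusters,
)
from acaritax.distances import DistanceMatrix, distance_matrix
from acaritax.simulate import SyntheticConfig, generate_library
from conftest import make_dm, make_library, make_record, oracle_clusters, oracle_silhouette


class TestSingleLinkage:
    def test_chaining_merges_distant_pair(self):
        D = make_dm(["s1", "s2", "s3"],
                    {("s1", "s2"): 0.03, ("s2", "s3"): 0.03, ("s1", "s3"): 0.08})
        part = single_linkage_clusters(D, 0.05)
        assert part.n_clusters == 1

    def test_tight_threshold_gives_singletons(self):
        D = make_dm(["s1", "s2", "s3"],
                    {("s1", "s2"): 0.03, ("s2", "s3"): 0.03, ("s1", "s3"): 0.08})
        part = single_linkage_clusters(D, 0.02)
        assert part.n_clusters == 3

    def test_boundary_distance_separates(self):
        # edge rule is strict <: a pair at exactly the threshold stays split
        D = make_dm(["a", "b"], {("a", "b"): 0.05})
        assert single_linkage_clusters(D, 0.05).n_clusters == 2

    def test_labels_contiguous_and_ordered_by_smallest_id(self):
        D = make_dm(["z", "a", "m"], {("z", "m"): 0.01})
        part = single_linkage_clusters(D, 0.05)
        # cluster containing "a" has the smallest member id -> label 1
        assert part.assignment["a"] == 1
        assert part.assignment["z"] == part.assignment["m"] == 2

    @pytest.mark.parametrize("threshold", [0.0, -0.1, 1.5])
    def test_threshold_domain(self, threshold):
        D = make_dm(["a", "b"], {("a", "b"): 0.1})
        with pytest.raises(ValueError):
            single_linkage_clusters(D, threshold)

    def test_matches_union_find_oracle(self, rng):
        n = 20
        ids = [f"s{i:02d}" for i in range(n)]
        d = rng.uniform(0, 0.3, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        D = DistanceMatrix(ids, d, np.full((n, n), 100, np.int64))
        for threshold in (0.02, 0.05, 0.10, 0.20):
            part = single_linkage_clusters(D, threshold)
            got = {frozenset(part.members(c)) for c in range(1, part.n_clusters + 1)}
            assert got == set(oracle_clusters(ids, d, threshold))

    def test_undefined_pairs_treated_as_far(self):
        d = np.array([[0.0, np.nan], [np.nan, 0.0]])
        D = DistanceMatrix(["a", "b"], d, np.array([[4, 0], [0, 4]]))
        with pytest.warns(UserWarning):
            part = single_linkage_clusters(D, 0.5)
        assert part.n_clusters == 2


class TestSilhouette:
    def test_hand_computed_example(self):
        D = make_dm(["a", "b", "c"],
                    {("a", "b"): 0.02, ("a", "c"): 0.2, ("b", "c"): 0.3})
        part = single_linkage_clusters(D, 0.05)  # {a,b} vs {c}
        s = silhouette_scores(D, part)
        assert s["a"] == pytest.approx((0.2 - 0.02) / 0.2)  # = 0.9
        assert s["c"] == 0.0  # singleton convention

    def test_single_cluster_partition_warns_and_zeroes(self):
        D = make_dm(["a", "b"], {("a", "b"): 0.01})
        part = single_linkage_clusters(D, 0.5)
        with pytest.warns(UserWarning):
            s = silhouette_scores(D, part)
        assert s == {"a": 0.0, "b": 0.0}

    def test_matches_naive_oracle(self, rng):
        n = 15
        ids = [f"s{i:02d}" for i in range(n)]
        d = rng.uniform(0.0, 0.4, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        D = DistanceMatrix(ids, d, np.full((n, n), 100, np.int64))
        from acaritax.dilution import ClusterPartition

        labels = np.array([i % 4 + 1 for i in range(n)])  # 4 clusters, sizes 4/4/4/3
        part = ClusterPartition(0.5, ids, labels)
        got = silhouette_scores(D, part)
        want = oracle_silhouette(ids, d, part.assignment)
        for rid in ids:
            assert got[rid] == pytest.approx(want[rid], abs=1e-12)

    def test_matches_sklearn(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        n = 12
        ids = [f"s{i:02d}" for i in range(n)]
        d = rng.uniform(0.05, 0.4, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        D = DistanceMatrix(ids, d, np.full((n, n), 100, np.int64))
        labels = np.array([i % 3 for i in range(n)])
        from acaritax.dilution import ClusterPartition

        part = ClusterPartition(0.5, ids, labels + 1)
        got = silhouette_scores(D, part)
        want = sklearn_metrics.silhouette_samples(d, labels, metric="precomputed")
        assert np.allclose([got[i] for i in ids], want)


class TestRepresentatives:
    def _lib(self):
        return make_library([
            make_record("a", "A" * 658),
            make_record("b", "A" * 640 + "-" * 18),
            make_record("c", "A" * 658),
        ])

    def test_highest_silhouette_wins(self):
        D = make_dm(["a", "b", "c"],
                    {("a", "b"): 0.01, ("a", "c"): 0.2, ("b", "c"): 0.15})
        part = single_linkage_clusters(D, 0.05)
        scores = silhouette_scores(D, part)
        assert scores["a"] > scores["b"]  # a sits farther from the other cluster
        res = select_representatives(part, scores, self._lib())
        assert len(res.representatives) == part.n_clusters
        assert res.representatives[0] == "a"

    def test_length_breaks_score_tie(self):
        D = make_dm(["a", "b", "c"], {("a", "b"): 0.01, ("a", "c"): 0.3,
                                      ("b", "c"): 0.3})
        part = single_linkage_clusters(D, 0.05)
        scores = {"a": 0.5, "b": 0.5, "c": 0.0}
        res = select_representatives(part, scores, self._lib())
        assert "a" in res.representatives  # 658 bp beats 640 bp

    def test_singleton_cluster_represents_itself(self):
        D = make_dm(["a", "b"], {("a", "b"): 0.5})
        part = single_linkage_clusters(D, 0.05)
        scores = silhouette_scores(D, part)
        lib = make_library([make_record("a", "AAAA"), make_record("b", "TTTT")])
        res = select_representatives(part, scores, lib)
        assert sorted(res.representatives) == ["a", "b"]


class TestDiluteSeries:
    def _synthetic(self, seed=0):
        cfg = SyntheticConfig(
            n_orders=2, families_per_order=3, bins_per_family=3,
            seqs_per_bin=2, ambiguity_rate=0.0, seed=seed,
        )
        lib, _ = generate_library(cfg)
        return lib

    def test_already_diverged_library_unchanged(self):
        lib = make_library([
            make_record("a", "A" * 20),
            make_record("b", "C" * 20),
            make_record("c", "G" * 20),
        ])
        levels = dilute_series(lib, (0.05, 0.10))
        for lev in levels:
            assert lev.library.ids == lib.ids

    def test_counts_monotone_non_increasing(self):
        lib = self._synthetic()
        levels = dilute_series(lib, (0.05, 0.10))
        assert len(lib) >= len(levels[0].library) >= len(levels[1].library)

    def test_rediluting_at_same_threshold_is_idempotent(self):
        lib = self._synthetic()
        first = dilute(lib, 0.05)
        again = dilute(first.library, 0.05)
        assert again.library.ids == first.library.ids

    def test_nesting_of_cuts_on_same_matrix(self):
        """0.10 clusters are unions of 0.05 clusters on the same matrix."""
        lib = self._synthetic(seed=3)
        D = distance_matrix(lib)
        fine = single_linkage_clusters(D, 0.05)
        coarse = single_linkage_clusters(D, 0.10)
        coarse_of = dict(zip(coarse.ids, coarse.labels))
        for c in range(1, fine.n_clusters + 1):
            members = fine.members(c)
            assert len({coarse_of[m] for m in members}) == 1

    def test_representatives_one_per_cluster(self):
        lib = self._synthetic(seed=5)
        lev = dilute(lib, 0.05)
        labels = [lev.partition.assignment[r] for r in lev.representatives]
        assert sorted(labels) == list(range(1, lev.partition.n_clusters + 1))

    def test_thresholds_must_increase(self):
        lib = self._synthetic()
        with pytest.raises(ValueError):
            dilute_series(lib, (0.10, 0.05))
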