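"""Ward family clustering: oracle agreement, hierarchy, representatives."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from peptoids.cluster import (
    cluster_profile, select_representatives, standardize, ward_cluster,
)
from peptoids.errors import ValidationError


def greedy_ward_labels(X, k):
    """Exhaustive ESS-greedy Ward oracle for tiny instances.

    Starts from singletons; at each step merges the pair whose union
    minimally increases the total within-cluster sum of squares,
    recomputed exactly (no Lance-Williams shortcut). Ties break toward
    the lowest pair of cluster indices.
    """
    X = np.asarray(X, dtype=float)
    clusters = [[i] for i in range(len(X))]

    def ess(members):
        sub = X[members]
        return float(((sub - sub.mean(axis=0)) ** 2).sum())

    while len(clusters) > k:
        best = None
        for (a, b) in itertools.combinations(range(len(clusters)), 2):
            delta = ess(clusters[a] + clusters[b]) - ess(clusters[a]) \
                - ess(clusters[b])
            if best is None or delta < best[0] - 1e-12:
                best = (delta, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(len(X), dtype=int)
    for lab, members in enumerate(clusters, start=1):
        labels[members] = lab
    return labels


class TestStandardize:
    def test_symmetric_three_point_column(self):
        Z = standardize(np.array([[1.0], [2.0], [3.0]]))
        assert Z.ravel() == pytest.approx([-1.0, 0.0, 1.0])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        Z1 = standardize(rng.normal(size=(20, 3)))
        assert standardize(Z1) == pytest.approx(Z1, abs=1e-12)

    def test_post_hoc_moments(self):
        rng = np.random.default_rng(1)
        Z = standardize(rng.normal(2.0, 5.0, size=(50, 4)))
        assert np.abs(Z.mean(axis=0)).max() < 1e-10
        assert np.abs(Z.std(axis=0, ddof=1) - 1).max() < 1e-10

    def test_constant_column_dropped_with_warning(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            Z = standardize(X)
        assert list(Z.columns) == ["a"]

    def test_errors(self):
        with pytest.raises(ValidationError):
            standardize(np.ones((1, 3)))
        with pytest.raises(ValidationError):
            standardize(np.ones((5, 2)))


class TestWardContract:
    def test_two_points_merge_at_euclidean_distance(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])
        a = ward_cluster(X, 1)
        assert a.labels.tolist() == [1, 1]
        assert a.merge_heights == pytest.approx([5.0])

    def test_k_equals_n_gives_singletons(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 2))
        a = ward_cluster(X, 6)
        assert sorted(a.labels) == [1, 2, 3, 4, 5, 6]

    @pytest.mark.parametrize("n,k", [(6, 2), (6, 3), (8, 2), (8, 3)])
    def test_matches_exhaustive_ess_oracle(self, n, k):
        rng = np.random.default_rng(10 * n + k)
        X = rng.normal(size=(n, 2))
        got = ward_cluster(X, k).labels
        want = greedy_ward_labels(X, k)
        assert adjusted_rand_score(want, got) == 1.0

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(3)
        a = ward_cluster(rng.normal(size=(30, 4)), 5)
        assert (np.diff(a.merge_heights) >= -1e-12).all()

    def test_cut_refinement_consistency(self):
        """Cutting at k-1 only merges clusters found at k."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 3))
        for k in (5, 4, 3, 2):
            fine = ward_cluster(X, k).labels
            coarse = ward_cluster(X, k - 1).labels
            mapping = {}
            for f, c in zip(fine, coarse):
                assert mapping.setdefault(f, c) == c

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 3))
        perm = rng.permutation(40)
        a = ward_cluster(X, 4).labels
        b = ward_cluster(X[perm], 4).labels
        assert adjusted_rand_score(a[perm], b) == 1.0

    def test_k_bounds(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValidationError):
            ward_cluster(X, 0)
        with pytest.raises(ValidationError):
            ward_cluster(X, 4)


class TestProfileAndRepresentatives:
    def test_k1_profile_is_global_means(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(12, 2)), columns=["u", "v"])
        a = ward_cluster(X.to_numpy(), 1)
        prof = cluster_profile(a, X)
        assert prof.shape[0] == 1
        assert prof.loc[0, "u_mean"] == pytest.approx(X["u"].mean())
        assert prof.loc[0, "n"] == 12

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(37, 3))
        a = ward_cluster(X, 5)
        assert cluster_profile(a, X)["n"].sum() == 37

    def test_three_blob_means_recovered(self):
        rng = np.random.default_rng(8)
        centers = np.array([[0, 0], [10, 0], [0, 10]], dtype=float)
        X = np.vstack([rng.normal(c, 1.0, size=(30, 2)) for c in centers])
        a = ward_cluster(X, 3)
        prof = cluster_profile(a, X)
        se = 1.0 / np.sqrt(30)
        found = prof[["x0_mean", "x1_mean"]].to_numpy()
        for c in centers:
            d = np.linalg.norm(found - c, axis=1).min()
            assert d < 2 * se * np.sqrt(2) + 0.5

    def test_tie_breaks_to_lowest_row_id(self):
        X = np.array([[0.0, 0.0], [2.0, 0.0]])  # equidistant from centroid
        a = ward_cluster(X, 1)
        assert select_representatives(a, X, 1) == [0]

    def test_small_cluster_returns_all_members(self):
        X = np.array([[0.0], [0.1], [10.0]])
        a = ward_cluster(X, 2)
        reps = select_representatives(a, X, 5)
        assert sorted(reps) == [0, 1, 2]

    def test_representatives_beat_random_members(self):
        """Centroid-proximal picks are closer than random picks, paired
        over 100 seeds."""
        rng = np.random.default_rng(9)
        X = rng.normal(size=(60, 3))
        a = ward_cluster(X, 4)
        reps = select_representatives(a, X, 2)
        rep_dist = _mean_centroid_distance(X, a.labels, reps)
        wins = 0
        for s in range(100):
            r = np.random.default_rng(s)
            rand = []
            for lab in range(1, 5):
                idx = np.flatnonzero(a.labels == lab)
                rand.extend(r.choice(idx, size=min(2, idx.size),
                                     replace=False))
            wins += rep_dist <= _mean_centroid_distance(X, a.labels, rand)
        assert wins >= 95


def _mean_centroid_distance(X, labels, chosen):
    ds = []
    for i in chosen:
        members = X[labels == labels[i]]
        ds.append(np.linalg.norm(X[i] - members.mean(axis=0)))
    return np.mean(ds)
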