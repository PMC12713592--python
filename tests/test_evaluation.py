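import numpy as np
import pytest
from scipy.special import gammaln

from mgw import (ami_transfer, auroc_auprc, cosine_shared, migration, morans_i,
                 pas_score)


# --------------------------------------------------------------------------
# Independent oracles
# --------------------------------------------------------------------------

def ami_oracle(u, v):
    """AMI from first principles: contingency MI, hypergeometric expected MI
    under the permutation model, arithmetic-mean normalization."""
    u = np.asarray(u)
    v = np.asarray(v)
    N = len(u)
    cu, ui = np.unique(u, return_inverse=True)
    cv, vi = np.unique(v, return_inverse=True)
    C = np.zeros((len(cu), len(cv)))
    for a, b in zip(ui, vi):
        C[a, b] += 1
    a = C.sum(1)
    b = C.sum(0)
    # mutual information
    mi = 0.0
    for i in range(len(cu)):
        for j in range(len(cv)):
            nij = C[i, j]
            if nij > 0:
                mi += nij / N * np.log(N * nij / (a[i] * b[j]))
    # expected MI under random permutations (hypergeometric)
    emi = 0.0
    lgN = gammaln(N + 1)
    for i in range(len(cu)):
        for j in range(len(cv)):
            ai, bj = a[i], b[j]
            lo = int(max(1, ai + bj - N))
            hi = int(min(ai, bj))
            for nij in range(lo, hi + 1):
                term = nij / N * np.log(N * nij / (ai * bj))
                lp = (gammaln(ai + 1) + gammaln(bj + 1)
                      + gammaln(N - ai + 1) + gammaln(N - bj + 1)
                      - lgN - gammaln(nij + 1) - gammaln(ai - nij + 1)
                      - gammaln(bj - nij + 1) - gammaln(N - ai - bj + nij + 1))
                emi += term * np.exp(lp)
    hu = -np.sum(a / N * np.log(a / N))
    hv = -np.sum(b / N * np.log(b / N))
    denom = 0.5 * (hu + hv) - emi
    if denom == 0:
        return 1.0 if mi == emi else 0.0
    return (mi - emi) / denom


def auroc_oracle(scores, labels):
    """O(n^2) pairwise-comparison probability with half credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


# --------------------------------------------------------------------------
# Migration
# --------------------------------------------------------------------------

class TestMigration:
    def test_identity_coupling_same_coords_is_zero(self, rng):
        c = rng.uniform(size=(30, 2))
        P = np.eye(30) / 30
        assert migration(P, c, c) == pytest.approx(0.0, abs=1e-10)

    def test_procrustes_absorbs_translation(self, rng):
        c = rng.uniform(size=(40, 2))
        P = np.eye(40) / 40
        assert migration(P, c + np.array([5.0, -3.0]), c,
                         register="procrustes") == pytest.approx(0.0, abs=1e-8)

    def test_common_frame_single_moved_point(self, rng):
        # move an interior point by 10% of the extent: migration = 10/n %
        n = 25
        c = np.column_stack([g.ravel() for g in
                             np.meshgrid(np.linspace(0, 1, 5),
                                         np.linspace(0, 1, 5))])
        extent = np.sqrt(2.0)
        cB = c.copy()
        cB[12] += 0.1 * extent / np.sqrt(2)  # diagonal move, interior point
        P = np.eye(n) / n
        got = migration(P, c, cB, register="common_frame")
        assert got == pytest.approx(10.0 / n, rel=1e-10)

    def test_invariant_to_common_rigid_motion(self, rng):
        c1 = rng.uniform(size=(35, 2))
        c2 = rng.uniform(size=(35, 2))
        P = rng.uniform(size=(35, 35))
        P /= P.sum()
        th = 1.1
        Q = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        b = np.array([2.0, -1.0])
        m1 = migration(P, c1, c2, register="procrustes")
        m2 = migration(P, c1 @ Q.T + b, c2 @ Q.T + b, register="procrustes")
        assert m1 == pytest.approx(m2, abs=1e-8)

    def test_zero_rows_excluded_with_warning(self, rng):
        c = rng.uniform(size=(10, 2))
        P = np.eye(10) / 10
        P[3] = 0.0
        with pytest.warns(UserWarning, match="zero-mass"):
            out = migration(P, c, c)
        assert out == pytest.approx(0.0, abs=1e-10)


# --------------------------------------------------------------------------
# AMI
# --------------------------------------------------------------------------

class TestAmi:
    def test_perfect_transfer_is_one(self):
        P = np.eye(20) / 20
        labels = np.repeat(["a", "b", "c", "d"], 5)
        assert ami_transfer(P, labels, labels) == pytest.approx(1.0, abs=1e-12)

    def test_independent_labels_near_zero(self, rng):
        # empirical null of the adjusted statistic
        vals = []
        for _ in range(20):
            u = rng.integers(0, 4, 1000).astype(str)
            v = rng.integers(0, 4, 1000).astype(str)
            P = np.eye(1000) / 1000
            vals.append(ami_transfer(P, u, v))
        assert max(np.abs(vals)) < 0.05

    def test_matches_first_principles_oracle(self, rng):
        from sklearn.metrics import adjusted_mutual_info_score

        for _ in range(20):
            u = rng.integers(0, 4, 120)
            v = rng.integers(0, 3, 120)
            assert adjusted_mutual_info_score(u, v) == pytest.approx(
                ami_oracle(u, v), abs=1e-10)

    def test_single_class_truth_returns_zero(self):
        P = np.eye(5) / 5
        with pytest.warns(UserWarning, match="single-class"):
            out = ami_transfer(P, np.repeat("a", 5), np.array(list("abcde")))
        assert out == 0.0


# --------------------------------------------------------------------------
# Cosine similarity of projected features
# --------------------------------------------------------------------------

class TestCosine:
    def test_exact_projection_gives_one(self, rng):
        X = rng.normal(size=(10, 6))
        P = np.eye(10) / 10
        mean, median = cosine_shared(P, X, X)
        assert mean == pytest.approx(1.0, abs=1e-12)
        assert median == pytest.approx(1.0, abs=1e-12)

    def test_negated_projection_gives_minus_one(self, rng):
        X = rng.normal(size=(8, 4))
        P = np.eye(8) / 8
        mean, _ = cosine_shared(P, X, -X)
        assert mean == pytest.approx(-1.0, abs=1e-12)

    def test_orthogonal_rows_give_zero(self):
        X = np.tile([1.0, 0.0], (5, 1))
        Z = np.tile([0.0, 1.0], (5, 1))
        mean, median = cosine_shared(np.eye(5) / 5, X, Z)
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_no_shared_features_rejected(self):
        with pytest.raises(ValueError):
            cosine_shared(np.eye(2) / 2, np.zeros((2, 0)), np.zeros((2, 0)))


# --------------------------------------------------------------------------
# Moran's I
# --------------------------------------------------------------------------

class TestMoransI:
    def test_smooth_gradient_strongly_positive(self):
        ax = np.linspace(0, 1, 32)
        coords = np.column_stack([g.ravel() for g in np.meshgrid(ax, ax)])
        vals = coords @ np.array([1.0, 0.5])
        assert morans_i(vals, coords, k_neighbors=8) > 0.9

    def test_checkerboard_rook_adjacency_is_minus_one(self):
        side = 4
        xy = np.array([[i, j] for i in range(side) for j in range(side)], float)
        vals = (xy.sum(axis=1) % 2).astype(float)
        W = (np.abs(xy[:, None] - xy[None]).sum(-1) == 1).astype(float)
        assert morans_i(vals, xy, weights=W) == pytest.approx(-1.0, abs=1e-10)

    def test_permutation_null_expectation(self, rng):
        # analytic expectation under permutation is -1/(n-1)
        n = 100
        coords = rng.uniform(size=(n, 2))
        vals = rng.normal(size=n)
        means = [morans_i(rng.permutation(vals), coords, k_neighbors=8)
                 for _ in range(50)]
        assert np.mean(means) == pytest.approx(-1 / (n - 1), abs=0.05)

    def test_affine_invariance(self, rng):
        coords = rng.uniform(size=(60, 2))
        vals = rng.normal(size=60)
        i1 = morans_i(vals, coords, 6)
        i2 = morans_i(3.0 * vals - 7.0, coords, 6)
        assert i1 == pytest.approx(i2, abs=1e-10)

    def test_constant_values_nan_with_warning(self, rng):
        with pytest.warns(UserWarning, match="constant"):
            out = morans_i(np.ones(20), rng.uniform(size=(20, 2)), 4)
        assert np.isnan(out)


# --------------------------------------------------------------------------
# PAS
# --------------------------------------------------------------------------

class TestPas:
    def test_single_cluster_is_zero(self, rng):
        coords = rng.uniform(size=(30, 2))
        assert pas_score(np.zeros(30), coords, 5) == 0.0

    def test_alternating_clusters_k2_is_one(self):
        # closed chain: both nearest neighbors of every point are adjacent,
        # and with strictly alternating clusters they always disagree
        t = np.linspace(0, 2 * np.pi, 20, endpoint=False)
        coords = np.column_stack([np.cos(t), np.sin(t)])
        clusters = np.arange(20) % 2
        assert pas_score(clusters, coords, k_neighbors=2) == 1.0

    def test_half_plane_clusters_match_enumeration(self):
        ax = np.linspace(0, 1, 10)
        coords = np.column_stack([g.ravel() for g in np.meshgrid(ax, ax)])
        clusters = (coords[:, 0] > 0.5).astype(int)
        k = 8
        got = pas_score(clusters, coords, k)
        # brute-force oracle with its own neighbor search
        D = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        cnt = 0
        for i in range(len(coords)):
            nb = np.argsort(D[i], kind="stable")[1:k + 1]
            if (clusters[nb] != clusters[i]).mean() > 0.5:
                cnt += 1
        assert got == pytest.approx(cnt / len(coords), abs=1e-12)


# --------------------------------------------------------------------------
# AUROC / AUPRC
# --------------------------------------------------------------------------

class TestAurocAuprc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        auroc, auprc = auroc_auprc(scores, labels)
        assert auroc == 1.0
        assert auprc == 1.0

    def test_anti_ordered_scores(self):
        auroc, _ = auroc_auprc(np.array([0.1, 0.2, 0.8, 0.9]),
                               np.array([1, 1, 0, 0]))
        assert auroc == 0.0

    def test_matches_pairwise_oracle_with_ties(self, rng):
        for _ in range(100):
            n = 30
            scores = rng.integers(0, 10, n).astype(float)  # many ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            auroc, _ = auroc_auprc(scores, labels)
            assert auroc == pytest.approx(auroc_oracle(scores, labels),
                                          abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc_auprc(np.array([0.1, 0.2]), np.array([1, 1]))
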