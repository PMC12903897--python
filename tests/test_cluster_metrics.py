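import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from spatialnmf.cluster import cluster_embedding, rank_marker_genes, relabel_first_appearance
from spatialnmf.metrics import (
    adjusted_rand_index,
    normalized_mutual_information,
    purity,
    score_clustering,
)

# ---------------------------------------------------------------------------
# independent O(s^2) oracles


def pair_count_ari(pred, truth):
    """ARI from explicit enumeration of all sample pairs."""
    n = len(pred)
    a = b = c = d = 0
    for i, j in itertools.combinations(range(n), 2):
        same_p, same_t = pred[i] == pred[j], truth[i] == truth[j]
        if same_p and same_t:
            a += 1
        elif same_t and not same_p:
            b += 1
        elif same_p and not same_t:
            c += 1
        else:
            d += 1
    total = a + b + c + d
    sum_t = a + b  # pairs together in truth
    sum_p = a + c  # pairs together in prediction
    expected = sum_t * sum_p / total
    max_index = (sum_t + sum_p) / 2
    if max_index == expected:
        return 1.0 if a == expected else 0.0
    return (a - expected) / (max_index - expected)


def contingency_nmi(pred, truth):
    """NMI by direct double summation over the contingency table."""
    n = len(pred)
    ps, ts = sorted(set(pred)), sorted(set(truth))
    joint = {(u, v): 0 for u in ts for v in ps}
    for p, t in zip(pred, truth):
        joint[(t, p)] += 1
    mi = 0.0
    for (u, v), cnt in joint.items():
        if cnt == 0:
            continue
        pu = sum(joint[(u, vv)] for vv in ps) / n
        pv = sum(joint[(uu, v)] for uu in ts) / n
        mi += (cnt / n) * math.log((cnt / n) / (pu * pv))
    h_t = -sum(
        (cu / n) * math.log(cu / n)
        for cu in [sum(joint[(u, vv)] for vv in ps) for u in ts]
    )
    h_p = -sum(
        (cv / n) * math.log(cv / n)
        for cv in [sum(joint[(uu, v)] for uu in ts) for v in ps]
    )
    if mi <= 0:
        return 0.0
    return 2 * mi / (h_t + h_p)


def naive_purity(pred, truth):
    total = 0
    for v in set(pred):
        members = [t for p, t in zip(pred, truth) if p == v]
        total += max(members.count(u) for u in set(members))
    return total / len(pred)


# ---------------------------------------------------------------------------


class TestARI:
    def test_identical_labelings_score_one(self):
        labels = [0, 0, 1, 1, 2]
        assert adjusted_rand_index(labels, labels) == pytest.approx(1.0)

    def test_hand_worked_alternating_case(self):
        # all 6 pairs: a=0, d=2 -> ARI = -0.5
        assert adjusted_rand_index([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(-0.5)

    def test_matches_pair_count_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 40))
            pred = rng.integers(0, 4, n).tolist()
            truth = rng.integers(0, 3, n).tolist()
            assert adjusted_rand_index(pred, truth) == pytest.approx(
                pair_count_ari(pred, truth), abs=1e-12
            )

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.integers(0, 4), min_size=4, max_size=30), st.permutations(range(5)))
    def test_label_permutation_invariance(self, truth, perm):
        pred = [(x * 7 + 1) % 3 for x in range(len(truth))]
        relabeled = [perm[p] for p in pred]
        assert adjusted_rand_index(pred, truth) == pytest.approx(
            adjusted_rand_index(relabeled, truth), abs=1e-12
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            adjusted_rand_index([0, 1], [0, 1, 2])


class TestNMI:
    def test_identical_labelings_score_one(self):
        assert normalized_mutual_information([0, 1, 1, 2], [0, 1, 1, 2]) == pytest.approx(1.0)

    def test_constant_prediction_scores_zero(self):
        assert normalized_mutual_information([1, 1, 1, 1], [0, 1, 0, 1]) == 0.0

    def test_matches_contingency_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 200))
            pred = rng.integers(0, 5, n).tolist()
            truth = rng.integers(0, 4, n).tolist()
            assert normalized_mutual_information(pred, truth) == pytest.approx(
                contingency_nmi(pred, truth), abs=1e-12
            )


class TestPurity:
    def test_singleton_clusters_are_pure(self):
        assert purity([0, 1, 2, 3], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_hand_worked_half_pure(self):
        # clusters {0,2} and {1,3} against truth [a,a,b,b]: (1+1)/4
        assert purity([0, 1, 0, 1], [0, 0, 1, 1]) == pytest.approx(0.5)

    def test_matches_naive_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 60))
            pred = rng.integers(0, 5, n).tolist()
            truth = rng.integers(0, 4, n).tolist()
            assert purity(pred, truth) == pytest.approx(naive_purity(pred, truth), abs=1e-15)

    def test_refinement_never_lowers_purity(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 40))
            pred = rng.integers(0, 3, n)
            truth = rng.integers(0, 3, n).tolist()
            # split cluster 0 into two arbitrary halves
            refined = pred.copy()
            members = np.flatnonzero(pred == 0)
            refined[members[: len(members) // 2]] = 3
            assert purity(refined.tolist(), truth) >= purity(pred.tolist(), truth) - 1e-15

    def test_score_clustering_bundles_all_three(self):
        s = score_clustering([0, 0, 1, 1], [0, 0, 1, 1])
        assert s.ari == s.nmi == s.pur == pytest.approx(1.0)


class TestClusterEmbedding:
    def test_well_separated_groups_recovered(self, rng):
        centers = np.array([[0.0, 0.0], [10.0, 10.0], [-10.0, 5.0]])
        h = np.repeat(centers, 8, axis=0).T + rng.normal(0, 0.01, size=(2, 24))
        got = cluster_embedding(h, k=3, seed=0)
        truth = np.repeat([0, 1, 2], 8)
        assert adjusted_rand_index(got.labels, truth) == pytest.approx(1.0)

    def test_same_seed_identical_labels(self, rng):
        h = rng.uniform(size=(3, 30))
        a = cluster_embedding(h, k=4, seed=9)
        b = cluster_embedding(h, k=4, seed=9)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_wcss_matches_exhaustive_assignment_oracle(self, rng):
        # two tight jittered groups, s <= 12: enumerate every 2-labeling
        pts = np.vstack([
            np.zeros((5, 2)) + rng.normal(0, 0.01, (5, 2)),
            np.full((5, 2), 10.0) + rng.normal(0, 0.01, (5, 2)),
        ])
        got = cluster_embedding(pts.T, k=2, seed=0)
        best = np.inf
        for assign in itertools.product([0, 1], repeat=10):
            assign = np.array(assign)
            if len(set(assign)) < 2:
                continue
            wcss = sum(
                np.sum((pts[assign == c] - pts[assign == c].mean(axis=0)) ** 2)
                for c in (0, 1)
            )
            best = min(best, wcss)
        wcss_got = sum(
            np.sum((pts[got.labels == c] - pts[got.labels == c].mean(axis=0)) ** 2)
            for c in (0, 1)
        )
        assert wcss_got == pytest.approx(best, rel=1e-10)

    def test_k_exceeding_distinct_columns_rejected(self):
        h = np.ones((2, 6))
        with pytest.raises(ValueError, match="distinct"):
            cluster_embedding(h, k=2, seed=0)

    def test_first_appearance_relabeling(self):
        np.testing.assert_array_equal(
            relabel_first_appearance(np.array([5, 5, 2, 5, 9, 2])), [0, 0, 1, 0, 2, 1]
        )


def exact_ranksum_pvalue(xs, ys):
    """Two-sided exact rank-sum p-value by full enumeration (no ties)."""
    combined = np.concatenate([xs, ys])
    ranks = rankdata(combined)
    n1 = len(xs)
    obs = ranks[:n1].sum()
    stats = [
        sum(ranks[list(subset)])
        for subset in itertools.combinations(range(len(combined)), n1)
    ]
    stats = np.asarray(stats)
    mu = stats.mean()
    p = np.mean(np.abs(stats - mu) >= np.abs(obs - mu) - 1e-12)
    return p


class TestMarkerGenes:
    def _toy(self, rng, n_in=10, n_out=20, n_genes=12):
        labels = np.array([0] * n_in + [1] * n_out)
        x = rng.uniform(0.5, 1.0, size=(n_genes, n_in + n_out))
        x[0, labels == 0] += 10.0  # strong exclusive marker of domain 0
        return x, labels

    def test_exclusive_gene_ranks_first(self, rng):
        x, labels = self._toy(rng)
        table = rank_marker_genes(x, labels, min_frac=0.25, min_abs_lfc=0.25)
        top = table[table["domain"] == 0].iloc[0]
        assert top["gene"] == "gene_0" and top["rank"] == 1
        assert top["pvalue"] < 1e-4

    def test_low_detection_fraction_excluded(self, rng):
        x, labels = self._toy(rng)
        x[1] = 0.0
        x[1, np.flatnonzero(labels == 0)[:2]] = 50.0  # in 20% of domain-0 spots
        table = rank_marker_genes(x, labels, min_frac=0.25, min_abs_lfc=0.25)
        assert "gene_1" not in set(table[table["domain"] == 0]["gene"])

    def test_pvalue_matches_exact_enumeration(self, rng):
        xs = np.array([1.3, 2.1, 0.7, 3.5, 2.8])
        ys = np.array([4.2, 5.1, 3.9, 6.0, 4.8])
        x = np.vstack([np.concatenate([xs, ys]), rng.uniform(1, 2, 10)])
        labels = np.array([0] * 5 + [1] * 5)
        table = rank_marker_genes(x, labels, min_frac=0.0, min_abs_lfc=0.0, top_n=5)
        got = table[(table["domain"] == 0) & (table["gene"] == "gene_0")]["pvalue"].iloc[0]
        assert got == pytest.approx(exact_ranksum_pvalue(xs, ys), abs=1e-12)

    def test_tiny_domain_skipped_with_warning(self, rng, caplog):
        x = rng.uniform(size=(5, 10))
        labels = np.array([0, 0, 1, 1, 1, 1, 1, 1, 1, 1])
        with caplog.at_level("WARNING"):
            table = rank_marker_genes(x, labels, min_frac=0.0, min_abs_lfc=0.0)
        assert "skipped" in caplog.text
        assert set(table["domain"]) <= {1}
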