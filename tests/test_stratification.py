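"""Weighted Jaccard distance, distance-based ω², and the cut-off search."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import rankdata

from gdrecon import find_best_cutoff, omega_squared, weighted_jaccard


class TestWeightedJaccard:
    @pytest.mark.parametrize("u,v,expect", [
        ((1, 0), (0, 1), 1.0),       # disjoint support
        ((2, 1), (1, 2), 0.5),       # Σmin=2, Σmax=4
        ((0, 0), (0, 0), 0.0),       # all-zero convention
        ((3, 4), (3, 4), 0.0),       # identity
    ])
    def test_hand_values(self, u, v, expect):
        assert weighted_jaccard(u, v) == pytest.approx(expect)

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            weighted_jaccard((1, -0.1), (0, 1))

    @given(st.lists(st.floats(min_value=0, max_value=10), min_size=2,
                    max_size=2),
           st.lists(st.floats(min_value=0, max_value=10), min_size=2,
                    max_size=2))
    def test_symmetry_and_range(self, u, v):
        d = weighted_jaccard(u, v)
        assert d == pytest.approx(weighted_jaccard(v, u))
        assert 0.0 <= d <= 1.0


class TestOmegaSquared:
    def test_zero_distance_matrix_gives_zero(self):
        D = np.zeros((6, 6))
        labels = np.array(["a"] * 3 + ["b"] * 3)
        assert omega_squared(D, labels) == 0.0

    def test_well_separated_clusters_near_one(self):
        # two tight clusters: within distance 0.01, between 0.99
        n = 10
        D = np.full((n, n), 0.99)
        D[:5, :5] = 0.01
        D[5:, 5:] = 0.01
        np.fill_diagonal(D, 0.0)
        labels = np.array(["low"] * 5 + ["high"] * 5)
        assert omega_squared(D, labels) > 0.9

    def test_matches_direct_sum_of_squares(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 1, size=(8, 2))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        labels = np.array(["a"] * 3 + ["b"] * 5)
        n = len(labels)
        ss_total = sum(D[i, j] ** 2 for i in range(n)
                       for j in range(i + 1, n)) / n
        ss_within = 0.0
        for g in ("a", "b"):
            idx = np.flatnonzero(labels == g)
            ss_within += sum(D[i, j] ** 2 for i in idx for j in idx
                             if i < j) / len(idx)
        ms_within = ss_within / (n - 2)
        expect = max(0.0, (ss_total - ss_within - ms_within)
                     / (ss_total + ms_within))
        assert omega_squared(D, labels) == pytest.approx(expect, abs=1e-12)

    def test_random_labels_on_homogeneous_points_average_near_zero(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(0, 1, size=(20, 2))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        vals = []
        for _ in range(300):
            labels = rng.permutation(np.array(["a"] * 10 + ["b"] * 10))
            vals.append(omega_squared(D, labels))
        assert np.mean(vals) < 0.05  # clipped at 0, so slightly positive

    def test_one_group_empty_rejected(self):
        D = np.zeros((4, 4))
        with pytest.raises(ValueError):
            omega_squared(D, np.array(["a"] * 4))


def _oracle_best_cutoff(abundances, min_group):
    """Naive re-implementation of the search from its post-condition."""
    items = sorted(abundances.items(), key=lambda kv: (kv[1], kv[0]))
    R = np.array([v for _, v in items])
    ranks = rankdata(R, method="average")

    def mm(x):
        return np.zeros_like(x) if np.ptp(x) == 0 else (x - x.min()) / np.ptp(x)

    Z = np.column_stack([mm(R), mm(ranks)])
    n = len(R)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            mx = np.maximum(Z[i], Z[j]).sum()
            D[i, j] = 0.0 if mx == 0 else 1 - np.minimum(Z[i], Z[j]).sum() / mx
    best_k, best_w = None, -1.0
    for k in range(min_group, n - min_group + 1):
        labels = np.array([0] * k + [1] * (n - k))
        dsq = D ** 2
        ss_total = dsq[np.triu_indices(n, 1)].sum() / n
        ss_within = 0.0
        for g in (0, 1):
            idx = np.flatnonzero(labels == g)
            sub = dsq[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        ms_w = ss_within / (n - 2)
        w = max(0.0, (ss_total - ss_within - ms_w) / (ss_total + ms_w)) \
            if ss_total + ms_w > 0 else 0.0
        if w > best_w + 1e-12:
            best_k, best_w = k, w
    return best_k, best_w


class TestFindBestCutoff:
    def test_planted_two_cluster_split(self):
        ab = {f"A{i}": 0.01 for i in range(5)}
        ab.update({f"B{i}": 0.50 for i in range(5)})
        res = find_best_cutoff(ab, min_group=3)
        assert res.k == 5
        assert all(res.labels[f"A{i}"] == "low" for i in range(5))
        assert all(res.labels[f"B{i}"] == "high" for i in range(5))
        assert 0.01 < res.cutoff_R < 0.50

    def test_all_equal_R_is_degenerate_with_zero_omega(self):
        ab = {f"P{i}": 0.2 for i in range(10)}
        res = find_best_cutoff(ab, min_group=3)
        assert res.degenerate and res.omega_squared == 0.0

    def test_input_order_invariance(self):
        rng = np.random.default_rng(2)
        vals = rng.lognormal(size=12)
        ab = {f"P{i:02d}": v for i, v in enumerate(vals)}
        r1 = find_best_cutoff(ab, min_group=3)
        shuffled = dict(sorted(ab.items(), key=lambda kv: kv[1]))
        r2 = find_best_cutoff(shuffled, min_group=3)
        assert r1.k == r2.k and r1.labels == r2.labels

    def test_agrees_with_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for trial in range(100):
            n = int(rng.integers(8, 21))
            vals = rng.lognormal(mean=-2, sigma=1.2, size=n)
            ab = {f"P{i:02d}": float(v) for i, v in enumerate(vals)}
            res = find_best_cutoff(ab, min_group=3)
            k_oracle, w_oracle = _oracle_best_cutoff(ab, min_group=3)
            assert res.k == k_oracle, f"trial {trial}"
            assert res.omega_squared == pytest.approx(w_oracle, abs=1e-10)

    def test_positive_affine_transform_leaves_labels_unchanged(self):
        rng = np.random.default_rng(12)
        vals = rng.lognormal(size=15)
        ab = {f"P{i:02d}": float(v) for i, v in enumerate(vals)}
        base = find_best_cutoff(ab, min_group=3)
        scaled = {k: 3.5 * v + 2.0 for k, v in ab.items()}
        res = find_best_cutoff(scaled, min_group=3)
        assert res.labels == base.labels and res.k == base.k

    def test_too_few_eligible_patients_reports_shortfall(self):
        with pytest.raises(ValueError, match="eligible"):
            find_best_cutoff({"P1": 0.1, "P2": 0.2}, min_group=3)

    def test_nan_R_patients_marked_ineligible(self):
        ab = {f"P{i}": float(i + 1) for i in range(10)}
        ab["PX"] = float("nan")
        res = find_best_cutoff(ab, min_group=3)
        assert res.ineligible == ["PX"] and res.eligible_n == 10

    def test_recovers_planted_bimodal_structure(self):
        # clusters separated like the planted donor-type Vδ2 contrast
        rng = np.random.default_rng(21)
        hits = 0
        trials = 30
        for _ in range(trials):
            lo = rng.lognormal(mean=np.log(0.004), sigma=0.7, size=20)
            hi = rng.lognormal(mean=np.log(0.05), sigma=0.7, size=29)
            ab = {f"L{i:02d}": float(v) for i, v in enumerate(lo)}
            ab.update({f"H{i:02d}": float(v) for i, v in enumerate(hi)})
            res = find_best_cutoff(ab)
            correct = sum((res.labels[k] == "low") == k.startswith("L")
                          for k in ab)
            hits += (correct >= 45) or (len(ab) - correct >= 45)
        assert hits >= 27  # >= 90% of replicates
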