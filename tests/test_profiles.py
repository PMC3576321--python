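"""Fractional appearance, transitions, correlation, clustering, robustness."""

import numpy as np
import pandas as pd
import pytest

from adam.efm import EFM, EFMSet
from adam.profiles import (
    classify_profiles,
    cluster_profiles,
    fractional_appearance,
    jaccard,
    kendall_matrix,
    overlap_smaller,
    perturb_weights,
    select_top_reactions,
)


def efm_set(*supports, network_id=None):
    return EFMSet(
        network_id=network_id,
        efms=[EFM(support=frozenset(s), coefficients=()) for s in supports],
    )


class TestFractionalAppearance:
    def test_diamond_counts(self):
        """Two modes sharing uptake/biomass: shared reactions X = 1.0,
        each branch X = 0.5 (brute-force counted)."""
        es = efm_set({"EX", "R1", "BM"}, {"EX", "R2", "BM"})
        X = fractional_appearance([es], [0.0])
        assert X.loc["EX", 0.0] == 1.0
        assert X.loc["BM", 0.0] == 1.0
        assert X.loc["R1", 0.0] == 0.5
        assert X.loc["R2", 0.0] == 0.5

    def test_absent_reaction_is_zero(self):
        e0 = efm_set({"a", "b"})
        e1 = efm_set({"a", "c"})
        X = fractional_appearance([e0, e1], [0.0, 10.0])
        assert X.loc["b", 10.0] == 0.0
        assert X.loc["c", 0.0] == 0.0

    def test_double_counting_identity(self):
        """sum_i count_i(j) == sum over EFMs of support size, exactly."""
        rng = np.random.default_rng(0)
        universe = [f"r{i}" for i in range(12)]
        sets, times = [], []
        for t in range(5):
            supports = set()
            while len(supports) < 6:
                supports.add(
                    frozenset(rng.choice(universe, size=rng.integers(2, 6),
                                         replace=False))
                )
            sets.append(efm_set(*supports))
            times.append(float(t))
        X = fractional_appearance(sets, times)
        for j, es in enumerate(sets):
            counts = X.iloc[:, j].to_numpy() * len(es)
            lhs = int(round(counts.sum()))
            rhs = sum(len(e.support) for e in es.efms)
            assert lhs == rhs

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError, match="empty EFM set"):
            fractional_appearance([efm_set()], [0.0])

    def test_bounds(self):
        es = efm_set({"a"}, {"a", "b"}, {"b", "c"})
        X = fractional_appearance([es], [0.0])
        assert ((X >= 0) & (X <= 1)).all().all()


class TestTopSelection:
    def test_n_larger_than_universe_selects_all(self):
        X = pd.DataFrame(np.random.default_rng(1).random((4, 3)),
                         index=list("abcd"), columns=[0.0, 1.0, 2.0])
        assert select_top_reactions(X, n=50) == list("abcd")

    def test_constant_profile_union_equals_per_time_top(self):
        X = pd.DataFrame(
            [[0.9] * 3, [0.5] * 3, [0.1] * 3],
            index=["hi", "mid", "lo"], columns=[0.0, 1.0, 2.0],
        )
        assert select_top_reactions(X, n=2) == ["hi", "mid"]

    def test_disjoint_per_time_tops_union(self):
        """Per-time winners differ: the union accumulates ~n*T entries,
        verified against a per-column brute-force sort."""
        rng = np.random.default_rng(2)
        reactions = [f"r{i:02d}" for i in range(12)]
        X = pd.DataFrame(0.0, index=reactions, columns=[0.0, 1.0, 2.0])
        X.iloc[0:4, 0] = rng.uniform(0.5, 1, 4)
        X.iloc[4:8, 1] = rng.uniform(0.5, 1, 4)
        X.iloc[8:12, 2] = rng.uniform(0.5, 1, 4)
        got = select_top_reactions(X, n=3)
        expected = set()
        for c in X.columns:
            expected |= set(X[c].sort_values(ascending=False).index[:3])
        assert set(got) == expected
        assert len(got) == 9

    def test_tie_break_is_lexicographic(self):
        X = pd.DataFrame({0.0: [1.0, 0.5, 0.5, 0.2]}, index=list("dcba"))
        assert select_top_reactions(X, n=2) == ["b", "d"]  # b beats c at 0.5


class TestJaccard:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"x", "y"}, {"x", "y"}, 1.0),
            ({"x"}, {"y"}, 0.0),
            ({"a", "b", "c"}, {"b", "c", "d"}, 0.5),
            (set(), set(), 1.0),
        ],
    )
    def test_values(self, a, b, expected):
        assert jaccard(a, b) == pytest.approx(expected)

    def test_matches_set_arithmetic_on_random_pairs(self):
        rng = np.random.default_rng(3)
        universe = list(range(30))
        for _ in range(100):
            a = set(rng.choice(universe, rng.integers(0, 20), replace=False))
            b = set(rng.choice(universe, rng.integers(0, 20), replace=False))
            expected = 1.0 if not (a | b) else len(a & b) / len(a | b)
            assert jaccard(a, b) == pytest.approx(expected)
            assert jaccard(a, b) == jaccard(b, a)


class TestKendall:
    def test_identical_and_reversed(self):
        X = pd.DataFrame(
            [[1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1]],
            index=["a", "b", "c"], columns=[0.0, 1.0, 2.0, 3.0],
        )
        tau = kendall_matrix(X)
        assert tau.loc["a", "b"] == pytest.approx(1.0)
        assert tau.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(tau), 1.0)

    def test_matches_pair_counting_oracle(self):
        """tau_b from O(n^2) concordant/discordant counting with tie
        corrections, on random length-7 profiles."""
        rng = np.random.default_rng(4)
        for _ in range(100):
            x = rng.integers(0, 4, 7).astype(float)
            y = rng.integers(0, 4, 7).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            C = D = tx = ty = 0
            n = len(x)
            for i in range(n):
                for j in range(i + 1, n):
                    a, b = x[i] - x[j], y[i] - y[j]
                    if a == 0 and b == 0:
                        continue
                    if a == 0:
                        tx += 1
                    elif b == 0:
                        ty += 1
                    elif a * b > 0:
                        C += 1
                    else:
                        D += 1
            denom = np.sqrt((C + D + tx) * (C + D + ty))
            expected = (C - D) / denom
            X = pd.DataFrame([x, y], index=["x", "y"],
                             columns=np.arange(7, dtype=float))
            assert kendall_matrix(X).loc["x", "y"] == pytest.approx(expected)

    def test_zero_variance_profile_is_missing_not_zero(self):
        X = pd.DataFrame(
            [[1, 1, 1], [1, 2, 3]], index=["flat", "rising"],
            columns=[0.0, 1.0, 2.0],
        )
        tau = kendall_matrix(X)
        assert np.isnan(tau.loc["flat", "rising"])
        assert tau.loc["flat", "flat"] == 1.0


class TestClustering:
    def test_two_groups_of_identical_profiles(self):
        X = pd.DataFrame(
            [[0, 1, 2, 3]] * 3 + [[3, 2, 1, 0]] * 3,
            index=list("abcdef"), columns=[0.0, 1.0, 2.0, 3.0],
        )
        res = cluster_profiles(X, k=2, seed=0)
        labels = res.assignment
        assert len(set(labels[list("abc")])) == 1
        assert len(set(labels[list("def")])) == 1
        assert labels["a"] != labels["f"]

    def test_singletons_at_k_equal_n(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.random((4, 5)), index=list("abcd"),
                         columns=np.arange(5, dtype=float))
        res = cluster_profiles(X, k=4, seed=0)
        assert res.assignment.nunique() == 4

    def test_archetype_recovery_is_perfect(self):
        """Three noiseless archetype shapes, k=3: adjusted Rand = 1."""
        from sklearn.metrics import adjusted_rand_score

        t = np.arange(7, dtype=float)
        arch = {
            "up": t,
            "down": -t,
            "peak": -np.abs(t - 3),
        }
        rows, truth = [], []
        for name, shape in arch.items():
            for i in range(4):
                rows.append(pd.Series(shape + 0.001 * i, name=f"{name}{i}"))
                truth.append(name)
        X = pd.DataFrame(rows)
        X.columns = t
        res = cluster_profiles(X, k=3, seed=0)
        assert adjusted_rand_score(truth, res.assignment.to_numpy()) == 1.0

    def test_deterministic_at_fixed_seed(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.random((10, 7)),
                         index=[f"r{i}" for i in range(10)],
                         columns=np.arange(7, dtype=float))
        a = cluster_profiles(X, k=3, seed=1, method="kmeans")
        b = cluster_profiles(X, k=3, seed=1, method="kmeans")
        assert a.assignment.equals(b.assignment)

    def test_invalid_k(self):
        X = pd.DataFrame(np.ones((2, 3)), index=["a", "b"],
                         columns=[0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="invalid"):
            cluster_profiles(X, k=5)


class TestClassification:
    def test_all_positive_is_flat(self):
        X = pd.DataFrame([[0.2, 0.4, 0.1]], index=["r"], columns=[0.0, 1.0, 2.0])
        assert classify_profiles(X).loc["r", "class"] == "flat"

    def test_single_zero_is_fluctuating(self):
        X = pd.DataFrame([[0.2, 0.0, 0.1]], index=["r"], columns=[0.0, 1.0, 2.0])
        got = classify_profiles(X).loc["r"]
        assert got["class"] == "fluctuating"
        assert got["n_zero_times"] == 1

    def test_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.random((6, 5)) * (rng.random((6, 5)) > 0.3),
                         index=[f"r{i}" for i in range(6)],
                         columns=np.arange(5, dtype=float))
        base = classify_profiles(X)["class"]
        scaled = classify_profiles(X * 7.3)["class"]
        assert base.equals(scaled)


class TestPerturbation:
    def _weights(self):
        rng = np.random.default_rng(8)
        return pd.Series(rng.normal(0, 2, 50),
                         index=[f"r{i:02d}" for i in range(50)])

    def test_exactly_n_entries_change(self):
        w = self._weights()
        out = perturb_weights(w, n_reactions=10, noise_fraction=0.01, seed=0)
        assert (out != w).sum() == 10

    def test_amplitude_bounded_by_range_fraction(self):
        w = self._weights()
        out = perturb_weights(w, n_reactions=50, noise_fraction=0.01, seed=1)
        m = 0.01 * (w.max() - w.min())
        assert (out - w).abs().max() <= m + 1e-15

    def test_seed_determinism(self):
        w = self._weights()
        a = perturb_weights(w, 10, 0.01, seed=42)
        b = perturb_weights(w, 10, 0.01, seed=42)
        assert a.equals(b)
        assert not a.equals(perturb_weights(w, 10, 0.01, seed=43))

    def test_degenerate_range_rejected(self):
        w = pd.Series(1.0, index=list("abc"))
        with pytest.raises(ValueError, match="degenerate"):
            perturb_weights(w, 1, 0.01, seed=0)


def test_overlap_smaller_convention():
    assert overlap_smaller({"a", "b", "c", "d"}, {"a", "b"}) == 100.0
    assert overlap_smaller({"a", "b", "c"}, {"b", "c", "d", "e"}) == pytest.approx(
        200.0 / 3
    )
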