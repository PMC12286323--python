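"""Stratified splitting, k-NN with deterministic ties, combo search."""

import math
from dataclasses import dataclass

import numpy as np
import pytest

from nirsax.classify import (
    SplitError,
    combo_search,
    enumerate_channel_combos,
    fit_knn,
    knn_predict,
    make_split,
    tune_k,
)


@dataclass(frozen=True)
class Item:
    trial_id: str
    label: str


def items_for(counts):
    out = []
    for label, n in counts.items():
        out += [Item(f"{label}{i}", label) for i in range(n)]
    return out


class TestMakeSplit:
    def test_study_marginals_reproduced(self):
        """70/30 per class matches the printed study distributions."""
        for counts, expected in [
            ({"understood": 248, "not_understood": 202}, (174, 74, 141, 61)),
            ({"understood": 174, "not_understood": 100}, (122, 52, 70, 30)),
        ]:
            plan = make_split(items_for(counts), seed=0)
            n_u_tr = sum(1 for t in plan.train_ids if t.startswith("understood"))
            n_u_te = sum(1 for t in plan.test_ids if t.startswith("understood"))
            n_n_tr = sum(1 for t in plan.train_ids if t.startswith("not_"))
            n_n_te = sum(1 for t in plan.test_ids if t.startswith("not_"))
            assert (n_u_tr, n_u_te, n_n_tr, n_n_te) == expected

    def test_partition_and_determinism(self):
        items = items_for({"understood": 31, "not_understood": 17})
        a = make_split(items, seed=5)
        b = make_split(items, seed=5)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids
        assert a.train_ids & a.test_ids == frozenset()
        assert a.train_ids | a.test_ids == {i.trial_id for i in items}

    def test_tiny_class_rejected(self):
        with pytest.raises(SplitError):
            make_split(items_for({"understood": 5, "not_understood": 1}), seed=0)


class TestKnnPredict:
    def test_identity_query(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0]])
        model = fit_knn(X, ["not_understood", "understood"], k=1)
        label, score = knn_predict(model, np.array([5.0, 5.0]))
        assert label == "understood" and score == 1.0

    def test_hand_enumerated_vote(self):
        X = np.array([[1.0, 0], [0, 1.0], [2.0, 0], [9.0, 9.0]])
        y = ["understood", "understood", "not_understood", "not_understood"]
        model = fit_knn(X, y, k=3)
        label, score = knn_predict(model, np.zeros(2))
        assert label == "understood"
        assert math.isclose(score, 2 / 3)

    def test_full_k_on_balanced_data_scores_half(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 3))
        y = ["understood"] * 10 + ["not_understood"] * 10
        model = fit_knn(X, y, k=20)
        _, scores = knn_predict(model, rng.standard_normal((7, 3)))
        assert np.all(scores == 0.5)

    def test_agrees_with_brute_force_oracle(self):
        """200 random queries vs an O(n^2) loop with the same tie rules."""
        rng = np.random.default_rng(1)
        Xtr = rng.standard_normal((150, 4))
        ytr = rng.choice(["understood", "not_understood"], 150)
        Q = rng.standard_normal((200, 4))
        for k in (1, 3, 7, 10):
            model = fit_knn(Xtr, ytr, k=k)
            pred, scores = knn_predict(model, Q)
            for qi in range(200):
                d = [float(np.sum((Q[qi] - Xtr[j]) ** 2)) for j in range(150)]
                order = sorted(range(150), key=lambda j: (d[j], j))[:k]
                votes = {}
                dist = {}
                for j in order:
                    votes[ytr[j]] = votes.get(ytr[j], 0) + 1
                    dist[ytr[j]] = dist.get(ytr[j], 0.0) + math.sqrt(d[j])
                best = max(votes.values())
                tied = sorted(
                    [c for c, v in votes.items() if v == best],
                    key=lambda c: (dist[c], c),
                )
                assert pred[qi] == tied[0]
                assert math.isclose(
                    scores[qi], votes.get("understood", 0) / k
                )

    def test_duplicated_dimensions_leave_ranking_unchanged(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((60, 3))
        y = rng.choice(["understood", "not_understood"], 60)
        Q = rng.standard_normal((30, 3))
        m1 = fit_knn(X, y, k=5)
        m2 = fit_knn(np.hstack([X, X]), y, k=5)
        p1, s1 = knn_predict(m1, Q)
        p2, s2 = knn_predict(m2, np.hstack([Q, Q]))
        assert np.array_equal(p1, p2) and np.allclose(s1, s2)

    def test_dimension_mismatch_rejected(self):
        model = fit_knn(np.zeros((4, 3)), ["a", "a", "b", "b"], k=1)
        with pytest.raises(ValueError, match="dimension"):
            knn_predict(model, np.zeros(5))


class TestTuneK:
    def test_singleton_range(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 2))
        y = ["a"] * 20 + ["b"] * 20
        assert tune_k(X, y, seed=0, k_range=(3, 3)) == 3

    def test_separable_blobs_prefer_smallest_k(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 0.1, (25, 2)), rng.normal(5, 0.1, (25, 2))])
        y = ["a"] * 25 + ["b"] * 25
        assert tune_k(X, y, seed=0) == 1

    def test_label_noise_pushes_k_above_one(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 1.0, (60, 2)), rng.normal(2.0, 1.0, (60, 2))])
        y = np.array(["a"] * 60 + ["b"] * 60)
        flip = rng.choice(120, 18, replace=False)
        y[flip] = np.where(y[flip] == "a", "b", "a")
        assert tune_k(X, list(y), seed=0) > 1


class TestComboEnumeration:
    def test_study_count(self):
        assert len(enumerate_channel_combos(20, 4)) == 6195

    def test_tiny_case(self):
        assert enumerate_channel_combos(3, 2) == [
            (0,), (1,), (2,), (0, 1), (0, 2), (1, 2)
        ]

    @pytest.mark.parametrize("n", [4, 7, 12])
    def test_binomial_sum_oracle(self, n):
        for mx in range(1, n + 1):
            expected = sum(math.comb(n, s) for s in range(1, mx + 1))
            assert len(enumerate_channel_combos(n, mx)) == expected

    def test_bad_max_size_rejected(self):
        with pytest.raises(ValueError):
            enumerate_channel_combos(3, 0)


def _feature_fixture(seed=0, n_trials=60, n_channels=8, informative=7):
    """Only one channel separates classes; three instances per trial."""
    rng = np.random.default_rng(seed)
    labels, tids, rows = [], [], []
    for t in range(n_trials):
        label = "understood" if t % 2 else "not_understood"
        for w in range(3):
            x = rng.standard_normal((n_channels, 5))
            if label == "understood":
                x[informative] += 3.0
            rows.append(x)
            labels.append(label)
            tids.append(f"t{t:02d}")
    return np.stack(rows), np.array(labels), np.array(tids)


class TestComboSearch:
    def test_single_channel_single_row(self):
        X, y, tids = _feature_fixture(n_channels=1, informative=0)
        plan = make_split([Item(t, l) for t, l in dict(zip(tids, y)).items()], 0)
        df = combo_search(X, y, tids, plan, seed=0, combos=[(0,)])
        assert len(df) == 1
        assert df.loc[0, "tp"] + df.loc[0, "fn"] + df.loc[0, "tn"] + df.loc[0, "fp"] == int(
            np.isin(tids, list(plan.test_ids)).sum()
        )

    def test_informative_channel_dominates_ranking(self):
        X, y, tids = _feature_fixture()
        plan = make_split([Item(t, l) for t, l in dict(zip(tids, y)).items()], 0)
        df = combo_search(X, y, tids, plan, seed=0,
                          combos=enumerate_channel_combos(8, 2))
        top = df.head(5)["combo"]
        assert all("7" in c.split("+") for c in top)

    def test_deterministic_repeat(self):
        X, y, tids = _feature_fixture(seed=1)
        plan = make_split([Item(t, l) for t, l in dict(zip(tids, y)).items()], 3)
        a = combo_search(X, y, tids, plan, seed=3, combos=[(0,), (1,), (0, 1)])
        b = combo_search(X, y, tids, plan, seed=3, combos=[(0,), (1,), (0, 1)])
        assert a.equals(b)

    def test_confusion_counts_sum_to_test_size(self):
        X, y, tids = _feature_fixture(seed=2)
        plan = make_split([Item(t, l) for t, l in dict(zip(tids, y)).items()], 1)
        df = combo_search(X, y, tids, plan, seed=1, combos=[(0,), (3,), (0, 7)])
        n_test = int(np.isin(tids, list(plan.test_ids)).sum())
        assert np.all(df[["tp", "fn", "tn", "fp"]].sum(axis=1) == n_test)
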