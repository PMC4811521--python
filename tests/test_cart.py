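"""Classification-tree construction, class assignment, HRR grouping."""

import math

import numpy as np
import pandas as pd
import pytest

from cartsurv._cox import cox_fit
from cartsurv.tree import (
    CartModel,
    assign_classes,
    build_cart,
    class_hrrs,
    group_classes,
    reference_tree,
)


def _random_binary(n, k, seed, signal=0.0, base_rate=0.35):
    """Binary features with an optional logit signal on f0/f{k-1}; the base
    label prevalence mirrors a three-year death fraction (an exactly
    balanced prevalence would make even the root's majority class unstable
    across CV folds)."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({f"f{j}": rng.integers(0, 2, n).astype(float)
                      for j in range(k)})
    logit = np.log(base_rate / (1 - base_rate)) \
        + signal * (X["f0"] - 0.5) + 0.5 * signal * (X[f"f{k-1}"] - 0.5)
    p = 1 / (1 + np.exp(-logit))
    y = (rng.random(n) < p).astype(float)
    return X, y


def _partition_error_oracle(X: pd.DataFrame, y) -> float:
    """Best achievable training misclassification of ANY tree over binary
    features: majority vote within each distinct feature pattern."""
    df = X.copy()
    df["_y"] = np.asarray(y, dtype=float)
    err = 0.0
    for _, grp in df.groupby(list(X.columns)):
        pos = grp["_y"].sum()
        err += min(pos, len(grp) - pos)
    return err / len(df)


class TestBuildCart:
    def test_single_perfect_feature(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"m": rng.integers(0, 2, 200).astype(float)})
        y = X["m"].to_numpy()
        model = build_cart(X, y, seed=0)
        assert model.n_leaves == 2 and model.cv_error == 0.0
        assert model.used_features() == ("m",)

    def test_xor_needs_depth_two(self):
        X = pd.DataFrame({"a": np.repeat([0.0, 0.0, 1.0, 1.0], 100),
                          "b": np.tile(np.repeat([0.0, 1.0], 50), 4)})
        y = np.logical_xor(X["a"], X["b"]).astype(float)
        model = build_cart(X, y, seed=1)
        assert model.root.depth() == 2
        assert model.cv_error < 0.05

    def test_null_labels_prune_to_root(self):
        roots = 0
        for s in range(10):
            X, y = _random_binary(400, 3, seed=s, signal=0.0)
            model = build_cart(X, y, seed=s)
            roots += model.n_leaves == 1
        assert roots >= 9

    def test_constant_labels_root_only(self):
        X, _ = _random_binary(100, 2, seed=3)
        model = build_cart(X, np.zeros(100), seed=0)
        assert model.n_leaves == 1 and model.cv_error == 0.0

    def test_empty_features_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_cart(pd.DataFrame(index=range(5)), np.zeros(5))

    def test_missing_features_rejected(self):
        X = pd.DataFrame({"a": [0.0, np.nan, 1.0]})
        with pytest.raises(ValueError, match="complete"):
            build_cart(X, np.array([0.0, 1.0, 1.0]))

    @pytest.mark.parametrize("seed", range(6))
    def test_small_n_training_error_equals_exhaustive_best(self, seed):
        """On tiny cohorts the unpruned tree attains the training error of
        the best tree found by exhaustive partition enumeration."""
        rng = np.random.default_rng(seed)
        n = rng.integers(8, 13)
        X = pd.DataFrame({f"f{j}": rng.integers(0, 2, n).astype(float)
                          for j in range(3)})
        y = rng.integers(0, 2, n).astype(float)
        if np.unique(y).size < 2:
            return
        model = build_cart(X, y, min_leaf=1, cv_folds=2, seed=seed)
        # evaluate the unpruned (alpha ~ 0) training error via a rebuild
        from cartsurv._cart import PatternData, grow_tree, predict_patterns, \
            collapse_alphas, tree_error
        data = PatternData.from_matrix(X.to_numpy(dtype=float))
        pos, tot = data.counts(y)
        full = grow_tree(data, pos, tot, min_leaf=1)
        collapse_alphas(full, float(n))
        pred = predict_patterns(full, len(data.bits), 0.0)
        train_err = tree_error(pred, pos, tot) / n
        assert train_err == pytest.approx(_partition_error_oracle(X, y))

    @pytest.mark.parametrize("seed", range(4))
    def test_unpruned_training_error_matches_sklearn(self, seed):
        """Independent oracle: scikit-learn's Gini tree reaches the same
        training error on binary features."""
        from sklearn.tree import DecisionTreeClassifier

        X, y = _random_binary(150, 4, seed=seed, signal=1.0)
        data_err = _partition_error_oracle(X, y)
        sk = DecisionTreeClassifier(criterion="gini", min_samples_leaf=1,
                                    random_state=0).fit(X, y)
        sk_err = float((sk.predict(X) != y).mean())
        assert sk_err == pytest.approx(data_err)
        # ours, unpruned
        from cartsurv._cart import PatternData, grow_tree, predict_patterns, \
            collapse_alphas, tree_error
        data = PatternData.from_matrix(X.to_numpy(dtype=float))
        pos, tot = data.counts(y)
        full = grow_tree(data, pos, tot, min_leaf=1)
        collapse_alphas(full, float(len(y)))
        pred = predict_patterns(full, len(data.bits), 0.0)
        assert tree_error(pred, pos, tot) / len(y) == pytest.approx(data_err)

    def test_strong_signal_partition_matches_sklearn_with_pruning(self):
        """With a clear single-feature signal both implementations select
        the same two-leaf partition after cost-complexity pruning."""
        from sklearn.tree import DecisionTreeClassifier

        rng = np.random.default_rng(12)
        X, _ = _random_binary(400, 3, seed=12)
        y = np.where(rng.random(400) < 0.2, 1 - X["f1"], X["f1"]).astype(float)
        model = build_cart(X, y, seed=2)
        assert model.used_features() == ("f1",)
        sk = DecisionTreeClassifier(criterion="gini", min_samples_leaf=10,
                                    ccp_alpha=0.01, random_state=0).fit(X, y)
        assert sk.get_n_leaves() == model.n_leaves == 2

    def test_cv_error_not_worse_than_majority(self, fig1_cohort,
                                              default_cutoffs):
        from conftest import tree_inputs

        _, feats, times, events, labels = tree_inputs(fig1_cohort,
                                                      default_cutoffs)
        defined = labels != "undefined"
        y = (labels[defined] == "died_within_36").astype(float)
        model = build_cart(feats.loc[defined], y, seed=0)
        majority = min(y.mean(), 1 - y.mean())
        assert model.cv_error <= majority + 0.02


class TestAssignClasses:
    def test_reference_tree_routing(self):
        model = reference_tree()
        feats = pd.DataFrame({
            "AURKA": [0.0, 1.0, 1.0, 1.0, 0.0],
            "PTGS2": [1.0, 0.0, 0.0, 1.0, np.nan],
            "MMP9": [0.0, 0.0, 1.0, np.nan, 1.0],
        })
        out = assign_classes(model, feats)
        # low AURKA -> A regardless of the rest (incl. missing PTGS2)
        assert out[0] == "A" and out[4] == "A"
        assert out[1] == "B"
        assert out[2] == "C"
        # high AURKA + high PTGS2 -> D; MMP9 is not on this path
        assert out[3] == "D"

    def test_missing_on_path_excludes(self):
        model = reference_tree()
        feats = pd.DataFrame({"AURKA": [np.nan, 1.0], "PTGS2": [1.0, np.nan],
                              "MMP9": [0.0, 0.0]})
        out = assign_classes(model, feats)
        assert out[0] is None and out[1] is None

    def test_lacking_feature_column_rejected(self):
        with pytest.raises(ValueError, match="MMP9"):
            assign_classes(reference_tree(),
                           pd.DataFrame({"AURKA": [1.0], "PTGS2": [0.0]}))

    def test_routing_is_a_partition(self, fig1_cohort, default_cutoffs):
        from conftest import tree_inputs

        _, feats, times, events, labels = tree_inputs(fig1_cohort,
                                                      default_cutoffs)
        out = assign_classes(reference_tree(), feats)
        assert out.notna().all()
        assert set(out.unique()) <= {"A", "B", "C", "D"}


class TestClassHRRs:
    def _two_group(self, hr, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        cls = np.where(rng.random(n) < 0.5, "A", "B")
        rate = 0.02 * np.where(cls == "B", hr, 1.0)
        t = rng.exponential(1 / rate)
        return cls, t, np.ones(n)

    def test_null_classes_near_one(self):
        cls, t, e = self._two_group(1.0, seed=1)
        ch = class_hrrs(cls, t, e)
        other = [lab for lab in ch.hrrs if lab != ch.reference][0]
        assert 0.85 < ch.hrrs[other] < 1.18

    def test_reference_is_exactly_one_and_best_surviving(self):
        cls, t, e = self._two_group(3.0, seed=2)
        ch = class_hrrs(cls, t, e)
        assert ch.reference == "A"
        assert ch.hrrs["A"] == 1.0

    def test_generative_ratio_recovered_vs_direct_fit(self):
        cls, t, e = self._two_group(3.0, seed=3)
        ch = class_hrrs(cls, t, e)
        assert 2.6 < ch.hrrs["B"] < 3.5
        direct = cox_fit(t, e, (cls == "B").astype(float))
        assert ch.hrrs["B"] == pytest.approx(float(np.exp(direct.coef[0])),
                                             abs=1e-10)

    def test_class_without_events_non_estimable(self):
        rng = np.random.default_rng(4)
        cls = np.array(["A"] * 100 + ["B"] * 100 + ["C"] * 30)
        t = np.r_[rng.exponential(50, 200), np.full(30, 120.0)]
        e = np.r_[np.ones(200), np.zeros(30)]
        ch = class_hrrs(cls, t, e, log_warnings=False)
        assert "C" in ch.non_estimable or ch.reference == "C"


class TestGroupClasses:
    def test_published_grouping(self):
        g = group_classes({"B": 1.5, "C": 2.8, "D": 3.2}, reference="A")
        assert g.group_I == ("A", "B") and g.group_II == ("C", "D")
        assert g.discriminative

    def test_all_below_threshold_is_degenerate(self):
        g = group_classes({"B": 1.1, "C": 1.4}, reference="A",
                          log_warnings=False)
        assert not g.discriminative and g.group_II == ()

    def test_boundary_exactly_two_goes_to_group_ii(self):
        g = group_classes({"B": 2.0}, reference="A")
        assert g.group_II == ("B",)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            group_classes({}, reference=None)

    def test_membership_routing(self):
        g = group_classes({"B": 1.5, "C": 2.8}, reference="A")
        mem = g.membership(pd.Series(["A", "B", "C", None]))
        assert list(mem[:3]) == ["I", "I", "II"] and mem[3] is None


class TestSerialization:
    def test_text_round_trip(self, fig1_cohort, default_cutoffs):
        from conftest import tree_inputs

        _, feats, times, events, labels = tree_inputs(fig1_cohort,
                                                      default_cutoffs)
        defined = labels != "undefined"
        y = (labels[defined] == "died_within_36").astype(float)
        model = build_cart(feats.loc[defined], y, seed=0)
        back = CartModel.from_text(model.to_text())
        assert back.to_text() == model.to_text()
        assert back.cv_error == model.cv_error
        pd.testing.assert_series_equal(assign_classes(back, feats),
                                       assign_classes(model, feats))
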