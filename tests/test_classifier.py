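"""Network training, grid search, serialization, ordinal baseline."""

import numpy as np
import pandas as pd
import pytest
from sklearn.datasets import make_blobs

from tdprisk.biomarkers import FEATURE_NAMES
from tdprisk.classifier import (
    CLASS_ORDER,
    DegenerateLabelError,
    OrdinalRiskModel,
    RiskANNClassifier,
    grid_search,
)

RNG = np.random.default_rng(42)


def blob_table(n=300, sep=5.0, seed=0, d=9):
    X, yk = make_blobs(n_samples=n, centers=3, n_features=d,
                       cluster_std=1.0, center_box=(-sep, sep), random_state=seed)
    y = np.array(CLASS_ORDER)[yk]
    df = pd.DataFrame(X, columns=FEATURE_NAMES[:d])
    df["risk"] = y
    df["drug"] = [f"d{k}" for k in yk]
    df["sample"] = np.arange(n)
    return df, X, y


class TestRiskANN:
    def test_separable_blobs_high_accuracy(self):
        _, X, y = blob_table(sep=8.0)
        clf = RiskANNClassifier(epochs=60, seed=1).fit(X, y)
        assert np.mean(clf.predict(X) == y) >= 0.95

    def test_seeded_determinism(self):
        _, X, y = blob_table()
        a = RiskANNClassifier(epochs=10, seed=3).fit(X, y)
        b = RiskANNClassifier(epochs=10, seed=3).fit(X, y)
        for (Wa, ba), (Wb, bb) in zip(a.weights_, b.weights_):
            np.testing.assert_array_equal(Wa, Wb)
            np.testing.assert_array_equal(ba, bb)

    def test_single_class_rejected(self):
        _, X, _ = blob_table()
        with pytest.raises(DegenerateLabelError):
            RiskANNClassifier(epochs=1).fit(X, ["high"] * len(X))

    def test_nonfinite_features_rejected(self):
        _, X, y = blob_table()
        X = X.copy()
        X[3, 2] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            RiskANNClassifier(epochs=1).fit(X, y)

    def test_proba_rows_sum_to_one(self, trained_classifier, signal_tables):
        train, _ = signal_tables
        P = trained_classifier.predict_proba(train[FEATURE_NAMES].to_numpy(float))
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-6)
        assert ((P >= 0) & (P <= 1)).all()

    def test_pure_function_on_duplicates(self, trained_classifier, signal_tables):
        train, _ = signal_tables
        row = train[FEATURE_NAMES].to_numpy(float)[:1]
        P = trained_classifier.predict_proba(np.vstack([row, row]))
        np.testing.assert_array_equal(P[0], P[1])

    def test_wrong_feature_count_rejected(self, trained_classifier):
        with pytest.raises(ValueError, match="features"):
            trained_classifier.predict_proba(np.zeros((2, 5)))

    @pytest.mark.parametrize("optimizer", ["adam", "rmsprop"])
    def test_both_optimizers_learn(self, optimizer):
        _, X, y = blob_table(sep=8.0)
        clf = RiskANNClassifier(epochs=40, optimizer=optimizer, seed=0).fit(X, y)
        assert np.mean(clf.predict(X) == y) >= 0.9
        assert clf.loss_curve_[-1] < clf.loss_curve_[0]

    def test_l1_shrinks_first_layer(self):
        _, X, y = blob_table()
        norms = []
        for l1 in (0.0, 10.0):
            per_seed = []
            for seed in (0, 1, 2):
                clf = RiskANNClassifier(epochs=30, l1=l1, seed=seed).fit(X, y)
                per_seed.append(np.abs(clf.weights_[0][0]).sum())
            norms.append(np.mean(per_seed))
        assert norms[1] < norms[0]

    def test_serialization_roundtrip(self, tmp_path, trained_classifier, signal_tables):
        train, _ = signal_tables
        X = train[FEATURE_NAMES].to_numpy(float)
        path = tmp_path / "model.json"
        trained_classifier.save(path)
        loaded = RiskANNClassifier.load(path)
        np.testing.assert_allclose(loaded.predict_proba(X),
                                   trained_classifier.predict_proba(X), atol=1e-6)

    def test_newer_format_rejected(self, tmp_path, trained_classifier):
        import json

        path = tmp_path / "model.json"
        trained_classifier.save(path)
        doc = json.loads(path.read_text())
        doc["format_version"] = 99
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="newer"):
            RiskANNClassifier.load(path)


class TestGridSearch:
    def test_sabotaged_config_loses(self):
        # at a 15-epoch budget lr 0.001 badly undertrains; lr 0.01 separates
        df, _, _ = blob_table(n=120, sep=8.0)
        grid = {"learning_rate": [0.001, 0.01], "hidden1": [6], "hidden2": [5]}
        best, scores = grid_search(df, grid, k=3, seed=0,
                                   base_params={"epochs": 15})
        assert best["learning_rate"] == 0.01
        assert len(scores) == 2
        accs = scores.set_index("learning_rate")["mean_val_accuracy"]
        assert accs[0.01] > accs[0.001]

    def test_fold_sizes_at_protocol_scale(self):
        # partition arithmetic mirrors the full-scale protocol on a small table
        df, X, y = blob_table(n=240)
        from sklearn.model_selection import StratifiedKFold

        folds = list(StratifiedKFold(10, shuffle=True, random_state=0).split(X, y))
        sizes = {(len(tr), len(va)) for tr, va in folds}
        assert sizes == {(216, 24)}
        all_val = np.concatenate([va for _, va in folds])
        assert len(np.unique(all_val)) == 240  # disjoint cover

    def test_seeded_determinism(self):
        df, _, _ = blob_table(n=90)
        grid = {"hidden1": [5, 6], "hidden2": [5]}
        b1, s1 = grid_search(df, grid, k=3, seed=7, base_params={"epochs": 5})
        b2, s2 = grid_search(df, grid, k=3, seed=7, base_params={"epochs": 5})
        assert b1 == b2
        pd.testing.assert_frame_equal(s1, s2)

    def test_class_thinner_than_folds_rejected(self):
        df, _, _ = blob_table(n=12)
        with pytest.raises(ValueError, match="stratification"):
            grid_search(df, {"hidden1": [5]}, k=10, base_params={"epochs": 1})


class TestOrdinalBaseline:
    def _table(self, x, y):
        df = pd.DataFrame({"qnet": x, "risk": y})
        return df

    def test_uninformative_feature_gives_class_frequencies(self):
        y = np.array(["high"] * 30 + ["intermediate"] * 50 + ["low"] * 20)
        df = self._table(np.full(100, 3.7), y)
        m = OrdinalRiskModel("qnet").fit(df)
        probs = m.predict_proba(df)
        np.testing.assert_allclose(probs[0], [0.3, 0.5, 0.2], atol=1e-3)
        assert abs(m.slope_) < 0.5

    def test_recovery_on_ordered_synthetic_feature(self):
        rng = np.random.default_rng(1)
        codes = np.repeat([0, 1, 2], 60)
        x = codes + rng.normal(0, 0.1, len(codes))
        y = np.array(CLASS_ORDER)[codes]
        m = OrdinalRiskModel("qnet").fit(self._table(x, y))
        assert m.slope_ > 0  # larger x pushes toward 'low' (higher category)
        assert np.mean(m.predict(self._table(x, y)) == y) >= 0.9

    def test_mle_dominates_null(self):
        rng = np.random.default_rng(2)
        codes = rng.integers(0, 3, 90)
        x = codes + rng.normal(0, 0.5, 90)
        df = self._table(x, np.array(CLASS_ORDER)[codes])
        m = OrdinalRiskModel("qnet").fit(df)
        null = OrdinalRiskModel("qnet")
        codes_arr = np.array([CLASS_ORDER.index(v) for v in df["risk"]])
        p = np.bincount(codes_arr, minlength=3) / len(df)
        null_ll = np.sum(np.log(p[codes_arr]))
        assert m.loglik_ >= null_ll - 1e-6

    def test_matches_statsmodels_oracle(self):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        rng = np.random.default_rng(3)
        codes = np.repeat([0, 1, 2], 50)
        x = codes + rng.normal(0, 0.8, len(codes))
        df = self._table(x, np.array(CLASS_ORDER)[codes])
        ours = OrdinalRiskModel("qnet").fit(df)
        cat = pd.Categorical.from_codes(codes, categories=list(CLASS_ORDER),
                                        ordered=True)
        sm = OrderedModel(cat.codes, x[:, None], distr="logit").fit(disp=False)
        assert ours.slope_ == pytest.approx(sm.params[0], rel=1e-3)
        assert ours.loglik_ == pytest.approx(sm.llf, rel=1e-6)

    def test_perfect_separation_flagged_and_capped(self):
        codes = np.repeat([0, 1, 2], 20)
        x = codes.astype(float) * 100.0  # perfectly separating
        df = self._table(x, np.array(CLASS_ORDER)[codes])
        with pytest.warns(UserWarning, match="cap"):
            m = OrdinalRiskModel("qnet").fit(df)
        assert m.separation_flagged_
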