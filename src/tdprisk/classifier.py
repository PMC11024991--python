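"""TdP risk classification: grid-searched feed-forward network and ordinal baseline.

:class:`RiskANNClassifier` is a scikit-learn-style estimator implementing the
study's small feed-forward network: nine standardized inputs, two hidden
layers with leaky-ReLU activation, an elastic (L1 + L2) penalty on the
first hidden layer's weights only, and a softmax output over the three
ordered risk classes (high, intermediate, low) trained by minibatch
RMSprop/Adam on categorical cross-entropy.  Hyperparameters are tuned by
exhaustive grid search under stratified k-fold cross-validation
(:func:`grid_search`).

:class:`OrdinalRiskModel` is the single-feature proportional-odds
(cumulative-logit) baseline: two ordered thresholds and one slope fitted by
maximum likelihood.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, softmax
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .biomarkers import FEATURE_NAMES, RISK_LEVELS

CLASS_ORDER = RISK_LEVELS  # ("high", "intermediate", "low"), fixed everywhere

# the hyperparameter grid of the study protocol
DEFAULT_GRID = dict(
    batch_size=[32, 64],
    optimizer=["rmsprop", "adam"],
    hidden1=[5, 6, 7],
    hidden2=[5, 6, 7],
    learning_rate=[0.1, 0.001, 0.01],
    leaky_alpha=[0.1, 0.01, 0.001, 0.2, 0.02, 0.002],
)

FORMAT_VERSION = 1


class DegenerateLabelError(ValueError):
    """Training data does not contain at least two classes."""


def _encode_labels(y):
    y = np.asarray(y)
    bad = set(np.unique(y)) - set(CLASS_ORDER)
    if bad:
        raise ValueError(f"unknown risk labels: {sorted(bad)}")
    codes = np.array([CLASS_ORDER.index(v) for v in y])
    if len(np.unique(codes)) < 2:
        raise DegenerateLabelError("training data contains fewer than two classes")
    return codes


class RiskANNClassifier(BaseEstimator, ClassifierMixin):
    """Two-hidden-layer softmax network for 3-class TdP risk.

    Parameters mirror the tuned grid.  ``l1``/``l2`` penalise the first
    hidden layer's weight matrix only.  Standardisation statistics are fit
    on the training rows inside ``fit``.  Deterministic given ``seed``.

    Attributes (post-fit)
    ---------------------
    classes_ : ndarray of class labels in fixed order (high, intermediate, low)
    center_, scale_ : per-feature standardisation statistics
    weights_ : list of (W, b) per layer
    loss_curve_ : per-epoch mean training loss
    """

    def __init__(self, hidden1=6, hidden2=5, leaky_alpha=0.1, learning_rate=0.001,
                 batch_size=32, optimizer="adam", l1=0.01, l2=0.01, epochs=200,
                 seed=0):
        self.hidden1 = hidden1
        self.hidden2 = hidden2
        self.leaky_alpha = leaky_alpha
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.optimizer = optimizer
        self.l1 = l1
        self.l2 = l2
        self.epochs = epochs
        self.seed = seed

    # -- core network ------------------------------------------------------

    def _leaky(self, z):
        return np.where(z > 0, z, self.leaky_alpha * z)

    def _leaky_grad(self, z):
        return np.where(z > 0, 1.0, self.leaky_alpha)

    def _forward(self, X):
        (W1, b1), (W2, b2), (W3, b3) = self.weights_
        z1 = X @ W1 + b1
        a1 = self._leaky(z1)
        z2 = a1 @ W2 + b2
        a2 = self._leaky(z2)
        logits = a2 @ W3 + b3
        return z1, a1, z2, a2, logits

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not np.all(np.isfinite(X)):
            rows = np.nonzero(~np.isfinite(X).all(axis=1))[0]
            raise ValueError(f"non-finite features at rows {rows.tolist()[:10]}")
        codes = _encode_labels(y)
        if len(codes) != len(X):
            raise ValueError("X and y length mismatch")
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array(CLASS_ORDER)
        self.center_ = X.mean(axis=0)
        scale = X.std(axis=0)
        self.scale_ = np.where(scale > 0, scale, 1.0)
        Xs = (X - self.center_) / self.scale_
        n, d = Xs.shape
        K = 3
        rng = np.random.default_rng(self.seed)

        def glorot(fan_in, fan_out):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=(fan_in, fan_out))

        sizes = [d, self.hidden1, self.hidden2, K]
        self.weights_ = [(glorot(a, b), np.zeros(b)) for a, b in zip(sizes, sizes[1:])]
        Y = np.eye(K)[codes]

        opt_state = [[(np.zeros_like(W), np.zeros_like(b)),
                      (np.zeros_like(W), np.zeros_like(b))] for W, b in self.weights_]
        t_step = 0
        self.loss_curve_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                t_step += 1
                losses.append(self._step(Xs[idx], Y[idx], opt_state, t_step))
            self.loss_curve_.append(float(np.mean(losses)))
        return self

    def _step(self, Xb, Yb, opt_state, t_step):
        m = len(Xb)
        z1, a1, z2, a2, logits = self._forward(Xb)
        P = softmax(logits, axis=1)
        eps = 1e-12
        (W1, b1), (W2, b2), (W3, b3) = self.weights_
        loss = -np.mean(np.sum(Yb * np.log(P + eps), axis=1))
        loss += self.l1 * np.abs(W1).sum() + self.l2 * np.square(W1).sum()

        dlogits = (P - Yb) / m
        gW3 = a2.T @ dlogits
        gb3 = dlogits.sum(axis=0)
        da2 = dlogits @ W3.T
        dz2 = da2 * self._leaky_grad(z2)
        gW2 = a1.T @ dz2
        gb2 = dz2.sum(axis=0)
        da1 = dz2 @ W2.T
        dz1 = da1 * self._leaky_grad(z1)
        gW1 = Xb.T @ dz1 + self.l1 * np.sign(W1) + 2.0 * self.l2 * W1
        gb1 = dz1.sum(axis=0)

        grads = [(gW1, gb1), (gW2, gb2), (gW3, gb3)]
        lr = self.learning_rate
        new_weights = []
        for (W, b), (gW, gb), state in zip(self.weights_, grads, opt_state):
            (mW, mb), (vW, vb) = state
            if self.optimizer == "adam":
                b1c, b2c = 0.9, 0.999
                mW[:] = b1c * mW + (1 - b1c) * gW
                mb[:] = b1c * mb + (1 - b1c) * gb
                vW[:] = b2c * vW + (1 - b2c) * gW**2
                vb[:] = b2c * vb + (1 - b2c) * gb**2
                corr1 = 1 - b1c**t_step
                corr2 = 1 - b2c**t_step
                W = W - lr * (mW / corr1) / (np.sqrt(vW / corr2) + 1e-8)
                b = b - lr * (mb / corr1) / (np.sqrt(vb / corr2) + 1e-8)
            elif self.optimizer == "rmsprop":
                rho = 0.9
                vW[:] = rho * vW + (1 - rho) * gW**2
                vb[:] = rho * vb + (1 - rho) * gb**2
                W = W - lr * gW / (np.sqrt(vW) + 1e-8)
                b = b - lr * gb / (np.sqrt(vb) + 1e-8)
            else:
                raise ValueError(f"unknown optimizer {self.optimizer!r}")
            new_weights.append((W, b))
        self.weights_ = new_weights
        return loss

    def predict_proba(self, X):
        check_is_fitted(self, "weights_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        Xs = (X - self.center_) / self.scale_
        logits = self._forward(Xs)[-1]
        return softmax(logits, axis=1)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    # -- serialization -----------------------------------------------------

    def save(self, path):
        check_is_fitted(self, "weights_")
        doc = {
            "format_version": FORMAT_VERSION,
            "config": self.get_params(),
            "class_order": list(CLASS_ORDER),
            "center": self.center_.tolist(),
            "scale": self.scale_.tolist(),
            "n_features": int(self.n_features_in_),
            "weights": [[W.tolist(), b.tolist()] for W, b in self.weights_],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path):
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format_version", 0) > FORMAT_VERSION:
            raise ValueError(
                f"model format version {doc['format_version']} is newer than "
                f"supported version {FORMAT_VERSION}"
            )
        model = cls(**doc["config"])
        model.classes_ = np.array(doc["class_order"])
        model.center_ = np.array(doc["center"])
        model.scale_ = np.array(doc["scale"])
        model.n_features_in_ = doc["n_features"]
        model.weights_ = [(np.array(W), np.array(b)) for W, b in doc["weights"]]
        model.loss_curve_ = []
        return model


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

def feature_matrix(df: pd.DataFrame, features=None):
    features = list(features or FEATURE_NAMES)
    return df[features].to_numpy(dtype=float), df["risk"].to_numpy()


def grid_search(train: pd.DataFrame, grid: dict | None = None, k: int = 10,
                seed: int = 0, base_params: dict | None = None,
                features=None):
    """Exhaustive grid search under stratified k-fold cross-validation.

    Every combination of the grid's value lists is scored by mean validation
    accuracy over k stratified folds (shuffled with ``seed``); ties break by
    enumeration order.  Returns ``(best_config_dict, scores_df)``.
    """
    grid = dict(grid or DEFAULT_GRID)
    if not grid or k < 2:
        raise ValueError("grid must be non-empty and k >= 2")
    X, y = feature_matrix(train, features)
    codes = _encode_labels(y)
    counts = np.bincount(codes, minlength=3)
    if (counts[counts > 0] < k).any():
        raise ValueError("a class has fewer rows than folds (stratification impossible)")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    keys = list(grid)
    rows = []
    best = None
    for combo in itertools.product(*(grid[kk] for kk in keys)):
        cfg = dict(zip(keys, combo))
        accs = []
        for tr, va in folds:
            clf = RiskANNClassifier(seed=seed, **{**(base_params or {}), **cfg})
            clf.fit(X[tr], y[tr])
            accs.append(float(np.mean(clf.predict(X[va]) == y[va])))
        score = float(np.mean(accs))
        rows.append({**cfg, "mean_val_accuracy": score})
        if best is None or score > best[0]:
            best = (score, cfg)
    return best[1], pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ordinal-logistic (proportional-odds) baseline
# ---------------------------------------------------------------------------

SLOPE_CAP = 20.0


@dataclass
class OrdinalFit:
    feature: str
    slope: float
    thresholds: tuple
    loglik: float
    separation_flagged: bool = False


class OrdinalRiskModel(BaseEstimator):
    """Single-feature proportional-odds model over high < intermediate < low.

    Cumulative-logit parameterisation: P(Y <= k | x) = sigmoid(c_k - beta*x)
    with two strictly ordered thresholds c_1 < c_2 and one slope beta,
    fitted by maximum likelihood.  When |beta| reaches the cap (perfect
    separation) the fit is flagged rather than rejected.
    """

    def __init__(self, feature: str):
        self.feature = feature

    @staticmethod
    def _nll(params, x, codes):
        beta, c1, log_gap = params
        c2 = c1 + np.exp(log_gap)
        eta1 = c1 - beta * x
        eta2 = c2 - beta * x
        p_le1 = expit(eta1)
        p_le2 = expit(eta2)
        p = np.select(
            [codes == 0, codes == 1, codes == 2],
            [p_le1, p_le2 - p_le1, 1.0 - p_le2],
        )
        return -np.sum(np.log(np.clip(p, 1e-12, None)))

    def fit(self, df: pd.DataFrame, y=None):
        if self.feature not in df.columns:
            raise KeyError(f"feature {self.feature!r} not in table")
        x = df[self.feature].to_numpy(dtype=float)
        codes = _encode_labels(df["risk"].to_numpy())
        # center/scale the covariate for a well-conditioned optimisation
        mu, sd = x.mean(), x.std()
        sd = sd if sd > 0 else 1.0
        xs = (x - mu) / sd
        p1 = np.mean(codes == 0)
        p12 = np.mean(codes <= 1)
        x0 = np.array([0.0, np.log(p1 / (1 - p1 + 1e-9) + 1e-9), 0.0])
        x0[2] = np.log(max(np.log((p12 + 1e-9) / (1 - p12 + 1e-9)) - x0[1], 0.5))
        res = minimize(
            self._nll, x0, args=(xs, codes), method="L-BFGS-B",
            bounds=[(-SLOPE_CAP, SLOPE_CAP), (-50, 50), (-10, 5)],
        )
        beta_s, c1_s, log_gap = res.x
        flagged = bool(abs(beta_s) >= SLOPE_CAP - 1e-6)
        if flagged:
            warnings.warn(
                f"ordinal fit of {self.feature!r}: slope at cap "
                f"(possible perfect separation)", UserWarning,
            )
        # back-transform to the raw covariate scale
        self.slope_ = float(beta_s / sd)
        c2_s = c1_s + np.exp(log_gap)
        self.thresholds_ = (float(c1_s + beta_s * mu / sd), float(c2_s + beta_s * mu / sd))
        self.loglik_ = float(-res.fun)
        self.separation_flagged_ = flagged
        self.result_ = OrdinalFit(self.feature, self.slope_, self.thresholds_,
                                  self.loglik_, flagged)
        return self

    def predict_proba(self, df: pd.DataFrame):
        check_is_fitted(self, "slope_")
        x = df[self.feature].to_numpy(dtype=float) if hasattr(df, "columns") \
            else np.asarray(df, dtype=float)
        c1, c2 = self.thresholds_
        p_le1 = expit(c1 - self.slope_ * x)
        p_le2 = expit(c2 - self.slope_ * x)
        return np.column_stack([p_le1, p_le2 - p_le1, 1.0 - p_le2])

    def predict(self, df):
        return np.array(CLASS_ORDER)[np.argmax(self.predict_proba(df), axis=1)]


def fit_ordinal_logistic(train: pd.DataFrame, feature: str) -> OrdinalRiskModel:
    """Functional wrapper: fit the proportional-odds baseline on one feature."""
    return OrdinalRiskModel(feature).fit(train)


def train_ann(train: pd.DataFrame, features=None, **config) -> RiskANNClassifier:
    """Functional wrapper: fit the network on a feature table."""
    X, y = feature_matrix(train, features)
    return RiskANNClassifier(**config).fit(X, y)
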