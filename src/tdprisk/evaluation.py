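"""Bootstrap evaluation protocol: per-class ROC/AUC, likelihood ratios, error CIs.

The protocol re-tests the trained classifier many times (10,000 at full
scale).  Each iteration draws exactly one biomarker sample per test drug,
scores the drawn rows, and computes one-vs-rest metrics per risk class:

* AUC from the class-probability ranking (concordance with ties counted
  half),
* sensitivity/specificity and the likelihood ratios
  LR+ = sens / (1 - spec) and LR- = (1 - sens) / spec from the argmax
  confusion counts (zero denominators are eps-clipped and flagged),
* the 3-class misclassification fraction.

Across iterations each metric is summarised by its median and empirical
[2.5th, 97.5th] percentiles; the mean classification error additionally
gets a normal-approximation interval mean +/- 1.96 * SD / sqrt(N) with
N = test drugs x samples per drug.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .biomarkers import FEATURE_NAMES, RISK_LEVELS

LR_EPS = 1e-6


class UndefinedMetricError(ValueError):
    """Metric undefined (single-class labels or empty positive/negative set)."""


def roc_auc(scores, labels) -> float:
    """One-vs-rest AUC as the rank-based concordance probability (ties half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC needs both positive and negative labels")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self):
        return self.tp + self.fp + self.tn + self.fn


def likelihood_ratios(c: ConfusionCounts):
    """(LR+, LR-, clipped_flag) from one-vs-rest confusion counts."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise UndefinedMetricError("empty positive or negative set")
    sens = c.tp / (c.tp + c.fn)
    spec = c.tn / (c.tn + c.fp)
    clipped = False
    one_minus_spec = 1.0 - spec
    if one_minus_spec == 0.0:
        one_minus_spec = LR_EPS
        clipped = True
    if spec == 0.0:
        spec_d = LR_EPS
        clipped = True
    else:
        spec_d = spec
    return sens / one_minus_spec, (1.0 - sens) / spec_d, clipped


def mean_error_ci(errors, n_total: int):
    """Normal-approximation CI for the mean error: mean +/- 1.96*SD/sqrt(N)."""
    errors = np.asarray(errors, dtype=float)
    if len(errors) < 2:
        raise ValueError("need at least two iterations")
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    mean = float(errors.mean())
    half = 1.96 * float(errors.std(ddof=0)) / np.sqrt(n_total)
    return mean, mean - half, mean + half


def _summary(values):
    q = np.percentile(values, [2.5, 50.0, 97.5])
    return {"median": float(q[1]), "p2.5": float(q[0]), "p97.5": float(q[2])}


@dataclass
class EvaluationSummary:
    per_class: dict              # class -> {metric -> {median, p2.5, p97.5}}
    mean_classification_error: float
    error_ci: tuple              # (low, high)
    n_iterations: int
    n_total: int
    per_iteration: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in RISK_LEVELS:
            for metric, s in self.per_class[cls].items():
                rows.append({"class": cls, "metric": metric, **s})
        rows.append({"class": "all", "metric": "mean_classification_error",
                     "median": self.mean_classification_error,
                     "p2.5": self.error_ci[0], "p97.5": self.error_ci[1]})
        return pd.DataFrame(rows)


def bootstrap_protocol(model, test: pd.DataFrame, n_iter: int = 10000,
                       seed: int = 0, features=None) -> EvaluationSummary:
    """Run the repeated one-sample-per-drug test protocol.

    ``model`` must expose ``predict_proba`` returning columns in the fixed
    class order (high, intermediate, low).  ``test`` is a feature table with
    drug, sample, features and risk columns.  Deterministic given ``seed``.
    """
    features = list(features or FEATURE_NAMES)
    drugs = sorted(test["drug"].unique())
    drug_risk = test.drop_duplicates("drug").set_index("drug")["risk"]
    present = set(drug_risk)
    missing = set(RISK_LEVELS) - present
    if missing:
        raise ValueError(f"test registry lacks risk classes: {sorted(missing)}")

    # score every test row once; iterations only re-index
    proba = model.predict_proba(test[features].to_numpy(dtype=float))
    drug_col = test["drug"].to_numpy()
    row_groups = [np.nonzero(drug_col == d)[0] for d in drugs]
    true_code = np.array([RISK_LEVELS.index(drug_risk[d]) for d in drugs])

    rng = np.random.default_rng(seed)
    n_drugs = len(drugs)
    draws = np.column_stack([
        g[rng.integers(0, len(g), size=n_iter)] for g in row_groups
    ])  # (n_iter, n_drugs) positional row indices
    P = proba[draws]                     # (n_iter, n_drugs, 3)
    pred = np.argmax(P, axis=2)          # (n_iter, n_drugs)

    per_iter = {"iteration": np.arange(n_iter)}
    per_class = {}
    err = np.mean(pred != true_code[None, :], axis=1)
    per_iter["error"] = err
    for k, cls in enumerate(RISK_LEVELS):
        is_pos = true_code == k          # (n_drugs,)
        n_pos, n_neg = int(is_pos.sum()), int((~is_pos).sum())
        scores = P[:, :, k]              # (n_iter, n_drugs)
        ranks = rankdata(scores, axis=1)
        auc = (ranks[:, is_pos].sum(axis=1) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
        pred_pos = pred == k
        tp = np.sum(pred_pos & is_pos[None, :], axis=1)
        fp = np.sum(pred_pos & ~is_pos[None, :], axis=1)
        fn = n_pos - tp
        tn = n_neg - fp
        sens = tp / n_pos
        spec = tn / n_neg
        lr_pos = sens / np.where(spec == 1.0, LR_EPS, 1.0 - spec)
        lr_neg = (1.0 - sens) / np.where(spec == 0.0, LR_EPS, spec)
        per_iter[f"auc_{cls}"] = auc
        per_iter[f"lr_pos_{cls}"] = lr_pos
        per_iter[f"lr_neg_{cls}"] = lr_neg
        per_class[cls] = {
            "auc": _summary(auc),
            "lr_pos": _summary(lr_pos),
            "lr_neg": _summary(lr_neg),
        }

    n_total = len(test)
    if n_iter >= 2:
        mean_err, lo, hi = mean_error_ci(err, n_total)
    else:  # single-draw base case: no spread to summarise
        mean_err = lo = hi = float(err.mean())
    return EvaluationSummary(
        per_class=per_class,
        mean_classification_error=mean_err,
        error_ci=(lo, hi),
        n_iterations=n_iter,
        n_total=n_total,
        per_iteration=pd.DataFrame(per_iter),
    )
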