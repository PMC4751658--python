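"""Prediction-accuracy metrics and the leave-one-out cross-validation driver.

Metrics follow the multinomial Brier-score convention: for sample i with
one-hot truth the score is sum_j (p_ij - [y_i = j])^2, averaged over samples —
it ranges from 0 (perfect) to 2 (all mass on a wrong class).  The scaled Brier
score sBS = 1 - BS / BS_baseline compares against the uniform-1/K baseline
(BS_baseline = (K-1)/K exactly); 0 means no better than uniform random
assignment, 1 means perfect, negative means worse than the baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geno_io import GenotypeMatrix, LabelVector
from .multiclass import OneVsAllThresholdClassifier, OneVsOneThresholdClassifier
from .threshold import ProbitGibbsClassifier, ThresholdModelSpec

logger = logging.getLogger(__name__)

__all__ = ["CVResult", "accuracy", "brier", "scaled_brier", "loo_cv"]

#: reduced chain defaults used inside each LOO fold for desk-scale feasibility
CV_N_ITER = 2000
CV_BURN_IN = 500


def accuracy(preds, truths) -> float:
    """Fraction of correct classifications."""
    preds = np.asarray(preds)
    truths = np.asarray(truths)
    if preds.shape != truths.shape:
        raise ValueError("preds and truths differ in length")
    return float(np.mean(preds == truths))


def _check_probs(probs, classes):
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2:
        raise ValueError("probs must be n x K")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must lie on the simplex")
    return probs


def brier(probs, truths, classes=None):
    """Total and per-class multinomial Brier score.

    Per-class scores average over the samples whose true class is that class.
    Returns ``(total, per_class_dict)``.
    """
    truths = np.asarray(truths)
    if classes is None:
        classes = np.unique(truths)
    probs = _check_probs(probs, classes)
    onehot = (truths[:, None] == np.asarray(classes)[None, :]).astype(float)
    per_sample = ((probs - onehot) ** 2).sum(axis=1)
    total = float(per_sample.mean())
    per_class = {c: float(per_sample[truths == c].mean())
                 if (truths == c).any() else np.nan for c in classes}
    return total, per_class


def scaled_brier(probs, truths, K=None, classes=None, baseline="uniform"):
    """sBS = 1 - BS / BS_baseline, per class and total.

    The default baseline predicts 1/K for every class, so BS_baseline equals
    (K-1)/K on every sample subset.  ``baseline="frequency"`` instead scores a
    predictor of the observed class frequencies.  Returns ``(total, per_class)``.
    """
    truths = np.asarray(truths)
    if classes is None:
        classes = np.unique(truths)
    classes = np.asarray(classes)
    if K is None:
        K = len(classes)
    probs = _check_probs(probs, classes)
    if baseline == "uniform":
        base = np.full((len(truths), K), 1.0 / K)
    elif baseline == "frequency":
        freqs = np.array([(truths == c).mean() for c in classes])
        base = np.tile(freqs, (len(truths), 1))
    else:
        raise ValueError("baseline must be 'uniform' or 'frequency'")
    bs_tot, bs_cls = brier(probs, truths, classes)
    bb_tot, bb_cls = brier(base, truths, classes)
    total = 1.0 - bs_tot / bb_tot
    per_class = {c: 1.0 - bs_cls[c] / bb_cls[c]
                 if np.isfinite(bs_cls[c]) and bb_cls[c] > 0 else np.nan
                 for c in classes}
    return float(total), per_class


@dataclass
class CVResult:
    """Per-sample predictions and aggregate metrics from cross-validation."""

    samples: list
    truths: np.ndarray
    probs: np.ndarray            # n x K on the simplex
    predicted: np.ndarray
    classes: list
    scheme: str

    def __post_init__(self):
        self.total_accuracy = accuracy(self.predicted, self.truths)
        self.per_class_accuracy = {
            c: accuracy(self.predicted[self.truths == c], self.truths[self.truths == c])
            for c in self.classes}
        self.total_brier, self.per_class_brier = brier(self.probs, self.truths,
                                                       self.classes)
        self.total_sbs, self.per_class_sbs = scaled_brier(self.probs, self.truths,
                                                          classes=self.classes)

    def summary(self) -> pd.DataFrame:
        """Per-class + Total table of Accuracy and sBS."""
        rows = [{"class": c,
                 "n": int((self.truths == c).sum()),
                 "accuracy": self.per_class_accuracy[c],
                 "sBS": self.per_class_sbs[c]} for c in self.classes]
        rows.append({"class": "Total", "n": len(self.truths),
                     "accuracy": self.total_accuracy, "sBS": self.total_sbs})
        return pd.DataFrame(rows)

    def predictions_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probs, columns=[f"p_{c}" for c in self.classes])
        df.insert(0, "sample_id", self.samples)
        df["true_class"] = self.truths
        df["predicted_class"] = self.predicted
        return df


def _make_multiclass(scheme, estimator, seed):
    if scheme == "ova":
        return OneVsAllThresholdClassifier(estimator=estimator, seed=seed)
    if scheme == "ovo_couple":
        return OneVsOneThresholdClassifier(estimator=estimator, seed=seed,
                                           coupling="couple")
    if scheme == "ovo_vote":
        return OneVsOneThresholdClassifier(estimator=estimator, seed=seed,
                                           coupling="vote")
    raise ValueError(f"unknown scheme {scheme!r}")


def loo_cv(g: GenotypeMatrix, labels: LabelVector, scheme: str = "ova",
           spec: ThresholdModelSpec | None = None, estimator=None,
           include_classes=None, exclude_classes=None, seed: int = 0,
           full_chains: bool = False) -> CVResult:
    """Leave-one-out cross-validation of a multinomial scheme.

    For every sample the multiclass model is retrained on the remainder — the
    binary estimators center features on their own training rows, so centering
    frequencies are recomputed per fold without leakage — and the left-out
    sample is predicted.  Classes can be restricted with ``include_classes`` /
    ``exclude_classes`` (the leave-a-breed-out design).  Unless
    ``full_chains`` or an explicit estimator/spec is given, a reduced chain
    (2000 iterations, 500 burn-in) is used inside each fold.
    """
    lab = labels.align(g.samples)
    keep = list(lab.classes)
    if include_classes is not None:
        keep = [c for c in keep if c in set(include_classes)]
    if exclude_classes is not None:
        keep = [c for c in keep if c not in set(exclude_classes)]
    idx, lab = lab.subset(keep)
    sample_pos = {s: i for i, s in enumerate(g.samples)}
    rows = np.array([sample_pos[s] for s in lab.sample_ids])
    X = g.impute_mean().dosage[rows]
    y = lab.labels
    counts = {c: int((y == c).sum()) for c in lab.classes}
    if min(counts.values()) < 2:
        bad = [c for c, n in counts.items() if n < 2]
        raise ValueError(f"class(es) {bad} have < 2 samples and cannot be "
                         "both trained on and tested")

    if estimator is None:
        spec = spec or ThresholdModelSpec(
            n_iter=30000 if full_chains else CV_N_ITER,
            burn_in=15000 if full_chains else CV_BURN_IN)
        estimator = ProbitGibbsClassifier(
            prior=spec.prior, n_iter=spec.n_iter, burn_in=spec.burn_in,
            thin=spec.thin, df_u=spec.df_u, scale_u=spec.scale_u, r2=spec.r2,
            pi_a=spec.pi_a, pi_b=spec.pi_b)

    n = len(y)
    K = lab.K
    probs = np.zeros((n, K))
    predicted = np.empty(n, dtype=y.dtype)
    for i in range(n):
        tr = np.delete(np.arange(n), i)
        model = _make_multiclass(scheme, estimator,
                                 seed=(int(seed) + 7919 * i) % (2 ** 31 - 1))
        model.fit(X[tr], y[tr])
        p = model.predict_proba(X[i:i + 1])[0]
        # order model classes to the label ordering
        order = [list(model.classes_).index(c) for c in lab.classes]
        probs[i] = p[order]
        predicted[i] = lab.classes[int(np.argmax(probs[i]))]
        logger.debug("loo fold %d/%d done", i + 1, n)
    # voting rows may be all-zero-sum-normalized already in predict_proba
    probs = probs / probs.sum(axis=1, keepdims=True)
    return CVResult(list(lab.sample_ids), y, probs, predicted,
                    list(lab.classes), scheme)
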