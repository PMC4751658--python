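"""Multinomial classifiers assembled from binary contrasts.

Two decomposition schemes are provided.  One-vs-all (OVA) trains K binary
classifiers of each class against the pooled remainder; class probabilities are
the normalized binary success probabilities.  One-vs-one (OVO) trains one
classifier per class pair; class probabilities come either from the voting
counting measure or from pairwise coupling: the pairwise conditionals
p_kk' ~ p_k / (p_k + p_k') are combined by solving the Markov fixed point
p = Q p on the simplex, which inverts the relation exactly when the table is
consistent.

Also here: multinomial breeding values — the expected offspring class fractions
of a selection candidate from class-specific OVA effect vectors, a base
population's allele frequencies, and the gamete-transmission factor 0.5 on the
candidate's centered genotype.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.utils.validation import check_array, check_is_fitted

from .threshold import ProbitGibbsClassifier

logger = logging.getLogger(__name__)

__all__ = [
    "PairwiseProbTable",
    "ClassProbVector",
    "BreedingValueResult",
    "OneVsAllThresholdClassifier",
    "OneVsOneThresholdClassifier",
    "train_ova",
    "train_ovo",
    "normalize_ova",
    "vote_ovo",
    "couple_ovo",
    "classify",
    "breeding_values",
]

CLIP = 1e-6


@dataclass
class PairwiseProbTable:
    """K x K table with entries p_kk' = Pr(class k | class in {k, k'}).

    Rows/columns follow ``classes``; the diagonal is unused.  Construction
    enforces p_kk' + p_k'k = 1 and clips entries to [CLIP, 1-CLIP].
    """

    values: np.ndarray
    classes: list = None

    def __post_init__(self):
        P = np.asarray(self.values, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("pairwise table must be square")
        K = P.shape[0]
        if self.classes is None:
            self.classes = list(range(K))
        iu = np.triu_indices(K, k=1)
        if not np.allclose(P[iu] + P.T[iu], 1.0, atol=1e-8):
            raise ValueError("pairwise probabilities must satisfy p_kk' + p_k'k = 1")
        P = np.clip(P, CLIP, 1.0 - CLIP)
        P[iu] = 1.0 - P.T[iu]  # keep the complement exact after clipping
        np.fill_diagonal(P, 0.0)
        self.values = P

    @property
    def K(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_true_p(cls, p, classes=None) -> "PairwiseProbTable":
        """Forward map of a simplex vector through p_kk' = p_k/(p_k+p_k')."""
        p = np.asarray(p, dtype=float)
        K = len(p)
        P = np.zeros((K, K))
        for k, l in itertools.combinations(range(K), 2):
            P[k, l] = p[k] / (p[k] + p[l])
            P[l, k] = 1.0 - P[k, l]
        return cls(P, classes)


@dataclass
class ClassProbVector:
    """Point on the K-simplex of class probabilities."""

    p: np.ndarray
    classes: list = None

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-6):
            raise ValueError("class probabilities must be nonnegative and sum to 1")
        self.p = p
        if self.classes is None:
            self.classes = list(range(len(p)))

    @property
    def K(self) -> int:
        return len(self.p)


@dataclass
class BreedingValueResult:
    """Expected offspring class fractions p_n and deviations g_n = p_n - p_0."""

    p_n: np.ndarray
    p_0: np.ndarray
    classes: list
    f: np.ndarray = field(repr=False, default=None)

    @property
    def g_n(self) -> np.ndarray:
        return self.p_n - self.p_0


# ---------------------------------------------------------------------------
# combination rules
# ---------------------------------------------------------------------------

def normalize_ova(binary_probs, classes=None) -> ClassProbVector:
    """Normalize the K OVA success probabilities onto the simplex."""
    v = np.clip(np.asarray(binary_probs, dtype=float), CLIP, 1.0 - CLIP)
    return ClassProbVector(v / v.sum(), classes)


def vote_ovo(pp: PairwiseProbTable) -> tuple[ClassProbVector, object]:
    """Counting-measure probabilities p_k = 2/(K(K-1)) * #pairwise wins.

    A pairing is won when p_kk' > p_k'k.  Exact ties at 0.5 credit neither
    side.  The predicted class is the argmax, breaking ties toward the lowest
    class index (logged).
    """
    P = pp.values
    K = pp.K
    wins = ((P > P.T) & ~np.eye(K, dtype=bool)).sum(axis=1)
    p = 2.0 * wins / (K * (K - 1))
    best = int(np.argmax(p))
    if (p == p[best]).sum() > 1:
        logger.warning("vote_ovo: tie between classes %s, choosing %r",
                       [pp.classes[i] for i in np.where(p == p[best])[0]],
                       pp.classes[best])
    cpv = ClassProbVector.__new__(ClassProbVector)  # may not sum to 1 with ties
    cpv.p = p
    cpv.classes = list(pp.classes)
    return cpv, pp.classes[best]


def _coupling_matrix(P: np.ndarray) -> np.ndarray:
    """Q with off-diagonal p_kk'/(K-1) and diagonal sum_{l!=k} p_kl / (K-1)."""
    K = P.shape[0]
    Q = P / (K - 1)
    np.fill_diagonal(Q, P.sum(axis=1) / (K - 1))
    return Q


def couple_ovo(pp: PairwiseProbTable, tol: float = 1e-10,
               max_iter: int = 10000) -> ClassProbVector:
    """Solve the pairwise-coupling fixed point p = Q p on the simplex.

    Q is column-stochastic, so p is the stationary vector of a Markov chain
    with strictly positive transition matrix: it exists and is unique.  The
    normalized linear system [(I - Q); 1'] p = (0, ..., 0, 1)' is solved by
    least squares, with power iteration as a fallback.  When the table is
    consistent with some simplex vector through p_kk' = p_k/(p_k + p_k'), that
    vector is recovered exactly.
    """
    P = pp.values
    K = pp.K
    Q = _coupling_matrix(P)
    A = np.vstack([np.eye(K) - Q, np.ones((1, K))])
    rhs = np.zeros(K + 1)
    rhs[-1] = 1.0
    p, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    if np.all(p > 0) and np.linalg.norm(Q @ p - p) < 1e-8:
        return ClassProbVector(p / p.sum(), list(pp.classes))
    # fallback: power iteration on the positive column-stochastic Q
    p = np.full(K, 1.0 / K)
    for _ in range(max_iter):
        p_new = Q @ p
        p_new /= p_new.sum()
        if np.max(np.abs(p_new - p)) < tol:
            return ClassProbVector(p_new, list(pp.classes))
        p = p_new
    resid = float(np.linalg.norm(Q @ p - p))
    raise RuntimeError(f"pairwise coupling did not converge (residual {resid:.2e})")


def classify(cpv: ClassProbVector):
    """Argmax class; ties break toward the lowest index with a warning."""
    best = int(np.argmax(cpv.p))
    if (cpv.p == cpv.p[best]).sum() > 1:
        logger.warning("classify: probability tie, choosing %r", cpv.classes[best])
    return cpv.classes[best]


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _default_base():
    return ProbitGibbsClassifier()


class _MultiBase(ClassifierMixin, BaseEstimator):
    def __init__(self, estimator=None, seed=0):
        self.estimator = estimator
        self.seed = seed

    def _base(self):
        return self.estimator if self.estimator is not None else _default_base()

    def _seeded_clone(self, offset):
        est = clone(self._base())
        params = est.get_params()
        if "seed" in params:
            est.set_params(seed=(int(self.seed) + offset) % (2 ** 31 - 1))
        elif "random_state" in params:
            est.set_params(random_state=(int(self.seed) + offset) % (2 ** 31 - 1))
        return est

    def predict(self, X, W=None):
        proba = self.predict_proba(X, W=W)
        return self.classes_[np.argmax(proba, axis=1)]


class OneVsAllThresholdClassifier(_MultiBase):
    """K binary fits of class k against the pooled complement.

    ``predict_proba`` normalizes the K binary success probabilities.  OVA
    contrasts are almost always unbalanced; a warning is logged when the
    positive class is below a third of the training samples.
    """

    def fit(self, X, y, W=None):
        X = check_array(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        counts = {c: int((y == c).sum()) for c in self.classes_}
        if min(counts.values()) == 0:  # pragma: no cover - np.unique precludes
            raise ValueError("empty class")
        if min(counts.values()) < len(y) / (3 * len(self.classes_)):
            logger.warning("OVA: strongly unbalanced contrasts (counts %s)", counts)
        self.estimators_ = []
        for k, c in enumerate(self.classes_):
            est = self._seeded_clone(k)
            # y in {0,1}: 1 = membership of class c; np.unique orders 0 < 1
            est.fit(X, (y == c).astype(int), **({"W": W} if W is not None else {}))
            self.estimators_.append(est)
        return self

    def binary_proba(self, X, W=None):
        check_is_fitted(self, "estimators_")
        cols = []
        for est in self.estimators_:
            kw = {"W": W} if W is not None else {}
            cols.append(est.predict_proba(X, **kw)[:, 1])
        return np.column_stack(cols)

    def predict_proba(self, X, W=None):
        B = self.binary_proba(X, W=W)
        return np.vstack([normalize_ova(row).p for row in B])


class OneVsOneThresholdClassifier(_MultiBase):
    """K(K-1)/2 pairwise binary fits combined by coupling or voting.

    ``coupling="couple"`` solves the p = Qp fixed point per sample (the
    default); ``coupling="vote"`` uses the counting measure.  A sample from an
    untrained class is still scored by every pairing — the coupling absorbs the
    inconsistency.
    """

    def __init__(self, estimator=None, seed=0, coupling="couple"):
        super().__init__(estimator=estimator, seed=seed)
        self.coupling = coupling

    def fit(self, X, y, W=None):
        if self.coupling not in ("couple", "vote"):
            raise ValueError("coupling must be 'couple' or 'vote'")
        X = check_array(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        self.pair_estimators_ = {}
        for t, (a, b) in enumerate(itertools.combinations(range(len(self.classes_)), 2)):
            ca, cb = self.classes_[a], self.classes_[b]
            mask = (y == ca) | (y == cb)
            if min((y == ca).sum(), (y == cb).sum()) < 2:
                logger.warning("OVO: pair (%r, %r) has a class with < 2 samples", ca, cb)
            est = self._seeded_clone(t)
            # binary response: 1 = first class of the pair
            kw = {"W": np.asarray(W)[mask]} if W is not None else {}
            est.fit(X[mask], (y[mask] == ca).astype(int), **kw)
            self.pair_estimators_[(a, b)] = est
        return self

    def pairwise_tables(self, X, W=None):
        """One PairwiseProbTable per prediction sample."""
        check_is_fitted(self, "pair_estimators_")
        n = X.shape[0]
        K = len(self.classes_)
        tables = np.zeros((n, K, K))
        for (a, b), est in self.pair_estimators_.items():
            kw = {"W": W} if W is not None else {}
            if hasattr(est, "predict_proba"):
                pa = est.predict_proba(X, **kw)[:, 1]
            else:  # label-only backend (e.g. max-margin): 0/1 votes
                pa = (np.asarray(est.predict(X)) == 1).astype(float)
            tables[:, a, b] = pa
            tables[:, b, a] = 1.0 - pa
        return [PairwiseProbTable(tables[i], list(self.classes_)) for i in range(n)]

    def predict_proba(self, X, W=None):
        out = []
        for tab in self.pairwise_tables(X, W=W):
            if self.coupling == "vote":
                cpv, _ = vote_ovo(tab)
                p = cpv.p
                p = p / p.sum() if p.sum() > 0 else np.full(tab.K, 1.0 / tab.K)
            else:
                p = couple_ovo(tab).p
            out.append(p)
        return np.asarray(out)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def train_ova(X, y, estimator=None, seed=0, W=None) -> OneVsAllThresholdClassifier:
    return OneVsAllThresholdClassifier(estimator=estimator, seed=seed).fit(X, y, W=W)


def train_ovo(X, y, estimator=None, seed=0, coupling="couple",
              W=None) -> OneVsOneThresholdClassifier:
    return OneVsOneThresholdClassifier(estimator=estimator, seed=seed,
                                       coupling=coupling).fit(X, y, W=W)


# ---------------------------------------------------------------------------
# multinomial breeding values
# ---------------------------------------------------------------------------

def breeding_values(z_n, f, ova_fit: OneVsAllThresholdClassifier,
                    w_bar=None, p_0=None) -> BreedingValueResult:
    """Expected offspring class fractions for a selection candidate.

    Per class k the numerator is Phi(w_bar' b_k + 0.5 (z_n - 2f)' u_k - delta_k)
    evaluated at the posterior-mean effect vectors of the k-th OVA fit; the K
    numerators are normalized.  The 0.5 halves the candidate's centered
    genotype — one transmitted gamete.  g_n = p_n - p_0 sums to zero whenever
    p_0 lies on the simplex.
    """
    check_is_fitted(ova_fit, "estimators_")
    z_n = np.asarray(z_n, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any((f <= 0) | (f >= 1)):
        raise ValueError("base allele frequencies must lie in (0, 1)")
    K = len(ova_fit.classes_)
    if p_0 is None:
        p_0 = np.full(K, 1.0 / K)
    p_0 = np.asarray(p_0, dtype=float)
    if not np.isclose(p_0.sum(), 1.0, atol=1e-6):
        raise ValueError("p_0 must lie on the simplex")
    num = np.empty(K)
    for k, est in enumerate(ova_fit.estimators_):
        if z_n.shape[0] != est.n_features_in_:
            raise ValueError("candidate marker vector does not match the fits")
        b_k, u_k = est.posterior_mean_effects()
        wb = float(np.dot(w_bar, b_k)) if w_bar is not None else float(b_k[0])
        # u_k was trained on features centered at est.feature_means_;
        # the candidate is centered at the base frequencies as printed
        num[k] = ndtr(wb + 0.5 * float((z_n - 2.0 * f) @ u_k) - est.delta_)
    p_n = num / num.sum()
    return BreedingValueResult(p_n, p_0, list(ova_fit.classes_), f)
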