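"""Pluggable binary-classifier backends and feature-source selection.

Every backend is a scikit-learn style binary classifier: ``fit(X, y)`` plus
either ``predict_proba`` (probabilistic backends, usable in all schemes) or
``predict`` only (label-only backends such as the max-margin adapter, usable
in one-vs-one voting).  The registry maps CLI names to constructors; the
max-margin entry is a thin adapter over an established SVM implementation with
library-default tuning.
"""

from __future__ import annotations

import numpy as np
from sklearn.svm import SVC

from .geno_io import GenotypeMatrix, PedigreeTable
from .relmat import center_markers, chol_lower, grm, nrm
from .threshold import ProbitGibbsClassifier

__all__ = ["BACKENDS", "register_backend", "get_backend", "feature_source",
           "LabelOnlySVM"]


class LabelOnlySVM(SVC):
    """Linear max-margin backend with default tuning; votes, no probabilities.

    Subclasses the reference implementation only to pin the linear kernel and
    accept (and ignore) the ``seed`` parameter the multiclass drivers set.
    """

    def __init__(self, seed=0, C=1.0):
        super().__init__(kernel="linear", C=C)
        self.seed = seed

    # deterministic: no predict_proba on purpose (voting only)
    predict_proba = property(doc="intentionally absent; label-only backend")


BACKENDS: dict = {}


def register_backend(name: str, constructor) -> None:
    """Register a binary-classifier constructor under a unique name."""
    if name in BACKENDS:
        raise ValueError(f"backend {name!r} already registered")
    BACKENDS[name] = constructor


def get_backend(name: str, **kwargs):
    if name not in BACKENDS:
        raise KeyError(f"unknown backend {name!r}; known: {sorted(BACKENDS)}")
    return BACKENDS[name](**kwargs)


register_backend("ridge", lambda **kw: ProbitGibbsClassifier(prior="ridge", **kw))
register_backend("bayes_a", lambda **kw: ProbitGibbsClassifier(prior="bayes_a", **kw))
register_backend("bayes_c_pi",
                 lambda **kw: ProbitGibbsClassifier(prior="bayes_c_pi", **kw))
register_backend("svm", lambda **kw: LabelOnlySVM(**{k: v for k, v in kw.items()
                                                     if k in ("seed", "C")}))


def feature_source(mode: str, g: GenotypeMatrix | None = None,
                   ped: PedigreeTable | None = None,
                   sample_ids=None):
    """Build the named training feature matrix.

    ``markers``  — centered gene content M (the default regression features),
    ``chol_A``   — lower Cholesky factor of the pedigree numerator matrix,
                   rows restricted/ordered to ``sample_ids`` after factorizing
                   the full pedigree,
    ``grm_rows`` — each sample's row of the genomic relationship matrix
                   (the relationship kernel's empirical feature map).

    Returns ``(X, meta)`` with provenance metadata.
    """
    if mode == "markers":
        if g is None:
            raise ValueError("markers mode needs genotypes")
        cm = center_markers(g)
        return cm.M, {"mode": mode, "n_features": cm.M.shape[1],
                      "centering": "sample frequencies"}
    if mode == "chol_A":
        if ped is None:
            raise ValueError("chol_A mode needs a pedigree")
        A = nrm(ped)
        L = chol_lower(A)
        if sample_ids is not None:
            pos = {s: i for i, s in enumerate(A.samples)}
            rows = [pos[s] for s in sample_ids]
            L = L[rows]
        return L, {"mode": mode, "n_features": L.shape[1], "kind": "pedigree"}
    if mode == "grm_rows":
        if g is None:
            raise ValueError("grm_rows mode needs genotypes")
        G = grm(center_markers(g))
        return np.asarray(G.values), {"mode": mode, "n_features": G.n,
                                      "kind": "genomic"}
    raise ValueError(f"unknown feature source {mode!r}")
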