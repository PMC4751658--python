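"""Relationship matrices: VanRaden genomic G, pedigree numerator A, factorizations.

G = M M' / sum_i 2 p_i (1 - p_i), with M the gene-content matrix centered at
2p per marker.  A is built with the tabular method in topological pedigree
order.  Both carry an eigendecomposition cache used by the population-structure
analyses and by the relationship-factor parameterization of the animal model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .geno_io import GenotypeMatrix, LabelVector, PedigreeTable

logger = logging.getLogger(__name__)

__all__ = [
    "CenteredMarkerMatrix",
    "RelationshipMatrix",
    "EigenBasis",
    "center_markers",
    "grm",
    "nrm",
    "eigen",
    "chol_lower",
    "relationship_summary",
]


@dataclass
class CenteredMarkerMatrix:
    """Centered gene content M = dosage - 2f and the VanRaden denominator."""

    M: np.ndarray
    f: np.ndarray
    samples: list
    markers: list

    @property
    def denom(self) -> float:
        return float(np.sum(2.0 * self.f * (1.0 - self.f)))


@dataclass
class RelationshipMatrix:
    values: np.ndarray
    kind: str  # {"genomic", "pedigree"}
    samples: list

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("relationship matrix must be square")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("relationship matrix must be symmetric")
        self.values = 0.5 * (v + v.T)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.samples)


@dataclass
class EigenBasis:
    """Eigenvectors U and eigenvalues d (decreasing) of a relationship matrix.

    ``cumvar`` accumulates the nonnegative eigenvalues only; small negative
    numerical eigenvalues are excluded from the variance total.
    """

    U: np.ndarray
    d: np.ndarray
    samples: list

    @property
    def cumvar(self) -> np.ndarray:
        pos = np.maximum(self.d, 0.0)
        tot = pos.sum()
        if tot == 0:
            return np.zeros_like(pos)
        return np.cumsum(pos) / tot


def center_markers(g: GenotypeMatrix, f: np.ndarray | None = None) -> CenteredMarkerMatrix:
    """Center gene content at 2f per marker.

    With sample-based f (default), monomorphic markers contribute zero columns
    and are excluded from the denominator.  Externally supplied f (e.g. from a
    training subset during cross-validation) must be interior in (0,1).
    """
    dosage = np.asarray(g.dosage, dtype=float)
    if not np.isfinite(dosage).all():
        g = g.impute_mean()
        dosage = g.dosage
    if f is None:
        f = dosage.mean(axis=0) / 2.0
    else:
        f = np.asarray(f, dtype=float)
        if f.shape != (g.n_markers,):
            raise ValueError("external frequencies must have one entry per marker")
        if np.any((f <= 0.0) | (f >= 1.0)):
            if not np.any((f > 0.0) & (f < 1.0)):
                raise ValueError("all external frequencies are degenerate (0 or 1)")
            raise ValueError("external centering frequencies must lie in (0, 1)")
    M = dosage - 2.0 * f
    return CenteredMarkerMatrix(M, f, list(g.samples), list(g.markers))


def grm(cm: CenteredMarkerMatrix) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix G = MM' / sum 2 p (1-p)."""
    denom = cm.denom
    if denom <= 0:
        raise ValueError("degenerate VanRaden denominator (no polymorphic markers)")
    G = cm.M @ cm.M.T / denom
    return RelationshipMatrix(G, "genomic", list(cm.samples))


def nrm(ped: PedigreeTable) -> RelationshipMatrix:
    """Numerator relationship matrix A via the tabular method.

    Founders get diagonal 1; a_ii = 1 + 0.5 a(sire, dam); a_ij for j earlier in
    topological order is the mean of j's relationships to i's parents.
    """
    order = ped.topological_order()
    parents = ped.parents()
    idx = {ind: k for k, ind in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for k, ind in enumerate(order):
        s, d = parents[ind]
        si = idx.get(s) if s is not None else None
        di = idx.get(d) if d is not None else None
        for j in range(k):
            a_sj = A[si, j] if si is not None else 0.0
            a_dj = A[di, j] if di is not None else 0.0
            A[k, j] = A[j, k] = 0.5 * (a_sj + a_dj)
        if si is not None and di is not None:
            A[k, k] = 1.0 + 0.5 * A[si, di]
        else:
            A[k, k] = 1.0
    # return in the pedigree's own record order
    perm = [idx[i] for i in ped.ids]
    return RelationshipMatrix(A[np.ix_(perm, perm)], "pedigree", list(ped.ids))


def eigen(R: RelationshipMatrix) -> EigenBasis:
    """Eigendecomposition with eigenvalues sorted in decreasing order."""
    d, U = np.linalg.eigh(R.values)
    order = np.argsort(d)[::-1]
    return EigenBasis(U[:, order], d[order], list(R.samples))


def chol_lower(R: RelationshipMatrix, jitter: float = 1e-8) -> np.ndarray:
    """Lower Cholesky factor L with L L' = R, used as a feature matrix.

    Adds ``jitter`` * I (logged) when the matrix is not numerically positive
    definite — pedigree A and sample-centered G are only PSD in general.
    """
    try:
        return np.linalg.cholesky(R.values)
    except np.linalg.LinAlgError:
        logger.info("chol_lower: adding jitter %.1e to the diagonal", jitter)
    try:
        return np.linalg.cholesky(R.values + jitter * np.eye(R.n))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"relationship matrix not positive definite after jitter {jitter:g}"
        ) from exc


def eigen_features(R: RelationshipMatrix, drop_last: bool = True,
                   scaling: str = "standardized",
                   tol: float = 1e-10) -> tuple[np.ndarray, EigenBasis]:
    """Eigenvector feature matrix for regression on a relationship matrix.

    ``scaling="standardized"`` (default) rescales the orthonormal eigenvectors
    to unit sample variance (a uniform factor sqrt(n): the eigenvectors of a
    sample-centered G are orthogonal to the constant, so their means are 0).
    Equal column variances give every eigenvector the same prior footing in a
    variable-selection model — variance-selection then reflects alignment with
    the response only.  ``scaling="sqrt_d"`` multiplies by sqrt(eigenvalue)
    instead, the parameterization for which an iid ridge prior reproduces the
    animal model var(Zu) = R * sigma2_u; it is unsuitable for spike-slab
    inclusion analysis because near-null-eigenvalue columns become penalty-free.

    The last column is dropped by default (a sample-centered G has the constant
    as a null vector, so rank <= n-1); eigenvalues below ``tol`` * leading are
    dropped too, with a log line.
    """
    eb = eigen(R)
    d = np.maximum(eb.d, 0.0)
    k = eb.U.shape[1] - 1 if drop_last else eb.U.shape[1]
    keep = np.where(d[:k] > tol * max(d[0], 1e-300))[0]
    if len(keep) < k:
        logger.info("eigen_features: dropped %d near-null column(s)", k - len(keep))
    if scaling == "standardized":
        Z = eb.U[:, keep] * np.sqrt(eb.U.shape[0])
    elif scaling == "sqrt_d":
        Z = eb.U[:, keep] * np.sqrt(d[keep])
    else:
        raise ValueError("scaling must be 'standardized' or 'sqrt_d'")
    return Z, eb


def relationship_summary(R: RelationshipMatrix, labels: LabelVector) -> pd.DataFrame:
    """K x K table of mean (SD) of pairwise relationships, diagonal excluded.

    Within-class cells use off-diagonal entries among that class's samples;
    a class with fewer than 2 samples gets a missing within-class entry.
    """
    lab = labels.align(R.samples)
    pos = {s: i for i, s in enumerate(R.samples)}
    members = {c: [pos[s] for s, l in zip(lab.sample_ids, lab.labels) if l == c]
               for c in lab.classes}
    rows = []
    for a in lab.classes:
        for b in lab.classes:
            ia, ib = members[a], members[b]
            if a == b:
                if len(ia) < 2:
                    rows.append((a, b, np.nan, np.nan, 0))
                    continue
                block = R.values[np.ix_(ia, ia)]
                vals = block[np.triu_indices(len(ia), k=1)]
            else:
                vals = R.values[np.ix_(ia, ib)].ravel()
            rows.append((a, b, float(np.mean(vals)),
                         float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                         len(vals)))
    return pd.DataFrame(rows, columns=["class_a", "class_b", "mean", "sd", "n_pairs"])
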