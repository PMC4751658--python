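"""Population-divergence statistics: F_ST, eigenvector inclusion (pEV), and
liability-scale heritability of subpopulation assignment.

F_ST is the ratio of between-subpopulation allele-frequency variance to a
heterozygosity-based total.  The default pairwise estimator is a
moment/ANOVA estimator on allele counts (Weir-Cockerham style): the
sampling-noise contribution is subtracted from the between-group mean square,
so the per-marker estimate is unbiased for the generative divergence and
equals exactly 1 at opposing fixation — at the price of occasional slightly
negative per-marker values (order 1/(2n)) when sample frequencies coincide.
The uncorrected Wright plug-in ratio is available via ``corrected=False``
(with a flag for the factor-2 heterozygosity convention).

The global estimator fits, per marker, a one-way random-effects model on gene
content (profile REML) and maps the variance ratio back to the
allele-frequency scale: between-group variance in gene content is 4 var(p_k)
and within-group binomial variance is ~2 p(1-p), so
F = (sigma2_a/4) / (sigma2_a/4 + sigma2_e/2).

pEV regresses subpopulation assignment on the eigenvectors of the two-class
genomic relationship matrix under a spike-slab (BayesC-pi) probit model and
reports the posterior mean proportion of eigenvectors with non-zero effect;
nEV = pEV * (N-1).  Strongly diverged pairs need ~1 eigenvector (small pEV);
entangled pairs need many.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .geno_io import GenotypeMatrix, LabelVector, class_frequencies
from .relmat import RelationshipMatrix, center_markers, chol_lower, eigen_features, grm
from .threshold import ProbitGibbsClassifier, ThresholdModelSpec

logger = logging.getLogger(__name__)

__all__ = ["FstResult", "PevResult", "fst_pairwise", "fst_global",
           "pev_analysis", "h2_subpop"]

#: chain defaults for the eigenvector-inclusion and heritability samplers
PEV_N_ITER = 60000
PEV_BURN_IN = 20000


@dataclass
class FstResult:
    markers: list
    fst: np.ndarray
    sigma2_alpha: np.ndarray
    sigma2_eps: np.ndarray
    scope: str

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.fst))

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.fst, ddof=1))

    @property
    def ratio_of_sums(self) -> float:
        """Multi-locus aggregate: sums of components before the ratio."""
        num = np.nansum(self.sigma2_alpha)
        den = np.nansum(self.sigma2_alpha + self.sigma2_eps)
        return float(num / den) if den > 0 else np.nan


@dataclass
class PevResult:
    pev: float
    n_samples: int
    inclusion_prob: np.ndarray
    pi_mean: float
    pi_samples: np.ndarray
    fit: ProbitGibbsClassifier

    @property
    def nev(self) -> float:
        return self.pev * (self.n_samples - 1)


def _class_counts_freqs(g: GenotypeMatrix, labels: LabelVector, classes):
    cf = class_frequencies(g, labels)
    lab = labels.align(g.samples)
    counts, freqs = [], []
    for c in classes:
        n_c = int((lab.labels == c).sum())
        if n_c == 0:
            raise ValueError(f"class {c!r} is empty")
        counts.append(n_c)
        freqs.append(cf[c].to_numpy())
    return np.asarray(counts), np.vstack(freqs)


def fst_pairwise(g: GenotypeMatrix, labels: LabelVector, class_k, class_kp,
                 corrected: bool = True,
                 denominator: str = "wright") -> FstResult:
    """Per-marker F_ST between two classes.

    With ``corrected=True`` (default) the allele-count ANOVA estimator is
    used: MSB/MSW on 2n_k allele counts, sigma2_alpha = (MSB - MSW)/n_c,
    F = sigma2_alpha / (sigma2_alpha + MSW).  With ``corrected=False`` the
    plug-in ratio of the sample-size-weighted between-class variance to
    p_bar(1-p_bar) (``denominator="wright"``) or 2 p_bar (1-p_bar)
    (``denominator="heterozygosity"``) is returned.
    """
    counts, freqs = _class_counts_freqs(g, labels, [class_k, class_kp])
    m_all = 2 * counts  # allele counts per class
    p = freqs
    pbar = (m_all[:, None] * p).sum(axis=0) / m_all.sum()
    poly = (pbar > 0) & (pbar < 1)

    if corrected:
        K = 2
        M = m_all.sum()
        ssb = (m_all[:, None] * (p - pbar) ** 2).sum(axis=0)
        msb = ssb / (K - 1)
        ssw = (m_all[:, None] * p * (1 - p)).sum(axis=0)
        msw = ssw / (M - K)
        n_c = (M - (m_all ** 2).sum() / M) / (K - 1)
        s2a = (msb - msw) / n_c
        s2e = msw
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where(poly, s2a / (s2a + s2e), 0.0)
        # opposing fixation: msw = 0, ratio = 1 exactly
        fst = np.where(poly & (s2a + s2e == 0), 0.0, fst)
    else:
        w = m_all / m_all.sum()
        s2a = (w[:, None] * (p - pbar) ** 2).sum(axis=0)
        het = pbar * (1 - pbar)
        if denominator == "heterozygosity":
            het = 2 * het
        elif denominator != "wright":
            raise ValueError("denominator must be 'wright' or 'heterozygosity'")
        s2e = het
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where(poly, s2a / s2e, 0.0)
    return FstResult(list(g.markers), fst, s2a, s2e,
                     scope=f"pairwise({class_k},{class_kp})")


def _reml_oneway(y_groups):
    """Profile REML of y_gi = mu + alpha_g + e; returns (s2_alpha, s2_eps).

    1-D optimization over the log variance ratio lambda = s2a/s2e; mu and s2e
    are profiled out in closed form.
    """
    n_g = np.array([len(v) for v in y_groups], dtype=float)
    ybar = np.array([v.mean() for v in y_groups])
    ssw = float(sum(((v - v.mean()) ** 2).sum() for v in y_groups))
    N = n_g.sum()
    G = len(y_groups)

    def neg2_reml(log_lam):
        lam = np.exp(log_lam)
        d = 1.0 + n_g * lam          # group-mean variance scale / s2e
        w = n_g / d
        mu = (w * ybar).sum() / w.sum()
        # y'P y with V = s2e (I + lam Z Z')
        quad = ssw + (n_g * (ybar - mu) ** 2 / d).sum()
        s2e = quad / (N - 1)
        val = (N - 1) * np.log(s2e) + np.log(d).sum() + np.log(w.sum())
        return val

    res = minimize_scalar(neg2_reml, bounds=(-18.0, 12.0), method="bounded",
                          options={"xatol": 1e-8})
    lam = float(np.exp(res.x))
    d = 1.0 + n_g * lam
    w = n_g / d
    mu = (w * ybar).sum() / w.sum()
    quad = ssw + (n_g * (ybar - mu) ** 2 / d).sum()
    s2e = quad / (N - 1)
    return lam * s2e, s2e


def fst_global(g: GenotypeMatrix, labels: LabelVector) -> FstResult:
    """Global per-marker F_ST from a one-way random-effects fit on gene content.

    For each marker, gene content = mean + random subpopulation effect +
    residual is fitted by profile REML; the variance ratio is mapped to the
    allele-frequency scale, F = (s2a/4) / (s2a/4 + s2e/2).  Monomorphic
    markers are excluded (NaN) with a warning count.
    """
    if labels.K < 2:
        raise ValueError("need K >= 2 classes")
    lab = labels.align(g.samples)
    pos = {s: i for i, s in enumerate(g.samples)}
    rows = {c: [pos[s] for s, l in zip(lab.sample_ids, lab.labels) if l == c]
            for c in lab.classes}
    dosage = g.impute_mean().dosage
    m = g.n_markers
    fst = np.full(m, np.nan)
    s2a_arr = np.full(m, np.nan)
    s2e_arr = np.full(m, np.nan)
    n_mono = 0
    for j in range(m):
        col = dosage[:, j]
        if np.var(col) == 0:
            n_mono += 1
            continue
        groups = [col[rows[c]] for c in lab.classes]
        s2a, s2e = _reml_oneway(groups)
        s2a_arr[j], s2e_arr[j] = s2a, s2e
        fst[j] = (s2a / 4.0) / (s2a / 4.0 + s2e / 2.0)
    if n_mono:
        logger.warning("fst_global: %d monomorphic marker(s) excluded", n_mono)
    return FstResult(list(g.markers), fst, s2a_arr, s2e_arr, scope="global")


def _two_class_subset(g: GenotypeMatrix, labels: LabelVector, class_k, class_kp):
    lab = labels.align(g.samples)
    idx, lab2 = lab.subset([class_k, class_kp])
    pos = {s: i for i, s in enumerate(g.samples)}
    rows = [pos[s] for s in lab2.sample_ids]
    return g.subset(sample_idx=rows), lab2


def pev_analysis(g_or_R, labels: LabelVector, class_k=None, class_kp=None,
                 spec: ThresholdModelSpec | None = None) -> PevResult:
    """Eigenvector-inclusion analysis of a two-class genomic relationship matrix.

    Fits a BayesC-pi probit model with the (sqrt-eigenvalue scaled)
    eigenvectors of G_kk' as features and returns the posterior mean
    proportion of eigenvectors with non-zero effect (pEV), the per-eigenvector
    inclusion probabilities, and nEV = pEV * (N-1).
    """
    if isinstance(g_or_R, RelationshipMatrix):
        R = g_or_R
        lab = labels.align(R.samples)
        if lab.K != 2:
            raise ValueError("pev_analysis needs exactly two classes")
    else:
        if class_k is None or class_kp is None:
            lab = labels.align(g_or_R.samples)
            if lab.K != 2:
                raise ValueError("pass class_k/class_kp or two-class labels")
            class_k, class_kp = lab.classes
        g2, lab = _two_class_subset(g_or_R, labels, class_k, class_kp)
        R = grm(center_markers(g2))
    N = R.n
    if N < 4:
        raise ValueError("need at least 4 samples")
    Z, _ = eigen_features(R, drop_last=True)
    spec = spec or ThresholdModelSpec(prior="bayes_c_pi", n_iter=PEV_N_ITER,
                                      burn_in=PEV_BURN_IN)
    if spec.prior != "bayes_c_pi":
        raise ValueError("pev_analysis requires the spike-slab prior")
    clf = ProbitGibbsClassifier(
        prior="bayes_c_pi", n_iter=spec.n_iter, burn_in=spec.burn_in,
        thin=spec.thin, seed=spec.seed, df_u=spec.df_u, scale_u=spec.scale_u,
        r2=spec.r2, pi_a=spec.pi_a, pi_b=spec.pi_b, center=False)
    clf.fit(Z, lab.codes())
    n_cols = Z.shape[1]
    # realized proportion of non-zero effects per kept draw, out of N-1
    # regression columns (near-null columns dropped from Z count as zero)
    prop = (clf.u_samples_ != 0.0).sum(axis=1) / (N - 1)
    pev = float(prop.mean())
    incl = np.zeros(N - 1)
    incl[:n_cols] = clf.inclusion_prob_
    return PevResult(pev, N, incl, float(clf.pi_samples_.mean()),
                     clf.pi_samples_, clf)


def h2_subpop(g_or_R, labels: LabelVector, class_k=None, class_kp=None,
              mode: str = "marker",
              spec: ThresholdModelSpec | None = None):
    """Liability-scale heritability of the trait "subpopulation assignment".

    Fits a probit animal model on two classes via the lower Cholesky factor of
    the relationship matrix (G for ``mode="marker"``, A for
    ``mode="pedigree"``) with a common-variance (ridge) prior, so sigma2_u is
    the additive variance; h2 = sigma2_a / (sigma2_a + 1).  Returns
    ``(mean, sd, fit)``.
    """
    if mode not in ("marker", "pedigree"):
        raise ValueError("mode must be 'marker' or 'pedigree'")
    if isinstance(g_or_R, RelationshipMatrix):
        lab = labels.align(g_or_R.samples)
        if lab.K != 2:
            _, lab = lab.subset([class_k, class_kp])
        # restrict to the labelled samples in label order (a pedigree A often
        # carries ancestors without subpopulation labels)
        pos = {s: i for i, s in enumerate(g_or_R.samples)}
        rows = [pos[s] for s in lab.sample_ids]
        R = RelationshipMatrix(g_or_R.values[np.ix_(rows, rows)], g_or_R.kind,
                               list(lab.sample_ids))
    else:
        if class_k is None or class_kp is None:
            lab = labels.align(g_or_R.samples)
            if lab.K != 2:
                raise ValueError("pass class_k/class_kp or two-class labels")
            class_k, class_kp = lab.classes
        g2, lab = _two_class_subset(g_or_R, labels, class_k, class_kp)
        R = grm(center_markers(g2))
    L = chol_lower(R)
    spec = spec or ThresholdModelSpec(prior="ridge", n_iter=PEV_N_ITER,
                                      burn_in=PEV_BURN_IN)
    clf = ProbitGibbsClassifier(
        prior=spec.prior, n_iter=spec.n_iter, burn_in=spec.burn_in,
        thin=spec.thin, seed=spec.seed, df_u=spec.df_u, scale_u=spec.scale_u,
        r2=spec.r2, center=False, relationship_factor=True)
    clf.fit(L, lab.codes())
    mean, sd = clf.heritability()
    return mean, sd, clf
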