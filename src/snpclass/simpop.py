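"""Synthetic populations with Balding-Nichols divergence, admixture and half-sib
family structure.

The generator states a small world mirroring a multi-breed SNP study: K
subpopulations whose per-marker allele frequencies diverge from a shared
ancestral frequency under the Balding-Nichols Beta model at a target F, an
optional admixed fraction drawing alleles from two parent populations, and
half-sib families from shared sires (each offspring gets a fresh dam, as in
typical horse pedigrees where nearly every dam is unique).  Markers are
simulated unlinked: the downstream methods act on relationship and frequency
structure, which the model captures without LD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geno_io import GenotypeMatrix, LabelVector, PedigreeTable

__all__ = ["SimSpec", "SimResult", "simulate", "simulate_liability_trait"]

F_MIN = 1e-6  # Beta parameters overflow below this


@dataclass
class SimSpec:
    """Stated world for one simulated dataset.

    Defaults give a desk-scale four-class study in the shape of the motivating
    application (four breeds with unequal sizes, the rarest far smaller), with
    modest divergence F = 0.05 and 1000 unlinked markers.
    """

    K: int = 4
    n_per_class: tuple = (60, 70, 45, 12)
    m: int = 1000
    F: float | tuple = 0.05
    ancestral_freq_range: tuple = (0.05, 0.95)
    admixture: tuple | None = None  # (class_a, class_b, lam, mix)
    n_sires: int = 0                # 0 -> unrelated founders
    offspring_per_sire: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if len(self.n_per_class) != self.K:
            raise ValueError("n_per_class must have K entries")
        if any(n < 1 for n in self.n_per_class):
            raise ValueError("class sizes must be positive")
        F = np.broadcast_to(np.asarray(self.F, dtype=float), (self.K,)).copy()
        if np.any(F >= 1):
            raise ValueError("F must lie in (0, 1)")
        self.F = tuple(np.clip(F, F_MIN, None))
        if self.admixture is not None:
            a, b, lam, mix = self.admixture
            if not (0 <= lam <= 1 and 0 <= mix <= 1):
                raise ValueError("admixture lambda and mix must lie in [0, 1]")


@dataclass
class SimResult:
    genotypes: GenotypeMatrix
    labels: LabelVector
    pedigree: PedigreeTable | None
    truth: dict = field(repr=False)


def _gamete(genotype_row: np.ndarray, rng) -> np.ndarray:
    """One transmitted allele per marker from a diploid 0/1/2 genotype."""
    return rng.binomial(1, genotype_row / 2.0)


def simulate(spec: SimSpec) -> SimResult:
    """Draw genotypes, labels, a pedigree and the generative truth record."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=spec.m)

    subpop_freq = np.empty((spec.K, spec.m))
    for k, F in enumerate(spec.F):
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        subpop_freq[k] = np.clip(rng.beta(a, b), 1e-12, 1.0 - 1e-12)

    samples, labels, dosage_rows, ped_records = [], [], [], []
    ancestry = {}

    for k in range(spec.K):
        cls = f"C{k + 1}"
        freq_k = subpop_freq[k]
        n_k = spec.n_per_class[k]
        if spec.n_sires > 0:
            sires = []
            for s in range(spec.n_sires):
                sid = f"{cls}_sire{s + 1}"
                ped_records.append((sid, None, None))
                sires.append((sid, rng.binomial(2, freq_k)))
            made = 0
            while made < n_k:
                sid, sire_geno = sires[(made // spec.offspring_per_sire) % len(sires)]
                iid = f"{cls}_ind{made + 1}"
                did = f"{cls}_dam{made + 1}"  # fresh dam per offspring
                dam_geno = rng.binomial(2, freq_k)
                geno = _gamete(sire_geno, rng) + _gamete(dam_geno, rng)
                ped_records.append((did, None, None))
                ped_records.append((iid, sid, did))
                samples.append(iid)
                labels.append(cls)
                dosage_rows.append(geno.astype(float))
                ancestry[iid] = {cls: 1.0}
                made += 1
        else:
            for i in range(n_k):
                iid = f"{cls}_ind{i + 1}"
                ped_records.append((iid, None, None))
                samples.append(iid)
                labels.append(cls)
                dosage_rows.append(rng.binomial(2, freq_k).astype(float))
                ancestry[iid] = {cls: 1.0}

    dosage = np.vstack(dosage_rows)
    labels = np.asarray(labels)

    if spec.admixture is not None:
        a, b, lam, mix = spec.admixture
        ca, cb = f"C{a + 1}", f"C{b + 1}"
        cand = np.where(labels == ca)[0]
        n_adm = int(round(lam * len(cand)))
        chosen = rng.choice(cand, size=n_adm, replace=False)
        for i in chosen:
            # each allele drawn from class b's frequencies with probability mix
            src_b = rng.random((2, spec.m)) < mix
            alleles = np.where(src_b,
                               rng.random((2, spec.m)) < subpop_freq[b],
                               rng.random((2, spec.m)) < subpop_freq[a])
            dosage[i] = alleles.sum(axis=0).astype(float)
            ancestry[samples[i]] = {ca: 1.0 - mix, cb: mix}

    g = GenotypeMatrix(samples, [f"M{j + 1}" for j in range(spec.m)], dosage)
    # a single-population world has no class structure to label
    lab = LabelVector(list(samples), labels) if spec.K >= 2 else None
    ped = PedigreeTable(ped_records) if ped_records else None
    truth = {
        "ancestral_freq": p_anc,
        "subpop_freq": subpop_freq,
        "F": spec.F,
        "ancestry": ancestry,
        "seed": spec.seed,
    }
    return SimResult(g, lab, ped, truth)


def simulate_liability_trait(g: GenotypeMatrix, h2: float, seed: int = 0):
    """Binary labels from a liability model at in-sample heritability h2.

    Marker effects are Gaussian, rescaled so var(Zu) / (var(Zu) + 1) = h2 on
    the centered genotypes; liability = Zu + N(0, 1); labels by sign.  Returns
    ``(y, truth)`` with the liabilities, effects and genetic values recorded.
    """
    if not (0 <= h2 < 1):
        raise ValueError("h2 must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    dosage = g.impute_mean().dosage
    Z = dosage - dosage.mean(axis=0)
    u = rng.normal(size=g.n_markers)
    gvals = Z @ u
    if h2 > 0:
        vg = np.var(gvals, ddof=1)
        scale = np.sqrt((h2 / (1.0 - h2)) / vg) if vg > 0 else 0.0
        u *= scale
        gvals *= scale
    else:
        u[:] = 0.0
        gvals[:] = 0.0
    liability = gvals + rng.normal(size=g.n_samples)
    y = (liability > 0).astype(int)
    truth = {"u": u, "genetic_values": gvals, "liability": liability,
             "h2": h2, "seed": seed}
    return y, truth
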