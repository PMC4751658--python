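"""Genotype, label and pedigree I/O with the QC filters used throughout the package.

Genotypes are handled as *gene content*: the per-marker count (0/1/2) of a
counted allele in a diploid genotype.  Three on-disk dialects are supported —
VCF (GT field only, counted allele = ALT), PLINK text ``.ped``/``.map`` pairs
(counted allele = minor allele) and a plain dosage TSV (stored as-is).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # sentinel for missing gene content in integer storage

__all__ = [
    "GenotypeMatrix",
    "LabelVector",
    "PedigreeTable",
    "QCReport",
    "read_genotypes",
    "read_labels",
    "read_pedigree",
    "read_covariates",
    "write_dosage_tsv",
    "qc_filter",
    "scan_opposing_fixation",
]


class GenotypeParseError(ValueError):
    """Raised when a genotype file does not parse under the named dialect."""


@dataclass
class GenotypeMatrix:
    """n x m gene-content matrix with sample/marker metadata.

    Parameters
    ----------
    samples : list of str
        Unique sample identifiers, row order of ``dosage``.
    markers : list of str
        Unique marker identifiers, column order of ``dosage``.
    dosage : ndarray of float, shape (n, m)
        Gene content in {0, 1, 2}; missing entries are ``nan``.
    chrom, pos : optional arrays of per-marker chromosome / position.
    """

    samples: list
    markers: list
    dosage: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be a 2-D array")
        n, m = self.dosage.shape
        if n < 1 or m < 1:
            raise ValueError("need at least one sample and one marker")
        if len(self.samples) != n or len(self.markers) != m:
            raise ValueError("sample/marker ID lengths do not match dosage shape")
        if len(set(self.samples)) != n:
            raise ValueError("sample IDs are not unique")
        if len(set(self.markers)) != m:
            raise ValueError("marker IDs are not unique")
        # observed calls are 0/1/2 (parsers enforce the exact domain); after
        # mean imputation entries are fractional but stay within [0, 2]
        finite = self.dosage[np.isfinite(self.dosage)]
        if finite.size and ((finite < 0).any() or (finite > 2).any()):
            bad = finite[(finite < 0) | (finite > 2)][0]
            raise GenotypeParseError(f"dosage value {bad!r} outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    @property
    def freq(self) -> np.ndarray:
        """Counted-allele frequency per marker, over non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosage, axis=0) / 2.0

    @property
    def call_rate(self) -> np.ndarray:
        return np.isfinite(self.dosage).mean(axis=0)

    def impute_mean(self) -> "GenotypeMatrix":
        """Replace missing dosages by 2*freq (frequency preserving)."""
        d = self.dosage.copy()
        f = self.freq
        miss = ~np.isfinite(d)
        if miss.any():
            d[miss] = np.broadcast_to(2.0 * f, d.shape)[miss]
        return GenotypeMatrix(list(self.samples), list(self.markers), d,
                              self.chrom, self.pos)

    def subset(self, sample_idx=None, marker_idx=None) -> "GenotypeMatrix":
        s = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        m = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypeMatrix(
            [self.samples[i] for i in s],
            [self.markers[j] for j in m],
            self.dosage[np.ix_(s, m)],
            None if self.chrom is None else self.chrom[m],
            None if self.pos is None else self.pos[m],
        )


@dataclass
class LabelVector:
    """Sample-to-class map with an ordered list of K >= 2 distinct classes."""

    sample_ids: list
    labels: np.ndarray
    classes: list = field(default=None)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("sample_ids and labels differ in length")
        if self.classes is None:
            self.classes = sorted(set(self.labels.tolist()))
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        unknown = set(self.labels.tolist()) - set(self.classes)
        if unknown:
            raise ValueError(f"labels not in class list: {unknown}")

    @property
    def K(self) -> int:
        return len(self.classes)

    def codes(self) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.classes)}
        return np.array([lut[v] for v in self.labels.tolist()])

    def align(self, sample_ids) -> "LabelVector":
        """Reorder to a genotype matrix's sample order; every label must exist there."""
        lut = dict(zip(self.sample_ids, self.labels.tolist()))
        missing = [s for s in self.sample_ids if s not in set(sample_ids)]
        if missing:
            raise ValueError(f"labelled samples absent from genotypes: {missing[:5]}")
        ids = [s for s in sample_ids if s in lut]
        return LabelVector(ids, np.array([lut[s] for s in ids]), list(self.classes))

    def subset(self, keep_classes) -> tuple[np.ndarray, "LabelVector"]:
        keep = [c for c in self.classes if c in set(keep_classes)]
        mask = np.isin(self.labels, keep)
        idx = np.where(mask)[0]
        return idx, LabelVector([self.sample_ids[i] for i in idx],
                                self.labels[idx], keep)


@dataclass
class PedigreeTable:
    """(id, sire, dam) records; unknown parents are None."""

    records: list  # list of (id, sire|None, dam|None)

    def __post_init__(self):
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("pedigree IDs are not unique")
        self._order = None
        self.topological_order()  # raises on cycles

    @property
    def ids(self):
        return [r[0] for r in self.records]

    def parents(self) -> dict:
        return {r[0]: (r[1], r[2]) for r in self.records}

    def topological_order(self) -> list:
        """Founders-first ordering; raises on a pedigree loop."""
        if self._order is not None:
            return self._order
        par = self.parents()
        order, state = [], {}

        def visit(i, stack):
            if i is None or i not in par:
                return
            if state.get(i) == 2:
                return
            if state.get(i) == 1:
                raise ValueError(f"pedigree cycle involving individual {i!r}")
            state[i] = 1
            for p in par[i]:
                visit(p, stack)
            state[i] = 2
            order.append(i)

        for i in par:
            visit(i, [])
        self._order = order
        return order


@dataclass
class QCReport:
    """Markers removed by qc_filter, with the reason for each."""

    removed: dict  # marker id -> reason string
    n_in: int
    n_out: int
    n_imputed: int

    def summary(self) -> str:
        return (f"{self.n_in} markers in, {self.n_out} retained, "
                f"{len(self.removed)} removed, {self.n_imputed} genotypes imputed")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise GenotypeParseError(f"cannot parse dosage TSV {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise GenotypeParseError(f"{path}: zero usable markers")
    vals = df.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    bad = finite[~np.isin(finite, [0.0, 1.0, 2.0])]
    if bad.size:
        # name the offending line for the user
        rows = np.where(~np.isin(np.nan_to_num(vals, nan=0.0), [0.0, 1.0, 2.0]).all(axis=1))[0]
        raise GenotypeParseError(
            f"{path}: dosage value {bad[0]!r} outside {{0,1,2}} at data line {rows[0] + 2}")
    return GenotypeMatrix([str(s) for s in df.index], [str(c) for c in df.columns], vals)


def _read_vcf(path: Path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF requires cyvcf2") from exc
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    markers, chroms, poss, rows = [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        mid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        markers.append(mid)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        gt = np.asarray(var.gt_types, dtype=float)  # 0,1,2, 3=missing under gts012
        gt[gt == 3] = np.nan
        rows.append(gt)
    if n_multi:
        logger.warning("skipped %d multiallelic VCF record(s) in %s", n_multi, path)
    if not markers:
        raise GenotypeParseError(f"{path}: zero usable markers")
    dosage = np.column_stack(rows)
    return GenotypeMatrix(samples, markers, dosage,
                          np.asarray(chroms), np.asarray(poss, dtype=int))


def _read_plink_text(path: Path) -> GenotypeMatrix:
    """PLINK .ped/.map text pair; counted allele is the minor allele."""
    path = Path(path)
    stem = path.with_suffix("")
    ped, mp = stem.with_suffix(".ped"), stem.with_suffix(".map")
    if not ped.exists() or not mp.exists():
        raise GenotypeParseError(f"missing PLINK text pair for {stem}")
    mdf = pd.read_csv(mp, sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos"])
    markers = [str(x) for x in mdf["id"]]
    m = len(markers)
    samples, allele_rows = [], []
    with open(ped) as fh:
        for ln, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * m:
                raise GenotypeParseError(
                    f"{ped}: line {ln} has {len(tok)} fields, expected {6 + 2 * m}")
            samples.append(tok[1])
            allele_rows.append(tok[6:])
    alleles = np.asarray(allele_rows, dtype=object)
    a1 = alleles[:, 0::2]
    a2 = alleles[:, 1::2]
    dosage = np.full((len(samples), m), np.nan)
    for j in range(m):
        col = np.concatenate([a1[:, j], a2[:, j]])
        obs = col[col != "0"]
        uniq, counts = np.unique(obs, return_counts=True)
        if len(uniq) > 2:
            raise GenotypeParseError(f"{ped}: marker {markers[j]} is multiallelic")
        if len(uniq) == 0:
            continue
        minor = uniq[np.argmin(counts)] if len(uniq) == 2 else uniq[0]
        miss = (a1[:, j] == "0") | (a2[:, j] == "0")
        dosage[:, j] = (a1[:, j] == minor).astype(float) + (a2[:, j] == minor)
        dosage[miss, j] = np.nan
    return GenotypeMatrix(samples, markers, dosage,
                          mdf["chrom"].to_numpy(), mdf["pos"].to_numpy())


def read_genotypes(path, format: str = "dosage_tsv") -> GenotypeMatrix:
    """Read a genotype matrix from ``vcf``, ``plink_text`` or ``dosage_tsv``."""
    path = Path(path)
    if not path.exists() and format != "plink_text":
        raise FileNotFoundError(path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink_text":
        return _read_plink_text(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_dosage_tsv(g: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(g.dosage, index=g.samples, columns=g.markers)
    df.to_csv(path, sep="\t", na_rep="NA")


def read_labels(path) -> LabelVector:
    """Labels CSV with header ``sample_id,class``."""
    df = pd.read_csv(path, dtype=str)
    if not {"sample_id", "class"}.issubset(df.columns):
        raise ValueError(f"{path}: expected header sample_id,class")
    return LabelVector(df["sample_id"].tolist(), df["class"].to_numpy())


def read_pedigree(path) -> PedigreeTable:
    """Pedigree CSV with header ``id,sire,dam``; '0' or empty = unknown."""
    df = pd.read_csv(path, dtype=str).fillna("0")
    if not {"id", "sire", "dam"}.issubset(df.columns):
        raise ValueError(f"{path}: expected header id,sire,dam")
    recs = [(r["id"],
             None if r["sire"] in ("0", "") else r["sire"],
             None if r["dam"] in ("0", "") else r["dam"])
            for _, r in df.iterrows()]
    return PedigreeTable(recs)


def read_covariates(path, sample_ids=None) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if sample_ids is not None:
        df = df.loc[list(sample_ids)]
    return df


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_filter(g: GenotypeMatrix, maf_min: float = 0.05,
              geno_rate_min: float = 0.90,
              autosomes_only: bool = False,
              impute: bool = True) -> tuple[GenotypeMatrix, QCReport]:
    """Remove low-MAF and low-call-rate markers; mean-impute what remains.

    A marker is dropped when min(p, 1-p) < ``maf_min`` (strict, so ties at the
    threshold are kept) or its call rate < ``geno_rate_min``.  Surviving
    missing dosages are imputed to 2*freq, which contributes exactly zero to
    centered covariates and leaves the allele frequency unchanged.
    """
    if not (0 <= maf_min <= 1) or not (0 <= geno_rate_min <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    removed = {}
    keep = np.ones(g.n_markers, dtype=bool)
    if autosomes_only and g.chrom is not None:
        sex = np.isin(np.char.upper(np.asarray(g.chrom, dtype=str)),
                      ["X", "Y", "CHRX", "CHRY", "MT", "CHRM"])
        for j in np.where(sex)[0]:
            removed[g.markers[j]] = "non-autosomal"
        keep &= ~sex
    cr = g.call_rate
    f = g.freq
    low_cr = cr < geno_rate_min
    with np.errstate(invalid="ignore"):
        maf = np.fmin(f, 1.0 - f)
    low_maf = ~np.isfinite(maf) | (maf < maf_min)
    for j in np.where(keep & low_cr)[0]:
        removed[g.markers[j]] = f"call rate {cr[j]:.3f} < {geno_rate_min}"
    for j in np.where(keep & ~low_cr & low_maf)[0]:
        removed[g.markers[j]] = f"MAF {maf[j]:.4f} < {maf_min}"
    keep &= ~(low_cr | low_maf)
    if not keep.any():
        raise ValueError("QC removed every marker")
    out = g.subset(marker_idx=np.where(keep)[0])
    n_missing = int((~np.isfinite(out.dosage)).sum())
    if impute and n_missing:
        out = out.impute_mean()
    report = QCReport(removed, g.n_markers, out.n_markers,
                      n_imputed=n_missing if impute else 0)
    logger.info("qc_filter: %s", report.summary())
    return out, report


def class_frequencies(g: GenotypeMatrix, labels: LabelVector) -> pd.DataFrame:
    """Per-class counted-allele frequencies (non-missing calls only)."""
    lab = labels.align(g.samples)
    rows = {}
    sample_pos = {s: i for i, s in enumerate(g.samples)}
    for c in lab.classes:
        idx = [sample_pos[s] for s, l in zip(lab.sample_ids, lab.labels) if l == c]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rows[c] = np.nanmean(g.dosage[idx], axis=0) / 2.0
    return pd.DataFrame(rows, index=g.markers)


def scan_opposing_fixation(g: GenotypeMatrix, labels: LabelVector) -> list:
    """Markers fixed for opposite alleles in at least one class pair.

    A marker is reported iff some class has counted-allele frequency exactly 0
    and another exactly 1 (computed over non-missing calls).
    """
    cf = class_frequencies(g, labels)
    vals = cf.to_numpy()
    with np.errstate(invalid="ignore"):
        any0 = (vals == 0.0).any(axis=1)
        any1 = (vals == 1.0).any(axis=1)
    return [g.markers[j] for j in np.where(any0 & any1)[0]]
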