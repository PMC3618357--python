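"""Burrows composite linkage disequilibrium between locus pairs.

For unphased diploid genotypes the gametic phase is unknown, so two-locus
association is measured by the Burrows composite disequilibrium

    delta_jk = P_jk - 2 p_j q_k,

where ``P_jk`` is the per-individual composite count of (j, k) pairings (in
[0, 2]) and p_j, q_k are the sample allele frequencies on the jointly typed
subset.  The squared phi correlation

    r^2_jk = delta_jk^2 / ([p(1-p) + D_A][q(1-q) + D_B])

uses Hardy-Weinberg-deviation-corrected variances with D the homozygote
excess f(jj) - p^2.  With the per-individual divisor, r_jk is algebraically
identical to the Pearson correlation of allele dosages, a property the test
suite exploits as an independent oracle.

By default delta carries the classical small-sample factor n/(n-1) of the
composite-disequilibrium estimator; the sampling expectation
E[r^2] = 1/S + 3.19/S^2 subtracted downstream is calibrated for that
corrected estimator, and omitting the factor would bias small-sample Ne
estimates upward.  ``small_sample=False`` gives the raw moment estimator
(for which r^2 is exactly the squared dosage correlation, in [0, 1]).

The weighted mean of r^2 over retained allele pairs (allele frequencies >=
Pcrit at both loci) is the raw ingredient of the effective-population-size
estimator; each pair is weighted by its jointly typed sample size n_AB, and
the effective sample size is the harmonic mean of n_AB over retained locus
pairs.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, locus_dosage

_DEN_EPS = 1e-12


@dataclass
class GenotypePairCounts:
    """Counts of the four genotype classes containing at least one A_j and
    one B_k, over individuals typed at both loci (n_ab)."""

    x_jjkk: int        # A_j A_j  B_k B_k
    x_jjkk_star: int   # A_j A_j  B_k B_k*
    x_jjstar_kk: int   # A_j A_j* B_k B_k
    x_jjstar_kkstar: int  # A_j A_j* B_k B_k* (double heterozygote)
    n_ab: int


@dataclass
class AllelePairLD:
    """Burrows composite LD for one allele pair at one locus pair."""

    p_a: float
    p_b: float
    d_a: float
    d_b: float
    delta: float
    r2: float
    n_ab: int
    defined: bool


@dataclass
class LocusPairRecord:
    """Per-locus-pair contribution retained for jackknifing."""

    locus_a: str
    locus_b: str
    n_ab: int
    n_allele_pairs: int
    sum_r2: float

    @property
    def weight(self) -> float:
        return self.n_ab * self.n_allele_pairs

    @property
    def weighted_sum(self) -> float:
        return self.n_ab * self.sum_r2


@dataclass
class LDSummary:
    """Filtered, weighted mean r^2 and its sampling correction."""

    mean_r2: float
    s_eff: float
    e_sample_r2: float
    r2_prime: float
    pcrit: float
    n_pairs_retained: int       # allele pairs
    n_locus_pairs: int          # locus pairs contributing
    n_undefined: int            # allele pairs excluded for zero variance
    records: list[LocusPairRecord] = field(default_factory=list)
    divisor: str = "individuals"

    def leave_one_out_means(self) -> np.ndarray:
        """Weighted mean r^2 with each locus pair deleted in turn."""
        w = np.array([r.weight for r in self.records], dtype=float)
        s = np.array([r.weighted_sum for r in self.records], dtype=float)
        tot_w, tot_s = w.sum(), s.sum()
        if len(self.records) < 2 or np.any(tot_w - w <= 0):
            raise ValueError("need >= 2 locus pairs for leave-one-out means")
        return (tot_s - s) / (tot_w - w)


def _joint_subset(gm: GenotypeMatrix, locus_a, locus_b):
    ia, ib = gm.locus_index(locus_a), gm.locus_index(locus_b)
    if ia == ib:
        raise ValueError("within-locus disequilibrium is not defined here")
    typed = gm.typed
    joint = typed[:, ia] & typed[:, ib]
    return ia, ib, joint


def count_genotype_pairs(gm: GenotypeMatrix, locus_a, locus_b,
                         allele_j, allele_k) -> GenotypePairCounts:
    """Classify jointly typed individuals into the four (j, k) genotype
    classes used by the composite-count formula."""
    ia, ib, joint = _joint_subset(gm, locus_a, locus_b)
    a = gm.calls[joint][:, ia, :]
    b = gm.calls[joint][:, ib, :]
    xa = (a == allele_j).sum(axis=1)
    xb = (b == allele_k).sum(axis=1)
    return GenotypePairCounts(
        x_jjkk=int(((xa == 2) & (xb == 2)).sum()),
        x_jjkk_star=int(((xa == 2) & (xb == 1)).sum()),
        x_jjstar_kk=int(((xa == 1) & (xb == 2)).sum()),
        x_jjstar_kkstar=int(((xa == 1) & (xb == 1)).sum()),
        n_ab=int(joint.sum()),
    )


def composite_pair_freq(counts: GenotypePairCounts,
                        divisor: str = "individuals") -> float:
    """Composite (j, k) pairing frequency.

    ``divisor="individuals"`` returns the per-individual composite count
    (range [0, 2]), the standard Burrows formulation under which delta
    vanishes for independent loci.  ``divisor="gametes"`` divides by 2n
    instead (the literal "total number of gametes" reading), halving the
    scale; it is provided for compatibility only.
    """
    if counts.n_ab < 1:
        raise ValueError("composite frequency undefined for n_ab = 0")
    num = (2 * counts.x_jjkk + counts.x_jjkk_star + counts.x_jjstar_kk
           + counts.x_jjstar_kkstar / 2.0)
    if divisor == "individuals":
        return num / counts.n_ab
    if divisor == "gametes":
        return num / (2.0 * counts.n_ab)
    raise ValueError(f"unknown divisor {divisor!r}")


@dataclass
class LocusPairLD:
    """Vectorised LD tables for every allele pair at one locus pair."""

    locus_a: str
    locus_b: str
    alleles_a: np.ndarray
    alleles_b: np.ndarray
    n_ab: int
    p_a: np.ndarray          # (J,)  frequencies on the jointly typed subset
    p_b: np.ndarray          # (K,)
    delta: np.ndarray        # (J, K)
    r2: np.ndarray           # (J, K); NaN where undefined
    defined: np.ndarray      # (J, K) bool


def pair_ld(gm: GenotypeMatrix, locus_a, locus_b,
            divisor: str = "individuals",
            small_sample: bool = True) -> LocusPairLD:
    """All-allele-pairs Burrows LD for one locus pair (vectorised)."""
    ia, ib, joint = _joint_subset(gm, locus_a, locus_b)
    sub = gm.subset(joint) if joint.sum() < gm.n_individuals else gm
    n = int(joint.sum())
    if n < 1:
        return LocusPairLD(gm.locus_names[ia], gm.locus_names[ib],
                           np.array([]), np.array([]), 0,
                           np.array([]), np.array([]),
                           np.empty((0, 0)), np.empty((0, 0)),
                           np.empty((0, 0), dtype=bool))
    al_a, xa = locus_dosage(sub, ia)
    al_b, xb = locus_dosage(sub, ib)
    xa = xa.astype(float)
    xb = xb.astype(float)
    p_a = xa.sum(axis=0) / (2 * n)
    p_b = xb.sum(axis=0) / (2 * n)
    hom_a = (xa == 2).mean(axis=0)
    hom_b = (xb == 2).mean(axis=0)
    d_a = hom_a - p_a ** 2
    d_b = hom_b - p_b ** 2
    den_a = p_a * (1 - p_a) + d_a
    den_b = p_b * (1 - p_b) + d_b

    comp = (xa.T @ xb) / 2.0          # composite count numerator
    p_pair = comp / n                 # per-individual composite count, [0, 2]
    if divisor == "gametes":
        p_pair = p_pair / 2.0
    elif divisor != "individuals":
        raise ValueError(f"unknown divisor {divisor!r}")
    delta = p_pair - 2 * np.outer(p_a, p_b)
    if small_sample and n > 1:
        delta = delta * (n / (n - 1.0))

    defined = np.outer(den_a > _DEN_EPS, den_b > _DEN_EPS)
    r2 = np.full_like(delta, np.nan)
    denom = np.outer(den_a, den_b)
    r2[defined] = delta[defined] ** 2 / denom[defined]
    return LocusPairLD(gm.locus_names[ia], gm.locus_names[ib], al_a, al_b, n,
                       p_a, p_b, delta, r2, defined)


def burrows_r2(gm: GenotypeMatrix, locus_a, locus_b, allele_j, allele_k,
               divisor: str = "individuals",
               small_sample: bool = True) -> AllelePairLD:
    """Burrows LD summary for a single allele pair."""
    pl = pair_ld(gm, locus_a, locus_b, divisor=divisor,
                 small_sample=small_sample)
    ja = np.flatnonzero(pl.alleles_a == allele_j)
    kb = np.flatnonzero(pl.alleles_b == allele_k)
    if ja.size == 0 or kb.size == 0:
        raise ValueError("allele not observed among jointly typed individuals")
    j, k = int(ja[0]), int(kb[0])
    ok = bool(pl.defined[j, k])
    ia = gm.locus_index(locus_a)
    ib = gm.locus_index(locus_b)
    # recompute D terms for reporting
    sub = gm.subset(gm.typed[:, ia] & gm.typed[:, ib])
    _, xa = locus_dosage(sub, ia)
    _, xb = locus_dosage(sub, ib)
    return AllelePairLD(
        p_a=float(pl.p_a[j]), p_b=float(pl.p_b[k]),
        d_a=float((xa[:, j] == 2).mean() - pl.p_a[j] ** 2),
        d_b=float((xb[:, k] == 2).mean() - pl.p_b[k] ** 2),
        delta=float(pl.delta[j, k]),
        r2=float(pl.r2[j, k]) if ok else float("nan"),
        n_ab=pl.n_ab, defined=ok,
    )


def mean_r2(gm: GenotypeMatrix, pcrit: float = 0.01,
            divisor: str = "individuals",
            small_sample: bool = True) -> LDSummary:
    """Pcrit-filtered, n_AB-weighted mean r^2 over all allele and locus pairs.

    Allele pairs are retained when both sample frequencies (computed on the
    jointly typed subset) are >= pcrit; a frequency exactly equal to pcrit is
    retained.  Monomorphic or zero-variance allele columns are excluded and
    counted in ``n_undefined``.
    """
    if gm.n_loci < 2:
        raise ValueError("need at least 2 loci for LD estimation")
    records: list[LocusPairRecord] = []
    n_undefined = 0
    for ia, ib in itertools.combinations(range(gm.n_loci), 2):
        pl = pair_ld(gm, ia, ib, divisor=divisor, small_sample=small_sample)
        if pl.n_ab < 2:
            continue
        n_undefined += int((~pl.defined).sum())
        keep = pl.defined & np.outer(pl.p_a >= pcrit, pl.p_b >= pcrit)
        k = int(keep.sum())
        if k == 0:
            continue
        records.append(LocusPairRecord(pl.locus_a, pl.locus_b, pl.n_ab, k,
                                       float(pl.r2[keep].sum())))
    if not records:
        raise ValueError(f"Pcrit {pcrit} too high for data: no allele pairs retained")

    tot_w = sum(r.weight for r in records)
    mean = sum(r.weighted_sum for r in records) / tot_w
    s_eff = len(records) / sum(1.0 / r.n_ab for r in records)
    from .ne import expected_sample_r2  # local import avoids a module cycle
    e_samp = expected_sample_r2(s_eff)
    return LDSummary(
        mean_r2=float(mean), s_eff=float(s_eff), e_sample_r2=float(e_samp),
        r2_prime=float(mean - e_samp), pcrit=float(pcrit),
        n_pairs_retained=int(sum(r.n_allele_pairs for r in records)),
        n_locus_pairs=len(records), n_undefined=int(n_undefined),
        records=records, divisor=divisor,
    )


def ld_table(gm: GenotypeMatrix, pcrit: float = 0.0,
             divisor: str = "individuals") -> pd.DataFrame:
    """Per-allele-pair LD audit table (one row per defined allele pair)."""
    rows = []
    for ia, ib in itertools.combinations(range(gm.n_loci), 2):
        pl = pair_ld(gm, ia, ib, divisor=divisor)
        if pl.n_ab < 2:
            continue
        keep = pl.defined & np.outer(pl.p_a >= pcrit, pl.p_b >= pcrit)
        for j, k in zip(*np.nonzero(keep)):
            rows.append({
                "locus_a": pl.locus_a, "locus_b": pl.locus_b,
                "allele_j": int(pl.alleles_a[j]), "allele_k": int(pl.alleles_b[k]),
                "n_ab": pl.n_ab, "p_a": float(pl.p_a[j]), "p_b": float(pl.p_b[k]),
                "delta": float(pl.delta[j, k]), "r2": float(pl.r2[j, k]),
            })
    return pd.DataFrame(rows)
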