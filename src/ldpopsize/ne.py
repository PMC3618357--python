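"""Effective population size from linkage disequilibrium.

The drift expectation for unlinked neutral loci in a random-mating diploid
population relates the sampling-corrected mean squared allele correlation to
the effective size:

    r^2' = 1/(3 Ne) - 0.69/Ne^2,

where r^2' = mean r^2 - E[r^2 | sampling] and E[r^2 | sampling] =
1/S + 3.19/S^2 removes the upward bias from genotyping S individuals.
Solving the quadratic for Ne gives

    Ne = [1/3 + sqrt(1/9 - 2.76 r^2')] / (2 r^2'),

which is strictly decreasing in r^2' and exactly inverts the drift
expectation.  A negative r^2' (sampling noise exceeding the LD signal)
yields a negative estimate, read as "Ne large/undefined"; the delete-one-
locus-pair jackknife can still give a finite lower confidence bound in that
case.

:class:`LDNeModel` / :class:`LDNeResults` wrap the whole pipeline in the
familiar model-object idiom: build the model from a genotype matrix (or a
Genepop file), call :meth:`~LDNeModel.fit`, inspect the results object.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .burrows import LDSummary, mean_r2
from .genotypes import GenotypeMatrix

_Z95 = 1.959963984540054


def expected_sample_r2(s: float) -> float:
    """Expected r^2 contribution of sampling ``s`` diploid individuals."""
    if s < 2:
        raise ValueError("sample size must be >= 2")
    return 1.0 / s + 3.19 / s ** 2


def ne_from_r2prime(r2_prime: float) -> float:
    """Invert the drift expectation r^2' = 1/(3 Ne) - 0.69/Ne^2.

    Returns ``inf`` for r2_prime == 0 (no resolvable LD signal: Ne
    undefined/infinite) and a negative value for negative r2_prime.  If the
    radicand 1/9 - 2.76 r^2' is negative (r^2' > ~0.0403, far outside the
    estimator's intended regime) the first-order estimate 1/(3 r^2') is
    returned with a warning.
    """
    if r2_prime == 0:
        return math.inf
    radicand = 1.0 / 9.0 - 2.76 * r2_prime
    if radicand < 0:
        warnings.warn("r2_prime beyond the quadratic's range; "
                      "falling back to the first-order estimate 1/(3 r2')",
                      RuntimeWarning, stacklevel=2)
        return 1.0 / (3.0 * r2_prime)
    return (1.0 / 3.0 + math.sqrt(radicand)) / (2.0 * r2_prime)


class JackknifeCI(NamedTuple):
    ci_lower: float
    ci_upper: float
    se_r2: float


def jackknife_ci(summary: LDSummary, z: float = _Z95) -> JackknifeCI:
    """Delete-one-locus-pair jackknife confidence interval for Ne.

    The jackknife standard error of the weighted mean r^2 gives a normal-
    approximation interval on r^2'; both bounds map through the (monotone
    decreasing) Ne transform, so the lower Ne bound comes from the upper
    r^2' bound.  A non-positive r^2' bound maps to an infinite Ne bound.
    """
    m = summary.n_locus_pairs
    if m < 3:
        raise ValueError("jackknife CI needs >= 3 locus pairs")
    loo = summary.leave_one_out_means()
    se = math.sqrt((m - 1) / m * float(((loo - loo.mean()) ** 2).sum()))
    hi_r2p = summary.r2_prime + z * se
    lo_r2p = summary.r2_prime - z * se
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ci_lower = ne_from_r2prime(hi_r2p) if hi_r2p > 0 else math.inf
        ci_upper = ne_from_r2prime(lo_r2p) if lo_r2p > 0 else math.inf
    return JackknifeCI(ci_lower, ci_upper, se)


class HarmonicMean(NamedTuple):
    value: float
    n_used: int
    n_excluded: int


def harmonic_mean_ne(estimates: Sequence[float]) -> HarmonicMean:
    """Harmonic mean over positive, finite estimates.

    Negative, zero, non-finite and missing estimates signal "Ne large or
    undefined" and are excluded; their count is reported so either
    aggregation convention can be reconstructed.
    """
    vals = np.asarray([e for e in estimates if e is not None], dtype=float)
    pos = vals[np.isfinite(vals) & (vals > 0)]
    n_excl = len(estimates) - pos.size
    if pos.size == 0:
        raise ValueError("no positive finite estimates to average")
    return HarmonicMean(float(pos.size / (1.0 / pos).sum()), int(pos.size),
                        int(n_excl))


@dataclass
class LDNeResults:
    """Fitted LD-Ne estimate with uncertainty and diagnostics."""

    ne_hat: float
    ci_lower: float
    ci_upper: float
    r2: float
    r2_prime: float
    e_sample_r2: float
    s_eff: float
    pcrit: float
    n_individuals: int
    n_loci: int
    n_locus_pairs: int
    n_pairs_retained: int
    jackknife_se: float | None
    quadratic_fallback: bool
    ld_summary: LDSummary

    def to_dict(self) -> dict:
        return {
            "ne_hat": self.ne_hat, "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper, "r2": self.r2,
            "r2_prime": self.r2_prime, "e_sample_r2": self.e_sample_r2,
            "s_eff": self.s_eff, "pcrit": self.pcrit,
            "n_pairs_retained": self.n_pairs_retained,
            "n_locus_pairs": self.n_locus_pairs,
        }

    def summary(self) -> str:
        def fmt(x):
            if x is None:
                return "n/a"
            if math.isinf(x):
                return "infinite"
            return f"{x:,.1f}" if abs(x) >= 100 else f"{x:.6g}"

        lines = [
            "Linkage-Disequilibrium Ne Estimate (Burrows composite)",
            "=" * 56,
            f"Individuals:             {self.n_individuals}",
            f"Loci:                    {self.n_loci}"
            f"    locus pairs used: {self.n_locus_pairs}",
            f"Pcrit:                   {self.pcrit:g}",
            f"Allele pairs retained:   {self.n_pairs_retained}",
            f"Weighted mean r^2:       {self.r2:.6e}",
            f"S (harmonic mean):       {self.s_eff:.1f}",
            f"E[r^2 | sampling]:       {self.e_sample_r2:.6e}",
            f"r^2' (drift component):  {self.r2_prime:.6e}",
            "-" * 56,
            f"Ne (point estimate):     {fmt(self.ne_hat)}",
            f"95% CI (jackknife):      [{fmt(self.ci_lower)}, {fmt(self.ci_upper)}]",
        ]
        if self.ne_hat is not None and self.ne_hat < 0:
            lines.append("Note: negative estimate indicates a large/undefined Ne")
        if self.quadratic_fallback:
            lines.append("Note: quadratic out of range; first-order estimate used")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<LDNeResults ne_hat={self.ne_hat:.6g} pcrit={self.pcrit:g}>"


class LDNeModel:
    """Linkage-disequilibrium effective-population-size model.

    Parameters
    ----------
    genotypes : GenotypeMatrix
    pcrit : float
        Minimum sample allele frequency for an allele to enter the mean r^2
        (frequencies exactly equal to pcrit are retained; 0 keeps every
        observed allele).
    divisor : {"individuals", "gametes"}
        Composite-count normalisation; see :mod:`ldpopsize.burrows`.
    small_sample : bool
        Apply the n/(n-1) factor to the composite delta (default True; the
        sampling-bias term assumes it).

    Examples
    --------
    >>> res = LDNeModel(gm, pcrit=0.01).fit()   # doctest: +SKIP
    >>> print(res.summary())                    # doctest: +SKIP
    """

    def __init__(self, genotypes: GenotypeMatrix, pcrit: float = 0.01,
                 divisor: str = "individuals", small_sample: bool = True):
        if pcrit < 0 or pcrit >= 1:
            raise ValueError("pcrit must be in [0, 1)")
        self.genotypes = genotypes
        self.pcrit = float(pcrit)
        self.divisor = divisor
        self.small_sample = small_sample

    @classmethod
    def from_genepop(cls, path, **kwargs) -> "LDNeModel":
        from .genepop import read_genepop
        return cls(read_genepop(path), **kwargs)

    def fit(self, compute_ci: bool = True) -> LDNeResults:
        summary = mean_r2(self.genotypes, pcrit=self.pcrit,
                          divisor=self.divisor, small_sample=self.small_sample)
        fallback = False
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", RuntimeWarning)
            ne_hat = ne_from_r2prime(summary.r2_prime)
            fallback = any(issubclass(w.category, RuntimeWarning) for w in caught)
        ci_lower = ci_upper = math.nan
        se = None
        if compute_ci and summary.n_locus_pairs >= 3:
            ci = jackknife_ci(summary)
            ci_lower, ci_upper, se = ci.ci_lower, ci.ci_upper, ci.se_r2
        return LDNeResults(
            ne_hat=ne_hat, ci_lower=ci_lower, ci_upper=ci_upper,
            r2=summary.mean_r2, r2_prime=summary.r2_prime,
            e_sample_r2=summary.e_sample_r2, s_eff=summary.s_eff,
            pcrit=self.pcrit, n_individuals=self.genotypes.n_individuals,
            n_loci=self.genotypes.n_loci, n_locus_pairs=summary.n_locus_pairs,
            n_pairs_retained=summary.n_pairs_retained, jackknife_se=se,
            quadratic_fallback=fallback, ld_summary=summary,
        )

    def fit_grid(self, pcrits: Sequence[float]) -> pd.DataFrame:
        """Fit across a Pcrit grid; one row per threshold.

        Thresholds at which no allele pair survives are reported as NaN rows.
        """
        rows = []
        for pc in pcrits:
            try:
                res = LDNeModel(self.genotypes, pcrit=pc, divisor=self.divisor,
                                small_sample=self.small_sample).fit()
                rows.append(res.to_dict())
            except ValueError:
                rows.append({"pcrit": pc, "ne_hat": math.nan,
                             "ci_lower": math.nan, "ci_upper": math.nan})
        return pd.DataFrame(rows).set_index("pcrit")


def estimate_ne(gm: GenotypeMatrix, pcrit: float = 0.01,
                divisor: str = "individuals") -> LDNeResults:
    """One-call convenience wrapper around :class:`LDNeModel`."""
    return LDNeModel(gm, pcrit=pcrit, divisor=divisor).fit()
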