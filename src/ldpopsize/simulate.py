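"""Forward Wright-Fisher diploid genotype simulation.

Discrete non-overlapping generations, constant population size N, equal sex
ratio (the first N/2 individuals of each generation are female, the rest
male), unlinked neutral loci, no mutation or selection.  Each offspring
draws a mother and a father independently with replacement and receives one
uniformly chosen allele per locus from each parent.

Long divergence horizons use a frequency-level fast path
(:func:`drift_frequencies`, per-generation multinomial resampling of 2N
allele copies) that is equivalent in distribution to individual-based drift
of allele frequencies; :func:`evolve_population` chains it with a terminal
individual-based phase long enough (>= 4 generations, default 8) for the
two-locus correlation r^2 to reach its asymptotic drift value before
sampling.
"""
from __future__ import annotations

import numpy as np

from .genotypes import AlleleFrequencyTable, GenotypeMatrix, as_rng


def _validate_popsize(n: int) -> None:
    if n < 4 or n % 2:
        raise ValueError("population size must be even and >= 4")


def found_population(freqs: AlleleFrequencyTable, n: int,
                     seed=None) -> GenotypeMatrix:
    """Random-union founder population: 2 alleles per locus drawn iid from
    the given frequencies (Hardy-Weinberg and linkage equilibrium in
    expectation)."""
    _validate_popsize(n)
    rng = as_rng(seed)
    calls = np.empty((n, freqs.n_loci, 2), dtype=np.int32)
    for li in range(freqs.n_loci):
        calls[:, li, :] = rng.choice(freqs.alleles[li], size=(n, 2),
                                     p=freqs.freqs[li])
    return GenotypeMatrix(calls, freqs.locus_names)


def advance_generations(gm: GenotypeMatrix, g: int, seed=None) -> GenotypeMatrix:
    """Advance ``g`` discrete Wright-Fisher generations.

    Sexes are positional (first N/2 female); selfing is impossible because
    each offspring draws one parent from each half.  Loci are transmitted
    independently (unlinked).
    """
    n, n_loci = gm.n_individuals, gm.n_loci
    _validate_popsize(n)
    if not gm.typed.all():
        raise ValueError("simulator genotypes must have no missing calls")
    rng = as_rng(seed)
    calls = gm.calls
    for _ in range(g):
        mothers = rng.integers(0, n // 2, n)
        fathers = rng.integers(n // 2, n, n)
        pick_m = rng.integers(0, 2, (n, n_loci, 1))
        pick_f = rng.integers(0, 2, (n, n_loci, 1))
        from_m = np.take_along_axis(calls[mothers], pick_m, axis=2)
        from_f = np.take_along_axis(calls[fathers], pick_f, axis=2)
        calls = np.concatenate([from_m, from_f], axis=2)
    return GenotypeMatrix(calls.copy(), gm.locus_names)


def drift_frequencies(freqs: AlleleFrequencyTable, n: int, g: int,
                      seed=None) -> AlleleFrequencyTable:
    """Pure genetic drift of allele frequencies for ``g`` generations.

    Each generation resamples 2N allele copies per locus multinomially;
    alleles lost stay lost.  ``g = 0`` returns the input unchanged.
    """
    _validate_popsize(n)
    if g < 0:
        raise ValueError("generation count must be >= 0")
    if g == 0:
        return freqs
    rng = as_rng(seed)
    alleles, out = [], []
    for li in range(freqs.n_loci):
        p = np.asarray(freqs.freqs[li], dtype=float)
        codes = np.asarray(freqs.alleles[li])
        for _ in range(g):
            counts = rng.multinomial(2 * n, p)
            p = counts / (2.0 * n)
        keep = p > 0
        alleles.append(codes[keep])
        out.append(p[keep])
    return AlleleFrequencyTable(list(freqs.locus_names), alleles, out)


def sample_individuals(gm: GenotypeMatrix, s: int, seed=None,
                       replace: bool = False) -> GenotypeMatrix:
    """Simple random sample of ``s`` individuals (plan 2: sampling does not
    remove individuals from the breeding pool)."""
    if s < 1:
        raise ValueError("sample size must be >= 1")
    if s > gm.n_individuals and not replace:
        raise ValueError("cannot sample more individuals than exist "
                         "without replacement")
    rng = as_rng(seed)
    idx = rng.choice(gm.n_individuals, size=s, replace=replace)
    return gm.subset(idx)


def mix_immigrants(focal: GenotypeMatrix, donor: GenotypeMatrix, m: int,
                   seed=None) -> tuple[GenotypeMatrix, np.ndarray]:
    """Replace ``m`` random focal individuals with ``m`` random donors.

    Both draws are without replacement.  Returns the mixed sample and the
    (sorted) positions of the planted immigrants, the ground truth for
    detection scoring.
    """
    if not 0 <= m <= focal.n_individuals:
        raise ValueError("immigrant count exceeds the focal sample")
    if m > donor.n_individuals:
        raise ValueError("immigrant count exceeds the donor sample")
    if focal.locus_names != donor.locus_names:
        raise ValueError("focal and donor locus panels differ")
    rng = as_rng(seed)
    out = focal.copy()
    if m == 0:
        return out, np.array([], dtype=int)
    slots = np.sort(rng.choice(focal.n_individuals, size=m, replace=False))
    picks = rng.choice(donor.n_individuals, size=m, replace=False)
    out.calls[slots] = donor.calls[picks]
    for s_i, p_i in zip(slots, picks):
        out.individual_ids[s_i] = f"imm_{donor.individual_ids[p_i]}"
    return out, slots


def evolve_population(freqs: AlleleFrequencyTable, n: int, generations: int,
                      seed=None, terminal_ib: int = 8) -> GenotypeMatrix:
    """Found from allele frequencies and evolve ``generations`` generations.

    The first ``generations - terminal_ib`` generations run on the
    frequency-level drift fast path; the final ``terminal_ib`` (>= 4,
    counting the founding draw) are individual-based so that genotypic LD
    reaches its drift asymptote.
    """
    if generations < 1:
        raise ValueError("need at least 1 generation")
    if terminal_ib < 4:
        raise ValueError("terminal individual-based phase must be >= 4 generations")
    rng = as_rng(seed)
    k = min(terminal_ib, generations)
    drifted = drift_frequencies(freqs, n, generations - k, rng)
    pop = found_population(drifted, n, rng)
    if k > 1:
        pop = advance_generations(pop, k - 1, rng)
    return pop
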