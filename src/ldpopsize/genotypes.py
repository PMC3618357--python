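"""Diploid multi-allelic genotype data: containers, allele frequencies,
synthetic allele-frequency spectra and missing-data emulation.

The central container is :class:`GenotypeMatrix`, an ``(individuals, loci, 2)``
array of integer allele codes with 0 as the missing sentinel.  Missingness is
always per-locus: a call is either fully typed (two positive codes) or fully
missing (both zero).  All estimators and the simulator exchange this type.

The synthetic spectrum generator reproduces the marginal structure of a
microsatellite panel summarised by its per-locus allele count, maximum allele
frequency and fraction of low-frequency (<= 0.01) alleles; the bundled default
(:func:`mackerel_spectrum`) describes the seven-locus Spanish mackerel panel
(24-38 alleles per locus, ~65% of alleles at frequency <= 0.01).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Missing-call sentinel for allele codes.
MISSING = 0


class GenotypeMatrix:
    """Individuals x loci diploid genotype calls.

    Parameters
    ----------
    calls : array-like, shape (n, L, 2)
        Integer allele codes; 0 denotes missing.  A call with only one zero
        allele is normalised to fully missing.
    locus_names : sequence of str
    individual_ids : sequence of str, optional
    populations : sequence of str, optional
        Per-individual population/block label (e.g. from a Genepop file).
    """

    def __init__(self, calls, locus_names, individual_ids=None, populations=None):
        calls = np.array(calls, dtype=np.int32)
        if calls.ndim != 3 or calls.shape[2] != 2:
            raise ValueError("calls must have shape (individuals, loci, 2)")
        if (calls < 0).any():
            raise ValueError("allele codes must be non-negative integers")
        # normalise half-missing calls (one zero allele) to fully missing
        half = (calls == MISSING).any(axis=2) & ~(calls == MISSING).all(axis=2)
        if half.any():
            calls[half] = MISSING
        self.calls = calls
        self.locus_names = list(locus_names)
        if len(self.locus_names) != calls.shape[1]:
            raise ValueError("locus_names length does not match calls")
        n = calls.shape[0]
        if individual_ids is None:
            individual_ids = [f"ind{i + 1}" for i in range(n)]
        self.individual_ids = list(individual_ids)
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match calls")
        if populations is not None:
            populations = list(populations)
            if len(populations) != n:
                raise ValueError("populations length does not match calls")
        self.populations = populations

    # -- basic introspection -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def typed(self) -> np.ndarray:
        """Boolean (n, L) mask, True where the call is fully typed."""
        return self.calls[:, :, 0] != MISSING

    def typed_locus_counts(self) -> np.ndarray:
        """Number of typed loci per individual."""
        return self.typed.sum(axis=1)

    def locus_index(self, locus) -> int:
        """Resolve a locus given by name or integer index."""
        if isinstance(locus, (int, np.integer)):
            if not 0 <= locus < self.n_loci:
                raise IndexError(f"locus index {locus} out of range")
            return int(locus)
        try:
            return self.locus_names.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    # -- manipulation --------------------------------------------------------
    def subset(self, indices) -> "GenotypeMatrix":
        """New matrix restricted to the given individual indices (order kept)."""
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.flatnonzero(indices)
        return GenotypeMatrix(
            self.calls[indices].copy(),
            self.locus_names,
            [self.individual_ids[i] for i in indices],
            None if self.populations is None else [self.populations[i] for i in indices],
        )

    def drop(self, indices) -> "GenotypeMatrix":
        """New matrix with the given individual indices removed."""
        keep = np.ones(self.n_individuals, dtype=bool)
        keep[np.asarray(indices, dtype=int)] = False
        return self.subset(keep)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.calls.copy(), list(self.locus_names),
            list(self.individual_ids),
            None if self.populations is None else list(self.populations),
        )

    @staticmethod
    def concat(matrices) -> "GenotypeMatrix":
        """Stack matrices sharing an identical locus panel."""
        matrices = list(matrices)
        names = matrices[0].locus_names
        for gm in matrices[1:]:
            if gm.locus_names != names:
                raise ValueError("locus panels differ; cannot concatenate")
        calls = np.concatenate([gm.calls for gm in matrices], axis=0)
        ids = [i for gm in matrices for i in gm.individual_ids]
        pops = None
        if all(gm.populations is not None for gm in matrices):
            pops = [p for gm in matrices for p in gm.populations]
        return GenotypeMatrix(calls, names, ids, pops)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            np.array_equal(self.calls, other.calls)
            and self.locus_names == other.locus_names
            and self.individual_ids == other.individual_ids
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<GenotypeMatrix {self.n_individuals} individuals x "
                f"{self.n_loci} loci>")


def locus_dosage(gm: GenotypeMatrix, locus) -> tuple[np.ndarray, np.ndarray]:
    """Allele codes and per-individual dosage (0/1/2 copies) at one locus.

    Missing individuals get an all-zero dosage row.  Returns
    ``(alleles, dosage)`` with ``dosage`` of shape ``(n, K)``.
    """
    li = gm.locus_index(locus)
    col = gm.calls[:, li, :]
    alleles = np.unique(col[col != MISSING])
    dosage = (
        (col[:, 0, None] == alleles[None, :]).astype(np.int8)
        + (col[:, 1, None] == alleles[None, :]).astype(np.int8)
    )
    return alleles, dosage


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class AlleleFrequencyTable:
    """Per-locus allele codes, relative frequencies and sample sizes.

    ``sample_sizes[l]`` (S_L) is the number of individuals scored at locus
    ``l``; it is None for population-level (synthetic) spectra.
    """

    locus_names: list[str]
    alleles: list[np.ndarray]
    freqs: list[np.ndarray]
    sample_sizes: np.ndarray | None = None

    def __post_init__(self):
        if not (len(self.locus_names) == len(self.alleles) == len(self.freqs)):
            raise ValueError("inconsistent per-locus field lengths")
        for name, a, f in zip(self.locus_names, self.alleles, self.freqs):
            a = np.asarray(a)
            f = np.asarray(f, dtype=float)
            if a.size != f.size or a.size < 1:
                raise ValueError(f"locus {name}: alleles/frequencies mismatch")
            if (f <= 0).any() or (f > 1).any():
                raise ValueError(f"locus {name}: frequencies must be in (0, 1]")
            if abs(f.sum() - 1.0) > 1e-9:
                raise ValueError(f"locus {name}: frequencies sum to {f.sum()}, not 1")

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, name in enumerate(self.locus_names):
            s_l = None if self.sample_sizes is None else int(self.sample_sizes[i])
            for a, f in zip(self.alleles[i], self.freqs[i]):
                rows.append({"locus": name, "allele": int(a), "frequency": float(f),
                             "sample_size": s_l})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def allele_frequencies(gm: GenotypeMatrix) -> AlleleFrequencyTable:
    """Empirical allele frequencies per locus.

    Frequency of allele a at locus l is (copies of a among typed calls) /
    (2 * S_L) with S_L the number of individuals typed at l.
    """
    alleles, freqs, sizes = [], [], []
    for li, name in enumerate(gm.locus_names):
        col = gm.calls[:, li, :]
        typed = col[col[:, 0] != MISSING]
        if typed.shape[0] == 0:
            raise ValueError(f"locus {name!r} has no typed individuals")
        codes, counts = np.unique(typed, return_counts=True)
        alleles.append(codes)
        freqs.append(counts / counts.sum())
        sizes.append(typed.shape[0])
    return AlleleFrequencyTable(list(gm.locus_names), alleles, freqs,
                                np.asarray(sizes))


# ---------------------------------------------------------------------------
# Synthetic allele-frequency spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusSpectrumSpec:
    """Marginal targets for one synthesized locus."""

    name: str
    n_alleles: int
    max_freq: float
    low_freq_fraction: float  # target fraction of alleles with frequency <= 0.01

    def __post_init__(self):
        if self.n_alleles < 2:
            raise ValueError(f"{self.name}: need at least 2 alleles")
        if not self.n_alleles * self.max_freq >= 1.0:
            raise ValueError(
                f"{self.name}: max frequency {self.max_freq} below 1/Na, infeasible")
        if not 0 < self.max_freq < 1:
            raise ValueError(f"{self.name}: max frequency must be in (0, 1)")
        if not 0 <= self.low_freq_fraction < 1:
            raise ValueError(f"{self.name}: low-frequency fraction must be in [0, 1)")


@dataclass(frozen=True)
class SpectrumSpec:
    """Full panel description for :func:`synthesize_spectrum`."""

    loci: tuple[LocusSpectrumSpec, ...]


# Seven-locus Spanish mackerel panel: (name, S_L, Na, max freq, n alleles <= 0.01)
_MACKEREL_PANEL = (
    ("SCA30", 5210, 36, 0.178, 25),
    ("SM3", 5206, 32, 0.183, 21),
    ("SM37", 4611, 37, 0.127, 25),
    ("SCA47", 4781, 27, 0.486, 18),
    ("SCA49", 4829, 25, 0.248, 13),
    ("90RTE", 5266, 24, 0.735, 17),
    ("SCA8", 5139, 38, 0.216, 23),
)

#: Total genotyped sample size of the empirical panel.
MACKEREL_SAMPLE_SIZE = 5413

#: Per-locus missing-call rates implied by the panel's per-locus sample sizes.
MACKEREL_MISSING_RATES = {name: 1.0 - s_l / MACKEREL_SAMPLE_SIZE
                        for name, s_l, *_ in _MACKEREL_PANEL}


def mackerel_spectrum() -> SpectrumSpec:
    """Marginal spectrum targets of the seven-locus mackerel panel."""
    return SpectrumSpec(tuple(
        LocusSpectrumSpec(name, na, mx, nlow / na)
        for name, _s, na, mx, nlow in _MACKEREL_PANEL
    ))


def _tail_base(n_tail: int, total: float, target_low: int,
               max_freq: float) -> np.ndarray:
    """Deterministic tail template: ``n_tail`` decreasing frequencies summing
    to ``total`` with ``target_low`` entries <= 0.01 and none above
    ``max_freq``.

    The tail splits into a "common" geometric series (between 0.01 and the
    head frequency) and a "rare" geometric series starting just below 0.01.
    """
    target_low = min(target_low, n_tail)
    n_common = n_tail - target_low
    rare = 0.009 * 0.7 ** np.arange(target_low)
    if n_common == 0:
        return np.sort(total * rare / rare.sum())[::-1]
    s_common = total - rare.sum()
    if s_common <= 0.01 * n_common:  # rare part too heavy: shrink it
        rare = rare * (total / 2) / rare.sum()
        s_common = total - rare.sum()
    # steepest geometric ratio keeping the common part within (0.01, max_freq]
    best = None
    for rho in np.linspace(0.55, 1.0, 46):
        w = rho ** np.arange(n_common) if rho < 1 else np.ones(n_common)
        common = s_common * w / w.sum()
        margin = min(max_freq - common.max(), common.min() - 0.0105)
        if best is None or margin > best[0]:
            best = (margin, common)
    return np.concatenate([best[1], rare])


def synthesize_spectrum(spec: SpectrumSpec, seed=None) -> AlleleFrequencyTable:
    """Draw a random allele-frequency table satisfying the marginal targets.

    Per locus the head allele is pinned at the target maximum and the tail is
    a geometric-decay series perturbed by a Dirichlet jitter, renormalised to
    1 - max; candidates are rejected until the realised maximum stays at the
    head allele and the low-frequency fraction is within +-10 percentage
    points of target.  Deterministic for a fixed seed.
    """
    rng = as_rng(seed)
    names, alleles, freqs = [], [], []
    for ls in spec.loci:
        na, mx = ls.n_alleles, ls.max_freq
        target_low = int(round(ls.low_freq_fraction * na))
        base = _tail_base(na - 1, 1.0 - mx, target_low, mx)
        f = None
        for _ in range(200):
            if na == 2:
                tail = base
            else:
                jitter = rng.dirichlet(2000.0 * base / base.sum())
                tail = (1.0 - mx) * jitter
                tail = np.sort(tail)[::-1]
            if (tail <= 0).any() or tail.max() > mx:
                continue
            cand = np.concatenate([[mx], tail])
            lowfrac = float((cand <= 0.01).mean())
            if abs(lowfrac - ls.low_freq_fraction) <= 0.10:
                f = cand
                break
        if f is None:
            raise RuntimeError(
                f"could not satisfy spectrum constraints for locus {ls.name}")
        names.append(ls.name)
        alleles.append(np.arange(1, na + 1))
        freqs.append(f / f.sum())
    return AlleleFrequencyTable(names, alleles, freqs)


# ---------------------------------------------------------------------------
# Missing-data emulation
# ---------------------------------------------------------------------------

@dataclass
class MissingnessPattern:
    """Either independent per-locus missing probabilities or a donor table of
    per-individual missing-locus masks resampled with replacement.

    Exactly one of ``locus_probs`` (length L, values in [0, 1)) and
    ``donor_masks`` (boolean (n_donor, L), True = missing) must be given.
    """

    locus_probs: np.ndarray | None = None
    donor_masks: np.ndarray | None = None
    max_retries: int = 100

    def __post_init__(self):
        if (self.locus_probs is None) == (self.donor_masks is None):
            raise ValueError("give exactly one of locus_probs or donor_masks")
        if self.locus_probs is not None:
            p = np.asarray(self.locus_probs, dtype=float)
            if (p < 0).any() or (p >= 1).any():
                raise ValueError("missing probabilities must be in [0, 1)")
            self.locus_probs = p
        else:
            m = np.asarray(self.donor_masks, dtype=bool)
            if m.ndim != 2 or m.shape[0] < 1:
                raise ValueError("donor_masks must be a 2-d boolean table")
            if ((~m).sum(axis=1) < 2).any():
                raise ValueError("every donor mask must leave >= 2 typed loci")
            self.donor_masks = m


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Deterministic apportionment of ``total`` counts proportional to weights."""
    weights = np.asarray(weights, dtype=float)
    quota = weights / weights.sum() * total
    counts = np.floor(quota).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def mackerel_missingness(table_size: int = 1000) -> MissingnessPattern:
    """Donor-mask pattern calibrated to the empirical panel's missing data.

    Reproduces jointly (a) the typed-locus-count distribution 71%/12%/10%/7%
    of individuals typed at 7/6/5/4 loci and (b) approximately the per-locus
    missing rates 1 - S_L/5413.  The table is built deterministically by
    largest-remainder apportionment, so no seed is needed here; randomness
    enters only when masks are resampled in :func:`apply_missingness`.
    """
    rates = np.array([MACKEREL_MISSING_RATES[name] for name, *_ in _MACKEREL_PANEL])
    L = len(rates)
    typed_dist = {0: 0.71, 1: 0.12, 2: 0.10, 3: 0.07}  # number of MISSING loci
    n_per_d = _largest_remainder(np.array(list(typed_dist.values())), table_size)
    masks = []
    for d, n_d in zip(typed_dist, n_per_d):
        if d == 0:
            masks.append(np.zeros((n_d, L), dtype=bool))
            continue
        combos = list(itertools.combinations(range(L), d))
        w = np.array([np.prod(rates[list(c)]) for c in combos])
        counts = _largest_remainder(w, n_d)
        for combo, c in zip(combos, counts):
            if c == 0:
                continue
            m = np.zeros(L, dtype=bool)
            m[list(combo)] = True
            masks.append(np.tile(m, (c, 1)))
    return MissingnessPattern(donor_masks=np.concatenate(masks, axis=0))


def apply_missingness(gm: GenotypeMatrix, pattern: MissingnessPattern,
                      seed=None) -> GenotypeMatrix:
    """Delete loci from genotypes according to a missingness pattern.

    Donor mode draws one mask per individual with replacement from the donor
    table; probability mode draws independent per-locus Bernoulli masks.  Any
    mask that would leave an individual typed at fewer than 2 loci is redrawn
    (bounded retries).
    """
    rng = as_rng(seed)
    n, L = gm.n_individuals, gm.n_loci
    already_typed = gm.typed

    def draw(k: int) -> np.ndarray:
        if pattern.donor_masks is not None:
            if pattern.donor_masks.shape[1] != L:
                raise ValueError("donor masks have wrong number of loci")
            idx = rng.integers(0, pattern.donor_masks.shape[0], k)
            return pattern.donor_masks[idx]
        if pattern.locus_probs.shape[0] != L:
            raise ValueError("locus_probs has wrong number of loci")
        return rng.random((k, L)) < pattern.locus_probs[None, :]

    masks = draw(n)
    for _ in range(pattern.max_retries):
        typed_after = (already_typed & ~masks).sum(axis=1)
        bad = typed_after < 2
        if not bad.any():
            break
        masks[bad] = draw(int(bad.sum()))
    else:
        raise RuntimeError("could not draw masks leaving >= 2 typed loci")

    calls = gm.calls.copy()
    calls[masks] = MISSING
    return GenotypeMatrix(calls, gm.locus_names, list(gm.individual_ids),
                          None if gm.populations is None else list(gm.populations))


def as_rng(seed) -> np.random.Generator:
    """Coerce None / int / SeedSequence / Generator to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
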