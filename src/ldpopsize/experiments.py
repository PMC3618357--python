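"""Weir-Cockerham FST and scripted simulation experiments.

The drivers reproduce three study designs on synthetic data:

* **divergence**: replicate populations drifting from a common founder for a
  range of horizons, with pairwise FST, LD-Ne per population, immigrant
  mixtures (m genotypes replaced by donors from a diverged population) and
  CA cleaning with detection scoring;
* **contamination**: progressive addition of nontarget-species genotypes
  (an independent allele-frequency spectrum, two loci non-amplifying) to a
  focal sample, with an Ne grid per contamination level and a cleaning pass;
* **ne distribution**: replicate LD-Ne estimates across population sizes
  and Pcrit thresholds, with the pooled-tail histogram convention used to
  display them.

Replication defaults are desk-scale; every driver takes explicit counts so
the full-size designs remain reachable.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ca import iterative_clean
from .genotypes import (AlleleFrequencyTable, GenotypeMatrix, MISSING,
                        MissingnessPattern, apply_missingness, as_rng,
                        synthesize_spectrum, mackerel_missingness,
                        mackerel_spectrum)
from .ne import LDNeModel, HarmonicMean, harmonic_mean_ne
from .simulate import (advance_generations, drift_frequencies,
                       evolve_population, found_population, mix_immigrants,
                       sample_individuals)


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------

def _locus_stats(calls: np.ndarray, alleles: np.ndarray):
    """Sample size, allele frequencies and one-copy (heterozygote-carrier)
    frequencies for one locus of one population."""
    typed = calls[calls[:, 0] != MISSING]
    n = typed.shape[0]
    if n == 0:
        return 0, None, None
    dos = ((typed[:, 0, None] == alleles[None, :]).astype(int)
           + (typed[:, 1, None] == alleles[None, :]).astype(int))
    p = dos.sum(axis=0) / (2.0 * n)
    h = (dos == 1).mean(axis=0)
    return n, p, h


def pairwise_fst(gm_a: GenotypeMatrix, gm_b: GenotypeMatrix) -> float:
    """Two-population Weir-Cockerham theta, multi-allelic.

    Variance components are summed over alleles and loci before the ratio;
    per locus only individuals typed at that locus are counted.  Raises if
    no shared polymorphic locus exists.
    """
    shared = [l for l in gm_a.locus_names if l in gm_b.locus_names]
    if not shared:
        raise ValueError("no shared loci")
    a_sum = b_sum = c_sum = 0.0
    r = 2.0
    for name in shared:
        ca = gm_a.calls[:, gm_a.locus_index(name), :]
        cb = gm_b.calls[:, gm_b.locus_index(name), :]
        alleles = np.unique(np.concatenate([ca[ca != MISSING], cb[cb != MISSING]]))
        if alleles.size < 2:
            continue
        n1, p1, h1 = _locus_stats(ca, alleles)
        n2, p2, h2 = _locus_stats(cb, alleles)
        if n1 < 2 or n2 < 2:
            continue
        n_bar = (n1 + n2) / r
        nc = (r * n_bar - (n1 ** 2 + n2 ** 2) / (r * n_bar)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        pq = p_bar * (1 - p_bar)
        a = (n_bar / nc) * (s2 - (pq - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (pq - (r - 1) / r * s2
                                     - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2
        a_sum += a.sum()
        b_sum += b.sum()
        c_sum += c.sum()
    denom = a_sum + b_sum + c_sum
    if denom <= 0:
        raise ValueError("no shared polymorphic locus: FST undefined")
    return float(a_sum / denom)


def mean_pairwise_fst(samples: list[GenotypeMatrix]) -> tuple[float, np.ndarray]:
    """Average theta over all unordered population pairs."""
    vals = np.array([pairwise_fst(a, b)
                     for a, b in itertools.combinations(samples, 2)])
    return float(vals.mean()), vals


# ---------------------------------------------------------------------------
# Divergence experiment
# ---------------------------------------------------------------------------

@dataclass
class MixtureResult:
    focal: int
    donor: int
    n_immigrants: int
    ne_before: dict[float, float]
    ne_after: dict[float, float]
    detected: int
    removed_total: int
    n_iterations: int


@dataclass
class HorizonResult:
    generations: int
    fst_mean: float | None
    fst_pairs: np.ndarray | None
    pop_ne: dict[float, list[float]]
    pop_ne_clean: dict[float, list[float]] | None
    mixtures: list[MixtureResult] = field(default_factory=list)

    def harmonic_mean_pop(self, pcrit: float) -> HarmonicMean:
        return harmonic_mean_ne(self.pop_ne[pcrit])

    def harmonic_mean_mixtures(self, pcrit: float,
                               cleaned: bool = False) -> HarmonicMean:
        vals = [(m.ne_after if cleaned else m.ne_before).get(pcrit)
                for m in self.mixtures]
        return harmonic_mean_ne(vals)

    def mean_detected(self) -> float:
        return float(np.mean([m.detected for m in self.mixtures]))


@dataclass
class DivergenceResult:
    horizons: list[HorizonResult]

    def horizon(self, g: int) -> HorizonResult:
        for h in self.horizons:
            if h.generations == g:
                return h
        raise KeyError(f"no horizon at {g} generations")

    def summary_frame(self) -> pd.DataFrame:
        """Harmonic-mean grid (one row per horizon x pcrit)."""
        rows = []
        for h in self.horizons:
            for pc in h.pop_ne:
                row = {"generations": h.generations, "pcrit": pc,
                       "fst_mean": h.fst_mean,
                       "ne_no_immigrants": h.harmonic_mean_pop(pc).value}
                if h.mixtures:
                    row["ne_with_immigrants"] = \
                        h.harmonic_mean_mixtures(pc).value
                    row["ne_with_immigrants_cleaned"] = \
                        h.harmonic_mean_mixtures(pc, cleaned=True).value
                    row["mean_detected"] = h.mean_detected()
                rows.append(row)
        return pd.DataFrame(rows)


def _mixture_pairs(n_pops: int, n_mixtures: int) -> list[tuple[int, int]]:
    """Deterministic directed (focal, donor) pairs cycling over offsets."""
    pairs = [(i, (i + d) % n_pops)
             for d in range(1, n_pops)
             for i in range(n_pops)]
    return pairs[:n_mixtures]


def _fit_grid(gm: GenotypeMatrix, pcrits) -> dict[float, float]:
    out = {}
    for pc in pcrits:
        try:
            out[pc] = LDNeModel(gm, pcrit=pc).fit(compute_ci=False).ne_hat
        except ValueError:
            out[pc] = None
    return out


def run_divergence_experiment(
    founder_freqs: AlleleFrequencyTable | None = None,
    n: int = 10_000,
    s: int = 5413,
    generations: tuple[int, ...] = (100, 200, 500, 1000, 2000),
    n_pops: int = 10,
    m: int = 100,
    pcrits: tuple[float, ...] = (0.0, 0.01),
    mixtures_at: tuple[int, ...] | None = None,
    n_mixtures: int | None = None,
    missingness: MissingnessPattern | None = None,
    clean_populations: bool = False,
    threshold: float = 2.0,
    max_iter: int = 10,
    terminal_ib: int = 8,
    compute_fst: bool = True,
    seed=None,
) -> DivergenceResult:
    """Replicate-population divergence experiment.

    ``n_pops`` populations drift independently from a common founder; at each
    horizon every population is sampled (``s`` genotypes, optional
    missingness emulation), pairwise FST and per-population LD-Ne are
    computed, and ``n_mixtures`` directed mixtures with ``m`` immigrants are
    built, estimated, CA-cleaned and re-estimated, with planted immigrants
    scored against the cleaning removals.  ``mixtures_at`` restricts the
    horizons at which mixtures are built (default: all).
    """
    rng = as_rng(seed)
    if founder_freqs is None:
        founder_freqs = synthesize_spectrum(mackerel_spectrum(), rng)
    if missingness is None:
        missingness = mackerel_missingness()
    if mixtures_at is None:
        mixtures_at = tuple(generations)
    if n_mixtures is None:
        n_mixtures = n_pops * (n_pops - 1)
    horizons = sorted(generations)

    # cumulative frequency-drift state per population, advanced between
    # checkpoints; the individual-based tail is branched per horizon
    state = [founder_freqs] * n_pops
    state_gen = [0] * n_pops
    results = []
    for g in horizons:
        samples = []
        for i in range(n_pops):
            target = max(g - terminal_ib, 0)
            if target > state_gen[i]:
                state[i] = drift_frequencies(state[i], n,
                                             target - state_gen[i], rng)
                state_gen[i] = target
            k = g - state_gen[i]
            pop = found_population(state[i], n, rng)
            if k > 1:
                pop = advance_generations(pop, k - 1, rng)
            smp = sample_individuals(pop, min(s, n), rng)
            if missingness is not None:
                smp = apply_missingness(smp, missingness, rng)
            samples.append(smp)

        fst_mean = fst_pairs = None
        if compute_fst and n_pops >= 2:
            fst_mean, fst_pairs = mean_pairwise_fst(samples)

        pop_ne = {pc: [] for pc in pcrits}
        for smp in samples:
            grid = _fit_grid(smp, pcrits)
            for pc in pcrits:
                pop_ne[pc].append(grid[pc])

        pop_ne_clean = None
        if clean_populations:
            pop_ne_clean = {pc: [] for pc in pcrits}
            for smp in samples:
                cleaned, _rep = iterative_clean(smp, threshold=threshold,
                                                max_iter=max_iter)
                grid = _fit_grid(cleaned, pcrits)
                for pc in pcrits:
                    pop_ne_clean[pc].append(grid[pc])

        mixtures = []
        if g in mixtures_at and m > 0 and n_pops >= 2:
            for focal_i, donor_i in _mixture_pairs(n_pops, n_mixtures):
                mixed, slots = mix_immigrants(samples[focal_i],
                                              samples[donor_i], m, rng)
                ne_before = _fit_grid(mixed, pcrits)
                cleaned, rep = iterative_clean(mixed, threshold=threshold,
                                               max_iter=max_iter)
                ne_after = _fit_grid(cleaned, pcrits)
                removed = rep.removed_indices
                detected = int(np.isin(slots, removed).sum())
                n_removal_iters = sum(1 for it in rep.iterations
                                      if it.removed.size > 0)
                mixtures.append(MixtureResult(
                    focal=focal_i, donor=donor_i, n_immigrants=m,
                    ne_before=ne_before, ne_after=ne_after,
                    detected=detected, removed_total=int(removed.size),
                    n_iterations=n_removal_iters))

        results.append(HorizonResult(g, fst_mean, fst_pairs, pop_ne,
                                     pop_ne_clean, mixtures))
    return DivergenceResult(results)


# ---------------------------------------------------------------------------
# Nontarget-species contamination experiment
# ---------------------------------------------------------------------------

@dataclass
class ContaminationResult:
    table: pd.DataFrame                 # index: contaminants added; cols: pcrit
    first_iteration_removed: int        # contaminants removed in CA round 1
    total_contaminants: int
    detected_total: int
    n_iterations: int


def make_contaminant_pool(locus_names: list[str], n: int,
                          missing_loci: tuple[str, ...] = ("SCA47", "SCA49"),
                          allele_offset: int = 500,
                          spectrum=None, seed=None) -> GenotypeMatrix:
    """Nontarget-species surrogate genotypes.

    Founded from an independently synthesized spectrum (no shared ancestry
    with the focal population); allele codes are offset so they are private
    to the contaminants, and the named loci are wholly missing (the
    nontarget species amplifies at only a subset of the panel).
    """
    rng = as_rng(seed)
    if spectrum is None:
        spectrum = mackerel_spectrum()
    freqs = synthesize_spectrum(spectrum, rng)
    if freqs.n_loci != len(locus_names):
        raise ValueError("contaminant spectrum does not match the focal panel")
    pool = found_population(freqs, max(4, n + n % 2), rng).subset(np.arange(n))
    pool.calls[pool.calls != MISSING] += allele_offset
    pool = GenotypeMatrix(pool.calls, locus_names,
                          [f"cont{i + 1}" for i in range(n)])
    for name in missing_loci:
        pool.calls[:, pool.locus_index(name), :] = MISSING
    return pool


def run_contamination_experiment(
    focal: GenotypeMatrix,
    counts: tuple[int, ...] = (0, 1, 2, 4, 8, 16, 32, 64, 100, 200),
    pcrits: tuple[float, ...] = (0.05, 0.02, 0.01, 0.001, 0.0005, 0.0001, 0.0),
    missing_loci: tuple[str, ...] = ("SCA47", "SCA49"),
    allele_offset: int = 500,
    spectrum=None,
    threshold: float = 2.0,
    max_iter: int = 10,
    seed=None,
) -> ContaminationResult:
    """Progressively add nontarget-species genotypes and re-estimate Ne.

    Contaminant sets are nested (the first ``c`` genotypes of one pool), so
    each row of the grid adds to the previous one.  After the largest count
    a CA cleaning pass is run and its removals scored against the known
    contaminants.
    """
    rng = as_rng(seed)
    pool = make_contaminant_pool(focal.locus_names, max(counts), missing_loci,
                                 allele_offset, spectrum, rng)
    rows = {}
    biggest = None
    for c in counts:
        gm = focal if c == 0 else GenotypeMatrix.concat(
            [focal, pool.subset(np.arange(c))])
        rows[c] = _fit_grid(gm, pcrits)
        biggest = gm
    cleaned, rep = iterative_clean(biggest, threshold=threshold,
                                   max_iter=max_iter)
    contaminant_idx = np.arange(focal.n_individuals,
                                focal.n_individuals + max(counts))
    first = rep.iterations[0].removed if rep.iterations else np.array([], int)
    table = pd.DataFrame(rows).T
    table.index.name = "contaminants_added"
    return ContaminationResult(
        table=table,
        first_iteration_removed=int(np.isin(contaminant_idx, first).sum()),
        total_contaminants=int(max(counts)),
        detected_total=int(np.isin(contaminant_idx, rep.removed_indices).sum()),
        n_iterations=sum(1 for it in rep.iterations if it.removed.size > 0),
    )


# ---------------------------------------------------------------------------
# Replicate Ne distribution across Pcrit
# ---------------------------------------------------------------------------

@dataclass
class NeDistributionResult:
    values: dict[float, np.ndarray]     # pcrit -> replicate ne_hat
    ci_lower: dict[float, np.ndarray]
    n: int
    s: int

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for pc, v in self.values.items():
            v = np.asarray([x for x in v if x is not None and np.isfinite(x)])
            rows.append({
                "pcrit": pc, "n_replicates": v.size,
                "sd": float(v.std(ddof=1)) if v.size > 1 else np.nan,
                "median": float(np.median(v)) if v.size else np.nan,
                "frac_negative": float((v < 0).mean()) if v.size else np.nan,
            })
        return pd.DataFrame(rows).set_index("pcrit")


def pooled_histogram(values, lower: float = -20_000, upper: float = 40_000,
                     bins: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """Histogram with extreme estimates pooled into the first/last bin
    (estimates below ``lower`` and above ``upper`` are clipped to the
    axis limits)."""
    v = np.clip(np.asarray(values, dtype=float), lower, upper)
    return np.histogram(v, bins=bins, range=(lower, upper))


def run_ne_distribution(
    founder_freqs: AlleleFrequencyTable | None = None,
    n: int = 10_000,
    reps: int = 200,
    s: int = 5413,
    pcrits: tuple[float, ...] = (0.05, 0.01, 0.001, 0.0001),
    generations: int = 4,
    missingness: MissingnessPattern | None = "mackerel",
    compute_ci: bool = False,
    seed=None,
) -> NeDistributionResult:
    """Replicate LD-Ne estimates from generation-``generations`` samples.

    Each replicate founds a population from the given frequencies, advances
    to the target generation (enough for r^2 to reach its asymptote),
    samples min(s, n) genotypes, emulates missingness and fits the model at
    each Pcrit.
    """
    rng = as_rng(seed)
    if founder_freqs is None:
        founder_freqs = synthesize_spectrum(mackerel_spectrum(), rng)
    if missingness == "mackerel":
        missingness = mackerel_missingness()
    values = {pc: [] for pc in pcrits}
    ci_lo = {pc: [] for pc in pcrits}
    for _ in range(reps):
        pop = found_population(founder_freqs, n, rng)
        if generations > 1:
            pop = advance_generations(pop, generations - 1, rng)
        smp = sample_individuals(pop, min(s, n), rng)
        if missingness is not None:
            smp = apply_missingness(smp, missingness, rng)
        for pc in pcrits:
            try:
                res = LDNeModel(smp, pcrit=pc).fit(compute_ci=compute_ci)
                values[pc].append(res.ne_hat)
                ci_lo[pc].append(res.ci_lower if compute_ci else np.nan)
            except ValueError:
                values[pc].append(None)
                ci_lo[pc].append(np.nan)
    return NeDistributionResult(
        values={pc: np.array([np.nan if v is None else v for v in vs])
                for pc, vs in values.items()},
        ci_lower={pc: np.asarray(v) for pc, v in ci_lo.items()},
        n=n, s=min(s, n),
    )
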