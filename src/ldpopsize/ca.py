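"""Iterative correspondence-analysis screening of outlier genotypes.

Genotypes are coded as an individuals x (locus, allele) dosage table
(0/1/2 copies; missing loci contribute zero).  Correspondence analysis of
that table places individuals in a low-dimensional space under the
chi-square metric, which up-weights rare allele columns — exactly the
columns that distinguish immigrants or nontarget-species genotypes from the
focal breeding population.  Individuals whose first two row principal
coordinates satisfy |PC1| + |PC2| > threshold are flagged, removed, and the
analysis repeated (allele columns are rebuilt from the retained rows each
round) until no individual is flagged or an iteration cap is reached.

Row *principal* coordinates (mass- and singular-value-scaled) are used: the
per-axis inertia of a many-allele dosage table is small, so typical
coordinates are well below 1 and a fixed threshold of 2 isolates genuine
outliers rather than the bulk of the sample.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .genotypes import GenotypeMatrix, locus_dosage


def build_indicator(gm: GenotypeMatrix) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Individuals x alleles dosage table.

    One column per (locus, allele) observed in the current dataset; entries
    are allele copy numbers (0/1/2).  Columns are never all-zero because the
    allele universe is rebuilt from the data itself.
    """
    if gm.n_individuals < 2 or gm.n_loci < 2:
        raise ValueError("need >= 2 individuals and >= 2 loci")
    if (gm.typed_locus_counts() == 0).any():
        raise ValueError("an individual with all loci missing cannot be scored")
    blocks, labels = [], []
    for li, name in enumerate(gm.locus_names):
        alleles, dosage = locus_dosage(gm, li)
        blocks.append(dosage)
        labels.extend((name, int(a)) for a in alleles)
    return np.concatenate(blocks, axis=1).astype(float), labels


@dataclass
class CAAxes:
    """First two row principal coordinates of a correspondence analysis."""

    coords: np.ndarray              # (n, 2)
    singular_values: np.ndarray     # (2,)
    rank_deficient: bool            # second axis unavailable (reported as 0)


def ca_axes(table: np.ndarray) -> CAAxes:
    """Correspondence analysis row principal coordinates (first two axes).

    The table is converted to correspondence matrix P = X / total, centred
    by the outer product of row and column masses, scaled by inverse
    square-root masses and decomposed by SVD; row principal coordinates are
    the left singular vectors scaled by the singular values and inverse
    square-root row masses.  Axis signs are normalised so the
    largest-magnitude column loading on each axis is positive.
    """
    table = np.asarray(table, dtype=float)
    total = table.sum()
    if total <= 0:
        raise ValueError("indicator table is empty")
    p = table / total
    r = p.sum(axis=1)
    if (r <= 0).any():
        raise ValueError("zero row mass: individual carries no alleles")
    p = p[:, p.sum(axis=0) > 0]         # all-zero columns carry no inertia
    c = p.sum(axis=0)
    sr, sc = np.sqrt(r), np.sqrt(c)
    s_mat = (p - np.outer(r, c)) / np.outer(sr, sc)
    u, sv, vt = scipy.linalg.svd(s_mat, full_matrices=False)

    n = table.shape[0]
    coords = np.zeros((n, 2))
    out_sv = np.zeros(2)
    tol = max(table.shape) * np.finfo(float).eps * (sv[0] if sv.size else 0.0)
    n_axes = int((sv > tol).sum()) if sv.size else 0
    for a in range(min(2, n_axes)):
        f = u[:, a] * sv[a] / sr
        g = vt[a, :] * sv[a] / sc
        j = int(np.argmax(np.abs(g)))
        if g[j] < 0:
            f = -f
        coords[:, a] = f
        out_sv[a] = sv[a]
    return CAAxes(coords=coords, singular_values=out_sv,
                  rank_deficient=n_axes < 2)


def flag_outliers(coords: np.ndarray, threshold: float = 2.0,
                  norm: str = "l1") -> np.ndarray:
    """Boolean mask of individuals beyond the distance threshold.

    The criterion combines the two axes as a distance from the origin:
    |PC1| + |PC2| (``norm="l1"``, default) or sqrt(PC1^2 + PC2^2)
    (``norm="l2"``).
    """
    coords = np.asarray(coords, dtype=float)
    if norm == "l1":
        dist = np.abs(coords[:, 0]) + np.abs(coords[:, 1])
    elif norm == "l2":
        dist = np.hypot(coords[:, 0], coords[:, 1])
    else:
        raise ValueError(f"unknown norm {norm!r}")
    return dist > threshold


@dataclass
class CAIteration:
    """Log of one cleaning round (indices refer to the ORIGINAL matrix)."""

    removed: np.ndarray
    threshold: float
    n_before: int
    rank_deficient: bool


@dataclass
class CAReport:
    """Full record of an iterative cleaning run."""

    iterations: list[CAIteration] = field(default_factory=list)
    retained: np.ndarray | None = None      # original indices kept
    coords: np.ndarray | None = None        # final PC1/PC2 of retained rows
    converged: bool = False

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)

    @property
    def removed_indices(self) -> np.ndarray:
        """All removed original indices across iterations (disjoint by
        construction)."""
        if not self.iterations:
            return np.array([], dtype=int)
        return np.concatenate([it.removed for it in self.iterations])

    def plot(self, ax=None):  # pragma: no cover - graphical
        """Scatter the final PC1/PC2 coordinates."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.coords[:, 0], self.coords[:, 1], s=6, alpha=0.5)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        return ax


def iterative_clean(gm: GenotypeMatrix, threshold: float = 2.0,
                    max_iter: int = 10, norm: str = "l1",
                    ) -> tuple[GenotypeMatrix, CAReport]:
    """Iteratively remove CA outliers until none are flagged.

    Returns the cleaned matrix and a :class:`CAReport`.  Raises if the
    threshold would remove every individual.
    """
    report = CAReport()
    current = gm
    orig_idx = np.arange(gm.n_individuals)
    coords = None
    for _ in range(max_iter):
        table, _labels = build_indicator(current)
        axes = ca_axes(table)
        coords = axes.coords
        flagged = flag_outliers(coords, threshold=threshold, norm=norm)
        report.iterations.append(CAIteration(
            removed=orig_idx[flagged], threshold=threshold,
            n_before=current.n_individuals, rank_deficient=axes.rank_deficient))
        if not flagged.any():
            report.converged = True
            break
        if flagged.all():
            raise ValueError("threshold too aggressive: all individuals removed")
        current = current.subset(~flagged)
        orig_idx = orig_idx[~flagged]
        coords = None
    if coords is None:  # recompute final coordinates after the last removal
        table, _labels = build_indicator(current)
        coords = ca_axes(table).coords
    report.retained = orig_idx
    report.coords = coords
    return current, report
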