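"""Correspondence-analysis outlier screening."""
import numpy as np
import pytest

import ldpopsize as lp
from ldpopsize.ca import build_indicator, ca_axes, flag_outliers
from ldpopsize.experiments import make_contaminant_pool

from conftest import make_gm


# ---------------------------------------------------------------------------
# indicator construction
# ---------------------------------------------------------------------------

def test_indicator_rows_are_dosages():
    gm = make_gm([[(1, 2), (2, 2)], [(3, 3), (1, 1)]])
    table, labels = build_indicator(gm)
    # locus L1 alleles (1,2,3), locus L2 alleles (1,2)
    assert labels == [("L1", 1), ("L1", 2), ("L1", 3), ("L2", 1), ("L2", 2)]
    assert table[0].tolist() == [1, 1, 0, 0, 2]
    assert table[1].tolist() == [0, 0, 2, 2, 0]


def test_indicator_column_sums_conserve_allele_counts():
    rng = np.random.default_rng(21)
    calls = rng.integers(1, 5, (30, 3, 2))
    calls[rng.random((30, 3)) < 0.2] = 0
    gm = make_gm(calls)
    table, labels = build_indicator(gm)
    freqs = lp.allele_frequencies(gm)
    for col, (locus, allele) in enumerate(labels):
        li = gm.locus_names.index(locus)
        s_l = freqs.sample_sizes[li]
        f = freqs.freqs[li][freqs.alleles[li] == allele][0]
        assert table[:, col].sum() == pytest.approx(2 * s_l * f)


def test_indicator_rejects_fully_missing_individual():
    gm = make_gm([[(0, 0), (0, 0)], [(1, 1), (2, 2)]])
    with pytest.raises(ValueError):
        build_indicator(gm)


# ---------------------------------------------------------------------------
# CA axes
# ---------------------------------------------------------------------------

def oracle_row_coords(table):
    """Dense eigendecomposition oracle for row principal coordinates."""
    table = np.asarray(table, dtype=float)
    p = table / table.sum()
    r, c = p.sum(1), p.sum(0)
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    evals, evecs = np.linalg.eigh(s @ s.T)
    order = np.argsort(evals)[::-1]
    coords = np.zeros((table.shape[0], 2))
    for a in range(2):
        lam = max(evals[order[a]], 0.0)
        if lam < 1e-18:
            continue
        u = evecs[:, order[a]]
        coords[:, a] = u * np.sqrt(lam) / np.sqrt(r)
    return coords


def test_identical_rows_have_zero_inertia():
    table = np.tile([1, 0, 2, 1], (6, 1))
    axes = ca_axes(table)
    assert np.allclose(axes.coords, 0.0)
    assert axes.rank_deficient


def test_two_clusters_separate_symmetrically_and_match_oracle():
    table = np.array([[2, 0, 1, 1]] * 5 + [[0, 2, 1, 1]] * 5, dtype=float)
    axes = ca_axes(table)
    pc1 = axes.coords[:, 0]
    assert np.allclose(pc1[:5], pc1[0]) and np.allclose(pc1[5:], pc1[5])
    assert pc1[0] == pytest.approx(-pc1[5])
    want = oracle_row_coords(table)
    assert np.allclose(np.abs(pc1), np.abs(want[:, 0]), atol=1e-8)
    # only two distinct rows: the second axis carries no real inertia
    assert np.abs(axes.coords[:, 1]).max() < 1e-6


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_axes_match_dense_eigendecomposition_oracle(seed):
    rng = np.random.default_rng(seed)
    table = rng.integers(0, 3, (40, 25)).astype(float)
    table[table.sum(1) == 0, 0] = 1
    table = table[:, table.sum(0) > 0]
    axes = ca_axes(table)
    want = oracle_row_coords(table)
    assert np.allclose(np.abs(axes.coords), np.abs(want), atol=1e-8)


def test_axis_sign_is_reproducible():
    rng = np.random.default_rng(3)
    table = rng.integers(0, 3, (20, 10)).astype(float) + 0.0
    table[table.sum(1) == 0, 0] = 1
    a = ca_axes(table)
    b = ca_axes(table[:, ::-1].copy()[:, ::-1])  # same table, fresh memory
    assert np.allclose(a.coords, b.coords)


def test_private_allele_carriers_have_extreme_coordinates(mackerel_freqs):
    rng = np.random.default_rng(22)
    focal = lp.found_population(mackerel_freqs, 100, rng)
    outliers = focal.subset(np.arange(5)).copy()
    outliers.calls[:, :, :] = 900 + np.arange(7)[None, :, None]  # private
    gm = lp.GenotypeMatrix.concat([focal.subset(np.arange(5, 100)), outliers])
    table, _ = build_indicator(gm)
    coords = ca_axes(table).coords
    dist = np.abs(coords).sum(axis=1)
    assert set(np.argsort(dist)[-5:]) == {95, 96, 97, 98, 99}


# ---------------------------------------------------------------------------
# flagging and the iterative loop
# ---------------------------------------------------------------------------

def test_flag_threshold_semantics():
    coords = np.zeros((4, 2))
    assert not flag_outliers(coords).any()
    coords[2] = (3.0, 0.0)
    assert flag_outliers(coords).tolist() == [False, False, True, False]
    coords[1] = (1.2, 1.2)   # L1 = 2.4 > 2 but L2 = 1.7 < 2
    assert flag_outliers(coords, norm="l1")[1]
    assert not flag_outliers(coords, norm="l2")[1]


def test_iterative_clean_log_invariants(mackerel_freqs):
    rng = np.random.default_rng(23)
    gm = lp.found_population(mackerel_freqs, 300, rng)
    cleaned, report = lp.iterative_clean(gm, threshold=1.5, max_iter=10)
    removed = report.removed_indices
    assert len(set(removed.tolist())) == removed.size          # disjoint
    assert report.n_iterations <= 10
    if report.converged:
        assert report.iterations[-1].removed.size == 0
    assert cleaned.n_individuals + removed.size == 300
    assert np.array_equal(np.sort(np.concatenate([report.retained, removed])),
                          np.arange(300))
    assert report.coords.shape == (cleaned.n_individuals, 2)


def test_overly_aggressive_threshold_raises():
    rng = np.random.default_rng(24)
    gm = make_gm(rng.integers(1, 6, (12, 3, 2)))
    with pytest.raises(ValueError, match="aggressive"):
        lp.iterative_clean(gm, threshold=1e-6)


def test_species_contaminants_removed_in_first_iteration(mackerel_freqs):
    """Nontarget-species genotypes (private alleles, two loci missing) are
    nearly all flagged by the first CA round."""
    rng = np.random.default_rng(25)
    focal = lp.found_population(mackerel_freqs, 1000, rng)
    pool = make_contaminant_pool(focal.locus_names, 40, seed=rng)
    gm = lp.GenotypeMatrix.concat([focal, pool])
    cleaned, report = lp.iterative_clean(gm)
    first = report.iterations[0].removed
    cont_idx = np.arange(1000, 1040)
    assert np.isin(cont_idx, first).mean() >= 0.95
    # false positives stay rare
    assert (np.isin(report.removed_indices, cont_idx, invert=True).sum()
            <= 0.05 * 1000)


def test_homogeneous_sample_cleaning_barely_moves_ne(mackerel_freqs):
    """On pure single-population samples cleaning removes few individuals
    and leaves the harmonic-mean estimate essentially unchanged."""
    rng = np.random.default_rng(26)
    before, after = [], []
    for _ in range(5):
        pop = lp.found_population(mackerel_freqs, 1000, rng)
        pop = lp.advance_generations(pop, 3, rng)
        before.append(lp.LDNeModel(pop, pcrit=0.02).fit(compute_ci=False).ne_hat)
        cleaned, rep = lp.iterative_clean(pop)
        assert rep.removed_indices.size <= 0.05 * 1000
        after.append(lp.LDNeModel(cleaned, pcrit=0.02).fit(compute_ci=False).ne_hat)
    hm_b = lp.harmonic_mean_ne(before).value
    hm_a = lp.harmonic_mean_ne(after).value
    assert abs(hm_a - hm_b) / hm_b < 0.10
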