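"""Burrows composite LD against independent oracles.

Two independent oracles are used: (1) a per-individual classification of the
four genotype classes with explicit branch logic, and (2) the algebraic
identity that the phi correlation with the per-individual composite count
equals the Pearson correlation of allele-copy dosages.
"""
import itertools

import numpy as np
import pytest

import ldpopsize as lp
from ldpopsize.burrows import mean_r2, pair_ld

from conftest import make_gm


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def oracle_counts(gm, la, lb, j, k):
    """Classify individuals one by one into the four genotype classes."""
    ia, ib = gm.locus_index(la), gm.locus_index(lb)
    c = dict(jjkk=0, jjkk_star=0, jjstar_kk=0, jjstar_kkstar=0)
    n = 0
    for row in gm.calls:
        a, b = row[ia], row[ib]
        if a[0] == 0 or b[0] == 0:
            continue
        n += 1
        nj = list(a).count(j)
        nk = list(b).count(k)
        if nj == 2 and nk == 2:
            c["jjkk"] += 1
        elif nj == 2 and nk == 1:
            c["jjkk_star"] += 1
        elif nj == 1 and nk == 2:
            c["jjstar_kk"] += 1
        elif nj == 1 and nk == 1:
            c["jjstar_kkstar"] += 1
    return c, n


def oracle_r2_pearson(gm, la, lb, j, k):
    """r^2 as the squared Pearson dosage correlation (independent route)."""
    ia, ib = gm.locus_index(la), gm.locus_index(lb)
    joint = gm.typed[:, ia] & gm.typed[:, ib]
    xa = (gm.calls[joint][:, ia, :] == j).sum(axis=1).astype(float)
    xb = (gm.calls[joint][:, ib, :] == k).sum(axis=1).astype(float)
    if xa.std() == 0 or xb.std() == 0:
        return None
    return float(np.corrcoef(xa, xb)[0, 1] ** 2)


# ---------------------------------------------------------------------------
# genotype-pair counts and composite frequency
# ---------------------------------------------------------------------------

def test_forced_genotype_classifications():
    gm = make_gm([[(1, 1), (2, 2)]])
    c = lp.count_genotype_pairs(gm, 0, 1, 1, 2)
    assert (c.x_jjkk, c.n_ab) == (1, 1)
    gm = make_gm([[(1, 3), (2, 4)]])        # double heterozygote
    c = lp.count_genotype_pairs(gm, 0, 1, 1, 2)
    assert c.x_jjstar_kkstar == 1 and c.x_jjkk == 0
    assert lp.composite_pair_freq(c) == pytest.approx(0.5)


def test_mixed_set_matches_per_individual_oracle():
    rng = np.random.default_rng(8)
    calls = rng.integers(1, 4, (6, 2, 2))
    calls[0, 0] = 0
    gm = make_gm(calls)
    for j, k in itertools.product([1, 2, 3], repeat=2):
        got = lp.count_genotype_pairs(gm, 0, 1, j, k)
        want, n = oracle_counts(gm, 0, 1, j, k)
        assert got.n_ab == n
        assert (got.x_jjkk, got.x_jjkk_star, got.x_jjstar_kk,
                got.x_jjstar_kkstar) == (want["jjkk"], want["jjkk_star"],
                                         want["jjstar_kk"],
                                         want["jjstar_kkstar"])


def test_within_locus_pair_rejected():
    gm = make_gm([[(1, 2), (1, 2)]])
    with pytest.raises(ValueError):
        lp.count_genotype_pairs(gm, 0, 0, 1, 1)


def test_composite_frequency_extremes():
    homs = make_gm([[(1, 1), (2, 2)]] * 4)
    c = lp.count_genotype_pairs(homs, 0, 1, 1, 2)
    assert lp.composite_pair_freq(c) == pytest.approx(2.0)
    assert lp.composite_pair_freq(c, divisor="gametes") == pytest.approx(1.0)
    none = make_gm([[(3, 3), (4, 4)]] * 4)
    c = lp.count_genotype_pairs(none, 0, 1, 1, 2)
    assert lp.composite_pair_freq(c) == 0.0


# ---------------------------------------------------------------------------
# burrows r^2
# ---------------------------------------------------------------------------

def test_perfect_association_hand_calculation():
    gm = make_gm([[(1, 1), (1, 1)], [(2, 2), (2, 2)]])
    ld = lp.burrows_r2(gm, 0, 1, 1, 1, small_sample=False)
    assert ld.p_a == pytest.approx(0.5)
    assert ld.d_a == pytest.approx(0.25)
    assert ld.delta == pytest.approx(0.5)
    assert ld.r2 == pytest.approx(1.0)


def test_small_sample_factor_scales_r2():
    # default delta carries n/(n-1); r2 scales by its square
    rng = np.random.default_rng(7)
    gm = make_gm(rng.integers(1, 3, (10, 2, 2)))
    raw = lp.burrows_r2(gm, 0, 1, 1, 1, small_sample=False)
    adj = lp.burrows_r2(gm, 0, 1, 1, 1)
    assert adj.delta == pytest.approx(raw.delta * 10 / 9, abs=1e-14)
    assert adj.r2 == pytest.approx(raw.r2 * (10 / 9) ** 2, abs=1e-12)


def test_monomorphic_locus_is_undefined():
    gm = make_gm([[(1, 1), (1, 2)], [(1, 1), (2, 2)]])
    ld = lp.burrows_r2(gm, 0, 1, 1, 2)
    assert ld.delta == pytest.approx(0.0)
    assert not ld.defined


def test_all_heterozygous_column_flagged_undefined():
    # p = 0.5 with zero dosage variance: p(1-p) + D = 0
    gm = make_gm([[(1, 2), (3, 3)], [(1, 2), (3, 4)], [(1, 2), (4, 4)]])
    ld = lp.burrows_r2(gm, 0, 1, 1, 3)
    assert not ld.defined and np.isnan(ld.r2)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_r2_matches_pearson_dosage_oracle(seed):
    rng = np.random.default_rng(seed)
    calls = rng.integers(1, 5, (30, 3, 2))
    calls[rng.random((30, 3)) < 0.2] = 0
    gm = make_gm(calls)
    checked = 0
    for la, lb in itertools.combinations(range(3), 2):
        pl = pair_ld(gm, la, lb, small_sample=False)
        for j, a in enumerate(pl.alleles_a):
            for k, b in enumerate(pl.alleles_b):
                want = oracle_r2_pearson(gm, la, lb, a, b)
                if want is None:
                    assert not pl.defined[j, k]
                else:
                    assert pl.r2[j, k] == pytest.approx(want, abs=1e-12)
                    checked += 1
    assert checked > 10


def test_r2_exhaustive_tiny_genotype_sets():
    """All 3-individual biallelic two-locus datasets against the oracle."""
    genos = [(1, 1), (1, 2), (2, 2)]
    checked = 0
    for combo in itertools.product(itertools.product(genos, repeat=2),
                                   repeat=3):
        gm = make_gm([list(ind) for ind in combo])
        pl = pair_ld(gm, 0, 1, small_sample=False)
        for j, a in enumerate(pl.alleles_a):
            for k, b in enumerate(pl.alleles_b):
                want = oracle_r2_pearson(gm, 0, 1, a, b)
                if want is None:
                    assert not pl.defined[j, k]
                else:
                    assert pl.r2[j, k] == pytest.approx(want, abs=1e-12)
                    checked += 1
    assert checked > 500


# ---------------------------------------------------------------------------
# mean r^2 with Pcrit filtering
# ---------------------------------------------------------------------------

def _random_gm(seed, n=40, n_loci=3, alleles=4):
    rng = np.random.default_rng(seed)
    return make_gm(rng.integers(1, alleles + 1, (n, n_loci, 2)))


def test_pcrit_excludes_rare_alleles():
    rng = np.random.default_rng(9)
    calls = rng.integers(1, 3, (100, 2, 2))
    calls[0, 0, 0] = 9          # a single copy: frequency 1/200 = 0.005
    gm = make_gm(calls)
    kept = mean_r2(gm, pcrit=0.01)
    all_pairs = mean_r2(gm, pcrit=0.0)
    assert all_pairs.n_pairs_retained > kept.n_pairs_retained
    # the rare allele contributes rows only in the unfiltered summary
    assert kept.n_pairs_retained == 4  # 2 alleles x 2 alleles


def test_pcrit_boundary_is_inclusive():
    # allele 9 at exactly 2/20 = 0.10 must be retained at pcrit = 0.10
    calls = np.array([[[1, 9], [1, 2]]] * 2 + [[[1, 1], [1, 1]]] * 4
                     + [[[1, 1], [2, 2]]] * 4)
    gm = make_gm(calls)
    s = mean_r2(gm, pcrit=0.10)
    assert s.n_pairs_retained == 4


def test_mean_equals_bruteforce_average_three_loci():
    gm = _random_gm(10)
    s = mean_r2(gm, pcrit=0.0, small_sample=False)
    vals = []
    for la, lb in itertools.combinations(range(3), 2):
        pl = pair_ld(gm, la, lb)
        for j, a in enumerate(pl.alleles_a):
            for k, b in enumerate(pl.alleles_b):
                want = oracle_r2_pearson(gm, la, lb, a, b)
                if want is not None:
                    vals.append(want)
    assert s.mean_r2 == pytest.approx(np.mean(vals), abs=1e-12)
    assert s.n_pairs_retained == len(vals)
    assert s.s_eff == pytest.approx(40.0)


def test_permuting_individuals_leaves_summary_unchanged():
    gm = _random_gm(11)
    perm = np.random.default_rng(1).permutation(gm.n_individuals)
    a = mean_r2(gm, pcrit=0.02)
    b = mean_r2(gm.subset(perm), pcrit=0.02)
    assert a.mean_r2 == pytest.approx(b.mean_r2, abs=1e-12)
    assert a.s_eff == b.s_eff
    assert a.n_pairs_retained == b.n_pairs_retained


def test_pcrit_too_high_raises():
    gm = _random_gm(12)
    with pytest.raises(ValueError, match="[Pp]crit"):
        mean_r2(gm, pcrit=0.999)


def test_weighting_follows_joint_sample_sizes():
    # locus pair (0,1) typed in all 30, pair (0,2)/(1,2) in only 10:
    # S_eff is the harmonic mean of the three joint sizes
    rng = np.random.default_rng(13)
    calls = rng.integers(1, 4, (30, 3, 2))
    calls[10:, 2] = 0
    s = mean_r2(make_gm(calls), pcrit=0.0)
    assert s.n_locus_pairs == 3
    assert s.s_eff == pytest.approx(3 / (1 / 30 + 1 / 10 + 1 / 10))


def test_independent_loci_mean_r2_matches_sampling_expectation(mackerel_freqs):
    """Under random union of gametes E[mean r^2] ~ 1/S + 3.19/S^2."""
    rng = np.random.default_rng(14)
    vals = []
    for _ in range(15):
        gm = lp.found_population(mackerel_freqs, 200, rng)
        vals.append(mean_r2(gm, pcrit=0.05).r2_prime)
    assert abs(np.mean(vals)) < 5e-4   # E[r2_sample] itself is ~5.1e-3
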