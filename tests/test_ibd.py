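from itertools import product

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kinseq import (GeneticMapConfig, Individual, Pedigree, estimate_ibd_pair,
                    estimate_ibd_matrix, expected_ibs_given_ibd, gene_drop,
                    ibs_state, make_panel, simulate_founder_haplotypes,
                    true_ibd_fractions)
from kinseq.calling import MISSING
from kinseq.ibd import IBDMomentEstimator, _expected_sums, _solve_moments, ibs_counts


# ---------------------------------------------------------------------------
# independent oracle: enumerate ordered genotype pairs under each IBD state
# ---------------------------------------------------------------------------

def _enumerate_ibs_given_ibd(freq):
    """P(IBS=s | IBD=k) by direct enumeration over allele draws.

    Under IBD=k the pair shares k allele copies; shared alleles and all free
    alleles are independent draws with P(alt) = freq.  IBS between the
    resulting dosage genotypes is 2 - |ga - gb|.
    """
    p = {0: 1 - freq, 1: freq}
    table = np.zeros((3, 3))
    for k in range(3):
        for alleles in product((0, 1), repeat=4 - k):
            prob = np.prod([p[x] for x in alleles])
            shared = alleles[:k]
            free = alleles[k:]
            if k == 0:
                ga, gb = free[0] + free[1], free[2] + free[3]
            elif k == 1:
                ga, gb = shared[0] + free[0], shared[0] + free[1]
            else:
                ga = gb = shared[0] + shared[1]
            table[k, 2 - abs(ga - gb)] += prob
    return table


@pytest.mark.parametrize("gta,gtb,expected", [
    (0, 0, 2), (2, 2, 2), (1, 1, 2), (0, 2, 0), (2, 0, 0),
    (0, 1, 1), (1, 0, 1), (1, 2, 1), (2, 1, 1),
])
def test_ibs_state_table(gta, gtb, expected):
    assert ibs_state(gta, gtb) == expected


def test_ibs_state_rejects_missing():
    with pytest.raises(ValueError):
        ibs_state(-1, 0)


def test_expected_ibs_half_frequency_values():
    t = expected_ibs_given_ibd(0.5)
    assert np.allclose(t[0], [0.125, 0.5, 0.375])
    assert np.allclose(t[1], [0.0, 0.5, 0.5])
    assert np.allclose(t[2], [0.0, 0.0, 1.0])


def test_expected_ibs_low_frequency_value():
    t = expected_ibs_given_ibd(0.1)
    assert t[0, 0] == pytest.approx(2 * 0.01 * 0.81, abs=1e-15)


def test_expected_ibs_matches_enumeration_oracle():
    for freq in np.linspace(0.02, 0.98, 25):
        formula = expected_ibs_given_ibd(freq)
        enumerated = _enumerate_ibs_given_ibd(freq)
        assert np.max(np.abs(formula - enumerated)) < 1e-12


@given(st.floats(1e-6, 1 - 1e-6))
def test_expected_ibs_rows_sum_to_one(freq):
    t = expected_ibs_given_ibd(freq)
    assert np.allclose(t.sum(axis=1), 1.0, atol=1e-9)
    assert (t >= 0).all()


def test_degenerate_frequency_rejected():
    for f in (0.0, 1.0):
        with pytest.raises(ValueError):
            expected_ibs_given_ibd(f)


def test_ibs_counts_match_per_site_enumeration():
    rng = np.random.default_rng(5)
    for _ in range(20):
        n = int(rng.integers(1, 21))
        a = rng.integers(-1, 3, n).astype(np.int8)
        b = rng.integers(-1, 3, n).astype(np.int8)
        got = ibs_counts(a, b)
        brute = [0, 0, 0]
        for x, y in zip(a, b):
            if x != MISSING and y != MISSING:
                brute[ibs_state(int(x), int(y))] += 1
        assert (got.n0, got.n1, got.n2) == tuple(brute)


# ---------------------------------------------------------------------------
# moment equations
# ---------------------------------------------------------------------------

def test_moment_solution_pure_unrelated():
    # at maf 0.5, 1000 sites: expected IBS counts under IBD0 are (125,500,375)
    e = _expected_sums(np.full(1000, 0.5))
    z = _solve_moments(125, 500, 375, e, 1000)
    assert np.allclose(z, (1.0, 0.0, 0.0), atol=1e-12)


def test_moment_solution_pure_parent_offspring():
    e = _expected_sums(np.full(1000, 0.5))
    z = _solve_moments(0, 500, 500, e, 1000)
    assert np.allclose(z, (0.0, 1.0, 0.0), atol=1e-12)
    assert z[2] + z[1] / 2 == pytest.approx(0.5)


def test_identical_vectors_estimate_duplicate():
    rng = np.random.default_rng(3)
    g = rng.integers(0, 3, 1000).astype(np.int8)
    est = estimate_ibd_pair(g, g, np.full(1000, 0.5))
    assert est.z2 == pytest.approx(1.0, abs=1e-9)
    assert est.pi_hat == pytest.approx(1.0, abs=1e-9)


@given(st.floats(0, 1), st.floats(0, 1))
def test_expected_value_fixed_point(u, v):
    """Feeding exact expected IBS counts for any IBD mixture back into the
    solver recovers that mixture."""
    z = np.sort([0.0, u, v, 1.0])
    mix = np.diff(z)  # a random point on the simplex
    rng = np.random.default_rng(11)
    freqs = rng.uniform(0.05, 0.95, 200)
    e = _expected_sums(freqs)
    expected_counts = mix @ e
    got = _solve_moments(*expected_counts, e, len(freqs))
    assert np.allclose(got, mix, atol=1e-9)


def test_estimator_symmetry():
    rng = np.random.default_rng(4)
    a = rng.integers(0, 3, 500).astype(np.int8)
    b = rng.integers(0, 3, 500).astype(np.int8)
    f = rng.uniform(0.3, 0.7, 500)
    ea = estimate_ibd_pair(a, b, f)
    eb = estimate_ibd_pair(b, a, f)
    assert ea.z == eb.z and ea.n_snps == eb.n_snps


def test_pairwise_complete_deletion():
    a = np.array([0, 1, MISSING, 2, 1], dtype=np.int8)
    b = np.array([0, MISSING, 1, 2, 1], dtype=np.int8)
    est = estimate_ibd_pair(a, b, np.full(5, 0.4))
    assert est.n_snps == 3


def test_matrix_combinatorics_and_flagging():
    rng = np.random.default_rng(6)
    G = rng.integers(0, 3, (3, 200)).astype(np.int8)
    f = np.full(200, 0.4)
    table = estimate_ibd_matrix(G, freqs=f)
    assert len(table) == 3
    assert set(zip(table.ID1, table.ID2)) == {("S0", "S1"), ("S0", "S2"),
                                              ("S1", "S2")}
    G[2] = MISSING
    flagged = estimate_ibd_matrix(G, freqs=f)
    bad = flagged[flagged.FLAG != ""]
    assert set(bad.ID2) == {"S2"} and bad.Z0.isna().all()


def test_no_shared_sites_raises():
    a = np.array([MISSING, 0], dtype=np.int8)
    b = np.array([1, MISSING], dtype=np.int8)
    with pytest.raises(ValueError, match="no shared"):
        estimate_ibd_pair(a, b, np.full(2, 0.4))


def test_sample_frequency_source(trio_haps, small_panel):
    _, haps = trio_haps
    G = haps.genotypes()
    est = IBDMomentEstimator(freq_source="sample").fit(G)
    assert est.freqs_.shape == (small_panel.n_sites,)
    obs = G.mean(axis=0) / 2
    assert np.allclose(est.freqs_, obs)


# ---------------------------------------------------------------------------
# estimation on gene-dropped truth
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def dense_panel():
    return make_panel(500, 4, {f"chr{i}": 100_000_000 for i in range(1, 11)},
                      maf_law=("uniform", 0.3, 0.5), seed=21)


def test_parent_offspring_z1_near_one(dense_panel):
    ped = Pedigree([Individual("FA", sex="male"), Individual("MO", sex="female"),
                    Individual("CH", "FA", "MO")])
    founders = simulate_founder_haplotypes(dense_panel, ped.founders, seed=1)
    gmap = GeneticMapConfig(1.0, dense_panel.chrom_lengths)
    haps = gene_drop(ped, founders, gmap, dense_panel, seed=2)
    G = haps.genotypes()
    est = estimate_ibd_pair(G[haps.index("FA")], G[haps.index("CH")],
                            dense_panel.maf)
    assert est.n_snps >= 2000
    assert est.z1 > 0.9
    assert est.pi_hat == pytest.approx(0.5, abs=0.05)


def test_high_maf_threshold_increases_bias(dense_panel):
    """Restricting to near-0.5 frequencies degrades the moment estimates,
    mirroring the distortion seen with an aggressive MAF threshold."""
    members = [Individual("FA", sex="male"), Individual("MO", sex="female"),
               Individual("K0", "FA", "MO"), Individual("K1", "FA", "MO")]
    ped = Pedigree(members)
    gmap = GeneticMapConfig(1.0, dense_panel.chrom_lengths)
    err_03, err_045 = [], []
    for r in range(20):
        founders = simulate_founder_haplotypes(dense_panel, ped.founders,
                                               seed=100 + r)
        haps = gene_drop(ped, founders, gmap, dense_panel, seed=200 + r)
        zt = np.array(true_ibd_fractions("K0", "K1", haps))
        G = haps.genotypes()
        ia, ib = haps.index("K0"), haps.index("K1")
        for min_maf, acc in ((0.3, err_03), (0.45, err_045)):
            keep = dense_panel.maf >= min_maf
            est = estimate_ibd_pair(G[ia][keep], G[ib][keep],
                                    dense_panel.maf[keep])
            acc.append(np.abs(np.array(est.z) - zt).mean())
    assert np.mean(err_045) > np.mean(err_03)
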