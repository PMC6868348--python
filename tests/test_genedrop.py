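import numpy as np
import pytest
from scipy import stats

from kinseq import (GeneticMapConfig, Individual, Pedigree, gene_drop,
                    make_panel, simulate_founder_haplotypes,
                    true_ibd_fractions)


def _sibship_pedigree(n_children=2):
    members = [Individual("FA", sex="male"), Individual("MO", sex="female")]
    members += [Individual(f"K{i}", "FA", "MO") for i in range(n_children)]
    return Pedigree(members)


def test_founder_alt_fraction_matches_maf():
    panel = make_panel(1, 4, {"chr1": 1_000_000}, maf_law=("fixed", 0.5), seed=1)
    haps = simulate_founder_haplotypes(panel, [f"F{i}" for i in range(5000)], seed=2)
    frac = haps.alleles.mean()
    n = haps.alleles.size
    assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)


def test_near_zero_maf_gives_all_ref():
    panel = make_panel(1, 5, {"chr1": 1_000_000}, maf_law=("fixed", 1e-9), seed=1)
    haps = simulate_founder_haplotypes(panel, ["A", "B", "C"], seed=3)
    assert haps.alleles.sum() == 0


def test_founder_determinism_and_duplicate_ids(small_panel):
    a = simulate_founder_haplotypes(small_panel, ["X", "Y"], seed=9)
    b = simulate_founder_haplotypes(small_panel, ["X", "Y"], seed=9)
    assert (a.alleles == b.alleles).all() and (a.origins == b.origins).all()
    with pytest.raises(ValueError, match="duplicate"):
        simulate_founder_haplotypes(small_panel, ["X", "X"], seed=1)


def test_parent_offspring_shares_exactly_one_allele_everywhere(trio_haps):
    ped, haps = trio_haps
    for parent in ("FA", "MO"):
        z0, z1, z2 = true_ibd_fractions(parent, "CH", haps)
        assert (z0, z1, z2) == (0.0, 1.0, 0.0)


def test_zero_recombination_transmits_intact_haplotypes(small_panel):
    ped = _sibship_pedigree(1)
    founders = simulate_founder_haplotypes(small_panel, ped.founders, seed=5)
    gmap = GeneticMapConfig(0.0, small_panel.chrom_lengths)
    haps = gene_drop(ped, founders, gmap, small_panel, seed=6)
    child = haps.index("K0")
    fa = haps.index("FA")
    pat = haps.origins[child, 0]
    assert np.isin(pat, haps.origins[fa]).all()
    # no crossovers: the whole gamete is one parental haplotype per chromosome
    for _, sl in small_panel.chrom_slices():
        assert len(np.unique(pat[sl])) == 1


def _dense_even_panel(length=100_000_000, spacing=50_000):
    """Evenly spaced marker sites so origin-label switches track crossovers."""
    import pandas as pd
    from kinseq.panel import PANEL_COLUMNS, VariantPanel
    pos = np.arange(spacing // 2, length, spacing)
    df = pd.DataFrame({
        "chrom": "chr1", "pos": pos, "ref": "A", "alt": "G", "maf": 0.5,
        "gene_id": "G0", "repeat": False, "imprinted": False, "segdup": False})
    return VariantPanel(df[PANEL_COLUMNS], {"chr1": length})


def test_crossover_count_mean_and_poisson_fit():
    """Crossovers per meiosis on 100 Mb at 1 cM/Mb are Poisson(1)."""
    panel = _dense_even_panel()
    n_meioses = 10_000
    members = [Individual("FA", sex="male"), Individual("MO", sex="female")]
    members += [Individual(f"K{i}", "FA", "MO") for i in range(n_meioses // 2)]
    ped = Pedigree(members)
    founders = simulate_founder_haplotypes(panel, ["FA", "MO"], seed=5)
    gmap = GeneticMapConfig(1.0, panel.chrom_lengths)
    haps = gene_drop(ped, founders, gmap, panel, seed=6)
    switches = []
    for iid in ped.nonfounders:
        i = haps.index(iid)
        for hap in (0, 1):
            lab = haps.origins[i, hap]
            switches.append(int((np.diff(lab) != 0).sum()))
    switches = np.asarray(switches)
    mean = switches.mean()
    assert abs(mean - 1.0) < 3 * 1.0 / np.sqrt(len(switches))
    # chi-squared goodness of fit against Poisson(1), alpha = 0.001
    kmax = 6
    observed = np.bincount(np.minimum(switches, kmax), minlength=kmax + 1)
    expect = stats.poisson.pmf(np.arange(kmax), 1.0)
    expect = np.append(expect, 1.0 - expect.sum()) * len(switches)
    chi2 = ((observed - expect) ** 2 / expect).sum()
    assert stats.chi2.sf(chi2, df=kmax) > 0.001


def test_mendelian_conservation_of_origin_labels(trio_haps):
    ped, haps = trio_haps
    for iid in ped.nonfounders:
        child = haps.index(iid)
        for hap, parent in enumerate((ped[iid].father, ped[iid].mother)):
            p = haps.index(parent)
            lab = haps.origins[child, hap]
            # each transmitted label matches one of the parent's two labels
            ok = (lab == haps.origins[p, 0]) | (lab == haps.origins[p, 1])
            assert ok.all()
            src = np.where(lab == haps.origins[p, 0], 0, 1)
            alleles = haps.alleles[p, src, np.arange(haps.n_sites)]
            assert (haps.alleles[child, hap] == alleles).all()


def test_true_ibd_symmetry_and_simplex(trio_haps):
    _, haps = trio_haps
    ab = true_ibd_fractions("FA", "CH", haps)
    ba = true_ibd_fractions("CH", "FA", haps)
    assert ab == ba
    assert sum(ab) == pytest.approx(1.0)
    assert true_ibd_fractions("FA", "FA", haps) == (0.0, 0.0, 1.0)
    assert true_ibd_fractions("FA", "MO", haps) == (1.0, 0.0, 0.0)


def test_full_sib_mean_sharing_matches_transmission_enumeration():
    """Mean (Z0, Z1, Z2) over replicate sibships approaches (1/4, 1/2, 1/4),
    the enumeration over the four parental-transmission combinations."""
    panel = make_panel(100, 4, {f"chr{i}": 50_000_000 for i in range(1, 9)},
                       maf_law=("fixed", 0.5), seed=20)
    gmap = GeneticMapConfig(1.0, panel.chrom_lengths)
    ped = _sibship_pedigree(2)
    zs = []
    for r in range(500):
        founders = simulate_founder_haplotypes(panel, ped.founders, seed=30_000 + r)
        haps = gene_drop(ped, founders, gmap, panel, seed=60_000 + r)
        zs.append(true_ibd_fractions("K0", "K1", haps))
    zs = np.asarray(zs)
    mean = zs.mean(axis=0)
    se = zs.std(axis=0, ddof=1) / np.sqrt(len(zs))
    for got, want, s in zip(mean, (0.25, 0.5, 0.25), se):
        assert abs(got - want) < 3 * s + 1e-12


def test_gene_drop_determinism_and_missing_founder(small_panel):
    ped = _sibship_pedigree(2)
    founders = simulate_founder_haplotypes(small_panel, ped.founders, seed=5)
    gmap = GeneticMapConfig(1.0, small_panel.chrom_lengths)
    a = gene_drop(ped, founders, gmap, small_panel, seed=8)
    b = gene_drop(ped, founders, gmap, small_panel, seed=8)
    assert (a.alleles == b.alleles).all() and (a.origins == b.origins).all()
    partial = simulate_founder_haplotypes(small_panel, ["FA"], seed=5)
    with pytest.raises(ValueError, match="founder haplotypes missing"):
        gene_drop(ped, partial, gmap, small_panel, seed=8)
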