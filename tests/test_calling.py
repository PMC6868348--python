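import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kinseq import (BinomialGenotypeCaller, CountSimParams, ExpressionProfile,
                    call_genotype, filter_calls, genotype_concordance,
                    genotype_likelihoods, infer_sex, simulate_allele_counts)
from kinseq.calling import MISSING, error_to_gq, gq_to_error
from kinseq.counts import AlleleCounts


def _counts(ref, alt):
    ref = np.asarray(ref)[None, :]
    alt = np.asarray(alt)[None, :]
    z = np.zeros(1, dtype=np.int64)
    return AlleleCounts(["S"], ref, alt, z.copy(), np.full(1, 10**6))


def test_likelihoods_match_direct_binomial():
    gl = genotype_likelihoods(10, 0, 0.01)
    want = [stats.binom.pmf(0, 10, p) for p in (0.01, 0.5, 0.99)]
    assert np.allclose(np.exp(gl.log_likelihoods), want, rtol=1e-9)
    # the published ratio: ~0.904 : 9.77e-4 : 1e-20
    assert np.exp(gl.log_likelihoods[0]) == pytest.approx(0.99**10)
    assert np.exp(gl.log_likelihoods[1]) == pytest.approx(0.5**10)
    assert np.exp(gl.log_likelihoods[2]) == pytest.approx(0.01**10)


def test_balanced_counts_call_het():
    gl = genotype_likelihoods(5, 5, 0.01)
    assert call_genotype(gl).gt == "RA"


def test_ref_alt_symmetry():
    a = genotype_likelihoods(0, 12, 0.01)
    b = genotype_likelihoods(12, 0, 0.01)
    assert np.allclose(a.log_likelihoods, b.log_likelihoods[::-1])
    ca, cb = call_genotype(a), call_genotype(b)
    assert (ca.gt, cb.gt) == ("AA", "RR")
    assert ca.gq == cb.gq


def test_unanimous_depth10_gq30():
    # posterior error ~= 1.08e-3 -> GQ 30
    call = call_genotype(genotype_likelihoods(10, 0, 0.01))
    assert call.gt == "RR"
    assert call.gq in (29, 30)


def test_gq20_means_error_rate_001():
    assert gq_to_error(20) == pytest.approx(0.01)
    assert error_to_gq(0.01) == 20


def test_zero_depth_is_missing():
    gl = genotype_likelihoods(0, 0, 0.01)
    assert gl.uninformative
    call = call_genotype(gl)
    assert call.gt == "missing" and call.gq == 0


def test_gq_reaches_cap_for_deep_unanimous_counts():
    # as the error rate vanishes at sufficient depth, the het alternative
    # is the only competitor and GQ saturates at the cap
    call = call_genotype(genotype_likelihoods(400, 0, 1e-6))
    assert call.gq == 99


def test_posterior_sums_to_one_matrix():
    caller = BinomialGenotypeCaller().fit()
    counts = _counts([10, 3, 0, 7], [0, 3, 12, 1])
    calls = caller.call(counts)
    assert calls.gt.shape == (1, 4)
    assert (calls.dp[0] == [10, 6, 12, 8]).all()


def test_hwe_prior_changes_borderline_calls():
    counts = _counts([1, 1], [1, 1])
    uniform = BinomialGenotypeCaller(min_dp=0, min_gq=0).call(counts)
    hwe = BinomialGenotypeCaller(prior="hwe", min_dp=0, min_gq=0).call(
        counts, alt_freqs=np.array([0.01, 0.99]))
    assert (uniform.gt[0] == [1, 1]).all()
    # extreme priors pull 1/1 counts toward the majority homozygote quality
    assert hwe.gq[0, 0] <= uniform.gq[0, 0]


def test_filter_boundaries():
    caller = BinomialGenotypeCaller(min_dp=10, min_gq=20)
    counts = _counts([9, 10, 40], [0, 0, 0])
    calls = caller.call(counts)
    filtered, summary = filter_calls(calls, 10, 20)
    # dp 9 fails despite high confidence; dp 10 with GQ ~30 passes
    assert filtered.gt[0, 0] == MISSING
    assert filtered.gt[0, 1] == 0 and filtered.passed[0, 1]
    assert summary["n_pass"] == 2 and summary["n_fail"] == 1
    loose, _ = filter_calls(calls, 0, 0)
    assert (loose.gt[0] != MISSING).all()


def test_concordance_identity_and_empty():
    caller = BinomialGenotypeCaller(min_dp=1, min_gq=0)
    counts = _counts([30, 15, 0], [0, 15, 30])
    calls = caller.call(counts)
    truth = np.array([[0, 1, 2]], dtype=np.int8)
    frac, table = genotype_concordance(calls, truth)
    assert frac == 1.0
    assert int(np.trace(table.to_numpy())) == 3
    empty = _counts([0], [0])
    with pytest.raises(ValueError, match="no passing"):
        genotype_concordance(BinomialGenotypeCaller().call(empty),
                             np.array([[0]], dtype=np.int8))


def _simulate_calls(small_panel, trio_haps, seed, **caller_kw):
    ped, haps = trio_haps
    genes = pd.unique(small_panel.gene_ids)
    profile = ExpressionProfile.lognormal(genes, sigma=1.0, total_reads=4_000_000,
                                          seed=1, silent_fraction=0.0)
    counts = simulate_allele_counts(haps, small_panel, profile,
                                    CountSimParams(capture_per_site=7.5e-6),
                                    seed=seed, sexes=ped.sexes())
    calls = BinomialGenotypeCaller(**caller_kw).call(counts)
    return haps.genotypes(), calls


def test_concordance_error_free_high_depth_is_exactly_one(small_panel, trio_haps):
    ped, haps = trio_haps
    genes = pd.unique(small_panel.gene_ids)
    profile = ExpressionProfile.lognormal(genes, sigma=0.0, total_reads=4_000_000,
                                          seed=1, silent_fraction=0.0)
    params = CountSimParams(error_rate=0.0, ase_concentration=1e9,
                            monoallelic_fraction=0.0, capture_per_site=2.5e-5)
    counts = simulate_allele_counts(haps, small_panel, profile, params, seed=2,
                                    sexes=ped.sexes())
    calls = BinomialGenotypeCaller(min_dp=20).call(counts)
    frac, _ = genotype_concordance(calls, haps.genotypes())
    assert frac == 1.0


def test_concordance_improves_with_stricter_thresholds(small_panel, trio_haps):
    fracs = {}
    for min_dp, min_gq in ((2, 5), (10, 20)):
        vals = []
        for seed in range(5):
            truth, calls = _simulate_calls(small_panel, trio_haps, 50 + seed,
                                           min_dp=min_dp, min_gq=min_gq)
            vals.append(genotype_concordance(calls, truth)[0])
        fracs[(min_dp, min_gq)] = np.mean(vals)
    assert fracs[(10, 20)] >= fracs[(2, 5)]


@pytest.mark.parametrize("y,total,expected", [
    (0, 10**6, "female"),
    (2000, 10**6, "male"),
    (150, 10**6, "unknown"),
])
def test_sex_inference_bands(y, total, expected):
    assert infer_sex(y, total, threshold=1e-3) == expected


def test_sex_inference_zero_total_rejected():
    with pytest.raises(ValueError):
        infer_sex(0, 0)
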