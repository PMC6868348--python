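"""Genotype calling from allele counts.

The caller is a binomial-mixture model over the three diploid genotypes at
a biallelic site: given depth ``d`` and alt count ``k``, the per-read alt
probability is ``eps`` under hom-ref, ``0.5`` under het and ``1 - eps``
under hom-alt.  The call is the maximum-posterior genotype (uniform prior
by default, Hardy-Weinberg prior optional) and the genotype quality is the
Phred-scaled posterior error, ``GQ = round(-10 log10 P(call wrong))``,
capped at 99 - so GQ 20 corresponds exactly to a 0.01 error probability.
Calls failing the depth/quality thresholds (defaults DP >= 10, GQ >= 20)
are set to missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from sklearn.base import BaseEstimator

from .counts import AlleleCounts

__all__ = [
    "GenotypeLikelihoods", "GenotypeCalls", "BinomialGenotypeCaller",
    "genotype_likelihoods", "call_genotype", "filter_calls",
    "genotype_concordance", "infer_sex", "error_to_gq", "gq_to_error",
]

MISSING = -1
GENOTYPE_LABELS = ("RR", "RA", "AA")


def error_to_gq(p_error: float, cap: int = 99) -> int:
    """Phred-scale a posterior error probability (GQ 20 <=> error 0.01)."""
    if p_error <= 0:
        return cap
    return int(min(cap, round(-10.0 * np.log10(p_error))))


def gq_to_error(gq: float) -> float:
    return 10.0 ** (-gq / 10.0)


@dataclass
class GenotypeLikelihoods:
    """Log-likelihoods of {RR, RA, AA} for one site/sample."""

    log_likelihoods: np.ndarray   # shape (3,)
    error_rate: float
    uninformative: bool = False   # zero depth: all genotypes equally likely


def _log_binom_coeff(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _loglik_matrix(ref: np.ndarray, alt: np.ndarray, eps: float) -> np.ndarray:
    """Vectorized binomial log-likelihoods, shape (..., 3)."""
    if not (0 < eps < 0.5):
        raise ValueError("error_rate must lie in (0, 0.5)")
    ref = np.asarray(ref, dtype=float)
    alt = np.asarray(alt, dtype=float)
    n = ref + alt
    coeff = _log_binom_coeff(n, alt)
    log_eps = np.log(eps)
    log_1me = np.log1p(-eps)
    # the het per-read alt probability is exactly 0.5 (the eps-perturbed
    # variant 0.5(1-eps) + 0.5 eps collapses to the same value)
    ll_rr = coeff + alt * log_eps + ref * log_1me
    ll_ra = coeff + n * np.log(0.5)
    ll_aa = coeff + ref * log_eps + alt * log_1me
    return np.stack([ll_rr, ll_ra, ll_aa], axis=-1)


def genotype_likelihoods(ref_count: int, alt_count: int,
                         error_rate: float = 0.01) -> GenotypeLikelihoods:
    """Binomial genotype log-likelihoods for a single (ref, alt) observation."""
    if ref_count < 0 or alt_count < 0:
        raise ValueError("counts must be non-negative")
    if not (0 < error_rate < 0.5):
        raise ValueError("error_rate must lie in (0, 0.5)")
    if ref_count + alt_count == 0:
        return GenotypeLikelihoods(np.zeros(3), error_rate, uninformative=True)
    ll = _loglik_matrix(np.array(ref_count), np.array(alt_count), error_rate)
    return GenotypeLikelihoods(np.asarray(ll, float).reshape(3), error_rate)


@dataclass
class GenotypeCalls:
    """Genotype matrix with per-call depth, quality and filter state.

    ``gt`` uses alt-allele dosage 0/1/2 with -1 for missing; ``passed``
    marks calls surviving the DP/GQ filters (missing calls never pass).
    """

    sample_ids: list[str]
    gt: np.ndarray       # (S, n) int8
    dp: np.ndarray       # (S, n) int32
    gq: np.ndarray       # (S, n) int16
    passed: np.ndarray   # (S, n) bool

    def __post_init__(self) -> None:
        self._index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_sites(self) -> int:
        return self.gt.shape[1]

    def index(self, iid: str) -> int:
        return self._index[iid]

    def masked_gt(self) -> np.ndarray:
        """Genotypes with non-passing calls set to missing."""
        return np.where(self.passed, self.gt, MISSING).astype(np.int8)

    def subset_sites(self, mask_or_index) -> "GenotypeCalls":
        arr = np.asarray(mask_or_index)
        return GenotypeCalls(list(self.sample_ids), self.gt[:, arr],
                             self.dp[:, arr], self.gq[:, arr], self.passed[:, arr])


class BinomialGenotypeCaller(BaseEstimator):
    """Maximum-posterior binomial genotype caller.

    Parameters
    ----------
    error_rate : float
        Per-read allele miscall probability assumed by the model.
    prior : {"uniform", "hwe"}
        Genotype prior; "hwe" requires per-site alt-allele frequencies at
        call time and uses ((1-f)^2, 2f(1-f), f^2).
    min_dp, min_gq : int
        Filter thresholds; failing calls are set to missing.
    gq_cap : int
        Cap on the Phred-scaled quality (VCF convention).
    """

    def __init__(self, error_rate: float = 0.01, prior: str = "uniform",
                 min_dp: int = 10, min_gq: int = 20, gq_cap: int = 99):
        self.error_rate = error_rate
        self.prior = prior
        self.min_dp = min_dp
        self.min_gq = min_gq
        self.gq_cap = gq_cap

    def fit(self, X=None, y=None) -> "BinomialGenotypeCaller":
        if not (0 < self.error_rate < 0.5):
            raise ValueError("error_rate must lie in (0, 0.5)")
        if self.prior not in ("uniform", "hwe"):
            raise ValueError("prior must be 'uniform' or 'hwe'")
        self.n_genotypes_ = 3
        return self

    def call(self, counts: AlleleCounts,
             alt_freqs: np.ndarray | None = None) -> GenotypeCalls:
        """Call genotypes for every sample x site cell of ``counts``."""
        self.fit()
        ll = _loglik_matrix(counts.ref, counts.alt, self.error_rate)
        if self.prior == "hwe":
            if alt_freqs is None:
                raise ValueError("HWE prior requires alt_freqs")
            f = np.asarray(alt_freqs, float)
            prior = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f ** 2], axis=-1)
            with np.errstate(divide="ignore"):
                ll = ll + np.log(prior)[None, :, :]
        post_log = ll - logsumexp(ll, axis=-1, keepdims=True)
        best = np.argmax(post_log, axis=-1)
        # P(call wrong) = 1 - max posterior, computed in log space for stability
        sorted_log = np.sort(post_log, axis=-1)
        log_perr = logsumexp(sorted_log[..., :2], axis=-1)
        with np.errstate(over="ignore"):
            gq = np.minimum(self.gq_cap,
                            np.round(-10.0 * log_perr / np.log(10.0))).astype(np.int16)
        depth = counts.depth
        gt = best.astype(np.int8)
        gt[depth == 0] = MISSING
        gq[depth == 0] = 0
        passed = (depth >= self.min_dp) & (gq >= self.min_gq) & (gt != MISSING)
        return GenotypeCalls(list(counts.sample_ids), gt,
                             depth.astype(np.int32), gq, passed)


@dataclass
class GenotypeCall:
    """A single genotype call (scalar convenience wrapper)."""

    gt: str          # "RR" | "RA" | "AA" | "missing"
    dp: int
    gq: int
    passed: bool


def call_genotype(gl: GenotypeLikelihoods, prior=None,
                  gq_cap: int = 99) -> GenotypeCall:
    """Maximum-posterior call from one likelihood triple.

    ``prior`` is a length-3 simplex vector (uniform if omitted).
    Uninformative likelihoods (zero depth) yield a missing call with GQ 0.
    """
    if prior is None:
        prior = np.full(3, 1.0 / 3.0)
    prior = np.asarray(prior, float)
    if not np.isclose(prior.sum(), 1.0):
        raise ValueError("prior must sum to 1")
    if gl.uninformative:
        return GenotypeCall("missing", 0, 0, False)
    with np.errstate(divide="ignore"):
        post_log = gl.log_likelihoods + np.log(prior)
    post_log = post_log - logsumexp(post_log)
    best = int(np.argmax(post_log))
    p_err = float(np.exp(logsumexp(np.delete(post_log, best))))
    gq = error_to_gq(p_err, cap=gq_cap)
    # depth is not tracked by the likelihood object; -1 marks "unknown"
    return GenotypeCall(GENOTYPE_LABELS[best], -1, gq, True)


def filter_calls(calls: GenotypeCalls, min_dp: int = 10,
                 min_gq: int = 20) -> tuple[GenotypeCalls, dict]:
    """Re-apply DP/GQ thresholds; failing calls become missing.

    Returns the filtered calls plus a summary dict with pass/fail tallies.
    """
    if min_dp < 0 or min_gq < 0:
        raise ValueError("thresholds must be >= 0")
    callable_mask = calls.gt != MISSING
    passed = callable_mask & (calls.dp >= min_dp) & (calls.gq >= min_gq)
    gt = np.where(passed, calls.gt, MISSING).astype(np.int8)
    out = GenotypeCalls(list(calls.sample_ids), gt, calls.dp.copy(),
                        calls.gq.copy(), passed)
    summary = {
        "n_calls": int(callable_mask.sum()),
        "n_pass": int(passed.sum()),
        "n_fail": int((callable_mask & ~passed).sum()),
    }
    return out, summary


def genotype_concordance(calls: GenotypeCalls, truth_gt: np.ndarray
                         ) -> tuple[float, pd.DataFrame]:
    """Fraction of passing calls that match the true genotypes.

    ``truth_gt`` is a (n_samples, n_sites) dosage matrix.  Also returns the
    3x3 confusion table (rows = truth, columns = call).  Raises if no call
    passes (empty denominator).
    """
    if truth_gt.shape != calls.gt.shape:
        raise ValueError("truth matrix shape mismatch")
    mask = calls.passed & (calls.gt != MISSING)
    if not mask.any():
        raise ValueError("no passing non-missing calls to compare")
    t = truth_gt[mask]
    c = calls.gt[mask]
    conf = np.zeros((3, 3), dtype=np.int64)
    np.add.at(conf, (t.astype(int), c.astype(int)), 1)
    frac = float(np.trace(conf) / conf.sum())
    table = pd.DataFrame(conf, index=[f"true_{g}" for g in GENOTYPE_LABELS],
                         columns=[f"called_{g}" for g in GENOTYPE_LABELS])
    return frac, table


def infer_sex(y_read_count: int, total_reads: int,
              threshold: float = 1e-3) -> str:
    """Sex from the chrY-mapped read fraction.

    Male when the fraction reaches ``threshold``; female when it is below
    ``threshold / 10`` (mismapping background); unknown in between.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    frac = y_read_count / total_reads
    if frac >= threshold:
        return "male"
    if frac <= threshold / 10.0:
        return "female"
    return "unknown"
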