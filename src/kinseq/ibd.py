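"""Method-of-moments pairwise IBD estimation.

For each pair of individuals, count the sites where they share 0, 1 or 2
alleles identical by state (N0, N1, N2 over the L pairwise-complete sites)
and compare with the expected IBS counts conditional on sharing k alleles
identical by descent.  With allele frequencies a (alt) and b = 1 - a the
per-site conditional probabilities are

    P(IBS=0|IBD=0) = 2 a^2 b^2
    P(IBS=1|IBD=0) = 4 a^3 b + 4 a b^3
    P(IBS=2|IBD=0) = a^4 + b^4 + 4 a^2 b^2
    P(IBS=1|IBD=1) = 2 a b
    P(IBS=2|IBD=1) = a^2 + b^2
    P(IBS=2|IBD=2) = 1

(assuming Hardy-Weinberg genotypes and no inbreeding).  Summing these over
the shared sites gives expected counts E[s|k]; the moment equations are
solved sequentially,

    Z0 = N0 / E[0|0]
    Z1 = (N1 - Z0 E[1|0]) / E[1|1]
    Z2 = (N2 - Z0 E[2|0] - Z1 E[2|1]) / L,

then each Z is clamped to [0, 1] and the triple renormalized to sum to 1.
PI_HAT = Z2 + Z1/2 is the coefficient of relatedness.  No small-sample
allele-frequency corrections are applied by default (panel truth
frequencies make them unnecessary); sites are treated as independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .calling import MISSING, GenotypeCalls

__all__ = [
    "IBSCounts", "IBDEstimate", "ibs_state", "ibs_counts",
    "expected_ibs_given_ibd", "IBDMomentEstimator", "estimate_ibd_pair",
    "estimate_ibd_matrix",
]

IBD_TABLE_COLUMNS = ["ID1", "ID2", "N_SNP", "Z0", "Z1", "Z2", "PI_HAT", "FLAG"]


@dataclass(frozen=True)
class IBSCounts:
    """Observed identity-by-state tallies for one pair."""

    n0: int
    n1: int
    n2: int

    @property
    def total(self) -> int:
        return self.n0 + self.n1 + self.n2


@dataclass(frozen=True)
class IBDEstimate:
    """Bounded method-of-moments IBD estimate for one pair."""

    id1: str
    id2: str
    z0: float
    z1: float
    z2: float
    n_snps: int

    @property
    def pi_hat(self) -> float:
        return self.z2 + self.z1 / 2.0

    @property
    def z(self) -> tuple[float, float, float]:
        return (self.z0, self.z1, self.z2)


def ibs_state(gt_a: int, gt_b: int) -> int:
    """Alleles shared identical-by-state between two dosage genotypes.

    Under optimal allele pairing this is ``2 - |a - b|`` for dosages in
    {0, 1, 2} (opposite homozygotes share 0, het pairs share 2).
    """
    if gt_a not in (0, 1, 2) or gt_b not in (0, 1, 2):
        raise ValueError("genotypes must be dosages in {0, 1, 2}")
    return 2 - abs(gt_a - gt_b)


def ibs_counts(gt_a: np.ndarray, gt_b: np.ndarray) -> IBSCounts:
    """Tally IBS states over the pairwise-complete sites of two dosage
    vectors (-1 marks missing)."""
    gt_a = np.asarray(gt_a)
    gt_b = np.asarray(gt_b)
    shared = (gt_a != MISSING) & (gt_b != MISSING)
    diff = np.abs(gt_a[shared].astype(int) - gt_b[shared].astype(int))
    n2 = int(np.sum(diff == 0))
    n1 = int(np.sum(diff == 1))
    return IBSCounts(int(shared.sum()) - n1 - n2, n1, n2)


def expected_ibs_given_ibd(maf: float) -> np.ndarray:
    """3x3 table P(IBS = s | IBD = k), rows k = 0, 1, 2, columns s.

    Valid for any allele frequency strictly inside (0, 1); rows sum to 1.
    """
    a = float(maf)
    if not (0.0 < a < 1.0):
        raise ValueError("allele frequency must lie strictly in (0, 1)")
    b = 1.0 - a
    row0 = (2 * a**2 * b**2,
            4 * a**3 * b + 4 * a * b**3,
            a**4 + b**4 + 4 * a**2 * b**2)
    row1 = (0.0, 2 * a * b, a**2 + b**2)
    row2 = (0.0, 0.0, 1.0)
    return np.array([row0, row1, row2], dtype=float)


def _expected_sums(freqs: np.ndarray) -> np.ndarray:
    """Summed E[IBS=s | IBD=k] over sites, shape (3, 3)."""
    a = np.asarray(freqs, float)
    b = 1.0 - a
    e = np.empty((3, 3))
    e[0, 0] = np.sum(2 * a**2 * b**2)
    e[0, 1] = np.sum(4 * a**3 * b + 4 * a * b**3)
    e[0, 2] = np.sum(a**4 + b**4 + 4 * a**2 * b**2)
    e[1, 0] = 0.0
    e[1, 1] = np.sum(2 * a * b)
    e[1, 2] = np.sum(a**2 + b**2)
    e[2, :] = (0.0, 0.0, float(len(a)))
    return e


def _solve_moments(n0: float, n1: float, n2: float,
                   e: np.ndarray, L: float) -> tuple[float, float, float]:
    """Sequential moment equations followed by clamp-and-renormalize."""
    if e[0, 0] <= 0:
        raise ValueError("all site frequencies degenerate: E[IBS0|IBD0] = 0")
    z0 = n0 / e[0, 0]
    z1 = (n1 - z0 * e[0, 1]) / e[1, 1]
    z2 = (n2 - z0 * e[0, 2] - z1 * e[1, 2]) / L
    z = np.clip([z0, z1, z2], 0.0, 1.0)
    total = z.sum()
    if total == 0:
        raise ValueError("degenerate estimate: all components clamped to 0")
    z = z / total
    return float(z[0]), float(z[1]), float(z[2])


def _pair_estimate(gt_a: np.ndarray, gt_b: np.ndarray, freqs: np.ndarray,
                   id1: str, id2: str) -> IBDEstimate:
    shared = (gt_a != MISSING) & (gt_b != MISSING)
    L = int(shared.sum())
    if L == 0:
        raise ValueError(f"no shared non-missing sites for pair ({id1}, {id2})")
    n = ibs_counts(gt_a, gt_b)
    e = _expected_sums(freqs[shared])
    z0, z1, z2 = _solve_moments(n.n0, n.n1, n.n2, e, L)
    return IBDEstimate(id1, id2, z0, z1, z2, L)


def estimate_ibd_pair(calls_a: np.ndarray, calls_b: np.ndarray,
                      freqs: np.ndarray, id1: str = "A", id2: str = "B"
                      ) -> IBDEstimate:
    """Moment-method IBD estimate for one pair of genotype vectors.

    ``calls_a``/``calls_b`` are dosage vectors with -1 for missing;
    ``freqs`` are per-site alt-allele frequencies.  Only pairwise-complete
    sites enter the counts and the expectation sums.
    """
    gt_a = np.asarray(calls_a)
    gt_b = np.asarray(calls_b)
    if gt_a.shape != gt_b.shape or gt_a.shape != np.asarray(freqs).shape:
        raise ValueError("genotype vectors and frequencies must align")
    return _pair_estimate(gt_a, gt_b, np.asarray(freqs, float), id1, id2)


class IBDMomentEstimator(BaseEstimator):
    """Pairwise method-of-moments IBD estimator over a genotype matrix.

    Parameters
    ----------
    freq_source : {"given", "sample"}
        "given": per-site allele frequencies are supplied to :meth:`fit`
        (panel truth).  "sample": frequencies are estimated from the
        non-missing genotypes of the fitted matrix.
    min_shared_sites : int
        Pairs with fewer pairwise-complete sites are flagged rather than
        estimated.

    Attributes
    ----------
    freqs_ : ndarray
        Per-site alt-allele frequencies used in the moment equations.
    """

    def __init__(self, freq_source: str = "given", min_shared_sites: int = 1):
        self.freq_source = freq_source
        self.min_shared_sites = min_shared_sites

    def fit(self, G: np.ndarray, freqs: np.ndarray | None = None
            ) -> "IBDMomentEstimator":
        G = np.asarray(G)
        if G.ndim != 2 or G.shape[0] < 2:
            raise ValueError("need a (n_samples >= 2, n_sites) genotype matrix")
        if self.freq_source == "given":
            if freqs is None:
                raise ValueError("freq_source='given' requires freqs")
            self.freqs_ = np.asarray(freqs, float)
        elif self.freq_source == "sample":
            obs = G != MISSING
            n_obs = obs.sum(axis=0)
            with np.errstate(invalid="ignore"):
                f = np.where(G == MISSING, 0, G).sum(axis=0) / np.maximum(1, 2 * n_obs)
            self.freqs_ = np.where(n_obs > 0, f, np.nan)
        else:
            raise ValueError("freq_source must be 'given' or 'sample'")
        if self.freqs_.shape[0] != G.shape[1]:
            raise ValueError("frequency vector length mismatch")
        self.n_sites_ = G.shape[1]
        return self

    def transform(self, G: np.ndarray,
                  sample_ids: list[str] | None = None) -> pd.DataFrame:
        """IBD table for all unordered pairs of rows of ``G``.

        Pair-level failures (no shared sites, degenerate frequencies) are
        returned as flagged rows with NaN estimates, not raised.
        """
        G = np.asarray(G)
        if sample_ids is None:
            sample_ids = [f"S{i}" for i in range(G.shape[0])]
        rows = []
        for i, j in combinations(range(G.shape[0]), 2):
            id1, id2 = sample_ids[i], sample_ids[j]
            try:
                shared = (G[i] != MISSING) & (G[j] != MISSING)
                if int(shared.sum()) < self.min_shared_sites:
                    raise ValueError("too few shared sites")
                est = _pair_estimate(G[i], G[j], self.freqs_, id1, id2)
                rows.append([id1, id2, est.n_snps, est.z0, est.z1, est.z2,
                             est.pi_hat, ""])
            except ValueError as exc:
                rows.append([id1, id2, 0, np.nan, np.nan, np.nan, np.nan,
                             str(exc)])
        return pd.DataFrame(rows, columns=IBD_TABLE_COLUMNS)

    def fit_transform(self, G: np.ndarray, freqs: np.ndarray | None = None,
                      sample_ids: list[str] | None = None) -> pd.DataFrame:
        return self.fit(G, freqs).transform(G, sample_ids)


def estimate_ibd_matrix(calls: GenotypeCalls | np.ndarray,
                        freqs: np.ndarray | None = None,
                        freq_source: str = "given",
                        sample_ids: list[str] | None = None) -> pd.DataFrame:
    """IBD estimates for all unordered sample pairs.

    Accepts either a :class:`GenotypeCalls` (its passing calls are used) or
    a raw dosage matrix with -1 for missing.
    """
    if isinstance(calls, GenotypeCalls):
        G = calls.masked_gt()
        sample_ids = sample_ids or list(calls.sample_ids)
    else:
        G = np.asarray(calls)
    est = IBDMomentEstimator(freq_source=freq_source)
    return est.fit_transform(G, freqs=freqs, sample_ids=sample_ids)
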