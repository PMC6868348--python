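"""RNA-seq-like allele counts at SNP sites.

Instead of emitting reads, the simulator works at the count level, which
preserves exactly the statistical structure genotyping and IBD estimation
see:

* sequencing depth at a site is Poisson with a gene-level mean proportional
  to the gene's expression weight (RPKM-like) times library size - the
  hallmark expression skew of RNA-seq coverage;
* at heterozygous sites the alt-read fraction follows a gene x individual
  allelic balance theta drawn from a symmetric Beta (allele-specific
  expression), with a configurable fraction of genes forced near-monoallelic
  (the "one allele masked" failure mode);
* at homozygous sites the absent allele appears with per-read error
  probability epsilon;
* males carry a small fraction of Y-mapped reads, used for sex inference.

Depth titration is binomial thinning of every count cell, the count-level
equivalent of subsampling reads from FASTQ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genedrop import HaplotypeSet
from .panel import VariantPanel

__all__ = [
    "ExpressionProfile", "CountSimParams", "AlleleCounts",
    "simulate_allele_counts", "subsample_counts",
]


@dataclass
class ExpressionProfile:
    """Relative expression weight per gene plus a target library size."""

    weights: pd.Series          # index gene_id, non-negative RPKM-like weights
    total_reads: int = 40_000_000

    def __post_init__(self) -> None:
        w = self.weights.to_numpy(float)
        if len(w) == 0 or not np.any(w > 0):
            raise ValueError("expression profile needs at least one positive weight")
        if np.any(w < 0):
            raise ValueError("expression weights must be non-negative")
        if self.total_reads < 0:
            raise ValueError("total_reads must be >= 0")

    @classmethod
    def lognormal(cls, gene_ids: Sequence[str], sigma: float = 1.5,
                  total_reads: int = 40_000_000, seed: int = 0,
                  silent_fraction: float = 0.1) -> "ExpressionProfile":
        """Log-normal expression weights with a silent-gene tail, emulating
        the skewed RPKM distribution of a lymphoblastoid transcriptome."""
        rng = np.random.default_rng(seed)
        w = rng.lognormal(mean=0.0, sigma=sigma, size=len(gene_ids))
        w[rng.random(len(gene_ids)) < silent_fraction] = 0.0
        if not np.any(w > 0):       # pathological tiny gene sets
            w[0] = 1.0
        return cls(pd.Series(w, index=list(gene_ids)), total_reads)

    @classmethod
    def from_tsv(cls, path, total_reads: int = 40_000_000) -> "ExpressionProfile":
        df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "weight"],
                         comment="#")
        return cls(pd.Series(df["weight"].to_numpy(float),
                             index=df["gene_id"].astype(str)), total_reads)

    def to_tsv(self, path) -> None:
        self.weights.rename_axis("gene_id").rename("weight").to_csv(
            path, sep="\t", header=False)

    def site_weights(self, gene_ids: np.ndarray) -> np.ndarray:
        """Per-site gene weight (0 for genes absent from the profile)."""
        return self.weights.reindex(gene_ids).fillna(0.0).to_numpy(float)


@dataclass
class CountSimParams:
    """Noise model for count simulation.

    error_rate
        Per-read allele miscall probability epsilon.
    ase_concentration
        Concentration of the symmetric Beta allelic-balance law at
        heterozygous sites (Beta(k/2, k/2)); larger = more balanced.
    monoallelic_fraction
        Fraction of expressed genes per individual with extreme skew
        (theta near 0 or 1), emulating monoallelic expression.
    capture_per_site
        Expected reads informative for one site per library read at a gene
        of average expression; site mean depth =
        total_reads * capture_per_site * (gene weight / mean site weight).
    y_male_fraction / y_female_fraction
        Expected fraction of the library mapping to chrY for males (true
        Y transcription) and females (mismapping background).
    """

    error_rate: float = 0.01
    ase_concentration: float = 20.0
    monoallelic_fraction: float = 0.02
    capture_per_site: float = 7.5e-7
    y_male_fraction: float = 2e-3
    y_female_fraction: float = 1e-5

    def __post_init__(self) -> None:
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must lie in [0, 0.5)")
        if self.ase_concentration <= 0:
            raise ValueError("ase_concentration must be > 0")
        if not (0 <= self.monoallelic_fraction <= 1):
            raise ValueError("monoallelic_fraction must lie in [0, 1]")


@dataclass
class AlleleCounts:
    """Per individual x site ref/alt read counts plus Y/total read tallies."""

    sample_ids: list[str]
    ref: np.ndarray            # (n_samples, n_sites) int64
    alt: np.ndarray
    y_reads: np.ndarray        # (n_samples,)
    total_reads: np.ndarray    # (n_samples,)

    def __post_init__(self) -> None:
        if self.ref.shape != self.alt.shape or self.ref.shape[0] != len(self.sample_ids):
            raise ValueError("count array shapes inconsistent with sample_ids")
        if np.any(self.ref < 0) or np.any(self.alt < 0):
            raise ValueError("counts must be non-negative")
        self._index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_sites(self) -> int:
        return self.ref.shape[1]

    @property
    def depth(self) -> np.ndarray:
        return self.ref + self.alt

    def index(self, iid: str) -> int:
        return self._index[iid]

    def subset_sites(self, mask_or_index) -> "AlleleCounts":
        arr = np.asarray(mask_or_index)
        return AlleleCounts(list(self.sample_ids), self.ref[:, arr],
                            self.alt[:, arr], self.y_reads.copy(),
                            self.total_reads.copy())


def simulate_allele_counts(haps: HaplotypeSet, panel: VariantPanel,
                           profile: ExpressionProfile, params: CountSimParams,
                           seed: int = 0,
                           sexes: Mapping[str, str] | None = None) -> AlleleCounts:
    """Simulate allele counts for every individual in ``haps``.

    Genes absent from the profile get weight 0 (depth 0 at their sites).
    ``sexes`` drives Y-read simulation; missing entries default to unknown
    (treated as female-level Y background).
    """
    if profile.total_reads < 0:
        raise ValueError("negative total_reads")
    rng = np.random.default_rng(seed)
    gt = haps.genotypes()                       # (S, n) in {0,1,2}
    s, n = gt.shape
    w_site = profile.site_weights(panel.gene_ids)
    mean_w = w_site.mean()
    if mean_w == 0:
        raise ValueError("no panel gene has positive expression weight")
    mu = profile.total_reads * params.capture_per_site * (w_site / mean_w)

    genes = pd.unique(panel.gene_ids)
    gene_pos = pd.Series(np.arange(len(genes)), index=genes)
    site_gene = gene_pos[panel.gene_ids].to_numpy()

    # gene x individual allelic balance; monoallelic genes get theta near 0/1
    a = params.ase_concentration / 2.0
    theta_gene = rng.beta(a, a, size=(s, len(genes)))
    mono = rng.random((s, len(genes))) < params.monoallelic_fraction
    if mono.any():
        extreme = rng.beta(1.0, 99.0, size=int(mono.sum()))
        flip = rng.random(int(mono.sum())) < 0.5
        theta_gene[mono] = np.where(flip, 1.0 - extreme, extreme)
    theta_site = theta_gene[:, site_gene]       # (S, n)

    depth = rng.poisson(np.broadcast_to(mu, (s, n)))
    p_alt = np.where(gt == 1, theta_site,
                     np.where(gt == 0, params.error_rate, 1.0 - params.error_rate))
    alt = rng.binomial(depth, p_alt)
    ref = depth - alt

    sexes = dict(sexes or {})
    y_frac = np.array([params.y_male_fraction if sexes.get(i) == "male"
                       else params.y_female_fraction for i in haps.sample_ids])
    y_reads = rng.poisson(y_frac * profile.total_reads)
    total = np.full(s, profile.total_reads, dtype=np.int64)
    return AlleleCounts(list(haps.sample_ids), ref.astype(np.int64),
                        alt.astype(np.int64), y_reads.astype(np.int64), total)


def subsample_counts(counts: AlleleCounts, fraction: float,
                     seed: int = 0) -> AlleleCounts:
    """Binomial thinning: keep each read independently with prob ``fraction``.

    Applies to every ref/alt cell and to the Y/total read tallies, the
    count-level equivalent of subsampling a FASTQ.  ``fraction`` 1 returns
    an identical copy; 0 empties everything.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if fraction == 1.0:
        return AlleleCounts(list(counts.sample_ids), counts.ref.copy(),
                            counts.alt.copy(), counts.y_reads.copy(),
                            counts.total_reads.copy())
    return AlleleCounts(
        list(counts.sample_ids),
        rng.binomial(counts.ref, fraction),
        rng.binomial(counts.alt, fraction),
        rng.binomial(counts.y_reads, fraction),
        rng.binomial(counts.total_reads, fraction),
    )
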