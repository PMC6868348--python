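"""Gene-dropping simulation of genotypes down a pedigree.

Founders receive haplotypes drawn independently per site from the panel
allele frequencies; every non-founder receives one recombinant gamete per
parent.  Crossovers along each chromosome form a homogeneous Poisson
process at ``recombination_rate`` cM/Mb (default 1), i.e. an expected
``L_Mb * rate / 100`` crossovers per meiosis per chromosome, with no
interference.  Every allele carries a *founder-origin label* (which founder
haplotype it was copied from), so identity-by-descent between any two
individuals is known exactly at every site - the ground truth the
moment-method estimator is judged against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .panel import VariantPanel, default_chrom_lengths
from .pedigree import Pedigree

__all__ = [
    "GeneticMapConfig", "HaplotypeSet",
    "simulate_founder_haplotypes", "gene_drop", "true_ibd_fractions",
]


@dataclass
class GeneticMapConfig:
    """Uniform genetic map: cM per Mb plus physical chromosome lengths."""

    recombination_rate: float = 1.0  # cM / Mb
    chrom_lengths: dict[str, int] = field(default_factory=default_chrom_lengths)

    def __post_init__(self) -> None:
        if self.recombination_rate < 0:
            raise ValueError("recombination rate must be >= 0")
        if any(v < 1 for v in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be >= 1 bp")

    @property
    def crossover_rate_per_bp(self) -> float:
        # rate cM/Mb -> Morgans/bp: (rate/100) per Mb = rate * 1e-8 per bp
        return self.recombination_rate * 1e-8


@dataclass
class HaplotypeSet:
    """Phased alleles plus founder-origin labels for a set of individuals.

    ``alleles``/``origins`` have shape (n_samples, 2, n_sites); alleles are
    0 = ref, 1 = alt; origins encode (founder index, haplotype) as
    ``2 * founder_index + hap`` over the founder ordering in ``founder_ids``.
    """

    sample_ids: list[str]
    alleles: np.ndarray
    origins: np.ndarray
    founder_ids: list[str]

    def __post_init__(self) -> None:
        if self.alleles.shape != self.origins.shape:
            raise ValueError("alleles and origins must have the same shape")
        if self.alleles.shape[0] != len(self.sample_ids):
            raise ValueError("sample axis does not match sample_ids")
        if self.alleles.ndim != 3 or self.alleles.shape[1] != 2:
            raise ValueError("expected shape (n_samples, 2, n_sites)")
        self._index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[2]

    def index(self, iid: str) -> int:
        return self._index[iid]

    def genotypes(self) -> np.ndarray:
        """Unphased alt-allele dosage matrix, shape (n_samples, n_sites)."""
        return self.alleles.sum(axis=1).astype(np.int8)

    def subset_sites(self, mask_or_index) -> "HaplotypeSet":
        arr = np.asarray(mask_or_index)
        return HaplotypeSet(list(self.sample_ids),
                            self.alleles[:, :, arr], self.origins[:, :, arr],
                            list(self.founder_ids))


def simulate_founder_haplotypes(panel: VariantPanel, founder_ids: Sequence[str],
                                seed: int = 0) -> HaplotypeSet:
    """Independent-site founder haplotypes with P(alt) = panel MAF.

    The alt allele is the minor allele by construction.  Sites are drawn
    independently (linkage equilibrium among founders); origin labels are
    ``2 * founder_index + haplotype``.
    """
    founder_ids = list(founder_ids)
    if len(set(founder_ids)) != len(founder_ids):
        raise ValueError("duplicate founder ids")
    if panel.n_sites == 0:
        raise ValueError("empty panel")
    rng = np.random.default_rng(seed)
    n, f = panel.n_sites, len(founder_ids)
    alleles = (rng.random((f, 2, n)) < panel.maf[None, None, :]).astype(np.int8)
    origins = np.empty((f, 2, n), dtype=np.int32)
    origins[:, 0, :] = (2 * np.arange(f))[:, None]
    origins[:, 1, :] = (2 * np.arange(f) + 1)[:, None]
    return HaplotypeSet(founder_ids, alleles, origins, founder_ids)


def _meiosis(alleles2: np.ndarray, origins2: np.ndarray,
             chrom_slices: list[tuple[str, slice]], positions: np.ndarray,
             gmap: GeneticMapConfig, rng: np.random.Generator
             ) -> tuple[np.ndarray, np.ndarray]:
    """One recombinant gamete from a parent's two haplotypes."""
    n = alleles2.shape[1]
    hap_idx = np.empty(n, dtype=np.int8)
    rate = gmap.crossover_rate_per_bp
    for chrom, sl in chrom_slices:
        length = gmap.chrom_lengths.get(chrom)
        if length is None:
            raise ValueError(f"chromosome {chrom} missing from genetic map")
        start = int(rng.integers(2))
        n_x = rng.poisson(rate * length)
        if n_x == 0:
            hap_idx[sl] = start
            continue
        xpos = np.sort(rng.uniform(0.0, float(length), n_x))
        # sites after an odd number of crossovers sit on the other haplotype
        switches = np.searchsorted(xpos, positions[sl].astype(float))
        hap_idx[sl] = (start + switches) % 2
    cols = np.arange(n)
    return alleles2[hap_idx, cols], origins2[hap_idx, cols]


def gene_drop(pedigree: Pedigree, founders: HaplotypeSet,
              gmap: GeneticMapConfig, panel: VariantPanel,
              seed: int = 0) -> HaplotypeSet:
    """Drop founder haplotypes through the pedigree with recombination.

    Each non-founder gets the paternal gamete as haplotype 0 and the
    maternal gamete as haplotype 1; origin labels travel with the alleles,
    so Mendelian transmission is verifiable site by site.  Founder rows are
    passed through unchanged.
    """
    missing = [f for f in pedigree.founders if f not in founders.sample_ids]
    if missing:
        raise ValueError(f"founder haplotypes missing for {missing}")
    rng = np.random.default_rng(seed)
    n = founders.n_sites
    if n != panel.n_sites:
        raise ValueError("haplotype set and panel disagree on site count")
    chrom_slices = panel.chrom_slices()
    positions = panel.sites["pos"].to_numpy()

    order = pedigree.topological_order()
    s = len(order)
    alleles = np.zeros((s, 2, n), dtype=np.int8)
    origins = np.zeros((s, 2, n), dtype=np.int32)
    idx = {iid: i for i, iid in enumerate(order)}
    for iid in order:
        member = pedigree[iid]
        i = idx[iid]
        if member.father is None:
            j = founders.index(iid)
            alleles[i] = founders.alleles[j]
            origins[i] = founders.origins[j]
        else:
            for hap, parent in enumerate((member.father, member.mother)):
                p = idx[parent]
                a, o = _meiosis(alleles[p], origins[p], chrom_slices,
                                positions, gmap, rng)
                alleles[i, hap] = a
                origins[i, hap] = o
    return HaplotypeSet(order, alleles, origins, list(founders.founder_ids))


def true_ibd_fractions(a: str, b: str, haps: HaplotypeSet
                       ) -> tuple[float, float, float]:
    """Realized genome-wide (Z0, Z1, Z2) for a pair, from origin labels.

    The per-site IBD state is the size of the maximum matching between the
    two individuals' origin-label pairs (well defined even for inbred
    pedigrees where both matchings exist).  Returns site fractions summing
    to 1; symmetric in its arguments.
    """
    ia, ib = haps.index(a), haps.index(b)
    a1, a2 = haps.origins[ia, 0], haps.origins[ia, 1]
    b1, b2 = haps.origins[ib, 0], haps.origins[ib, 1]
    m11, m12 = a1 == b1, a1 == b2
    m21, m22 = a2 == b1, a2 == b2
    two = (m11 & m22) | (m12 & m21)
    one = ~two & (m11 | m12 | m21 | m22)
    z2 = float(np.mean(two))
    z1 = float(np.mean(one))
    return (1.0 - z1 - z2, z1, z2)
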