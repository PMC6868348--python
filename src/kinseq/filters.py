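"""Panel- and call-level site filters.

Three independent, composable filters mirror the SNP-cleaning cascade used
before IBD estimation from transcriptome genotypes:

* interval exclusion (repeats, imprinted genes, optionally segmental
  duplications) from BED intervals or synthetic panel flags;
* restriction to autosomal, strictly biallelic SNPs;
* a minor-allele-frequency floor (default 0.3), folded as min(f, 1 - f).

Coordinates: BED intervals are 0-based half-open, panel/VCF positions are
1-based; a site at 1-based p falls inside [start, end) iff
start <= p - 1 < end.  All filters are idempotent, order-independent and
only ever remove sites.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .panel import VariantPanel

__all__ = [
    "ExclusionIntervals", "FilterConfig", "exclude_intervals",
    "exclude_flagged", "filter_maf", "maf_mask", "restrict_autosomes_biallelic",
]

_AUTOSOME_RE = re.compile(r"^(chr)?\d+$")


@dataclass
class ExclusionIntervals:
    """Labelled genomic intervals in BED (0-based half-open) coordinates."""

    intervals: pd.DataFrame     # columns chrom, start, end
    label: str = "custom"

    def __post_init__(self) -> None:
        df = self.intervals
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"intervals need a {col!r} column")
        if len(df) and (df["start"] >= df["end"]).any():
            raise ValueError("malformed interval: start must be < end")

    @classmethod
    def from_bed(cls, path, label: str = "custom") -> "ExclusionIntervals":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"])
        return cls(df, label)

    def to_bed(self, path) -> None:
        self.intervals[["chrom", "start", "end"]].to_csv(
            path, sep="\t", header=False, index=False)

    def trees(self) -> dict[str, IntervalTree]:
        out: dict[str, IntervalTree] = {}
        for chrom, sub in self.intervals.groupby("chrom"):
            out[str(chrom)] = IntervalTree.from_tuples(
                zip(sub["start"].astype(int), sub["end"].astype(int)))
        return out


@dataclass
class FilterConfig:
    """Thresholds for the site-filter cascade."""

    min_maf: float = 0.3
    autosomes_only: bool = True
    excluded_labels: tuple[str, ...] = ("repeat", "imprinted")

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_maf <= 0.5):
            raise ValueError("min_maf must lie in [0, 0.5]")


def interval_mask(panel: VariantPanel,
                  excl: ExclusionIntervals | Iterable[ExclusionIntervals]
                  ) -> np.ndarray:
    """Boolean keep-mask: True for sites outside every exclusion interval."""
    if isinstance(excl, ExclusionIntervals):
        excl = [excl]
    keep = np.ones(panel.n_sites, dtype=bool)
    for e in excl:
        trees = e.trees()
        chroms = panel.sites["chrom"].to_numpy()
        pos = panel.sites["pos"].to_numpy()
        for chrom, tree in trees.items():
            idx = np.flatnonzero(chroms == chrom)
            for i in idx:
                if tree.overlaps_point(int(pos[i]) - 1):
                    keep[i] = False
    return keep


def exclude_intervals(panel: VariantPanel,
                      excl: ExclusionIntervals | Iterable[ExclusionIntervals]
                      ) -> VariantPanel:
    """Drop sites falling inside any exclusion interval, order preserved."""
    return panel.subset(interval_mask(panel, excl))


def exclude_flagged(panel: VariantPanel,
                    labels: Sequence[str] = ("repeat", "imprinted")) -> VariantPanel:
    """Drop sites carrying any of the given synthetic panel flags."""
    keep = np.ones(panel.n_sites, dtype=bool)
    for label in labels:
        if label not in panel.sites.columns:
            raise ValueError(f"panel has no flag column {label!r}")
        keep &= ~panel.sites[label].to_numpy(bool)
    return panel.subset(keep)


def maf_mask(allele_freqs: np.ndarray, min_maf: float) -> np.ndarray:
    """Keep-mask for the folded-frequency filter min(f, 1-f) >= min_maf."""
    f = np.asarray(allele_freqs, float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    if not (0.0 <= min_maf <= 0.5):
        raise ValueError("min_maf must lie in [0, 0.5]")
    return np.minimum(f, 1.0 - f) >= min_maf


def filter_maf(panel: VariantPanel, min_maf: float = 0.3,
               allele_freqs: np.ndarray | None = None) -> VariantPanel:
    """MAF filter on a panel.

    By default uses the panel's own (truth) frequencies; pass
    ``allele_freqs`` (e.g. sample-estimated alt frequencies) to filter on an
    alternative source - which source was used is the caller's recorded
    parameter.
    """
    freqs = panel.maf if allele_freqs is None else allele_freqs
    return panel.subset(maf_mask(freqs, min_maf))


def restrict_autosomes_biallelic(panel: VariantPanel) -> VariantPanel:
    """Keep only autosomal, strictly biallelic single-base SNPs."""
    df = panel.sites
    autosomal = df["chrom"].astype(str).str.match(_AUTOSOME_RE)
    biallelic = (df["ref"].str.len() == 1) & (df["alt"].str.len() == 1) \
        & (df["ref"] != df["alt"])
    return panel.subset((autosomal & biallelic).to_numpy())
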