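"""Synthetic variant panels.

A panel is the universe of common biallelic SNPs the pipeline genotypes:
each site has a chromosome, a 1-based position, ref/alt alleles, a
population minor-allele frequency (MAF), the gene it falls in, and optional
exclusion flags (``repeat``, ``imprinted``, ``segdup``) mimicking the
annotation tracks used to blacklist problematic regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["VariantPanel", "make_panel", "default_chrom_lengths"]

_BASES = np.array(list("ACGT"))

#: Columns every panel table carries, in order.
PANEL_COLUMNS = [
    "chrom", "pos", "ref", "alt", "maf", "gene_id",
    "repeat", "imprinted", "segdup",
]


def default_chrom_lengths(n_chroms: int = 22, length_bp: int = 100_000_000) -> dict[str, int]:
    """Equal-length autosome map, ``chr1`` .. ``chr{n}``."""
    return {f"chr{i}": int(length_bp) for i in range(1, n_chroms + 1)}


@dataclass
class VariantPanel:
    """An ordered table of biallelic SNP sites plus the chromosome map.

    ``sites`` is a :class:`pandas.DataFrame` with :data:`PANEL_COLUMNS`;
    rows are sorted by (chrom, pos) with a 0..n-1 RangeIndex so that
    haplotype/count arrays can be aligned positionally.
    """

    sites: pd.DataFrame
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.sites
        missing = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"panel table missing columns {missing}")
        if len(df):
            maf = df["maf"].to_numpy(float)
            if np.any(maf <= 0) or np.any(maf > 0.5):
                raise ValueError("maf must lie in (0, 0.5]")
            if np.any(df["pos"].to_numpy() < 1):
                raise ValueError("positions are 1-based and must be >= 1")
            if (df["ref"] == df["alt"]).any():
                raise ValueError("ref and alt alleles must differ")
        self.sites = df.reset_index(drop=True)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def maf(self) -> np.ndarray:
        return self.sites["maf"].to_numpy(float)

    @property
    def gene_ids(self) -> np.ndarray:
        return self.sites["gene_id"].to_numpy()

    def chrom_slices(self) -> list[tuple[str, slice]]:
        """Contiguous (chrom, row-slice) blocks in panel order."""
        out: list[tuple[str, slice]] = []
        chroms = self.sites["chrom"].to_numpy()
        if len(chroms) == 0:
            return out
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out.append((chroms[start], slice(start, i)))
                start = i
        return out

    def subset(self, mask_or_index) -> "VariantPanel":
        """Row-subset preserving order; accepts a boolean mask or index array."""
        arr = np.asarray(mask_or_index)
        sub = self.sites[arr] if arr.dtype == bool else self.sites.iloc[arr]
        return VariantPanel(sub.reset_index(drop=True), dict(self.chrom_lengths))

    def to_tsv(self, path) -> None:
        self.sites.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, chrom_lengths: Mapping[str, int] | None = None) -> "VariantPanel":
        df = pd.read_csv(path, sep="\t")
        for flag in ("repeat", "imprinted", "segdup"):
            if flag not in df.columns:
                df[flag] = False
            df[flag] = df[flag].astype(bool)
        return cls(df, dict(chrom_lengths or {}))


def _resolve_maf_law(maf_law) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Accept a callable ``(rng, n) -> array`` or a ('fixed', v) /
    ('uniform', lo, hi) / ('beta', a, b) tuple; beta draws are folded to the
    minor allele and truncated away from 0."""
    if callable(maf_law):
        return maf_law
    kind = maf_law[0]
    if kind == "fixed":
        v = float(maf_law[1])
        return lambda rng, n: np.full(n, v)
    if kind == "uniform":
        lo, hi = float(maf_law[1]), float(maf_law[2])
        return lambda rng, n: rng.uniform(lo, hi, n)
    if kind == "beta":
        a, b = float(maf_law[1]), float(maf_law[2])

        def draw(rng: np.random.Generator, n: int) -> np.ndarray:
            f = rng.beta(a, b, n)
            f = np.minimum(f, 1.0 - f)
            return np.clip(f, 1e-6, 0.5)

        return draw
    raise ValueError(f"unknown maf law {maf_law!r}")


def make_panel(
    n_genes: int,
    sites_per_gene: int,
    chrom_lengths: Mapping[str, int] | None = None,
    maf_law=("uniform", 0.05, 0.5),
    seed: int = 0,
    *,
    gene_span_bp: int = 20_000,
    imprinted_gene_fraction: float = 0.0,
    repeat_site_fraction: float = 0.0,
    segdup_site_fraction: float = 0.0,
) -> VariantPanel:
    """Draw a synthetic SNP panel.

    Genes are placed on chromosomes with probability proportional to length;
    each gene owns ``sites_per_gene`` SNPs scattered over a ``gene_span_bp``
    window.  MAFs come from ``maf_law``.  Optional fractions of genes/sites
    are flagged imprinted / repeat / segdup so the exclusion filters have
    something to act on.  Fully deterministic given ``seed``.
    """
    if n_genes < 1 or sites_per_gene < 1:
        raise ValueError("n_genes and sites_per_gene must be >= 1")
    chrom_lengths = dict(chrom_lengths or default_chrom_lengths())
    rng = np.random.default_rng(seed)

    chroms = list(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in chroms], float)
    if np.any(lens < 1):
        raise ValueError("chromosome lengths must be >= 1 bp")
    gene_chrom = rng.choice(len(chroms), size=n_genes, p=lens / lens.sum())

    span = min(gene_span_bp, int(lens.min()))
    records: list[dict] = []
    imprinted_genes = set(
        np.flatnonzero(rng.random(n_genes) < imprinted_gene_fraction))
    for g in range(n_genes):
        ci = gene_chrom[g]
        chrom = chroms[ci]
        start = int(rng.integers(1, max(2, int(lens[ci]) - span + 1)))
        offsets = rng.choice(span, size=sites_per_gene, replace=sites_per_gene > span)
        for off in np.sort(offsets):
            records.append({
                "chrom": chrom,
                "pos": start + int(off),
                "gene_id": f"G{g:05d}",
                "imprinted": g in imprinted_genes,
            })
    df = pd.DataFrame.from_records(records)

    n = len(df)
    mafs = np.asarray(_resolve_maf_law(maf_law)(rng, n), float)
    if np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise ValueError("maf law produced values outside (0, 0.5]")
    ref_idx = rng.integers(0, 4, n)
    alt_idx = (ref_idx + rng.integers(1, 4, n)) % 4
    df["ref"] = _BASES[ref_idx]
    df["alt"] = _BASES[alt_idx]
    df["maf"] = mafs
    df["repeat"] = rng.random(n) < repeat_site_fraction
    df["segdup"] = rng.random(n) < segdup_site_fraction

    order = {c: i for i, c in enumerate(chroms)}
    df["_c"] = df["chrom"].map(order)
    df = df.sort_values(["_c", "pos"], kind="mergesort").drop(columns="_c")
    # collapse rare position collisions within a chromosome
    df = df.drop_duplicates(subset=["chrom", "pos"], keep="first")
    return VariantPanel(df[PANEL_COLUMNS].reset_index(drop=True), chrom_lengths)
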