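"""End-to-end orchestration: simulate -> call -> filter -> estimate -> classify.

A single master seed feeds named substreams (panel, founders, gene drop,
expression, counts, thinning) via :class:`numpy.random.SeedSequence`, so an
identical config reproduces every artifact bit for bit.  The depth
titration reruns calling/filtering/estimation on binomially thinned counts,
emulating read subsampling; ``extra_unrelated`` appends founder-like
individuals drawn from the same panel frequencies before count simulation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .calling import BinomialGenotypeCaller
from .classify import (NearestCentroidKinshipClassifier, class_separation,
                       pedigree_consistency)
from .counts import (AlleleCounts, CountSimParams, ExpressionProfile,
                     simulate_allele_counts, subsample_counts)
from .filters import maf_mask
from .genedrop import GeneticMapConfig, gene_drop, simulate_founder_haplotypes, \
    true_ibd_fractions
from .ibd import IBDMomentEstimator
from .panel import VariantPanel, default_chrom_lengths, make_panel
from .pedigree import Pedigree, pedigree_preset
from . import vcfio

logger = logging.getLogger("kinseq.pipeline")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "run_depth_titration",
           "add_unrelated"]

_STREAMS = ("panel", "founders", "genedrop", "expression", "counts",
            "thinning", "extra")


def _substream_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: int(c.generate_state(1)[0] % (2**31))
            for name, c in zip(_STREAMS, children)}


@dataclass
class RunConfig:
    """Everything a reproducible run needs.

    Scale defaults: 22 equal 100 Mb autosomes, 2,500 genes x 4 SNPs
    (10,000 panel sites), a 40M-read library per individual - the regime
    where the DP>=10 / GQ>=20 / MAF>=0.3 cascade leaves a few thousand
    usable SNPs per pair.
    """

    seed: int = 0
    # genome / panel
    n_chroms: int = 22
    chrom_length_bp: int = 100_000_000
    n_genes: int = 2500
    sites_per_gene: int = 4
    maf_law: tuple = ("uniform", 0.05, 0.5)
    recombination_rate: float = 1.0     # cM / Mb
    imprinted_gene_fraction: float = 0.01
    repeat_site_fraction: float = 0.10
    # pedigree
    pedigree: str = "type1"             # preset name or FAM path
    extra_unrelated: int = 0
    # expression / counts
    total_reads: int = 40_000_000
    expression_profile: str | None = None   # TSV path; None = built-in lognormal
    expression_sigma: float = 1.5
    error_rate: float = 0.01
    ase_concentration: float = 20.0
    monoallelic_fraction: float = 0.02
    capture_per_site: float = 7.5e-7
    # filters
    min_dp: int = 10
    min_gq: int = 20
    min_maf: float = 0.3
    excluded_labels: tuple = ("repeat", "imprinted")
    freq_source: str = "panel"          # "panel" truth or "sample" estimated
    # classifier
    relatedness_cutoff: float = 0.2
    # titration
    titration_fractions: tuple = (1.0, 0.75, 0.5, 0.25, 0.2, 0.15, 0.1, 0.05)
    # output
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("maf_law", "excluded_labels", "titration_fractions"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for key in ("maf_law", "excluded_labels", "titration_fractions"):
            d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class RunReport:
    """All artifacts of one pipeline run."""

    config: RunConfig
    stage_counts: dict[str, int]
    ibd: pd.DataFrame                  # per-pair table with relationship calls
    truth: pd.DataFrame                # realized IBD truth + expected classes
    confusion: pd.DataFrame
    sensitivity: pd.Series
    overlap: pd.DataFrame              # expected-class hull overlap matrix
    min_distance: pd.DataFrame
    sex_calls: dict[str, str]
    artifacts: dict[str, str] = field(default_factory=dict)


def _load_pedigree(config: RunConfig) -> Pedigree:
    if Path(config.pedigree).exists():
        ped = Pedigree.from_fam(config.pedigree)
    else:
        ped = pedigree_preset(config.pedigree)
    if config.extra_unrelated:
        ped = ped.with_extra_founders(config.extra_unrelated)
    return ped


def _simulate(config: RunConfig):
    """Shared simulation front end: panel, pedigree, haplotypes, counts."""
    seeds = _substream_seeds(config.seed)
    chrom_lengths = default_chrom_lengths(config.n_chroms, config.chrom_length_bp)
    panel = make_panel(config.n_genes, config.sites_per_gene, chrom_lengths,
                       maf_law=config.maf_law, seed=seeds["panel"],
                       imprinted_gene_fraction=config.imprinted_gene_fraction,
                       repeat_site_fraction=config.repeat_site_fraction)
    ped = _load_pedigree(config)
    founders = simulate_founder_haplotypes(panel, ped.founders, seeds["founders"])
    gmap = GeneticMapConfig(config.recombination_rate, chrom_lengths)
    haps = gene_drop(ped, founders, gmap, panel, seeds["genedrop"])
    genes = pd.unique(panel.gene_ids)
    if config.expression_profile:
        profile = ExpressionProfile.from_tsv(config.expression_profile,
                                             total_reads=config.total_reads)
    else:
        profile = ExpressionProfile.lognormal(genes, sigma=config.expression_sigma,
                                              total_reads=config.total_reads,
                                              seed=seeds["expression"])
    params = CountSimParams(error_rate=config.error_rate,
                            ase_concentration=config.ase_concentration,
                            monoallelic_fraction=config.monoallelic_fraction,
                            capture_per_site=config.capture_per_site)
    counts = simulate_allele_counts(haps, panel, profile, params,
                                    seed=seeds["counts"], sexes=ped.sexes())
    return seeds, panel, ped, haps, profile, counts


def _analyse(config: RunConfig, panel: VariantPanel, ped: Pedigree, haps,
             counts: AlleleCounts) -> tuple[dict, pd.DataFrame, dict]:
    """Call, filter, estimate and classify; returns (stage counts, table, sex)."""
    stage: dict[str, int] = {"panel_sites": panel.n_sites}

    caller = BinomialGenotypeCaller(error_rate=config.error_rate,
                                    min_dp=config.min_dp, min_gq=config.min_gq)
    calls = caller.call(counts)
    stage["calls_pass_dp_gq"] = int(calls.passed.sum())

    keep = np.ones(panel.n_sites, dtype=bool)
    for label in config.excluded_labels:
        keep &= ~panel.sites[label].to_numpy(bool)
    keep_idx = np.flatnonzero(keep)
    stage["sites_after_interval_exclusion"] = len(keep_idx)

    maf_keep = maf_mask(panel.maf[keep_idx], config.min_maf)
    keep_idx = keep_idx[maf_keep]
    stage["sites_after_maf"] = len(keep_idx)
    if len(keep_idx) == 0:
        raise RuntimeError("site filtering: no sites survive the cascade")

    sub_calls = calls.subset_sites(keep_idx)
    covered = (sub_calls.passed.any(axis=0))
    stage["sites_usable_any_sample"] = int(covered.sum())

    freqs = panel.maf[keep_idx]
    est = IBDMomentEstimator(
        freq_source="given" if config.freq_source == "panel" else "sample")
    G = sub_calls.masked_gt()
    table = est.fit_transform(
        G, freqs=freqs if config.freq_source == "panel" else None,
        sample_ids=list(sub_calls.sample_ids))
    stage["pairs"] = len(table)

    clf = NearestCentroidKinshipClassifier(config.relatedness_cutoff)
    table = clf.classify_table(table)

    from .calling import infer_sex
    sex_calls = {sid: infer_sex(int(counts.y_reads[i]),
                                max(1, int(counts.total_reads[i])))
                 for i, sid in enumerate(counts.sample_ids)}
    return stage, table, sex_calls


def _truth_table(ped: Pedigree, haps) -> pd.DataFrame:
    rows = []
    for a, b in ped.pairs():
        z0, z1, z2 = true_ibd_fractions(a, b, haps)
        exp = ped.expected_relationship(a, b)
        rows.append([a, b, z0, z1, z2, exp.relationship, exp.relatedness])
    return pd.DataFrame(rows, columns=["ID1", "ID2", "Z0_TRUE", "Z1_TRUE",
                                       "Z2_TRUE", "expected", "relatedness"])


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full workflow under a single master seed."""
    logger.info("run_pipeline seed=%d pedigree=%s", config.seed, config.pedigree)
    seeds, panel, ped, haps, profile, counts = _simulate(config)
    stage, table, sex_calls = _analyse(config, panel, ped, haps, counts)

    truth = _truth_table(ped, haps)
    merged = table.merge(truth[["ID1", "ID2", "expected"]], on=["ID1", "ID2"],
                         how="left")
    confusion, sensitivity, _ = pedigree_consistency(ped, table)
    valid = merged[merged[["Z0", "Z1", "Z2"]].notna().all(axis=1)]
    overlap, min_dist = class_separation(
        valid[["Z0", "Z1", "Z2"]].to_numpy(), valid["expected"].tolist())

    artifacts: dict[str, str] = {}
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        caller = BinomialGenotypeCaller(error_rate=config.error_rate,
                                        min_dp=config.min_dp, min_gq=config.min_gq)
        vcfio.write_vcf(out / "calls.vcf", panel, counts, caller.call(counts))
        vcfio.write_ibd_table(out / "ibd.tsv", merged)
        vcfio.write_truth_ibd(out / "truth_ibd.tsv", haps)
        ped.to_fam(out / "pedigree.fam")
        profile.to_tsv(out / "expression.tsv")
        confusion.to_csv(out / "confusion.tsv", sep="\t")
        with open(out / "stage_counts.json", "w") as fh:
            json.dump(stage, fh, indent=2)
        config.to_yaml(out / "config.yaml")
        try:
            from .plotting import ternary_plot
            fig = ternary_plot(valid[["Z0", "Z1", "Z2"]].to_numpy(),
                               valid["expected"].tolist())
            fig.savefig(out / "ternary.svg")
        except Exception as exc:   # plotting is best-effort reporting
            logger.warning("ternary plot failed: %s", exc)
        artifacts = {p.name: str(p) for p in out.iterdir()}
    for name, count in stage.items():
        logger.info("stage %-32s %d", name, count)
    return RunReport(config, stage, merged, truth, confusion, sensitivity,
                     overlap, min_dist, sex_calls, artifacts)


def run_depth_titration(config: RunConfig,
                        fractions: Sequence[float] | None = None
                        ) -> tuple[pd.DataFrame, dict[float, pd.DataFrame]]:
    """Re-analyse binomially thinned counts at each titration fraction.

    Returns a per-fraction summary (mean/min/max shared SNPs per pair,
    overlap flags between the key class pairs) and the per-fraction
    expected-class overlap matrices.  Fraction 1.0 reuses the unthinned
    counts, so its row equals the base run.
    """
    fractions = tuple(fractions if fractions is not None
                      else config.titration_fractions)
    if not fractions:
        raise ValueError("titration fractions must be non-empty")
    seeds, panel, ped, haps, profile, counts = _simulate(config)
    truth = _truth_table(ped, haps)
    thin_children = np.random.SeedSequence(seeds["thinning"]).spawn(len(fractions))

    summaries = []
    overlaps: dict[float, pd.DataFrame] = {}
    for frac, child in zip(fractions, thin_children):
        thin_seed = int(child.generate_state(1)[0] % (2**31))
        thinned = subsample_counts(counts, float(frac), seed=thin_seed)
        stage, table, _ = _analyse(config, panel, ped, haps, thinned)
        merged = table.merge(truth[["ID1", "ID2", "expected"]],
                             on=["ID1", "ID2"], how="left")
        valid = merged[merged[["Z0", "Z1", "Z2"]].notna().all(axis=1)]
        overlap, _ = class_separation(valid[["Z0", "Z1", "Z2"]].to_numpy(),
                                      valid["expected"].tolist())
        overlaps[float(frac)] = overlap

        def _pairwise(a: str, b: str):
            if a in overlap.index and b in overlap.index:
                return bool(overlap.loc[a, b])
            return np.nan

        summaries.append({
            "fraction": float(frac),
            "reads_per_individual": float(frac) * config.total_reads,
            "usable_sites": stage["sites_usable_any_sample"],
            "mean_pair_snps": float(valid["N_SNP"].mean()) if len(valid) else 0.0,
            "min_pair_snps": int(valid["N_SNP"].min()) if len(valid) else 0,
            "max_pair_snps": int(valid["N_SNP"].max()) if len(valid) else 0,
            "overlap_second_unrelated": _pairwise("second-degree", "unrelated"),
            "overlap_third_unrelated": _pairwise("third-degree", "unrelated"),
            "overlap_fs_second": _pairwise("full-sibling", "second-degree"),
        })
    return pd.DataFrame(summaries), overlaps


def add_unrelated(config: RunConfig, n: int) -> RunReport:
    """Run the pipeline with ``n`` extra unrelated individuals appended."""
    if n < 0:
        raise ValueError("n must be >= 0")
    cfg = dataclasses.replace(config, extra_unrelated=config.extra_unrelated + n)
    return run_pipeline(cfg)
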