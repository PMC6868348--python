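"""VCF, BED-adjacent and TSV I/O.

Genotypes and allele counts travel as uncompressed VCF v4.2 (written and
read with pysam) with the conventional FORMAT fields: GT, AD (ref,alt
depths), DP and - once calling has happened - GQ.  The site INFO carries
AF (panel alt-allele frequency) and GENE.  Pedigrees use 6-column FAM
(see :mod:`kinseq.pedigree`); IBD tables, relationship calls and truth
sidecars are plain TSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

from .calling import MISSING, GenotypeCalls
from .counts import AlleleCounts
from .panel import PANEL_COLUMNS, VariantPanel

__all__ = [
    "write_vcf", "read_vcf", "write_ibd_table", "read_ibd_table",
    "write_truth_ibd",
]

_GT_TUPLES = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}


def _make_header(panel: VariantPanel, sample_ids, with_gq: bool) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    chroms = dict(panel.chrom_lengths)
    for chrom in pd.unique(panel.sites["chrom"]):
        header.contigs.add(str(chrom), length=chroms.get(chrom))
    header.info.add("AF", number="A", type="Float", description="Alt allele frequency")
    header.info.add("GENE", number=1, type="String", description="Containing gene")
    header.formats.add("GT", number=1, type="String", description="Genotype")
    header.formats.add("AD", number="R", type="Integer",
                       description="Allelic depths (ref,alt)")
    header.formats.add("DP", number=1, type="Integer", description="Read depth")
    if with_gq:
        header.formats.add("GQ", number=1, type="Integer",
                           description="Phred-scaled genotype quality")
    for s in sample_ids:
        header.add_sample(str(s))
    return header


def write_vcf(path, panel: VariantPanel, counts: AlleleCounts | None = None,
              calls: GenotypeCalls | None = None) -> None:
    """Write panel sites with per-sample AD/DP and, if available, GT/GQ.

    ``counts`` and/or ``calls`` must cover exactly the panel's sites in
    panel order.  With only counts, GT is emitted as missing (uncalled).
    """
    if counts is None and calls is None:
        raise ValueError("need counts and/or calls to write")
    sample_ids = (calls or counts).sample_ids
    for obj in (counts, calls):
        if obj is not None and obj.n_sites != panel.n_sites:
            raise ValueError("sample data does not align with the panel")
    header = _make_header(panel, sample_ids, with_gq=calls is not None)
    # genotypes failing the DP/GQ filters are emitted as missing (./.)
    masked = calls.masked_gt() if calls is not None else None
    df = panel.sites
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for i in range(panel.n_sites):
            rec = vf.new_record(
                contig=str(df.at[i, "chrom"]), start=int(df.at[i, "pos"]) - 1,
                alleles=(str(df.at[i, "ref"]), str(df.at[i, "alt"])))
            rec.info["AF"] = float(df.at[i, "maf"])
            gene = df.at[i, "gene_id"]
            if isinstance(gene, str) and gene:
                rec.info["GENE"] = gene
            for s_idx, sid in enumerate(sample_ids):
                sample = rec.samples[str(sid)]
                if calls is not None:
                    sample["GT"] = _GT_TUPLES[int(masked[s_idx, i])]
                    sample["DP"] = int(calls.dp[s_idx, i])
                    sample["GQ"] = int(calls.gq[s_idx, i])
                else:
                    sample["GT"] = (None, None)
                if counts is not None:
                    sample["AD"] = (int(counts.ref[s_idx, i]),
                                    int(counts.alt[s_idx, i]))
                    if calls is None:
                        sample["DP"] = int(counts.ref[s_idx, i]
                                           + counts.alt[s_idx, i])
            vf.write(rec)


def read_vcf(path) -> tuple[VariantPanel, AlleleCounts | None, GenotypeCalls | None]:
    """Read a VCF written by :func:`write_vcf` (or compatible).

    Returns the panel plus AlleleCounts (if AD present) and GenotypeCalls
    (if any GT is non-missing; GQ defaults to 0 when absent).  Sites lacking
    an AF INFO get frequency 0.5 so they survive panel validation.
    """
    with pysam.VariantFile(str(path)) as vf:
        sample_ids = list(vf.header.samples)
        lengths = {c: (vf.header.contigs[c].length or 10**9)
                   for c in vf.header.contigs}
        site_rows, ad_ref, ad_alt, gts, dps, gqs = [], [], [], [], [], []
        has_ad = has_gt = False
        for rec in vf:
            if len(rec.alts or ()) != 1:
                continue
            af = rec.info.get("AF", (0.5,))
            af = float(af[0] if isinstance(af, tuple) else af)
            site_rows.append({
                "chrom": rec.contig, "pos": rec.pos, "ref": rec.ref,
                "alt": rec.alts[0], "maf": min(af, 1 - af) if af < 1 else 0.5,
                "gene_id": rec.info.get("GENE", ""),
                "repeat": False, "imprinted": False, "segdup": False,
            })
            row_r, row_a, row_g, row_d, row_q = [], [], [], [], []
            for sid in sample_ids:
                sample = rec.samples[sid]
                ad = sample.get("AD")
                if ad is not None and ad[0] is not None:
                    has_ad = True
                    row_r.append(int(ad[0]))
                    row_a.append(int(ad[1]))
                else:
                    row_r.append(0)
                    row_a.append(0)
                gt = sample.get("GT")
                if gt is not None and gt[0] is not None:
                    has_gt = True
                    row_g.append(int(gt[0]) + int(gt[1]))
                else:
                    row_g.append(MISSING)
                row_d.append(int(sample.get("DP") or 0))
                row_q.append(int(sample.get("GQ") or 0))
            ad_ref.append(row_r)
            ad_alt.append(row_a)
            gts.append(row_g)
            dps.append(row_d)
            gqs.append(row_q)
    panel = VariantPanel(pd.DataFrame(site_rows, columns=PANEL_COLUMNS), lengths)
    counts = calls = None
    if has_ad:
        ref = np.array(ad_ref, dtype=np.int64).T
        alt = np.array(ad_alt, dtype=np.int64).T
        zeros = np.zeros(len(sample_ids), dtype=np.int64)
        counts = AlleleCounts(sample_ids, ref, alt, zeros.copy(), zeros.copy())
    if has_gt:
        gt = np.array(gts, dtype=np.int8).T
        dp = np.array(dps, dtype=np.int32).T
        gq = np.array(gqs, dtype=np.int16).T
        calls = GenotypeCalls(sample_ids, gt, dp, gq, gt != MISSING)
    return panel, counts, calls


def write_ibd_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_ibd_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_ibd(path, haps, pairs=None) -> None:
    """TSV sidecar of realized (Z0, Z1, Z2) truth for sample pairs."""
    from .genedrop import true_ibd_fractions

    ids = haps.sample_ids
    if pairs is None:
        pairs = [(ids[i], ids[j]) for i in range(len(ids))
                 for j in range(i + 1, len(ids))]
    rows = []
    for a, b in pairs:
        z0, z1, z2 = true_ibd_fractions(a, b, haps)
        rows.append([a, b, z0, z1, z2])
    pd.DataFrame(rows, columns=["ID1", "ID2", "Z0_TRUE", "Z1_TRUE", "Z2_TRUE"]
                 ).to_csv(path, sep="\t", index=False, float_format="%.6f")
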