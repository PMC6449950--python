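"""Joining RNA-seq allelic counts to DNA-heterozygous SNPs.

An *informative SNP* is a SNP that is heterozygous in DNA and covered
deeply enough in RNA-seq to score its allelic balance.  This module joins
per-position allelic read counts onto the heterozygous genotype table,
computes the B-allele frequency (BAF), applies the read-depth and
coding-sequence filters, and assigns an RNA genotype (HomA / HomB / Het)
from the BAF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["sample_id", "chrom", "pos", "count_a", "count_b", "depth"]

_JOIN_KEYS = ["sample_id", "chrom", "pos"]


@dataclass(frozen=True)
class CountFilterConfig:
    """Filters applied to joined SNP count records.

    Parameters
    ----------
    depth_min
        Minimum total read depth, strict inequality: a SNP is kept only
        if depth > depth_min (default 5).
    hom_baf_tau
        BAF threshold for RNA homozygosity: HomA if baf <= tau, HomB if
        baf >= 1 - tau (default 0.05).
    require_cds
        Drop SNPs outside every coding-sequence interval (default True).
    binomial_guard
        If True, a call is only made homozygous when, in addition to the
        BAF threshold, a two-sided exact binomial test of count_b against
        p = 0.5 rejects at ``binomial_alpha``.  Guards against spurious
        homozygous calls at low depth.
    """

    depth_min: int = 5
    hom_baf_tau: float = 0.05
    require_cds: bool = True
    binomial_guard: bool = False
    binomial_alpha: float = 1e-3

    def __post_init__(self) -> None:
        if not 0 <= self.hom_baf_tau < 0.5:
            raise ValueError(f"hom_baf_tau must be in [0, 0.5), got {self.hom_baf_tau}")
        if self.depth_min < 0:
            raise ValueError("depth_min must be >= 0")


class CountJoinError(ValueError):
    """Raised when count and genotype tables cannot be reconciled."""


def load_counts(path: str, fmt: str = "tsv") -> pd.DataFrame:
    """Load per-SNP allelic read counts.

    ``tsv`` expects columns Sample_ID, Chr, Position, Count_A, Count_B;
    ``vcf`` reads the AD (allelic depth) FORMAT field of a multi-sample
    VCF, taking REF as allele A and the single ALT as allele B.
    """
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"Chr": "string"})
        need = ["Sample_ID", "Chr", "Position", "Count_A", "Count_B"]
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise CountJoinError(f"count table {path} lacks columns {missing}")
        from .genotype_io import normalize_chrom

        out = pd.DataFrame(
            {
                "sample_id": df["Sample_ID"].astype(str),
                "chrom": normalize_chrom(df["Chr"]),
                "pos": df["Position"].astype(np.int64),
                "count_a": df["Count_A"].astype(np.int64),
                "count_b": df["Count_B"].astype(np.int64),
            }
        )
    elif fmt == "vcf":
        out = _load_counts_vcf(path)
    else:
        raise ValueError(f"unknown count format {fmt!r}")
    if (out[["count_a", "count_b"]] < 0).any().any():
        raise CountJoinError(f"negative read counts in {path}")
    out["depth"] = out["count_a"] + out["count_b"]
    return out[COUNT_COLUMNS]


def _load_counts_vcf(path: str) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows = []
    for var in vcf:
        ad = var.format("AD")
        if ad is None:
            raise CountJoinError(f"{path}: no AD field at {var.CHROM}:{var.POS}")
        chrom = str(var.CHROM).removeprefix("chr").upper()
        for i, s in enumerate(samples):
            a, b = int(ad[i][0]), int(ad[i][1])
            if a < 0 or b < 0:  # cyvcf2 encodes missing as negative
                continue
            rows.append((s, chrom, var.POS, a, b))
    out = pd.DataFrame(rows, columns=COUNT_COLUMNS[:5])
    out["depth"] = out["count_a"] + out["count_b"]
    return out


def compute_baf(count_a, count_b):
    """B-allele frequency count_b / (count_a + count_b).

    Accepts scalars or arrays; zero-depth entries yield NaN (such records
    are excluded upstream by the depth filter).
    """
    a = np.asarray(count_a, dtype=float)
    b = np.asarray(count_b, dtype=float)
    depth = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        baf = np.where(depth > 0, b / np.where(depth > 0, depth, 1.0), np.nan)
    if np.ndim(count_a) == 0 and np.ndim(count_b) == 0:
        return float(baf)
    return baf


def join_counts(
    het_snps: pd.DataFrame, counts: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join RNA allelic counts onto DNA-heterozygous SNPs.

    Returns
    -------
    (joined, uncovered)
        ``joined`` has one row per heterozygous SNP with a matching count
        entry, carrying the genotype columns plus count_a/count_b/depth
        and baf.  ``uncovered`` lists heterozygous SNPs with no count
        entry ("not expressed or uncovered"); count rows without a
        heterozygous SNP are ignored.
    """
    shared = set(het_snps["sample_id"]) & set(counts["sample_id"])
    if not shared:
        raise CountJoinError("no overlap between genotype and count sample identifiers")

    merged = het_snps.merge(counts, on=_JOIN_KEYS, how="left", indicator=True)
    uncovered = (
        merged[merged["_merge"] == "left_only"]
        .drop(columns=["_merge", "count_a", "count_b", "depth"])
        .reset_index(drop=True)
    )
    joined = merged[merged["_merge"] == "both"].drop(columns="_merge").reset_index(drop=True)
    joined["count_a"] = joined["count_a"].astype(np.int64)
    joined["count_b"] = joined["count_b"].astype(np.int64)
    joined["depth"] = joined["depth"].astype(np.int64)
    joined["baf"] = compute_baf(joined["count_a"].values, joined["count_b"].values)
    if len(uncovered):
        logger.info("%d heterozygous SNPs had no RNA count entry", len(uncovered))
    return joined, uncovered


def load_cds_intervals(path: str, fmt: str | None = None) -> dict[str, IntervalTree]:
    """Load CDS intervals from BED or GFF3 into per-chromosome interval trees.

    BED intervals are half-open 0-based and converted to 1-based inclusive;
    GFF3 rows of type CDS are used as-is (1-based inclusive), with the gene
    identifier taken from the ``gene_id`` or ``Parent`` or ``ID`` attribute.
    Interval data payloads are gene identifiers.
    """
    if fmt is None:
        low = path.lower()
        fmt = "gff3" if low.endswith((".gff", ".gff3")) else "bed"
    trees: dict[str, IntervalTree] = {}

    from .genotype_io import normalize_chrom

    def add(chrom: str, start1: int, end1: int, gene: str) -> None:
        if end1 < start1:
            return
        # IntervalTree is half-open; store [start1, end1] as [start1, end1+1)
        trees.setdefault(chrom, IntervalTree()).addi(start1, end1 + 1, gene)

    if fmt == "bed":
        bed = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3],
        )
        bed["chrom"] = normalize_chrom(bed["chrom"])
        for row in bed.itertuples(index=False):
            add(row.chrom, int(row.start) + 1, int(row.end), str(row.name))
    elif fmt == "gff3":
        gff = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "source", "type", "start", "end", "score", "strand",
                   "frame", "attributes"],
        )
        gff = gff[gff["type"].str.upper() == "CDS"]
        gff["chrom"] = normalize_chrom(gff["chrom"])
        for row in gff.itertuples(index=False):
            gene = None
            for field in str(row.attributes).split(";"):
                k, _, v = field.strip().partition("=")
                if k in ("gene_id", "Parent", "ID"):
                    gene = v
                    break
            add(row.chrom, int(row.start), int(row.end), gene or "NA")
    else:
        raise ValueError(f"unknown CDS format {fmt!r}")
    return trees


def filter_depth_cds(
    snps: pd.DataFrame,
    cds_intervals: dict[str, IntervalTree] | None,
    config: CountFilterConfig = CountFilterConfig(),
) -> pd.DataFrame:
    """Apply the depth and CDS filters and annotate overlapping genes.

    Keeps records with depth strictly greater than ``config.depth_min``
    and, when ``config.require_cds``, position inside at least one CDS
    interval.  ``gene_ids`` is populated with every overlapping gene
    (a SNP in two overlapping genes counts for both downstream).
    """
    if config.require_cds and not cds_intervals:
        raise ValueError("require_cds=True but no CDS intervals supplied")

    out = snps[snps["depth"] > config.depth_min].copy()

    genes: list[tuple[str, ...]] = []
    in_cds: list[bool] = []
    trees = cds_intervals or {}
    for chrom, pos in zip(out["chrom"], out["pos"]):
        tree = trees.get(str(chrom))
        hits = tree[pos] if tree is not None else set()
        ids = tuple(sorted({iv.data for iv in hits}))
        genes.append(ids)
        in_cds.append(bool(ids))
    out["in_cds"] = in_cds
    out["gene_ids"] = genes
    if config.require_cds:
        out = out[out["in_cds"]]
    return out.reset_index(drop=True)


def call_rna_genotype(
    baf,
    config: CountFilterConfig = CountFilterConfig(),
    depth=None,
    count_b=None,
):
    """Assign RNA genotypes from BAF: HomA, HomB or Het.

    HomA if baf <= tau, HomB if baf >= 1 - tau, else Het.  With
    ``config.binomial_guard`` a homozygous call additionally requires a
    two-sided exact binomial test of count_b given p = 0.5 to reject at
    ``config.binomial_alpha`` (depth and count_b must then be supplied).
    """
    from scipy import stats

    baf_arr = np.atleast_1d(np.asarray(baf, dtype=float))
    tau = config.hom_baf_tau
    call = np.where(
        baf_arr <= tau, "HomA", np.where(baf_arr >= 1.0 - tau, "HomB", "Het")
    ).astype(object)

    if config.binomial_guard:
        if depth is None or count_b is None:
            raise ValueError("binomial_guard requires depth and count_b")
        d = np.atleast_1d(np.asarray(depth, dtype=np.int64))
        k = np.atleast_1d(np.asarray(count_b, dtype=np.int64))
        pval = np.array(
            [stats.binomtest(int(ki), int(di), 0.5).pvalue for ki, di in zip(k, d)]
        )
        call[(call != "Het") & (pval >= config.binomial_alpha)] = "Het"

    if np.ndim(baf) == 0:
        return str(call[0])
    return call


def annotate_rna_genotype(
    snps: pd.DataFrame, config: CountFilterConfig = CountFilterConfig()
) -> pd.DataFrame:
    """Add an ``rna_call`` column to a joined, filtered SNP table."""
    out = snps.copy()
    out["rna_call"] = call_rna_genotype(
        out["baf"].values,
        config,
        depth=out["depth"].values if config.binomial_guard else None,
        count_b=out["count_b"].values if config.binomial_guard else None,
    )
    return out
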