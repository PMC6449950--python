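"""Aggregation of MAE SNPs to genes and the recurrent-MAE gene list.

A gene shows MAE in a sample when at least ``min_mae_snps_per_gene`` of
its informative SNPs are completely monoallelic in that sample; genes
showing MAE in at least ``min_samples`` samples are reported as
recurrently monoallelically expressed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class RecurrenceConfig:
    """Thresholds for the recurrent-MAE gene filter.

    ``min_mae_snps_per_gene``: SNPs per gene per sample that must be both
    informative and CompleteMAE (default 2).  ``min_samples``: number of
    samples in which the gene must meet that rule (default 8).  With
    ``relaxed_rule`` a sample qualifies with min_mae_snps_per_gene
    informative SNPs of which at least one is MAE (an alternative reading
    of "informative SNPs showing MAE").
    """

    min_mae_snps_per_gene: int = 2
    min_samples: int = 8
    relaxed_rule: bool = False

    def __post_init__(self) -> None:
        if self.min_mae_snps_per_gene < 1 or self.min_samples < 1:
            raise ValueError("recurrence thresholds must be >= 1")


def gene_profiles(mae_calls: pd.DataFrame) -> pd.DataFrame:
    """Per gene x sample counts of informative and CompleteMAE SNPs.

    ``gene_ids`` must be populated (tuples of overlapping genes); a SNP
    assigned to several genes contributes to each of them.
    """
    df = mae_calls[["sample_id", "gene_ids", "status"]].copy()
    df = df[df["gene_ids"].map(len) > 0]
    df = df.explode("gene_ids").rename(columns={"gene_ids": "gene_id"})
    out = (
        df.groupby(["gene_id", "sample_id"], sort=True)
        .agg(
            n_informative_snps=("status", "size"),
            n_mae_snps=("status", lambda s: int((s == "CompleteMAE").sum())),
        )
        .reset_index()
    )
    return out


def recurrent_genes(
    profiles: pd.DataFrame, config: RecurrenceConfig = RecurrenceConfig()
) -> pd.DataFrame:
    """Genes meeting the per-sample SNP rule in enough samples.

    Returns gene_id and n_samples_with_mae, ranked by descending sample
    count with gene_id as a deterministic tie-break.
    """
    k = config.min_mae_snps_per_gene
    if config.relaxed_rule:
        qualifies = (profiles["n_informative_snps"] >= k) & (profiles["n_mae_snps"] >= 1)
    else:
        qualifies = profiles["n_mae_snps"] >= k
    counts = (
        profiles.loc[qualifies]
        .groupby("gene_id")["sample_id"]
        .nunique()
        .rename("n_samples_with_mae")
        .reset_index()
    )
    out = counts[counts["n_samples_with_mae"] >= config.min_samples]
    return out.sort_values(
        ["n_samples_with_mae", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)
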