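"""Per-SNP MAE classification and per-sample MAE frequency statistics.

The MAE frequency of a sample is the number of informative SNPs whose RNA
genotype is homozygous divided by the number of informative SNPs.  At the
SNP level the B-allele frequency separates three regimes: complete
monoallelic expression (BAF at or near 0 or 1), skewed differential
allelic expression (unequal but not exclusive), and balanced biallelic
expression around 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MAE_STATES = ("BiallelicBalanced", "SkewedDAE", "CompleteMAE")


@dataclass(frozen=True)
class DaeBands:
    """BAF bands separating complete MAE, skewed DAE and balanced expression.

    ``complete_tau`` mirrors the RNA homozygosity threshold: BAF <= tau or
    >= 1 - tau is complete MAE.  BAF in (tau, skew_lo] or [skew_hi, 1 - tau)
    is skewed DAE; the middle band is balanced.  Defaults (0.05, 0.35, 0.65)
    separate the central mass of typical BAF histograms from their tails.
    """

    complete_tau: float = 0.05
    skew_lo: float = 0.35
    skew_hi: float = 0.65

    def __post_init__(self) -> None:
        if not (self.complete_tau < self.skew_lo < 0.5 < self.skew_hi < 1 - self.complete_tau):
            raise ValueError(
                "require complete_tau < skew_lo < 0.5 < skew_hi < 1 - complete_tau, got "
                f"({self.complete_tau}, {self.skew_lo}, {self.skew_hi})"
            )


def classify_baf(baf, bands: DaeBands = DaeBands()):
    """Classify BAF values into the three expression states.

    Vectorized; returns a string array (or a single string for scalar
    input) with values from :data:`MAE_STATES`.
    """
    b = np.atleast_1d(np.asarray(baf, dtype=float))
    tau = bands.complete_tau
    complete = (b <= tau) | (b >= 1.0 - tau)
    skewed = (~complete) & ((b <= bands.skew_lo) | (b >= bands.skew_hi))
    out = np.where(complete, "CompleteMAE", np.where(skewed, "SkewedDAE", "BiallelicBalanced"))
    if np.ndim(baf) == 0:
        return str(out[0])
    return out.astype(object)


def classify_snps(snps: pd.DataFrame, bands: DaeBands = DaeBands()) -> pd.DataFrame:
    """Add a ``status`` column classifying each informative SNP."""
    out = snps.copy()
    out["status"] = classify_baf(out["baf"].values, bands)
    return out


def mae_frequency(
    snps: pd.DataFrame,
    input_set: str = "non-imputed",
    mutational_status: dict[str, str] | None = None,
    include_x: bool = False,
) -> pd.DataFrame:
    """Per-sample MAE summary: informative SNPs, RNA-homozygous SNPs, frequency.

    The headline frequency is computed over autosomes; X-linked SNPs are
    summarized separately (``n_informative_x`` / ``mae_frequency_x``)
    unless ``include_x`` is set, because X inactivation in females is
    monoallelic for reasons unrelated to the tumor genome.

    A sample with zero informative SNPs gets a missing frequency and a
    warning, never an exception.
    """
    df = snps.copy()
    is_hom = df["rna_call"].isin(("HomA", "HomB"))
    df["_hom"] = is_hom
    on_x = df["chrom"].astype(str) == "X"

    rows = []
    for sample, grp in df.groupby("sample_id", sort=True):
        auto = grp if include_x else grp[~on_x.loc[grp.index]]
        xg = grp[on_x.loc[grp.index]]
        n_inf = len(auto)
        n_hom = int(auto["_hom"].sum())
        if n_inf == 0:
            logger.warning("sample %s has no informative SNPs", sample)
            freq = np.nan
        else:
            freq = n_hom / n_inf
        rows.append(
            {
                "sample_id": sample,
                "input_set": input_set,
                "mutational_status": (mutational_status or {}).get(sample, "NA"),
                "n_informative": n_inf,
                "n_hom_rna": n_hom,
                "mae_frequency": freq,
                "n_informative_x": len(xg),
                "mae_frequency_x": (xg["_hom"].mean() if len(xg) else np.nan),
            }
        )
    return pd.DataFrame(rows)


def cohort_summary(summaries: pd.DataFrame | pd.Series | np.ndarray | list) -> dict:
    """Mean, sample SD (n-1 denominator), min and max of MAE frequencies.

    Accepts a summary table (uses its ``mae_frequency`` column) or a bare
    sequence of frequencies.  With a single sample the SD is reported as
    missing.
    """
    if isinstance(summaries, pd.DataFrame):
        values = summaries["mae_frequency"].to_numpy(dtype=float)
    else:
        values = np.asarray(summaries, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("no MAE frequencies to summarize")
    return {
        "n": int(values.size),
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)) if values.size >= 2 else None,
        "min": float(np.min(values)),
        "max": float(np.max(values)),
    }


def group_compare(
    summaries: pd.DataFrame,
    group_col: str = "mutational_status",
    groups: tuple[str, str] = ("NRAS", "BRAF"),
) -> dict:
    """Compare MAE frequency between two sample groups.

    Reports per-group descriptive statistics and a Welch two-sample
    t-test (unequal variances).  Groups of size one are reported
    descriptively with the test marked missing.
    """
    out: dict = {"groups": {}}
    vals = []
    for g in groups:
        v = summaries.loc[summaries[group_col] == g, "mae_frequency"].dropna().to_numpy()
        if v.size == 0:
            raise ValueError(f"group {g!r} is empty")
        out["groups"][g] = cohort_summary(v)
        vals.append(v)
    if min(v.size for v in vals) < 2:
        out["t_statistic"] = None
        out["p_value"] = None
    else:
        t, p = stats.ttest_ind(vals[0], vals[1], equal_var=False)
        out["t_statistic"] = float(t)
        out["p_value"] = float(p)
    return out


def baf_histogram(baf, n_bins: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of BAF occurrence counts on [0, 1].

    Bins are closed-left half-open, with the final bin closed so BAF = 1
    is counted; counts sum to the number of scored SNPs.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = np.asarray(baf, dtype=float)
    values = values[~np.isnan(values)]
    counts, edges = np.histogram(values, bins=n_bins, range=(0.0, 1.0))
    return counts, edges
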