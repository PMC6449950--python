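"""Per-chromosome MAE summaries, complete-chromosome calls and enrichment.

A chromosome is called under *complete MAE* in a sample when (nearly) all
of its informative SNPs are monoallelically expressed — operationally,
when the MAE fraction reaches ``theta_chrom`` with at least ``min_snps``
informative SNPs.  Enrichment of complete-MAE calls on one chromosome
against all other autosomes is tested with a two-sided exact test on the
2x2 table of flagged/unflagged sample-chromosome pairs, computed by exact
hypergeometric enumeration in integer arithmetic.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_right
from dataclasses import dataclass, field
from itertools import accumulate

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AUTOSOMES = tuple(str(c) for c in range(1, 23))


@dataclass(frozen=True)
class ChromCallConfig:
    """Thresholds for calling a chromosome under complete MAE.

    ``theta_chrom``: minimum MAE fraction (default 0.90); ``min_snps``:
    minimum informative SNPs on the chromosome (default 50) so sparse
    chromosomes are never flagged on a handful of SNPs.
    """

    theta_chrom: float = 0.90
    min_snps: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.theta_chrom <= 1:
            raise ValueError("theta_chrom must be in (0, 1]")
        if self.min_snps < 1:
            raise ValueError("min_snps must be >= 1")


@dataclass(frozen=True)
class ControlGeneSets:
    """Positive-control annotations: imprinted and olfactory-receptor genes
    plus per-sample sex flags ('F'/'M')."""

    imprinted: frozenset = field(default_factory=frozenset)
    olfactory: frozenset = field(default_factory=frozenset)
    sample_sex: dict | None = None


def chromosome_matrix(
    mae_calls: pd.DataFrame,
    config: ChromCallConfig = ChromCallConfig(),
    include_x: bool = False,
) -> pd.DataFrame:
    """Samples x chromosomes MAE fractions and complete-MAE flags.

    Returns a long-format table with one row per (sample, chromosome)
    that has at least one informative SNP: n_informative,
    n_complete_mae, fraction and complete_flag (fraction >= theta_chrom
    and n_informative >= min_snps).  Chromosomes with zero informative
    SNPs are simply absent (excluded from totals).
    """
    chroms = AUTOSOMES + (("X",) if include_x else ())
    df = mae_calls[mae_calls["chrom"].astype(str).isin(chroms)]
    grouped = df.groupby(["sample_id", "chrom"], sort=True)
    out = grouped.agg(
        n_informative=("status", "size"),
        n_complete_mae=("status", lambda s: int((s == "CompleteMAE").sum())),
    ).reset_index()
    out["fraction"] = out["n_complete_mae"] / out["n_informative"]
    out["complete_flag"] = (out["fraction"] >= config.theta_chrom) & (
        out["n_informative"] >= config.min_snps
    )
    return out


def matrix_margins(matrix: pd.DataFrame) -> dict:
    """Row (per-sample) and column (per-chromosome) complete-flag totals."""
    per_sample = (
        matrix.groupby("sample_id")["complete_flag"].sum().astype(int).to_dict()
    )
    per_chrom = matrix.groupby("chrom")["complete_flag"].sum().astype(int).to_dict()
    grand = int(matrix["complete_flag"].sum())
    return {"per_sample": per_sample, "per_chromosome": per_chrom, "grand_total": grand}


def exact_test_pvalues(K: int, n: int, N: int) -> list[float]:
    """Two-sided exact p-values for every table with margins (K, n, N).

    For a 2x2 table with row sums (K, N-K) and column sums (n, N-n), the
    count a in the top-left cell follows a hypergeometric distribution
    under independence.  The two-sided p for observed a sums the
    probabilities of all tables no more probable than the observed one.
    All arithmetic is exact (integer numerators over a common binomial
    denominator), so ties are handled without floating-point tolerance.

    Returns p-values indexed by a - max(0, n - (N - K)).
    """
    kmin = max(0, n - (N - K))
    kmax = min(K, n)
    NK = N - K
    v = math.comb(K, kmin) * math.comb(NK, n - kmin)
    nums = [v]
    for k in range(kmin, kmax):
        v = v * (K - k) * (n - k) // ((k + 1) * (NK - n + k + 1))
        nums.append(v)
    denom = math.comb(N, n)
    ordered = sorted(nums)
    prefix = list(accumulate(ordered))
    return [prefix[bisect_right(ordered, x) - 1] / denom for x in nums]


def fisher_exact_two_sided(table) -> tuple[float, float]:
    """Odds ratio and exact two-sided p for a 2x2 contingency table."""
    (a, b), (c, d) = (int(x) for x in np.ravel(table)[:2]), (
        int(x) for x in np.ravel(table)[2:]
    )
    K, n, N = a + b, a + c, a + b + c + d
    if N == 0:
        return math.nan, 1.0
    kmin = max(0, n - (N - K))
    p = exact_test_pvalues(K, n, N)[a - kmin]
    odds = (a * d) / (b * c) if b * c else math.inf if a * d else math.nan
    return odds, p


def chromosome_enrichment(
    matrix: pd.DataFrame,
    target_chrom: str = "9",
    exclude: tuple[str, ...] = ("X",),
) -> dict:
    """Test whether complete-MAE calls are enriched on one chromosome.

    Builds the 2x2 table [[flagged on target, unflagged on target],
    [flagged on other autosomes, unflagged on other autosomes]] over
    sample-chromosome pairs and returns the table, odds ratio and exact
    two-sided p.  X is excluded by default (confounded by X inactivation).
    """
    target_chrom = str(target_chrom)
    chroms = set(matrix["chrom"].astype(str)) - set(exclude)
    if target_chrom not in chroms:
        raise ValueError(f"target chromosome {target_chrom!r} absent from matrix")
    if len(chroms) < 2:
        raise ValueError("need at least two chromosomes for enrichment testing")
    on_target = matrix["chrom"].astype(str) == target_chrom
    rest = matrix["chrom"].astype(str).isin(chroms - {target_chrom})
    a = int(matrix.loc[on_target, "complete_flag"].sum())
    b = int(on_target.sum()) - a
    c = int(matrix.loc[rest, "complete_flag"].sum())
    d = int(rest.sum()) - c
    odds, p = fisher_exact_two_sided([[a, b], [c, d]])
    return {
        "table": [[a, b], [c, d]],
        "odds_ratio": odds,
        "p_value": p,
        "target_chrom": target_chrom,
    }


def validate_controls(
    mae_calls: pd.DataFrame,
    controls: ControlGeneSets,
    floor: float = 0.8,
) -> dict:
    """Positive-control validation of MAE detection.

    Reports the MAE fraction among X-linked informative SNPs of female
    samples (X inactivation should make these monoallelic), and among
    SNPs overlapping imprinted and olfactory-receptor genes; each is
    compared against a configurable floor.  Checks without data are
    skipped with a warning rather than failed.
    """
    report: dict = {"floor": floor, "checks": {}}

    sex = controls.sample_sex or {}
    females = {s for s, v in sex.items() if str(v).upper().startswith("F")}
    x = mae_calls[
        (mae_calls["chrom"].astype(str) == "X")
        & mae_calls["sample_id"].isin(females)
    ]
    if females and len(x):
        frac = float((x["status"] == "CompleteMAE").mean())
        report["checks"]["x_inactivation"] = {
            "n_snps": len(x),
            "n_samples": int(x["sample_id"].nunique()),
            "mae_fraction": frac,
            "passed": frac >= floor,
        }
    else:
        logger.warning("X-inactivation check skipped: no female X-linked SNPs")
        report["checks"]["x_inactivation"] = {"skipped": True}

    for name, genes in (("imprinted", controls.imprinted), ("olfactory", controls.olfactory)):
        if not genes:
            report["checks"][name] = {"skipped": True}
            continue
        genes = set(genes)
        hit = mae_calls[
            mae_calls["gene_ids"].map(lambda ids: bool(genes.intersection(ids)))
        ]
        if not len(hit):
            logger.warning("%s-gene check skipped: no overlapping SNPs", name)
            report["checks"][name] = {"skipped": True}
            continue
        frac = float((hit["status"] == "CompleteMAE").mean())
        report["checks"][name] = {
            "n_snps": len(hit),
            "mae_fraction": frac,
            "passed": frac >= floor,
        }
    return report
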