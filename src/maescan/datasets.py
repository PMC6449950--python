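"""Bundled worked-example datasets.

Two small tables from a published 15-cell-line melanoma cohort ship with
the package so the summary statistics can be reproduced without any
download:

* per-cell-line MAE frequencies (non-imputed and imputed genotype sets),
* per-cell-line complete-chromosome MAE flags.  Only the row and column
  totals of that table (and one cell line's flagged chromosomes) are
  published; the per-cell flags bundled here are a synthetic
  reconstruction consistent with those margins — see the fixture file
  header — and are intended for exercising the matrix/margin machinery,
  not as per-cell ground truth.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

_AUTOSOMES = tuple(str(c) for c in range(1, 23))


def _data_path(name: str):
    return resources.files("maescan.data").joinpath(name)


def load_mae_frequency_table() -> pd.DataFrame:
    """Per-cell-line MAE frequencies for both genotype input sets.

    Columns: cell_line, mutational_status, mae_frequency (non-imputed),
    mae_frequency_imputed.
    """
    with resources.as_file(_data_path("table1_mae_frequencies.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def sample_summaries(input_set: str = "non-imputed") -> pd.DataFrame:
    """The bundled frequencies shaped like a per-sample MAE summary table."""
    t = load_mae_frequency_table()
    col = "mae_frequency_imputed" if input_set == "imputed" else "mae_frequency"
    return pd.DataFrame(
        {
            "sample_id": t["cell_line"],
            "input_set": input_set,
            "mutational_status": t["mutational_status"],
            "mae_frequency": t[col],
        }
    )


def load_complete_mae_flags() -> pd.DataFrame:
    """Per-cell-line complete-chromosome MAE flags (synthetic cells, real margins).

    Returns a long table with sample_id, mutational_status, chrom and
    complete_flag for all 22 autosomes of the 15 cell lines.
    """
    with resources.as_file(
        _data_path("table2_complete_mae_flags_synthetic.tsv")
    ) as p:
        raw = pd.read_csv(p, sep="\t", comment="#", keep_default_na=False)
    rows = []
    for r in raw.itertuples(index=False):
        flagged = {c for c in str(r.flagged_chromosomes).split(",") if c}
        for chrom in _AUTOSOMES:
            rows.append(
                (r.cell_line, r.mutational_status, chrom, chrom in flagged)
            )
    return pd.DataFrame(
        rows, columns=["sample_id", "mutational_status", "chrom", "complete_flag"]
    )


def complete_mae_example_calls(
    n_snps_per_chrom: int = 60, unflagged_fraction: float = 0.3
) -> pd.DataFrame:
    """Deterministic per-SNP MAE calls realizing the bundled flag matrix.

    For every (cell line, autosome) cell, emits ``n_snps_per_chrom``
    informative SNPs: all CompleteMAE where the cell is flagged, and a
    ``unflagged_fraction`` MAE mixture otherwise.  Feeding these calls to
    :func:`maescan.chrom_mae.chromosome_matrix` (with min_snps <=
    n_snps_per_chrom) reproduces the flag matrix and hence its margins.
    """
    flags = load_complete_mae_flags()
    n_mae_unflagged = int(round(unflagged_fraction * n_snps_per_chrom))
    rows = []
    for r in flags.itertuples(index=False):
        n_mae = n_snps_per_chrom if r.complete_flag else n_mae_unflagged
        for i in range(n_snps_per_chrom):
            mae = i < n_mae
            rows.append(
                (
                    r.sample_id,
                    r.chrom,
                    (i + 1) * 1000,
                    0.0 if mae else 0.5,
                    "CompleteMAE" if mae else "BiallelicBalanced",
                )
            )
    out = pd.DataFrame(
        rows, columns=["sample_id", "chrom", "pos", "baf", "status"]
    )
    out["rna_call"] = np.where(out["status"] == "CompleteMAE", "HomA", "Het")
    return out
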