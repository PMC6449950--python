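"""Explaining MAE by copy-number imbalance.

Copy-number segments are consumed pre-called (SEG-like TSV from an aCGH
or sequencing caller).  A monoallelically expressed SNP inside a loss or
gain segment is *CN-explained*: a one-copy locus, or one with an
amplified allele, must look monoallelic in RNA regardless of any
epigenetic state.  Per sample and chromosome we report the fraction of
MAE SNPs inside imbalanced segments and a verdict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "state", "score"]
CN_STATES = ("loss", "gain", "neutral")


@dataclass(frozen=True)
class CnSegment:
    """A called copy-number segment, 1-based inclusive coordinates."""

    sample_id: str
    chrom: str
    start: int
    end: int
    state: str
    score: float | None = None


class SegmentParseError(ValueError):
    """Raised for malformed segment input."""


def load_segments(path: str) -> pd.DataFrame:
    """Load and normalize copy-number segments from a SEG-like TSV.

    Expected columns: Sample_ID, Chr, Start, End, State and optionally
    Score.  Segments are sorted and same-state overlapping or adjacent
    segments of one sample-chromosome are merged.  A start beyond its end
    raises with the 1-based data line number.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"Chr": "string"})
    need = ["Sample_ID", "Chr", "Start", "End", "State"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise SegmentParseError(f"segment file {path} lacks columns {missing}")
    from .genotype_io import normalize_chrom

    out = pd.DataFrame(
        {
            "sample_id": df["Sample_ID"].astype(str),
            "chrom": normalize_chrom(df["Chr"]),
            "start": df["Start"].astype(int),
            "end": df["End"].astype(int),
            "state": df["State"].astype(str).str.lower(),
            "score": pd.to_numeric(df["Score"], errors="coerce")
            if "Score" in df.columns
            else float("nan"),
        }
    )
    bad_state = ~out["state"].isin(CN_STATES)
    if bad_state.any():
        raise SegmentParseError(
            f"unknown CN states {sorted(out.loc[bad_state, 'state'].unique())} in {path}"
        )
    bad = out["start"] > out["end"]
    if bad.any():
        line = int(bad.idxmax()) + 2  # 1-based, counting the header line
        raise SegmentParseError(f"{path} line {line}: segment start exceeds end")
    if out.empty:
        logger.warning("segment file %s is empty", path)
        return out[SEGMENT_COLUMNS]
    return normalize_segments(out)


def normalize_segments(segments: pd.DataFrame) -> pd.DataFrame:
    """Sort segments and merge overlapping/adjacent same-state intervals."""
    rows = []
    for (sample, chrom, state), grp in segments.groupby(
        ["sample_id", "chrom", "state"], sort=True
    ):
        grp = grp.sort_values("start")
        cur_start = cur_end = None
        cur_score = float("nan")
        for r in grp.itertuples(index=False):
            if cur_start is None:
                cur_start, cur_end, cur_score = r.start, r.end, r.score
            elif r.start <= cur_end + 1:
                cur_end = max(cur_end, r.end)
            else:
                rows.append((sample, chrom, cur_start, cur_end, state, cur_score))
                cur_start, cur_end, cur_score = r.start, r.end, r.score
        rows.append((sample, chrom, cur_start, cur_end, state, cur_score))
    out = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    return out.sort_values(["sample_id", "chrom", "start"]).reset_index(drop=True)


def _imbalance_trees(
    segments: pd.DataFrame, states: tuple[str, ...]
) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    sel = segments[segments["state"].isin(states)]
    for r in sel.itertuples(index=False):
        # 1-based inclusive [start, end] stored as half-open [start, end+1)
        trees.setdefault((r.sample_id, str(r.chrom)), IntervalTree()).addi(
            r.start, r.end + 1
        )
    return trees


def explain_mae(
    mae_calls: pd.DataFrame,
    segments: pd.DataFrame | None,
    theta_cn: float = 0.8,
    imbalance_states: tuple[str, ...] = ("loss", "gain"),
) -> pd.DataFrame:
    """Classify each sample-chromosome's MAE as CN-explained or not.

    For every (sample, chromosome) with at least one CompleteMAE SNP,
    counts how many of those SNPs fall inside a loss or gain segment
    (``imbalance_states`` configurable, e.g. losses only) and derives a
    verdict: CN-explained if the explained fraction >= theta_cn,
    unexplained if <= 1 - theta_cn, partial otherwise.  Samples with no
    segment data at all get verdict "no-data".
    """
    if not 0.5 < theta_cn <= 1.0:
        raise ValueError("theta_cn must be in (0.5, 1]")
    mae = mae_calls[mae_calls["status"] == "CompleteMAE"]
    have_segments = (
        set(segments["sample_id"]) if segments is not None and len(segments) else set()
    )
    trees = (
        _imbalance_trees(segments, imbalance_states)
        if segments is not None and len(segments)
        else {}
    )

    rows = []
    for (sample, chrom), grp in mae.groupby(["sample_id", "chrom"], sort=True):
        n = len(grp)
        if sample not in have_segments:
            rows.append((sample, str(chrom), n, 0, float("nan"), "no-data"))
            continue
        tree = trees.get((sample, str(chrom)))
        if tree is None:
            hit = 0
        else:
            hit = int(sum(bool(tree[p]) for p in grp["pos"]))
        frac = hit / n
        if frac >= theta_cn:
            verdict = "CN-explained"
        elif frac <= 1.0 - theta_cn:
            verdict = "unexplained"
        else:
            verdict = "partial"
        rows.append((sample, str(chrom), n, hit, frac, verdict))
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "chrom",
            "n_mae_snps",
            "n_mae_in_imbalance",
            "explained_fraction",
            "verdict",
        ],
    )
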