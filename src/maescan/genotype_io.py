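"""Reading, quality control and heterozygosity selection of DNA genotype calls.

Genotype calls come either from an array-style long-format matrix (one row
per sample x marker, Illumina final-report flavour) or from a multi-sample
VCF.  In-memory, calls live in a pandas DataFrame with one row per
(sample, marker) and the columns listed in :data:`GENOTYPE_COLUMNS`.

Quality control follows standard genotyping-array practice: individual
calls below a GenCall-style per-call confidence score are masked to NoCall,
markers with a poor GenTrain-style cluster score are removed, and samples
and markers whose resulting call rate falls below a floor are dropped
entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical column order for genotype call tables.
GENOTYPE_COLUMNS = [
    "sample_id",
    "snp_id",
    "chrom",
    "pos",
    "allele_a",
    "allele_b",
    "call",
    "gencall",
    "imputed",
]

#: Canonical column order for marker metadata tables.
MARKER_COLUMNS = ["snp_id", "chrom", "pos", "gentrain"]

CALL_STATES = ("AA", "AB", "BB", "NoCall")

_MATRIX_REQUIRED = [
    "SNP_Name",
    "Sample_ID",
    "Chr",
    "Position",
    "Allele1",
    "Allele2",
]

_MISSING_ALLELES = {"-", ".", "", "0", "N"}


class GenotypeParseError(ValueError):
    """Raised when a genotype input file cannot be parsed."""


class QcError(ValueError):
    """Raised when quality control leaves no usable data."""


@dataclass(frozen=True)
class QcThresholds:
    """Quality-control thresholds for array genotype calls.

    Parameters
    ----------
    min_call_rate
        Samples and markers with a call rate below this fraction are
        removed entirely (default 0.95).
    min_gencall
        Calls with a per-call confidence score below this value are set
        to NoCall; calls at exactly the cutoff are retained (default 0.15).
    min_gentrain
        Markers with a cluster-quality score below this value are removed
        (default 0.5).
    """

    min_call_rate: float = 0.95
    min_gencall: float = 0.15
    min_gentrain: float = 0.5

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_gencall", "min_gentrain"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")


def normalize_chrom(values) -> pd.Series:
    """Normalize chromosome labels: strip any ``chr`` prefix, uppercase X/Y."""
    s = pd.Series(values, dtype="string").str.strip()
    s = s.str.replace(r"^[Cc][Hh][Rr]", "", regex=True)
    return s.str.upper().str.replace("23", "X", regex=False).astype(object)


def _finalize_genotypes(df: pd.DataFrame) -> pd.DataFrame:
    dup = df.duplicated(subset=["sample_id", "snp_id"])
    if dup.any():
        pairs = df.loc[dup, ["sample_id", "snp_id"]].head(5).to_records(index=False)
        raise GenotypeParseError(
            f"duplicate (sample, marker) pairs in genotype input, e.g. {list(pairs)}"
        )
    bad_pos = df["pos"] < 1
    if bad_pos.any():
        raise GenotypeParseError(
            f"{int(bad_pos.sum())} records with position < 1 (positions are 1-based)"
        )
    return df.reset_index(drop=True)[GENOTYPE_COLUMNS]


def _calls_from_alleles(
    a1: pd.Series, a2: pd.Series, snp_ids: pd.Series
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Derive AA/AB/BB/NoCall calls and per-marker A/B allele labels.

    The A allele of each marker is the lexicographically smaller of the
    two bases observed across samples, which makes the labelling
    deterministic and independent of sample order.
    """
    a1 = a1.astype("string").str.upper()
    a2 = a2.astype("string").str.upper()
    missing = a1.isin(_MISSING_ALLELES) | a2.isin(_MISSING_ALLELES) | a1.isna() | a2.isna()

    alleles_a: dict[str, str] = {}
    alleles_b: dict[str, str] = {}
    obs = pd.DataFrame({"snp_id": snp_ids, "a1": a1, "a2": a2}).loc[~missing]
    for snp, grp in obs.groupby("snp_id", sort=False):
        seen = sorted(set(grp["a1"]) | set(grp["a2"]))
        if len(seen) > 2:
            raise GenotypeParseError(f"marker {snp} has more than two alleles: {seen}")
        alleles_a[snp] = seen[0]
        alleles_b[snp] = seen[1] if len(seen) > 1 else "N"

    allele_a = snp_ids.map(lambda s: alleles_a.get(s, "N"))
    allele_b = snp_ids.map(lambda s: alleles_b.get(s, "N"))

    call = np.where(
        missing,
        "NoCall",
        np.where(
            a1 == a2,
            np.where(a1 == allele_a, "AA", "BB"),
            "AB",
        ),
    )
    return pd.Series(call), pd.Series(allele_a), pd.Series(allele_b)


def load_genotypes(
    path: str,
    fmt: str = "matrix",
    marker_manifest: str | None = None,
    imputed: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load DNA genotype calls and marker metadata.

    Parameters
    ----------
    path
        Genotype file.  ``matrix`` format is a long TSV with columns
        SNP_Name, Sample_ID, Chr, Position, Allele1, Allele2 and an
        optional GC_Score; ``vcf`` is a multi-sample VCF whose GT field
        provides the calls (an optional per-call FORMAT field ``GC`` is
        read as the GenCall-style score).
    marker_manifest
        Optional TSV with columns SNP_Name and GenTrain_Score supplying
        per-marker cluster scores.
    imputed
        Flag every record as imputed (imputed calls are supplied as a
        separate input set; no imputation is performed here).

    Returns
    -------
    (genotypes, markers)
        DataFrames with :data:`GENOTYPE_COLUMNS` and :data:`MARKER_COLUMNS`.
    """
    if fmt == "matrix":
        genotypes, markers = _load_matrix(path)
    elif fmt == "vcf":
        genotypes, markers = _load_vcf(path)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")

    genotypes["imputed"] = bool(imputed)
    if marker_manifest is not None:
        manifest = load_marker_manifest(marker_manifest)
        markers = markers.drop(columns=["gentrain"]).merge(
            manifest[["snp_id", "gentrain"]], on="snp_id", how="left"
        )
    return _finalize_genotypes(genotypes), markers.reset_index(drop=True)[MARKER_COLUMNS]


def load_marker_manifest(path: str) -> pd.DataFrame:
    """Load a marker manifest TSV (SNP_Name, GenTrain_Score)."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # pragma: no cover - message passthrough
        raise GenotypeParseError(f"cannot parse marker manifest {path}: {exc}") from exc
    for col in ("SNP_Name", "GenTrain_Score"):
        if col not in df.columns:
            raise GenotypeParseError(f"marker manifest {path} lacks column {col}")
    out = pd.DataFrame(
        {
            "snp_id": df["SNP_Name"].astype(str),
            "gentrain": pd.to_numeric(df["GenTrain_Score"], errors="coerce"),
        }
    )
    if out["snp_id"].duplicated().any():
        raise GenotypeParseError(f"marker manifest {path} has duplicate SNP_Name entries")
    return out


def _load_matrix(path: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"Chr": "string"})
    except pd.errors.ParserError as exc:
        raise GenotypeParseError(f"cannot parse genotype matrix {path}: {exc}") from exc
    missing = [c for c in _MATRIX_REQUIRED if c not in df.columns]
    if missing:
        raise GenotypeParseError(f"genotype matrix {path} lacks columns {missing}")

    snp_ids = df["SNP_Name"].astype(str)
    call, allele_a, allele_b = _calls_from_alleles(df["Allele1"], df["Allele2"], snp_ids)
    gencall = (
        pd.to_numeric(df["GC_Score"], errors="coerce")
        if "GC_Score" in df.columns
        else pd.Series(np.nan, index=df.index)
    )
    genotypes = pd.DataFrame(
        {
            "sample_id": df["Sample_ID"].astype(str),
            "snp_id": snp_ids,
            "chrom": normalize_chrom(df["Chr"]),
            "pos": pd.to_numeric(df["Position"], errors="raise").astype(np.int64),
            "allele_a": allele_a.values,
            "allele_b": allele_b.values,
            "call": call.values,
            "gencall": gencall.values,
            "imputed": False,
        }
    )
    markers = (
        genotypes[["snp_id", "chrom", "pos"]]
        .drop_duplicates("snp_id")
        .assign(gentrain=np.nan)
    )
    return genotypes, markers


def _load_vcf(path: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows: list[tuple] = []
    marker_rows: list[tuple] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise GenotypeParseError(
                f"{path}: only biallelic sites supported, got {var.CHROM}:{var.POS}"
            )
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        chrom = str(var.CHROM).removeprefix("chr").upper()
        gentrain = var.INFO.get("GenTrain_Score")
        marker_rows.append((snp_id, chrom, var.POS, np.nan if gentrain is None else gentrain))
        try:
            gc = var.format("GC")
        except KeyError:
            gc = None
        gts = var.genotypes  # [allele1, allele2, phased]
        for i, s in enumerate(samples):
            a1, a2 = gts[i][0], gts[i][1]
            if a1 < 0 or a2 < 0:
                call = "NoCall"
            elif a1 == a2:
                call = "AA" if a1 == 0 else "BB"
            else:
                call = "AB"
            score = float(gc[i][0]) if gc is not None and not np.isnan(gc[i][0]) else np.nan
            rows.append((s, snp_id, chrom, var.POS, var.REF, var.ALT[0], call, score, False))
    genotypes = pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)
    markers = pd.DataFrame(marker_rows, columns=MARKER_COLUMNS)
    return genotypes, markers


def apply_qc(
    genotypes: pd.DataFrame,
    markers: pd.DataFrame,
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply array-style QC and return (filtered genotypes, QC report).

    Steps, in order: (1) calls with a confidence score strictly below
    ``min_gencall`` are masked to NoCall (missing scores are left alone);
    (2) markers with a cluster score strictly below ``min_gentrain`` are
    removed; (3) markers, then samples, whose call rate falls below
    ``min_call_rate`` are removed, iterating to a fixed point so a second
    application changes nothing.

    The report lists every exclusion with level (call/marker/sample),
    identifier, reason and offending value.
    """
    report_rows: list[dict] = []
    df = genotypes.copy()

    mask = df["gencall"].notna() & (df["gencall"] < thresholds.min_gencall)
    n_masked = int(mask.sum())
    if n_masked:
        df.loc[mask, "call"] = "NoCall"
        report_rows.append(
            {
                "level": "call",
                "id": f"{n_masked} calls",
                "reason": "gencall_below_cutoff",
                "value": float(thresholds.min_gencall),
            }
        )

    gentrain = markers.set_index("snp_id")["gentrain"]
    bad_markers = gentrain[gentrain.notna() & (gentrain < thresholds.min_gentrain)]
    for snp, v in bad_markers.items():
        report_rows.append(
            {"level": "marker", "id": snp, "reason": "gentrain_below_cutoff", "value": float(v)}
        )
    df = df[~df["snp_id"].isin(set(bad_markers.index))]

    # Call-rate pruning to a fixed point (marker pass, then sample pass).
    while True:
        if df.empty:
            break
        called = df["call"] != "NoCall"
        marker_rate = called.groupby(df["snp_id"]).mean()
        bad = marker_rate[marker_rate < thresholds.min_call_rate]
        for snp, v in bad.items():
            report_rows.append(
                {"level": "marker", "id": snp, "reason": "call_rate_below_min", "value": float(v)}
            )
        if len(bad):
            df = df[~df["snp_id"].isin(set(bad.index))]
            if df.empty:
                break
        called = df["call"] != "NoCall"
        sample_rate = called.groupby(df["sample_id"]).mean()
        bad_s = sample_rate[sample_rate < thresholds.min_call_rate]
        for s, v in bad_s.items():
            report_rows.append(
                {"level": "sample", "id": s, "reason": "call_rate_below_min", "value": float(v)}
            )
        if len(bad_s):
            df = df[~df["sample_id"].isin(set(bad_s.index))]
        if not len(bad) and not len(bad_s):
            break

    report = pd.DataFrame(report_rows, columns=["level", "id", "reason", "value"])
    if df.empty:
        raise QcError("quality control removed every genotype record")
    return df.reset_index(drop=True), report


def select_heterozygous(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Return only AB (heterozygous) calls; AA, BB and NoCall are dropped."""
    het = genotypes[genotypes["call"] == "AB"].reset_index(drop=True)
    for sample in set(genotypes["sample_id"]) - set(het["sample_id"]):
        logger.warning("sample %s has no heterozygous calls", sample)
    return het
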