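"""End-to-end orchestration: genotypes -> counts -> MAE -> chromosomes -> CN -> genes.

``run_pipeline`` executes every stage from one declarative configuration
and writes plain-TSV outputs plus a machine-readable JSON run report
(package version, configuration hash, record counts after every filter
step).  Rerunning with the same configuration and inputs produces
identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import __version__
from .allelic_counts import (
    CountFilterConfig,
    annotate_rna_genotype,
    filter_depth_cds,
    join_counts,
    load_cds_intervals,
    load_counts,
)
from .chrom_mae import (
    ChromCallConfig,
    chromosome_enrichment,
    chromosome_matrix,
    matrix_margins,
)
from .cn_overlap import explain_mae, load_segments
from .gene_recurrence import RecurrenceConfig, gene_profiles, recurrent_genes
from .genotype_io import QcThresholds, apply_qc, load_genotypes, select_heterozygous
from .mae_core import DaeBands, baf_histogram, classify_snps, mae_frequency

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage of the pipeline failed."""


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    genotypes: str
    counts: str
    cds: str
    out_dir: str
    genotype_format: str = "matrix"
    marker_manifest: str | None = None
    segments: str | None = None
    metadata: str | None = None
    input_set: str = "non-imputed"
    qc: QcThresholds = field(default_factory=QcThresholds)
    count_filter: CountFilterConfig = field(default_factory=CountFilterConfig)
    bands: DaeBands = field(default_factory=DaeBands)
    chrom_call: ChromCallConfig = field(default_factory=ChromCallConfig)
    recurrence: RecurrenceConfig = field(default_factory=RecurrenceConfig)
    theta_cn: float = 0.8
    target_chrom: str = "9"
    include_x: bool = False
    n_baf_bins: int = 50

    def validate(self) -> None:
        for name in ("genotypes", "counts", "cds", "marker_manifest", "segments",
                     "metadata"):
            path = getattr(self, name)
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(f"{name} file not found: {path}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        nested = {
            "qc": QcThresholds,
            "count_filter": CountFilterConfig,
            "bands": DaeBands,
            "chrom_call": ChromCallConfig,
            "recurrence": RecurrenceConfig,
        }
        kwargs = {}
        for k, v in raw.items():
            if k in nested and isinstance(v, dict):
                kwargs[k] = nested[k](**v)
            else:
                kwargs[k] = v
        return cls(**kwargs)


def _write_table(df: pd.DataFrame, path: str, config_hash: str) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# maescan {__version__} config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g",
                  lineterminator="\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write all output tables.

    Returns the run report (also written as ``run_report.json``): package
    version, configuration hash, per-stage record counts, chromosome
    enrichment result and output paths.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    h = config.config_hash()
    counts_log: dict[str, int] = {}

    def stage(name):
        logger.info("stage %s", name)

    try:
        stage("genotype_io")
        genotypes, markers = load_genotypes(
            config.genotypes,
            fmt=config.genotype_format,
            marker_manifest=config.marker_manifest,
            imputed=config.input_set == "imputed",
        )
        counts_log["genotype_records"] = len(genotypes)
        filtered, qc_report = apply_qc(genotypes, markers, config.qc)
        counts_log["after_qc"] = len(filtered)
        het = select_heterozygous(filtered)
        counts_log["heterozygous"] = len(het)

        stage("allelic_counts")
        rna_counts = load_counts(config.counts)
        joined, uncovered = join_counts(het, rna_counts)
        counts_log["with_rna_counts"] = len(joined)
        cds = load_cds_intervals(config.cds)
        informative = filter_depth_cds(joined, cds, config.count_filter)
        counts_log["informative"] = len(informative)
        informative = annotate_rna_genotype(informative, config.count_filter)

        stage("mae_core")
        calls = classify_snps(informative, config.bands)
        status_map = {}
        if config.metadata:
            meta = pd.read_csv(config.metadata, sep="\t", comment="#")
            status_map = dict(
                zip(meta["Sample_ID"].astype(str), meta["Mutational_Status"])
            )
        summaries = mae_frequency(
            calls,
            input_set=config.input_set,
            mutational_status=status_map,
            include_x=False,
        )
        hist_counts, hist_edges = baf_histogram(
            calls["baf"].to_numpy(), config.n_baf_bins
        )

        stage("chrom_mae")
        matrix = chromosome_matrix(calls, config.chrom_call, include_x=config.include_x)
        margins = matrix_margins(matrix)
        enrichment = None
        if str(config.target_chrom) in set(matrix["chrom"].astype(str)):
            enrichment = chromosome_enrichment(matrix, config.target_chrom)

        stage("cn_overlap")
        cn_table = None
        if config.segments:
            segments = load_segments(config.segments)
            cn_table = explain_mae(calls, segments, theta_cn=config.theta_cn)

        stage("gene_recurrence")
        profiles = gene_profiles(calls)
        recurrent = recurrent_genes(profiles, config.recurrence)
        counts_log["recurrent_genes"] = len(recurrent)
    except (PipelineError, Exception) as exc:
        raise PipelineError(f"pipeline failed: {exc}") from exc

    out = config.out_dir
    snp_table = calls.copy()
    snp_table["gene_ids"] = snp_table["gene_ids"].map(",".join)
    _write_table(snp_table, os.path.join(out, "informative_snps.tsv"), h)
    _write_table(qc_report, os.path.join(out, "qc_report.tsv"), h)
    _write_table(uncovered, os.path.join(out, "uncovered_snps.tsv"), h)
    _write_table(summaries, os.path.join(out, "sample_mae_summary.tsv"), h)
    hist = pd.DataFrame(
        {
            "bin_left": hist_edges[:-1],
            "bin_right": hist_edges[1:],
            "occurrence": hist_counts,
        }
    )
    _write_table(hist, os.path.join(out, "baf_histogram.tsv"), h)
    _write_table(matrix, os.path.join(out, "chromosome_mae_matrix.tsv"), h)
    if cn_table is not None:
        _write_table(cn_table, os.path.join(out, "cn_explanation.tsv"), h)
    _write_table(profiles, os.path.join(out, "gene_mae_profiles.tsv"), h)
    _write_table(recurrent, os.path.join(out, "recurrent_genes.tsv"), h)

    report = {
        "version": __version__,
        "config_hash": h,
        "record_counts": counts_log,
        "margins": margins,
        "enrichment": enrichment,
        "outputs": sorted(os.listdir(out)),
    }
    with open(os.path.join(out, "run_report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
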