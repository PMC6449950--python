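"""Synthetic cohorts with known per-SNP expression truth.

The generator emulates the data modalities the pipeline consumes — array
genotypes, RNA-seq allelic counts at SNP positions, gene CDS intervals,
copy-number segments and sample metadata — for a cohort of tumor-style
cell lines.  Expression truth per heterozygous SNP is a three-way mixture
(balanced / skewed DAE / complete MAE) with designated causes: genome-wide
random MAE, copy-number events that force MAE over a span, X inactivation
in females, imprinted genes, and optional purely epigenetic MAE spans.

Read counts are binomial given a truncated-Poisson (optionally negative
binomial) depth; a symmetric allele-flip error at rate ``error_rate``
makes complete MAE produce BAF near, not exactly at, 0 and 1, as in real
pileups.  All layers draw from independent substreams of one seed, so two
runs with the same configuration are byte-identical and adding a CN event
does not perturb any unrelated SNP.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

AUTOSOMES = tuple(str(c) for c in range(1, 23))
_BASES = np.array(list("ACGT"))

_LAYERS = (
    "marker",
    "genotype",
    "expression",
    "allele",
    "depth",
    "counts",
    "cn",
    "xci",
    "quality",
)


@dataclass(frozen=True)
class CnEvent:
    """A simulated copy-number event forcing MAE over its span."""

    sample_id: str
    chrom: str
    start: int
    end: int
    state: str = "loss"


@dataclass(frozen=True)
class MaeEvent:
    """A purely epigenetic MAE span (no copy-number change)."""

    sample_id: str
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class SimConfig:
    """Cohort simulation parameters.

    Defaults describe a 15-line cohort genotyped on a dense array and
    sequenced to moderate depth: 30x mean RNA depth, 30% heterozygosity,
    0.5% allele-flip error, and a 30%/10% complete-MAE/skewed-DAE mixture
    among expressed heterozygous SNPs.
    """

    n_samples: int = 15
    n_snps_per_chrom: int = 200
    n_chromosomes: int = 22
    include_x: bool = True
    n_genes_per_chrom: int = 20
    cds_fraction: float = 0.8
    snp_spacing: int = 2000
    het_rate: float = 0.3
    depth_mean: float = 30.0
    depth_dispersion: float | None = None  # None = Poisson; else NB size
    error_rate: float = 0.005
    mae_fraction: float = 0.3
    dae_fraction: float = 0.1
    dae_skew: float = 0.8
    cn_events: tuple[CnEvent, ...] = ()
    mae_events: tuple[MaeEvent, ...] = ()
    female_fraction: float = 0.5
    xci_skew: float = 1.0
    imprinted_genes: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("het_rate", "error_rate", "mae_fraction", "dae_fraction",
                     "female_fraction", "cds_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mae_fraction + self.dae_fraction > 1.0:
            raise ValueError("mae_fraction + dae_fraction must be <= 1")
        if not 0.5 < self.dae_skew < 1.0:
            raise ValueError("dae_skew must be in (0.5, 1)")
        if not 0.5 <= self.xci_skew <= 1.0:
            raise ValueError("xci_skew must be in [0.5, 1]")
        if self.depth_mean <= 0 or self.n_samples < 1 or self.n_snps_per_chrom < 1:
            raise ValueError("depth_mean, n_samples, n_snps_per_chrom must be positive")

    @property
    def chromosomes(self) -> tuple[str, ...]:
        chroms = AUTOSOMES[: self.n_chromosomes]
        return chroms + (("X",) if self.include_x else ())

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(f"S{i + 1:02d}" for i in range(self.n_samples))


@dataclass
class SyntheticCohort:
    """In-memory result of :func:`generate_cohort`."""

    config: SimConfig
    genotypes: pd.DataFrame  # matrix-dialect rows
    markers: pd.DataFrame  # SNP_Name, GenTrain_Score
    counts: pd.DataFrame  # Sample_ID, Chr, Position, Count_A, Count_B
    cds: pd.DataFrame  # BED-style chrom, start, end, name
    segments: pd.DataFrame  # Sample_ID, Chr, Start, End, State, Score
    metadata: pd.DataFrame  # Sample_ID, Sex, Mutational_Status
    truth: pd.DataFrame
    paths: dict = field(default_factory=dict)


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_LAYERS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_LAYERS, children)}


def _uniform_open(rng: np.random.Generator, size) -> np.ndarray:
    # Keep away from 0 and 1 so discrete ppf() stays within support.
    return np.clip(rng.random(size), 1e-12, 1.0 - 1e-12)


def generate_cohort(config: SimConfig, out_dir: str | None = None) -> SyntheticCohort:
    """Simulate a cohort; optionally write all pipeline input files.

    When ``out_dir`` is given the genotype matrix (and an equivalent VCF),
    marker manifest, allelic count table, CDS BED, copy-number SEG table,
    sample metadata and the per-SNP truth table are written there; the
    same tables are returned in memory.
    """
    rngs = _rngs(config.seed)
    chroms = config.chromosomes
    samples = list(config.sample_ids)
    n_per = config.n_snps_per_chrom

    # --- genome geometry: SNPs and tiled genes with CDS blocks ---
    snp_rows = []
    cds_rows = []
    snp_gene: dict[tuple[str, int], str] = {}
    for chrom in chroms:
        block = max(1, n_per // config.n_genes_per_chrom) * config.snp_spacing
        for g in range(config.n_genes_per_chrom):
            start1 = g * block + 1
            cds_end = start1 + int(block * config.cds_fraction) - 1
            name = f"GENE_{chrom}_{g + 1:03d}"
            cds_rows.append((chrom, start1 - 1, cds_end, name))  # BED half-open
        for i in range(n_per):
            pos = i * config.snp_spacing + config.snp_spacing // 2
            snp_rows.append((f"rs_{chrom}_{i + 1:05d}", chrom, pos))
            g = (pos - 1) // block
            block_off = (pos - 1) % block
            if g < config.n_genes_per_chrom and block_off < int(block * config.cds_fraction):
                snp_gene[(chrom, pos)] = f"GENE_{chrom}_{g + 1:03d}"
    snps = pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos"])
    cds = pd.DataFrame(cds_rows, columns=["chrom", "start", "end", "name"])
    n_snps = len(snps)

    # --- marker-level draws ---
    mr = rngs["marker"]
    ref_idx = mr.integers(0, 4, n_snps)
    alt_idx = (ref_idx + 1 + mr.integers(0, 3, n_snps)) % 4
    allele_a = _BASES[ref_idx]
    allele_b = _BASES[alt_idx]
    gentrain = 0.7 + 0.3 * mr.random(n_snps)
    markers = pd.DataFrame(
        {"SNP_Name": snps["snp_id"], "GenTrain_Score": np.round(gentrain, 4)}
    )

    # --- sample metadata ---
    qr = rngs["quality"]
    n_f = int(round(config.female_fraction * config.n_samples))
    sex = np.array(["F"] * n_f + ["M"] * (config.n_samples - n_f))
    status_cycle = ["BRAF", "NRAS", "WT"]
    weights = [8, 6, 1]  # melanoma-like mutation mix
    statuses = []
    for i in range(config.n_samples):
        pick = qr.choice(3, p=np.array(weights) / sum(weights))
        statuses.append(status_cycle[pick])
    metadata = pd.DataFrame(
        {"Sample_ID": samples, "Sex": sex, "Mutational_Status": statuses}
    )
    sex_by_sample = dict(zip(samples, sex))

    # --- per sample x SNP layers (SNP-major arrays, fixed order) ---
    gr = rngs["genotype"]
    er = rngs["expression"]
    ar = rngs["allele"]
    dr = rngs["depth"]
    cr = rngs["counts"]
    xr = rngs["xci"]

    u_het = gr.random((config.n_samples, n_snps))
    u_homside = gr.random((config.n_samples, n_snps))
    u_state = er.random((config.n_samples, n_snps))
    u_allele = ar.random((config.n_samples, n_snps))
    u_skewdir = ar.random((config.n_samples, n_snps))
    u_depth = _uniform_open(dr, (config.n_samples, n_snps))
    u_count = _uniform_open(cr, (config.n_samples, n_snps))
    gencall = np.round(0.6 + 0.4 * qr.random((config.n_samples, n_snps)), 4)
    xci_allele = xr.random(config.n_samples)  # one inactive X per sample

    chrom_arr = snps["chrom"].to_numpy()
    pos_arr = snps["pos"].to_numpy()
    is_x = chrom_arr == "X"

    het = u_het < config.het_rate
    # males are hemizygous on X: never heterozygous there
    for si, s in enumerate(samples):
        if sex_by_sample[s] == "M":
            het[si, is_x] = False

    # expression truth for het SNPs
    state = np.full((config.n_samples, n_snps), "Balanced", dtype=object)
    cause = np.full((config.n_samples, n_snps), "none", dtype=object)
    state[u_state < config.mae_fraction] = "CompleteMAE"
    mid = (u_state >= config.mae_fraction) & (
        u_state < config.mae_fraction + config.dae_fraction
    )
    state[mid] = "DAE"
    cause[state == "CompleteMAE"] = "random"
    cause[state == "DAE"] = "random"

    # imprinted genes: constitutive MAE in every sample
    if config.imprinted_genes:
        imp = set(config.imprinted_genes)
        imp_mask = np.array(
            [snp_gene.get((c, p)) in imp for c, p in zip(chrom_arr, pos_arr)]
        )
        state[:, imp_mask] = "CompleteMAE"
        cause[:, imp_mask] = "imprinting"

    # X inactivation in females
    for si, s in enumerate(samples):
        if sex_by_sample[s] == "F":
            state[si, is_x] = "CompleteMAE" if config.xci_skew >= 1.0 else "DAE"
            cause[si, is_x] = "xci"

    # epigenetic MAE spans
    sample_index = {s: i for i, s in enumerate(samples)}
    for ev in config.mae_events:
        si = sample_index[ev.sample_id]
        span = (chrom_arr == str(ev.chrom)) & (pos_arr >= ev.start) & (pos_arr <= ev.end)
        state[si, span] = "CompleteMAE"
        cause[si, span] = "epigenetic"

    # CN events override everything inside their span
    cn_rng = rngs["cn"]
    seg_rows = []
    for ev in config.cn_events:
        si = sample_index[ev.sample_id]
        span = (chrom_arr == str(ev.chrom)) & (pos_arr >= ev.start) & (pos_arr <= ev.end)
        expressed_b = cn_rng.random() < 0.5  # surviving haplotype, fixed per event
        state[si, span] = "CompleteMAE"
        cause[si, span] = "cn"
        u_allele[si, span] = 0.0 if expressed_b else 1.0  # below: <0.5 means B expressed
        seg_rows.append((ev.sample_id, ev.chrom, ev.start, ev.end, ev.state, 10.0))
    segments = pd.DataFrame(
        seg_rows, columns=["Sample_ID", "Chr", "Start", "End", "State", "Score"]
    )

    # expressed allele and success probability of the B allele
    expressed_b = u_allele < 0.5
    skew_to_b = u_skewdir < 0.5
    p_b = np.full((config.n_samples, n_snps), 0.5)
    p_b[state == "DAE"] = np.where(
        skew_to_b[state == "DAE"], config.dae_skew, 1.0 - config.dae_skew
    )
    xci_partial = (cause == "xci") & (state == "DAE")
    if xci_partial.any():
        for si in range(config.n_samples):
            row = xci_partial[si]
            direction = xci_allele[si] < 0.5
            p_b[si, row] = config.xci_skew if direction else 1.0 - config.xci_skew
    mae_mask = state == "CompleteMAE"
    p_b[mae_mask] = np.where(
        expressed_b[mae_mask], 1.0 - config.error_rate, config.error_rate
    )

    # depth and counts (quantile transforms keep substreams independent)
    if config.depth_dispersion is None:
        depth = stats.poisson.ppf(u_depth, config.depth_mean)
    else:
        size = config.depth_dispersion
        p_nb = size / (size + config.depth_mean)
        depth = stats.nbinom.ppf(u_depth, size, p_nb)
    depth = np.maximum(depth, 1).astype(np.int64)
    count_b = stats.binom.ppf(u_count, depth, p_b).astype(np.int64)
    count_a = depth - count_b

    # --- assemble long tables over het SNPs ---
    si_idx, snp_idx = np.nonzero(het)
    sample_arr = np.array(samples)[si_idx]
    geno_rows = pd.DataFrame(
        {
            "SNP_Name": snps["snp_id"].to_numpy()[snp_idx],
            "Sample_ID": sample_arr,
            "Chr": chrom_arr[snp_idx],
            "Position": pos_arr[snp_idx],
            "Allele1": allele_a[snp_idx],
            "Allele2": allele_b[snp_idx],
            "GC_Score": gencall[si_idx, snp_idx],
        }
    )
    # homozygous calls for the remaining (sample, SNP) pairs
    hi, hj = np.nonzero(~het)
    hom_b = u_homside[hi, hj] < 0.5
    hom_base = np.where(hom_b, allele_b[hj], allele_a[hj])
    hom_rows = pd.DataFrame(
        {
            "SNP_Name": snps["snp_id"].to_numpy()[hj],
            "Sample_ID": np.array(samples)[hi],
            "Chr": chrom_arr[hj],
            "Position": pos_arr[hj],
            "Allele1": hom_base,
            "Allele2": hom_base,
            "GC_Score": gencall[hi, hj],
        }
    )
    genotypes = (
        pd.concat([geno_rows, hom_rows], ignore_index=True)
        .sort_values(["Sample_ID", "Chr", "Position"], kind="mergesort")
        .reset_index(drop=True)
    )

    counts = pd.DataFrame(
        {
            "Sample_ID": sample_arr,
            "Chr": chrom_arr[snp_idx],
            "Position": pos_arr[snp_idx],
            "Count_A": count_a[si_idx, snp_idx],
            "Count_B": count_b[si_idx, snp_idx],
        }
    ).sort_values(["Sample_ID", "Chr", "Position"], kind="mergesort").reset_index(drop=True)

    truth = pd.DataFrame(
        {
            "sample_id": sample_arr,
            "chrom": chrom_arr[snp_idx],
            "pos": pos_arr[snp_idx],
            "expression_state": state[si_idx, snp_idx],
            "cause": cause[si_idx, snp_idx],
            "expressed_allele": np.where(
                state[si_idx, snp_idx] == "CompleteMAE",
                np.where(expressed_b[si_idx, snp_idx], "B", "A"),
                "",
            ),
            "gene_id": [
                snp_gene.get((c, p), "") for c, p in zip(chrom_arr[snp_idx], pos_arr[snp_idx])
            ],
            "true_depth": depth[si_idx, snp_idx],
        }
    ).sort_values(["sample_id", "chrom", "pos"], kind="mergesort").reset_index(drop=True)

    cohort = SyntheticCohort(
        config=config,
        genotypes=genotypes,
        markers=markers,
        counts=counts,
        cds=cds,
        segments=segments,
        metadata=metadata,
        truth=truth,
    )
    if out_dir is not None:
        cohort.paths = write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: SyntheticCohort, out_dir: str) -> dict:
    """Write every pipeline input file; returns a name -> path mapping."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "genotypes": os.path.join(out_dir, "genotypes.tsv"),
        "genotypes_vcf": os.path.join(out_dir, "genotypes.vcf"),
        "markers": os.path.join(out_dir, "markers.tsv"),
        "counts": os.path.join(out_dir, "counts.tsv"),
        "cds": os.path.join(out_dir, "cds.bed"),
        "segments": os.path.join(out_dir, "segments.seg.tsv"),
        "metadata": os.path.join(out_dir, "metadata.tsv"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    kw = dict(sep="\t", index=False, float_format="%.4f", lineterminator="\n")
    cohort.genotypes.to_csv(paths["genotypes"], **kw)
    cohort.markers.to_csv(paths["markers"], **kw)
    cohort.counts.to_csv(paths["counts"], **kw)
    cohort.cds.to_csv(paths["cds"], sep="\t", index=False, header=False,
                      lineterminator="\n")
    cohort.segments.to_csv(paths["segments"], **kw)
    cohort.metadata.to_csv(paths["metadata"], **kw)
    cohort.truth.to_csv(paths["truth"], **kw)
    _write_vcf(cohort, paths["genotypes_vcf"])
    return paths


def _write_vcf(cohort: SyntheticCohort, path: str) -> None:
    """Write DNA genotypes as a minimal multi-sample VCF (text)."""
    samples = list(cohort.config.sample_ids)
    wide = cohort.genotypes.pivot_table(
        index=["Chr", "Position", "SNP_Name"],
        columns="Sample_ID",
        values=["Allele1", "Allele2"],
        aggfunc="first",
    )
    # recover per-marker ref/alt from the biallelic design
    marker_alleles = {}
    for r in cohort.genotypes.itertuples(index=False):
        rec = marker_alleles.setdefault(r.SNP_Name, set())
        rec.update((r.Allele1, r.Allele2))
    with open(path, "w", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in cohort.config.chromosomes:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for (chrom, pos, snp) in sorted(
            wide.index, key=lambda t: (str(t[0]), int(t[1]))
        ):
            alleles = sorted(marker_alleles[snp])
            ref = alleles[0]
            alt = alleles[1] if len(alleles) > 1 else "N"
            gts = []
            for s in samples:
                try:
                    a1 = wide.loc[(chrom, pos, snp), ("Allele1", s)]
                    a2 = wide.loc[(chrom, pos, snp), ("Allele2", s)]
                except KeyError:
                    a1 = a2 = None
                if a1 is None or pd.isna(a1):
                    gts.append("./.")
                else:
                    code = {ref: "0", alt: "1"}
                    gts.append(f"{code.get(a1, '.')}/{code.get(a2, '.')}")
            fh.write(
                f"{chrom}\t{pos}\t{snp}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


_CALL_TO_TRUTH = {
    "BiallelicBalanced": "Balanced",
    "SkewedDAE": "DAE",
    "CompleteMAE": "CompleteMAE",
}


def truth_compare(mae_calls: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Confusion matrix and recovery metrics of pipeline calls vs truth.

    ``mae_calls`` must carry sample_id/chrom/pos and a ``status`` column;
    every call must have a truth row (a missing key raises).  Returns the
    truth x called confusion matrix, overall accuracy and per-state
    recall.
    """
    keys = ["sample_id", "chrom", "pos"]
    calls = mae_calls[keys + ["status"]].copy()
    calls["chrom"] = calls["chrom"].astype(str)
    t = truth[keys + ["expression_state"]].copy()
    t["chrom"] = t["chrom"].astype(str)
    merged = calls.merge(t, on=keys, how="left")
    if merged["expression_state"].isna().any():
        missing = merged.loc[merged["expression_state"].isna(), keys].head(5)
        raise ValueError(f"calls without truth rows, e.g.\n{missing}")
    merged["called"] = merged["status"].map(_CALL_TO_TRUTH)
    confusion = pd.crosstab(merged["expression_state"], merged["called"])
    labels = ["Balanced", "DAE", "CompleteMAE"]
    confusion = confusion.reindex(index=labels, columns=labels, fill_value=0)
    total = int(confusion.to_numpy().sum())
    correct = int(np.trace(confusion.to_numpy()))
    recall = {
        lab: (confusion.loc[lab, lab] / confusion.loc[lab].sum())
        if confusion.loc[lab].sum()
        else np.nan
        for lab in labels
    }
    return {
        "confusion": confusion,
        "n": total,
        "accuracy": correct / total if total else np.nan,
        "recall": recall,
    }


def recurrence_metrics(predicted: pd.DataFrame, truth_genes: set[str]) -> dict:
    """Precision/recall of a recurrent-gene list against truth gene ids."""
    pred = set(predicted["gene_id"])
    tp = len(pred & truth_genes)
    return {
        "precision": tp / len(pred) if pred else np.nan,
        "recall": tp / len(truth_genes) if truth_genes else np.nan,
        "n_predicted": len(pred),
        "n_truth": len(truth_genes),
    }


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy a configuration with a different seed."""
    return replace(config, seed=seed)
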