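import pandas as pd
import pytest

from maescan.synthetic import CnEvent, MaeEvent, SimConfig, generate_cohort


def make_genotypes(rows):
    """Build a genotype-call DataFrame from compact tuples.

    rows: (sample_id, snp_id, chrom, pos, allele_a, allele_b, call, gencall)
    """
    df = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "snp_id", "chrom", "pos",
            "allele_a", "allele_b", "call", "gencall",
        ],
    )
    df["imputed"] = False
    return df


def make_markers(rows):
    """rows: (snp_id, chrom, pos, gentrain)"""
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "gentrain"])


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic 3-sample cohort with CN-driven and epigenetic MAE."""
    config = SimConfig(
        n_samples=3,
        n_snps_per_chrom=150,
        mae_fraction=0.3,
        dae_fraction=0.1,
        depth_mean=30.0,
        seed=11,
        cn_events=(CnEvent("S01", "9", 1, 10**7, "loss"),),
        mae_events=(MaeEvent("S01", "5", 1, 10**7),),
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def cohort_files(tmp_path_factory):
    """The same small cohort written to disk once per session."""
    config = SimConfig(
        n_samples=3,
        n_snps_per_chrom=150,
        mae_fraction=0.3,
        dae_fraction=0.1,
        seed=11,
        cn_events=(CnEvent("S01", "9", 1, 10**7, "loss"),),
        mae_events=(MaeEvent("S01", "5", 1, 10**7),),
    )
    out = tmp_path_factory.mktemp("cohort")
    cohort = generate_cohort(config, out_dir=str(out))
    return cohort
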