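"""Genotype loading, array-style QC and heterozygosity selection."""

import numpy as np
import pandas as pd
import pytest

from maescan.genotype_io import (
    GenotypeParseError,
    QcError,
    QcThresholds,
    apply_qc,
    load_genotypes,
    normalize_chrom,
    select_heterozygous,
)

from conftest import make_genotypes, make_markers


MATRIX = """SNP_Name\tSample_ID\tChr\tPosition\tAllele1\tAllele2\tGC_Score
rs1\tS1\tchr9\t1000\tC\tT\t0.82
rs2\tS1\t9\t2000\tA\tA\t0.90
rs3\tS1\tX\t3000\tG\tG\t0.70
rs1\tS2\t9\t1000\tC\tC\t0.88
rs2\tS2\t9\t2000\tA\tG\t0.91
rs3\tS2\tX\t3000\t-\t-\t0.00
"""


@pytest.fixture()
def matrix_path(tmp_path):
    p = tmp_path / "geno.tsv"
    p.write_text(MATRIX)
    return str(p)


def test_matrix_loading_cardinality_calls_and_scores(matrix_path):
    geno, markers = load_genotypes(matrix_path, fmt="matrix")
    assert len(geno) == 6  # 2 samples x 3 markers
    assert set(markers["snp_id"]) == {"rs1", "rs2", "rs3"}
    rec = geno.set_index(["sample_id", "snp_id"])
    # deterministic A/B labels: lexicographically smaller base is A
    assert rec.loc[("S1", "rs1"), "call"] == "AB"
    assert rec.loc[("S1", "rs1"), "allele_a"] == "C"
    assert rec.loc[("S1", "rs1"), "allele_b"] == "T"
    assert rec.loc[("S2", "rs1"), "call"] == "AA"
    assert rec.loc[("S2", "rs2"), "call"] == "AB"
    assert rec.loc[("S2", "rs3"), "call"] == "NoCall"
    assert rec.loc[("S1", "rs1"), "gencall"] == pytest.approx(0.82)
    # chr prefix stripped
    assert set(geno["chrom"]) == {"9", "X"}


def test_vcf_loading_matches_gt_semantics(tmp_path):
    vcf = tmp_path / "g.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=9>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
        "9\t1000\trs1\tC\tT\t.\tPASS\t.\tGT\t0/1\t1/1\n"
        "9\t2000\trs2\tA\tG\t.\tPASS\t.\tGT\t./.\t0/0\n"
    )
    geno, markers = load_genotypes(str(vcf), fmt="vcf")
    rec = geno.set_index(["sample_id", "snp_id"])
    assert rec.loc[("S1", "rs1"), "call"] == "AB"
    assert rec.loc[("S1", "rs1"), "allele_a"] == "C"
    assert rec.loc[("S1", "rs1"), "allele_b"] == "T"
    assert rec.loc[("S2", "rs1"), "call"] == "BB"
    assert rec.loc[("S1", "rs2"), "call"] == "NoCall"
    assert rec.loc[("S2", "rs2"), "call"] == "AA"


def test_duplicate_sample_marker_pairs_rejected(tmp_path):
    p = tmp_path / "dup.tsv"
    p.write_text(
        "SNP_Name\tSample_ID\tChr\tPosition\tAllele1\tAllele2\tGC_Score\n"
        "rs1\tS1\t1\t100\tA\tC\t0.9\n"
        "rs1\tS1\t1\t100\tA\tC\t0.9\n"
    )
    with pytest.raises(GenotypeParseError, match="duplicate"):
        load_genotypes(str(p), fmt="matrix")


def test_marker_manifest_supplies_gentrain(matrix_path, tmp_path):
    manifest = tmp_path / "manifest.tsv"
    manifest.write_text(
        "SNP_Name\tGenTrain_Score\nrs1\t0.8\nrs2\t0.4\nrs3\t0.9\n"
    )
    _, markers = load_genotypes(matrix_path, fmt="matrix", marker_manifest=str(manifest))
    assert markers.set_index("snp_id").loc["rs2", "gentrain"] == pytest.approx(0.4)


class TestApplyQc:
    def _base(self):
        rows = [
            ("S1", "rs1", "1", 100, "A", "C", "AB", 0.9),
            ("S1", "rs2", "1", 200, "A", "G", "AA", 0.9),
            ("S2", "rs1", "1", 100, "A", "C", "BB", 0.9),
            ("S2", "rs2", "1", 200, "A", "G", "AB", 0.9),
        ]
        markers = make_markers(
            [("rs1", "1", 100, 0.9), ("rs2", "1", 200, 0.9)]
        )
        return make_genotypes(rows), markers

    def test_low_gentrain_marker_removed(self):
        geno, markers = self._base()
        markers.loc[markers["snp_id"] == "rs2", "gentrain"] = 0.4
        out, report = apply_qc(geno, markers)
        assert set(out["snp_id"]) == {"rs1"}
        assert (
            (report["level"] == "marker")
            & (report["reason"] == "gentrain_below_cutoff")
        ).sum() == 1

    def test_gencall_boundary_retained_and_below_masked(self):
        geno, markers = self._base()
        geno.loc[0, "gencall"] = 0.15  # exactly at cutoff: kept
        geno.loc[1, "gencall"] = 0.14  # below: masked to NoCall
        thresholds = QcThresholds(min_call_rate=0.0)
        out, _ = apply_qc(geno, markers, thresholds)
        rec = out.set_index(["sample_id", "snp_id"])
        assert rec.loc[("S1", "rs1"), "call"] == "AB"
        assert rec.loc[("S1", "rs2"), "call"] == "NoCall"

    def test_low_call_rate_sample_removed(self):
        # SB has call rate 9/10 = 0.9 < 0.95; with 21 samples the marker it
        # misses keeps a 20/21 call rate and survives, so only SB is dropped.
        rows = []
        markers = []
        good = [f"S{i}" for i in range(20)]
        for i in range(10):
            snp = f"rs{i}"
            markers.append((snp, "1", 100 + i, 0.9))
            for s in good:
                rows.append((s, snp, "1", 100 + i, "A", "C", "AB", 0.9))
            call = "NoCall" if i == 0 else "AB"
            rows.append(("SB", snp, "1", 100 + i, "A", "C", call, 0.9))
        out, report = apply_qc(make_genotypes(rows), make_markers(markers))
        assert set(out["sample_id"]) == set(good)
        assert set(out["snp_id"]) == {f"rs{i}" for i in range(10)}
        assert ((report["level"] == "sample") & (report["id"] == "SB")).any()

    def test_idempotent(self):
        geno, markers = self._base()
        geno.loc[2, "gencall"] = 0.05
        once, _ = apply_qc(geno, markers)
        twice, report2 = apply_qc(once, markers)
        pd.testing.assert_frame_equal(once, twice)
        assert not (report2["level"] == "sample").any()

    def test_everything_filtered_is_fatal(self):
        geno, markers = self._base()
        geno["gencall"] = 0.01
        with pytest.raises(QcError):
            apply_qc(geno, markers)

    def test_order_invariance_of_het_selection(self):
        geno, markers = self._base()
        shuffled = geno.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = select_heterozygous(apply_qc(geno, markers)[0])
        b = select_heterozygous(apply_qc(shuffled, markers)[0])
        key = ["sample_id", "snp_id"]
        pd.testing.assert_frame_equal(
            a.sort_values(key).reset_index(drop=True),
            b.sort_values(key).reset_index(drop=True),
        )


def test_select_heterozygous_keeps_exactly_ab():
    rows = [
        ("S1", "rs1", "1", 100, "A", "C", "AA", 0.9),
        ("S1", "rs2", "1", 200, "A", "C", "AB", 0.9),
        ("S1", "rs3", "1", 300, "A", "C", "BB", 0.9),
        ("S1", "rs4", "1", 400, "A", "C", "NoCall", 0.9),
    ]
    out = select_heterozygous(make_genotypes(rows))
    assert list(out["snp_id"]) == ["rs2"]


def test_allele_relabeling_leaves_het_set_unchanged():
    rows = [
        ("S1", "rs1", "1", 100, "A", "C", "AA", 0.9),
        ("S1", "rs2", "1", 200, "A", "C", "AB", 0.9),
        ("S2", "rs1", "1", 100, "A", "C", "AB", 0.9),
    ]
    geno = make_genotypes(rows)
    swapped = geno.copy()
    swapped["call"] = swapped["call"].map({"AA": "BB", "BB": "AA", "AB": "AB"})
    swapped[["allele_a", "allele_b"]] = swapped[["allele_b", "allele_a"]].values
    a = select_heterozygous(geno)[["sample_id", "snp_id"]]
    b = select_heterozygous(swapped)[["sample_id", "snp_id"]]
    pd.testing.assert_frame_equal(a, b)


def test_normalize_chrom():
    out = list(normalize_chrom(["chr1", "Chr2", "x", "chrX", "22"]))
    assert out == ["1", "2", "X", "X", "22"]
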