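"""Format I/O and the hard-filter / SNP-cluster rules, including the exact
inclusive/exclusive boundaries of every printed clause."""

from __future__ import annotations

import numpy as np
import pytest

from ppdscan.variant_io import (
    GenotypeMatrix,
    ParseError,
    ValidationError,
    VariantRecord,
    apply_hard_filters,
    read_gene_model,
    read_pedigree,
    read_vcf,
    snp_cluster_filter,
    write_vcf,
)


def _vcf(tmp_path, body: str, samples=("s1", "s2")) -> str:
    header = (
        "##fileformat=VCFv4.2\n"
        '##contig=<ID=11,length=100000>\n'
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="d">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n"
    )
    p = tmp_path / "t.vcf"
    p.write_text(header + body)
    return str(p)


def test_read_single_site_phased_genotypes(tmp_path):
    path = _vcf(tmp_path, "11\t42\t.\tA\tG\t50\t.\t.\tGT\t0|0\t1|1\n")
    records, matrix = read_vcf(path)
    assert len(records) == 1 and records[0].pos == 42
    assert matrix.alleles[0].tolist() == [[0, 0], [1, 1]]
    assert matrix.phased.all()


def test_missing_genotype_excluded_from_allele_counts(tmp_path):
    path = _vcf(tmp_path, "11\t42\t.\tA\tG\t50\t.\t.\tGT\t./.\t0|1\n")
    records, matrix = read_vcf(path)
    assert (matrix.alleles[0, 0] == -1).all()
    from ppdscan.association import _group_allele_counts

    ref, alt = _group_allele_counts(matrix.alleles, np.array([0, 1]))
    assert (int(ref[0]), int(alt[0])) == (1, 1)  # only the called sample counts


def test_multiallelic_and_phase_preserved_roundtrip(tmp_path, small_dataset):
    paths, _, _ = small_dataset
    records, matrix = read_vcf(str(paths["vcf"]))
    out = tmp_path / "rt.vcf"
    write_vcf(records, matrix, str(out))
    records2, matrix2 = read_vcf(str(out))
    assert len(records) == len(records2)
    for a, b in zip(records, records2):
        assert (a.chrom, a.pos, a.ref, a.alts) == (b.chrom, b.pos, b.ref, b.alts)
        assert a.qual == pytest.approx(b.qual, abs=0.01)
        assert a.annotations == pytest.approx(b.annotations, rel=1e-3)
    assert np.array_equal(matrix.alleles, matrix2.alleles)
    assert np.array_equal(matrix.phased, matrix2.phased)


def test_unsorted_vcf_rejected_with_record_number(tmp_path):
    body = "11\t42\t.\tA\tG\t50\t.\t.\tGT\t0|0\t1|1\n11\t10\t.\tA\tG\t50\t.\t.\tGT\t0|0\t1|1\n"
    with pytest.raises(ParseError, match="record 2"):
        read_vcf(_vcf(tmp_path, body))


def _snp(**ann):
    qual = ann.pop("QUAL", 100.0)
    return VariantRecord("11", 100, None, "A", ["G"], qual=qual, annotations=ann)


def _indel(**ann):
    qual = ann.pop("QUAL", 100.0)
    return VariantRecord("11", 100, None, "AT", ["A"], qual=qual, annotations=ann)


PASSING_SNP = dict(QD=20.0, MQ=55.0, FS=5.0, MQRankSum=0.0, ReadPosRankSum=0.0, MQ0=0.0,
                   DP=500.0)


@pytest.mark.parametrize(
    "override, expected_flags",
    [
        # each clause fails singly; thresholds/operators exactly as printed
        ({"QUAL": 39.0}, {"QUAL"}),
        ({"QUAL": 40.0}, {"QUAL"}),      # inclusive boundary
        ({"QUAL": 40.01}, set()),
        ({"QD": 1.5}, {"QD"}),
        ({"QD": 2.0}, {"QD"}),           # inclusive
        ({"QD": 2.01}, set()),
        ({"MQ": 40.0}, {"MQ"}),          # inclusive
        ({"FS": 60.0}, {"FS"}),          # inclusive (SNP rule)
        ({"FS": 59.99}, set()),
        ({"MQRankSum": -12.5}, {"MQRankSum"}),  # inclusive
        ({"MQRankSum": -12.49}, set()),
        ({"ReadPosRankSum": -8.0}, set()),      # strict '<'
        ({"ReadPosRankSum": -8.01}, {"ReadPosRankSum"}),
        ({"MQ0": 4.0, "DP": 30.0}, {"MQ0"}),    # 4/30 > 0.1 and MQ0 >= 4
        ({"MQ0": 4.0, "DP": 50.0}, set()),      # ratio 0.08 <= 0.1
        ({"MQ0": 3.0, "DP": 10.0}, set()),      # MQ0 < 4
    ],
)
def test_snp_hard_filter_clauses_and_boundaries(override, expected_flags):
    rec = _snp(**{**PASSING_SNP, **override})
    apply_hard_filters([rec], "SNP")
    assert rec.filter_flags == expected_flags


@pytest.mark.parametrize(
    "override, expected_flags",
    [
        ({"QD": 1.99}, {"QD"}),
        ({"QD": 2.0}, set()),            # strict '<' (INDEL rule)
        ({"FS": 200.0}, set()),          # strict '>'
        ({"FS": 200.01}, {"FS"}),
        ({"ReadPosRankSum": -20.0}, set()),
        ({"ReadPosRankSum": -20.01}, {"ReadPosRankSum"}),
    ],
)
def test_indel_hard_filter_clauses_and_boundaries(override, expected_flags):
    rec = _indel(**{**dict(QD=20.0, FS=5.0, ReadPosRankSum=0.0), **override})
    apply_hard_filters([rec], "INDEL")
    assert rec.filter_flags == expected_flags


def test_flag_set_is_union_of_independently_failing_clauses():
    rec = _snp(**{**PASSING_SNP, "QD": 1.0, "FS": 100.0, "QUAL": 10.0})
    apply_hard_filters([rec], "SNP")
    assert rec.filter_flags == {"QD", "FS", "QUAL"}


def test_missing_annotation_skips_clause_not_fails_it():
    rec = VariantRecord("11", 100, None, "A", ["G"], qual=100.0, annotations={})
    apply_hard_filters([rec], "SNP")
    assert rec.filter_flags == set()
    # MQ0 clause needs both MQ0 and DP
    rec2 = _snp(**{**PASSING_SNP})
    del rec2.annotations["DP"]
    rec2.annotations["MQ0"] = 10.0
    apply_hard_filters([rec2], "SNP")
    assert rec2.filter_flags == set()


def test_mode_only_touches_matching_variant_class():
    snp = _snp(**{**PASSING_SNP, "QD": 1.0})
    apply_hard_filters([snp], "INDEL")
    assert snp.filter_flags == set()
    with pytest.raises(ValueError, match="mode"):
        apply_hard_filters([snp], "MNP")


@pytest.mark.parametrize(
    "positions, flagged",
    [
        ((100, 105, 109), {100, 105, 109}),  # span 10 bp: cluster
        ((100, 105, 111), set()),            # span 12 bp: no 10-bp window holds 3
        ((100, 109), set()),                 # below min_snps, never flagged
        ((100, 101, 102, 150, 155, 159, 300), {100, 101, 102, 150, 155, 159}),
    ],
)
def test_snp_cluster_flagging(positions, flagged):
    recs = [VariantRecord("11", p, None, "A", ["G"]) for p in positions]
    snp_cluster_filter(recs)
    assert {r.pos for r in recs if "SnpCluster" in r.filter_flags} == flagged


def test_cluster_filter_counts_snps_only():
    recs = [
        VariantRecord("11", 100, None, "A", ["G"]),
        VariantRecord("11", 105, None, "AT", ["A"]),  # INDEL between two SNPs
        VariantRecord("11", 109, None, "C", ["T"]),
    ]
    snp_cluster_filter(recs)
    assert all("SnpCluster" not in r.filter_flags for r in recs)


def test_cluster_filter_requires_sorted_records():
    recs = [VariantRecord("11", p, None, "A", ["G"]) for p in (105, 100, 109)]
    with pytest.raises(ValidationError):
        snp_cluster_filter(recs)


def test_pedigree_groups_and_missing_phenotype(tmp_path, small_dataset):
    paths, truth, _ = small_dataset
    ped = read_pedigree(str(paths["ped"]))
    assert len(ped.samples) == 17
    assert len(ped.cases) == 4 and len(ped.controls) == 13
    assert set(ped.cases) == {s for s, v in truth.phenotypes.items() if v == 2}
    # phenotype 0 excluded from both groups
    p = tmp_path / "p.ped"
    p.write_text("F\ts1\t0\t0\t1\t2\nF\ts2\t0\t0\t2\t1\nF\ts3\t0\t0\t1\t0\n")
    ped2 = read_pedigree(str(p))
    assert ped2.cases == ["s1"] and ped2.controls == ["s2"]


def test_duplicate_sample_id_rejected(tmp_path):
    p = tmp_path / "p.ped"
    p.write_text("F\ts1\t0\t0\t1\t2\nF\ts1\t0\t0\t1\t1\n")
    with pytest.raises(ValidationError, match="duplicate"):
        read_pedigree(str(p))


def test_gene_model_validates_cds_frame(tmp_path, small_dataset):
    paths, truth, _ = small_dataset
    model = read_gene_model(str(paths["gtf"]))
    for g in model.genes:
        t = g.longest_cds_transcript()
        assert t.cds_length % 3 == 0
    assert truth.causal_gene_id in {g.id for g in model.genes}
    # a broken frame is rejected
    bad = tmp_path / "bad.gtf"
    bad.write_text(
        '11\tx\tgene\t10\t100\t.\t+\t.\tgene_id "g1";\n'
        '11\tx\ttranscript\t10\t100\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        '11\tx\texon\t10\t100\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        '11\tx\tCDS\t10\t21\t.\t+\t0\tgene_id "g1"; transcript_id "t1";\n'
        '11\tx\tCDS\t30\t33\t.\t+\t0\tgene_id "g1"; transcript_id "t1";\n'
    )
    with pytest.raises(ValidationError, match="divisible by 3"):
        read_gene_model(str(bad))


def test_haplotype_view_refuses_missing_or_unphased():
    samples = ["a", "b"]
    alleles = np.array([[[0, 1], [1, 1]]], dtype=np.int16)
    m = GenotypeMatrix(samples, alleles, phased=np.array([[False, True]]))
    with pytest.raises(ValidationError, match="unphased"):
        m.haplotypes()
    m2 = GenotypeMatrix(samples, np.array([[[-1, -1], [1, 1]]], dtype=np.int16))
    with pytest.raises(ValidationError, match="missing"):
        m2.haplotypes()
    m3 = GenotypeMatrix(samples, alleles)
    assert m3.haplotypes().tolist() == [[0], [1], [1], [1]]
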