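"""Genotype table IO: allele normalisation, round-trips, schema errors."""

import numpy as np
import pytest

from hlafinemap.genotype_io import (
    AlleleCall,
    GenotypeParseError,
    HaplotypeFreqTable,
    SchemaError,
    parse_allele,
    read_haplotype_freqs,
    read_hla_table,
    read_snp_table,
    write_haplotype_freqs,
    write_hla_table,
    write_snp_table,
)
from hlafinemap.synth_cohort import (
    reference_table,
    simulate_to_files,
    study_like_preset,
)

from conftest import SUITE_SEED


class TestAlleleParsing:
    @pytest.mark.parametrize(
        "text,locus,expected",
        [
            ("13:02", "DRB1", "DRB1*13:02"),
            ("DRB1*13:02", None, "DRB1*13:02"),
            ("HLA-DQB1*06:04", None, "DQB1*06:04"),
            ("02:01/07/18", "A", "A*02:01/07/18"),
            ("11", "A", "A*11"),  # single-field ambiguity group
        ],
    )
    def test_normalisation(self, text, locus, expected):
        assert str(parse_allele(text, locus)) == expected

    @pytest.mark.parametrize("bad", ["13:", "x:02", "13:02/", "1302"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(GenotypeParseError):
            parse_allele(bad, "DRB1")

    def test_locus_mismatch_rejected(self):
        with pytest.raises(GenotypeParseError):
            parse_allele("DQB1*06:04", "DRB1")

    def test_unknown_locus_rejected(self):
        with pytest.raises(SchemaError):
            AlleleCall("DRB9", "13:02")

    def test_ambiguity_group_is_atomic(self):
        group = parse_allele("02:01/07/18", "A")
        assert group != parse_allele("02:01", "A")


class TestHlaTable:
    def test_direct_parse(self, tmp_path):
        f = tmp_path / "hla.tsv"
        f.write_text(
            "id\tphenotype\tsex\tDRB1_1\tDRB1_2\tDQB1_1\tDQB1_2\n"
            "P1\tcase\tF\t13:02\t08:03\t06:04\t06:01\n"
            "C1\tcontrol\tM\t\t\t03:01\t03:01\n"
        )
        cohort = read_hla_table(f)
        assert (cohort.n_cases, cohort.n_controls) == (1, 1)
        p1 = cohort.subjects[0]
        assert p1.hla["DRB1"] == (
            AlleleCall("DRB1", "13:02"),
            AlleleCall("DRB1", "08:03"),
        )
        assert cohort.subjects[1].genotype("DRB1") is None  # MISSING locus
        assert cohort.subjects[1].genotype("DQB1") is not None

    def test_per_locus_missing_counts(self, tmp_path):
        rows = ["id\tphenotype\tDQA1_1\tDQA1_2"]
        rows += [f"P{i}\tcase\t01:02\t01:03" for i in range(5)]
        rows += [f"C{i}\tcontrol\t01:02\t01:03" for i in range(3)]
        rows += [f"C{i + 3}\tcontrol\t\t" for i in range(4)]
        f = tmp_path / "hla.tsv"
        f.write_text("\n".join(rows) + "\n")
        cohort = read_hla_table(f)
        typed = cohort.typed_mask("DQA1")
        assert int((typed & ~cohort.case_mask()).sum()) == 3
        assert int((typed & cohort.case_mask()).sum()) == 5

    def test_half_call_rejected(self, tmp_path):
        f = tmp_path / "hla.tsv"
        f.write_text(
            "id\tphenotype\tDRB1_1\tDRB1_2\nP1\tcase\t13:02\t\n"
        )
        with pytest.raises(GenotypeParseError, match="half-call"):
            read_hla_table(f)

    def test_unknown_locus_column_rejected(self, tmp_path):
        f = tmp_path / "hla.tsv"
        f.write_text("id\tphenotype\tDRB9_1\tDRB9_2\nP1\tcase\t13:02\t13:02\n")
        with pytest.raises(SchemaError):
            read_hla_table(f)

    def test_malformed_allele_names_line(self, tmp_path):
        f = tmp_path / "hla.tsv"
        f.write_text(
            "id\tphenotype\tDRB1_1\tDRB1_2\n"
            "P1\tcase\t13:02\t13:02\n"
            "P2\tcase\tbad!\t13:02\n"
        )
        with pytest.raises(GenotypeParseError, match="line 3"):
            read_hla_table(f)

    def test_roundtrip_idempotent(self, tmp_path):
        cohort, _ = simulate_to_files(
            study_like_preset(seed=SUITE_SEED, snps=0), tmp_path / "sim"
        )
        first = (tmp_path / "sim" / "hla.tsv").read_bytes()
        write_hla_table(cohort, tmp_path / "again.tsv")
        assert (tmp_path / "again.tsv").read_bytes() == first


class TestSnpTable:
    def _base_cohort(self, tmp_path):
        f = tmp_path / "hla.tsv"
        f.write_text(
            "id\tphenotype\tDRB1_1\tDRB1_2\n"
            + "\n".join(
                f"{sid}\t{ph}\t13:02\t13:02"
                for sid, ph in [
                    ("P1", "case"),
                    ("P2", "case"),
                    ("C1", "control"),
                    ("C2", "control"),
                ]
            )
            + "\n"
        )
        return read_hla_table(f)

    def test_toy_table(self, tmp_path):
        cohort = self._base_cohort(tmp_path)
        f = tmp_path / "snps.tsv"
        f.write_text(
            "rsid\tchrom\tpos\tref\talt\tP1\tP2\tC1\tC2\n"
            "rs1\t6\t100\tA\tG\t0\t1\t2\tNA\n"
            "rs2\t6\t200\tA\tG\t1\t1\t0\t0\n"
            "rs3\t6\t300\tA\tG\t2\t2\t2\t2\n"
        )
        cohort = read_snp_table(f, cohort)
        assert cohort.snp_matrix.shape == (4, 3)
        assert cohort.snp_matrix[3, 0] == -1  # NA
        assert [r.pos for r in cohort.snps] == [100, 200, 300]

    def test_subject_absent_gets_missing_vector(self, tmp_path, caplog):
        cohort = self._base_cohort(tmp_path)
        f = tmp_path / "snps.tsv"
        f.write_text(
            "rsid\tchrom\tpos\tref\talt\tP1\tP2\tC1\n"
            "rs1\t6\t100\tA\tG\t0\t1\t2\n"
        )
        with caplog.at_level("WARNING"):
            cohort = read_snp_table(f, cohort)
        assert (cohort.snp_matrix[3] == -1).all()
        assert "C2" in caplog.text

    def test_duplicate_rsid_rejected(self, tmp_path):
        cohort = self._base_cohort(tmp_path)
        f = tmp_path / "snps.tsv"
        f.write_text(
            "rsid\tchrom\tpos\tref\talt\tP1\tP2\tC1\tC2\n"
            "rs1\t6\t100\tA\tG\t0\t1\t2\t0\n"
            "rs1\t6\t200\tA\tG\t0\t1\t2\t0\n"
        )
        with pytest.raises(SchemaError, match="rsid"):
            read_snp_table(f, cohort)

    def test_nonincreasing_positions_rejected(self, tmp_path):
        cohort = self._base_cohort(tmp_path)
        f = tmp_path / "snps.tsv"
        f.write_text(
            "rsid\tchrom\tpos\tref\talt\tP1\tP2\tC1\tC2\n"
            "rs1\t6\t200\tA\tG\t0\t1\t2\t0\n"
            "rs2\t6\t100\tA\tG\t0\t1\t2\t0\n"
        )
        with pytest.raises(SchemaError, match="increasing"):
            read_snp_table(f, cohort)

    def test_bad_genotype_value_rejected(self, tmp_path):
        cohort = self._base_cohort(tmp_path)
        f = tmp_path / "snps.tsv"
        f.write_text(
            "rsid\tchrom\tpos\tref\talt\tP1\tP2\tC1\tC2\n"
            "rs1\t6\t100\tA\tG\t3\t1\t2\t0\n"
        )
        with pytest.raises(GenotypeParseError):
            read_snp_table(f, cohort)

    def test_snp_roundtrip(self, tmp_path):
        cohort = self._base_cohort(tmp_path)
        f = tmp_path / "snps.tsv"
        f.write_text(
            "rsid\tchrom\tpos\tref\talt\tP1\tP2\tC1\tC2\n"
            "rs1\t6\t100\tA\tG\t0\t1\t2\tNA\n"
        )
        cohort = read_snp_table(f, cohort)
        out = tmp_path / "snps2.tsv"
        write_snp_table(cohort, out)
        again = read_snp_table(out, cohort)
        assert (again.snp_matrix == cohort.snp_matrix).all()


class TestHaplotypeFreqs:
    def test_read_and_residual_mass(self, tmp_path):
        f = tmp_path / "ref.tsv"
        f.write_text("drb1\tdqb1\tfreq\n13:02\t06:04\t0.066\n08:03\t06:01\t0.080\n")
        table = read_haplotype_freqs(f)
        assert len(table.entries) == 2
        assert table.residual_mass == pytest.approx(0.854)
        assert table.freq("13:02", "06:04") == pytest.approx(0.066)
        assert table.freq("13:02", "06:01", 1e-6) == 1e-6

    def test_negative_freq_rejected(self, tmp_path):
        f = tmp_path / "ref.tsv"
        f.write_text("drb1\tdqb1\tfreq\n13:02\t06:04\t-0.1\n")
        with pytest.raises(ValueError, match="negative"):
            read_haplotype_freqs(f)

    def test_duplicate_pair_rejected(self, tmp_path):
        f = tmp_path / "ref.tsv"
        f.write_text(
            "drb1\tdqb1\tfreq\n13:02\t06:04\t0.05\n13:02\t06:04\t0.01\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_haplotype_freqs(f)

    def test_sum_above_one_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            HaplotypeFreqTable(
                entries=[
                    (AlleleCall("DRB1", "13:02"), AlleleCall("DQB1", "06:04"), 0.7),
                    (AlleleCall("DRB1", "08:03"), AlleleCall("DQB1", "06:01"), 0.4),
                ]
            )

    def test_roundtrip(self, tmp_path):
        table = reference_table(study_like_preset(snps=0))
        write_haplotype_freqs(table, tmp_path / "ref.tsv")
        again = read_haplotype_freqs(tmp_path / "ref.tsv")
        assert {
            (d.name, q.name): f for d, q, f in again.entries
        } == {(d.name, q.name): f for d, q, f in table.entries}


def test_vcf_adapter(tmp_path):
    """GT fields become ALT-copy counts; missing calls become -1."""
    cyvcf2 = pytest.importorskip("cyvcf2")
    hla = tmp_path / "hla.tsv"
    hla.write_text(
        "id\tphenotype\tDRB1_1\tDRB1_2\n"
        "P1\tcase\t13:02\t13:02\nC1\tcontrol\t13:02\t13:02\n"
    )
    cohort = read_hla_table(hla)
    vcf = tmp_path / "toy.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=6>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tC1\n"
        "6\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1\n"
        "6\t200\trs2\tA\tG\t.\tPASS\t.\tGT\t0/0\t./.\n"
    )
    from hlafinemap.genotype_io import read_snp_vcf

    cohort = read_snp_vcf(vcf, cohort)
    assert cohort.snp_matrix.tolist() == [[1, 0], [2, -1]]
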