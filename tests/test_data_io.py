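import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famphase.data import ModelParams, Pedigree, SiteTable, genetic_distance, is_chrx
from famphase.io import (
    apply_include_mask,
    load_allele_counts,
    load_pedigree,
    load_vcf,
    write_allele_counts,
    write_pedigree,
    write_vcf,
)


class TestSiteTable:
    def test_unsorted_input_is_sorted(self, toy_table):
        perm = [2, 0, 1]
        shuffled = SiteTable(
            toy_table.sites.iloc[perm], {s: toy_table.counts_for(s)[perm] for s in toy_table.samples}
        )
        assert shuffled.equals(toy_table)

    def test_duplicate_positions_rejected(self, toy_table):
        sites = toy_table.sites.copy()
        sites.loc[1, "pos"] = sites.loc[0, "pos"]
        with pytest.raises(ValueError, match="duplicate"):
            SiteTable(sites, toy_table.counts)

    def test_invalid_sites_rejected(self, toy_table):
        bad = toy_table.sites.copy()
        bad.loc[0, "alt"] = bad.loc[0, "ref"]
        with pytest.raises(ValueError, match="alleles"):
            SiteTable(bad, toy_table.counts)
        bad = toy_table.sites.copy()
        bad.loc[0, "alt_freq"] = 1.5
        with pytest.raises(ValueError, match="alt_freq"):
            SiteTable(bad, toy_table.counts)

    def test_chrom_slices_cover_table(self, child_family):
        table = child_family.table
        slices = table.chrom_slices()
        assert sum(sl.stop - sl.start for sl in slices.values()) == table.n_sites

    def test_chrx_recognised_case_insensitively(self):
        assert is_chrx("chrX") and is_chrx("CHRx") and is_chrx("X")
        assert not is_chrx("chr10")


class TestGeneticDistance:
    @pytest.mark.parametrize(
        "pos_a,pos_b,cm_per_mb,expected",
        [
            (5_000, 5_000, 1.0, 0.0),
            (1, 1_000_001, 1.0, 0.01),
            (1_000_000, 3_500_000, 2.0, 0.05),
        ],
    )
    def test_values(self, pos_a, pos_b, cm_per_mb, expected):
        params = ModelParams(cm_per_mb=cm_per_mb)
        assert genetic_distance(pos_a, pos_b, params) == pytest.approx(expected)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            genetic_distance(10, 5, ModelParams())

    @given(
        a=st.integers(1, 10**8), span1=st.integers(0, 10**7), span2=st.integers(0, 10**7)
    )
    @settings(max_examples=50, deadline=None)
    def test_additive_over_adjacent_intervals(self, a, span1, span2):
        p = ModelParams()
        total = genetic_distance(a, a + span1 + span2, p)
        assert total == pytest.approx(
            genetic_distance(a, a + span1, p) + genetic_distance(a + span1, a + span1 + span2, p)
        )


class TestAlleleCountTsv:
    def test_round_trip(self, toy_table, toy_pedigree, tmp_path):
        path = tmp_path / "counts.tsv"
        write_allele_counts(toy_table, path)
        again = load_allele_counts(path, toy_pedigree)
        assert again.equals(toy_table)

    def test_toy_parse_counts(self, toy_table, toy_pedigree, tmp_path):
        path = tmp_path / "counts.tsv"
        write_allele_counts(toy_table, path)
        table = load_allele_counts(path, toy_pedigree)
        assert table.n_sites == 3
        assert tuple(table.counts_for("mom")[0]) == (3, 2)

    def test_empty_file_with_header(self, toy_pedigree, tmp_path):
        path = tmp_path / "empty.tsv"
        header = ["chrom", "pos", "ref", "alt", "alt_freq"] + [
            f"{s}_{x}" for s in ("mom", "dad", "kid", "e1") for x in ("ref", "alt")
        ]
        path.write_text("\t".join(header) + "\n")
        assert load_allele_counts(path, toy_pedigree).n_sites == 0

    def test_missing_sample_column_is_config_error(self, toy_table, tmp_path):
        path = tmp_path / "counts.tsv"
        write_allele_counts(toy_table, path)
        ped = Pedigree(
            mother_id="mom", father_id="dad", embryos=["e9"],
            reference_mode="child", reference_child_id="kid",
        )
        with pytest.raises(ValueError, match="e9"):
            load_allele_counts(path, ped)

    def test_malformed_row_reported_with_line_number(self, toy_table, toy_pedigree, tmp_path):
        path = tmp_path / "counts.tsv"
        write_allele_counts(toy_table, path)
        lines = path.read_text().splitlines()
        fields = lines[2].split("\t")
        fields[5] = "-1"  # negative read count in the second data row
        lines[2] = "\t".join(fields)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match=r"\[3\]"):
            load_allele_counts(path, toy_pedigree)


class TestVcf:
    def test_vcf_and_tsv_agree(self, child_family, tmp_path):
        table, pedigree, _ = child_family
        vcf_path = tmp_path / "family.vcf"
        tsv_path = tmp_path / "family.tsv"
        write_vcf(table, vcf_path)
        write_allele_counts(table, tsv_path)
        from_vcf = load_vcf(vcf_path, pedigree)
        from_tsv = load_allele_counts(tsv_path, pedigree)
        assert from_vcf.equals(from_tsv)
        assert from_vcf.sites["alt_freq"].to_numpy() == pytest.approx(
            table.sites["alt_freq"].to_numpy(), abs=1e-6
        )

    def test_indel_records_skipped(self, toy_pedigree, tmp_path):
        path = tmp_path / "mix.vcf"
        samples = "\t".join(["mom", "dad", "kid", "e1"])
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="AD">\n'
            f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n"
            "chr1\t100\t.\tA\tAT\t.\tPASS\t.\tAD\t4,1\t4,1\t4,1\t4,1\n"
            "chr1\t200\t.\tG\tC\t.\tPASS\t.\tAD\t4,1\t2,0\t1,1\t0,0\n"
        )
        table = load_vcf(path, toy_pedigree)
        assert table.n_sites == 1
        assert tuple(table.counts_for("mom")[0]) == (4, 1)
        assert table.sites["alt_freq"].iloc[0] == 0.5  # default prior without AF

    def test_vcf_without_ad_rejected(self, toy_pedigree, tmp_path):
        path = tmp_path / "noad.vcf"
        samples = "\t".join(["mom", "dad", "kid", "e1"])
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n"
            "chr1\t200\t.\tG\tC\t.\tPASS\t.\tGT\t./.\t./.\t./.\t./.\n"
        )
        with pytest.raises(ValueError, match="AD"):
            load_vcf(path, toy_pedigree)


class TestPedigree:
    def test_yaml_round_trip(self, tmp_path):
        ped = Pedigree(
            mother_id="m", father_id="f", embryos=["e1", "e2"],
            reference_mode="grandparent", grandparents={"maternal": ["g1", "g2"]},
            sex={"e1": "male"},
        )
        path = tmp_path / "ped.yaml"
        write_pedigree(ped, path)
        assert load_pedigree(path) == ped

    def test_child_mode_requires_reference_child(self):
        with pytest.raises(ValueError):
            Pedigree(mother_id="m", father_id="f", embryos=["e"], reference_mode="child")

    def test_grandparent_mode_requires_a_grandparent(self):
        with pytest.raises(ValueError):
            Pedigree(mother_id="m", father_id="f", embryos=["e"], reference_mode="grandparent")

    def test_phaseable_sides(self):
        ped = Pedigree(
            mother_id="m", father_id="f", embryos=["e"],
            reference_mode="grandparent", grandparents={"maternal": ["g1"]},
        )
        assert ped.phaseable_sides() == ["maternal"]


class TestModelParams:
    @pytest.mark.parametrize(
        "kwargs", [{"eps": 0.7}, {"ado": 1.2}, {"cm_per_mb": 0.0}, {"conf_hi": 0.4}]
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_conf_lo_complements_conf_hi(self):
        assert ModelParams(conf_hi=0.95).conf_lo == pytest.approx(0.05)


def test_include_mask_restricts_sites(toy_table, tmp_path):
    bed = tmp_path / "mask.bed"
    bed.write_text("chr1\t0\t3000000\n")
    masked = apply_include_mask(toy_table, bed)
    assert masked.n_sites == 2
    assert masked.sites["pos"].tolist() == [100, 2_000_000]
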