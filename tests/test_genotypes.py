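"""Genotype model, encodings, table parsing and VCF round-trips."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import snpfingerprint as sf
from snpfingerprint.genotypes import FormatError, genotype_to_codes

BASES = "ACGT"
ALL_GENOTYPES = [
    sf.Genotype.from_alleles(a, b)
    for a, b in itertools.combinations_with_replacement(BASES, 2)
]


class TestGenotype:
    def test_unordered_equality(self):
        assert sf.Genotype.from_alleles("A", "G") == sf.Genotype.from_alleles("G", "A")

    def test_missing_has_no_alleles(self):
        g = sf.Genotype.missing()
        assert g.is_missing and g.alleles is None

    @given(st.sampled_from(BASES), st.sampled_from(BASES))
    @settings(max_examples=20)
    def test_parse_order_symmetry(self, a, b):
        assert (
            sf.parse_genotype_cell(f"{a}/{b}")[0]
            == sf.parse_genotype_cell(f"{b}/{a}")[0]
        )


class TestIupac:
    @pytest.mark.parametrize(
        "pair,letter",
        [(("A", "G"), "R"), (("C", "T"), "Y"), (("A", "C"), "M"),
         (("G", "T"), "K"), (("C", "G"), "S"), (("A", "T"), "W"),
         (("C", "C"), "C"), (("T", "T"), "T")],
    )
    def test_encoding_table(self, pair, letter):
        assert sf.iupac_encode(sf.Genotype.from_alleles(*pair)) == letter

    def test_missing_symbol(self):
        assert sf.iupac_encode(sf.Genotype.missing()) == "N"
        assert sf.iupac_encode(sf.Genotype.missing(), missing_symbol="-") == "-"

    def test_injective_on_all_genotypes(self):
        letters = {sf.iupac_encode(g) for g in ALL_GENOTYPES + [sf.Genotype.missing()]}
        assert len(letters) == 11

    def test_decode_inverts_encode(self):
        for g in ALL_GENOTYPES + [sf.Genotype.missing()]:
            assert sf.iupac_decode(sf.iupac_encode(g)) == g


class TestCategoryEncode:
    @pytest.mark.parametrize(
        "cell,cat",
        [("A/A", "HOM_A"), ("C/C", "HOM_C"), ("T/T", "HOM_T"), ("G/G", "HOM_G"),
         ("A/G", "HET"), ("Y/C", "HET"), ("./.", "MISSING")],
    )
    def test_categories(self, cell, cat):
        g, _ = sf.parse_genotype_cell(cell)
        assert sf.category_encode(g) == sf.GenotypeCategory[cat]


class TestCellParsing:
    def test_ambiguity_call_with_reference(self):
        g, ref = sf.parse_genotype_cell("R/A")
        assert g == sf.Genotype.from_alleles("A", "G") and ref == "A"

    def test_transposed_ambiguity_cell(self):
        # order-transposed dialect: the ambiguity letter is still the call
        g, ref = sf.parse_genotype_cell("G/R")
        assert g == sf.Genotype.from_alleles("A", "G") and ref == "G"

    def test_plain_het(self):
        g, ref = sf.parse_genotype_cell("T/G")
        assert g == sf.Genotype.from_alleles("G", "T") and ref is None

    def test_unknown_letter_raises(self):
        with pytest.raises(FormatError):
            sf.parse_genotype_cell("Z/A")

    def test_unknown_letter_error_names_location(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("Marker\tsampleX\nMarkerBad\tZ/Q\n")
        with pytest.raises(FormatError, match="MarkerBad.*sampleX"):
            sf.read_genotype_table(p)


class TestGenotypeTables:
    def test_table_shapes(self, table5, table6, table7):
        assert table5.shape == (4, 15)
        assert table6.shape == (10, 15)
        assert table7.shape == (3, 15)

    def test_marker_ids_normalised_across_tables(self, table5, table6):
        assert table5.marker_ids == table6.marker_ids

    def test_reference_base_recorded_from_ambiguity_cells(self, table5):
        m3 = table5.markers[table5.marker_index("Marker3")]
        assert m3.ref == "A"  # from the "R/A" cell

    def test_roundtrip_through_tsv(self, table6, tmp_path):
        out = tmp_path / "t6.tsv"
        sf.write_genotype_table(table6, out)
        back = sf.read_genotype_table(out)
        assert back.marker_ids == table6.marker_ids
        assert back.sample_ids == table6.sample_ids
        assert np.array_equal(back.calls, table6.calls)


VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1>
##INFO=<ID=QD,Number=1,Type=Float,Description="x">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
"""


def write_vcf_text(path, records):
    path.write_text(VCF_HEADER + "".join(r + "\n" for r in records))


class TestReadVcf:
    def test_biallelic_snps(self, tmp_path):
        p = tmp_path / "a.vcf"
        write_vcf_text(p, [
            "chr1\t100\tm1\tA\tG\t50\t.\tQD=20\tGT\t0/0\t0/1",
            "chr1\t200\tm2\tC\tT\t50\t.\t.\tGT\t1/1\t./.",
            "chr1\t300\tm3\tG\tA\t50\t.\t.\tGT\t0/1\t1/0",
        ])
        panel = sf.read_vcf(p)
        assert panel.shape == (2, 3)
        assert panel.genotype("s2", "m1") == sf.Genotype.from_alleles("A", "G")
        assert panel.genotype("s2", "m2").is_missing
        # phase ignored: 0/1 and 1/0 parse identically
        assert panel.genotype("s1", "m3") == panel.genotype("s2", "m3")
        assert panel.markers[0].annotations["QD"] == pytest.approx(20.0)

    def test_indel_skipped(self, tmp_path, caplog):
        p = tmp_path / "b.vcf"
        write_vcf_text(p, [
            "chr1\t100\tm1\tA\tAT\t50\t.\t.\tGT\t0/0\t0/1",
            "chr1\t200\tm2\tC\tT\t50\t.\t.\tGT\t1/1\t0/0",
        ])
        import logging

        with caplog.at_level(logging.INFO, logger="snpfingerprint"):
            panel = sf.read_vcf(p)
        assert panel.n_markers == 1 and panel.marker_ids == ["m2"]
        assert "skipped 1" in caplog.text

    def test_multiallelic_drop_and_split(self, tmp_path):
        p = tmp_path / "c.vcf"
        write_vcf_text(p, [
            "chr1\t100\tm1\tA\tC,T\t50\t.\t.\tGT\t0/1\t0/2",
            "chr1\t200\tm2\tC\tT\t50\t.\t.\tGT\t1/1\t0/0",
        ])
        dropped = sf.read_vcf(p)
        assert dropped.marker_ids == ["m2"]
        split = sf.read_vcf(p, multiallelic="split")
        assert split.n_markers == 3
        # sample 2 carries the T alt: missing at the A->C split site
        assert split.genotype("s2", "m1_C").is_missing
        assert split.genotype("s1", "m1_C") == sf.Genotype.from_alleles("A", "C")

    def test_sample_subset(self, tmp_path):
        p = tmp_path / "d.vcf"
        write_vcf_text(p, ["chr1\t100\tm1\tA\tG\t50\t.\t.\tGT\t0/0\t0/1"])
        panel = sf.read_vcf(p, sample_subset=["s2"])
        assert panel.sample_ids == ["s2"]
        with pytest.raises(KeyError):
            sf.read_vcf(p, sample_subset=["nope"])


class TestWriteVcf:
    def test_roundtrip_exact(self, tmp_path):
        panel, _ = sf.simulate_panel(sf.SimConfig(seed=2, n_markers=40))
        out = tmp_path / "rt.vcf"
        sf.write_vcf(panel, out)
        back = sf.read_vcf(out)
        reordered = panel.subset_markers(back.marker_ids)
        assert np.array_equal(reordered.calls, back.calls)
        for a, b in zip(reordered.markers, back.markers):
            assert (a.chrom, a.pos, a.ref, a.alt) == (b.chrom, b.pos, b.ref, b.alt)

    def test_empty_panel_rejected(self):
        panel = sf.GenotypePanel(
            [], [sf.SampleMeta(sample_id="s1")], np.empty((1, 0, 2), dtype=np.int8)
        )
        with pytest.raises(ValueError):
            sf.write_vcf(panel, "/tmp/never.vcf")

    def test_missing_calls_written_as_dots(self, tmp_path):
        panel, _ = sf.simulate_panel(
            sf.SimConfig(seed=3, n_markers=10, missing_rate=0.5)
        )
        out = tmp_path / "m.vcf"
        sf.write_vcf(panel, out)
        assert "./." in out.read_text()
        back = sf.read_vcf(out)
        assert back.missing_mask().sum() == panel.missing_mask().sum()


class TestPanelInvariants:
    def test_duplicate_marker_ids_rejected(self):
        markers = [sf.MarkerSite(id="m", chrom="c", pos=1),
                   sf.MarkerSite(id="m", chrom="c", pos=2)]
        samples = [sf.SampleMeta(sample_id="s")]
        with pytest.raises(ValueError):
            sf.GenotypePanel(markers, samples, np.zeros((1, 2, 2), dtype=np.int8))

    def test_parents_iff_crossbreed(self):
        with pytest.raises(ValueError):
            sf.SampleMeta(sample_id="x", variety_type="crossbreed")
        with pytest.raises(ValueError):
            sf.SampleMeta(sample_id="x", variety_type="cultivar", parents=("a", "b"))

    def test_ref_equal_alt_rejected(self):
        with pytest.raises(ValueError):
            sf.MarkerSite(id="m", chrom="c", pos=1, ref="A", alt="A")
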