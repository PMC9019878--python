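"""Alteration parsing, the common-variant filter, risk tiers and weights."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thyrisk.alterations import (
    Alteration,
    AlterationKind,
    DEFAULT_WEIGHT_TABLE,
    RiskTier,
    WeightTable,
    assign_tier,
    filter_common_variants,
    format_alteration,
    parse_alteration,
    parse_alteration_list,
    read_weight_table,
    write_weight_table,
)
from thyrisk.errors import AlterationParseError, DomainError, LoadError


class TestParsing:
    @pytest.mark.parametrize(
        "text, gene, kind, detail",
        [
            ("BRAF:V600E", "BRAF", AlterationKind.SNV, "V600E"),
            ("BRAF:K601E", "BRAF", AlterationKind.SNV, "K601E"),
            ("TERT", "TERT", AlterationKind.SNV, ""),
            ("NRAS", "NRAS", AlterationKind.SNV, ""),
            ("ETV6-NTRK3:fusion", "ETV6-NTRK3", AlterationKind.FUSION, "ETV6-NTRK3"),
            ("CCDC6-RET:fusion", "CCDC6-RET", AlterationKind.FUSION, "CCDC6-RET"),
            ("STRN-ALK", "STRN-ALK", AlterationKind.FUSION, "STRN-ALK"),
            ("MALIG_EXPR:expression", "MALIG_EXPR", AlterationKind.EXPRESSION, ""),
            ("KIT:D816V:snv", "KIT", AlterationKind.SNV, "D816V"),
            ("TP53:c.215del:indel", "TP53", AlterationKind.INDEL, "c.215del"),
        ],
    )
    def test_grammar(self, text, gene, kind, detail):
        a = parse_alteration(text)
        assert (a.gene, a.kind, a.detail) == (gene, kind, detail)

    @pytest.mark.parametrize("bad", ["", "  ", ":", "BRAF:", "A:B:C:D", "BR AF", "GENE::snv"])
    def test_malformed_raises_naming_input(self, bad):
        with pytest.raises(AlterationParseError):
            parse_alteration(bad)

    def test_error_message_names_offending_token(self):
        with pytest.raises(AlterationParseError, match="BR AF"):
            parse_alteration("BR AF")

    @pytest.mark.parametrize(
        "text",
        ["BRAF:V600E", "TERT", "NRAS", "HRAS", "KRAS", "BRAF:K601E",
         "ETV6-NTRK3:fusion", "CCDC6-RET:fusion", "NCOA4-RET:fusion", "STRN-ALK:fusion"],
    )
    def test_round_trip(self, text):
        """Every alteration string in the reference listing survives parse→format→parse."""
        a = parse_alteration(text)
        assert parse_alteration(format_alteration(a)) == a

    def test_reference_cohort_round_trips(self, resected):
        for cell in resected["alterations"]:
            alts = parse_alteration_list(cell)
            again = parse_alteration_list(";".join(map(format_alteration, alts)))
            assert again == alts

    def test_fusion_requires_two_partners(self):
        with pytest.raises(DomainError):
            Alteration(gene="RET", kind=AlterationKind.FUSION, detail="RET")

    def test_population_frequency_domain(self):
        with pytest.raises(DomainError):
            Alteration(gene="BRAF", population_frequency=1.5)


class TestCommonVariantFilter:
    def test_threshold_is_strict(self):
        kept = filter_common_variants(
            [Alteration("A", population_frequency=0.005),
             Alteration("B", population_frequency=0.0001)],
            threshold=0.001,
        )
        assert [a.gene for a in kept] == ["B"]

    def test_exact_threshold_retained(self):
        # removal applies strictly above the cutoff
        a = Alteration("A", population_frequency=0.001)
        assert filter_common_variants([a]) == [a]

    def test_unknown_frequency_retained(self):
        a = Alteration("A")
        assert filter_common_variants([a]) == [a]

    def test_empty(self):
        assert filter_common_variants([]) == []

    @settings(derandomize=True, max_examples=50)
    @given(
        freqs=st.lists(
            st.one_of(st.none(), st.floats(min_value=0, max_value=1)), max_size=100
        ),
        threshold=st.floats(min_value=0, max_value=1),
    )
    def test_matches_brute_force_and_is_idempotent(self, freqs, threshold):
        alts = [Alteration(f"G{i}", population_frequency=f) for i, f in enumerate(freqs)]
        expected = [a for a in alts if a.population_frequency is None
                    or a.population_frequency <= threshold]
        got = filter_common_variants(alts, threshold)
        assert got == expected
        assert filter_common_variants(got, threshold) == got
        assert len(got) <= len(alts)


class TestTiers:
    @pytest.mark.parametrize(
        "text, tier",
        [
            ("BRAF:V600E", RiskTier.HIGH_RISK),
            ("TERT", RiskTier.HIGH_RISK),
            ("ETV6-NTRK3:fusion", RiskTier.HIGH_RISK),
            ("STRN-ALK:fusion", RiskTier.HIGH_RISK),
            ("NRAS", RiskTier.RAS_LIKE),
            ("HRAS", RiskTier.RAS_LIKE),
            ("KRAS", RiskTier.RAS_LIKE),
            ("BRAF:K601E", RiskTier.RAS_LIKE),
            ("EIF1AX", RiskTier.OTHER),
            ("BRAF:G469A", RiskTier.OTHER),  # non-V600E/K601E BRAF is unmapped
        ],
    )
    def test_default_partition(self, text, tier):
        assert assign_tier(parse_alteration(text)) is tier

    def test_purity(self):
        a = parse_alteration("NRAS:Q61R")
        assert all(assign_tier(a) is assign_tier(a) for _ in range(3))


class TestWeightTable:
    def test_lookup_precedence(self):
        wt = WeightTable(
            by_variant={("BRAF", "V600E"): 95.0},
            by_gene_kind={("BRAF", AlterationKind.INDEL): 30.0},
            by_gene={"BRAF": 25.0},
            by_kind={AlterationKind.FUSION: 90.0},
            default_weight=10.0,
        )
        assert wt.lookup(parse_alteration("BRAF:V600E")) == 95.0
        assert wt.lookup(parse_alteration("BRAF:x:indel")) == 30.0
        assert wt.lookup(parse_alteration("BRAF:K601E")) == 25.0
        assert wt.lookup(parse_alteration("ETV6-NTRK3:fusion")) == 90.0
        assert wt.lookup(parse_alteration("EIF1AX")) == 10.0

    def test_same_gene_different_details_differ(self):
        wt = DEFAULT_WEIGHT_TABLE
        v600e = wt.lookup(parse_alteration("BRAF:V600E"))
        k601e = wt.lookup(parse_alteration("BRAF:K601E"))
        assert v600e != k601e

    def test_weights_outside_range_rejected(self):
        with pytest.raises(DomainError):
            WeightTable(default_weight=120.0)

    def test_tsv_round_trip(self, tmp_path):
        path = tmp_path / "weights.tsv"
        write_weight_table(DEFAULT_WEIGHT_TABLE, path)
        back = read_weight_table(path)
        probes = ["BRAF:V600E", "BRAF:K601E", "TERT", "NRAS", "CCDC6-RET:fusion", "EIF1AX"]
        for p in probes:
            a = parse_alteration(p)
            assert back.lookup(a) == DEFAULT_WEIGHT_TABLE.lookup(a)

    def test_tsv_comments_and_errors(self, tmp_path):
        good = tmp_path / "w.tsv"
        good.write_text("# comment\ngene\tkind\tdetail\tweight\nBRAF\t\tV600E\t95\n")
        assert read_weight_table(good).lookup(parse_alteration("BRAF:V600E")) == 95.0
        bad = tmp_path / "bad.tsv"
        bad.write_text("gene\tkind\tdetail\tweight\nBRAF\t\tV600E\thigh\n")
        with pytest.raises(LoadError, match="row 2"):
            read_weight_table(bad)


class TestVcfIngestion:
    def test_snv_records_map_to_alterations(self, tmp_path):
        cyvcf2 = pytest.importorskip("cyvcf2")
        del cyvcf2
        from thyrisk.alterations import read_vcf_alterations

        vcf = tmp_path / "variants.vcf"
        ann = "##INFO=<ID=ANN,Number=.,Type=String,Description=\"Functional annotations: 'Allele|Annotation|Impact|Gene_Name|Gene_ID|Feature_Type|Feature_ID|BioType|Rank|HGVS.c|HGVS.p'\">\n"
        vcf.write_text(
            "##fileformat=VCFv4.2\n" + ann
            + "##INFO=<ID=AF,Number=A,Type=Float,Description=\"AF\">\n"
            + "##contig=<ID=7>\n##contig=<ID=1>\n"
            + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            + "7\t140453136\t.\tA\tT\t.\tPASS\tANN=T|missense_variant|MODERATE|BRAF|g|t|f|pc|15|c.1799T>A|p.V600E;AF=0.0\n"
            + "1\t115256529\t.\tT\tC\t.\tPASS\tANN=C|missense_variant|MODERATE|NRAS|g|t|f|pc|3|c.182A>G|p.Q61R;AF=0.002\n"
        )
        alts = read_vcf_alterations(vcf)
        assert [(a.gene, a.detail, a.kind) for a in alts] == [
            ("BRAF", "V600E", AlterationKind.SNV),
            ("NRAS", "Q61R", AlterationKind.SNV),
        ]
        # the common-variant rule then drops the frequent NRAS call
        assert [a.gene for a in filter_common_variants(alts)] == ["BRAF"]
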