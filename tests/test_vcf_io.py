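import pytest

from conftest import callset_from_positions, make_variant, write_vcf
from varcons.consensus import combine_at_threshold
from varcons.errors import ConfigError, FormatError
from varcons.variant_model import VariantKey
from varcons.vcf_io import (
    PRESET_DIALECTS,
    CallerDialect,
    CallSet,
    Strategy,
    extract_support,
    get_dialect,
    load_dialect_config,
    read_caller_vcf,
    read_consensus_vcf,
    write_consensus_vcf,
)

AD_HEADERS = (
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="d">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">',
    '##FORMAT=<ID=AF,Number=A,Type=Float,Description="f">',
)

GENERIC = CallerDialect("generic", (Strategy("ad_pair", "AD"), Strategy("af_tag", "AF")))


class TestExtractSupport:
    def test_af_tag_direct(self):
        plan = (Strategy("af_tag", "AF"),)
        assert extract_support({"AF": 0.12}, "A", "G", 0, plan) == (None, None, 0.12)

    def test_ad_pair_ratio(self):
        plan = (Strategy("ad_pair", "AD"),)
        ad, dp, vaf = extract_support({"AD": (18, 2), "DP": 20}, "A", "G", 0, plan)
        assert (ad, dp) == (2, 20)
        assert vaf == pytest.approx(0.1)

    def test_percent_string(self):
        plan = (Strategy("freq_percent", "FREQ"),)
        assert extract_support({"FREQ": "10%"}, "A", "G", 0, plan)[2] == pytest.approx(0.1)

    def test_alt_dp(self):
        plan = (Strategy("alt_dp", "VD", "DP"),)
        ad, dp, vaf = extract_support({"VD": 5, "DP": 50}, "A", "G", 0, plan)
        assert (ad, dp) == (5, 50)
        assert vaf == pytest.approx(0.1)

    def test_dp4(self):
        plan = (Strategy("dp4", "DP4"),)
        ad, dp, vaf = extract_support({"DP4": (10, 8, 3, 4)}, "A", "G", 0, plan)
        assert (ad, dp) == (7, 25)
        assert vaf == pytest.approx(7 / 25)

    def test_strelka_snv_tiers(self):
        plan = (Strategy("tier_counts"),)
        fields = {"AU": (30, 32), "CU": (0, 0), "GU": (10, 11), "TU": (0, 0)}
        ad, dp, vaf = extract_support(fields, "A", "G", 0, plan)
        assert (ad, dp) == (10, 40)
        assert vaf == pytest.approx(0.25)

    def test_strelka_indel_tiers(self):
        plan = (Strategy("tier_indel"),)
        ad, dp, vaf = extract_support({"TAR": (36, 37), "TIR": (12, 12)}, "AT", "A", 0, plan)
        assert (ad, dp) == (12, 48)
        assert vaf == pytest.approx(0.25)

    def test_unknown_yields_none_not_guess(self):
        plan = (Strategy("ad_pair", "AD"), Strategy("af_tag", "AF"))
        assert extract_support({}, "A", "G", 0, plan) == (None, None, None)

    def test_first_applicable_strategy_wins(self):
        plan = (Strategy("af_tag", "AF"), Strategy("ad_pair", "AD"))
        ad, dp, vaf = extract_support({"AF": 0.4, "AD": (9, 1)}, "A", "G", 0, plan)
        assert vaf == 0.4  # AF wins over the AD-derived 0.1
        assert (ad, dp) == (1, 10)  # depths still filled from AD

    def test_multiallelic_alt_index(self):
        plan = (Strategy("ad_pair", "AD"),)
        ad, dp, vaf = extract_support({"AD": (10, 2, 8)}, "A", "G", 1, plan)
        assert ad == 8
        assert dp == 20
        assert vaf == pytest.approx(0.4)

    def test_zero_denominator(self):
        plan = (Strategy("ad_pair", "AD"),)
        assert extract_support({"AD": (0, 0)}, "A", "G", 0, plan) == (0, 0, 0.0)

    def test_unknown_strategy_kind(self):
        with pytest.raises(ConfigError):
            extract_support({}, "A", "G", 0, (Strategy("bogus"),))


class TestReadCallerVcf:
    def test_symbolic_alt_skipped(self, tmp_path):
        path = write_vcf(
            tmp_path / "x.vcf",
            [
                "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:AD\t0/1:20,5",
                "chr1\t200\t.\tA\t<DEL>\t.\tPASS\t.\tGT:AD\t0/1:20,5",
                "chr1\t300\t.\tC\tT\t.\tPASS\t.\tGT:AD\t0/1:20,5",
            ],
            format_headers=AD_HEADERS,
            extra_headers=['##ALT=<ID=DEL,Description="del">'],
        )
        cs = read_caller_vcf(path, GENERIC)
        assert len(cs) == 2
        assert cs.records_read == 3
        assert cs.records_skipped == 1
        assert cs.records_retained + cs.records_skipped == cs.records_read

    def test_duplicate_representations_collapse(self, tmp_path):
        # same deletion written untrimmed and trimmed
        path = write_vcf(
            tmp_path / "x.vcf",
            [
                "chr1\t100\t.\tATG\tAG\t.\tPASS\t.\tGT:AD\t0/1:20,5",
                "chr1\t100\t.\tAT\tA\t.\tPASS\t.\tGT:AD\t0/1:20,9",
            ],
            format_headers=AD_HEADERS,
        )
        cs = read_caller_vcf(path, GENERIC)
        assert len(cs) == 1
        key = VariantKey("chr1", 100, "AT", "A")
        assert cs.variants[key].alt_depth == 9  # higher alt_depth wins

    def test_empty_vcf(self, tmp_path):
        path = write_vcf(tmp_path / "x.vcf", [], format_headers=AD_HEADERS)
        cs = read_caller_vcf(path, GENERIC)
        assert len(cs) == 0
        assert cs.records_read == cs.records_retained == cs.records_skipped == 0

    def test_multiallelic_decomposition(self, tmp_path):
        path = write_vcf(
            tmp_path / "x.vcf",
            ["chr1\t7\t.\tA\tG,T\t.\tPASS\t.\tGT:AD\t0/1:10,3,6"],
            format_headers=AD_HEADERS,
        )
        cs = read_caller_vcf(path, GENERIC)
        assert cs.keys == {VariantKey("chr1", 7, "A", "G"), VariantKey("chr1", 7, "A", "T")}
        assert cs.variants[VariantKey("chr1", 7, "A", "T")].alt_depth == 6

    def test_garbled_header_raises_format_error(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text("this is not a vcf\nat all\n")
        with pytest.raises(FormatError):
            read_caller_vcf(str(path), GENERIC)

    def test_tumor_sample_resolution(self, tmp_path):
        records = ["chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:AD\t0/1:5,5\t0/0:20,0"]
        path = write_vcf(tmp_path / "x.vcf", records, samples=("NORMAL", "TUMOR"),
                         format_headers=AD_HEADERS)
        cs = read_caller_vcf(path, GENERIC)  # finds the literal TUMOR sample
        assert cs.variants[VariantKey("chr1", 100, "A", "G")].alt_depth == 0

        named = CallerDialect("generic", GENERIC.plan, tumor_sample="NORMAL")
        cs2 = read_caller_vcf(path, named)
        assert cs2.variants[VariantKey("chr1", 100, "A", "G")].alt_depth == 5

        path2 = write_vcf(tmp_path / "y.vcf", records, samples=("S1", "S2"),
                          format_headers=AD_HEADERS)
        with pytest.raises(ConfigError):
            read_caller_vcf(path2, GENERIC)
        with pytest.raises(ConfigError):
            read_caller_vcf(path2, CallerDialect("g", GENERIC.plan, tumor_sample="NOPE"))

    def test_contig_alias_map(self, tmp_path):
        path = write_vcf(
            tmp_path / "x.vcf",
            ["chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:AD\t0/1:20,5"],
            format_headers=AD_HEADERS,
        )
        cs = read_caller_vcf(path, GENERIC, contig_aliases={"chr1": "1"})
        assert cs.keys == {VariantKey("1", 100, "A", "G")}

    def test_filter_status_preserved(self, tmp_path):
        path = write_vcf(
            tmp_path / "x.vcf",
            ["chr1\t100\t.\tA\tG\t.\tgermline_risk\t.\tGT:AD\t0/1:20,5"],
            format_headers=AD_HEADERS,
            extra_headers=['##FILTER=<ID=germline_risk,Description="g">'],
        )
        cs = read_caller_vcf(path, GENERIC)
        assert next(iter(cs.variants.values())).filter_status == "germline_risk"


class TestDialects:
    def test_presets_cover_common_callers(self):
        for name in ("muse", "mutect", "mutect2", "pindel", "somaticsniper",
                     "vardict", "varscan", "strelka"):
            assert name in PRESET_DIALECTS
            assert PRESET_DIALECTS[name].plan

    def test_get_dialect_unknown_gets_generic_plan(self):
        d = get_dialect("mystery")
        assert d.caller_id == "mystery"
        assert d.plan

    def test_empty_plan_rejected(self):
        with pytest.raises(ConfigError):
            CallerDialect("x", ())

    def test_load_dialect_config(self, tmp_path):
        ini = tmp_path / "dialects.ini"
        ini.write_text(
            "[mycaller]\nplan = alt_dp:VD/DP, af_tag:AF\ntumor_sample = TUMOR\n"
        )
        dialects = load_dialect_config(str(ini))
        plan = dialects["mycaller"].plan
        assert plan[0] == Strategy("alt_dp", "VD", "DP")
        assert plan[1] == Strategy("af_tag", "AF", "DP")
        assert dialects["mycaller"].tumor_sample == "TUMOR"


class TestConsensusVcfRoundTrip:
    def test_write_then_read(self, tmp_path):
        callsets = [
            callset_from_positions("A", [10, 20], vaf=0.3),
            callset_from_positions("B", [10, 30], vaf=0.25),
            callset_from_positions("C", [10, 20], vaf=0.35),
        ]
        table = combine_at_threshold(callsets, 2)
        out = tmp_path / "consensus.vcf"
        write_consensus_vcf(table, callsets, str(out))
        back = read_consensus_vcf(str(out))
        assert set(back) == table.accepted
        for key, (support, callers) in back.items():
            assert support == len(table.support[key])
            assert set(callers) == set(table.support[key])

    def test_empty_acceptance_header_only(self, tmp_path):
        callsets = [callset_from_positions("A", [10]), callset_from_positions("B", [20])]
        table = combine_at_threshold(callsets, 2)
        out = tmp_path / "c.vcf"
        write_consensus_vcf(table, callsets, str(out))
        assert read_consensus_vcf(str(out)) == {}
        text = out.read_text()
        assert text.startswith("##fileformat=VCFv4.2")

    def test_sorted_output(self, tmp_path):
        cs = CallSet(caller_id="A")
        for chrom, pos in [("chr10", 5), ("chr2", 7), ("chr2", 3), ("chr1", 9)]:
            cs.add(make_variant(chrom=chrom, pos=pos, caller_id="A"))
        table = combine_at_threshold([cs], 1)
        out = tmp_path / "c.vcf"
        write_consensus_vcf(table, [cs], str(out))
        data = [l.split("\t")[:2] for l in out.read_text().splitlines()
                if not l.startswith("#")]
        assert data == [["chr1", "9"], ["chr2", "3"], ["chr2", "7"], ["chr10", "5"]]

    def test_reread_as_callset_recovers_keys(self, tmp_path):
        callsets = [callset_from_positions("A", [10, 20]), callset_from_positions("B", [10])]
        table = combine_at_threshold(callsets, 1)
        out = tmp_path / "c.vcf"
        write_consensus_vcf(table, callsets, str(out))
        cs = read_caller_vcf(str(out), get_dialect("consensus"))
        assert cs.keys == table.accepted
        assert cs.records_skipped == 0


class TestCallSet:
    def test_of_class_projection(self):
        cs = CallSet(caller_id="A")
        cs.add(make_variant(pos=10))
        cs.add(make_variant(pos=20, ref="AT", alt="A"))
        assert set(cs.of_class("SNV").keys) == {VariantKey("chr1", 10, "A", "G")}
        assert set(cs.of_class("INDEL").keys) == {VariantKey("chr1", 20, "AT", "A")}

    def test_duplicate_tie_keeps_first(self):
        cs = CallSet(caller_id="A")
        cs.add(make_variant(pos=10, alt_depth=5, vaf=0.1))
        cs.add(make_variant(pos=10, alt_depth=5, vaf=0.9))
        assert cs.variants[VariantKey("chr1", 10, "A", "G")].vaf == 0.1
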