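"""Domain types and format readers/writers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aneuvar import io
from aneuvar.types import (
    AcmgCriterion,
    CallSet,
    Consequence,
    ConsequenceClass,
    CriterionTier,
    GenomicPosition,
    MafCategory,
    Pedigree,
    Individual,
    Affection,
    PopulationFrequency,
    PredictorScores,
    SpliceEffect,
    SplicePredictor,
    VariantKey,
    Zygosity,
    categorize_maf,
)

from conftest import make_callset


# --------------------------------------------------------------------------
# value-type invariants
# --------------------------------------------------------------------------

class TestVariantIdentity:
    def test_genomic_requires_distinct_alleles_and_positive_pos(self):
        with pytest.raises(ValueError):
            GenomicPosition("1", 100, "A", "A")
        with pytest.raises(ValueError):
            GenomicPosition("1", 0, "A", "G")

    def test_key_equality_ignores_optional_fields(self):
        a = VariantKey("PCNT", "NM_006031", "c.4354G>A", hgvs_p="p.Gly1452Arg")
        b = VariantKey("PCNT", "NM_006031", "c.4354G>A", rsid="rs143796569")
        assert a == b
        assert len({a, b}) == 1


class TestConsequenceClass:
    def test_intronic_boundary_requires_nonzero_offset(self):
        with pytest.raises(ValueError):
            ConsequenceClass(Consequence.INTRONIC_BOUNDARY, 0)
        with pytest.raises(ValueError):
            ConsequenceClass(Consequence.INTRONIC_BOUNDARY, None)
        assert ConsequenceClass(Consequence.INTRONIC_BOUNDARY, -2).intron_offset == -2

    def test_other_classes_carry_no_offset(self):
        with pytest.raises(ValueError):
            ConsequenceClass(Consequence.MISSENSE, 1)


class TestPopulationFrequency:
    def test_printed_row_consistency(self):
        # published allele-count convention: MAF = AC / AN
        f = PopulationFrequency("gnomad_all", maf=0.01139,
                                allele_count=3221, hom_count=32,
                                total_alleles=282740)
        assert f.maf == pytest.approx(3221 / 282740, rel=1e-3)

    @pytest.mark.parametrize("kwargs", [
        dict(maf=1.5),
        dict(maf=0.5, allele_count=10, total_alleles=5),
        dict(maf=0.1, allele_count=4, hom_count=3),
        dict(maf=0.5, allele_count=10, total_alleles=100),  # inconsistent
    ])
    def test_invalid_counts_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PopulationFrequency("gnomad_all", **kwargs)


class TestPredictorScores:
    def test_one_call_per_splice_predictor_by_construction(self):
        s = PredictorScores(splice_calls={
            SplicePredictor.HSF: SpliceEffect.DONOR_LOSS})
        assert s.splice_calls[SplicePredictor.HSF] is SpliceEffect.DONOR_LOSS

    def test_score_ranges(self):
        with pytest.raises(ValueError):
            PredictorScores(revel=1.2)
        with pytest.raises(ValueError):
            PredictorScores(cadd=-1)


class TestMafCategories:
    @pytest.mark.parametrize("maf,expected", [
        (0.0, MafCategory.UNKNOWN),
        (1e-6, MafCategory.VERY_RARE),
        (0.001, MafCategory.VERY_RARE),
        (0.0010001, MafCategory.RARE),
        (0.01, MafCategory.RARE),
        (0.01864, MafCategory.LOW_FREQUENCY),
        (0.05, MafCategory.LOW_FREQUENCY),
        (0.0500001, MafCategory.COMMON),
        (1.0, MafCategory.COMMON),
    ])
    def test_partition_with_boundaries_in_lower_tier(self, maf, expected):
        assert categorize_maf(maf) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize_maf(-0.1)
        with pytest.raises(ValueError):
            categorize_maf(1.1)

    @given(st.floats(min_value=0.0, max_value=1.0,
                     allow_nan=False, allow_subnormal=False))
    @settings(max_examples=200, derandomize=True)
    def test_total_and_monotone(self, maf):
        order = [MafCategory.UNKNOWN, MafCategory.VERY_RARE, MafCategory.RARE,
                 MafCategory.LOW_FREQUENCY, MafCategory.COMMON]
        cat = categorize_maf(maf)
        assert cat in order
        # monotone: a strictly smaller MAF never lands in a higher tier
        smaller = maf / 2
        assert order.index(categorize_maf(smaller)) <= order.index(cat)


class TestAcmgCriterionCodes:
    def test_tier_is_function_of_prefix(self):
        assert AcmgCriterion("PVS1").tier is CriterionTier.PATHOGENIC_VERY_STRONG
        assert AcmgCriterion("PM2").tier is CriterionTier.PATHOGENIC_MODERATE
        assert AcmgCriterion("BA1").tier is CriterionTier.BENIGN_STANDALONE
        assert AcmgCriterion("BP7").tier is CriterionTier.BENIGN_SUPPORTING

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            AcmgCriterion("PM9")


class TestPedigreeStructure:
    def test_unresolved_parent_rejected(self):
        with pytest.raises(ValueError):
            Pedigree([Individual("kid", "F1", "ghost", None, "male",
                                 Affection.AFFECTED)])

    def test_cyclic_ancestry_rejected(self):
        with pytest.raises(ValueError):
            Pedigree([
                Individual("a", "F1", "b", None, "male", Affection.UNKNOWN),
                Individual("b", "F1", "a", None, "male", Affection.UNKNOWN),
            ])


# --------------------------------------------------------------------------
# VCF reader/writer
# --------------------------------------------------------------------------

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
)


class TestReadCallset:
    def test_het_and_ref_genotypes(self):
        vcf = VCF_HEADER + "1\t100\t.\tA\tG\t.\t.\tGENE=X;TX=NM_1;HGVSC=c.1A>G\tGT\t0/1\t0/0\n"
        cs = io.read_callset(vcf)
        assert cs.sample_ids == ["S1", "S2"]
        assert cs.zygosity_of("S1", cs.variants[0]) is Zygosity.HET
        assert cs.carriers_of(cs.variants[0]) == ["S1"]

    def test_hom_genotype(self):
        vcf = VCF_HEADER + "1\t100\t.\tA\tG\t.\t.\t.\tGT\t1/1\t0|1\n"
        cs = io.read_callset(vcf)
        assert cs.zygosity_of("S1", cs.variants[0]) is Zygosity.HOM
        assert cs.zygosity_of("S2", cs.variants[0]) is Zygosity.HET

    def test_missing_genotype_counts_as_noncarrier_and_is_tallied(self):
        vcf = VCF_HEADER + "1\t100\t.\tA\tG\t.\t.\t.\tGT\t./.\t0/1\n"
        cs = io.read_callset(vcf)
        assert cs.missing_count == 1
        assert cs.zygosity_of("S1", cs.variants[0]) is Zygosity.REF

    @pytest.mark.parametrize("line,fragment", [
        ("1\t100\t.\tA\tG,T\t.\t.\t.\tGT\t0/1\t0/0", "multi-allelic"),
        ("1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/1", "columns"),
        ("1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/1/1\t0/0", "non-diploid"),
        ("1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/2\t0/0", "beyond 1"),
    ])
    def test_malformed_lines_name_their_line_number(self, line, fragment):
        with pytest.raises(io.ParseError) as err:
            io.read_callset(VCF_HEADER + line + "\n")
        assert err.value.line == 3
        assert fragment in str(err.value)

    def test_malformed_header_rejected(self):
        with pytest.raises(io.ParseError):
            io.read_callset("#CHROM\tPOS\n")

    def test_fixture_vcf_regeneration_preserves_carrier_count(
            self, table2_fixture):
        callset, annotations = table2_fixture
        panel_variants = {a.key for a in annotations
                          if a.key.gene_symbol in
                          ("ADAMTS15", "ANGPTL6", "ARHGEF17", "LOXL2",
                           "PCNT", "RNF213", "THSD1", "TMEM132B")
                          and (a.maf("gnomad_all") or 0.0) <= 0.05}
        cs2 = io.read_callset(io.callset_to_vcf(callset))
        carriers = {s for v in cs2.variants if v in panel_variants
                    for s in cs2.carriers_of(v)}
        assert len(carriers) == 18

    def test_roundtrip_identity_on_zygosity(self, table2_fixture):
        callset, _ = table2_fixture
        again = io.read_callset(io.callset_to_vcf(callset))
        assert again == callset
        assert np.array_equal(again.zygosity, callset.zygosity)

    def test_roundtrip_against_pysam(self, tmp_path):
        pysam = pytest.importorskip("pysam")
        variants = [
            VariantKey("G1", "NM_1", "c.1A>G",
                       genomic=GenomicPosition("1", 100, "A", "G")),
            VariantKey("G2", "NM_2", "c.2C>T",
                       genomic=GenomicPosition("1", 200, "C", "T")),
        ]
        cs = CallSet(["S1", "S2", "S3"], variants,
                     np.array([[1, 0], [2, 1], [0, 0]], dtype=np.int8))
        path = tmp_path / "x.vcf"
        path.write_text(io.callset_to_vcf(cs))
        with pysam.VariantFile(str(path)) as vf:
            records = list(vf)
        assert len(records) == 2
        gts = [records[0].samples[s]["GT"] for s in ("S1", "S2", "S3")]
        assert gts == [(0, 1), (1, 1), (0, 0)]


# --------------------------------------------------------------------------
# PED reader
# --------------------------------------------------------------------------

class TestReadPedigree:
    def test_trio_affection_mapping(self):
        ped = ("F1 dad 0 0 1 1\n"
               "F1 mom 0 0 2 1\n"
               "F1 kid dad mom 1 2\n")
        p = io.read_pedigree(ped)
        assert len(p.affected("F1")) == 1
        assert p["kid"].father_id == "dad"
        assert p["mom"].affection is Affection.UNAFFECTED

    def test_three_affected_siblings(self, family_fixture):
        _cs, _ann, pedigree, _ctrl = family_fixture
        assert len(pedigree.affected("FAM_A")) == 3

    def test_probable_affected_code_configurable(self):
        p = io.read_pedigree("F1 x 0 0 1 9\n", probable_affected_code="9")
        assert p["x"].affection is Affection.PROBABLE_AFFECTED

    def test_short_line_is_parse_error(self):
        with pytest.raises(io.ParseError) as err:
            io.read_pedigree("F1 kid 0 0 1\n")
        assert err.value.line == 1

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            io.read_pedigree("F1 kid 0 0 1 1\nF1 kid 0 0 1 2\n")

    def test_roundtrip(self, family_fixture):
        _cs, _ann, pedigree, _ctrl = family_fixture
        text = io.pedigree_to_ped(pedigree)
        again = io.read_pedigree(text)
        assert [i.individual_id for i in again.individuals] == \
               [i.individual_id for i in pedigree.individuals]
        assert [i.affection for i in again.individuals] == \
               [i.affection for i in pedigree.individuals]


# --------------------------------------------------------------------------
# annotation TSV
# --------------------------------------------------------------------------

ANN_HEADER = "\t".join(io.ANNOTATION_COLUMNS
                       + ["gnomad_all.maf", "gnomad_all.ac",
                          "gnomad_all.hom", "gnomad_all.an"])


def ann_row(**overrides):
    cells = {
        "gene": "ANGPTL6", "transcript": "NM_031917", "hgvs_c": "c.1072G>A",
        "hgvs_p": "p.Arg358Cys", "rsid": "rs147149731",
        "consequence": "missense", "intron_offset": "n.a.",
        "cadd": "13.39", "revel": "0.238", "mcap": "n.a.",
        "clinpred": "0.014", "splice": "n.a.", "mis_z": "0.64", "pli": "0.0",
        "domain_tags": "n.a.", "criteria": "PM1+BP4",
        "gnomad_all.maf": "0.01139", "gnomad_all.ac": "3221",
        "gnomad_all.hom": "32", "gnomad_all.an": "282740",
    }
    cells.update(overrides)
    order = io.ANNOTATION_COLUMNS + ["gnomad_all.maf", "gnomad_all.ac",
                                     "gnomad_all.hom", "gnomad_all.an"]
    return "\t".join(cells[c] for c in order)


class TestReadAnnotations:
    def test_missing_score_stored_as_absent_never_zero(self):
        [v] = io.read_annotations(ANN_HEADER + "\n" + ann_row())
        assert v.scores.mcap is None
        assert v.scores.cadd == 13.39

    def test_count_consistency_accepts_printed_maf(self):
        [v] = io.read_annotations(ANN_HEADER + "\n" + ann_row())
        assert v.frequencies["gnomad_all"].allele_count == 3221

    def test_out_of_range_maf_rejected(self):
        row = ann_row(**{"gnomad_all.maf": "1.5", "gnomad_all.ac": "n.a.",
                         "gnomad_all.hom": "n.a.", "gnomad_all.an": "n.a."})
        with pytest.raises(io.ParseError) as err:
            io.read_annotations(ANN_HEADER + "\n" + row)
        assert err.value.line == 2

    def test_inconsistent_counts_rejected(self):
        row = ann_row(**{"gnomad_all.maf": "0.5"})
        with pytest.raises(io.ParseError):
            io.read_annotations(ANN_HEADER + "\n" + row)

    def test_missing_identity_column_rejected(self):
        with pytest.raises(io.ParseError):
            io.read_annotations("gene\ttranscript\nA\tB")

    @given(st.lists(st.booleans(), min_size=4, max_size=4))
    @settings(max_examples=16, derandomize=True)
    def test_random_missing_masks_never_coerced(self, mask):
        names = ["cadd", "revel", "mcap", "clinpred"]
        values = {"cadd": "25.0", "revel": "0.6", "mcap": "0.3",
                  "clinpred": "0.9"}
        overrides = {n: ("n.a." if m else values[n])
                     for n, m in zip(names, mask)}
        [v] = io.read_annotations(ANN_HEADER + "\n" + ann_row(**overrides))
        for n, m in zip(names, mask):
            got = getattr(v.scores, n)
            assert (got is None) == m
            if not m:
                assert got == float(values[n])

    def test_roundtrip(self, table2_fixture):
        _cs, annotations = table2_fixture
        text = io.annotations_to_tsv(annotations)
        assert io.read_annotations(text) == annotations


# --------------------------------------------------------------------------
# report writer
# --------------------------------------------------------------------------

class TestWriteReport:
    def test_empty_results_still_valid(self, tmp_path):
        paths = io.write_report({"screen": []}, tmp_path)
        assert (tmp_path / "screen.tsv").exists()
        assert (tmp_path / "report.json").exists()
        assert len((tmp_path / "screen.tsv").read_text().splitlines()) == 1

    def test_screen_report_has_twenty_rows(self, tmp_path, table2_fixture):
        from aneuvar import screen, simulate
        cs, anns = table2_fixture
        result = screen.screen_risk_genes(cs, anns,
                                          list(simulate.RISK_GENE_PANEL))
        io.write_report({"screen": result.to_rows()}, tmp_path)
        lines = (tmp_path / "screen.tsv").read_text().splitlines()
        assert len(lines) == 21  # header + 20 data rows

    def test_determinism_byte_identical(self, tmp_path, table2_fixture):
        from aneuvar import screen, simulate
        cs, anns = table2_fixture
        result = screen.screen_risk_genes(cs, anns,
                                          list(simulate.RISK_GENE_PANEL))
        payload = {"screen": result.to_rows(),
                   "summary": {"n": len(result.retained)}}
        io.write_report(payload, tmp_path / "a")
        io.write_report(payload, tmp_path / "b")
        for name in ("screen.tsv", "report.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()
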