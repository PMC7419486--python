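"""Family-based candidate filter: sharing, novelty, consequence,
prediction stages and their composition."""

import itertools

import numpy as np
import pytest

from aneuvar import simulate
from aneuvar.family import (
    DEFAULT_THRESHOLDS,
    absent_from_controls,
    consequence_filter,
    predictor_vote,
    prioritize_family,
    shared_variants,
    splice_vote,
)
from aneuvar.types import (
    AnnotatedVariant,
    Consequence,
    ConsequenceClass,
    PredictorScores,
    SpliceEffect,
    SplicePredictor,
    VariantKey,
)

EXPECTED_CANDIDATE_GENES = {"NEK4", "EDIL3", "EDNRB", "DNAH9", "GGA3"}

STAGE_BY_RULE = {
    "not_shared": "not_shared",
    "in_controls": "in_controls",
    "wrong_consequence": "consequence",
    "insufficient_predictor_votes": "prediction",
    "insufficient_splice_votes": "prediction",
    "truncating_low_cadd": "prediction",
}


class TestSharedVariants:
    def test_all_candidates_shared_by_three_sibs(self, family_fixture):
        callset, _ann, pedigree, _ = family_fixture
        shared = shared_variants(callset, pedigree, simulate.FAMILY_ID)
        genes = {v.gene_symbol for v in shared}
        assert EXPECTED_CANDIDATE_GENES <= genes

    def test_two_of_three_sibs_not_shared(self, family_fixture,
                                          family_metadata):
        callset, _ann, pedigree, _ = family_fixture
        _roles, rules = family_metadata
        shared = set(shared_variants(callset, pedigree, simulate.FAMILY_ID))
        for key, rule in rules.items():
            if rule == "not_shared":
                assert key not in shared

    def test_no_affected_genotyped_member_is_error(self, family_fixture):
        callset, _ann, pedigree, _ = family_fixture
        with pytest.raises(ValueError):
            shared_variants(callset, pedigree, "NOFAM")


class TestAbsentFromControls:
    def test_edil3_retained_and_decoy_removed(self, family_fixture):
        callset, annotations, pedigree, _ = family_fixture
        by_key = {a.key: a for a in annotations}
        shared = shared_variants(callset, pedigree, simulate.FAMILY_ID)
        kept = absent_from_controls(shared, by_key,
                                    ["gnomad_all", "popgen_ikmb"])
        kept_genes = {v.gene_symbol for v in kept}
        assert "EDIL3" in kept_genes
        assert "SYNDG3" not in kept_genes  # gnomAD MAF 1.06e-5
        assert "SYNDG4" not in kept_genes  # population controls 2e-4

    def test_empty_control_list_rejected(self, family_fixture):
        _cs, annotations, _ped, _ = family_fixture
        by_key = {a.key: a for a in annotations}
        with pytest.raises(ValueError):
            absent_from_controls(list(by_key), by_key, [])

    def test_epsilon_relaxes_strict_zero(self, family_fixture):
        _cs, annotations, _ped, _ = family_fixture
        by_key = {a.key: a for a in annotations}
        syndg3 = [k for k in by_key if k.gene_symbol == "SYNDG3"]
        kept = absent_from_controls(syndg3, by_key,
                                    ["gnomad_all", "popgen_ikmb"],
                                    epsilon=1e-4)
        assert kept == syndg3


def _ann(consequence, offset=None, **scores):
    return AnnotatedVariant(
        key=VariantKey("X", "NM_X", "c.1A>G"),
        consequence=ConsequenceClass(consequence, offset),
        scores=PredictorScores(**scores),
    )


class TestConsequenceFilter:
    @pytest.mark.parametrize("consequence,offset,kept", [
        (Consequence.MISSENSE, None, True),
        (Consequence.SYNONYMOUS, None, True),
        (Consequence.NONSENSE, None, True),
        (Consequence.FRAMESHIFT_INDEL, None, True),
        (Consequence.INTRONIC_BOUNDARY, 2, True),
        (Consequence.INTRONIC_BOUNDARY, -2, True),
        (Consequence.INTRONIC_BOUNDARY, 5, False),
        (Consequence.INTRONIC_BOUNDARY, -3, False),
        (Consequence.OTHER, None, False),
    ])
    def test_admitted_classes(self, consequence, offset, kept):
        ann = _ann(consequence, offset)
        out = consequence_filter([ann.key], {ann.key: ann})
        assert (ann.key in out) == kept


class TestPredictorVote:
    @pytest.mark.parametrize("scores,expected", [
        # all four at/above threshold (candidate-gene missense)
        (dict(cadd=29.1, revel=0.946, mcap=0.523, clinpred=0.998), (4, 4)),
        # none of three available (M-CAP missing)
        (dict(cadd=13.39, revel=0.238, clinpred=0.014), (0, 3)),
        # two of four
        (dict(cadd=23.7, revel=0.303, mcap=0.020, clinpred=0.972), (2, 4)),
        (dict(), (0, 0)),
    ])
    def test_counts_available_scores_at_inclusive_thresholds(
            self, scores, expected):
        assert predictor_vote(PredictorScores(**scores)) == expected

    def test_threshold_boundary_is_inclusive(self):
        assert predictor_vote(PredictorScores(cadd=20.0)) == (1, 1)
        assert predictor_vote(PredictorScores(cadd=19.999)) == (0, 1)


class TestSpliceVote:
    def test_three_predictors_calling_donor_gain(self):
        s = PredictorScores(splice_calls={
            SplicePredictor.HSF: SpliceEffect.DONOR_GAIN,
            SplicePredictor.NETGENE2: SpliceEffect.DONOR_GAIN,
            SplicePredictor.MAXENTSCAN: SpliceEffect.DONOR_GAIN,
        })
        assert splice_vote(s) == 3

    def test_no_impact_and_empty_score_zero(self):
        assert splice_vote(PredictorScores(splice_calls={
            SplicePredictor.HSF: SpliceEffect.NO_IMPACT})) == 0
        assert splice_vote(PredictorScores()) == 0


class TestPrioritizeFamily:
    def test_exactly_the_five_published_candidates(self, family_fixture):
        callset, annotations, pedigree, _ = family_fixture
        candidates, _trace = prioritize_family(
            callset, annotations, pedigree, simulate.FAMILY_ID)
        assert {v.gene_symbol for v in candidates} == EXPECTED_CANDIDATE_GENES
        assert len(candidates) == 5

    def test_every_decoy_removed_at_its_designated_stage(
            self, family_fixture, family_metadata):
        callset, annotations, pedigree, _ = family_fixture
        roles, rules = family_metadata
        _cands, trace = prioritize_family(
            callset, annotations, pedigree, simulate.FAMILY_ID)
        for key, role in roles.items():
            if role == "decoy":
                assert trace.stage_of(key) == STAGE_BY_RULE[rules[key]], key

    def test_trace_conservation(self, family_fixture):
        callset, annotations, pedigree, _ = family_fixture
        candidates, trace = prioritize_family(
            callset, annotations, pedigree, simulate.FAMILY_ID)
        assert len(trace.records) == len(callset.variants)
        removed = [r for r in trace.records if r.outcome == "removed"]
        assert len(candidates) + len(removed) == len(callset.variants)
        assert all(r.removal_stage is not None for r in removed)

    def test_nonsense_with_high_cadd_retained(self, family_fixture):
        # swap the low-CADD truncating decoy for a qualifying one
        callset, annotations, pedigree, _ = family_fixture
        patched = []
        for a in annotations:
            if a.key.gene_symbol == "SYNDG11":
                patched.append(AnnotatedVariant(
                    key=a.key, consequence=a.consequence,
                    frequencies=a.frequencies,
                    scores=PredictorScores(cadd=35.0)))
            else:
                patched.append(a)
        candidates, _ = prioritize_family(
            callset, patched, pedigree, simulate.FAMILY_ID)
        assert any(v.gene_symbol == "SYNDG11" for v in candidates)

    def test_stage_order_invariance_of_final_set(self, family_fixture):
        # stages (ii)-(iv) are independent predicates: applying them in any
        # order after sharing yields the same retained set
        callset, annotations, pedigree, _ = family_fixture
        by_key = {a.key: a for a in annotations}
        shared = shared_variants(callset, pedigree, simulate.FAMILY_ID)
        from aneuvar.family import _passes_prediction

        def stage2(vs):
            return absent_from_controls(vs, by_key,
                                        ["gnomad_all", "popgen_ikmb"])

        def stage3(vs):
            return consequence_filter(vs, by_key)

        def stage4(vs):
            return [v for v in vs
                    if by_key[v].consequence.kind.value != "other"
                    and _passes_prediction(by_key[v], DEFAULT_THRESHOLDS)[0]]

        reference = None
        for order in itertools.permutations([stage2, stage3, stage4]):
            vs = list(shared)
            for stage in order:
                vs = stage(vs)
            result = set(vs)
            reference = result if reference is None else reference
            assert result == reference

    def test_raising_thresholds_never_grows_retained_set(
            self, family_fixture):
        callset, annotations, pedigree, _ = family_fixture
        base, _ = prioritize_family(callset, annotations, pedigree,
                                    simulate.FAMILY_ID)
        for factor in (1.5, 2.0, 10.0):
            stricter = {k: v * factor for k, v in DEFAULT_THRESHOLDS.items()}
            tightened, _ = prioritize_family(
                callset, annotations, pedigree, simulate.FAMILY_ID,
                thresholds=stricter)
            assert set(tightened) <= set(base)
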