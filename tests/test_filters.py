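"""Filter cascade: QC, consequence, frequency stages and their composition."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chordsift.errors import InputError
from chordsift.filters import (
    FilterConfig,
    QCFields,
    Reason,
    apply_qc,
    consequence_filter,
    frequency_filter,
    run_cascade,
)
from chordsift.model import AnnotationBundle, VariantRecord, VariantType


def _variant(vtype):
    return VariantRecord("1", 100, "A", "G", "TBXT", vtype, carriers=frozenset({"s"}))


class TestQC:
    @pytest.mark.parametrize(
        "qc, expected_reasons",
        [
            (QCFields(9, 0.5, 3, False), (Reason.LOW_DEPTH,)),
            (QCFields(30, 0.5, 3, False), ()),
            (QCFields(30, None, 1, False), (Reason.SINGLE_CALLER,)),
            (QCFields(30, 0.1, 3, False), (Reason.ABHET_OUT_OF_RANGE,)),
            (QCFields(30, 0.85, 3, False), (Reason.ABHET_OUT_OF_RANGE,)),
            (QCFields(30, 0.5, 3, True), (Reason.PIPELINE_FLAG,)),
            (QCFields(30, 0.2, 3, False), ()),  # boundary values retained
            (QCFields(30, 0.8, 3, False), ()),
            (QCFields(10, 0.5, 2, False), ()),
        ],
    )
    def test_rules(self, qc, expected_reasons):
        decision = apply_qc(qc)
        assert decision.reasons == expected_reasons
        assert decision.retained == (not expected_reasons)

    def test_homozygous_calls_skip_abhet(self):
        assert apply_qc(QCFields(30, None, 3, False)).retained

    def test_negative_depth_rejected(self):
        with pytest.raises(InputError):
            apply_qc(QCFields(-1, 0.5, 3, False))


class TestConsequence:
    @pytest.mark.parametrize(
        "vtype, retained",
        [
            (VariantType.SYNONYMOUS, False),
            (VariantType.MISSENSE, True),
            (VariantType.STOP_LOST, True),  # e.g. a stop-lost read-through extension
            (VariantType.FRAMESHIFT, True),
            (VariantType.STRUCTURAL_INTERACTION, True),
            (VariantType.OTHER, False),
        ],
    )
    def test_allowed_set(self, vtype, retained):
        assert consequence_filter(_variant(vtype)).retained == retained


class TestFrequency:
    def test_rare_in_ancestry_population_retained(self):
        # the most frequent retained discovery variant: 9.24e-4 in NFE exomes
        ann = AnnotationBundle(maf_by_source={("gnomad_exomes", "NFE"): 9.24e-4})
        assert frequency_filter(ann).retained

    def test_absent_everywhere_retained(self):
        assert frequency_filter(AnnotationBundle()).retained

    def test_combinator_semantics(self):
        ann = AnnotationBundle(maf_by_source={("gnomad_exomes", "NFE"): 0.005})
        assert not frequency_filter(ann, FilterConfig()).retained
        both = FilterConfig(frequency_combinator="both_criteria_exclude")
        assert frequency_filter(ann, both).retained

    def test_both_criteria_jointly_exclude(self):
        ann = AnnotationBundle(
            maf_by_source={("gnomad_exomes", "NFE"): 0.005}, inhouse_family_count=5
        )
        cfg = FilterConfig(frequency_combinator="both_criteria_exclude")
        decision = frequency_filter(ann, cfg)
        assert not decision.retained
        assert set(decision.reasons) == {Reason.COMMON_IN_POPULATION, Reason.RECURRENT_INHOUSE}

    def test_population_scope(self):
        ann = AnnotationBundle(maf_by_source={("gnomad_exomes", "EAS"): 0.005})
        assert frequency_filter(ann, FilterConfig()).retained  # EAS out of European scope
        any_pop = FilterConfig(frequency_population_scope="any_population")
        assert not frequency_filter(ann, any_pop).retained

    def test_recurrent_inhouse(self):
        ann = AnnotationBundle(inhouse_family_count=3)
        assert not frequency_filter(ann).retained
        assert frequency_filter(AnnotationBundle(inhouse_family_count=2)).retained


class TestConfigSerialization:
    def test_round_trip(self):
        cfg = FilterConfig(maf_threshold=0.005, frequency_combinator="both_criteria_exclude")
        assert FilterConfig.from_dict(cfg.to_dict()) == cfg

    def test_unknown_key_rejected(self):
        with pytest.raises(InputError, match="unknown filter config key"):
            FilterConfig.from_dict({"maf_ceiling": 0.1})


class TestCascade:
    def test_reasons_accumulate_across_stages(self):
        decision = run_cascade(
            _variant(VariantType.SYNONYMOUS),
            QCFields(9, 0.5, 3, False),
            AnnotationBundle(),
        )
        assert decision.reasons == (Reason.LOW_DEPTH, Reason.SYNONYMOUS)

    def test_any_stage_excluding_excludes(self):
        decision = run_cascade(
            _variant(VariantType.MISSENSE),
            QCFields(30, 0.5, 3, False),
            AnnotationBundle(inhouse_family_count=9),
        )
        assert not decision.retained

    def test_all_table1_rows_pass_frequency_stage(self, table1):
        cfg = FilterConfig()
        retained = [
            run_cascade(rec, None, ann, cfg, skip_stages=frozenset({"qc"})).retained
            for rec, ann in table1.items()
        ]
        assert sum(retained) == 34

    def test_qc_required_unless_prepassed(self):
        with pytest.raises(InputError):
            run_cascade(_variant(VariantType.MISSENSE), None, AnnotationBundle())


@settings(max_examples=60, deadline=None)
@given(
    maf=st.floats(0.0, 0.02),
    thr_lo=st.floats(0.0001, 0.001),
    thr_hi_delta=st.floats(0.0, 0.01),
    inhouse=st.integers(0, 5),
)
def test_raising_maf_threshold_is_monotone(maf, thr_lo, thr_hi_delta, inhouse):
    """A looser frequency threshold never shrinks the retained set."""
    ann = AnnotationBundle(
        maf_by_source={("gnomad_exomes", "NFE"): maf}, inhouse_family_count=inhouse
    )
    lo = FilterConfig(maf_threshold=thr_lo)
    hi = FilterConfig(maf_threshold=thr_lo + thr_hi_delta)
    if frequency_filter(ann, lo).retained:
        assert frequency_filter(ann, hi).retained


@settings(max_examples=60, deadline=None)
@given(depth=st.integers(0, 40), min_depth=st.integers(0, 20), extra=st.integers(0, 15))
def test_raising_min_depth_is_monotone(depth, min_depth, extra):
    strict = FilterConfig(min_depth=min_depth + extra)
    loose = FilterConfig(min_depth=min_depth)
    qc = QCFields(depth, 0.5, 3, False)
    if apply_qc(qc, strict).retained:
        assert apply_qc(qc, loose).retained


@settings(max_examples=60, deadline=None)
@given(
    maf=st.one_of(st.none(), st.floats(0.0, 0.02)),
    inhouse=st.integers(0, 5),
    depth=st.integers(0, 40),
    vtype=st.sampled_from(list(VariantType)),
)
def test_both_mode_retains_superset_and_stage_order_irrelevant(maf, inhouse, depth, vtype):
    """The conjunctive combinator retains a superset of the disjunctive one,
    and the retained/excluded outcome does not depend on stage order."""
    sources = {} if maf is None else {("gnomad_exomes", "NFE"): maf}
    ann = AnnotationBundle(maf_by_source=sources, inhouse_family_count=inhouse)
    qc = QCFields(depth, 0.5, 3, False)
    v = _variant(vtype)

    any_cfg = FilterConfig()
    both_cfg = FilterConfig(frequency_combinator="both_criteria_exclude")
    if run_cascade(v, qc, ann, any_cfg).retained:
        assert run_cascade(v, qc, ann, both_cfg).retained

    # order-independence: composition retains iff every stage retains
    stage_wise = (
        apply_qc(qc, any_cfg).retained
        and consequence_filter(v, any_cfg).retained
        and frequency_filter(ann, any_cfg).retained
    )
    assert run_cascade(v, qc, ann, any_cfg).retained == stage_wise
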