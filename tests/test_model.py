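"""Data model: fixture loading, table round-trip, panel construction."""

import numpy as np
import pytest

from chordsift.errors import ConfigurationError, FixtureError, InputError
from chordsift.model import (
    AnnotationBundle,
    CohortGenotypes,
    VariantRecord,
    VariantType,
    build_panel,
    load_fixture,
    parse_variant_type,
    read_table,
    write_table,
)
from chordsift.pathogenicity import HIGH_IMPACT_TYPES


class TestFixtures:
    def test_row_counts(self, table1, table2):
        assert len(table1.records) == 34
        assert len(table2.records) == 20

    def test_discovery_consequence_split(self, table1):
        """The discovery table holds 7 loss-of-function-like and 27 missense
        records under the primary-type convention."""
        high = [r for r in table1.records if r.variant_type in HIGH_IMPACT_TYPES]
        mis = [r for r in table1.records if r.variant_type is VariantType.MISSENSE]
        assert len(high) == 7
        assert len(mis) == 27

    def test_gdf3_row_transcription(self, table1):
        (rec, ann), = [
            (r, a) for r, a in table1.items() if r.gene == "GDF3"
        ]
        assert rec.rsid == "rs146973734"
        assert ann.cadd_phred == pytest.approx(0.004)
        assert ann.clinvar == "P"
        assert ann.hgmd == "DM"
        assert ann.metasvm == "T" and ann.metalr == "T"

    def test_ext2_maf_evidence(self, table1):
        (rec, ann), = [(r, a) for r, a in table1.items() if r.gene == "EXT2"]
        assert ann.maf_by_source[("gnomad_exomes", "NFE")] == pytest.approx(9.24e-4)
        assert ann.hgmd == "DM"

    def test_compound_types_resolve_to_primary(self):
        assert parse_variant_type("frameshift & stop_gained") is VariantType.FRAMESHIFT
        assert parse_variant_type("missense & splice region") is VariantType.MISSENSE
        assert parse_variant_type("structural interaction") is VariantType.STRUCTURAL_INTERACTION

    def test_missing_cells_are_missing_not_zero(self, table1):
        (_, ann), = [(r, a) for r, a in table1.items() if r.gene == "LYST"]
        assert ann.metasvm is None and ann.cadd_phred is None
        assert ann.maf_by_source == {}

    def test_explicit_zero_maf_is_present(self, table1):
        (_, ann), = [(r, a) for r, a in table1.items() if r.gene == "TBXT"]
        assert ann.maf_by_source[("gnomad_exomes", "NFE")] == 0.0

    def test_prepassed_stages(self, table1):
        assert table1.prepassed_stages == frozenset({"qc", "frequency"})

    def test_unknown_fixture_raises(self):
        with pytest.raises(FixtureError, match="unknown fixture"):
            load_fixture("nonexistent_table")

    def test_patient_metadata(self, table2):
        assert set(table2.patients.columns) >= {"ID", "Gender", "Age", "Morphology"}
        assert len(table2.patients) == 18  # distinct printed identifiers

    @pytest.mark.parametrize("name", ["european_table1", "chinese_table2"])
    def test_round_trip(self, name, tmp_path):
        """Writing a table to the dialect and re-reading reproduces every
        record and annotation field-by-field."""
        bundle = load_fixture(name)
        out = tmp_path / "table.tsv"
        write_table(bundle, out)
        back = read_table(out, dialect=bundle.dialect)
        assert len(back.records) == len(bundle.records)
        for r1, r2 in zip(bundle.records, back.records):
            assert r1 == r2
        for a1, a2 in zip(bundle.annotations, back.annotations):
            assert a1.metasvm == a2.metasvm and a1.metalr == a2.metalr
            assert a1.clinvar == a2.clinvar and a1.hgmd == a2.hgmd
            if a1.cadd_phred is None:
                assert a2.cadd_phred is None
            else:
                assert a2.cadd_phred == pytest.approx(a1.cadd_phred)
            assert set(a1.maf_by_source) == set(a2.maf_by_source)
            for k, v in a1.maf_by_source.items():
                assert a2.maf_by_source[k] == pytest.approx(v)


class TestVariantRecord:
    def test_invariants(self):
        with pytest.raises(InputError):
            VariantRecord("1", 0, "A", "G", "TBXT", VariantType.MISSENSE, carriers=frozenset({"s"}))
        with pytest.raises(InputError):
            VariantRecord("1", 5, "A", "A", "TBXT", VariantType.MISSENSE, carriers=frozenset({"s"}))
        with pytest.raises(InputError):
            VariantRecord("1", 5, "A", "G", "TBXT", VariantType.MISSENSE, carriers=frozenset())

    def test_annotation_frequency_bounds(self):
        with pytest.raises(InputError):
            AnnotationBundle(maf_by_source={("db", "POP"): 1.5})
        with pytest.raises(InputError):
            AnnotationBundle(cadd_phred=-1.0)


class TestPanel:
    def test_build_from_document(self):
        panel = build_panel({"notochord": ["GDF3", "COL2A1"]})
        assert panel.genes == {"GDF3", "COL2A1"}
        assert panel.categories["GDF3"] == {"notochord"}

    def test_empty_document_rejected(self):
        with pytest.raises(ConfigurationError):
            build_panel({})

    def test_multi_category_union(self):
        panel = build_panel({"notochord": ["TBXT"], "mesoderm_commitment": ["TBXT"]})
        assert len(panel.genes) == 1
        assert panel.categories["TBXT"] == {"notochord", "mesoderm_commitment"}

    def test_unknown_category_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown category"):
            build_panel({"not_a_category": ["TBXT"]})

    def test_bundled_panel_category_sizes(self, panel):
        assert len(panel.genes_in_category("mesoderm_commitment")) == 16
        assert len(panel.genes_in_category("driver")) == 1


class TestCohortGenotypes:
    def test_dimension_and_value_checks(self, table1):
        recs = table1.records[:2]
        with pytest.raises(InputError):
            CohortGenotypes(["s1"], [True], np.zeros((1, 3), dtype=np.int8), recs)
        with pytest.raises(InputError):
            CohortGenotypes(
                ["s1", "s2"], [True, False],
                np.array([[5, 0], [0, 0]], dtype=np.int8), recs,
            )

    def test_carrier_consistency_checker(self):
        rec = VariantRecord("1", 10, "A", "G", "TBXT", VariantType.MISSENSE,
                            carriers=frozenset({"s2"}))
        cohort = CohortGenotypes(["s1", "s2"], [True, False],
                                 np.array([[0], [1]], dtype=np.int8), [rec])
        assert cohort.check_carrier_consistency()
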