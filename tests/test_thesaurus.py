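"""Thesaurus records, hierarchy reasoning, label lookup, and the XML/TSV readers."""

import xml.etree.ElementTree as ET

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meshlingua import (
    Descriptor,
    IntegrityError,
    LanguageError,
    MeshXmlError,
    Qualifier,
    RecordKind,
    Relation,
    Thesaurus,
    UnknownIdentifierError,
    load_mesh_xml,
    load_translations,
    normalize_label,
    write_mesh_xml,
    write_translations,
)

MINIMAL_XML = """<?xml version="1.0" encoding="utf-8"?>
<DescriptorRecordSet>
  <DescriptorRecord>
    <DescriptorUI>D000505</DescriptorUI>
    <DescriptorName><String>Alopecia Areata</String></DescriptorName>
    <TreeNumberList><TreeNumber>C17.800.55.620</TreeNumber></TreeNumberList>
  </DescriptorRecord>
</DescriptorRecordSet>
"""


class TestNormalization:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Alopecia  Areata", "alopecia areata"),
            ("PELADÉ", "pelade"),
            ("Rupture, Spontaneous", "rupture, spontaneous"),
            ("  états-unis   d'amérique ", "etats-unis d'amerique"),
        ],
    )
    def test_folding_contract(self, raw, expected):
        assert normalize_label(raw) == expected

    @settings(max_examples=50, derandomize=True)
    @given(st.text(max_size=40))
    def test_idempotent(self, text):
        once = normalize_label(text)
        assert normalize_label(once) == once


class TestXmlReader:
    def test_single_record_identity(self, tmp_path):
        path = tmp_path / "one.xml"
        path.write_text(MINIMAL_XML, encoding="utf-8")
        th = load_mesh_xml(path)
        assert len(th.descriptors) == 1
        rec = th.descriptors["D000505"]
        assert rec.labels["en"] == "Alopecia Areata"
        assert rec.tree_numbers == ["C17.800.55.620"]

    def test_empty_record_set(self, tmp_path):
        path = tmp_path / "empty.xml"
        path.write_text("<DescriptorRecordSet/>", encoding="utf-8")
        th = load_mesh_xml(path)
        assert len(th.descriptors) == 0

    def test_malformed_xml_names_line(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text("<DescriptorRecordSet>\n<oops>", encoding="utf-8")
        with pytest.raises(MeshXmlError, match="line"):
            load_mesh_xml(path)

    def test_duplicate_ui_rejected(self, tmp_path):
        doubled = MINIMAL_XML.replace(
            "</DescriptorRecordSet>",
            MINIMAL_XML.split("<DescriptorRecordSet>")[1],
        )
        path = tmp_path / "dup.xml"
        path.write_text(doubled, encoding="utf-8")
        with pytest.raises(IntegrityError):
            load_mesh_xml(path)

    def test_round_trip_fixture(self, thesaurus, tmp_path):
        """write -> load -> identical records (including translations via TSV)."""
        xml_path = tmp_path / "th.xml"
        tsv_path = tmp_path / "fr.tsv"
        write_mesh_xml(thesaurus, xml_path)
        write_translations(thesaurus, "fr", tsv_path)
        reloaded = load_mesh_xml(xml_path)
        load_translations(reloaded, tsv_path, "fr")
        assert reloaded.descriptors == thesaurus.descriptors
        assert reloaded.qualifiers == thesaurus.qualifiers


class TestTranslations:
    def test_row_adds_language(self, tmp_path):
        th = Thesaurus()
        th.add(Descriptor(ui="D000505", labels={"en": "Alopecia Areata"},
                          tree_numbers=["C17.800.55.620"]))
        path = tmp_path / "fr.tsv"
        path.write_text("D000505\tpelade\talopécie en aires\n", encoding="utf-8")
        load_translations(th, path, "fr")
        assert th.lookup_label("pelade", "fr").ui == "D000505"
        assert th.lookup_label("alopécie en aires", "fr").ui == "D000505"

    def test_empty_file_is_noop(self, tmp_path):
        th = Thesaurus()
        th.add(Descriptor(ui="D1", labels={"en": "thing"}))
        before = dict(th.descriptors)
        path = tmp_path / "empty.tsv"
        path.write_text("", encoding="utf-8")
        load_translations(th, path, "fr")
        assert th.descriptors == before

    def test_idempotent_reload(self, tmp_path):
        th = Thesaurus()
        th.add(Descriptor(ui="D1", labels={"en": "Alopecia Areata"}))
        path = tmp_path / "en.tsv"
        path.write_text("D1\tAlopecia Areata\tAlopecia Areata|pelade\n", encoding="utf-8")
        load_translations(th, path, "en")
        load_translations(th, path, "en")
        # no duplicates, and the label itself is not re-added as a synonym
        assert th.descriptors["D1"].synonyms["en"] == ["pelade"]

    def test_unknown_ui_lists_rows(self, tmp_path):
        th = Thesaurus()
        th.add(Descriptor(ui="D1", labels={"en": "thing"}))
        path = tmp_path / "bad.tsv"
        path.write_text("D1\tchose\nD999\tfantôme\n", encoding="utf-8")
        with pytest.raises(IntegrityError, match="D999"):
            load_translations(th, path, "fr")
        # aborted without partial application
        assert "fr" not in th.descriptors["D1"].labels


class TestRelation:
    def test_same(self, thesaurus):
        assert thesaurus.relation("D001249", "D001249") is Relation.SAME

    def test_prefix_definition(self):
        th = Thesaurus()
        th.add(Descriptor(ui="A", labels={"en": "a"}, tree_numbers=["A01.2.3"]))
        th.add(Descriptor(ui="B", labels={"en": "b"}, tree_numbers=["A01.2"]))
        th.add(Descriptor(ui="C", labels={"en": "c"}, tree_numbers=["A01.22"]))
        assert th.relation("A", "B") is Relation.DESCENDANT
        assert th.relation("B", "A") is Relation.ANCESTOR
        # dotted-prefix, not string-prefix: A01.2 is not an ancestor of A01.22
        assert th.relation("C", "B") is Relation.UNRELATED

    def test_dysgeusia_under_taste_disorders(self, thesaurus):
        dys = thesaurus.lookup_label("dysgeusia", "en").ui
        td = thesaurus.lookup_label("taste disorders", "en").ui
        assert thesaurus.relation(dys, td) is Relation.DESCENDANT

    def test_unknown_ui(self, thesaurus):
        with pytest.raises(UnknownIdentifierError):
            thesaurus.relation("D001249", "D999999")

    def test_cross_kind_is_error(self, thesaurus):
        with pytest.raises(IntegrityError):
            thesaurus.relation("D001249", "Q000628")

    def test_partial_order_on_fixture(self, thesaurus):
        """Never both descendant and ancestor; converse pairs are symmetric."""
        uis = sorted(thesaurus.descriptors)[:25]
        for a in uis:
            for b in uis:
                r_ab = thesaurus.relation(a, b)
                r_ba = thesaurus.relation(b, a)
                if a == b:
                    assert r_ab is Relation.SAME
                else:
                    assert r_ab is not Relation.SAME
                    expected = {
                        Relation.DESCENDANT: Relation.ANCESTOR,
                        Relation.ANCESTOR: Relation.DESCENDANT,
                        Relation.UNRELATED: Relation.UNRELATED,
                    }[r_ab]
                    assert r_ba is expected

    def test_language_invariance(self, thesaurus):
        """Hierarchy answers depend only on tree numbers, not labels."""
        dys_fr = thesaurus.lookup_label("dysgueusie", "fr").ui
        td_fr = thesaurus.lookup_label("troubles du goût", "fr").ui
        assert thesaurus.relation(dys_fr, td_fr) is Relation.DESCENDANT


class TestLookup:
    def test_exact_label(self, thesaurus):
        assert thesaurus.lookup_label("alopecia areata", "en").ui == "D000505"

    def test_case_and_diacritics(self, thesaurus):
        assert thesaurus.lookup_label("PELADE", "fr").ui == "D000505"

    def test_no_match(self, thesaurus):
        assert thesaurus.lookup_label("zzz-unknown", "en") is None

    def test_unknown_language(self, thesaurus):
        with pytest.raises(LanguageError):
            thesaurus.lookup_label("anything", "xx")

    def test_preferred_beats_synonym(self):
        th = Thesaurus()
        th.add(Descriptor(ui="D1", labels={"en": "screening"}))
        th.add(Descriptor(ui="D2", labels={"en": "mass screening"},
                          synonyms={"en": ["screening"]}))
        assert th.lookup_label("screening", "en").ui == "D1"

    def test_kind_restriction(self, thesaurus):
        # "epidemiology" names both a discipline descriptor and a subheading
        desc = thesaurus.lookup_label("epidemiology", "en", kind="descriptor")
        qual = thesaurus.lookup_label("epidemiology", "en", kind="qualifier")
        assert desc.kind is RecordKind.DESCRIPTOR
        assert isinstance(qual, Qualifier)


class TestInvariants:
    def test_publication_type_has_no_qualifiers(self, thesaurus):
        for d in thesaurus.descriptors.values():
            if d.kind is RecordKind.PUBLICATION_TYPE:
                assert d.allowed_qualifiers == []

    def test_bad_tree_number_rejected(self):
        th = Thesaurus()
        with pytest.raises(IntegrityError):
            th.add(Descriptor(ui="D1", labels={"en": "x"}, tree_numbers=["17.800"]))

    def test_missing_pivot_label_rejected(self):
        th = Thesaurus()
        with pytest.raises(IntegrityError):
            th.add(Descriptor(ui="D1", labels={"fr": "chose"}))
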