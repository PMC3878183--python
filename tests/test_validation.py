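"""Rule-based validation: mandatory parts, rule catalogue, XSD agreement."""

import pytest
from lxml import etree

from elnmanifest import (
    RULES,
    to_xml,
    validate_against_schema,
    validate_manifest,
)

NS = "urn:elnmanifest:schema:1.0"

#: Top-level parts of a manifest document, as (name, is_mandatory).
TOP_LEVEL_PARTS = [
    ("unitType", True), ("Title", True), ("Identifiers", True),
    ("Contact", True), ("Contributors", True), ("Source", True),
    ("Date", True), ("Content", True),
    ("Keywords", False), ("LicensingBasis", False), ("RelatedItems", False),
    ("AccessIdentifier", False),
]


def _delete_part(document: str, part: str) -> bytes:
    """Remove one named part from a serialized manifest document."""
    root = etree.fromstring(document.encode())
    if part == "unitType":
        del root.attrib["unitType"]
    elif part == "AccessIdentifier":
        el = root.find(f"{{{NS}}}Identifiers/{{{NS}}}AccessIdentifier")
        el.getparent().remove(el)
    else:
        el = root.find(f"{{{NS}}}{part}")
        el.getparent().remove(el)
    return etree.tostring(root)


class TestMandatoryBruteForce:
    def test_each_mandatory_deletion_invalidates(self, full_manifest):
        document = to_xml(full_manifest)
        outcomes = {
            part: validate_manifest(_delete_part(document, part)).valid
            for part, _ in TOP_LEVEL_PARTS
        }
        invalid = {part for part, ok in outcomes.items() if not ok}
        assert invalid == {p for p, mandatory in TOP_LEVEL_PARTS if mandatory}

    def test_optional_deletions_stay_schema_valid(self, full_manifest):
        document = to_xml(full_manifest)
        for part, mandatory in TOP_LEVEL_PARTS:
            errors = validate_against_schema(_delete_part(document, part))
            assert bool(errors) == mandatory, part


class TestRules:
    def test_valid_built_manifests_have_zero_errors(self, small_store):
        for entry in small_store:
            report = validate_manifest(entry.manifest)
            assert report.valid, report.to_text()

    def test_malformed_email_reported_at_contact(self, full_manifest):
        root = etree.fromstring(to_xml(full_manifest).encode())
        root.find(f"{{{NS}}}Contact").text = "no-at-sign"
        report = validate_manifest(etree.tostring(root))
        assert not report.valid
        assert [(v.ruleId, v.path) for v in report.errors] == [
            ("E.CONTACT_SYNTAX", "Contact")
        ]

    def test_unit_type_outside_enumeration(self, full_manifest):
        root = etree.fromstring(to_xml(full_manifest).encode())
        root.set("unitType", "Experiment")
        report = validate_manifest(etree.tostring(root))
        assert any(v.ruleId == "E.UNIT_TYPE" for v in report.errors)

    def test_release_before_creation(self, full_manifest):
        root = etree.fromstring(to_xml(full_manifest).encode())
        root.find(f"{{{NS}}}Date/{{{NS}}}ReleaseDate").text = "2010-01-01"
        report = validate_manifest(etree.tostring(root))
        assert any(v.ruleId == "E.DATE_ORDER" for v in report.errors)

    def test_bad_media_type(self, full_manifest):
        root = etree.fromstring(to_xml(full_manifest).encode())
        root.find(f"{{{NS}}}Content/{{{NS}}}ContentItem/{{{NS}}}DataType").text = "plain"
        report = validate_manifest(etree.tostring(root))
        assert any(v.ruleId == "E.MEDIA_TYPE" for v in report.errors)

    def test_publication_without_doi_warns_only(self, full_manifest):
        root = etree.fromstring(to_xml(full_manifest).encode())
        root.find(
            f"{{{NS}}}RelatedItems/{{{NS}}}RelatedItem/{{{NS}}}Id"
        ).text = "our earlier blog post"
        report = validate_manifest(etree.tostring(root))
        assert report.valid
        assert any(v.ruleId == "W.DOI_PREFERRED" for v in report.warnings)

    @pytest.mark.parametrize("doi", [
        "10.5555/eln.2013.42",
        "doi:10.5555/eln.2013.42",
        "https://doi.org/10.5555/eln.2013.42",
    ])
    def test_doi_forms_recognised(self, doi, full_manifest):
        from dataclasses import replace
        from elnmanifest import RelatedItem
        m = replace(full_manifest, relatedItems=(RelatedItem("publication", doi),))
        assert not validate_manifest(m).warnings

    def test_empty_keywords_element_warns(self, full_manifest):
        root = etree.fromstring(to_xml(full_manifest).encode())
        kw = root.find(f"{{{NS}}}Keywords")
        for child in list(kw):
            kw.remove(child)
        report = validate_manifest(etree.tostring(root))
        assert any(v.ruleId == "W.EMPTY_KEYWORDS" for v in report.warnings)

    def test_unrecognized_role_warns(self, full_manifest):
        from dataclasses import replace
        from elnmanifest import ContributorInformation
        m = replace(full_manifest, contributors=(
            ContributorInformation("Chief Alchemist", "Z. Zeta"),
        ))
        report = validate_manifest(m)
        assert report.valid
        assert any(v.ruleId == "W.ROLE_VOCAB" for v in report.warnings)

    def test_every_rule_id_in_catalogue(self, full_manifest):
        report = validate_manifest(full_manifest)
        assert all(v.ruleId in RULES for v in report.violations)

    def test_idempotent(self, full_manifest):
        assert validate_manifest(full_manifest) == validate_manifest(full_manifest)


class TestSchemaAgreement:
    """Any document the XSD rejects must also draw at least one rule error."""

    def _corruptions(self, document: str):
        for part, mandatory in TOP_LEVEL_PARTS:
            if mandatory:
                yield _delete_part(document, part)
        root = etree.fromstring(document.encode())
        root.set("unitType", "Workflow")
        yield etree.tostring(root)
        root = etree.fromstring(document.encode())
        root.find(f"{{{NS}}}Title").text = ""
        yield etree.tostring(root)
        root = etree.fromstring(document.encode())
        root.find(
            f"{{{NS}}}Content/{{{NS}}}ContentItem/{{{NS}}}DataType"
        ).text = "no-slash"
        yield etree.tostring(root)

    def test_xsd_rejection_implies_rule_error(self, small_store):
        checked = 0
        for entry in list(small_store)[:5]:
            for corrupt in self._corruptions(to_xml(entry.manifest)):
                if validate_against_schema(corrupt):
                    assert not validate_manifest(corrupt).valid
                    checked += 1
        assert checked >= 40
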