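"""XML serialization of the elnItemManifest and the Dublin Core crosswalk.

The manifest is written in a versioned XML dialect whose root element is
``elnItemManifest``.  Child order follows the layout of the metadata scheme
(Title, Keywords, Identifiers, Contact, LicensingBasis, Contributors, Source,
Date, RelatedItems, Content); the unit type travels as an attribute of the
root because it qualifies the manifest as a whole rather than being one of
its parts.  An XML Schema Definition shipped with the package
(``elnItemManifest-1.0.xsd``) captures everything about the dialect that XSD
1.0 can express; the semantic rules it cannot (mode-dependent contact syntax,
date ordering) are enforced on read and reported by the validation module.

Serialization is canonical: equal manifests produce byte-identical UTF-8
documents.  Foreign-namespace elements are tolerated on read (with a logged
warning) and never written, so third parties may extend instances without
breaking consumers of the core dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from importlib import resources
from typing import Optional, Union

from lxml import etree

from .schema_model import (
    ContactOption,
    ContentItem,
    ContributorInformation,
    DateSet,
    ElnItemManifest,
    IdentifierSet,
    ManifestError,
    RelatedItem,
    UnitType,
    ConstructionError,
)

__all__ = [
    "XmlDialect",
    "DEFAULT_DIALECT",
    "XmlParseError",
    "XmlValidationError",
    "to_xml",
    "from_xml",
    "validate_against_schema",
    "schema_path",
    "dc_crosswalk",
    "dc_to_json",
    "dc_to_xml",
    "DCMES_ELEMENTS",
]

logger = logging.getLogger("elnmanifest")

_SCHEMA_FILENAME = "elnItemManifest-1.0.xsd"


@dataclass(frozen=True)
class XmlDialect:
    """Namespace + version identifying one revision of the XML dialect."""

    namespaceUri: str = "urn:elnmanifest:schema:1.0"
    schemaVersion: str = "1.0"
    rootElementName: str = "elnItemManifest"

    def __post_init__(self):
        if self.rootElementName != "elnItemManifest":
            raise ManifestError("root element name is fixed as 'elnItemManifest'")


DEFAULT_DIALECT = XmlDialect()


class XmlParseError(ManifestError):
    """Document is not well-formed XML."""


class XmlValidationError(ManifestError):
    """Document is well-formed but violates the dialect.

    ``paths`` lists the element paths of the offending parts.
    """

    def __init__(self, message: str, paths: tuple[str, ...] = ()):
        self.paths = paths
        detail = f" [{'; '.join(paths)}]" if paths else ""
        super().__init__(message + detail)


# --------------------------------------------------------------------------
# Schema access
# --------------------------------------------------------------------------

def schema_path() -> str:
    """Filesystem path of the shipped XSD."""
    return str(resources.files(__package__).joinpath(_SCHEMA_FILENAME))


_schema_cache: Optional[etree.XMLSchema] = None


def _schema() -> etree.XMLSchema:
    global _schema_cache
    if _schema_cache is None:
        with resources.files(__package__).joinpath(_SCHEMA_FILENAME).open("rb") as fh:
            _schema_cache = etree.XMLSchema(etree.parse(fh))
    return _schema_cache


def validate_against_schema(document: Union[str, bytes, etree._Element]) -> list[str]:
    """Validate a document against the shipped XSD; return error messages."""
    root = _parse(document)
    schema = _schema()
    if schema.validate(root):
        return []
    return [f"{e.path}: {e.message}" for e in schema.error_log]


# --------------------------------------------------------------------------
# Writing
# --------------------------------------------------------------------------

def to_xml(manifest: ElnItemManifest, dialect: XmlDialect = DEFAULT_DIALECT) -> str:
    """Serialize a manifest to a canonical UTF-8 XML document.

    The manifest is re-validated first; a manifest with rule errors (possible
    only by tampering with a frozen instance) is refused with its report.
    """
    from .validation import validate_manifest  # late import: validation reads documents via this module

    report = validate_manifest(manifest)
    if not report.valid:
        raise XmlValidationError(
            "refusing to serialize an invalid manifest",
            tuple(v.path for v in report.violations if v.severity == "error"),
        )

    ns = dialect.namespaceUri
    q = lambda name: f"{{{ns}}}{name}"
    root = etree.Element(q(dialect.rootElementName), nsmap={None: ns})
    root.set("unitType", manifest.unitType.value)
    root.set("schemaVersion", dialect.schemaVersion)

    etree.SubElement(root, q("Title")).text = manifest.title
    if manifest.keywords:
        kws = etree.SubElement(root, q("Keywords"))
        for kw in manifest.keywords:
            etree.SubElement(kws, q("Keyword")).text = kw
    ids = etree.SubElement(root, q("Identifiers"))
    etree.SubElement(ids, q("PrimaryLocalIdentifier")).text = (
        manifest.identifiers.primaryLocalIdentifier
    )
    for other in manifest.identifiers.otherLocalIdentifiers:
        etree.SubElement(ids, q("OtherLocalIdentifier")).text = other
    if manifest.identifiers.accessIdentifier is not None:
        etree.SubElement(ids, q("AccessIdentifier")).text = manifest.identifiers.accessIdentifier
    contact = etree.SubElement(root, q("Contact"))
    contact.set("mode", manifest.contact.mode.value)
    contact.text = manifest.contact.value
    if manifest.licensingBasis is not None:
        etree.SubElement(root, q("LicensingBasis")).text = manifest.licensingBasis
    contribs = etree.SubElement(root, q("Contributors"))
    for c in manifest.contributors:
        ci = etree.SubElement(contribs, q("ContributorInformation"))
        etree.SubElement(ci, q("Role")).text = c.role
        etree.SubElement(ci, q("Name")).text = c.name
        for ident in c.identifiers:
            etree.SubElement(ci, q("Identifier")).text = ident
    etree.SubElement(root, q("Source")).text = manifest.source
    dates = etree.SubElement(root, q("Date"))
    etree.SubElement(dates, q("CreationDate")).text = manifest.dates.creationDate.isoformat()
    for name, value in (
        ("ReleaseDate", manifest.dates.releaseDate),
        ("PublicationDate", manifest.dates.publicationDate),
        ("SubmissionDate", manifest.dates.submissionDate),
    ):
        if value is not None:
            etree.SubElement(dates, q(name)).text = value.isoformat()
    if manifest.relatedItems:
        rel = etree.SubElement(root, q("RelatedItems"))
        for item in manifest.relatedItems:
            ri = etree.SubElement(rel, q("RelatedItem"))
            etree.SubElement(ri, q("Relationship")).text = item.relationship
            etree.SubElement(ri, q("Id")).text = item.id
    cont = etree.SubElement(root, q("Content"))
    for item in manifest.content:
        ci = etree.SubElement(cont, q("ContentItem"))
        etree.SubElement(ci, q("Description")).text = item.description
        etree.SubElement(ci, q("DataType")).text = item.dataType
        if item.locator is not None:
            etree.SubElement(ci, q("Locator")).text = item.locator

    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")


# --------------------------------------------------------------------------
# Reading
# --------------------------------------------------------------------------

def _parse(document: Union[str, bytes, etree._Element]) -> etree._Element:
    if isinstance(document, etree._Element):
        return document
    if isinstance(document, str):
        document = document.encode("utf-8")
    try:
        return etree.fromstring(document)
    except etree.XMLSyntaxError as exc:
        raise XmlParseError(f"not well-formed XML: {exc}") from exc


def _date(text: str, path: str) -> date:
    # xs:date allows an optional timezone suffix; the calendar day is the
    # first ten characters.
    try:
        return date.fromisoformat(text.strip()[:10])
    except ValueError as exc:
        raise XmlValidationError(f"invalid date {text!r}", (path,)) from exc


def from_xml(
    document: Union[str, bytes, etree._Element],
    dialect: XmlDialect = DEFAULT_DIALECT,
) -> ElnItemManifest:
    """Parse and validate an elnItemManifest document into the typed model.

    The document must be well-formed, schema-valid against the shipped XSD,
    and satisfy the semantic rules the XSD cannot express.  Unknown elements
    in the dialect namespace are rejected by the schema; elements in foreign
    namespaces are ignored with a logged warning.  An ``OtherLocalIdentifier``
    equal to the primary identifier is dropped with a warning (the writer
    never produces one).
    """
    root = _parse(document)
    ns = dialect.namespaceUri
    expected = f"{{{ns}}}{dialect.rootElementName}"
    if root.tag != expected:
        raise XmlValidationError(
            f"root element is {root.tag!r}, expected {expected!r}", ("/",)
        )
    errors = validate_against_schema(root)
    if errors:
        raise XmlValidationError("document does not conform to the schema", tuple(errors))

    for el in root.iter():
        if isinstance(el.tag, str) and not el.tag.startswith(f"{{{ns}}}"):
            logger.warning("ignoring foreign-namespace element %s", el.tag)

    def children(parent, name):
        return parent.findall(f"{{{ns}}}{name}")

    def child(parent, name):
        found = children(parent, name)
        return found[0] if found else None

    def text(el) -> str:
        return (el.text or "").strip()

    title = text(child(root, "Title"))
    kw_el = child(root, "Keywords")
    keywords = tuple(text(k) for k in children(kw_el, "Keyword")) if kw_el is not None else ()

    ids_el = child(root, "Identifiers")
    primary = text(child(ids_el, "PrimaryLocalIdentifier"))
    others = []
    for other in children(ids_el, "OtherLocalIdentifier"):
        value = text(other)
        if value == primary:
            logger.warning("dropping OtherLocalIdentifier duplicating the primary identifier")
        else:
            others.append(value)
    access_el = child(ids_el, "AccessIdentifier")
    identifiers = IdentifierSet(
        primaryLocalIdentifier=primary,
        otherLocalIdentifiers=tuple(others),
        accessIdentifier=text(access_el) if access_el is not None else None,
    )

    contact_el = child(root, "Contact")
    try:
        contact = ContactOption(contact_el.get("mode"), text(contact_el))
    except ConstructionError as exc:
        raise XmlValidationError(str(exc), (exc.path,)) from exc

    license_el = child(root, "LicensingBasis")
    contributors = tuple(
        ContributorInformation(
            role=text(child(ci, "Role")) if child(ci, "Role") is not None else "",
            name=text(child(ci, "Name")),
            identifiers=tuple(text(i) for i in children(ci, "Identifier")),
        )
        for ci in children(child(root, "Contributors"), "ContributorInformation")
    )
    source = text(child(root, "Source"))

    date_el = child(root, "Date")
    opt_date = lambda name: (
        _date(text(child(date_el, name)), f"Date/{name}")
        if child(date_el, name) is not None else None
    )
    try:
        dates = DateSet(
            creationDate=_date(text(child(date_el, "CreationDate")), "Date/CreationDate"),
            releaseDate=opt_date("ReleaseDate"),
            publicationDate=opt_date("PublicationDate"),
            submissionDate=opt_date("SubmissionDate"),
        )
    except ConstructionError as exc:
        raise XmlValidationError(str(exc), (exc.path,)) from exc

    rel_el = child(root, "RelatedItems")
    related = tuple(
        RelatedItem(text(child(ri, "Relationship")), text(child(ri, "Id")))
        for ri in children(rel_el, "RelatedItem")
    ) if rel_el is not None else ()

    content = tuple(
        ContentItem(
            description=text(child(ci, "Description")),
            dataType=text(child(ci, "DataType")),
            locator=text(child(ci, "Locator")) if child(ci, "Locator") is not None else None,
        )
        for ci in children(child(root, "Content"), "ContentItem")
    )

    try:
        return ElnItemManifest(
            unitType=UnitType.coerce(root.get("unitType")),
            title=title,
            identifiers=identifiers,
            contact=contact,
            contributors=contributors,
            source=source,
            dates=dates,
            content=content,
            keywords=keywords,
            licensingBasis=text(license_el) if license_el is not None else None,
            relatedItems=related,
        )
    except ConstructionError as exc:
        raise XmlValidationError(str(exc), (exc.path,)) from exc


# --------------------------------------------------------------------------
# Dublin Core crosswalk
# --------------------------------------------------------------------------

#: The 15 elements of the Dublin Core Metadata Element Set.
DCMES_ELEMENTS = frozenset({
    "title", "creator", "subject", "description", "publisher", "contributor",
    "date", "type", "format", "identifier", "source", "language", "relation",
    "coverage", "rights",
})


def dc_crosswalk(manifest: ElnItemManifest) -> list[tuple[str, str]]:
    """Project a manifest onto the 15-element Dublin Core element set.

    The mapping is fixed: title→title, keywords→subject, primary and access
    identifiers→identifier, contributors→creator (role Author) or contributor
    (any other role), licensingBasis→rights, source→source, the creation
    date→date, relatedItems→relation, content media types→format and the
    unit type→type.  Values are carried over verbatim (dates as their ISO
    8601 string); no value is invented and nothing outside the 15 elements
    is ever emitted.  Element order follows the manifest's own field order.
    """
    pairs: list[tuple[str, str]] = [("title", manifest.title)]
    pairs += [("subject", kw) for kw in manifest.keywords]
    pairs.append(("identifier", manifest.identifiers.primaryLocalIdentifier))
    if manifest.identifiers.accessIdentifier is not None:
        pairs.append(("identifier", manifest.identifiers.accessIdentifier))
    for c in manifest.contributors:
        element = "creator" if c.role.strip().lower() == "author" else "contributor"
        pairs.append((element, c.name))
    if manifest.licensingBasis is not None:
        pairs.append(("rights", manifest.licensingBasis))
    pairs.append(("source", manifest.source))
    pairs.append(("date", manifest.dates.creationDate.isoformat()))
    pairs += [("relation", item.id) for item in manifest.relatedItems]
    pairs += [("format", item.dataType) for item in manifest.content]
    pairs.append(("type", manifest.unitType.value))
    return pairs


def dc_to_json(pairs: list[tuple[str, str]]) -> dict[str, list[str]]:
    """Group crosswalk pairs into a JSON-friendly element→values mapping."""
    out: dict[str, list[str]] = {}
    for element, value in pairs:
        out.setdefault(element, []).append(value)
    return out


_DC_NS = "http://purl.org/dc/elements/1.1/"


def dc_to_xml(pairs: list[tuple[str, str]]) -> str:
    """Render crosswalk pairs as a flat ``dc``-namespaced XML record."""
    root = etree.Element("record", nsmap={"dc": _DC_NS})
    for element, value in pairs:
        etree.SubElement(root, f"{{{_DC_NS}}}{element}").text = value
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")
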