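"""Rule-based semantic validation of manifests.

Validation never throws on bad content: every problem becomes a
:class:`Violation` with a rule id, a severity, an element path and a
human-readable message, collected into a :class:`ValidationReport`.  Errors
mark violations of the metadata scheme itself (a missing mandatory part, a
malformed contact address, an embargo that ends before the record was
created); warnings flag departures from recommended practice (a publication
related-item whose id is not a DOI, an unrecognised contributor role) that
do not make the record unusable.

The same rule set runs on typed :class:`ElnItemManifest` instances and on
parsed XML documents, so a document that fails XSD validation can still be
diagnosed element by element.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date
from typing import Any, Optional, Union

from lxml import etree

from . import xml_io
from .schema_model import (
    ContactMode,
    ElnItemManifest,
    UnitType,
    is_absolute_uri,
    is_email,
    is_media_type,
)

__all__ = ["Violation", "ValidationReport", "validate_manifest", "RULES"]


#: The documented rule catalogue: every Violation.ruleId appears here.
RULES: dict[str, str] = {
    "E.MANDATORY": "a mandatory element is missing or empty",
    "E.UNIT_TYPE": "unitType is outside {Package, Record, Component}",
    "E.CONTACT_MODE": "contact mode is outside {EMail, SystemURI, Instruction}",
    "E.CONTACT_SYNTAX": "contact value malformed for the declared mode",
    "E.ACCESS_URI": "accessIdentifier (or a content locator) is not an absolute URI",
    "E.DATE_ORDER": "releaseDate precedes creationDate",
    "E.MEDIA_TYPE": "content dataType is not in type/subtype form",
    "W.DOI_PREFERRED": "a publication related-item id is not a DOI (DOI preferred)",
    "W.EMPTY_KEYWORDS": "Keywords element present but empty",
    "W.ROLE_VOCAB": "contributor role outside the commonly used set",
}

#: Roles the scheme's description names explicitly; anything else only warns,
#: because no controlled vocabulary has been agreed for contributor roles.
RECOGNIZED_ROLES = frozenset({"author", "pi", "principal investigator",
                              "funding body", "institution"})

_DOI_RE = re.compile(r"^(doi:|https?://(dx\.)?doi\.org/)?10\.\d{4,9}/\S+$", re.IGNORECASE)


def is_doi(value: str) -> bool:
    """Accepts bare ``10.x/y``, ``doi:10.x/y`` and ``https://doi.org/10.x/y``."""
    return bool(_DOI_RE.match(value.strip()))


@dataclass(frozen=True)
class Violation:
    ruleId: str
    severity: str  # "error" | "warning"
    path: str
    message: str

    def __post_init__(self):
        assert self.ruleId in RULES, f"undocumented rule id {self.ruleId}"
        assert self.severity in ("error", "warning")


@dataclass(frozen=True)
class ValidationReport:
    violations: tuple[Violation, ...]
    valid: bool = field(init=False)

    def __post_init__(self):
        object.__setattr__(
            self, "valid", not any(v.severity == "error" for v in self.violations)
        )

    @property
    def errors(self) -> tuple[Violation, ...]:
        return tuple(v for v in self.violations if v.severity == "error")

    @property
    def warnings(self) -> tuple[Violation, ...]:
        return tuple(v for v in self.violations if v.severity == "warning")

    def to_dict(self) -> dict:
        return {
            "valid": self.valid,
            "violations": [
                {"ruleId": v.ruleId, "severity": v.severity,
                 "path": v.path, "message": v.message}
                for v in self.violations
            ],
        }

    def to_text(self) -> str:
        lines = [f"{'VALID' if self.valid else 'INVALID'} "
                 f"({len(self.errors)} error(s), {len(self.warnings)} warning(s))"]
        lines += [f"  [{v.severity}] {v.ruleId} at {v.path}: {v.message}"
                  for v in self.violations]
        return "\n".join(lines)


# --------------------------------------------------------------------------
# Raw intermediate form
# --------------------------------------------------------------------------
# Rules run over a loose dict so that documents too broken to become typed
# manifests can still be diagnosed.  ``None`` means "element absent"; an
# empty list means "element present but empty".

def _manifest_to_raw(m: ElnItemManifest) -> dict[str, Any]:
    return {
        "unitType": m.unitType.value,
        "Title": m.title,
        "Keywords": list(m.keywords) if m.keywords else None,
        "Identifiers": {
            "primary": m.identifiers.primaryLocalIdentifier,
            "access": m.identifiers.accessIdentifier,
        },
        "Contact": {"mode": m.contact.mode.value, "value": m.contact.value},
        "Contributors": [{"role": c.role, "name": c.name} for c in m.contributors],
        "Source": m.source,
        "Date": {"creation": m.dates.creationDate, "release": m.dates.releaseDate},
        "RelatedItems": [
            {"relationship": r.relationship, "id": r.id} for r in m.relatedItems
        ] or None,
        "Content": [
            {"description": c.description, "dataType": c.dataType, "locator": c.locator}
            for c in m.content
        ],
    }


def _element_to_raw(root: etree._Element) -> dict[str, Any]:
    ns = xml_io.DEFAULT_DIALECT.namespaceUri

    def child(parent, name):
        found = parent.findall(f"{{{ns}}}{name}") if parent is not None else []
        return found[0] if found else None

    def children(parent, name):
        return parent.findall(f"{{{ns}}}{name}") if parent is not None else []

    def text(el) -> Optional[str]:
        return (el.text or "").strip() if el is not None else None

    def parse_date(el) -> Optional[Any]:
        if el is None:
            return None
        try:
            return date.fromisoformat((el.text or "").strip()[:10])
        except ValueError:
            return (el.text or "").strip()  # left as string; ordering rule skips it

    raw: dict[str, Any] = {"unitType": root.get("unitType"), "Title": text(child(root, "Title"))}
    kw = child(root, "Keywords")
    raw["Keywords"] = [text(k) for k in children(kw, "Keyword")] if kw is not None else None
    ids = child(root, "Identifiers")
    raw["Identifiers"] = None if ids is None else {
        "primary": text(child(ids, "PrimaryLocalIdentifier")),
        "access": text(child(ids, "AccessIdentifier")),
    }
    contact = child(root, "Contact")
    raw["Contact"] = None if contact is None else {
        "mode": contact.get("mode"), "value": text(contact),
    }
    raw["Contributors"] = None
    contribs = child(root, "Contributors")
    if contribs is not None:
        raw["Contributors"] = [
            {"role": text(child(ci, "Role")) or "", "name": text(child(ci, "Name")) or ""}
            for ci in children(contribs, "ContributorInformation")
        ]
    raw["Source"] = text(child(root, "Source"))
    dates = child(root, "Date")
    raw["Date"] = None if dates is None else {
        "creation": parse_date(child(dates, "CreationDate")),
        "release": parse_date(child(dates, "ReleaseDate")),
    }
    rel = child(root, "RelatedItems")
    raw["RelatedItems"] = None if rel is None else [
        {"relationship": text(child(ri, "Relationship")) or "",
         "id": text(child(ri, "Id")) or ""}
        for ri in children(rel, "RelatedItem")
    ]
    cont = child(root, "Content")
    raw["Content"] = None if cont is None else [
        {"description": text(child(ci, "Description")) or "",
         "dataType": text(child(ci, "DataType")) or "",
         "locator": text(child(ci, "Locator"))}
        for ci in children(cont, "ContentItem")
    ]
    return raw


# --------------------------------------------------------------------------
# The rules
# --------------------------------------------------------------------------

def _check(raw: dict[str, Any]) -> list[Violation]:
    out: list[Violation] = []
    err = lambda rule, path, msg: out.append(Violation(rule, "error", path, msg))
    warn = lambda rule, path, msg: out.append(Violation(rule, "warning", path, msg))

    if not raw.get("unitType"):
        err("E.MANDATORY", "unitType", "unitType attribute is missing")
    elif raw["unitType"] not in {u.value for u in UnitType}:
        err("E.UNIT_TYPE", "unitType",
            f"{raw['unitType']!r} is not one of Package, Record, Component")

    if not raw.get("Title"):
        err("E.MANDATORY", "Title", "Title is missing or empty")

    if raw.get("Keywords") is not None and not any(raw["Keywords"]):
        warn("W.EMPTY_KEYWORDS", "Keywords", "Keywords element carries no keywords")

    ids = raw.get("Identifiers")
    if ids is None or not ids.get("primary"):
        err("E.MANDATORY", "Identifiers/PrimaryLocalIdentifier",
            "primary local identifier is missing or empty")
    elif ids.get("access") and not is_absolute_uri(ids["access"]):
        err("E.ACCESS_URI", "Identifiers/AccessIdentifier",
            f"{ids['access']!r} is not an absolute URI")

    contact = raw.get("Contact")
    if contact is None or not contact.get("value"):
        err("E.MANDATORY", "Contact", "Contact is missing or empty")
    else:
        mode, value = contact.get("mode"), contact["value"]
        if mode not in {m.value for m in ContactMode}:
            err("E.CONTACT_MODE", "Contact",
                f"mode {mode!r} is not one of EMail, SystemURI, Instruction")
        elif mode == ContactMode.EMAIL.value and not is_email(value):
            err("E.CONTACT_SYNTAX", "Contact",
                f"{value!r} is not an e-mail address (mode=EMail)")
        elif mode == ContactMode.SYSTEM_URI.value and not is_absolute_uri(value):
            err("E.CONTACT_SYNTAX", "Contact",
                f"{value!r} is not an absolute URI (mode=SystemURI)")

    contribs = raw.get("Contributors")
    if not contribs:
        err("E.MANDATORY", "Contributors", "at least one contributor is required")
    else:
        for i, c in enumerate(contribs):
            path = f"Contributors/ContributorInformation[{i + 1}]"
            if not c.get("name"):
                err("E.MANDATORY", f"{path}/Name", "contributor name is empty")
            role = (c.get("role") or "").strip()
            if role and role.lower() not in RECOGNIZED_ROLES:
                warn("W.ROLE_VOCAB", f"{path}/Role",
                     f"role {role!r} is outside the commonly used set "
                     "(Author, PI, Funding Body, institution)")

    if not raw.get("Source"):
        err("E.MANDATORY", "Source", "Source is missing or empty")

    dates = raw.get("Date")
    if dates is None or not dates.get("creation"):
        err("E.MANDATORY", "Date/CreationDate", "creation date is missing")
    else:
        creation, release = dates["creation"], dates.get("release")
        if (isinstance(creation, date) and isinstance(release, date)
                and release < creation):
            err("E.DATE_ORDER", "Date/ReleaseDate",
                f"release {release.isoformat()} precedes creation {creation.isoformat()}")

    for i, item in enumerate(raw.get("RelatedItems") or []):
        if (item.get("relationship", "").strip().lower() == "publication"
                and item.get("id") and not is_doi(item["id"])):
            warn("W.DOI_PREFERRED", f"RelatedItems/RelatedItem[{i + 1}]/Id",
                 f"{item['id']!r} is not a DOI; DOIs are preferred for publications")

    content = raw.get("Content")
    if not content:
        err("E.MANDATORY", "Content", "at least one content item is required")
    else:
        for i, item in enumerate(content):
            path = f"Content/ContentItem[{i + 1}]"
            if not item.get("description"):
                err("E.MANDATORY", f"{path}/Description", "description is empty")
            if not is_media_type(item.get("dataType") or ""):
                err("E.MEDIA_TYPE", f"{path}/DataType",
                    f"{item.get('dataType')!r} is not in type/subtype form")
            if item.get("locator") and not is_absolute_uri(item["locator"]):
                err("E.ACCESS_URI", f"{path}/Locator",
                    f"{item['locator']!r} is not an absolute URI")

    return out


def validate_manifest(
    obj: Union[ElnItemManifest, etree._Element, str, bytes, dict],
) -> ValidationReport:
    """Run the full rule catalogue; problems are reported, never raised.

    Accepts a typed manifest, a parsed or textual XML document, or the loose
    dict form used internally.  Validation is pure and idempotent: the same
    input always yields the same report.
    """
    if isinstance(obj, ElnItemManifest):
        raw = _manifest_to_raw(obj)
    elif isinstance(obj, etree._Element):
        raw = _element_to_raw(obj)
    elif isinstance(obj, (str, bytes)):
        raw = _element_to_raw(xml_io._parse(obj))
    elif isinstance(obj, dict):
        raw = obj
    else:
        raise TypeError(f"cannot validate object of type {type(obj).__name__}")
    return ValidationReport(tuple(_check(raw)))
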