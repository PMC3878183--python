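"""Typed in-memory model of the elnItemManifest.

The elnItemManifest is a compact, machine-readable metadata description of one
unit held in an Electronic Laboratory Notebook (ELN): a whole package of
records, a single record, or a component of a record such as a spectrum.  It
plays the role of the *knowledge layer* in a three-tier metadata architecture
(knowledge / information / processing): enough information for a person or a
harvesting agent to decide whether the unit is of interest, who to contact,
under what license it is available, and what kinds of content it carries.

Every structure here is a frozen dataclass with its invariants checked at
construction time, so equality is structural and an instance that exists is
valid by construction.  Mandatory parts of a manifest are: unit type, title,
identifiers, contact, contributors, source, dates (at least a creation date)
and a non-empty content list.  Keywords, licensing basis, related items, the
access identifier and the three non-creation dates are optional.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from typing import Iterable, Optional, Sequence, Union

from dateutil.relativedelta import relativedelta

__all__ = [
    "UnitType",
    "ContactMode",
    "IdentifierSet",
    "ContactOption",
    "ContributorInformation",
    "DateSet",
    "RelatedItem",
    "ContentItem",
    "ElnItemManifest",
    "ManifestError",
    "ConstructionError",
    "build_manifest",
    "parse_duration",
    "compute_release_date",
    "is_absolute_uri",
    "is_email",
    "is_media_type",
    "MANDATORY_PARTS",
    "OPTIONAL_PARTS",
]


# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------

class ManifestError(ValueError):
    """Base class for all manifest-layer errors."""


class ConstructionError(ManifestError):
    """Raised when a manifest (or part) cannot be built.

    ``path`` is the element path of the offending part, using the canonical
    XML element names (e.g. ``"Identifiers/AccessIdentifier"``).
    """

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


# --------------------------------------------------------------------------
# Syntactic helpers
# --------------------------------------------------------------------------

# scheme ":" hier-part — we require a scheme and a non-empty remainder.
_URI_RE = re.compile(r"^[A-Za-z][A-Za-z0-9+.\-]*:\S+$")
# addr-spec, deliberately loose: one "@", non-empty local and domain parts.
_EMAIL_RE = re.compile(r"^[^@\s]+@[^@\s]+$")
# IANA type/subtype; tokens per RFC 6838 restricted-name characters.
_MEDIA_RE = re.compile(r"^[A-Za-z0-9][A-Za-z0-9!#$&^_.+\-]*/[A-Za-z0-9][A-Za-z0-9!#$&^_.+\-]*$")


def is_absolute_uri(value: str) -> bool:
    """True if ``value`` has the shape of an absolute URI (scheme + rest)."""
    return bool(_URI_RE.match(value))


def is_email(value: str) -> bool:
    """Syntactic addr-spec check: exactly one ``@`` with non-empty sides."""
    return bool(_EMAIL_RE.match(value))


def is_media_type(value: str) -> bool:
    """True if ``value`` is in IANA ``type/subtype`` form."""
    return bool(_MEDIA_RE.match(value))


# --------------------------------------------------------------------------
# Enumerations
# --------------------------------------------------------------------------

class UnitType(Enum):
    """Nature of the described unit: many records, one record, or a part."""

    PACKAGE = "Package"
    RECORD = "Record"
    COMPONENT = "Component"

    @classmethod
    def coerce(cls, value: Union["UnitType", str], path: str = "unitType") -> "UnitType":
        if isinstance(value, cls):
            return value
        for member in cls:
            if member.value == value:
                return member
        raise ConstructionError(
            path,
            f"unitType must be one of {[m.value for m in cls]}, got {value!r}",
        )


class ContactMode(Enum):
    """How the contact value is to be interpreted."""

    EMAIL = "EMail"
    SYSTEM_URI = "SystemURI"
    INSTRUCTION = "Instruction"

    @classmethod
    def coerce(cls, value: Union["ContactMode", str], path: str = "Contact") -> "ContactMode":
        if isinstance(value, cls):
            return value
        for member in cls:
            if member.value == value:
                return member
        raise ConstructionError(
            path, f"contact mode must be one of {[m.value for m in cls]}, got {value!r}"
        )


# --------------------------------------------------------------------------
# Component structures
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IdentifierSet:
    """Handles locating the record in (and beyond) the originating system.

    ``primaryLocalIdentifier`` uniquely locates the record in the originating
    ELN; it may be any string, commonly a URL or an experiment ID.
    ``accessIdentifier``, when present, must be an absolute ("linked data")
    URI giving open access to the content.
    """

    primaryLocalIdentifier: str
    otherLocalIdentifiers: tuple[str, ...] = ()
    accessIdentifier: Optional[str] = None

    def __post_init__(self):
        if not self.primaryLocalIdentifier or not self.primaryLocalIdentifier.strip():
            raise ConstructionError(
                "Identifiers/PrimaryLocalIdentifier", "must be non-empty"
            )
        object.__setattr__(self, "otherLocalIdentifiers", tuple(self.otherLocalIdentifiers))
        if self.primaryLocalIdentifier in self.otherLocalIdentifiers:
            raise ConstructionError(
                "Identifiers/OtherLocalIdentifier",
                "must not duplicate the primaryLocalIdentifier",
            )
        if self.accessIdentifier is not None and not is_absolute_uri(self.accessIdentifier):
            raise ConstructionError(
                "Identifiers/AccessIdentifier",
                f"must be an absolute URI, got {self.accessIdentifier!r}",
            )


@dataclass(frozen=True)
class ContactOption:
    """Who or what to contact for more information about the record."""

    mode: ContactMode
    value: str

    def __post_init__(self):
        object.__setattr__(self, "mode", ContactMode.coerce(self.mode))
        if not self.value or not self.value.strip():
            raise ConstructionError("Contact", "contact value must be non-empty")
        if self.mode is ContactMode.EMAIL and not is_email(self.value):
            raise ConstructionError(
                "Contact", f"mode=EMail requires an addr-spec value, got {self.value!r}"
            )
        if self.mode is ContactMode.SYSTEM_URI and not is_absolute_uri(self.value):
            raise ConstructionError(
                "Contact", f"mode=SystemURI requires an absolute URI, got {self.value!r}"
            )


@dataclass(frozen=True)
class ContributorInformation:
    """One contributory person or organisation (Author, PI, Funding Body...).

    ``role`` is free text — the community has no agreed controlled vocabulary
    yet, so unusual roles are merely warned about at validation time.
    """

    role: str
    name: str
    identifiers: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.name or not self.name.strip():
            raise ConstructionError("Contributors/ContributorInformation/Name", "must be non-empty")
        object.__setattr__(self, "identifiers", tuple(self.identifiers))


@dataclass(frozen=True)
class DateSet:
    """Datestamps: creation (mandatory), embargo end, publication, submission."""

    creationDate: date
    releaseDate: Optional[date] = None
    publicationDate: Optional[date] = None
    submissionDate: Optional[date] = None

    def __post_init__(self):
        if not isinstance(self.creationDate, date):
            raise ConstructionError("Date/CreationDate", "must be a calendar date")
        if self.releaseDate is not None and self.releaseDate < self.creationDate:
            raise ConstructionError(
                "Date/ReleaseDate",
                f"{self.releaseDate.isoformat()} precedes creationDate "
                f"{self.creationDate.isoformat()}",
            )


@dataclass(frozen=True)
class RelatedItem:
    """A related item; the id may be any string, DOI preferred for publications."""

    relationship: str
    id: str

    def __post_init__(self):
        if not self.relationship or not self.relationship.strip():
            raise ConstructionError("RelatedItems/RelatedItem/Relationship", "must be non-empty")
        if not self.id or not self.id.strip():
            raise ConstructionError("RelatedItems/RelatedItem/Id", "must be non-empty")


@dataclass(frozen=True)
class ContentItem:
    """One item of content: human-readable description, media type, locator.

    The content list is the access point to the processing layer: an agent
    interested in a particular media type can decide from the manifest alone
    whether to fetch and process the record.
    """

    description: str
    dataType: str
    locator: Optional[str] = None

    def __post_init__(self):
        if not self.description or not self.description.strip():
            raise ConstructionError("Content/ContentItem/Description", "must be non-empty")
        if not is_media_type(self.dataType):
            raise ConstructionError(
                "Content/ContentItem/DataType",
                f"must be an IANA type/subtype media type, got {self.dataType!r}",
            )
        if self.locator is not None and not is_absolute_uri(self.locator):
            raise ConstructionError(
                "Content/ContentItem/Locator",
                f"must be an absolute URI, got {self.locator!r}",
            )


# --------------------------------------------------------------------------
# The manifest itself
# --------------------------------------------------------------------------

#: Canonical names of the eight mandatory top-level parts, in document order.
MANDATORY_PARTS = (
    "unitType", "Title", "Identifiers", "Contact",
    "Contributors", "Source", "Date", "Content",
)

#: Optional parts a manifest may omit entirely.
OPTIONAL_PARTS = ("Keywords", "LicensingBasis", "RelatedItems", "AccessIdentifier")


@dataclass(frozen=True)
class ElnItemManifest:
    """The full knowledge-layer metadata record for one ELN unit."""

    unitType: UnitType
    title: str
    identifiers: IdentifierSet
    contact: ContactOption
    contributors: tuple[ContributorInformation, ...]
    source: str
    dates: DateSet
    content: tuple[ContentItem, ...]
    keywords: tuple[str, ...] = ()
    licensingBasis: Optional[str] = None
    relatedItems: tuple[RelatedItem, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "unitType", UnitType.coerce(self.unitType))
        title = self.title.strip() if isinstance(self.title, str) else ""
        if not title:
            raise ConstructionError("Title", "must be a non-empty string")
        object.__setattr__(self, "title", title)
        object.__setattr__(self, "contributors", tuple(self.contributors))
        if not self.contributors:
            raise ConstructionError("Contributors", "at least one contributor is required")
        if not self.source or not self.source.strip():
            raise ConstructionError("Source", "must be non-empty")
        object.__setattr__(self, "content", tuple(self.content))
        if not self.content:
            raise ConstructionError("Content", "at least one content item is required")
        # keywords: trimmed, case-sensitively deduplicated, order-preserving
        seen: dict[str, None] = {}
        for kw in self.keywords:
            kw = kw.strip()
            if kw and kw not in seen:
                seen[kw] = None
        object.__setattr__(self, "keywords", tuple(seen))
        object.__setattr__(self, "relatedItems", tuple(self.relatedItems))


# --------------------------------------------------------------------------
# Construction helper
# --------------------------------------------------------------------------

def _coerce_contact(value) -> ContactOption:
    if isinstance(value, ContactOption):
        return value
    if isinstance(value, (tuple, list)) and len(value) == 2:
        return ContactOption(ContactMode.coerce(value[0]), value[1])
    raise ConstructionError("Contact", f"cannot interpret {value!r} as a contact option")


def _coerce_contributor(value) -> ContributorInformation:
    if isinstance(value, ContributorInformation):
        return value
    if isinstance(value, (tuple, list)) and len(value) in (2, 3):
        ids = tuple(value[2]) if len(value) == 3 else ()
        return ContributorInformation(value[0], value[1], ids)
    raise ConstructionError(
        "Contributors", f"cannot interpret {value!r} as contributor information"
    )


def _coerce_content(value) -> ContentItem:
    if isinstance(value, ContentItem):
        return value
    if isinstance(value, (tuple, list)) and len(value) in (2, 3):
        loc = value[2] if len(value) == 3 else None
        return ContentItem(value[0], value[1], loc)
    raise ConstructionError("Content", f"cannot interpret {value!r} as a content item")


def build_manifest(
    *,
    unitType: Union[UnitType, str, None] = None,
    title: Optional[str] = None,
    identifiers: Union[IdentifierSet, str, None] = None,
    contact: Union[ContactOption, tuple, None] = None,
    contributors: Optional[Sequence] = None,
    source: Optional[str] = None,
    dates: Union[DateSet, date, None] = None,
    content: Optional[Sequence] = None,
    keywords: Optional[Iterable[str]] = None,
    licensingBasis: Optional[str] = None,
    relatedItems: Optional[Sequence] = None,
) -> ElnItemManifest:
    """Build a manifest from loosely typed keyword fields.

    Mandatory fields are ``unitType``, ``title``, ``identifiers``, ``contact``,
    ``contributors``, ``source``, ``dates`` and ``content``; a missing one
    raises :class:`ConstructionError` naming the field.  Convenience
    coercions: a bare string for ``identifiers`` becomes the primary local
    identifier, a bare :class:`datetime.date` for ``dates`` becomes the
    creation date, and ``(mode, value)`` / ``(role, name)`` /
    ``(description, dataType[, locator])`` tuples stand in for the component
    dataclasses.  Values are otherwise passed through untouched apart from
    whitespace trimming of the title and keywords.
    """
    missing = [
        name for name, val in [
            ("unitType", unitType), ("Title", title), ("Identifiers", identifiers),
            ("Contact", contact), ("Contributors", contributors), ("Source", source),
            ("Date", dates), ("Content", content),
        ] if val is None
    ]
    if missing:
        raise ConstructionError(missing[0], f"mandatory field(s) missing: {', '.join(missing)}")

    if isinstance(identifiers, str):
        identifiers = IdentifierSet(identifiers)
    if isinstance(dates, date):
        dates = DateSet(dates)
    return ElnItemManifest(
        unitType=UnitType.coerce(unitType),
        title=title,
        identifiers=identifiers,
        contact=_coerce_contact(contact),
        contributors=tuple(_coerce_contributor(c) for c in contributors),
        source=source,
        dates=dates,
        content=tuple(_coerce_content(c) for c in content),
        keywords=tuple(keywords) if keywords else (),
        licensingBasis=licensingBasis,
        relatedItems=tuple(
            RelatedItem(*r) if not isinstance(r, RelatedItem) else r
            for r in (relatedItems or ())
        ),
    )


# --------------------------------------------------------------------------
# Embargo arithmetic
# --------------------------------------------------------------------------

_DURATION_RE = re.compile(
    r"^P(?:(?P<years>\d+)Y)?(?:(?P<months>\d+)M)?(?:(?P<weeks>\d+)W)?(?:(?P<days>\d+)D)?$"
)


def parse_duration(text: str) -> relativedelta:
    """Parse an ISO 8601 date duration (``PnYnMnWnD``) into a relativedelta.

    Time components (``T...``) are not meaningful for embargo periods and are
    rejected, as are negative or empty durations.
    """
    if not isinstance(text, str) or text.startswith("-"):
        raise ManifestError(f"embargo duration must be a non-negative ISO 8601 string, got {text!r}")
    m = _DURATION_RE.match(text)
    if not m or text == "P":
        raise ManifestError(f"unparsable ISO 8601 date duration: {text!r}")
    parts = {k: int(v) for k, v in m.groupdict().items() if v is not None}
    return relativedelta(
        years=parts.get("years", 0),
        months=parts.get("months", 0),
        days=parts.get("days", 0) + 7 * parts.get("weeks", 0),
    )


def compute_release_date(base: date, embargo: Union[str, relativedelta]) -> date:
    """Advance ``base`` by an embargo period using calendar arithmetic.

    Month and year arithmetic clamps to the last valid day of the target
    month (e.g. 2013-08-31 plus six months is 2014-02-28), matching how
    repository embargoes are conventionally computed.
    """
    if isinstance(embargo, str):
        embargo = parse_duration(embargo)
    result = base + embargo
    if result < base:
        raise ManifestError("embargo period must not be negative")
    return result
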