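"""Deriving elnItemManifests from source ELN records.

Mirrors the two demonstrated integration styles: a blog-style ELN whose
records live at open permalink URLs (so the record URL doubles as both the
primary local identifier and an open-access link), and a commercial ELN
whose deposition plugin pulls most fields programmatically, reads contact
and contributor details from an editable site configuration file, and asks
the user for a licensing basis and an embargo period per deposition — the
release date is then computed from the record's creation date plus the
embargo.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Optional, Sequence, Union

from .schema_model import (
    ContactOption,
    ContactMode,
    ContentItem,
    ContributorInformation,
    DateSet,
    ElnItemManifest,
    IdentifierSet,
    ManifestError,
    RelatedItem,
    UnitType,
    compute_release_date,
    is_absolute_uri,
    is_media_type,
    parse_duration,
)

__all__ = [
    "Attachment",
    "ELNRecordSource",
    "SiteConfig",
    "UserDepositionInput",
    "DerivationError",
    "ConfigError",
    "derive_manifest",
    "load_site_config",
    "save_site_config",
    "record_to_json",
    "record_from_json",
    "FALLBACK_MEDIA_TYPE",
]

logger = logging.getLogger("elnmanifest")

FALLBACK_MEDIA_TYPE = "application/octet-stream"


class DerivationError(ManifestError):
    pass


class ConfigError(ManifestError):
    def __init__(self, key: str, message: str):
        self.key = key
        super().__init__(f"site config key {key!r}: {message}")


@dataclass(frozen=True)
class Attachment:
    """One file attached to an ELN record."""

    filename: str
    mediaType: Optional[str] = None
    description: Optional[str] = None
    locator: Optional[str] = None


@dataclass(frozen=True)
class ELNRecordSource:
    """Neutral view of a source ELN record, as any vendor system would expose it."""

    localId: str
    title: str
    authors: tuple[tuple[str, str], ...]  # (role, name)
    createdOn: date
    systemName: str
    systemVersion: str
    attachments: tuple[Attachment, ...] = ()
    relatedPublications: tuple[tuple[str, str], ...] = ()  # (relationship, id)
    bodyMediaType: str = "text/html"

    def __post_init__(self):
        if not self.localId or not self.localId.strip():
            raise DerivationError("source record localId must be non-empty")
        if not self.title or not self.title.strip():
            raise DerivationError("source record title must be non-empty")
        object.__setattr__(self, "authors", tuple(tuple(a) for a in self.authors))
        object.__setattr__(self, "attachments", tuple(self.attachments))
        object.__setattr__(
            self, "relatedPublications", tuple(tuple(r) for r in self.relatedPublications)
        )


@dataclass(frozen=True)
class SiteConfig:
    """Per-installation contact and contributor details (plugin config file)."""

    contact: ContactOption
    contributors: tuple[ContributorInformation, ...]

    def __post_init__(self):
        object.__setattr__(self, "contributors", tuple(self.contributors))
        if not self.contributors:
            raise ConfigError("contributor", "at least one contributor is required")


@dataclass(frozen=True)
class UserDepositionInput:
    """Per-deposition user entries: licensing basis and embargo period."""

    licensingBasis: Optional[str] = None
    embargo: Optional[str] = None  # ISO 8601 date duration, e.g. "P6M"

    def __post_init__(self):
        if self.embargo is not None:
            parse_duration(self.embargo)  # raises on negative/unparsable


def derive_manifest(
    source: ELNRecordSource,
    config: SiteConfig,
    user: UserDepositionInput = UserDepositionInput(),
    unitType: Union[UnitType, str] = UnitType.RECORD,
) -> ElnItemManifest:
    """Build a manifest for one source record.

    Field provenance: identifiers and title come from the record itself; the
    generating-system string is ``systemName/systemVersion`` (user-agent
    style); contributors are the site-configured ones merged with the
    record's authors, deduplicated on (role, name); contact comes from the
    site config; the creation date is the record's; a release date is
    computed from the user-entered embargo when one is given.  Content lists
    the record body first, then one item per attachment; an attachment with
    no declared media type falls back to ``application/octet-stream`` with a
    logged warning.  When the record's local identifier is itself an
    absolute URL (openly published blog-style records), it is additionally
    exposed as the open-access ``accessIdentifier``.
    """
    seen: set[tuple[str, str]] = set()
    contributors: list[ContributorInformation] = []
    for contrib in list(config.contributors) + [
        ContributorInformation(role, name) for role, name in source.authors
    ]:
        key = (contrib.role, contrib.name)
        if key not in seen:
            seen.add(key)
            contributors.append(contrib)

    content = [ContentItem(
        description=f"ELN record narrative: {source.title}",
        dataType=source.bodyMediaType,
        locator=source.localId if is_absolute_uri(source.localId) else None,
    )]
    for att in source.attachments:
        media = att.mediaType
        if not media or not is_media_type(media):
            logger.warning(
                "attachment %r has no usable media type; substituting %s",
                att.filename, FALLBACK_MEDIA_TYPE,
            )
            media = FALLBACK_MEDIA_TYPE
        content.append(ContentItem(
            description=att.description or att.filename,
            dataType=media,
            locator=att.locator,
        ))

    release = (
        compute_release_date(source.createdOn, user.embargo)
        if user.embargo is not None else None
    )

    return ElnItemManifest(
        unitType=UnitType.coerce(unitType),
        title=source.title,
        identifiers=IdentifierSet(
            primaryLocalIdentifier=source.localId,
            accessIdentifier=source.localId if is_absolute_uri(source.localId) else None,
        ),
        contact=config.contact,
        contributors=tuple(contributors),
        source=f"{source.systemName}/{source.systemVersion}",
        dates=DateSet(creationDate=source.createdOn, releaseDate=release),
        content=tuple(content),
        licensingBasis=user.licensingBasis,
        relatedItems=tuple(RelatedItem(rel, rid) for rel, rid in source.relatedPublications),
    )


# --------------------------------------------------------------------------
# Site configuration file (flat key = value text format)
# --------------------------------------------------------------------------
# contact.mode        = EMail | SystemURI | Instruction
# contact.value       = ...
# contributor.<n>.role = ...
# contributor.<n>.name = ...
# contributor.<n>.ids  = id1|id2          (optional)
# Lines starting with '#' are comments.

def load_site_config(path: Union[str, Path]) -> SiteConfig:
    """Parse a plugin site-configuration file into a :class:`SiteConfig`."""
    entries: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}", f"expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        entries[key.strip()] = value.strip()

    if "contact.mode" not in entries:
        raise ConfigError("contact.mode", "missing")
    if "contact.value" not in entries:
        raise ConfigError("contact.value", "missing")
    try:
        contact = ContactOption(ContactMode.coerce(entries["contact.mode"]),
                                entries["contact.value"])
    except ManifestError as exc:
        raise ConfigError("contact.value", str(exc)) from exc

    indices = sorted({
        int(k.split(".")[1]) for k in entries
        if k.startswith("contributor.") and k.split(".")[1].isdigit()
    })
    contributors = []
    for i in indices:
        name = entries.get(f"contributor.{i}.name")
        if not name:
            raise ConfigError(f"contributor.{i}.name", "missing or empty")
        ids = entries.get(f"contributor.{i}.ids", "")
        contributors.append(ContributorInformation(
            role=entries.get(f"contributor.{i}.role", ""),
            name=name,
            identifiers=tuple(s for s in ids.split("|") if s) if ids else (),
        ))
    if not contributors:
        raise ConfigError("contributor", "at least one contributor is required")
    return SiteConfig(contact=contact, contributors=tuple(contributors))


def save_site_config(config: SiteConfig, path: Union[str, Path]) -> None:
    """Write a :class:`SiteConfig` in the flat key = value format."""
    lines = [
        "# elnmanifest site configuration",
        f"contact.mode = {config.contact.mode.value}",
        f"contact.value = {config.contact.value}",
    ]
    for i, c in enumerate(config.contributors, 1):
        lines.append(f"contributor.{i}.role = {c.role}")
        lines.append(f"contributor.{i}.name = {c.name}")
        if c.identifiers:
            lines.append(f"contributor.{i}.ids = {'|'.join(c.identifiers)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------
# ELNRecordSource JSON serialization (the documented record interchange form)
# --------------------------------------------------------------------------

def record_to_json(source: ELNRecordSource) -> str:
    """Serialize a source record to the documented JSON interchange form."""
    return json.dumps({
        "localId": source.localId,
        "title": source.title,
        "authors": [list(a) for a in source.authors],
        "createdOn": source.createdOn.isoformat(),
        "systemName": source.systemName,
        "systemVersion": source.systemVersion,
        "attachments": [
            {"filename": a.filename, "mediaType": a.mediaType,
             "description": a.description, "locator": a.locator}
            for a in source.attachments
        ],
        "relatedPublications": [list(r) for r in source.relatedPublications],
        "bodyMediaType": source.bodyMediaType,
    }, indent=2, sort_keys=False)


def record_from_json(text: str) -> ELNRecordSource:
    """Parse the JSON interchange form back into an :class:`ELNRecordSource`."""
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise DerivationError(f"record JSON is unparsable: {exc}") from exc
    for key in ("localId", "title", "authors", "createdOn",
                "systemName", "systemVersion"):
        if key not in data:
            raise DerivationError(f"record JSON missing required key {key!r}")
    return ELNRecordSource(
        localId=data["localId"],
        title=data["title"],
        authors=tuple((r, n) for r, n in data["authors"]),
        createdOn=date.fromisoformat(data["createdOn"]),
        systemName=data["systemName"],
        systemVersion=data["systemVersion"],
        attachments=tuple(
            Attachment(a["filename"], a.get("mediaType"),
                       a.get("description"), a.get("locator"))
            for a in data.get("attachments", [])
        ),
        relatedPublications=tuple((r, i) for r, i in data.get("relatedPublications", [])),
        bodyMediaType=data.get("bodyMediaType", "text/html"),
    )
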