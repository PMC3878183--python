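"""Harvestable knowledge-layer feed over a collection of manifests.

A :class:`ManifestStore` holds (storeId, manifest, lastModified) entries —
in memory or loaded from a directory of manifest XML files — and exposes
them the way an OAI-PMH-style harvester expects: filtered, ordered by
modification time, paginated with opaque resumption tokens.  A harvesting
agent ("information-gathering robot") uses the filter to decide from the
manifest alone whether a record is of interest, e.g. because it carries a
content item of a particular media type, then follows one of the three
metadata tiers:

* ``knowledge``  — the manifest's descriptive core, for discovery/citation;
* ``information`` — the related items, the route to contextual links
  (publications, funding, collections);
* ``processing`` — the content items plus the open-access identifier, the
  access point for automated content processing.

Embargo enforcement is a feed-level concern: ``requireReleased`` excludes
records whose release date lies in the future, while private harvesters may
simply not set it.
"""

from __future__ import annotations

import base64
import binascii
import hashlib
import json
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Union

from .schema_model import ContentItem, ElnItemManifest, ManifestError, UnitType
from . import xml_io

__all__ = [
    "StoreEntry",
    "ManifestStore",
    "FilterSpec",
    "Tier",
    "TokenError",
    "ManifestSummary",
    "ProcessingView",
    "match",
    "list_manifests",
    "resolve_tier",
]


class TokenError(ManifestError):
    """Resumption token is unknown, corrupt, or belongs to another query."""


@dataclass(frozen=True)
class StoreEntry:
    storeId: str
    manifest: ElnItemManifest
    lastModified: datetime


class ManifestStore:
    """A queryable collection of manifests with unique store ids."""

    def __init__(self, entries: Iterable[StoreEntry] = ()):
        self._entries: dict[str, StoreEntry] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: StoreEntry) -> None:
        if entry.storeId in self._entries:
            raise ManifestError(f"duplicate storeId {entry.storeId!r}")
        self._entries[entry.storeId] = entry

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def __eq__(self, other) -> bool:
        return isinstance(other, ManifestStore) and self._entries == other._entries

    def get(self, storeId: str) -> Optional[StoreEntry]:
        return self._entries.get(storeId)

    def save_directory(self, directory: Union[str, Path]) -> None:
        """Write one manifest XML file per entry, plus a timestamp index."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        index = {}
        for entry in self:
            (directory / f"{entry.storeId}.xml").write_text(
                xml_io.to_xml(entry.manifest), encoding="utf-8"
            )
            index[entry.storeId] = entry.lastModified.isoformat()
        (directory / "index.json").write_text(
            json.dumps(index, indent=2, sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def load_directory(cls, directory: Union[str, Path]) -> "ManifestStore":
        """Load a directory of manifest XML files written by save_directory.

        Without an ``index.json``, file modification times stand in for the
        lastModified timestamps.
        """
        directory = Path(directory)
        index_file = directory / "index.json"
        index = (
            json.loads(index_file.read_text(encoding="utf-8"))
            if index_file.exists() else {}
        )
        store = cls()
        for path in sorted(directory.glob("*.xml")):
            store_id = path.stem
            stamp = (
                datetime.fromisoformat(index[store_id]) if store_id in index
                else datetime.fromtimestamp(path.stat().st_mtime)
            )
            store.add(StoreEntry(store_id, xml_io.from_xml(path.read_bytes()), stamp))
        return store


@dataclass(frozen=True)
class FilterSpec:
    """Predicate a harvesting agent applies to decide record relevance.

    Every constraint is optional; an empty FilterSpec matches everything.
    Matching is case-sensitive except for ``licensePrefix``.
    """

    unitTypes: Optional[frozenset[UnitType]] = None
    mediaTypes: Optional[frozenset[str]] = None
    keywordsAny: Optional[frozenset[str]] = None
    requireReleased: bool = False
    licensePrefix: Optional[str] = None
    modifiedSince: Optional[datetime] = None

    def __post_init__(self):
        for name in ("unitTypes", "mediaTypes", "keywordsAny"):
            value = getattr(self, name)
            if value is not None:
                object.__setattr__(self, name, frozenset(value))

    def cache_key(self) -> str:
        payload = json.dumps({
            "u": sorted(u.value for u in self.unitTypes) if self.unitTypes is not None else None,
            "m": sorted(self.mediaTypes) if self.mediaTypes is not None else None,
            "k": sorted(self.keywordsAny) if self.keywordsAny is not None else None,
            "r": self.requireReleased,
            "l": self.licensePrefix,
            "s": self.modifiedSince.isoformat() if self.modifiedSince else None,
        }, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def match(manifest: ElnItemManifest, filter: FilterSpec, today: date) -> bool:
    """True iff the manifest satisfies every present constraint of the filter.

    ``requireReleased`` passes when the manifest has no release date at all
    (nothing is embargoed) or when the release date is on or before
    ``today``.  ``modifiedSince`` concerns store timestamps, not manifest
    fields, and is applied by :func:`list_manifests`.
    """
    if filter.unitTypes is not None and manifest.unitType not in filter.unitTypes:
        return False
    if filter.mediaTypes is not None:
        if not any(c.dataType in filter.mediaTypes for c in manifest.content):
            return False
    if filter.keywordsAny is not None:
        if not filter.keywordsAny.intersection(manifest.keywords):
            return False
    if filter.requireReleased:
        release = manifest.dates.releaseDate
        if release is not None and release > today:
            return False
    if filter.licensePrefix is not None:
        basis = manifest.licensingBasis or ""
        if not basis.lower().startswith(filter.licensePrefix.lower()):
            return False
    return True


@dataclass(frozen=True)
class ManifestSummary:
    """One feed row: enough to decide whether to fetch the full manifest."""

    storeId: str
    title: str
    unitType: UnitType
    primaryLocalIdentifier: str
    lastModified: datetime


def _encode_token(filter_key: str, offset: int) -> str:
    raw = json.dumps({"f": filter_key, "o": offset}).encode()
    return base64.urlsafe_b64encode(raw).decode()


def _decode_token(token: str, filter_key: str) -> int:
    try:
        data = json.loads(base64.urlsafe_b64decode(token.encode()))
        key, offset = data["f"], int(data["o"])
    except (binascii.Error, ValueError, KeyError, TypeError) as exc:
        raise TokenError(f"malformed resumption token {token!r}") from exc
    if key != filter_key:
        raise TokenError("resumption token does not belong to this query")
    if offset < 0:
        raise TokenError("resumption token offset is negative")
    return offset


def list_manifests(
    store: ManifestStore,
    filter: FilterSpec = FilterSpec(),
    pageSize: int = 20,
    resumptionToken: Optional[str] = None,
    today: Optional[date] = None,
) -> tuple[list[ManifestSummary], Optional[str]]:
    """One page of the harvest feed, OAI-PMH style.

    Entries matching the filter are ordered by (lastModified, storeId) and
    cut into ``pageSize`` pages; the returned resumption token is ``None``
    on the final page.  The union of all pages is exactly the matched set.
    """
    if pageSize < 1:
        raise ManifestError("pageSize must be >= 1")
    if today is None:
        today = date.today()
    filter_key = filter.cache_key()
    offset = _decode_token(resumptionToken, filter_key) if resumptionToken else 0

    matched = sorted(
        (
            e for e in store
            if (filter.modifiedSince is None or e.lastModified >= filter.modifiedSince)
            and match(e.manifest, filter, today)
        ),
        key=lambda e: (e.lastModified, e.storeId),
    )
    if offset > len(matched):
        raise TokenError("resumption token is past the end of the result set (expired?)")
    page = matched[offset:offset + pageSize]
    summaries = [
        ManifestSummary(
            storeId=e.storeId,
            title=e.manifest.title,
            unitType=e.manifest.unitType,
            primaryLocalIdentifier=e.manifest.identifiers.primaryLocalIdentifier,
            lastModified=e.lastModified,
        )
        for e in page
    ]
    next_offset = offset + len(page)
    token = _encode_token(filter_key, next_offset) if next_offset < len(matched) else None
    return summaries, token


# --------------------------------------------------------------------------
# Three-tier resolution
# --------------------------------------------------------------------------

class Tier(Enum):
    KNOWLEDGE = "knowledge"
    INFORMATION = "information"
    PROCESSING = "processing"

    @classmethod
    def coerce(cls, value: Union["Tier", str]) -> "Tier":
        if isinstance(value, cls):
            return value
        for member in cls:
            if member.value == value:
                return member
        raise ManifestError(
            f"unknown tier {value!r}; valid tiers are "
            f"{', '.join(m.value for m in cls)}"
        )


@dataclass(frozen=True)
class ProcessingView:
    """Processing-layer access point: content items + open-access link."""

    content: tuple[ContentItem, ...]
    accessIdentifier: Optional[str]


def resolve_tier(manifest: ElnItemManifest, tier: Union[Tier, str]):
    """Project a manifest onto one of the three metadata tiers.

    * ``knowledge`` returns the manifest's descriptive core: a reduced
      manifest with the related items removed and content locators stripped
      (content descriptions and media types stay — they are discovery
      information).
    * ``information`` returns the tuple of related items.
    * ``processing`` returns the content items together with the
      accessIdentifier when one is present.
    """
    tier = Tier.coerce(tier)
    if tier is Tier.INFORMATION:
        return manifest.relatedItems
    if tier is Tier.PROCESSING:
        return ProcessingView(
            content=manifest.content,
            accessIdentifier=manifest.identifiers.accessIdentifier,
        )
    return replace(
        manifest,
        relatedItems=(),
        content=tuple(
            ContentItem(c.description, c.dataType, None) for c in manifest.content
        ),
    )
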