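"""Deterministic synthetic ELN fixtures.

Generates source ELN records, site configurations, molfiles and whole
manifest stores so that every part of the package can be exercised without
any external system.  Records emulate the two demonstrated ELN styles: blog
style, whose local identifier is an open permalink URL, and experiment
style, whose local identifier is an opaque experiment id known only to the
originating system.

Generation is counter-based: every field of every record is drawn from a
PRNG keyed on ``(seed, index, fieldName)``, so any record is reproducible
on its own, independent of generation order, locale and wall clock.  The
default profile is chosen so that a modest store exercises every optional
manifest part (keywords, licensing basis, related items, access identifier,
release date) at least once.
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Optional

from .derivation import (
    Attachment,
    ELNRecordSource,
    SiteConfig,
    UserDepositionInput,
    derive_manifest,
)
from .harvest_feed import FilterSpec, ManifestStore, StoreEntry
from .schema_model import (
    ContactMode,
    ContactOption,
    ContributorInformation,
    ManifestError,
    UnitType,
)

__all__ = [
    "FixtureProfile",
    "DEFAULT_MEDIA_PALETTE",
    "default_site_config",
    "generate_record",
    "generate_user_input",
    "generate_unit_type",
    "generate_store",
    "generate_molfile",
    "generate_filter_spec",
]

#: Media types attachments are drawn from, with per-record inclusion rates.
DEFAULT_MEDIA_PALETTE: dict[str, float] = {
    "chemical/x-mdl-sdfile": 0.35,
    "chemical/x-cml": 0.25,
    "image/png": 0.45,
    "text/csv": 0.30,
    "application/pdf": 0.30,
}

_EXTENSIONS = {
    "chemical/x-mdl-sdfile": "sdf",
    "chemical/x-cml": "cml",
    "image/png": "png",
    "text/csv": "csv",
    "application/pdf": "pdf",
}

_COMPOUNDS = [
    "bromophenyl oxindole", "methyl oxindole", "aryl boronate", "indole carboxamide",
    "pyridyl sulfonamide", "benzyl azide", "quinoline N-oxide", "ferrocene ester",
]
_ACTIONS = [
    "Synthesis", "NMR spectrum", "Purification", "Crystallisation screen",
    "Reaction optimisation", "IR spectrum", "Mass spectrum", "Stability study",
]
_NAMES = [
    "A. Hargreaves", "B. Okafor", "C. Lindqvist", "D. Moreau", "E. Tanaka",
    "F. Szabo", "G. Whitfield", "H. Rahman", "I. Petrov", "J. Callaghan",
]
_KEYWORD_POOL = [
    "synthesis", "oxindole", "NMR", "catalysis", "crystallography",
    "spectroscopy", "yield", "kinetics", "purification", "boronate",
]
_LICENSES = ["CC-BY-4.0", "CC0-1.0", "CC-BY-NC-4.0"]
_EMBARGOES = ["P1M", "P6M", "P1Y", "P2Y"]


@dataclass(frozen=True)
class FixtureProfile:
    """Knobs of the synthetic generator; defaults are the study conditions."""

    seed: int = 0
    nRecords: int = 50
    attachmentRate: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MEDIA_PALETTE)
    )
    embargoRate: float = 0.3
    publicationRate: float = 0.4
    licenseRate: float = 0.5
    keywordRate: float = 0.8
    dateRange: tuple[date, date] = (date(2012, 1, 1), date(2014, 12, 31))

    def __post_init__(self):
        for name in ("embargoRate", "publicationRate", "licenseRate", "keywordRate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ManifestError(f"{name} must be in [0, 1]")
        if any(not 0.0 <= p <= 1.0 for p in self.attachmentRate.values()):
            raise ManifestError("attachment rates must be in [0, 1]")
        if self.dateRange[0] > self.dateRange[1]:
            raise ManifestError("dateRange start must be <= end")


def _rng(seed: int, index: int, fieldName: str) -> random.Random:
    key = f"{seed}:{index}:{fieldName}".encode()
    return random.Random(int.from_bytes(hashlib.sha256(key).digest()[:8], "big"))


def default_site_config() -> SiteConfig:
    """The site configuration used for generated stores."""
    return SiteConfig(
        contact=ContactOption(ContactMode.EMAIL, "eln-curator@example.ac.uk"),
        contributors=(
            ContributorInformation("PI", "Prof. R. Whitmore",
                                   identifiers=("orcid:0000-0002-0000-0001",)),
            ContributorInformation("Funding Body", "National Research Agency"),
        ),
    )


def generate_record(profile: FixtureProfile, index: int) -> ELNRecordSource:
    """One deterministic source ELN record for ``(profile.seed, index)``."""
    if not 0 <= index < profile.nRecords:
        raise ManifestError(
            f"index {index} out of range for a {profile.nRecords}-record profile"
        )
    seed = profile.seed

    r_title = _rng(seed, index, "title")
    title = (f"{r_title.choice(_ACTIONS)} of "
             f"{r_title.choice(_COMPOUNDS)} (run {index + 1})")

    # Alternate the two demonstrated ELN styles.
    blog_style = index % 2 == 0
    slug = title.lower().replace(" ", "_").replace("(", "").replace(")", "").replace("-", "")
    if blog_style:
        local_id = f"http://eln.example.org/notebook/{5000 + index}/{slug}.html"
        system, version = "LabTroveLike", "2.3"
        body_type = "text/html"
    else:
        local_id = f"EXP-{seed % 1000:03d}-{index:05d}"
        system, version = "WorkbookLike", "9.4.1"
        body_type = "application/xhtml+xml"

    r_auth = _rng(seed, index, "authors")
    n_authors = r_auth.randint(1, 3)
    authors = tuple(
        ("Author", name) for name in r_auth.sample(_NAMES, n_authors)
    )

    span = (profile.dateRange[1] - profile.dateRange[0]).days
    created = profile.dateRange[0] + timedelta(
        days=_rng(seed, index, "createdOn").randint(0, span)
    )

    attachments = []
    for media, rate in sorted(profile.attachmentRate.items()):
        r_att = _rng(seed, index, f"attachment:{media}")
        if r_att.random() < rate:
            ext = _EXTENSIONS.get(media, "dat")
            attachments.append(Attachment(
                filename=f"item{index:04d}_{ext}.{ext}",
                mediaType=media,
                description=f"{media.split('/')[1]} attachment for run {index + 1}",
                locator=(
                    f"http://eln.example.org/files/{5000 + index}/{ext}.{ext}"
                    if blog_style else None
                ),
            ))

    related = ()
    if _rng(seed, index, "publication").random() < profile.publicationRate:
        related = (("publication", f"doi:10.5555/eln.{seed}.{index}"),)

    return ELNRecordSource(
        localId=local_id,
        title=title,
        authors=authors,
        createdOn=created,
        systemName=system,
        systemVersion=version,
        attachments=tuple(attachments),
        relatedPublications=related,
        bodyMediaType=body_type,
    )


def generate_user_input(profile: FixtureProfile, index: int) -> UserDepositionInput:
    """Deterministic per-deposition user entries (license + embargo)."""
    r_lic = _rng(profile.seed, index, "license")
    r_emb = _rng(profile.seed, index, "embargo")
    return UserDepositionInput(
        licensingBasis=(
            r_lic.choice(_LICENSES) if r_lic.random() < profile.licenseRate else None
        ),
        embargo=(
            r_emb.choice(_EMBARGOES) if r_emb.random() < profile.embargoRate else None
        ),
    )


def generate_keywords(profile: FixtureProfile, index: int) -> tuple[str, ...]:
    r_kw = _rng(profile.seed, index, "keywords")
    if r_kw.random() >= profile.keywordRate:
        return ()
    return tuple(r_kw.sample(_KEYWORD_POOL, r_kw.randint(1, 4)))


def generate_unit_type(profile: FixtureProfile, index: int) -> UnitType:
    roll = _rng(profile.seed, index, "unitType").random()
    if roll < 0.10:
        return UnitType.PACKAGE
    if roll < 0.25:
        return UnitType.COMPONENT
    return UnitType.RECORD


def generate_store(
    profile: FixtureProfile, config: Optional[SiteConfig] = None
) -> ManifestStore:
    """A store of ``nRecords`` derived manifests, all valid by construction."""
    if config is None:
        config = default_site_config()
    store = ManifestStore()
    for index in range(profile.nRecords):
        record = generate_record(profile, index)
        manifest = derive_manifest(
            record, config,
            user=generate_user_input(profile, index),
            unitType=generate_unit_type(profile, index),
        )
        keywords = generate_keywords(profile, index)
        if keywords:
            from dataclasses import replace
            manifest = replace(manifest, keywords=keywords)
        stamp = datetime.combine(record.createdOn, datetime.min.time()) + timedelta(
            hours=_rng(profile.seed, index, "modified").randint(0, 23)
        )
        store.add(StoreEntry(f"rec-{index:04d}", manifest, stamp))
    return store


# --------------------------------------------------------------------------
# Molfiles
# --------------------------------------------------------------------------

def generate_molfile(seed: int, nAtoms: int) -> str:
    """A syntactically valid V2000 molfile: C/N/O chain on a unit grid.

    Atom count must lie in 1..99 (fixed-width V2000 count fields); bonds
    form a simple chain so counts are always consistent.
    """
    if not 1 <= nAtoms <= 99:
        raise ManifestError("nAtoms must be in 1..99 for a V2000 molfile")
    rng = random.Random(int.from_bytes(
        hashlib.sha256(f"mol:{seed}:{nAtoms}".encode()).digest()[:8], "big"
    ))
    n_bonds = nAtoms - 1
    lines = [
        f"ELN-MOL-{seed}",
        "  elnmanifest",
        "synthetic chain structure",
        f"{nAtoms:3d}{n_bonds:3d}  0  0  0  0  0  0  0  0999 V2000",
    ]
    for i in range(nAtoms):
        element = rng.choice(["C", "C", "C", "N", "O"])
        x, y = float(i % 10), float(i // 10)
        lines.append(
            f"{x:10.4f}{y:10.4f}{0.0:10.4f} {element:<3s} 0  0  0  0  0  0  0  0  0  0  0  0"
        )
    for i in range(n_bonds):
        # single bonds only: any C/N/O chain then has sensible valences
        lines.append(f"{i + 1:3d}{i + 2:3d}  1  0")
    lines.append("M  END")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Random filter specs (for feed-equivalence testing)
# --------------------------------------------------------------------------

def generate_filter_spec(seed: int, index: int) -> FilterSpec:
    """A random FilterSpec mixing all constraint kinds, empty ones included."""
    rng = _rng(seed, index, "filter")
    kwargs = {}
    if rng.random() < 0.4:
        kwargs["unitTypes"] = frozenset(
            rng.sample(list(UnitType), rng.randint(1, 2))
        )
    if rng.random() < 0.5:
        kwargs["mediaTypes"] = frozenset(
            rng.sample(sorted(DEFAULT_MEDIA_PALETTE), rng.randint(1, 3))
        )
    if rng.random() < 0.4:
        kwargs["keywordsAny"] = frozenset(
            rng.sample(_KEYWORD_POOL, rng.randint(1, 3))
        )
    if rng.random() < 0.5:
        kwargs["requireReleased"] = True
    if rng.random() < 0.3:
        kwargs["licensePrefix"] = rng.choice(["CC-BY", "CC0", "cc-"])
    return FilterSpec(**kwargs)
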