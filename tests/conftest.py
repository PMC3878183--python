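import calendar
from datetime import date, timedelta

import pytest
from hypothesis import strategies as st

from elnmanifest import (
    ContactMode,
    ContactOption,
    ContentItem,
    ContributorInformation,
    DateSet,
    ElnItemManifest,
    IdentifierSet,
    RelatedItem,
    UnitType,
)
from elnmanifest.fixtures import FixtureProfile, default_site_config, generate_store


@pytest.fixture(scope="session")
def site_config():
    return default_site_config()


@pytest.fixture(scope="session")
def small_store(site_config):
    return generate_store(FixtureProfile(seed=11, nRecords=20), site_config)


@pytest.fixture()
def full_manifest():
    """A manifest exercising every optional part (for deletion brute force)."""
    return ElnItemManifest(
        unitType=UnitType.RECORD,
        title="Synthesis of methyl oxindole",
        identifiers=IdentifierSet(
            primaryLocalIdentifier="http://eln.example.org/notebook/5606/record.html",
            otherLocalIdentifiers=("EXP-001-00042",),
            accessIdentifier="http://eln.example.org/notebook/5606/record.html",
        ),
        contact=ContactOption(ContactMode.EMAIL, "curator@example.ac.uk"),
        contributors=(
            ContributorInformation("Author", "A. Hargreaves"),
            ContributorInformation("PI", "Prof. R. Whitmore"),
        ),
        source="LabTroveLike/2.3",
        dates=DateSet(
            creationDate=date(2013, 8, 1),
            releaseDate=date(2014, 2, 1),
            publicationDate=date(2013, 12, 20),
            submissionDate=date(2013, 10, 2),
        ),
        content=(
            ContentItem("ELN record narrative", "text/html",
                        "http://eln.example.org/notebook/5606/record.html"),
            ContentItem("NMR spectrum", "chemical/x-jcamp-dx"),
        ),
        keywords=("synthesis", "oxindole"),
        licensingBasis="CC-BY-4.0",
        relatedItems=(RelatedItem("publication", "doi:10.5555/demo.1"),),
    )


# ---------------------------------------------------------------------------
# Independent calendar-arithmetic oracle for embargo release dates
# ---------------------------------------------------------------------------

def oracle_release_date(base: date, years: int, months: int, days: int) -> date:
    """Reference month/year addition with end-of-month clamping.

    Written directly from the calendar definition (via calendar.monthrange),
    independently of the implementation under test.
    """
    total_months = base.month - 1 + 12 * years + months
    y, m = base.year + total_months // 12, total_months % 12 + 1
    d = min(base.day, calendar.monthrange(y, m)[1])
    return date(y, m, d) + timedelta(days=days)


# ---------------------------------------------------------------------------
# Hypothesis strategy for random valid manifests
# ---------------------------------------------------------------------------

_text = st.text(
    alphabet=st.characters(
        codec="utf-8", categories=("L", "N", "P", "S"), max_codepoint=0x2FF
    ),
    min_size=1, max_size=30,
).map(str.strip).filter(bool)

_uri = st.builds(lambda s: f"https://example.org/{s}",
                 st.text(alphabet="abcdefghij0123456789", min_size=1, max_size=12))

_media = st.sampled_from([
    "text/html", "text/csv", "image/png", "application/pdf",
    "chemical/x-mdl-sdfile", "chemical/x-cml",
])

_date = st.dates(min_value=date(2000, 1, 1), max_value=date(2030, 12, 31))

_contact = st.one_of(
    st.builds(lambda s: ContactOption(ContactMode.EMAIL, f"{s}@example.org"),
              st.text(alphabet="abcxyz123", min_size=1, max_size=10)),
    st.builds(lambda u: ContactOption(ContactMode.SYSTEM_URI, u), _uri),
    st.builds(lambda s: ContactOption(ContactMode.INSTRUCTION, s), _text),
)

_contributor = st.builds(
    ContributorInformation,
    role=st.sampled_from(["Author", "PI", "Funding Body", "institution", "Curator"]),
    name=_text,
    identifiers=st.lists(_text, max_size=2).map(tuple),
)

_content_item = st.builds(
    ContentItem,
    description=_text,
    dataType=_media,
    locator=st.one_of(st.none(), _uri),
)

_dates = _date.flatmap(
    lambda creation: st.builds(
        DateSet,
        creationDate=st.just(creation),
        releaseDate=st.one_of(
            st.none(),
            st.integers(min_value=0, max_value=900).map(
                lambda d: creation + timedelta(days=d)
            ),
        ),
        publicationDate=st.one_of(st.none(), _date),
        submissionDate=st.one_of(st.none(), _date),
    )
)

_identifiers = st.builds(
    lambda primary, others, access: IdentifierSet(
        primary, tuple(o for o in others if o != primary), access
    ),
    _text,
    st.lists(_text.map(lambda s: f"alt:{s}"), max_size=2, unique=True),
    st.one_of(st.none(), _uri),
)

manifests = st.builds(
    ElnItemManifest,
    unitType=st.sampled_from(list(UnitType)),
    title=_text,
    identifiers=_identifiers,
    contact=_contact,
    contributors=st.lists(_contributor, min_size=1, max_size=3).map(tuple),
    source=_text,
    dates=_dates,
    content=st.lists(_content_item, min_size=1, max_size=3).map(tuple),
    keywords=st.lists(_text, max_size=3, unique=True).map(tuple),
    licensingBasis=st.one_of(st.none(), st.sampled_from(["CC-BY-4.0", "CC0-1.0"])),
    relatedItems=st.lists(
        st.builds(RelatedItem,
                  relationship=st.sampled_from(["publication", "related work"]),
                  id=st.one_of(_text, st.just("doi:10.5555/x.1"))),
        max_size=2,
    ).map(tuple),
)
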