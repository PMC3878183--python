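"""Feed filtering, OAI-PMH-style pagination, and three-tier resolution."""

from dataclasses import replace
from datetime import date, datetime, timedelta

import pytest

from elnmanifest import (
    FilterSpec,
    ManifestStore,
    ProcessingView,
    StoreEntry,
    Tier,
    TokenError,
    UnitType,
    dc_crosswalk,
    list_manifests,
    match,
    resolve_tier,
)
from elnmanifest.fixtures import (
    FixtureProfile,
    generate_filter_spec,
    generate_store,
)

TODAY = date(2015, 1, 1)


def naive_scan(store, spec, today=TODAY):
    """Constraint-by-constraint reference filter, written from the field
    definitions rather than via match()."""
    hits = []
    for entry in store:
        m = entry.manifest
        if spec.modifiedSince is not None and entry.lastModified < spec.modifiedSince:
            continue
        if spec.unitTypes is not None and m.unitType not in spec.unitTypes:
            continue
        if spec.mediaTypes is not None and not (
            {c.dataType for c in m.content} & spec.mediaTypes
        ):
            continue
        if spec.keywordsAny is not None and not (set(m.keywords) & spec.keywordsAny):
            continue
        if spec.requireReleased and m.dates.releaseDate is not None \
                and m.dates.releaseDate > today:
            continue
        if spec.licensePrefix is not None and not (
            (m.licensingBasis or "").lower().startswith(spec.licensePrefix.lower())
        ):
            continue
        hits.append(entry.storeId)
    return set(hits)


def harvest_all(store, spec, page_size, today=TODAY):
    ids, token, pages = [], None, []
    while True:
        page, token = list_manifests(store, spec, page_size, token, today=today)
        pages.append(len(page))
        ids.extend(s.storeId for s in page)
        if token is None:
            return ids, pages


class TestMatch:
    def test_media_type_membership(self, small_store):
        spec = FilterSpec(mediaTypes=frozenset({"chemical/x-mdl-sdfile"}))
        for entry in small_store:
            expected = any(c.dataType == "chemical/x-mdl-sdfile"
                           for c in entry.manifest.content)
            assert match(entry.manifest, spec, TODAY) is expected

    def test_embargoed_record_excluded_when_released_only(self, full_manifest):
        embargoed = replace(
            full_manifest,
            dates=replace(full_manifest.dates, releaseDate=date(2099, 1, 1)),
        )
        spec = FilterSpec(requireReleased=True)
        assert match(embargoed, spec, TODAY) is False
        assert match(full_manifest, spec, TODAY) is True  # released in the past

    def test_no_release_date_counts_as_released(self, full_manifest):
        open_record = replace(
            full_manifest, dates=replace(full_manifest.dates, releaseDate=None)
        )
        assert match(open_record, FilterSpec(requireReleased=True), TODAY)

    def test_empty_filter_matches_everything(self, small_store):
        assert all(match(e.manifest, FilterSpec(), TODAY) for e in small_store)

    def test_license_prefix_case_insensitive(self, full_manifest):
        assert match(full_manifest, FilterSpec(licensePrefix="cc-by"), TODAY)

    def test_relaxing_a_constraint_never_shrinks_matches(self, small_store):
        for i in range(20):
            spec = generate_filter_spec(77, i)
            matched = naive_scan(small_store, spec)
            for relaxed in (
                replace(spec, unitTypes=None),
                replace(spec, mediaTypes=None),
                replace(spec, keywordsAny=None),
                replace(spec, requireReleased=False),
                replace(spec, licensePrefix=None),
            ):
                assert matched <= naive_scan(small_store, relaxed)


class TestListManifests:
    def test_empty_store(self):
        page, token = list_manifests(ManifestStore(), FilterSpec(), 10)
        assert page == [] and token is None

    def test_page_arithmetic_25_by_10(self, full_manifest):
        base = datetime(2014, 1, 1)
        store = ManifestStore(
            StoreEntry(f"r{i:02d}", full_manifest, base + timedelta(hours=i))
            for i in range(25)
        )
        ids, pages = harvest_all(store, FilterSpec(), 10)
        assert pages == [10, 10, 5]
        assert ids == sorted(ids) and len(set(ids)) == 25

    def test_pagination_matches_naive_scan(self, small_store):
        for i in range(25):
            spec = generate_filter_spec(13, i)
            ids, _ = harvest_all(small_store, spec, 7)
            assert len(ids) == len(set(ids))
            assert set(ids) == naive_scan(small_store, spec)

    def test_ordering_is_by_last_modified_then_id(self, small_store):
        ids, _ = harvest_all(small_store, FilterSpec(), 6)
        entries = {e.storeId: e for e in small_store}
        keys = [(entries[i].lastModified, i) for i in ids]
        assert keys == sorted(keys)

    def test_malformed_token_rejected(self, small_store):
        with pytest.raises(TokenError):
            list_manifests(small_store, FilterSpec(), 5, "not-a-token")

    def test_token_bound_to_its_query(self, small_store):
        _, token = list_manifests(small_store, FilterSpec(), 5)
        other = FilterSpec(unitTypes=frozenset({UnitType.RECORD}))
        with pytest.raises(TokenError):
            list_manifests(small_store, other, 5, token)

    def test_store_directory_round_trip(self, tmp_path, small_store):
        small_store.save_directory(tmp_path / "store")
        reloaded = ManifestStore.load_directory(tmp_path / "store")
        assert reloaded == small_store

    def test_duplicate_store_ids_rejected(self, full_manifest):
        store = ManifestStore()
        store.add(StoreEntry("a", full_manifest, datetime(2014, 1, 1)))
        with pytest.raises(Exception):
            store.add(StoreEntry("a", full_manifest, datetime(2014, 1, 2)))


class TestResolveTier:
    def test_information_is_the_related_items(self, full_manifest):
        view = resolve_tier(full_manifest, Tier.INFORMATION)
        assert view == full_manifest.relatedItems
        assert [(r.relationship, r.id) for r in view] == [
            ("publication", "doi:10.5555/demo.1")
        ]

    def test_processing_is_content_plus_access_identifier(self, full_manifest):
        view = resolve_tier(full_manifest, "processing")
        assert isinstance(view, ProcessingView)
        assert view.content == full_manifest.content
        assert view.accessIdentifier == full_manifest.identifiers.accessIdentifier

    def test_knowledge_strips_related_items_and_locators(self, full_manifest):
        view = resolve_tier(full_manifest, Tier.KNOWLEDGE)
        assert view.relatedItems == ()
        assert all(c.locator is None for c in view.content)
        assert view.title == full_manifest.title
        assert view.contact == full_manifest.contact

    def test_information_and_processing_are_disjoint(self, small_store):
        for entry in small_store:
            info = resolve_tier(entry.manifest, Tier.INFORMATION)
            proc = resolve_tier(entry.manifest, Tier.PROCESSING)
            assert not set(info) & set(proc.content)

    def test_knowledge_crosswalk_matches_full_crosswalk(self, small_store):
        # The knowledge view omits relatedItems, so its crosswalk equals the
        # full manifest's on every element except dc:relation.
        for entry in small_store:
            full = [p for p in dc_crosswalk(entry.manifest) if p[0] != "relation"]
            view = dc_crosswalk(resolve_tier(entry.manifest, Tier.KNOWLEDGE))
            assert view == full

    def test_unknown_tier_lists_the_valid_ones(self, full_manifest):
        with pytest.raises(Exception, match="knowledge.*information.*processing"):
            resolve_tier(full_manifest, "metadata")
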