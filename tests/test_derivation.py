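"""Record-to-manifest derivation and the site configuration file."""

from datetime import date

import pytest

from elnmanifest import (
    Attachment,
    ConfigError,
    ContactMode,
    ContactOption,
    ContributorInformation,
    DerivationError,
    ELNRecordSource,
    SiteConfig,
    UnitType,
    UserDepositionInput,
    derive_manifest,
    load_site_config,
    record_from_json,
    record_to_json,
    save_site_config,
    validate_manifest,
)
from elnmanifest.derivation import FALLBACK_MEDIA_TYPE
from elnmanifest.fixtures import FixtureProfile, generate_record

PERMALINK = ("http://www.ourexperiment.example.org/synth_methyl_oxin/5606/"
             "Spectrum_of_31Bromophenyl_1_3Dihydroindol2Hone.html")


def blog_record(**overrides) -> ELNRecordSource:
    base = dict(
        localId=PERMALINK,
        title="Spectrum of 3-(1-bromophenyl)-1,3-dihydroindol-2H-one",
        authors=(("Author", "A. Hargreaves"),),
        createdOn=date(2013, 8, 1),
        systemName="LabTroveLike",
        systemVersion="2.3",
        attachments=(Attachment("spectrum.jdx", "chemical/x-jcamp-dx", "NMR spectrum"),),
        relatedPublications=(("publication", "doi:10.5555/demo.1"),),
    )
    base.update(overrides)
    return ELNRecordSource(**base)


class TestDeriveManifest:
    def test_permalink_becomes_primary_identifier(self, site_config):
        m = derive_manifest(blog_record(), site_config)
        assert m.identifiers.primaryLocalIdentifier == PERMALINK
        # an openly published permalink doubles as the open-access link
        assert m.identifiers.accessIdentifier == PERMALINK

    def test_opaque_experiment_id_gets_no_access_identifier(self, site_config):
        m = derive_manifest(blog_record(localId="EXP-001-00042"), site_config)
        assert m.identifiers.accessIdentifier is None

    def test_source_is_user_agent_style(self, site_config):
        assert derive_manifest(blog_record(), site_config).source == "LabTroveLike/2.3"

    def test_body_only_content_for_attachment_free_record(self, site_config):
        m = derive_manifest(blog_record(attachments=()), site_config)
        assert len(m.content) == 1
        assert m.content[0].dataType == "text/html"

    def test_content_counts_attachments_plus_body(self, site_config):
        for index in range(12):
            record = generate_record(FixtureProfile(seed=3, nRecords=12), index)
            m = derive_manifest(record, site_config)
            assert len(m.content) == len(record.attachments) + 1

    def test_missing_media_type_falls_back_with_warning(self, site_config, caplog):
        import logging
        record = blog_record(attachments=(Attachment("blob.bin"),))
        with caplog.at_level(logging.WARNING, logger="elnmanifest"):
            m = derive_manifest(record, site_config)
        assert m.content[1].dataType == FALLBACK_MEDIA_TYPE
        assert any("octet-stream" in r.message for r in caplog.records)

    def test_zero_embargo_releases_on_creation(self, site_config):
        m = derive_manifest(blog_record(), site_config,
                            UserDepositionInput(embargo="P0D"))
        assert m.dates.releaseDate == m.dates.creationDate

    def test_no_embargo_means_no_release_date(self, site_config):
        m = derive_manifest(blog_record(), site_config)
        assert m.dates.releaseDate is None

    def test_six_month_embargo(self, site_config):
        m = derive_manifest(blog_record(), site_config,
                            UserDepositionInput(embargo="P6M", licensingBasis="CC-BY-4.0"))
        assert m.dates.releaseDate == date(2014, 2, 1)
        assert m.licensingBasis == "CC-BY-4.0"

    def test_contributors_merged_and_deduplicated(self, site_config):
        record = blog_record(authors=(("Author", "A. Hargreaves"),
                                      ("PI", "Prof. R. Whitmore")))
        m = derive_manifest(record, site_config)
        assert [(c.role, c.name) for c in m.contributors].count(
            ("PI", "Prof. R. Whitmore")) == 1
        assert ("Author", "A. Hargreaves") in [(c.role, c.name) for c in m.contributors]

    def test_derived_manifests_validate_cleanly(self, site_config):
        profile = FixtureProfile(seed=5, nRecords=15)
        for index in range(profile.nRecords):
            m = derive_manifest(generate_record(profile, index), site_config)
            report = validate_manifest(m)
            assert report.valid, report.to_text()

    def test_determinism(self, site_config):
        assert derive_manifest(blog_record(), site_config) == \
            derive_manifest(blog_record(), site_config)

    def test_empty_title_rejected(self, site_config):
        with pytest.raises(DerivationError):
            blog_record(title="  ")

    def test_negative_embargo_rejected(self):
        with pytest.raises(Exception):
            UserDepositionInput(embargo="-P6M")


class TestSiteConfig:
    def test_round_trip(self, tmp_path, site_config):
        path = tmp_path / "site.cfg"
        save_site_config(site_config, path)
        assert load_site_config(path) == site_config

    def test_example_config_parses(self, tmp_path):
        path = tmp_path / "site.cfg"
        path.write_text(
            "# demo\n"
            "contact.mode = EMail\n"
            "contact.value = curator@example.ac.uk\n"
            "contributor.1.role = Author\n"
            "contributor.1.name = A. Hargreaves\n"
            "contributor.2.role = PI\n"
            "contributor.2.name = Prof. R. Whitmore\n"
        )
        config = load_site_config(path)
        assert config.contact == ContactOption(ContactMode.EMAIL, "curator@example.ac.uk")
        assert [(c.role, c.name) for c in config.contributors] == [
            ("Author", "A. Hargreaves"), ("PI", "Prof. R. Whitmore")
        ]

    def test_empty_contributors_rejected(self, tmp_path):
        path = tmp_path / "site.cfg"
        path.write_text("contact.mode = EMail\ncontact.value = a@b.org\n")
        with pytest.raises(ConfigError, match="contributor"):
            load_site_config(path)

    def test_offending_key_named(self, tmp_path):
        path = tmp_path / "site.cfg"
        path.write_text(
            "contact.mode = EMail\n"
            "contact.value = not-an-email\n"
            "contributor.1.name = X\n"
        )
        with pytest.raises(ConfigError, match="contact.value"):
            load_site_config(path)

    def test_empty_contributor_list_invariant(self):
        with pytest.raises(ConfigError):
            SiteConfig(ContactOption(ContactMode.INSTRUCTION, "ask"), ())


class TestRecordJson:
    def test_round_trip(self):
        record = blog_record()
        assert record_from_json(record_to_json(record)) == record

    def test_missing_key_named(self):
        with pytest.raises(DerivationError, match="localId"):
            record_from_json('{"title": "x"}')
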