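# elnmanifest

Knowledge-layer metadata records for Electronic Laboratory Notebooks (ELNs).

Vast amounts of experimental chemistry — including the sub-optimal and
negative results that never reach journals — sit in ELNs behind proprietary,
vendor-specific data structures. Before that content can be discovered,
cited, or mined automatically, each ELN unit needs a compact, standard,
machine-readable description. `elnmanifest` implements such a description,
the **elnItemManifest**: one metadata record per ELN unit (a *Package* of
records, a single *Record*, or a *Component* such as a spectrum) carrying

| part | content |
|---|---|
| `unitType` | Package \| Record \| Component |
| `Title` | short human-readable title |
| `Keywords` | optional search terms |
| `Identifiers` | primary local identifier; alternates; optional open-access `AccessIdentifier` URI |
| `Contact` | e-mail, system URI, or free-text instruction |
| `LicensingBasis` | optional license indication (e.g. a Creative Commons name) |
| `Contributors` | roles + names (Author, PI, Funding Body, institution, …) |
| `Source` | generating system, user-agent style (`vendor/version`) |
| `Date` | creation date; optional release (embargo end), publication, submission dates |
| `RelatedItems` | optional links outward — DOIs preferred for publications |
| `Content` | one item per piece of content: description, MIME type, optional locator |

The manifest is the **knowledge layer** of a three-tier metadata
architecture: it answers *"is this record of interest, and can I access
it?"*. Its `RelatedItems` element is the route into the **information
layer** (context: publications, funding, collections), and its `Content`
element — MIME types plus dereferencable locators and the optional
`AccessIdentifier` — is the access point to the **processing layer**, where
agents fetch and process the data itself.

The package provides, as a library and an `elnmanifest` CLI:

* a typed data model with all invariants enforced at construction;
* canonical XML serialization, a versioned XML Schema Definition, and
  schema validation (`urn:elnmanifest:schema:1.0`);
* rule-based semantic validation with a documented rule catalogue
  (errors and warnings, e.g. *DOI preferred* for publication links);
* derivation of manifests from source ELN records — both blog-style
  records with open permalinks and experiment-style records exported via a
  site configuration file plus per-deposition user input (license + embargo,
  from which the release date is computed);
* an OAI-PMH-style harvest feed over a manifest store: filtering by unit
  type, media type, keywords, license and embargo status; pagination with
  resumption tokens; three-tier resolution;
* a crosswalk onto the 15-element Dublin Core set, for interoperability
  with institutional-repository and data-citation tooling;
* SDF deposition packaging: each structure (V2000 molfile, preserved
  verbatim) annotated with AUTHOR / PRINCIPAL_INVESTIGATOR /
  ELN_EXPERIMENT_ID data fields, the full manifest travelling as a separate
  XML file;
* a deterministic fixture generator so everything is testable offline.

## Worked example

```python
from datetime import date
from elnmanifest import *

source = ELNRecordSource(
    localId="http://eln.example.org/notebook/5606/spectrum_of_bromophenyl_oxindole.html",
    title="Spectrum of 3-(1-bromophenyl)-1,3-dihydroindol-2H-one",
    authors=(("Author", "A. Hargreaves"),),
    createdOn=date(2013, 8, 1),
    systemName="LabTrove", systemVersion="2.3",
    attachments=(Attachment("spectrum.jdx", "chemical/x-jcamp-dx", "1H NMR spectrum"),),
    relatedPublications=(("publication", "doi:10.5555/demo.1"),),
)
config = SiteConfig(
    contact=ContactOption(ContactMode.EMAIL, "curator@example.ac.uk"),
    contributors=(ContributorInformation("PI", "Prof. R. Whitmore"),),
)
manifest = derive_manifest(
    source, config,
    UserDepositionInput(licensingBasis="CC-BY-4.0", embargo="P6M"),
)
print(manifest.dates.releaseDate)   # 2014-02-01  (creation + 6-month embargo)
print(to_xml(manifest))
```

prints a schema-valid document (abridged):

```xml
<?xml version='1.0' encoding='UTF-8'?>
<elnItemManifest xmlns="urn:elnmanifest:schema:1.0" unitType="Record" schemaVersion="1.0">
  <Title>Spectrum of 3-(1-bromophenyl)-1,3-dihydroindol-2H-one</Title>
  <Identifiers>
    <PrimaryLocalIdentifier>http://eln.example.org/notebook/5606/spectrum_of_bromophenyl_oxindole.html</PrimaryLocalIdentifier>
    <AccessIdentifier>http://eln.example.org/notebook/5606/spectrum_of_bromophenyl_oxindole.html</AccessIdentifier>
  </Identifiers>
  <Contact mode="EMail">curator@example.ac.uk</Contact>
  <LicensingBasis>CC-BY-4.0</LicensingBasis>
  ...
  <Date>
    <CreationDate>2013-08-01</CreationDate>
    <ReleaseDate>2014-02-01</ReleaseDate>
  </Date>
  ...
</elnItemManifest>
```

The release date is the creation date advanced by the ISO 8601 embargo
period with end-of-month clamping (2013-08-31 + P6M → 2014-02-28). The
record's open permalink doubles as both the primary local identifier and
the open-access `AccessIdentifier`. Crosswalking the same manifest
(`dc_crosswalk(manifest)`) yields a pure Dublin Core record — `title`,
`creator` = A. Hargreaves (role Author), `contributor` = Prof. R. Whitmore,
`rights` = CC-BY-4.0, `relation` = doi:10.5555/demo.1, `format` =
text/html + chemical/x-jcamp-dx, `type` = Record — every value verbatim
from the manifest.

From the shell, the same pipeline:

```sh
elnmanifest gen-fixtures --seed 3 --n 10 --out fx
elnmanifest derive --source fx/records/rec-0000.json --config fx/site.cfg \
    --embargo P6M --license CC-BY-4.0 -o m.xml
elnmanifest validate m.xml
elnmanifest crosswalk m.xml --format dc-json
elnmanifest harvest fx/store --media-type chemical/x-mdl-sdfile --released-only
elnmanifest resolve m.xml --tier processing
```

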