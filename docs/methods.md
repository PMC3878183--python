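# Methods

## The metadata model

An elnItemManifest describes exactly one ELN unit. The unit's granularity
is declared by `unitType`, a closed three-member enumeration: *Package*
(several records released together), *Record* (one notebook entry) and
*Component* (a part of a record, e.g. a single spectrum). Eight parts are
mandatory — unit type, title, identifiers, contact, contributors, source,
dates and content — and four are optional: keywords, licensing basis,
related items and the open-access identifier. Within the date set only the
creation date is required; release (embargo end), publication and
submission dates are optional, and at most one date of each kind is kept
(one-per-kind is a deliberate restriction: multiple dates of the same kind
have no defined consumer semantics, and collapsing to one keeps the
citation mapping unambiguous).

The model is a set of frozen dataclasses whose invariants are checked at
construction, so any instance in memory is valid and equality is
structural. Normalisation is limited to whitespace-trimming the title and
trimming/deduplicating keywords (case-sensitively); every other value is
stored verbatim.

Validation choices that were genuinely open:

* **Contact syntax.** E-mail checking is syntactic only (exactly one `@`,
  non-empty local and domain parts). Full RFC 5322 grammar is out of
  proportion for a metadata field whose consumers are humans and mailto
  handlers.
* **Absolute URIs.** `AccessIdentifier`, `SystemURI` contacts and content
  locators must look like `scheme:remainder`. No network dereferencing is
  ever attempted.
* **Contributor roles are free text.** There is no agreed controlled
  vocabulary for ELN contributor roles, so unusual roles draw a warning
  (`W.ROLE_VOCAB`), never an error. The recognised set is Author, PI /
  Principal Investigator, Funding Body, institution (case-insensitive).
* **"DOI preferred."** A related item whose relationship is `publication`
  (case-insensitive literal) but whose id is not recognisably a DOI gets a
  warning, not an error — any identifier string is legal. DOI recognition
  accepts `10.x/y`, `doi:10.x/y` and `https://doi.org/10.x/y`.
* **Date ordering** is enforced only between creation and release dates.
  Publication and submission dates are deliberately unordered: an article
  may be submitted before or after the ELN record is released.

## Embargo arithmetic

`compute_release_date(base, embargo)` advances the creation date by an ISO
8601 date duration (`PnYnMnWnD`; time components are rejected as
meaningless for embargoes). Month and year arithmetic clamps to the last
valid day of the target month — 2013-08-31 + P6M = 2014-02-28 — matching
repository convention and `dateutil.relativedelta` semantics. The test
suite checks this against an independently written oracle built directly on
`calendar.monthrange`. The embargo base is the creation date: it is the
only mandatory date, and an embargo clock starting at record creation is
the natural reading for notebook records. Negative durations are rejected.

## XML dialect

Documents live in the project namespace `urn:elnmanifest:schema:1.0` with a
`schemaVersion` attribute on the root; the shipped XSD
(`elnItemManifest-1.0.xsd`) is the normative grammar. Conventions fixed
here (the element-naming and casing of the scheme's parts is mixed in
informal use, so one convention had to be chosen):

* camelCase for the root and for compound leaf terms
  (`elnItemManifest`, `PrimaryLocalIdentifier` children keep their
  initial-capital label form), initial-capital labels for all child
  elements (`Title`, `Keywords`, `Contact`, …);
* `unitType` is an attribute of the root, since it qualifies the manifest
  as a whole rather than being one of its parts; the contact `mode`
  likewise rides as an attribute of `Contact`;
* child order is fixed (Title, Keywords, Identifiers, Contact,
  LicensingBasis, Contributors, Source, Date, RelatedItems, Content);
  absent optional parts produce no element at all;
* encoding is UTF-8 without BOM; serialization is canonical, so equal
  manifests produce byte-identical documents;
* a lax `xs:any ##other` extension point at the end of the root sequence
  tolerates foreign-namespace extensions: they are ignored with a logged
  warning on read and never written.

Two semantic rules are beyond XSD 1.0 (no conditional assertions):
mode-dependent contact syntax and creation/release ordering. `from_xml`
enforces them after schema validation, so such documents are schema-valid
but still rejected with an element-path error; the rule validator reports
the same problems non-fatally. On read, an `OtherLocalIdentifier` equal to
the primary identifier is dropped with a warning rather than rejected
(lenient read, strict write).

## Dublin Core crosswalk

The crosswalk is a fixed projection onto the 15-element DCMES: title→title,
keywords→subject, primary and access identifiers→identifier, contributors
with role Author→creator and all others→contributor, licensingBasis→rights,
source→source, creationDate→date (ISO string), relatedItems→relation
(their ids), content media types→format, unitType→type. It never invents a
value — every emitted string is verbatim a manifest field — and never emits
an element outside the 15. Description, publisher, language and coverage
have no manifest counterpart and are never produced.

## Harvest feed and tier resolution

The store is file/directory-backed (one XML per manifest plus a JSON
timestamp index) rather than a network service: harvesting is specified
protocol-independently, and a filesystem store keeps the artifact
desk-scale while an HTTP layer can wrap it later. Feed pages are ordered by
(lastModified, storeId) and navigated by opaque resumption tokens encoding
the filter hash and offset; a token presented against a different filter is
rejected. Embargo enforcement is a feed-level predicate (`requireReleased`:
release date absent or ≤ today), not suppression at serialization, so
private/internal harvesting of embargoed records remains possible. All
filter matching is case-sensitive except the license prefix.

Tier resolution projects one manifest three ways: *information* is the
related-items list; *processing* is the content list plus the
accessIdentifier when present; *knowledge* is the remaining descriptive
core — the manifest with related items removed and content locators
stripped (descriptions and media types stay: they are discovery
information). Consequently the knowledge view's Dublin Core crosswalk
equals the full manifest's on every element except `relation`, which is
exactly the information-layer content; the tests assert this relationship.
Contact details are part of the core discovery metadata and are retained in
the knowledge view.

## SDF deposition packaging

A deposition is one SDF file plus the manifest as a separate XML document.
Molfiles are opaque validated text: the only check is a well-formed V2000
counts line (fixed-width fields, `V2000` tag), and each molfile's bytes
survive package→split verbatim — no chemistry toolkit normalisation, which
would re-write coordinates and atom order. The three provenance data
fields (`AUTHOR`, `PRINCIPAL_INVESTIGATOR`, `ELN_EXPERIMENT_ID`; the tag
strings are package constants) are replicated into every record, because
SDF consumers routinely split files record-wise. Author resolution takes
the first contributor with role Author, falling back to the first
contributor; PI takes the first contributor with role PI / Principal
Investigator and is left empty otherwise. The splitter additionally
enforces that all records of a file agree on the triple. RDKit serves as an
independent parser oracle in the tests; it is never on the read/write path.

## Synthetic fixtures

The generator emulates the two integration styles the package targets:
blog-style records (open permalink URL as local identifier, `text/html`
body, locators on attachments) and experiment-style records (opaque
`EXP-nnn-nnnnn` ids, no open locators), alternating per index. Defaults:
50 records per store; attachment palette
{`chemical/x-mdl-sdfile` 0.35, `chemical/x-cml` 0.25, `image/png` 0.45,
`text/csv` 0.30, `application/pdf` 0.30} (per-record inclusion
probabilities); embargo probability 0.3 with periods drawn from
{P1M, P6M, P1Y, P2Y}; publication-DOI probability 0.4; license probability
0.5 over common Creative Commons names; keyword probability 0.8; creation
dates uniform over 2012-01-01..2014-12-31. Rates are round figures chosen
to make a modest store exercise every optional manifest part several times
over; the media palette is a stand-in for the heterogeneous real content
(spectra, CIF, CML, images) an ELN holds, and is configurable.

Generation is counter-based: each field is drawn from a PRNG seeded with
SHA-256 of `(seed, index, fieldName)`, so any record is reproducible in
isolation, independent of generation order, locale or wall clock.
Generated molfiles are single-bonded C/N/O chains on a unit grid —
syntactically valid and chemically unobjectionable, but not meaningful
structures.

What passing tests on these fixtures do **not** show: real exports have
messier titles and author lists, media types missing or wrong (only the
missing-type fallback path is exercised), multi-valued dates, and
vendor-specific identifier shapes; none of the fixture content tests
semantic parsing of the attached data. The guarantees demonstrated are
structural — schema conformance, round-trip fidelity, filter/pagination
correctness, crosswalk discipline — and those transfer to real records
because they do not depend on field content.

## Problem sizes and determinism

The acceptance script uses the documented sizes — 50-manifest stores for
conformance/crosswalk/tier checks, 500 manifests for round-trip identity,
100 manifests × 50 random filters for feed equivalence, 100 depositions,
1,000 embargo cases (every fifth forced to a month-end base) — all derived
from the single `--seed` argument, with a fixed evaluation day (2015-01-01)
for embargo filtering so results are reproducible. Property-based tests run
derandomised with fixed example budgets.

## Known limitations

* No live ELN, repository or DOI connectivity: derivation consumes the
  neutral record-source form, and identifiers are never dereferenced.
* One date per kind (see above); multi-venue submission dates are not
  representable.
* The feed implements the list/resume pattern only — no full OAI-PMH verb
  set, no SWORD deposit, no OAI-ORE packaging.
* Molfile validation is syntactic (counts line); chemical perception,
  standardisation and InChI generation are out of scope.
* Only chemical structures are packaged for deposition; spectra, reactions
  and property datasets would need their own packaging conventions.
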