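"""SDF deposition packaging: structures + manifest, repository-ready.

A deposition to a structure-centric repository (the ChemSpider-style
workflow) ships one SDF file containing every chemical structure of an ELN
experiment in molfile (V2000) form, each record annotated with three
provenance data fields — author, principal investigator and the ELN
experiment id — and, alongside it, the full metadata as a separate
elnItemManifest XML file.  Keeping the rich metadata out of the SDF means
the same deposition mechanism works for any kind of ELN data while SDF
consumers still see basic provenance on every record.

Molfiles are treated as opaque validated text: the only structural check is
a well-formed V2000 counts line, and the bytes of each molfile survive
packaging and splitting verbatim (no chemistry toolkit normalisation).
The provenance fields are replicated into every record because SDF files
are routinely split record-wise downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from . import xml_io
from .schema_model import ElnItemManifest, ManifestError

__all__ = [
    "DepositionPackage",
    "DepositionError",
    "package_deposition",
    "split_deposition",
    "AUTHOR_TAG",
    "PI_TAG",
    "EXPERIMENT_TAG",
]

AUTHOR_TAG = "AUTHOR"
PI_TAG = "PRINCIPAL_INVESTIGATOR"
EXPERIMENT_TAG = "ELN_EXPERIMENT_ID"

_RECORD_TERMINATOR = "$$$$"

# V2000 counts line (line 4 of a molfile): atom and bond counts in fixed
# 3-character fields, version tag "V2000" at the end.  Fields are packed
# without separators, so parse by position rather than by whitespace.
def _parse_counts(line: str) -> tuple[int, int]:
    if not line.rstrip().endswith("V2000"):
        raise ValueError("missing V2000 version tag")
    return int(line[0:3]), int(line[3:6])


class DepositionError(ManifestError):
    pass


@dataclass(frozen=True)
class DepositionPackage:
    """One repository deposition: SDF text + separate manifest document."""

    sdf: str
    manifestFile: str


def _check_molfile(molfile: str, index: int) -> None:
    lines = molfile.splitlines()
    if len(lines) < 4:
        raise DepositionError(
            f"structure {index}: molfile too short to contain a counts line"
        )
    try:
        _parse_counts(lines[3])
    except ValueError:
        raise DepositionError(
            f"structure {index}: line 4 is not a V2000 counts line: {lines[3]!r}"
        ) from None


def _pick_contributor(manifest: ElnItemManifest, roles: set[str], fallback_first: bool) -> str:
    for c in manifest.contributors:
        if c.role.strip().lower() in roles:
            return c.name
    return manifest.contributors[0].name if fallback_first else ""


def package_deposition(
    structures: Sequence[str],
    manifest: ElnItemManifest,
    experimentId: str,
) -> DepositionPackage:
    """Assemble the SDF + manifest pair for one deposition.

    The author field takes the first contributor with role Author (falling
    back to the first contributor of any role); the principal-investigator
    field takes the first contributor with role PI and is left empty when
    there is none.  Every record carries all three fields and ends with the
    ``$$$$`` terminator.
    """
    if not structures:
        raise DepositionError("deposition requires at least one structure")
    for i, molfile in enumerate(structures):
        _check_molfile(molfile, i)

    author = _pick_contributor(manifest, {"author"}, fallback_first=True)
    pi = _pick_contributor(manifest, {"pi", "principal investigator"}, fallback_first=False)

    records = []
    for molfile in structures:
        body = molfile if molfile.endswith("\n") else molfile + "\n"
        fields = (
            f"> <{AUTHOR_TAG}>\n{author}\n\n"
            f"> <{PI_TAG}>\n{pi}\n\n"
            f"> <{EXPERIMENT_TAG}>\n{experimentId}\n\n"
        )
        records.append(body + fields + _RECORD_TERMINATOR + "\n")
    return DepositionPackage(sdf="".join(records), manifestFile=xml_io.to_xml(manifest))


def _parse_record(record: str, index: int) -> tuple[str, dict[str, str]]:
    lines = record.split("\n")
    first_field = next(
        (i for i, line in enumerate(lines) if line.startswith("> <")), None
    )
    if first_field is None:
        raise DepositionError(f"record {index}: no data fields found")
    molfile = "\n".join(lines[:first_field]) + "\n"

    fields: dict[str, str] = {}
    i = first_field
    while i < len(lines):
        line = lines[i]
        if line.startswith("> <") and line.rstrip().endswith(">"):
            tag = line.rstrip()[3:-1]
            values = []
            i += 1
            while i < len(lines) and lines[i] != "":
                values.append(lines[i])
                i += 1
            fields[tag] = "\n".join(values)
        i += 1
    return molfile, fields


def split_deposition(
    package: DepositionPackage,
) -> tuple[list[str], tuple[str, str, str], ElnItemManifest]:
    """Inverse of :func:`package_deposition`.

    Returns the molfile texts (data fields stripped), the (author, PI,
    experimentId) provenance triple, and the parsed manifest.  Records whose
    provenance fields disagree raise a consistency error — the triple is a
    per-deposition property and must be uniform.
    """
    chunks = []
    current: list[str] = []
    for line in package.sdf.split("\n"):
        if line.strip() == _RECORD_TERMINATOR:
            chunks.append("\n".join(current))
            current = []
        else:
            current.append(line)
    if any(s.strip() for s in current):
        raise DepositionError("trailing content after the last $$$$ terminator")
    if not chunks:
        raise DepositionError("SDF contains no records")

    molfiles: list[str] = []
    triple: tuple[str, str, str] | None = None
    for i, chunk in enumerate(chunks):
        molfile, fields = _parse_record(chunk, i)
        for tag in (AUTHOR_TAG, PI_TAG, EXPERIMENT_TAG):
            if tag not in fields:
                raise DepositionError(f"record {i}: missing data field <{tag}>")
        record_triple = (fields[AUTHOR_TAG], fields[PI_TAG], fields[EXPERIMENT_TAG])
        if triple is None:
            triple = record_triple
        elif record_triple != triple:
            raise DepositionError(
                f"record {i}: provenance fields disagree with record 0 "
                f"({record_triple!r} vs {triple!r})"
            )
        molfiles.append(molfile)

    return molfiles, triple, xml_io.from_xml(package.manifestFile)
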