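"""AAindex1 flat-file parsing, validation and export.

An AAindex1 record assigns one numerical value per standard amino acid
(a "property scale"): hydrophobicity, volume, charge, secondary-structure
propensity and so on. Records are keyed by a 10-character accession
(e.g. ``LEVM760107``) and carry their values on two rows of ten numbers
following the ``I`` line, in the fixed residue order
``A R N D C Q E G H I`` / ``L K M F P S T W Y V``. Missing values are
written as ``NA``.

The bundled fixture (:func:`load_bundled`) is a synthetic database: it
reuses published accession identifiers and property descriptions, but its
numerical values are constructed to follow each property's semantics, not
copied from the database. It exists so the whole pipeline is runnable and
testable offline.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import pandas as pd

#: Residue order of the two value rows in an AAindex1 ``I`` block.
AAINDEX_RESIDUE_ORDER = tuple("ARNDCQEGHI") + tuple("LKMFPSTWYV")

#: The 20 standard one-letter codes, alphabetical.
STANDARD_RESIDUES = tuple(sorted(AAINDEX_RESIDUE_ORDER))


class AAIndexParseError(ValueError):
    """Raised for malformed AAindex1 input; names the accession and line."""


@dataclass(frozen=True)
class AAIndexEntry:
    """One amino-acid property scale.

    Parameters
    ----------
    accession
        Database identifier, e.g. ``"LEVM760107"``.
    description
        Free-text property description from the ``D`` line.
    values
        Mapping residue code -> value, covering exactly the 20 standard
        residues minus ``missing_residues``.
    missing_residues
        Residues whose value was ``NA`` in the source record.
    """

    accession: str
    description: str
    values: dict[str, float]
    missing_residues: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        expected = set(STANDARD_RESIDUES) - set(self.missing_residues)
        if set(self.values) != expected:
            raise ValueError(
                f"{self.accession}: values must cover the 20 standard residues "
                f"minus missing_residues (got {sorted(self.values)})"
            )

    @property
    def is_complete(self) -> bool:
        return not self.missing_residues

    def value(self, residue: str) -> float:
        try:
            return self.values[residue]
        except KeyError:
            raise KeyError(
                f"property {self.accession} has no value for residue {residue!r}"
            ) from None


def _iter_records(lines: Iterable[str]) -> Iterator[tuple[int, list[tuple[int, str]]]]:
    """Yield (start_line_number, record_lines) for each ``H``..``//`` block."""
    record: list[tuple[int, str]] = []
    start = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n").rstrip()
        if not record:
            if not line:
                continue
            if not line.startswith("H "):
                raise AAIndexParseError(
                    f"line {lineno}: expected an 'H <accession>' line to start "
                    f"a record, got {line!r}"
                )
            start = lineno
            record.append((lineno, line))
        elif line == "//":
            yield start, record
            record = []
        else:
            record.append((lineno, line))
    if record:
        acc = record[0][1].split(maxsplit=1)[-1]
        raise AAIndexParseError(
            f"record {acc} starting at line {record[0][0]} is not terminated by '//'"
        )


def _parse_record(start: int, lines: list[tuple[int, str]]) -> AAIndexEntry:
    header = lines[0][1]
    parts = header.split(maxsplit=1)
    if len(parts) != 2 or not parts[1].strip():
        raise AAIndexParseError(f"line {start}: H line carries no accession")
    accession = parts[1].strip()

    description_parts: list[str] = []
    tokens: list[str] = []
    value_lines = 0
    in_d = False
    in_i = False
    for lineno, line in lines[1:]:
        tag = line[:1]
        if tag == "D":
            description_parts.append(line[2:].strip())
            in_d, in_i = True, False
        elif tag == "I":
            in_i, in_d = True, False
        elif tag == " " or tag == "\t":
            if in_i:
                tokens.extend(line.split())
                value_lines += 1
            elif in_d:
                description_parts.append(line.strip())
        else:
            # R/A/T/J/C and any other keys are metadata we do not retain.
            in_d = in_i = False
    if value_lines != 2 or len(tokens) != 20:
        raise AAIndexParseError(
            f"record {accession} (line {start}): expected 2 value rows with 20 "
            f"entries after the I line, found {len(tokens)} entries on "
            f"{value_lines} rows"
        )

    values: dict[str, float] = {}
    missing: set[str] = set()
    for residue, token in zip(AAINDEX_RESIDUE_ORDER, tokens):
        if token.upper() == "NA":
            missing.add(residue)
            continue
        try:
            values[residue] = float(token)
        except ValueError:
            raise AAIndexParseError(
                f"record {accession} (line {start}): bad value {token!r} "
                f"for residue {residue}"
            ) from None
    return AAIndexEntry(
        accession=accession,
        description=" ".join(description_parts),
        values=values,
        missing_residues=frozenset(missing),
    )


def parse_aaindex(stream: IO[str] | Iterable[str]) -> list[AAIndexEntry]:
    """Parse an AAindex1 flat file into a list of entries.

    Entry order follows the file. Duplicate accessions and malformed value
    blocks raise :class:`AAIndexParseError` naming the offending accession
    and line.
    """
    entries: list[AAIndexEntry] = []
    seen: dict[str, int] = {}
    for start, record in _iter_records(stream):
        entry = _parse_record(start, record)
        if entry.accession in seen:
            raise AAIndexParseError(
                f"duplicate accession {entry.accession} at line {start} "
                f"(first seen at line {seen[entry.accession]})"
            )
        seen[entry.accession] = start
        entries.append(entry)
    return entries


def write_aaindex(entries: Iterable[AAIndexEntry], stream: IO[str]) -> None:
    """Write entries back out in AAindex1 flat format (H/D/I blocks)."""
    for entry in entries:
        stream.write(f"H {entry.accession}\n")
        stream.write(f"D {entry.description}\n")
        stream.write(
            "I    A/L     R/K     N/M     D/F     C/P     Q/S     "
            "E/T     G/W     H/Y     I/V\n"
        )
        for row in (AAINDEX_RESIDUE_ORDER[:10], AAINDEX_RESIDUE_ORDER[10:]):
            cells = []
            for residue in row:
                if residue in entry.missing_residues:
                    cells.append("NA".rjust(8))
                else:
                    cells.append(f"{entry.values[residue]:8.4f}")
            stream.write("  " + " ".join(cells) + "\n")
        stream.write("//\n")


def filter_complete(entries: Iterable[AAIndexEntry]) -> list[AAIndexEntry]:
    """Keep only entries with a value for all 20 residues, order preserved."""
    return [e for e in entries if e.is_complete]


def to_frame(entries: Iterable[AAIndexEntry]) -> pd.DataFrame:
    """Normalised table: one row per entry, one column per residue."""
    rows = []
    for e in entries:
        row: dict[str, object] = {"accession": e.accession, "description": e.description}
        for residue in STANDARD_RESIDUES:
            row[residue] = e.values.get(residue, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def load_bundled() -> list[AAIndexEntry]:
    """Load the synthetic property fixture shipped with the package.

    Contains the seven accessions used throughout the worked examples plus
    extra synthetic scales (one deliberately incomplete, to exercise
    NA handling). Values are constructed, not database values.
    """
    ref = importlib.resources.files("pepqsar.data") / "synthetic_aaindex.txt"
    with ref.open("r") as handle:
        return parse_aaindex(handle)
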