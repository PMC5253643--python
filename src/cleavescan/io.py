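"""Substrate input and tabular report output.

FASTA reading is delegated to Biopython's parser; this module owns the
validation policy (duplicate ids, alphabet strictness, stop-codon ``*``
stripping, whitespace/digit removal) and the deterministic TSV/JSON report
layouts.
"""

from __future__ import annotations

import csv
import io as _stdio
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, TYPE_CHECKING, Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .patterns import NONSTANDARD_LETTERS, STANDARD_AA_SET

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids an import cycle
    from .digest import DigestResult, Fragment
    from .scanner import ConsensusOccurrence

logger = logging.getLogger("cleavescan")

#: Fragment sequences longer than this are abbreviated head…tail in reports.
ABBREV_THRESHOLD = 20

OCCURRENCE_COLUMNS = ["Sequence_ID", "Pattern", "Consensus", "Start", "End", "Cleavage_After"]
FRAGMENT_COLUMNS = [
    "Sequence_ID", "Scenario", "Fragment_Seq", "Start", "End", "Avg_Mass_Da", "Mono_Mass_Da",
]


class InputError(ValueError):
    """Raised for malformed or inconsistent substrate input (exit code 2)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One substrate protein with 1-based residue coordinates.

    ``id`` is the first whitespace-delimited token of the FASTA definition
    line; ``description`` is the remainder. The sequence is upper-case and
    free of whitespace, digits and stop marks.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("protein record with empty id")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """Substrate residues *start*..*end*, both 1-based inclusive."""
        return self.sequence[start - 1 : end]


def _canonicalize(raw: str, record_id: str, alphabet: str) -> str:
    seq = "".join(ch for ch in raw.upper() if not ch.isspace() and not ch.isdigit())
    seq = seq.rstrip("*")
    allowed = STANDARD_AA_SET if alphabet == "strict" else STANDARD_AA_SET | NONSTANDARD_LETTERS
    bad = sorted(set(seq) - allowed)
    if bad:
        raise InputError(
            f"record {record_id!r}: illegal sequence character(s) {''.join(bad)!r}"
            + (" (use alphabet='permissive' to accept ambiguity codes)"
               if alphabet == "strict" and set(bad) <= NONSTANDARD_LETTERS else "")
        )
    return seq


def read_fasta(source: str | os.PathLike | IO[str], *, alphabet: str = "strict") -> list[ProteinRecord]:
    """Read a multi-record FASTA file into :class:`ProteinRecord` objects.

    Line wrapping is irrelevant; a trailing ``*`` is stripped; sequences
    are upper-cased. ``alphabet='strict'`` (default) rejects any letter
    outside the 20 standard residues; ``'permissive'`` additionally keeps
    ambiguity codes (which the scanner will simply never match).
    """
    if alphabet not in ("strict", "permissive"):
        raise ValueError(f"alphabet must be 'strict' or 'permissive', got {alphabet!r}")
    close = False
    if isinstance(source, (str, os.PathLike)):
        path = Path(source)
        if not path.exists():
            raise InputError(f"input file not found: {path}")
        handle: IO[str] = open(path)
        close = True
    else:
        handle = source
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    try:
        text = handle.read()
    finally:
        if close:
            handle.close()
    stripped = text.lstrip()
    if not stripped:
        raise InputError("no FASTA records in input")
    if not stripped.startswith(">"):
        raise InputError("sequence data before first '>' header")
    for rec in SeqIO.parse(_stdio.StringIO(text), "fasta"):
        rid = rec.id
        if not rid:
            raise InputError("FASTA record with empty id")
        if rid in seen:
            raise InputError(f"duplicate record id {rid!r}")
        seen.add(rid)
        description = rec.description[len(rec.id):].strip() if rec.description else ""
        seq = _canonicalize(str(rec.seq), rid, alphabet)
        records.append(ProteinRecord(id=rid, sequence=seq, description=description))
        logger.info("read record %s (%d aa)", rid, len(seq))
    if not records:
        raise InputError("no FASTA records in input")
    return records


def write_fasta(records: Iterable[ProteinRecord], destination: str | os.PathLike | IO[str], *, width: int = 60) -> None:
    """Write records as wrapped FASTA (inverse of :func:`read_fasta`)."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description) for r in records
    ]
    if isinstance(destination, (str, os.PathLike)):
        with open(destination, "w") as handle:
            _write_wrapped(seqrecords, handle, width)
    else:
        _write_wrapped(seqrecords, destination, width)


def _write_wrapped(seqrecords: Sequence[SeqRecord], handle: IO[str], width: int) -> None:
    writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
    writer.write_file(seqrecords)


def abbreviate(sequence: str, threshold: int = ABBREV_THRESHOLD) -> str:
    """Head…tail display form for long sequences, e.g. ``MTTT…DSID``."""
    if len(sequence) <= threshold:
        return sequence
    return sequence[:4] + "…" + sequence[-4:]


def _occurrence_rows(occurrences: Iterable["ConsensusOccurrence"], *, context: int = 0,
                     sequences: dict[str, str] | None = None) -> list[dict]:
    rows = []
    for occ in occurrences:
        shown = occ.matched_subsequence
        if context > 0 and sequences and occ.protein_id in sequences:
            seq = sequences[occ.protein_id]
            shown = seq[max(0, occ.start - 1 - context): min(len(seq), occ.end + context)]
        rows.append({
            "Sequence_ID": occ.protein_id,
            "Pattern": occ.pattern_name,
            "Consensus": shown,
            "Start": occ.start,
            "End": occ.end,
            "Cleavage_After": occ.cleavage_position,
        })
    return rows


def write_occurrences(
    occurrences: Iterable["ConsensusOccurrence"],
    destination: str | os.PathLike | IO[str],
    *,
    format: str = "tsv",
    context: int = 0,
    sequences: dict[str, str] | None = None,
) -> None:
    """Write a consensus-occurrence table (TSV or JSON).

    ``context`` pads the displayed consensus with that many residues of
    substrate context on each side (display only; coordinates are those of
    the core match). Requires ``sequences`` (id → sequence) when non-zero.
    """
    rows = _occurrence_rows(occurrences, context=context, sequences=sequences)
    _write_rows(rows, OCCURRENCE_COLUMNS, destination, format)


def _scenario_label(key: tuple[int, ...]) -> str:
    return "+".join(str(c) for c in key)


def _fragment_rows(result: "DigestResult") -> list[dict]:
    def row(frag: "Fragment", scenario: str) -> dict:
        return {
            "Sequence_ID": frag.protein_id,
            "Scenario": scenario,
            "Fragment_Seq": abbreviate(frag.sequence),
            "Start": frag.start,
            "End": frag.end,
            "Avg_Mass_Da": round(frag.avg_mass, 4) if frag.avg_mass is not None else "",
            "Mono_Mass_Da": round(frag.mono_mass, 4) if frag.mono_mass is not None else "",
        }

    rows: list[dict] = []
    for key in sorted(result.scenarios):
        rows.extend(row(f, _scenario_label(key)) for f in result.scenarios[key])
    rows.extend(row(f, "distinct") for f in result.distinct_fragments)
    return rows


def write_report(
    results: "DigestResult" | Iterable["DigestResult"],
    destination: str | os.PathLike | IO[str],
    *,
    format: str = "tsv",
) -> None:
    """Write the fragment (breakdown-product) report for one or more digests.

    Rows are ordered by protein input order, then scenario (a ``+``-joined
    list of the cut sites applied, or ``distinct`` for the deduplicated
    union), then fragment start. JSON output mirrors the TSV fields
    exactly. Long sequences are abbreviated head…tail; full fragment
    sequences are available via :func:`write_fragment_fasta`.
    """
    from .digest import DigestResult  # local import: io ↔ digest cycle

    if isinstance(results, DigestResult):
        results = [results]
    rows: list[dict] = []
    for result in results:
        rows.extend(_fragment_rows(result))
    _write_rows(rows, FRAGMENT_COLUMNS, destination, format)


def write_fragment_fasta(result: "DigestResult", destination: str | os.PathLike | IO[str]) -> None:
    """Full sequences of the distinct fragments, id = proteinid_start_end."""
    records = [
        ProteinRecord(id=f"{frag.protein_id}_{frag.start}_{frag.end}", sequence=frag.sequence)
        for frag in result.distinct_fragments
    ]
    write_fasta(records, destination)


def _write_rows(rows: list[dict], columns: list[str], destination, format: str) -> None:
    if format not in ("tsv", "json"):
        raise ValueError(f"format must be 'tsv' or 'json', got {format!r}")
    if isinstance(destination, (str, os.PathLike)):
        with open(destination, "w", newline="") as handle:
            _write_rows_handle(rows, columns, handle, format)
    else:
        _write_rows_handle(rows, columns, destination, format)


def _write_rows_handle(rows: list[dict], columns: list[str], handle: IO[str], format: str) -> None:
    if format == "tsv":
        writer = csv.DictWriter(handle, fieldnames=columns, delimiter="\t", lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)
    else:
        json.dump(rows, handle, indent=2, ensure_ascii=False)
        handle.write("\n")
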