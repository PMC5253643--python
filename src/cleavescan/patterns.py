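"""Protease consensus patterns as positional residue constraints.

A protease recognises a short consensus motif and hydrolyses one specific
peptide bond at a fixed offset inside (or immediately after) that motif.
Here a motif is an ordered list of residue *sets*: a singleton set pins a
position to one amino acid, the full 20-letter set is the wildcard ``X``,
and any other subset expresses alternatives such as ``[LVI]``.

Built-ins cover the two executioner proteases of neural cell death:

* caspase-3 — ``DXXD|`` (cleaves after the second Asp; apoptosis),
* calpain-2 — ``[LVI]X|`` (cleaves two residues after Leu/Val/Ile;
  necrosis and some apoptosis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Mapping

#: The 20 standard amino acids, one-letter codes, alphabetical.
STANDARD_AA: str = "ACDEFGHIKLMNPQRSTVWY"
STANDARD_AA_SET: frozenset[str] = frozenset(STANDARD_AA)

#: Letters that may legally appear in real-world sequence files but never
#: denote one specific standard residue (ambiguity/rare codes and stops).
NONSTANDARD_LETTERS: frozenset[str] = frozenset("BJZUOX*")


class PatternError(ValueError):
    """Raised for malformed pattern specifications or invalid patterns."""


class CoordinateError(ValueError):
    """Raised when a 1-based coordinate falls outside its sequence."""


@dataclass(frozen=True)
class ProteasePattern:
    """A consensus motif plus the position of the scissile bond.

    Parameters
    ----------
    name:
        Label used in reports and result mappings.
    positions:
        Ordered residue-constraint sets, N- to C-terminal. Each set must be
        a non-empty subset of the 20 standard amino acids.
    cleavage_offset:
        Number of motif positions N-terminal of the cut: the bond between
        substrate residue ``start + cleavage_offset - 1`` and the next
        residue is hydrolysed. Must lie in ``[1, len(positions)]``.
    """

    name: str
    positions: tuple[frozenset[str], ...]
    cleavage_offset: int

    def __post_init__(self) -> None:
        if not self.positions:
            raise PatternError(f"pattern {self.name!r}: no positions")
        for i, pos in enumerate(self.positions, start=1):
            if not pos:
                raise PatternError(f"pattern {self.name!r}: empty set at position {i}")
            if not pos <= STANDARD_AA_SET:
                bad = "".join(sorted(pos - STANDARD_AA_SET))
                raise PatternError(
                    f"pattern {self.name!r}: non-standard residue(s) {bad!r} at position {i}"
                )
        if not 1 <= self.cleavage_offset <= len(self.positions):
            raise PatternError(
                f"pattern {self.name!r}: cleavage offset {self.cleavage_offset} "
                f"outside [1, {len(self.positions)}]"
            )

    def __len__(self) -> int:
        return len(self.positions)

    def __iter__(self) -> Iterator[frozenset[str]]:
        return iter(self.positions)

    def format(self) -> str:
        """Canonical text form of the motif, e.g. ``DXXD|`` or ``[ILV]X|``.

        Sets with more than one residue are bracketed and alphabetised;
        the full alphabet prints as ``X``; ``|`` marks the cut.
        """
        parts: list[str] = []
        for i, pos in enumerate(self.positions, start=1):
            if pos == STANDARD_AA_SET:
                parts.append("X")
            elif len(pos) == 1:
                parts.append(next(iter(pos)))
            else:
                parts.append("[" + "".join(sorted(pos)) + "]")
            if i == self.cleavage_offset:
                parts.append("|")
        return "".join(parts)


#: Caspase-3 consensus DXXD with the cut after the C-terminal Asp.
CASPASE3 = ProteasePattern(
    name="caspase3",
    positions=(
        frozenset("D"),
        STANDARD_AA_SET,
        STANDARD_AA_SET,
        frozenset("D"),
    ),
    cleavage_offset=4,
)

#: Calpain-2 consensus [LVI]X, one pattern covering the LX/VX/IX family.
CALPAIN2 = ProteasePattern(
    name="calpain2",
    positions=(frozenset("LVI"), STANDARD_AA_SET),
    cleavage_offset=2,
)


def builtin_patterns() -> dict[str, ProteasePattern]:
    """Return the built-in protease models keyed by name."""
    return {"caspase3": CASPASE3, "calpain2": CALPAIN2}


def count_instances(pattern: ProteasePattern) -> int:
    """Number of distinct literal words matching *pattern*.

    The product of the position-set sizes: 400 for caspase-3 (two fixed
    Asp, two wildcards), 60 for calpain-2 (three alternatives, one
    wildcard).
    """
    return math.prod(len(pos) for pos in pattern.positions)


def matches_at(
    sequence: str,
    start: int,
    pattern: ProteasePattern,
    *,
    permissive_wildcard: bool = False,
) -> bool:
    """True iff *pattern* matches *sequence* at 1-based position *start*.

    Non-standard letters (B, J, Z, U, O, X, ``*``) never satisfy a fixed
    position and, unless ``permissive_wildcard`` is set, do not satisfy a
    wildcard either — ambiguity codes must not fabricate cleavage sites.
    """
    m = len(pattern)
    if start < 1 or start + m - 1 > len(sequence):
        raise CoordinateError(
            f"window [{start}, {start + m - 1}] outside sequence of length {len(sequence)}"
        )
    for offset, pos in enumerate(pattern.positions):
        residue = sequence[start - 1 + offset]
        if residue in pos:
            continue
        if permissive_wildcard and pos == STANDARD_AA_SET and residue not in "*":
            continue
        return False
    return True


def parse_pattern(spec: str, name: str | None = None) -> ProteasePattern:
    """Parse a motif mini-language string into a :class:`ProteasePattern`.

    Grammar: one-letter amino-acid codes; ``X``/``x`` for the wildcard;
    ``[...]`` for alternatives; exactly one ``|`` marking the cut point,
    after at least one position. Examples: ``DXXD|``, ``[LVI]X|``.

    The parse round-trips: ``parse_pattern(p.format()) == p`` for the
    canonical form. ``name`` defaults to the canonical form itself.
    """
    if not spec or not spec.strip():
        raise PatternError("empty pattern spec")
    positions: list[frozenset[str]] = []
    cleavage_offset: int | None = None
    i = 0
    text = spec.strip()
    while i < len(text):
        ch = text[i]
        if ch == "|":
            if cleavage_offset is not None:
                raise PatternError(f"multiple '|' in pattern spec {spec!r}")
            if not positions:
                raise PatternError(f"'|' before any position in pattern spec {spec!r}")
            cleavage_offset = len(positions)
            i += 1
        elif ch == "[":
            end = text.find("]", i)
            if end == -1:
                raise PatternError(f"unclosed '[' in pattern spec {spec!r}")
            letters = text[i + 1 : end].upper()
            if not letters:
                raise PatternError(f"empty alternative set in pattern spec {spec!r}")
            bad = set(letters) - STANDARD_AA_SET
            if bad:
                raise PatternError(
                    f"unknown residue(s) {''.join(sorted(bad))!r} in pattern spec {spec!r}"
                )
            positions.append(frozenset(letters))
            i = end + 1
        elif ch.upper() == "X":
            positions.append(STANDARD_AA_SET)
            i += 1
        elif ch.upper() in STANDARD_AA_SET:
            positions.append(frozenset(ch.upper()))
            i += 1
        else:
            raise PatternError(f"unexpected character {ch!r} in pattern spec {spec!r}")
    if cleavage_offset is None:
        raise PatternError(f"missing '|' cleavage mark in pattern spec {spec!r}")
    pattern = ProteasePattern(
        name=name or "", positions=tuple(positions), cleavage_offset=cleavage_offset
    )
    if not name:
        pattern = ProteasePattern(
            name=pattern.format(), positions=pattern.positions,
            cleavage_offset=pattern.cleavage_offset,
        )
    return pattern
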