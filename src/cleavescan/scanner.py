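"""Consensus-occurrence scanning via a local-alignment scoring table.

The scan aligns each consensus motif locally against the substrate with a
Smith–Waterman-style dynamic-programming table, then prunes every
alignment containing an insertion, deletion or fixed-position mismatch,
leaving exactly the full-length exact occurrences of the motif (wildcard
and alternative positions accept any of their residues). A naive
sliding-window scan is provided as an independent oracle; the two are
contractually identical on every input.

Scoring: match +1; mismatch and gap both −m (the motif length), with the
local-alignment floor at 0. An alignment of the full motif therefore
reaches the maximum score m only if it is gap-free and matches at every
position, which is precisely the pruning rule. A useful consequence: the
best score in row i is at most i, so a vertical or horizontal (gap) move
scores at most i − m ≤ 0 and can never beat the floor — each DP row
reduces to ``max(0, diag + score)`` and vectorises, while the table
remains exactly the one the full recurrence defines.

Complexity per (protein, motif) pair: O(mn) time and space for motif
length m and substrate length n; a multi-protein scan streams one table
at a time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import ProteinRecord
from .patterns import ProteasePattern, matches_at

logger = logging.getLogger("cleavescan")


@dataclass(frozen=True)
class ConsensusOccurrence:
    """One motif hit: coordinates are 1-based and inclusive.

    ``cleavage_position`` is the substrate residue after which the bond is
    cut (``start + cleavage_offset − 1``; for the built-in proteases this
    equals ``end``).
    """

    protein_id: str
    pattern_name: str
    matched_subsequence: str
    start: int
    end: int
    cleavage_position: int


@dataclass(frozen=True)
class ScoringTable:
    """The (m+1)×(n+1) local-alignment score matrix for one motif/substrate."""

    scores: np.ndarray
    pattern_name: str = ""

    @property
    def m(self) -> int:
        """Motif length (rows − 1)."""
        return self.scores.shape[0] - 1

    @property
    def n(self) -> int:
        """Substrate length (cols − 1)."""
        return self.scores.shape[1] - 1


def _membership_rows(sequence: str, pattern: ProteasePattern) -> np.ndarray:
    """Boolean (m, n) matrix: does substrate residue j satisfy motif position i."""
    n = len(sequence)
    codes = np.frombuffer(sequence.encode("latin-1"), dtype=np.uint8) if n else np.empty(0, np.uint8)
    rows = np.zeros((len(pattern), n), dtype=bool)
    for i, pos in enumerate(pattern.positions):
        lut = np.zeros(256, dtype=bool)
        for aa in pos:
            lut[ord(aa)] = True
        rows[i] = lut[codes]
    return rows


def build_scoring_table(sequence: str, pattern: ProteasePattern) -> ScoringTable:
    """Fill the local-alignment DP table for *pattern* against *sequence*."""
    m, n = len(pattern), len(sequence)
    scores = np.zeros((m + 1, n + 1), dtype=np.int64)
    if n:
        member = _membership_rows(sequence, pattern)
        penalty = -m  # mismatch == gap == −m: see module docstring
        for i in range(1, m + 1):
            substitution = np.where(member[i - 1], 1, penalty)
            scores[i, 1:] = np.maximum(0, scores[i - 1, :-1] + substitution)
    return ScoringTable(scores=scores, pattern_name=pattern.name)


def extract_occurrences(
    table: ScoringTable,
    sequence: str,
    pattern: ProteasePattern,
    protein_id: str = "",
) -> list[ConsensusOccurrence]:
    """Recover full-length, gap-free maximal alignments from the table.

    Keeps exactly the cells of the last row that attain the maximum score
    m and whose traceback is purely diagonal with a match at every step
    (INDEL-containing and partial alignments are pruned). Overlapping
    occurrences are all retained; output is ordered by start position.
    """
    m, n = len(pattern), len(sequence)
    if table.scores.shape != (m + 1, n + 1):
        raise ValueError(
            f"scoring table shape {table.scores.shape} does not fit "
            f"motif length {m} and substrate length {n}"
        )
    scores = table.scores
    hits: list[ConsensusOccurrence] = []
    for j in np.flatnonzero(scores[m, 1:] == m) + 1:
        # Gap-free traceback: each step must be the diagonal match move.
        ok = all(
            scores[i, j - (m - i)] == scores[i - 1, j - (m - i) - 1] + 1
            and sequence[j - (m - i) - 1] in pattern.positions[i - 1]
            for i in range(m, 0, -1)
        )
        if not ok:
            continue
        start = int(j) - m + 1
        hits.append(
            ConsensusOccurrence(
                protein_id=protein_id,
                pattern_name=pattern.name,
                matched_subsequence=sequence[start - 1 : int(j)],
                start=start,
                end=int(j),
                cleavage_position=start + pattern.cleavage_offset - 1,
            )
        )
    return hits


def naive_scan(protein: ProteinRecord, pattern: ProteasePattern) -> list[ConsensusOccurrence]:
    """Sliding-window oracle: test every start position directly."""
    m = len(pattern)
    hits = []
    for start in range(1, protein.length - m + 2):
        if matches_at(protein.sequence, start, pattern):
            hits.append(
                ConsensusOccurrence(
                    protein_id=protein.id,
                    pattern_name=pattern.name,
                    matched_subsequence=protein.slice(start, start + m - 1),
                    start=start,
                    end=start + m - 1,
                    cleavage_position=start + pattern.cleavage_offset - 1,
                )
            )
    return hits


def scan(protein: ProteinRecord, pattern: ProteasePattern) -> list[ConsensusOccurrence]:
    """Find every occurrence of *pattern* in *protein* via the DP table."""
    table = build_scoring_table(protein.sequence, pattern)
    hits = extract_occurrences(table, protein.sequence, pattern, protein.id)
    logger.debug("%s × %s: %d occurrence(s)", protein.id, pattern.name, len(hits))
    return hits


def scan_many(
    proteins: Sequence[ProteinRecord],
    patterns: Iterable[ProteasePattern],
) -> dict[str, dict[str, list[ConsensusOccurrence]]]:
    """Scan every (protein, pattern) pair, streaming one protein at a time.

    Peak table storage stays proportional to m×n for a single pair; the
    result maps protein id → pattern name → occurrence list, preserving
    protein input order.
    """
    patterns = list(patterns)
    ids = [p.id for p in proteins]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate protein id(s): {', '.join(dupes)}")
    results: dict[str, dict[str, list[ConsensusOccurrence]]] = {}
    for protein in proteins:
        logger.info("scanning %s (%d aa) with %d pattern(s)", protein.id, protein.length, len(patterns))
        results[protein.id] = {pat.name: scan(protein, pat) for pat in patterns}
    return results


def context_window(sequence: str, occurrence: ConsensusOccurrence, width: int) -> str:
    """Matched subsequence padded with *width* residues of substrate context.

    Display helper only — the occurrence coordinates are unchanged.
    """
    lo = max(0, occurrence.start - 1 - width)
    hi = min(len(sequence), occurrence.end + width)
    return sequence[lo:hi]
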