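"""Synthetic substrates with known planted motifs, plus one real worked case.

The generator builds random amino-acid sequences with consensus motifs
planted at recorded positions, so scanner output can be checked against
an exact ground truth at any scale — a desk-scale stand-in for whole-
proteome runs. One real substrate is embedded: a 775-residue mouse
protein (record id "194") whose acidic region carries five DEED
occurrences, three of them mutually overlapping, which makes it the
canonical test of overlap handling.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .io import ProteinRecord
from .patterns import STANDARD_AA, ProteasePattern, builtin_patterns
from .scanner import naive_scan

_TABLE4_SEQUENCE = (
    "MLQDSITGIVNSFNLFFPSTMSRPTLMPTCVAFCSILFLTLATGCQAFPKVERRETAQEYAEKEQSQKMN"
    "TDDQENISFAPKYMLQQMSSEAPMVLSEGPSEIPLIKVFSVNKESHLPGAGLLHPTSPGVYSSSEPVVSA"
    "SEQEPGPSLLERMSSEHSLSKVMLTVAVSSPASLNPDQEGPYNSLSTQPIVAAVTDVTHGSLDYLDNQLF"
    "AAKSQEAVSLGNSPSSSINTKEPEIIKADAAMGTTVVPGVDSTGDMEPDRERPSEMAADDGQSTTTKYLV"
    "TIPNNFLTTEPTAGSILGDAKVTVSVSTAGPVSSIFNEEWDDTKFESISRGRPPEPGDNAETQMRTKPPH"
    "GTYESFEGTEESPSSTAVLKVAPGHLGGEPALGTALVTALGDERSPVLTHQISFTPMSLAEDPEVSTMKL"
    "FPSAGGFRASTQGDRTQLSSETAFSTSQYESVPQQEAGNVLKDITQERKMATQAMNTTSPVVTQEHMATI"
    "EVPRGSGEPEEGMPSLSPVPAEVADAELSRRGESLATPASTTVVPLSLKLTSSMEDLMDTITGPSEEFIP"
    "VLGSPMAPPAMTVEAPTISSALPSEGRTSPSISRPNTAASYGLEQLESEEVEDDEDEEDEEDEEEEEEDE"
    "EDEEDEEDKETDSLYKDFDGDTEPPGFTLPGITSQEPDIRSGSMDLLEVATYQVPETIEWEQQNQGLVRS"
    "WMEKLKDKAGYMSGMLVPVGVGIAGALFILGALYSIKVMNRRRRNGFKRHKRKQREFNSMQDRVMLLADS"
    "SEDEF"
)


def table4_record() -> ProteinRecord:
    """The embedded 775-residue worked-example substrate, id ``"194"``."""
    return ProteinRecord(id="194", sequence=_TABLE4_SEQUENCE,
                         description="mouse protein with overlapping DEED occurrences")


@dataclass(frozen=True)
class PlantedTruth:
    """A synthetic substrate plus the exact motif placements it contains."""

    record: ProteinRecord
    #: (pattern_name, start, cleavage_position) for every planted motif
    planted: tuple[tuple[str, int, int], ...]
    seed: int
    #: residue → sampling weight for the background positions
    background: Mapping[str, float]


def _resolve(pattern: str | ProteasePattern) -> ProteasePattern:
    if isinstance(pattern, ProteasePattern):
        return pattern
    try:
        return builtin_patterns()[pattern]
    except KeyError:
        raise ValueError(f"unknown built-in protease {pattern!r}") from None


def plant_motifs(
    length: int,
    placements: Sequence[tuple[str | ProteasePattern, int]],
    seed: int,
    *,
    collision_free: bool = False,
    allow_overlap: bool = False,
    background: Mapping[str, float] | None = None,
    record_id: str = "planted",
    max_rerolls: int = 1000,
) -> PlantedTruth:
    """Generate a random substrate with motifs planted at fixed positions.

    Each placement is ``(pattern_or_builtin_name, 1-based start)``; a
    concrete word matching the pattern is sampled for each. Overlapping
    placements are rejected unless ``allow_overlap`` is set, in which case
    the residue constraints of all covering patterns are intersected
    (an empty intersection is an error). With ``collision_free``,
    background residues are re-rolled until a naive scan recovers exactly
    the planted truth set and nothing else.

    Deterministic for a fixed seed.
    """
    rng = random.Random(seed)
    weights = dict.fromkeys(STANDARD_AA, 1.0) if background is None else dict(background)
    bg_letters = sorted(weights)
    bg_weights = [weights[aa] for aa in bg_letters]

    resolved = [(_resolve(p), start) for p, start in placements]
    constraints: dict[int, frozenset[str]] = {}  # 0-based index → allowed residues
    covered: set[int] = set()
    for pattern, start in resolved:
        end = start + len(pattern) - 1
        if start < 1 or end > length:
            raise ValueError(
                f"placement of {pattern.name!r} at {start} exceeds substrate length {length}"
            )
        window = set(range(start - 1, end))
        if window & covered and not allow_overlap:
            raise ValueError(
                f"placement of {pattern.name!r} at {start} overlaps another placement "
                "(pass allow_overlap=True to permit)"
            )
        covered |= window
        for offset, pos in enumerate(pattern.positions):
            idx = start - 1 + offset
            merged = constraints.get(idx, pos) & pos
            if not merged:
                raise ValueError(
                    f"overlapping placements leave no legal residue at position {idx + 1}"
                )
            constraints[idx] = merged

    residues = [
        rng.choice(sorted(constraints[i])) if i in constraints
        else rng.choices(bg_letters, weights=bg_weights)[0]
        for i in range(length)
    ]

    truth = tuple(
        (pattern.name, start, start + pattern.cleavage_offset - 1)
        for pattern, start in resolved
    )
    patterns_used = {pattern.name: pattern for pattern, _ in resolved}

    if collision_free:
        expected = {(name, start) for name, start, _ in truth}
        for _ in range(max_rerolls):
            record = ProteinRecord(id=record_id, sequence="".join(residues))
            spurious = [
                occ
                for pattern in patterns_used.values()
                for occ in naive_scan(record, pattern)
                if (occ.pattern_name, occ.start) not in expected
            ]
            if not spurious:
                break
            for occ in spurious:
                # Re-roll any residue of the hit window that is not pinned to
                # a single letter; wildcard positions of planted windows are
                # re-sampled within their constraint sets.
                free = [
                    i for i in range(occ.start - 1, occ.end)
                    if i not in constraints or len(constraints[i]) > 1
                ]
                if not free:
                    raise RuntimeError(
                        f"spurious {occ.pattern_name!r} hit at {occ.start} is fully "
                        "pinned by the planted motifs and cannot be re-rolled"
                    )
                for i in free:
                    if i in constraints:
                        residues[i] = rng.choice(sorted(constraints[i]))
                    else:
                        residues[i] = rng.choices(bg_letters, weights=bg_weights)[0]
        else:
            raise RuntimeError(f"could not reach a collision-free substrate in {max_rerolls} re-rolls")

    return PlantedTruth(
        record=ProteinRecord(id=record_id, sequence="".join(residues)),
        planted=truth,
        seed=seed,
        background=weights,
    )


def random_proteome(
    n_records: int,
    length_range: tuple[int, int] = (50, 500),
    seed: int = 0,
) -> list[ProteinRecord]:
    """Uniform random amino-acid sequences, deterministic under *seed*.

    Record ids are ``S0001`` … ``S{n}``; lengths are drawn uniformly from
    the inclusive ``length_range``.
    """
    if n_records < 0:
        raise ValueError("n_records must be non-negative")
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid length range {length_range}")
    rng = random.Random(seed)
    return [
        ProteinRecord(
            id=f"S{i + 1:04d}",
            sequence="".join(rng.choices(STANDARD_AA, k=rng.randint(lo, hi))),
        )
        for i in range(n_records)
    ]
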