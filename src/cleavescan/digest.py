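"""Cut-site derivation and breakdown-product (fragment) enumeration.

Each consensus occurrence contributes one candidate cut site. Because any
subset of the sites may be cleaved in a given molecule, the digest offers
three views:

* ``per-site`` — one scenario per single cut site (the per-occurrence
  fragment pairs shown in a classic cleavage table);
* ``scenarios`` — every non-empty subset of the k sites (2^k − 1
  scenarios; guarded by ``max_sites``);
* ``distinct``  — the deduplicated union of fragments over all scenarios,
  computed in O(k²) from boundary pairs, count (k+1)(k+2)/2 − 1.

Cut sites falling after the final residue are suppressed (they would
yield an empty product), and the intact protein is not itself reported as
a breakdown product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .io import ProteinRecord
from .patterns import ProteasePattern
from .scanner import ConsensusOccurrence, scan

#: Enumerating all subsets is refused above this many cut sites (65535
#: scenarios); use the distinct-fragment union instead, or raise the cap.
DEFAULT_MAX_SITES = 16

DIGEST_MODES = ("per-site", "scenarios", "distinct")


class CombinationCapError(RuntimeError):
    """Raised when subset enumeration would explode (exit code 3)."""


@dataclass
class Fragment:
    """One breakdown product, bounded by two cut positions.

    ``left_cut`` = 0 means the protein N-terminus; ``right_cut`` equal to
    the protein length means the C-terminus. Coordinates are 1-based
    inclusive, with ``start = left_cut + 1`` and ``end = right_cut``.
    Masses are filled in by :func:`cleavescan.mass.annotate_fragments`.
    """

    protein_id: str
    start: int
    end: int
    sequence: str
    left_cut: int
    right_cut: int
    avg_mass: float | None = None
    mono_mass: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class DigestResult:
    """Occurrences, merged cut sites and fragments for one substrate."""

    protein: ProteinRecord
    occurrences: dict[str, list[ConsensusOccurrence]]
    cut_sites: list[int]
    #: cut position → names of the proteases whose occurrences produced it
    site_proteases: dict[int, tuple[str, ...]]
    mode: str
    scenarios: dict[tuple[int, ...], list[Fragment]] = field(default_factory=dict)
    distinct_fragments: list[Fragment] = field(default_factory=list)
    parent_avg_mass: float | None = None
    parent_mono_mass: float | None = None

    @property
    def protein_id(self) -> str:
        return self.protein.id


def cut_sites(occurrences: Iterable[ConsensusOccurrence], protein: ProteinRecord) -> list[int]:
    """Deduplicated, sorted cleavage positions from *occurrences*.

    A position equal to the protein length is dropped: cutting after the
    last residue would produce an empty product. Overlapping occurrences
    with distinct cleavage positions each contribute their own site.
    """
    sites: set[int] = set()
    for occ in occurrences:
        if occ.protein_id != protein.id:
            raise ValueError(
                f"occurrence belongs to protein {occ.protein_id!r}, not {protein.id!r}"
            )
        if occ.cleavage_position < protein.length:
            sites.add(occ.cleavage_position)
    return sorted(sites)


def fragments_for_subset(protein: ProteinRecord, subset: Iterable[int]) -> list[Fragment]:
    """Fragments produced by cleaving at exactly the positions in *subset*.

    Returns |subset| + 1 contiguous fragments partitioning the substrate;
    the empty subset yields the intact protein as a single fragment.
    """
    cuts = sorted(set(subset))
    for c in cuts:
        if not 0 < c < protein.length:
            raise ValueError(
                f"cut position {c} outside (0, {protein.length}) for protein {protein.id!r}"
            )
    bounds = [0, *cuts, protein.length]
    return [
        Fragment(
            protein_id=protein.id,
            start=left + 1,
            end=right,
            sequence=protein.slice(left + 1, right),
            left_cut=left,
            right_cut=right,
        )
        for left, right in zip(bounds[:-1], bounds[1:])
    ]


def enumerate_scenarios(
    protein: ProteinRecord,
    sites: Sequence[int],
    max_sites: int = DEFAULT_MAX_SITES,
) -> dict[tuple[int, ...], list[Fragment]]:
    """All 2^k − 1 cleavage scenarios for k cut sites.

    Each non-empty subset of *sites* is one scenario, keyed by the sorted
    tuple of its cut positions. Refuses to enumerate when k exceeds
    ``max_sites``; callers may raise the cap or fall back to
    :func:`distinct_fragments`.
    """
    sites = sorted(set(sites))
    k = len(sites)
    if k > max_sites:
        raise CombinationCapError(
            f"{k} cut sites would give {2 ** k - 1} scenarios (cap {max_sites}); "
            "raise max_sites or use distinct fragments"
        )
    scenarios: dict[tuple[int, ...], list[Fragment]] = {}
    for r in range(1, k + 1):
        for subset in combinations(sites, r):
            scenarios[subset] = fragments_for_subset(protein, subset)
    return scenarios


def distinct_fragments(protein: ProteinRecord, sites: Sequence[int]) -> list[Fragment]:
    """Deduplicated union of fragments over every cleavage scenario.

    Every ordered pair of boundaries drawn from {0} ∪ sites ∪ {length}
    delimits one candidate fragment; the intact (0, length) pair is
    excluded, giving (k+1)(k+2)/2 − 1 fragments for k sites in O(k²)
    without subset enumeration. Ordered by (start, end).
    """
    sites = sorted(set(sites))
    bounds = [0, *sites, protein.length]
    out: list[Fragment] = []
    for i, left in enumerate(bounds[:-1]):
        for right in bounds[i + 1 :]:
            if left == 0 and right == protein.length:
                continue
            out.append(
                Fragment(
                    protein_id=protein.id,
                    start=left + 1,
                    end=right,
                    sequence=protein.slice(left + 1, right),
                    left_cut=left,
                    right_cut=right,
                )
            )
    out.sort(key=lambda f: (f.start, f.end))
    return out


def combined_digest(
    protein: ProteinRecord,
    patterns: Sequence[ProteasePattern],
    mode: str = "distinct",
    max_sites: int = DEFAULT_MAX_SITES,
) -> DigestResult:
    """Scan with every protease, merge cut sites, and generate fragments.

    Sites from different proteases falling on the same bond merge into one
    site whose provenance lists every contributing protease. ``mode``
    selects the fragment view (see module docstring); the distinct union
    is always populated.
    """
    if not patterns:
        raise ValueError("at least one protease pattern is required")
    if mode not in DIGEST_MODES:
        raise ValueError(f"mode must be one of {DIGEST_MODES}, got {mode!r}")
    occurrences: dict[str, list[ConsensusOccurrence]] = {}
    provenance: dict[int, set[str]] = {}
    for pattern in patterns:
        hits = scan(protein, pattern)
        occurrences[pattern.name] = hits
        for site in cut_sites(hits, protein):
            provenance.setdefault(site, set()).add(pattern.name)
    sites = sorted(provenance)
    result = DigestResult(
        protein=protein,
        occurrences=occurrences,
        cut_sites=sites,
        site_proteases={s: tuple(sorted(provenance[s])) for s in sites},
        mode=mode,
    )
    if mode == "per-site":
        result.scenarios = {(s,): fragments_for_subset(protein, (s,)) for s in sites}
    elif mode == "scenarios":
        result.scenarios = enumerate_scenarios(protein, sites, max_sites)
    result.distinct_fragments = distinct_fragments(protein, sites)
    return result
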