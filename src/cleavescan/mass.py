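"""Peptide molecular mass annotation.

Fragment masses let predicted breakdown products be compared with the
signature molecular weights observed on gels and in MS. A peptide's mass
is the sum of its residue (water-loss) masses plus one water; hydrolysis
therefore adds exactly one water per cut, which the tests use as a
conservation law.

The residue masses are the standard published values for the 20
unmodified amino acids (average and monoisotopic). No post-translational
modifications and no terminal modifications are modelled. Note that
computed chemical masses are not expected to coincide with apparent
SDS-PAGE mobilities of named signature fragments; gel mobility is not a
chemical mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

from .digest import DigestResult
from .mass_constants import AVERAGE_RESIDUE_MASS, MONOISOTOPIC_RESIDUE_MASS

MASS_MODES = ("average", "monoisotopic", "both")


@dataclass(frozen=True)
class ResidueMassTable:
    """Per-residue masses (Da) plus the mass of one water molecule."""

    average: Mapping[str, float]
    monoisotopic: Mapping[str, float]
    water_average: float = 18.0153
    water_monoisotopic: float = 18.0105646863

    def __post_init__(self) -> None:
        for name, table in (("average", self.average), ("monoisotopic", self.monoisotopic)):
            if sorted(table) != sorted("ACDEFGHIKLMNPQRSTVWY"):
                raise ValueError(f"{name} table must cover exactly the 20 standard residues")
            if any(v <= 0 for v in table.values()):
                raise ValueError(f"{name} table contains a non-positive mass")
        if any(self.average[aa] < self.monoisotopic[aa] for aa in self.average):
            raise ValueError("average residue mass below monoisotopic mass")

    def water(self, mode: str) -> float:
        return self.water_average if mode == "average" else self.water_monoisotopic

    def residue(self, aa: str, mode: str) -> float:
        table = self.average if mode == "average" else self.monoisotopic
        return table[aa]


STANDARD_MASSES = ResidueMassTable(
    average=MappingProxyType(AVERAGE_RESIDUE_MASS),
    monoisotopic=MappingProxyType(MONOISOTOPIC_RESIDUE_MASS),
)


def peptide_mass(
    sequence: str,
    mode: str = "average",
    *,
    table: ResidueMassTable = STANDARD_MASSES,
    on_nonstandard: str = "error",
) -> float:
    """Molecular mass of *sequence* in Da: residue masses plus one water.

    ``mode`` is ``'average'`` or ``'monoisotopic'``. Non-standard letters
    raise by default; ``on_nonstandard='skip'`` omits them from the sum
    (useful for sequences carrying ambiguity codes).
    """
    if mode not in ("average", "monoisotopic"):
        raise ValueError(f"mode must be 'average' or 'monoisotopic', got {mode!r}")
    if not sequence:
        raise ValueError("cannot compute the mass of an empty sequence")
    if on_nonstandard not in ("error", "skip"):
        raise ValueError(f"on_nonstandard must be 'error' or 'skip', got {on_nonstandard!r}")
    total = table.water(mode)
    for aa in sequence:
        try:
            total += table.residue(aa, mode)
        except KeyError:
            if on_nonstandard == "error":
                raise ValueError(f"non-standard residue {aa!r} in sequence") from None
    return total


def annotate_fragments(
    result: DigestResult,
    mode: str = "both",
    *,
    table: ResidueMassTable = STANDARD_MASSES,
    on_nonstandard: str = "error",
) -> DigestResult:
    """Attach masses to every fragment of *result*, and to the parent.

    ``mode`` selects which mass(es) to compute: ``'average'``,
    ``'monoisotopic'`` or ``'both'`` (default). Fragments are annotated in
    place across all scenarios and the distinct union; the annotated
    result is returned for chaining. An empty fragment set is a no-op.
    """
    if mode not in MASS_MODES:
        raise ValueError(f"mode must be one of {MASS_MODES}, got {mode!r}")
    modes = ("average", "monoisotopic") if mode == "both" else (mode,)

    def fill(fragment) -> None:
        for m in modes:
            value = peptide_mass(fragment.sequence, m, table=table, on_nonstandard=on_nonstandard)
            if m == "average":
                fragment.avg_mass = value
            else:
                fragment.mono_mass = value

    for fragments in result.scenarios.values():
        for fragment in fragments:
            fill(fragment)
    for fragment in result.distinct_fragments:
        fill(fragment)
    if result.protein.length:
        for m in modes:
            parent = peptide_mass(result.protein.sequence, m, table=table, on_nonstandard=on_nonstandard)
            if m == "average":
                result.parent_avg_mass = parent
            else:
                result.parent_mono_mass = parent
    return result
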