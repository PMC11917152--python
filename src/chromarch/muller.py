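"""Muller element allocation and orientation.

Scaffolds are allocated to one of the six Muller elements (A-F, i.e. the
dm6 arms X, 2L, 2R, 3L, 3R, 4) by best overall mutual alignment: the arm
receiving the largest summed aligned length wins, provided it holds at
least a minimum share of the scaffold's total aligned bp.  Element
orientation follows the TE-density convention of the reference: elements
A, B and D end in the TE-rich pericentromere, C and E begin with it.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import (
    DensityTrack,
    MULLER_ELEMENTS,
    MalformedInputError,
    InconsistentInputError,
    InvalidParameterError,
    REF_CHROM_TO_ELEMENT,
    UNPLACED,
)

#: which half of the element carries the pericentromeric TE block in the
#: reference orientation; F is not covered by the convention.
TE_RICH_HALF = {"A": "last", "B": "last", "D": "last", "C": "first", "E": "first"}


@dataclass(frozen=True)
class AlignmentHit:
    scaffold_id: str
    ref_chrom: str
    scaffold_start: int
    scaffold_end: int
    ref_start: int
    ref_end: int
    aligned_length: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.scaffold_end <= self.scaffold_start or self.ref_end <= self.ref_start:
            raise MalformedInputError("hit end must exceed start")
        if self.aligned_length <= 0:
            raise MalformedInputError("aligned length must be positive")
        if self.element is None:
            raise MalformedInputError(f"unknown reference arm {self.ref_chrom!r}")

    @property
    def element(self) -> str | None:
        if self.ref_chrom in MULLER_ELEMENTS:
            return self.ref_chrom
        return REF_CHROM_TO_ELEMENT.get(self.ref_chrom)


@dataclass
class ScaffoldAssignment:
    scaffold_id: str
    element: str
    support_bp: int | None
    mutual_share: float | None
    orientation: str = "undetermined"


def allocate_scaffolds(
    hits: list[AlignmentHit], min_share: float = 0.5
) -> list[ScaffoldAssignment]:
    """Assign each scaffold to the reference arm with the largest summed
    aligned length.

    ``mutual_share`` is that arm's share of the scaffold's total aligned
    bp; scaffolds whose best arm falls below ``min_share``, or that tie
    between arms, are left UNPLACED.
    """
    if not 0.0 <= min_share <= 1.0:
        raise InvalidParameterError("min_share must lie in [0, 1]")
    support: dict[str, dict[str, int]] = {}
    for hit in hits:
        support.setdefault(hit.scaffold_id, {})
        el = hit.element
        support[hit.scaffold_id][el] = (
            support[hit.scaffold_id].get(el, 0) + hit.aligned_length
        )

    out = []
    for scaffold in sorted(support):
        per_el = support[scaffold]
        total = sum(per_el.values())
        best = max(per_el.values())
        winners = sorted(el for el, bp in per_el.items() if bp == best)
        share = best / total
        if len(winners) > 1 or share < min_share:
            out.append(ScaffoldAssignment(scaffold, UNPLACED, None, None))
        else:
            out.append(ScaffoldAssignment(scaffold, winners[0], best, share))
    return out


def orient_element(element: str, te_track: DensityTrack) -> str:
    """Orientation call from the TE asymmetry of the two element halves.

    ``forward`` means the scaffold already matches the reference
    convention; element F has no stated convention and is always
    ``undetermined``, as are exact ties.
    """
    if element not in MULLER_ELEMENTS:
        raise InvalidParameterError(f"unknown element {element!r}")
    values = te_track.values
    if values.size == 0:
        raise MalformedInputError("empty density track")
    if element not in TE_RICH_HALF:
        return "undetermined"
    half = values.size // 2
    first = float(values[:half].mean()) if half else float(values.mean())
    last = float(values[half:].mean())
    if first == last:
        return "undetermined"
    te_rich_last = last > first
    if TE_RICH_HALF[element] == "last":
        return "forward" if te_rich_last else "reverse"
    return "reverse" if te_rich_last else "forward"


def placement_summary(
    assignments: list[ScaffoldAssignment], scaffold_lengths: dict[str, int]
) -> tuple[float, dict[str, int]]:
    """Fraction of assembly bp placed on elements, and bp per element."""
    placed_bp = 0
    total_bp = 0
    per_element: dict[str, int] = {}
    for a in assignments:
        if a.scaffold_id not in scaffold_lengths:
            raise InconsistentInputError(f"no length for scaffold {a.scaffold_id!r}")
        length = scaffold_lengths[a.scaffold_id]
        total_bp += length
        if a.element != UNPLACED:
            placed_bp += length
            per_element[a.element] = per_element.get(a.element, 0) + length
    if total_bp == 0:
        raise InconsistentInputError("no scaffolds to summarise")
    return placed_bp / total_bp, per_element
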