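"""Shared domain types for chromosome-architecture analyses.

The six Muller elements (A-F) are the ancestral *Drosophila* chromosome
arms; across the genus they are reshuffled into chromosomes by fusion and
fission while retaining their gene content.  Types defined here are shared
by the simulation and inference modules: chromosome configurations, binned
density tracks, heterochromatin interval sets and binned Hi-C contact
matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MULLER_ELEMENTS: tuple[str, ...] = ("A", "B", "C", "D", "E", "F")

#: dm6 reference arm -> Muller element (X, 2L, 2R, 3L, 3R, 4 = A..F).
REF_CHROM_TO_ELEMENT: dict[str, str] = {
    "X": "A",
    "2L": "B",
    "2R": "C",
    "3L": "D",
    "3R": "E",
    "4": "F",
}

UNPLACED = "UNPLACED"


class ChromarchError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(ChromarchError, ValueError):
    pass


class MalformedInputError(ChromarchError, ValueError):
    pass


class InconsistentInputError(ChromarchError, ValueError):
    pass


@dataclass(frozen=True)
class ElementConfiguration:
    """Partition of Muller elements into chromosomes.

    ``chromosomes`` is a tuple of ordered element groups; within a group,
    consecutive elements are physically fused end-to-start (the junction is
    the putative centromeric region of a metacentric chromosome).
    ``internal_centromere`` marks singleton elements that are metacentric on
    their own (centromere mid-element) rather than acrocentric.
    """

    chromosomes: tuple[tuple[str, ...], ...]
    internal_centromere: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        seen: list[str] = [e for group in self.chromosomes for e in group]
        if len(seen) != len(set(seen)):
            raise InvalidParameterError("element repeated across chromosomes")
        for e in self.internal_centromere:
            if (e,) not in self.chromosomes:
                raise InvalidParameterError(
                    f"internal centromere flag on non-singleton element {e!r}"
                )

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(sorted(e for g in self.chromosomes for e in g))

    @property
    def fused_pairs(self) -> frozenset[frozenset[str]]:
        pairs = set()
        for group in self.chromosomes:
            for a, b in zip(group, group[1:]):
                pairs.add(frozenset((a, b)))
        return frozenset(pairs)

    def partition(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(g) for g in self.chromosomes)

    def chromosome_of(self, element: str) -> tuple[str, ...]:
        for group in self.chromosomes:
            if element in group:
                return group
        raise KeyError(element)


def _cfg(groups: str, internal: str = "") -> ElementConfiguration:
    chromosomes = tuple(tuple(g) for g in groups.split("|"))
    return ElementConfiguration(chromosomes, frozenset(internal))


#: The eight chromosomal organisations observed across the genus: singleton
#: acrocentric elements unless fused (junction = centromere) or flagged as
#: metacentric singletons.  Keys name the subgroup/species each organisation
#: is typical of.
CONFIGURATION_CATALOGUE: dict[str, ElementConfiguration] = {
    "melanogaster": _cfg("A|BC|DE|F"),
    "montium": _cfg("A|BC|DE|F"),
    "ananassae": _cfg("A|BC|DE|F", internal="AF"),
    "obscura": _cfg("AD|BC|E|F"),
    "subobscura": _cfg("A|B|C|D|E|F"),
    "willistoni": _cfg("AD|BC|EF"),
    "virilis": _cfg("A|B|C|D|E|F"),
    "littoralis": _cfg("A|B|C|D|E|F", internal="E"),
}


@dataclass
class DensityTrack:
    """Binned per-element fraction track (e.g. TE density per 100-kb bin)."""

    element: str
    bin_size: int
    values: np.ndarray
    element_length: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise MalformedInputError("density track must be a non-empty vector")
        if np.any(self.values < -1e-9) or np.any(self.values > 1 + 1e-9):
            raise MalformedInputError("density values must lie in [0, 1]")
        if self.bin_size <= 0 or self.element_length <= 0:
            raise InvalidParameterError("bin size and element length must be positive")

    @property
    def n_bins(self) -> int:
        return int(self.values.size)

    def bin_bounds(self, i: int) -> tuple[int, int]:
        start = i * self.bin_size
        return start, min(start + self.bin_size, self.element_length)


@dataclass
class HetBlocks:
    """Heterochromatic intervals of one element (bp, 0-based half-open)."""

    element: str
    intervals: list[tuple[int, int]]
    flavors: list[str] = field(default_factory=list)
    element_length: int | None = None

    def __post_init__(self) -> None:
        ivs = sorted((int(a), int(b)) for a, b in self.intervals)
        for (a, b) in ivs:
            if b <= a or a < 0:
                raise MalformedInputError(f"bad interval ({a}, {b})")
            if self.element_length is not None and b > self.element_length:
                raise MalformedInputError("interval beyond element end")
        for (_, b), (a2, _) in zip(ivs, ivs[1:]):
            if a2 < b:
                raise MalformedInputError("heterochromatin intervals overlap")
        self.intervals = ivs
        if not self.flavors:
            self.flavors = ["unknown"] * len(ivs)
        if len(self.flavors) != len(ivs):
            raise InconsistentInputError("one flavor per interval required")

    def contains(self, pos: int) -> bool:
        return any(a <= pos < b for a, b in self.intervals)

    @property
    def total_bp(self) -> int:
        return sum(b - a for a, b in self.intervals)


class ContactMatrix:
    """Symmetric binned Hi-C contact matrix with a bin -> (element, span) map.

    ``bins`` must have columns ``element``, ``start``, ``end`` (bp, 0-based
    half-open within each element); bins of one element are contiguous and
    non-overlapping.
    """

    def __init__(self, counts: np.ndarray, bins: pd.DataFrame) -> None:
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise MalformedInputError("counts must be a square matrix")
        if counts.shape[0] != len(bins):
            raise InconsistentInputError("bin table length != matrix dimension")
        if not np.allclose(counts, counts.T):
            raise MalformedInputError("contact matrix must be symmetric")
        if np.any(counts < 0):
            raise MalformedInputError("contact counts must be non-negative")
        required = {"element", "start", "end"}
        if not required.issubset(bins.columns):
            raise MalformedInputError(f"bin table needs columns {sorted(required)}")
        self.counts = counts
        self.bins = bins.reset_index(drop=True)
        for el, sub in self.bins.groupby("element", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if np.any(ends <= starts):
                raise MalformedInputError("empty bin span")
            if np.any(starts[1:] != ends[:-1]):
                raise MalformedInputError(f"bins of element {el!r} do not tile")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def elements(self) -> list[str]:
        return list(dict.fromkeys(self.bins["element"]))

    def element_bins(self, element: str) -> np.ndarray:
        return np.flatnonzero((self.bins["element"] == element).to_numpy())

    def element_length(self, element: str) -> int:
        sub = self.bins[self.bins["element"] == element]
        if sub.empty:
            raise KeyError(element)
        return int((sub["end"] - sub["start"]).sum())

    def submatrix(self, element: str) -> tuple[np.ndarray, np.ndarray]:
        idx = self.element_bins(element)
        return self.counts[np.ix_(idx, idx)], idx


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of possibly-overlapping half-open intervals."""
    if not intervals:
        return []
    ivs = sorted((int(a), int(b)) for a, b in intervals)
    merged = [list(ivs[0])]
    for a, b in ivs[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def patristic_distances(tree) -> dict[frozenset[str], float]:
    """All pairwise path-length distances between leaf taxa of a dendropy tree."""
    pdm = tree.phylogenetic_distance_matrix()
    out: dict[frozenset[str], float] = {}
    taxa = list(tree.taxon_namespace)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i:]:
            out[frozenset((t1.label, t2.label))] = float(pdm.patristic_distance(t1, t2))
    return out
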