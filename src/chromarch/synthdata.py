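"""Synthetic species sets with planted ground truth.

Every downstream stage of the package (element allocation, Hi-C
configuration and compartments, heterochromatin segmentation, synteny,
satellite clustering) assumes a particular statistical structure in its
input.  This module generates small genomes that exhibit exactly that
structure with known truth:

* an ultrametric species tree (coalescent topology rescaled to a chosen
  root-to-tip depth, in substitutions per site),
* per-element TE annotations with one contiguous TE-rich pericentromeric
  block (terminal for acrocentric elements, internal for metacentric ones)
  against a TE-poor euchromatic background,
* gene orders that diverge along the tree by within-element inversions,
* satellite arrays drawn from a small number of diverged monomer families,
  a fraction emitted reverse-complemented,
* binned Hi-C contact matrices with intra-chromosomal distance decay,
  elevated near-junction contacts for fused element pairs, and a planted
  A/B checkerboard compartment correlation.

All randomness flows from one master seed through fixed per-component
labels, so adding a generator never perturbs the streams of the others,
and identical parameters give bit-identical output.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .alignment import DNA, revcomp
from .core import (
    CONFIGURATION_CATALOGUE,
    MULLER_ELEMENTS,
    ContactMatrix,
    ElementConfiguration,
    HetBlocks,
    InconsistentInputError,
    InvalidParameterError,
)

_BASES = np.frombuffer(DNA.encode(), dtype=np.uint8)


def component_rng(seed: int, label: str) -> np.random.Generator:
    """Independent deterministic stream for one logical generator component."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    )


@dataclass(frozen=True)
class FamilySpec:
    """One planted satellite family: arrays per species drawn from a common
    ancestral monomer, placed in the named compartment."""

    name: str
    monomer_length: int
    n_arrays: int
    compartment: str = "het"  # "het" | "eu"

    def __post_init__(self) -> None:
        if self.monomer_length < 10:
            raise InvalidParameterError("monomer length must be >= 10 bp")
        if self.n_arrays < 1:
            raise InvalidParameterError("n_arrays must be positive")
        if self.compartment not in ("het", "eu"):
            raise InvalidParameterError("compartment must be 'het' or 'eu'")


DEFAULT_FAMILIES = (
    FamilySpec("Fam1", 170, 25, "het"),
    FamilySpec("Fam2", 140, 25, "het"),
    FamilySpec("Fam3", 250, 25, "het"),
    FamilySpec("EuSat", 12, 15, "eu"),
)


@dataclass(frozen=True)
class SimParams:
    """Parameters of one synthetic species set.

    Lengths are in bp, densities are per-100-kb-bin TE fractions, and
    ``density_noise_sd`` is a *relative* standard deviation (sd of a bin's
    realised fraction = density_noise_sd x its mean).  ``divergence`` is the
    expected per-site substitution fraction between an array consensus and
    its family ancestor.
    """

    seed: int = 0
    n_species: int = 6
    n_elements: int = 6
    element_length: int = 3_000_000
    bin_size: int = 100_000
    het_fraction: float = 0.2
    te_density_het: float = 0.5
    te_density_eu: float = 0.05
    density_noise_sd: float = 0.1
    n_genes: int = 100
    inversions_per_branch: float = 5.0
    tree_depth: float = 0.3
    family_specs: tuple[FamilySpec, ...] = DEFAULT_FAMILIES
    divergence: float = 0.05
    copy_divergence: float = 0.01
    revcomp_fraction: float = 0.5
    min_array_copies: int = 10
    max_array_copies: int = 40
    contact_decay_exponent: float = 1.0
    contact_scale: float = 300.0
    contact_background: float = 1.0
    junction_scale_bins: float = 15.0
    fusion_boost: float = 10.0
    compartment_corr: float = 0.3
    compartment_block_bins: int = 5
    configuration: ElementConfiguration = CONFIGURATION_CATALOGUE["melanogaster"]

    def __post_init__(self) -> None:
        fractions = {
            "het_fraction": self.het_fraction,
            "te_density_het": self.te_density_het,
            "te_density_eu": self.te_density_eu,
            "divergence": self.divergence,
            "copy_divergence": self.copy_divergence,
            "revcomp_fraction": self.revcomp_fraction,
            "compartment_corr": self.compartment_corr,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1]")
        if self.het_fraction >= 1.0 and self.het_fraction != 0.0:
            # a whole-element het block leaves no euchromatin to contrast
            raise InvalidParameterError("het_fraction must be < 1")
        positive = {
            "n_species": self.n_species,
            "n_elements": self.n_elements,
            "element_length": self.element_length,
            "bin_size": self.bin_size,
            "n_genes": self.n_genes,
            "min_array_copies": self.min_array_copies,
            "max_array_copies": self.max_array_copies,
        }
        for name, value in positive.items():
            if value <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.n_elements > len(MULLER_ELEMENTS):
            raise InvalidParameterError("at most six elements supported")
        if self.density_noise_sd < 0 or self.inversions_per_branch < 0:
            raise InvalidParameterError("rates must be non-negative")
        if self.fusion_boost < 1:
            raise InvalidParameterError("fusion_boost must be >= 1")

    @property
    def elements(self) -> tuple[str, ...]:
        return MULLER_ELEMENTS[: self.n_elements]


@dataclass
class GenomeLayout:
    """Planted annotation layout shared by all species of a set."""

    bin_size: int
    element_lengths: dict[str, int]
    te_intervals: pd.DataFrame  # element, start, end
    genes: pd.DataFrame  # element, index, gene_id, midpoint, strand
    het_truth: dict[str, HetBlocks]
    bin_fractions: dict[str, np.ndarray]
    compartment_labels: dict[str, np.ndarray]

    @property
    def elements(self) -> list[str]:
        return list(self.element_lengths)

    def n_bins(self, element: str) -> int:
        return int(
            math.ceil(self.element_lengths[element] / self.bin_size)
        )


@dataclass
class GeneOrderSet:
    """Per-species, per-element gene orders plus the planted inversion record."""

    species: list[str]
    elements: list[str]
    orders: dict[str, dict[str, list[tuple[str, str]]]]
    events: list[tuple[str, str, int, int]]  # (child node, element, start, end)
    breakpoint_truth: dict[frozenset, dict[str, tuple[int, ...]]] | None

    def ortholog_map(self, species_a: str, species_b: str) -> dict[str, str]:
        """One-to-one ortholog map; synthetic genes keep their ids."""
        ids = [g for el in self.elements for g, _ in self.orders[species_a][el]]
        return {g: g for g in ids}


@dataclass
class SatelliteDataSet:
    arrays: pd.DataFrame  # array_id, species, element, start, end, width, ...
    sequences: dict[str, str]  # array_id -> full array sequence
    references: list  # FamilyReference for complex families
    family_truth: dict[str, tuple[str, str]]  # array_id -> (family, strand)
    ancestral_monomers: dict[str, str]


@dataclass
class SyntheticTruth:
    configuration: ElementConfiguration
    compartment_labels: dict[str, np.ndarray]
    het_intervals: dict[str, HetBlocks]
    family_of_array: dict[str, tuple[str, str]]
    ancestral_monomers: dict[str, str]
    breakpoints: dict[frozenset, dict[str, tuple[int, ...]]] | None


@dataclass
class SimulatedDataset:
    params: SimParams
    tree: dendropy.Tree
    layout: GenomeLayout
    orders: GeneOrderSet
    satellites: SatelliteDataSet
    contacts: ContactMatrix
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# species tree


def gen_species_tree(seed: int, n_species: int, depth: float) -> dendropy.Tree:
    """Random rooted binary ultrametric tree with root-to-tip length ``depth``.

    Topology and node times come from a Kingman coalescent; all heights are
    then rescaled so every root-to-leaf path sums to exactly ``depth``.
    """
    if n_species < 2:
        raise InvalidParameterError("need at least 2 species")
    if depth <= 0:
        raise InvalidParameterError("depth must be positive")
    rng = component_rng(seed, "tree")
    lineages: list[tuple[str, float]] = [
        (f"S{i + 1:02d}", 0.0) for i in range(n_species)
    ]
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (sub_j, h_j) = lineages.pop(j)
        (sub_i, h_i) = lineages.pop(i)
        lineages.append(((sub_i, h_i, sub_j, h_j), t))
    root, height = lineages[0]
    scale = depth / height

    def newick(node, parent_height: float) -> str:
        if isinstance(node, str):
            return node
        sub_a, h_a, sub_b, h_b = node
        a = newick(sub_a, parent_height=0.0)
        b = newick(sub_b, parent_height=0.0)
        return f"({a}:{(_h(node) - h_a) * scale:.12f},{b}:{(_h(node) - h_b) * scale:.12f})"

    def _h(node) -> float:
        # height of an internal node is stored with it on creation
        return node_heights[id(node)]

    # record heights: leaves 0, internal nodes by construction order
    node_heights: dict[int, float] = {}

    def register(node, h) -> None:
        if not isinstance(node, str):
            node_heights[id(node)] = h

    # re-walk: the final merge gave (root, height); recover heights by
    # rebuilding (children carry their heights in the tuple)
    stack = [(root, height)]
    while stack:
        node, h = stack.pop()
        register(node, h)
        if not isinstance(node, str):
            sub_a, h_a, sub_b, h_b = node
            stack.append((sub_a, h_a))
            stack.append((sub_b, h_b))

    text = newick(root, height) + ";"
    tree = dendropy.Tree.get(data=text, schema="newick")
    tree.seed_node.edge.length = None
    return tree


def tree_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# genome layout


def _het_bin_span(
    element: str,
    n_bins: int,
    het_bins: int,
    configuration: ElementConfiguration,
) -> tuple[int, int] | None:
    """Bin range [s, e) of the planted pericentromeric block."""
    if het_bins <= 0:
        return None
    group = configuration.chromosome_of(element)
    if len(group) == 1:
        if element in configuration.internal_centromere:
            s = (n_bins - het_bins) // 2
            return s, s + het_bins
        return 0, het_bins  # acrocentric: block at the element start
    pos = group.index(element)
    if pos < len(group) - 1:
        return n_bins - het_bins, n_bins  # joins the next element at its end
    return 0, het_bins  # last of the group: joined at its start


def gen_genome_layout(params: SimParams) -> GenomeLayout:
    """TE intervals, gene positions and planted heterochromatin truth.

    Each 100-kb bin receives a realised TE fraction drawn around its
    compartment mean (relative noise ``density_noise_sd``), emitted as one
    TE interval at the bin start covering exactly that fraction.
    """
    rng = component_rng(params.seed, "layout")
    cfg = params.configuration
    for el in params.elements:
        if el not in {e for g in cfg.chromosomes for e in g}:
            raise InvalidParameterError(f"configuration misses element {el!r}")

    element_lengths = {el: params.element_length for el in params.elements}
    te_rows: list[tuple[str, int, int]] = []
    gene_rows: list[tuple[str, int, str, int, str]] = []
    het_truth: dict[str, HetBlocks] = {}
    bin_fractions: dict[str, np.ndarray] = {}
    labels: dict[str, np.ndarray] = {}

    for el in params.elements:
        length = element_lengths[el]
        n_bins = int(math.ceil(length / params.bin_size))
        het_bins = int(round(params.het_fraction * n_bins))
        span = _het_bin_span(el, n_bins, het_bins, cfg)
        is_het = np.zeros(n_bins, dtype=bool)
        if span is not None:
            is_het[span[0] : span[1]] = True
            start_bp = span[0] * params.bin_size
            end_bp = min(span[1] * params.bin_size, length)
            flavor = "terminal" if span[0] == 0 or span[1] == n_bins else "internal"
            het_truth[el] = HetBlocks(el, [(start_bp, end_bp)], [flavor], length)
        else:
            het_truth[el] = HetBlocks(el, [], [], length)

        means = np.where(is_het, params.te_density_het, params.te_density_eu)
        noise = rng.normal(0.0, 1.0, size=n_bins)
        fracs = np.clip(means * (1.0 + params.density_noise_sd * noise), 0.0, 1.0)
        bin_fractions[el] = fracs
        for b in range(n_bins):
            b_start = b * params.bin_size
            b_end = min(b_start + params.bin_size, length)
            te_bp = int(round(fracs[b] * (b_end - b_start)))
            fracs[b] = te_bp / (b_end - b_start)  # realised fraction, exact
            if te_bp > 0:
                te_rows.append((el, b_start, b_start + te_bp))

        lab = np.empty(n_bins, dtype="<U1")
        lab[is_het] = "B"
        eu_idx = np.flatnonzero(~is_het)
        for k, b in enumerate(eu_idx):
            lab[b] = "A" if (k // params.compartment_block_bins) % 2 == 0 else "B"
        labels[el] = lab

        step = length / params.n_genes
        for i in range(params.n_genes):
            mid = int((i + 0.5) * step)
            gene_rows.append((el, i, f"{el}g{i:04d}", mid, "+"))

    te = pd.DataFrame(te_rows, columns=["element", "start", "end"])
    genes = pd.DataFrame(
        gene_rows, columns=["element", "index", "gene_id", "midpoint", "strand"]
    )
    return GenomeLayout(
        bin_size=params.bin_size,
        element_lengths=element_lengths,
        te_intervals=te,
        genes=genes,
        het_truth=het_truth,
        bin_fractions=bin_fractions,
        compartment_labels=labels,
    )


# ---------------------------------------------------------------------------
# gene orders


def identity_order(element: str, n_genes: int) -> list[tuple[str, str]]:
    return [(f"{element}g{i:04d}", "+") for i in range(n_genes)]


def apply_inversion(
    order: list[tuple[str, str]], start: int, end: int
) -> list[tuple[str, str]]:
    """Reverse genes in [start, end) and flip their strands."""
    if end - start < 2 or start < 0 or end > len(order):
        raise InvalidParameterError("inversion must cover >= 2 genes in range")
    seg = [(g, "-" if s == "+" else "+") for g, s in reversed(order[start:end])]
    return order[:start] + seg + order[end:]


def _candidate_pool(
    rng: np.random.Generator, n_genes: int, max_len: int = 6
) -> list[tuple[int, int]]:
    """Disjoint interior intervals separated by >= 1 gene (for exact truth)."""
    pool: list[tuple[int, int]] = []
    start = 1
    while start + 2 <= n_genes - 1:
        length = int(rng.integers(2, max_len + 1))
        length = min(length, n_genes - 1 - start)
        if length < 2:
            break
        pool.append((start, start + length))
        start += length + 1
    perm = rng.permutation(len(pool))
    return [pool[i] for i in perm]


def gen_gene_orders(
    seed: int,
    tree: dendropy.Tree,
    n_genes: int,
    inversions_per_branch: float,
    elements: tuple[str, ...] = MULLER_ELEMENTS,
    non_overlapping: bool = False,
    protected: dict[str, tuple[int, int]] | None = None,
) -> GeneOrderSet:
    """Evolve gene orders along ``tree`` by within-element inversions.

    Each branch applies Poisson(rate x branch length) inversions, each
    reversing a uniformly chosen contiguous run of >= 2 genes of one
    element.  With ``non_overlapping`` every inversion in the whole tree is
    drawn without replacement from a pre-tiled set of disjoint interior
    intervals, so each contributes exactly two breakpoints and the
    per-species-pair breakpoint truth is exact.  ``protected`` excludes a
    gene-index range per element from rearrangement.
    """
    if n_genes < 10:
        raise InvalidParameterError("need at least 10 genes per element")
    rng = component_rng(seed, "gene-orders")
    protected = protected or {}

    pools: dict[str, list[tuple[int, int]]] = {}
    if non_overlapping:
        for el in elements:
            pool = _candidate_pool(rng, n_genes)
            if el in protected:
                p0, p1 = protected[el]
                pool = [(a, b) for a, b in pool if b <= p0 or a >= p1]
            pools[el] = pool

    species = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    root_state = {el: identity_order(el, n_genes) for el in elements}
    states: dict[int, dict[str, list[tuple[str, str]]]] = {
        id(tree.seed_node): root_state
    }
    events: list[tuple[str, str, int, int]] = []
    edge_intervals: dict[str, list[tuple[str, int, int]]] = {}
    node_labels: dict[int, str] = {}
    counter = 0

    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            node_labels[id(node)] = "root"
            continue
        counter += 1
        label = node.taxon.label if node.is_leaf() else f"n{counter}"
        node_labels[id(node)] = label
        parent_state = states[id(node.parent_node)]
        state = {el: list(order) for el, order in parent_state.items()}
        blen = node.edge.length or 0.0
        k = int(rng.poisson(inversions_per_branch * blen))
        applied: list[tuple[str, int, int]] = []
        for _ in range(k):
            el = str(rng.choice(list(elements)))
            if non_overlapping:
                if not pools[el]:
                    continue
                s, e = pools[el].pop()
            else:
                s, e = _draw_inversion(rng, n_genes, protected.get(el))
                if s is None:
                    continue
            state[el] = apply_inversion(state[el], s, e)
            events.append((label, el, s, e))
            applied.append((el, s, e))
        edge_intervals[label] = applied
        states[id(node)] = state

    orders = {}
    leaf_edges: dict[str, set[str]] = {}
    for leaf in tree.leaf_node_iter():
        orders[leaf.taxon.label] = states[id(leaf)]
        path = set()
        node = leaf
        while node is not tree.seed_node:
            path.add(node_labels[id(node)])
            node = node.parent_node
        leaf_edges[leaf.taxon.label] = path

    breakpoint_truth = None
    if non_overlapping:
        breakpoint_truth = {}
        for i, sp1 in enumerate(species):
            for sp2 in species[i + 1 :]:
                diff = leaf_edges[sp1] ^ leaf_edges[sp2]
                per_el: dict[str, set[int]] = {el: set() for el in elements}
                for edge in diff:
                    for el, s, e in edge_intervals.get(edge, []):
                        per_el[el].update((s - 1, e - 1))
                breakpoint_truth[frozenset((sp1, sp2))] = {
                    el: tuple(sorted(v)) for el, v in per_el.items()
                }

    return GeneOrderSet(
        species=species,
        elements=list(elements),
        orders=orders,
        events=events,
        breakpoint_truth=breakpoint_truth,
    )


def _draw_inversion(rng, n_genes: int, protected: tuple[int, int] | None):
    for _ in range(200):
        s = int(rng.integers(0, n_genes - 1))
        e = s + int(rng.integers(2, n_genes - s + 1))
        if protected is None or e <= protected[0] or s >= protected[1]:
            return s, e
    return None, None


# ---------------------------------------------------------------------------
# satellites


def _random_monomer(rng, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def _mutate(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    codes = np.searchsorted(_BASES, arr)  # ACGT already sorted
    hit = rng.random(arr.size) < rate
    shifts = rng.integers(1, 4, size=arr.size)
    codes[hit] = (codes[hit] + shifts[hit]) % 4
    return bytes(_BASES[codes]).decode()


def gen_satellite_dataset(
    params: SimParams,
    layout: GenomeLayout,
    species: list[str] | None = None,
) -> SatelliteDataSet:
    """Tandem-repeat arrays from planted monomer families.

    Each family has one random ancestral monomer; every array consensus is
    that ancestor with i.i.d. substitutions at rate ``divergence``, and the
    array sequence is ``copies`` tandem repeats of the consensus, each copy
    lightly mutated (``copy_divergence``).  A fraction ``revcomp_fraction``
    of arrays is emitted reverse-complemented.  Heterochromatic families are
    placed only inside planted het intervals, euchromatic families outside.
    """
    from .satellites import FamilyReference

    rng = component_rng(params.seed, "satellites")
    if species is None:
        species = [f"S{i + 1:02d}" for i in range(params.n_species)]

    ancestors = {
        spec.name: _random_monomer(rng, spec.monomer_length)
        for spec in params.family_specs
    }

    # per (species, element, compartment) allocation cursors over free space
    free: dict[tuple[str, str, str], list[list[int]]] = {}
    for sp in species:
        for el in layout.elements:
            het = layout.het_truth[el].intervals
            length = layout.element_lengths[el]
            eu: list[list[int]] = []
            prev = 0
            for a, b in het:
                if a > prev:
                    eu.append([prev, a])
                prev = b
            if prev < length:
                eu.append([prev, length])
            free[(sp, el, "het")] = [list(iv) for iv in het]
            free[(sp, el, "eu")] = eu

    spacing = 500
    rows = []
    sequences: dict[str, str] = {}
    truth: dict[str, tuple[str, str]] = {}
    arr_n = 0
    for sp in species:
        for spec in params.family_specs:
            for _ in range(spec.n_arrays):
                consensus = _mutate(rng, ancestors[spec.name], params.divergence)
                copies = int(
                    rng.integers(params.min_array_copies, params.max_array_copies + 1)
                )
                seq = "".join(
                    _mutate(rng, consensus, params.copy_divergence)
                    for _ in range(copies)
                )
                strand = "-" if rng.random() < params.revcomp_fraction else "+"
                out_consensus = consensus if strand == "+" else revcomp(consensus)
                out_seq = seq if strand == "+" else revcomp(seq)
                width = len(out_seq)

                el_order = [
                    layout.elements[i]
                    for i in rng.permutation(len(layout.elements))
                ]
                placed = False
                for el in el_order:
                    for region in free[(sp, el, spec.compartment)]:
                        if region[1] - region[0] >= width + spacing:
                            start = region[0]
                            region[0] += width + spacing
                            placed = True
                            break
                    if placed:
                        break
                if not placed:
                    raise InvalidParameterError(
                        f"no room left to place arrays of family {spec.name!r}"
                    )
                arr_n += 1
                array_id = f"arr{arr_n:05d}"
                rows.append(
                    {
                        "array_id": array_id,
                        "species": sp,
                        "element": el,
                        "start": start,
                        "end": start + width,
                        "width": width,
                        "repeat_length": len(consensus),
                        "repeat_count": copies,
                        "consensus": out_consensus,
                        "class": "simple" if len(consensus) < 50 else "complex",
                        "strand": "+",
                    }
                )
                sequences[array_id] = out_seq
                truth[array_id] = (spec.name, strand)

    arrays = pd.DataFrame(rows)
    references = [
        FamilyReference(spec.name, ancestors[spec.name], spec.monomer_length)
        for spec in params.family_specs
        if spec.monomer_length >= 50
    ]
    return SatelliteDataSet(arrays, sequences, references, truth, ancestors)


# ---------------------------------------------------------------------------
# contact matrices


def contact_bins(layout: GenomeLayout) -> pd.DataFrame:
    rows = []
    for el in layout.elements:
        length = layout.element_lengths[el]
        for b in range(layout.n_bins(el)):
            start = b * layout.bin_size
            rows.append((el, start, min(start + layout.bin_size, length)))
    df = pd.DataFrame(rows, columns=["element", "start", "end"])
    df.insert(0, "bin_id", np.arange(len(df)))
    return df


def expected_contacts(
    params: SimParams,
    layout: GenomeLayout,
    configuration: ElementConfiguration,
    compartment_labels: dict[str, np.ndarray],
) -> tuple[np.ndarray, pd.DataFrame]:
    """Expected (Poisson-mean) contact matrix under the planted model."""
    bins = contact_bins(layout)
    n = len(bins)
    elements = layout.elements
    for el in elements:
        if el not in compartment_labels or len(compartment_labels[el]) != layout.n_bins(el):
            raise InconsistentInputError(f"compartment labels mismatch for {el!r}")

    el_of = bins["element"].to_numpy()
    offset = {el: int(np.flatnonzero(el_of == el)[0]) for el in elements}
    nbins = {el: int((el_of == el).sum()) for el in elements}
    labels = np.concatenate([compartment_labels[el] for el in elements])

    E = np.full((n, n), params.contact_background, dtype=float)
    alpha = params.contact_decay_exponent
    for el in elements:
        o, m = offset[el], nbins[el]
        d = np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
        block = params.contact_scale * (1.0 + d) ** (-alpha)
        same = (
            labels[o : o + m, None] == labels[None, o : o + m]
        )
        block = block * (1.0 + params.compartment_corr * same)
        E[o : o + m, o : o + m] = block

    for group in configuration.chromosomes:
        for x, y in zip(group, group[1:]):
            if x not in offset or y not in offset:
                continue
            ox, mx = offset[x], nbins[x]
            oy, my = offset[y], nbins[y]
            # x's end joins y's start
            dx = (mx - 1) - np.arange(mx)
            dy = np.arange(my)
            w = np.exp(
                -(dx[:, None] + dy[None, :]) / params.junction_scale_bins
            )
            block = params.contact_background * (
                1.0 + (params.fusion_boost - 1.0) * w
            )
            E[ox : ox + mx, oy : oy + my] = block
            E[oy : oy + my, ox : ox + mx] = block.T
    return E, bins


def gen_contact_matrix(
    params: SimParams,
    layout: GenomeLayout,
    configuration: ElementConfiguration | None = None,
    compartment_labels: dict[str, np.ndarray] | None = None,
) -> ContactMatrix:
    """Poisson-sampled symmetric contact matrix under the planted model."""
    configuration = configuration or params.configuration
    compartment_labels = compartment_labels or layout.compartment_labels
    E, bins = expected_contacts(params, layout, configuration, compartment_labels)
    rng = component_rng(params.seed, "contacts")
    upper = rng.poisson(np.triu(E))
    counts = np.triu(upper) + np.triu(upper, 1).T
    return ContactMatrix(counts.astype(float), bins)


# ---------------------------------------------------------------------------
# orchestration


def simulate(params: SimParams) -> SimulatedDataset:
    """Full synthetic dataset: tree, layout, orders, satellites, contacts."""
    tree = gen_species_tree(params.seed, params.n_species, params.tree_depth)
    layout = gen_genome_layout(params)
    orders = gen_gene_orders(
        params.seed,
        tree,
        params.n_genes,
        params.inversions_per_branch,
        elements=params.elements,
    )
    satellites = gen_satellite_dataset(params, layout, species=orders.species)
    contacts = gen_contact_matrix(params, layout)
    truth = SyntheticTruth(
        configuration=params.configuration,
        compartment_labels=layout.compartment_labels,
        het_intervals=layout.het_truth,
        family_of_array=satellites.family_truth,
        ancestral_monomers=satellites.ancestral_monomers,
        breakpoints=orders.breakpoint_truth,
    )
    return SimulatedDataset(params, tree, layout, orders, satellites, contacts, truth)
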