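"""Collinear block detection and synteny-breakpoint statistics.

Between two species, orthologous genes of one Muller element are chained
into collinear (synteny) blocks: maximal runs of anchors whose partner
indices move strictly monotonically (same or inverted orientation) with a
bounded number of skipped genes between consecutive anchors.  Block
borders projected onto a reference gene order are synteny breakpoints;
their counts per 10-gene bin expose rearrangement cold spots, and block
sizes shrink with evolutionary distance following an exponential decay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import (
    ChromarchError,
    InconsistentInputError,
    InvalidParameterError,
    MalformedInputError,
    patristic_distances,
)


class FitFailureError(ChromarchError):
    pass


@dataclass
class SyntenyBlock:
    """Collinear anchor chain between two gene orders (gene indices are
    0-based inclusive ranges in each order)."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    orientation: str  # "same" | "inverted"
    n_genes: int
    anchors: list[tuple[int, int]]
    span_bp: float | None = None


@dataclass
class BreakpointProfile:
    """Breakpoint counts on a reference order, in bins of ``bin_genes``."""

    bin_genes: int
    counts: np.ndarray
    conserved_runs: list[tuple[int, int]]  # [start_bin, end_bin) zero runs


@dataclass
class DecayFit:
    amplitude: float
    rate: float
    rss: float


def chain_collinear_blocks(
    order_a: list[tuple[str, str]],
    order_b: list[tuple[str, str]],
    orthologs: dict[str, str],
    min_genes: int = 5,
    max_gap: int = 5,
) -> list[SyntenyBlock]:
    """Chain ortholog anchors into maximal strictly monotone runs.

    Consecutive anchors of a chain may skip at most ``max_gap`` genes in
    either species; chains with fewer than ``min_genes`` anchors are
    dropped.  Orthology must be one-to-one.
    """
    targets = list(orthologs.values())
    if len(targets) != len(set(targets)):
        raise MalformedInputError("ortholog map must be one-to-one")
    pos_b = {g: j for j, (g, _) in enumerate(order_b)}
    anchors = []
    for i, (g, _) in enumerate(order_a):
        partner = orthologs.get(g)
        if partner is not None and partner in pos_b:
            anchors.append((i, pos_b[partner]))

    chains: list[list[tuple[int, int]]] = []
    current: list[tuple[int, int]] = []
    direction = 0
    for anchor in anchors:
        if not current:
            current = [anchor]
            direction = 0
            continue
        i1, j1 = current[-1]
        i2, j2 = anchor
        dj = j2 - j1
        gap_ok = (i2 - i1 - 1) <= max_gap and (abs(dj) - 1) <= max_gap
        dir_ok = dj != 0 and (direction == 0 or np.sign(dj) == direction)
        if gap_ok and dir_ok:
            current.append(anchor)
            if direction == 0:
                direction = int(np.sign(dj))
        else:
            chains.append(current)
            current = [anchor]
            direction = 0
    if current:
        chains.append(current)

    blocks = []
    for chain in chains:
        if len(chain) < min_genes:
            continue
        a_idx = [i for i, _ in chain]
        b_idx = [j for _, j in chain]
        orientation = "inverted" if len(chain) > 1 and b_idx[1] < b_idx[0] else "same"
        blocks.append(
            SyntenyBlock(
                a_start=min(a_idx),
                a_end=max(a_idx),
                b_start=min(b_idx),
                b_end=max(b_idx),
                orientation=orientation,
                n_genes=len(chain),
                anchors=chain,
            )
        )
    return blocks


def add_block_spans(
    blocks: list[SyntenyBlock], midpoints: dict[str, int], order_a
) -> None:
    """Fill ``span_bp`` from reference gene midpoints (in place)."""
    for blk in blocks:
        g_first = order_a[blk.a_start][0]
        g_last = order_a[blk.a_end][0]
        blk.span_bp = abs(float(midpoints[g_last]) - float(midpoints[g_first]))


def reference_breakpoints(
    blocks: list[SyntenyBlock], n_ref_genes: int
) -> list[int]:
    """Breakpoint positions on the reference order.

    Each reference gene is assigned to the block whose reference range
    covers it; a breakpoint sits between adjacent genes with different
    assignments (block vs other block, or block vs none) and is reported
    as the left gene's index.  Element ends are not breakpoints.
    """
    assign = np.full(n_ref_genes, -1, dtype=int)
    for bid, blk in enumerate(blocks):
        assign[blk.a_start : blk.a_end + 1] = bid
    return [i for i in range(n_ref_genes - 1) if assign[i] != assign[i + 1]]


def breakpoints_per_gene_bins(
    breakpoint_lists: list[list[int]],
    n_ref_genes: int,
    bin_genes: int = 10,
    min_conserved_bins: int = 2,
) -> BreakpointProfile:
    """Total breakpoint counts per bin of ``bin_genes`` reference genes.

    A breakpoint is binned by its left flanking gene.  Conserved runs are
    maximal stretches of at least ``min_conserved_bins`` consecutive
    zero-count bins.
    """
    if bin_genes < 1:
        raise InvalidParameterError("bin must cover >= 1 gene")
    n_bins = -(-n_ref_genes // bin_genes)
    counts = np.zeros(n_bins, dtype=int)
    for bps in breakpoint_lists:
        for left in bps:
            if not 0 <= left < n_ref_genes:
                raise InconsistentInputError("breakpoint outside reference order")
            counts[left // bin_genes] += 1
    runs = []
    b = 0
    while b < n_bins:
        if counts[b] == 0:
            e = b
            while e < n_bins and counts[e] == 0:
                e += 1
            if e - b >= min_conserved_bins:
                runs.append((b, e))
            b = e
        else:
            b += 1
    return BreakpointProfile(bin_genes, counts, runs)


def block_stats_vs_distance(records: list[dict], tree) -> pd.DataFrame:
    """Per species pair: patristic distance, block-size summary, breaks/Mb.

    Each record must carry ``species_a``, ``species_b``,
    ``block_spans_bp`` (list), ``n_breakpoints`` and ``ref_length_bp``.
    """
    dists = patristic_distances(tree)
    taxa = {t.label for t in tree.taxon_namespace}
    rows = []
    for rec in records:
        a, b = rec["species_a"], rec["species_b"]
        for sp in (a, b):
            if sp not in taxa:
                raise InvalidParameterError(f"species {sp!r} missing from tree")
        spans = np.asarray(rec["block_spans_bp"], dtype=float)
        rows.append(
            {
                "species_a": a,
                "species_b": b,
                "distance": dists[frozenset((a, b))],
                "n_blocks": spans.size,
                "median_block_bp": float(np.median(spans)) if spans.size else np.nan,
                "block_iqr_bp": float(
                    np.subtract(*np.percentile(spans, [75, 25]))
                )
                if spans.size
                else np.nan,
                "n_breakpoints": int(rec["n_breakpoints"]),
                "breaks_per_mb": rec["n_breakpoints"]
                / (rec["ref_length_bp"] / 1e6),
            }
        )
    return pd.DataFrame(rows)


def fit_exponential_decay(distances, sizes) -> DecayFit:
    """Least-squares fit of size = a exp(-b distance).

    Initialised from the log-linear fit; degenerate flat data fits b ~ 0.
    """
    x = np.asarray(distances, dtype=float)
    y = np.asarray(sizes, dtype=float)
    if x.size < 3:
        raise InvalidParameterError("need >= 3 points")
    if np.any(y <= 0):
        raise MalformedInputError("sizes must be positive")
    slope, intercept = np.polyfit(x, np.log(y), 1)
    p0 = (float(np.exp(intercept)), float(-slope))
    try:
        popt, _ = curve_fit(
            lambda d, a, b: a * np.exp(-b * d), x, y, p0=p0, maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - scipy non-convergence
        raise FitFailureError(str(exc)) from exc
    a, b = float(popt[0]), float(popt[1])
    if a <= 0:
        raise FitFailureError("non-positive fitted amplitude")
    rss = float(np.sum((y - a * np.exp(-b * x)) ** 2))
    return DecayFit(a, b, rss)


def compare_orders(
    orderset,
    species_a: str,
    species_b: str,
    min_genes: int = 5,
    max_gap: int = 5,
    midpoints: dict[str, int] | None = None,
) -> dict:
    """All-element synteny comparison of two species of a GeneOrderSet."""
    orthologs = orderset.ortholog_map(species_a, species_b)
    blocks_per_el = {}
    breakpoints_per_el = {}
    spans = []
    n_breaks = 0
    for el in orderset.elements:
        oa = orderset.orders[species_a][el]
        ob = orderset.orders[species_b][el]
        el_orth = {g: orthologs[g] for g, _ in oa if g in orthologs}
        blocks = chain_collinear_blocks(oa, ob, el_orth, min_genes, max_gap)
        if midpoints is not None:
            add_block_spans(blocks, midpoints, oa)
            spans.extend(b.span_bp for b in blocks)
        bps = reference_breakpoints(blocks, len(oa))
        blocks_per_el[el] = blocks
        breakpoints_per_el[el] = bps
        n_breaks += len(bps)
    return {
        "species_a": species_a,
        "species_b": species_b,
        "blocks": blocks_per_el,
        "breakpoints": breakpoints_per_el,
        "block_spans_bp": spans,
        "n_breakpoints": n_breaks,
    }
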