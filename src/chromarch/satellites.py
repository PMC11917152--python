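"""Satellite-DNA consensus analysis downstream of tandem-repeat annotation.

Tandem-repeat arrays (TRASH-style tables: per-array coordinates plus a
monomer consensus) are classified as simple (< 50 bp monomer) or complex,
grouped by near-identical consensus length, multiple-aligned to derive
majority-rule group consensuses, and embedded by principal coordinate
analysis of alignment-identity distances.  Because consensus strands are
deliberately left untreated, one family can split into two mirrored PCoA
clusters; :func:`detect_strand_duplicates` finds and collapses such
reverse-complement pairs.  Family membership and eu/het abundance are
assigned by local alignment against reference monomers, and the
higher-order structure of long arrays is visualised through a windowed
identity matrix.

Two identity conventions coexist and are kept explicit: the gap-counting
identity (gaps opposite residues count as mismatches; basis of the
distance sqrt(1 - identity)) and the gap-excluding identity (only
columns where both sequences have residues).  The former is never larger
than the latter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import (
    DEFAULT_SCORING,
    align_pair,
    alignment_identity,
    local_hit,
    local_score,
    msa_center_star,
    pair_distance,
    revcomp,
)
from .core import (
    HetBlocks,
    InconsistentInputError,
    InvalidParameterError,
    MalformedInputError,
)

SIMPLE_COMPLEX_THRESHOLD = 50  # bp monomer length


@dataclass(frozen=True)
class FamilyReference:
    """Reference consensus of a complex satellite family."""

    name: str
    consensus: str
    monomer_length: int

    def __post_init__(self) -> None:
        if self.monomer_length < SIMPLE_COMPLEX_THRESHOLD:
            raise InvalidParameterError(
                "family references describe complex satellites (>= 50 bp)"
            )
        if len(self.consensus) != self.monomer_length:
            raise InconsistentInputError("consensus length != monomer_length")


@dataclass
class ConsensusGroup:
    member_ids: list[str]
    length_class: tuple[int, int]  # (min, max) member consensus length
    total_coverage: int
    alignment: list[str] = field(default_factory=list)
    group_consensus: str = ""
    retained: bool = True


@dataclass
class PCoAResult:
    coordinates: np.ndarray  # (n items, k)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray


@dataclass
class IdentityHeatmap:
    window: int
    matrix: np.ndarray


def classify_repeat_class(monomer_length: int) -> str:
    """simple (< 50 bp monomer) vs complex (>= 50 bp)."""
    return "simple" if monomer_length < SIMPLE_COMPLEX_THRESHOLD else "complex"


def select_for_pcoa(arrays: pd.DataFrame) -> pd.DataFrame:
    """Keep arrays with consensus length >= 50 bp.

    Deliberately no other filtering and no strand normalisation, so that
    reverse-complemented consensuses of one family form mirrored clusters.
    """
    if arrays.empty:
        return arrays
    keep = arrays["consensus"].str.len() >= SIMPLE_COMPLEX_THRESHOLD
    return arrays[keep].reset_index(drop=True)


def group_arrays_by_length(
    arrays: pd.DataFrame, tolerance: int = 1, min_coverage: int = 5000
) -> list[ConsensusGroup]:
    """Group arrays whose consensus lengths are within ``tolerance`` bp.

    Groups are formed greedily on the sorted lengths (a group's span never
    exceeds ``tolerance``).  Groups below ``min_coverage`` total bp are
    marked ``retained=False`` rather than dropped.
    """
    if arrays.empty:
        return []
    df = arrays.assign(clen=arrays["consensus"].str.len()).sort_values(
        ["clen", "array_id"], kind="stable"
    )
    groups: list[ConsensusGroup] = []
    current: list[tuple[str, int, int]] = []
    base = None
    for row in df.itertuples(index=False):
        length = int(row.clen)
        coverage = int(row.end - row.start)
        if base is None or length - base <= tolerance:
            current.append((row.array_id, length, coverage))
            if base is None:
                base = length
        else:
            groups.append(_finish_group(current, min_coverage))
            current = [(row.array_id, length, coverage)]
            base = length
    if current:
        groups.append(_finish_group(current, min_coverage))
    return groups


def _finish_group(members, min_coverage: int) -> ConsensusGroup:
    ids = [m[0] for m in members]
    lengths = [m[1] for m in members]
    coverage = sum(m[2] for m in members)
    return ConsensusGroup(
        member_ids=ids,
        length_class=(min(lengths), max(lengths)),
        total_coverage=coverage,
        retained=coverage > min_coverage,
    )


def build_group_consensus(
    members: list[str], msa=None, max_gap_freq: float = 0.5
) -> tuple[list[str], str]:
    """Multiple-align group members and take the per-column majority base.

    ``msa`` is a callable list[str] -> list[str] (gapped); the default is
    the internal center-star aligner.  Columns whose gap frequency exceeds
    ``max_gap_freq`` are dropped from the consensus.  Base ties break
    alphabetically (A < C < G < T) for determinism.
    """
    if not members:
        raise InvalidParameterError("empty consensus group")
    aligned = (msa or msa_center_star)(members)
    width = len(aligned[0])
    if any(len(s) != width for s in aligned):
        raise InconsistentInputError("aligner returned ragged alignment")
    consensus = []
    n = len(aligned)
    for col in range(width):
        column = [s[col] for s in aligned]
        gaps = column.count("-")
        if gaps / n > max_gap_freq:
            continue
        counts: dict[str, int] = {}
        for c in column:
            if c != "-":
                counts[c] = counts.get(c, 0) + 1
        best = max(counts.values())
        consensus.append(sorted(c for c, k in counts.items() if k == best)[0])
    return aligned, "".join(consensus)


def _check_shared_alignment(aligned: list[str]) -> int:
    if not aligned:
        raise InvalidParameterError("no sequences")
    width = len(aligned[0])
    if any(len(s) != width for s in aligned):
        raise InconsistentInputError("sequences do not share one alignment")
    return width


def consensus_distance_matrix(aligned: list[str]) -> np.ndarray:
    """Pairwise distances sqrt(1 - identity) under the gap-counting
    convention (gap vs residue = non-identical; gap-gap columns excluded).
    """
    _check_shared_alignment(aligned)
    n = len(aligned)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            f = alignment_identity(aligned[i], aligned[j])
            D[i, j] = D[j, i] = np.sqrt(1.0 - f)
    _assert_distance_matrix(D)
    return D


def pairwise_distance_matrix(seqs: list[str], scoring=DEFAULT_SCORING) -> np.ndarray:
    """Gap-counting distances from per-pair global alignments (pairwise
    mode, for inputs that do not share one multiple alignment)."""
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pair_distance(seqs[i], seqs[j], scoring)
    _assert_distance_matrix(D)
    return D


def _assert_distance_matrix(D: np.ndarray) -> None:
    assert np.allclose(np.diag(D), 0.0)
    assert np.allclose(D, D.T)
    assert D.min() >= -1e-12 and D.max() <= 1.0 + 1e-12


def pairwise_identity_excluding_gaps(
    aligned: list[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Identity over columns where both sequences have residues.

    Returns (identity matrix, defined mask); a pair with zero co-residue
    columns is undefined (NaN) and flagged False.
    """
    _check_shared_alignment(aligned)
    n = len(aligned)
    ident = np.ones((n, n))
    defined = np.ones((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            both = same = 0
            for x, y in zip(aligned[i], aligned[j]):
                if x != "-" and y != "-":
                    both += 1
                    if x == y:
                        same += 1
            if both == 0:
                ident[i, j] = ident[j, i] = np.nan
                defined[i, j] = defined[j, i] = False
            else:
                ident[i, j] = ident[j, i] = same / both
    return ident, defined


def pcoa(D: np.ndarray, k: int = 2) -> PCoAResult:
    """Classical scaling of a distance matrix.

    B = -1/2 J D^2 J with J the centering operator; coordinates are the
    eigenvectors of B scaled by sqrt(eigenvalue) for the k largest
    positive eigenvalues.  Negative eigenvalues are reported, not used.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise MalformedInputError("distance matrix must be square")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
        raise MalformedInputError("not a distance matrix")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, v = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(w)[::-1]
    w = w[order]
    v = v[:, order]
    positive = w > max(w.max(), 0.0) * 1e-12 if w.size else w > 0
    n_pos = int(positive.sum())
    if k > n_pos:
        warnings.warn(
            f"requested {k} axes but only {n_pos} positive eigenvalues; truncating",
            stacklevel=2,
        )
        k = n_pos
    coords = v[:, :k] * np.sqrt(w[:k])
    total_pos = w[positive].sum() if n_pos else 1.0
    explained = np.where(w > 0, w / total_pos, 0.0)
    return PCoAResult(coords, w, explained)


def canonical_strand(seq: str) -> str:
    """Lexicographically smaller of a sequence and its reverse complement."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def detect_strand_duplicates(
    consensuses: dict[str, str], tau: float = 0.3, scoring=DEFAULT_SCORING
) -> tuple[list[tuple[str, str, float]], dict[str, str]]:
    """Find consensus pairs that match only after reverse complementing.

    A pair (x, y) is flagged iff distance(x, revcomp(y)) < tau while
    distance(x, y) >= tau.  Returns the flagged pairs with their
    reverse-complement distance, and a canonical-strand sequence for every
    flagged item.
    """
    ids = list(consensuses)
    flagged = []
    canonical: dict[str, str] = {}
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            x, y = consensuses[ids[a]], consensuses[ids[b]]
            d_rc = pair_distance(x, revcomp(y), scoring)
            if d_rc >= tau:
                continue
            d_fwd = pair_distance(x, y, scoring)
            if d_fwd >= tau:
                flagged.append((ids[a], ids[b], d_rc))
                canonical[ids[a]] = canonical_strand(x)
                canonical[ids[b]] = canonical_strand(y)
    return flagged, canonical


def collapse_strands(
    consensuses: dict[str, str],
    attach_tau: float = 0.5,
    scoring=DEFAULT_SCORING,
) -> tuple[dict[str, str], dict[str, str]]:
    """Orient every consensus onto one strand per sequence neighbourhood.

    Greedy anchor pass: sequences are visited in id order; each is compared
    against the existing anchors in both orientations and adopts the
    orientation closest to its nearest anchor (if within ``attach_tau``),
    otherwise it becomes a new anchor on its lexicographic canonical
    strand.  Robust to the per-sequence noise that breaks plain
    lexicographic canonicalisation on diverged family members.

    Returns (oriented sequences, strand flags relative to the input:
    ``+`` kept, ``-`` reverse-complemented).
    """
    anchors: list[str] = []
    oriented: dict[str, str] = {}
    strands: dict[str, str] = {}
    for key in sorted(consensuses):
        seq = consensuses[key]
        rc = revcomp(seq)
        best = None  # (distance, flipped)
        for anchor in anchors:
            for flipped, cand in ((False, seq), (True, rc)):
                d = pair_distance(anchor, cand, scoring)
                if best is None or d < best[0]:
                    best = (d, flipped)
        if best is not None and best[0] < attach_tau:
            flipped = best[1]
        else:
            canonical = canonical_strand(seq)
            flipped = canonical != seq
            anchors.append(canonical)
        oriented[key] = rc if flipped else seq
        strands[key] = "-" if flipped else "+"
    return oriented, strands


def assign_families(
    arrays: pd.DataFrame,
    sequences: dict[str, str],
    refs: list[FamilyReference],
    min_query_cov: float = 0.8,
    min_aln_len: int = 50,
    het_blocks: dict[str, HetBlocks] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign arrays to reference families by local alignment.

    Each reference is aligned locally against the array sequence on both
    strands; hits shorter than ``min_aln_len`` are discarded, and an
    assignment requires at least ``min_query_cov`` of the reference
    covered.  Among qualifying references the best local score wins.
    Abundance sums assigned array coverage bp per
    (species, element, family), split eu/het by array midpoint when
    ``het_blocks`` is given.
    """
    if not refs:
        raise InvalidParameterError("no family references given")
    rows = []
    for arr in arrays.itertuples(index=False):
        seq = sequences[arr.array_id]
        # cheap score pass picks the candidate; one full alignment verifies
        # the coverage and length thresholds
        candidates = sorted(
            (
                (local_score(ref.consensus, target), ref.name, strand)
                for ref in refs
                for strand, target in (("+", seq), ("-", revcomp(seq)))
            ),
            reverse=True,
        )
        by_name = {ref.name: ref for ref in refs}
        best = None
        for score0, name, strand in candidates:
            if score0 <= 0:
                break
            ref = by_name[name]
            target = seq if strand == "+" else revcomp(seq)
            hit = local_hit(ref.consensus, target)
            if hit is None:
                continue
            q_bp, aln_len, identity, score = hit
            if aln_len < min_aln_len:
                continue
            cov = q_bp / ref.monomer_length
            if cov < min_query_cov:
                continue
            best = ((cov, score, identity), name, strand)
            break
        compartment = ""
        if het_blocks is not None:
            mid = (int(arr.start) + int(arr.end)) // 2
            blocks = het_blocks.get(arr.element)
            compartment = (
                "het" if blocks is not None and blocks.contains(mid) else "eu"
            )
        rows.append(
            {
                "array_id": arr.array_id,
                "species": arr.species,
                "element": arr.element,
                "family": best[1] if best else "",
                "strand": best[2] if best else "",
                "query_cov": best[0][0] if best else np.nan,
                "coverage_bp": int(arr.end - arr.start),
                "compartment": compartment,
            }
        )
    assignments = pd.DataFrame(rows)
    group_cols = ["species", "element", "family"]
    if het_blocks is not None:
        group_cols.append("compartment")
    assigned = assignments[assignments["family"] != ""]
    abundance = (
        assigned.groupby(group_cols, as_index=False)["coverage_bp"]
        .sum()
        .sort_values(group_cols, kind="stable")
        .reset_index(drop=True)
    )
    return assignments, abundance


def _rotations(seq: str) -> list[str]:
    return [seq[i:] + seq[:i] for i in range(len(seq))]


def validate_known_repeats(
    known: list[tuple[str, str]],
    observed: list[str],
    max_exact_len: int = 12,
    min_query_cov: float = 0.8,
) -> pd.DataFrame:
    """Cross-check literature repeats against observed consensuses.

    Repeats up to ``max_exact_len`` bp must match exactly — any cyclic
    rotation of the repeat or of its reverse complement, searched in each
    observed consensus doubled (so the observed rotation is free too).
    Longer repeats must be covered to ``min_query_cov`` by a local
    alignment against some observed consensus.
    """
    rows = []
    for name, seq in known:
        seq = seq.upper()
        matched = False
        how = ""
        if len(seq) <= max_exact_len:
            patterns = set(_rotations(seq)) | set(_rotations(revcomp(seq)))
            for obs in observed:
                doubled = obs + obs
                if any(p in doubled for p in patterns if len(p) <= len(doubled)):
                    matched = True
                    how = "exact-rotation"
                    break
        else:
            for obs in observed:
                for target in (obs, revcomp(obs)):
                    hit = local_hit(seq, target)
                    if hit is None:
                        continue
                    q_bp, _, _, _ = hit
                    if q_bp / len(seq) >= min_query_cov:
                        matched = True
                        how = "local-alignment"
                        break
                if matched:
                    break
        rows.append({"name": name, "matched": matched, "method": how})
    return pd.DataFrame(rows)


def identity_heatmap(region: str, window: int = 1000) -> IdentityHeatmap:
    """Pairwise identity of consecutive sequence windows.

    Entry (i, j) is identical columns / alignment length of the global
    alignment of windows i and j; the diagonal is 1.  Only full windows
    are used.
    """
    if window < 10:
        raise InvalidParameterError("window too small")
    n_win = len(region) // window
    if n_win < 2:
        raise InvalidParameterError("region must span at least 2 windows")
    windows = [region[i * window : (i + 1) * window] for i in range(n_win)]
    M = np.eye(n_win)
    for i in range(n_win):
        for j in range(i + 1, n_win):
            ga, gb, _ = align_pair(windows[i], windows[j])
            same = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
            M[i, j] = M[j, i] = same / len(ga)
    return IdentityHeatmap(window, M)


def partition_satellites(
    arrays: pd.DataFrame,
    het_blocks: dict[str, HetBlocks],
    labels: dict[str, str] | None = None,
    bin_size: int = 30_000,
    element_lengths: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Satellite bp per (compartment, class, family/cluster label).

    Arrays fall eu/het by the midpoint rule against ``het_blocks``;
    ``labels`` maps array_id to a cluster or family name (defaults to the
    simple/complex class).  Also returns per-element satellite density in
    ``bin_size`` bins when ``element_lengths`` is given.
    """
    rows = []
    for arr in arrays.itertuples(index=False):
        blocks = het_blocks.get(arr.element)
        if blocks is None:
            raise InconsistentInputError(
                f"no heterochromatin blocks for element {arr.element!r}"
            )
        mid = (int(arr.start) + int(arr.end)) // 2
        compartment = "het" if blocks.contains(mid) else "eu"
        label = (
            labels.get(arr.array_id, "")
            if labels is not None
            else classify_repeat_class(len(arr.consensus))
        )
        rows.append(
            {
                "compartment": compartment,
                "class": classify_repeat_class(len(arr.consensus)),
                "label": label,
                "bp": int(arr.end - arr.start),
            }
        )
    if rows:
        shares = (
            pd.DataFrame(rows)
            .groupby(["compartment", "class", "label"], as_index=False)["bp"]
            .sum()
            .sort_values(["compartment", "class", "label"], kind="stable")
            .reset_index(drop=True)
        )
    else:
        shares = pd.DataFrame(columns=["compartment", "class", "label", "bp"])

    tracks: dict[str, np.ndarray] = {}
    if element_lengths is not None:
        from .heterochromatin import bin_density

        for el, length in element_lengths.items():
            sub = arrays[arrays["element"] == el]
            ivs = list(zip(sub["start"].astype(int), sub["end"].astype(int)))
            tracks[el] = bin_density(ivs, length, bin_size, el).values
    return shares, tracks
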