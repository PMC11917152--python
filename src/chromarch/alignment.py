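"""Global pairwise alignment and center-star multiple alignment.

The global aligner is a Needleman-Wunsch dynamic program with linear gap
costs and a fixed tie-break order (match/mismatch preferred over a gap in
the first sequence, preferred over a gap in the second), so that alignments
— and every identity statistic derived from them — are fully deterministic.
The inner DP is compiled with numba.

The multiple-alignment fallback is center-star: the member minimising the
summed pairwise distance is the center, and pairwise alignments to the
center are merged under the usual "once a gap, always a gap" rule.  An
external MSA backend can be plugged in wherever an ``msa`` callable is
accepted.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .core import InvalidParameterError, MalformedInputError

DNA = "ACGT"
_ENCODE = {c: i for i, c in enumerate(DNA)}
_IUPAC_EXTRA = set("RYSWKMBDHVN")

#: default scoring: match +2, mismatch -2, gap -3 (linear)
DEFAULT_SCORING = (2.0, -2.0, -3.0)

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide sequence."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _encode(seq: str, allow_iupac: bool) -> np.ndarray:
    seq = seq.upper()
    out = np.empty(len(seq), dtype=np.int8)
    for i, c in enumerate(seq):
        code = _ENCODE.get(c)
        if code is None:
            if allow_iupac and c in _IUPAC_EXTRA:
                code = 4  # ambiguity: never matches
            else:
                raise MalformedInputError(f"non-ACGT symbol {c!r} at position {i}")
        out[i] = code
    return out


@njit(cache=True)
def _nw(a, b, match, mismatch, gap):  # pragma: no cover - compiled
    n, m = a.shape[0], b.shape[0]
    score = np.empty((n + 1, m + 1), dtype=np.float64)
    # pointers: 0 diag, 1 gap in a (consume b), 2 gap in b (consume a)
    ptr = np.empty((n + 1, m + 1), dtype=np.int8)
    score[0, 0] = 0.0
    for j in range(1, m + 1):
        score[0, j] = gap * j
        ptr[0, j] = 1
    for i in range(1, n + 1):
        score[i, 0] = gap * i
        ptr[i, 0] = 2
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] and a[i - 1] < 4 else mismatch
            diag = score[i - 1, j - 1] + s
            up_b = score[i, j - 1] + gap  # gap in a
            up_a = score[i - 1, j] + gap  # gap in b
            best = diag
            p = 0
            if up_b > best:
                best = up_b
                p = 1
            if up_a > best:
                best = up_a
                p = 2
            score[i, j] = best
            ptr[i, j] = p
    return score[n, m], ptr


def align_pair(
    a: str,
    b: str,
    scoring: tuple[float, float, float] = DEFAULT_SCORING,
    allow_iupac: bool = False,
) -> tuple[str, str, float]:
    """Optimal global alignment of two sequences.

    Returns ``(gapped_a, gapped_b, score)``.  Ties are broken by preferring
    a match/mismatch column, then a gap in ``a``, then a gap in ``b``.
    """
    if not a or not b:
        raise MalformedInputError("sequences must be non-empty")
    match, mismatch, gap = scoring
    ea, eb = _encode(a, allow_iupac), _encode(b, allow_iupac)
    score, ptr = _nw(ea, eb, float(match), float(mismatch), float(gap))
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = len(a), len(b)
    while i > 0 or j > 0:
        p = ptr[i, j]
        if i > 0 and j > 0 and p == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif j > 0 and (p == 1 or i == 0):
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
        else:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(score)


def alignment_identity(ga: str, gb: str) -> float:
    """Identical columns / columns where at least one sequence has a residue.

    Gap-vs-residue columns count as non-identical; gap-gap columns are
    ignored.  This is the gap-counting convention.
    """
    if len(ga) != len(gb):
        raise MalformedInputError("gapped sequences differ in length")
    ident = denom = 0
    for x, y in zip(ga, gb):
        if x == "-" and y == "-":
            continue
        denom += 1
        if x == y:
            ident += 1
    if denom == 0:
        raise MalformedInputError("alignment has no residue columns")
    return ident / denom


def pair_distance(a: str, b: str, scoring=DEFAULT_SCORING) -> float:
    """sqrt(1 - identity) of the optimal global alignment of a and b."""
    ga, gb, _ = align_pair(a, b, scoring)
    return float(np.sqrt(1.0 - alignment_identity(ga, gb)))


def msa_center_star(seqs: list[str], scoring=DEFAULT_SCORING) -> list[str]:
    """Multiple alignment by the center-star heuristic.

    The center is the member with the smallest summed pairwise distance
    (ties: smallest index); every other member is aligned to the center and
    merged, keeping previously introduced gaps.
    Returns gapped sequences in input order.
    """
    if not seqs:
        raise InvalidParameterError("no sequences to align")
    if len(seqs) == 1:
        return [seqs[0]]
    n = len(seqs)
    dist_sum = np.zeros(n)
    pair_aln: dict[tuple[int, int], tuple[str, str]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            ga, gb, _ = align_pair(seqs[i], seqs[j], scoring)
            d = np.sqrt(1.0 - alignment_identity(ga, gb))
            dist_sum[i] += d
            dist_sum[j] += d
            pair_aln[(i, j)] = (ga, gb)
    center = int(np.argmin(dist_sum))

    rows: list[list[str]] = [list(seqs[center])]
    order = [center]
    center_row = 0
    for k in range(n):
        if k == center:
            continue
        if (center, k) in pair_aln:
            gc, gk = pair_aln[(center, k)]
        else:
            gk, gc = pair_aln[(k, center)]
        rows = _merge_into_star(rows, center_row, gc, gk)
        order.append(k)

    width = len(rows[0])
    out = [""] * n
    for row, orig in zip(rows, order):
        assert len(row) == width
        out[orig] = "".join(row)
    return out


def _merge_into_star(
    rows: list[list[str]], center_row: int, gc: str, gk: str
) -> list[list[str]]:
    """Merge one center-aligned sequence into the growing star alignment."""
    master = rows[center_row]
    new_rows: list[list[str]] = [[] for _ in rows]
    new_seq: list[str] = []
    mpos = 0  # column in master

    def copy_master_column(col: int, seq_char: str) -> None:
        for r, nr in zip(rows, new_rows):
            nr.append(r[col])
        new_seq.append(seq_char)

    def insert_gap_column(seq_char: str) -> None:
        for nr in new_rows:
            nr.append("-")
        new_seq.append(seq_char)

    for cc, kc in zip(gc, gk):
        if cc == "-":
            insert_gap_column(kc)
        else:
            # advance past master columns where the center has a gap
            while master[mpos] == "-":
                copy_master_column(mpos, "-")
                mpos += 1
            copy_master_column(mpos, kc)
            mpos += 1
    while mpos < len(master):
        copy_master_column(mpos, "-")
        mpos += 1
    new_rows.append(new_seq)
    return new_rows


def _local_aligner(scoring):
    from Bio import Align

    match, mismatch, gap = scoring
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def local_score(query: str, target: str, scoring=DEFAULT_SCORING) -> float:
    """Best local alignment score only (cheap prefilter)."""
    return float(_local_aligner(scoring).score(query, target))


def local_hit(query: str, target: str, scoring=DEFAULT_SCORING):
    """Best local alignment of ``query`` against ``target`` via Biopython.

    Returns ``(aligned_query_bp, alignment_length, identity, score)`` of the
    highest-scoring local hit, or None when no positive-score hit exists.
    """
    aligner = _local_aligner(scoring)
    score = aligner.score(query, target)
    if score <= 0:
        return None
    aln = aligner.align(query, target)[0]
    q_aligned = int(sum(e - s for s, e in aln.aligned[0]))
    matches = 0
    length = 0
    qa, ta = str(aln[0]), str(aln[1])
    for x, y in zip(qa, ta):
        length += 1
        if x == y and x != "-":
            matches += 1
    identity = matches / length if length else 0.0
    return q_aligned, length, identity, float(score)
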