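"""Inter-element contact statistics, chromosome configuration, compartments.

Hi-C contacts between Muller elements reveal which elements are fused into
one chromosome: a fused pair shows strongly elevated inter-element contact
concentrated near the junction.  The contact statistic follows the
length-normalised convention raw / sqrt(len_i x len_j); a pair is called
fused when it is the mutual contact maximum of both elements and clearly
exceeds the inter-element background.

A/B chromatin compartments come from the leading eigenvector of the
Pearson correlation matrix of the normalised contact map.  Normalisation
is z-scoring; the default stratifies by genomic distance (per diagonal,
the observed/expected-style convention of Hi-C compartment analysis),
with plain per-row and whole-matrix z-scores available behind the
``zscore`` switch.  The eigenvector sign is fixed against TE density:
repeat-rich bins are the B compartment and get negative values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .core import (
    ChromarchError,
    ContactMatrix,
    DensityTrack,
    ElementConfiguration,
    InconsistentInputError,
    InvalidParameterError,
)


class DegenerateMatrixError(ChromarchError):
    """The contact sub-matrix carries no usable correlation structure."""


@dataclass
class CompartmentTrack:
    """Per-bin compartment eigenvector with A/B labels.

    Masked (zero-coverage) bins carry NaN in ``eigenvector`` and ``""`` in
    ``labels``.  ``explained`` is the leading eigenvalue's share of the
    correlation-matrix trace.  ``oriented`` records whether the sign was
    fixed against a TE track; ``orientation_warning`` flags a degenerate
    (constant-TE) orientation attempt.
    """

    bins: pd.DataFrame
    eigenvector: np.ndarray
    labels: np.ndarray
    explained: float
    scope: str
    oriented: bool = False
    orientation_warning: bool = False


def inter_element_contacts(matrix: ContactMatrix) -> pd.DataFrame:
    """Raw and length-normalised contacts for every unordered element pair.

    normalized = raw / sqrt(len_i x len_j), lengths in bp summed over the
    element's bins, so the statistic is self-contained given the matrix.
    """
    elements = matrix.elements
    if len(elements) < 2:
        raise InvalidParameterError("need >= 2 elements for inter-element pairs")
    lengths = {el: matrix.element_length(el) for el in elements}
    idx = {el: matrix.element_bins(el) for el in elements}
    rows = []
    for el1, el2 in itertools.combinations(elements, 2):
        raw = float(matrix.counts[np.ix_(idx[el1], idx[el2])].sum())
        norm = raw / np.sqrt(float(lengths[el1]) * float(lengths[el2]))
        rows.append((el1, el2, raw, norm))
    return pd.DataFrame(
        rows, columns=["element_1", "element_2", "raw_count", "normalized"]
    )


def infer_configuration(
    contact_table: pd.DataFrame, fusion_ratio: float = 2.0
) -> ElementConfiguration:
    """Call fused element pairs and assemble chromosomes.

    A pair is fused iff it is the mutual contact maximum for both of its
    elements AND its normalised value reaches ``fusion_ratio`` times the
    median of all inter-element normalised values.  Fused pairs merge
    transitively; everything else stays a singleton chromosome.
    """
    if len(contact_table) < 3:
        raise InvalidParameterError(
            "need >= 3 element pairs to estimate the contact background"
        )
    elements = sorted(
        set(contact_table["element_1"]) | set(contact_table["element_2"])
    )
    value: dict[frozenset, float] = {}
    for row in contact_table.itertuples(index=False):
        value[frozenset((row.element_1, row.element_2))] = float(row.normalized)

    best: dict[str, tuple[float, str]] = {}
    for el in elements:
        partners = sorted(e for e in elements if e != el)
        scores = [(value[frozenset((el, p))], p) for p in partners]
        top = max(s for s, _ in scores)
        # deterministic tie-break: first partner alphabetically
        pick = next(p for s, p in scores if s == top)
        best[el] = (top, pick)

    median = float(np.median(list(value.values())))
    cutoff = fusion_ratio * median
    fused = []
    for el1, el2 in itertools.combinations(elements, 2):
        v = value[frozenset((el1, el2))]
        mutual = best[el1][1] == el2 and best[el2][1] == el1
        strong = v >= cutoff and v > 0
        if mutual and strong:
            fused.append((el1, el2))

    parent = {el: el for el in elements}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in fused:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    groups: dict[str, list[str]] = {}
    for el in elements:
        groups.setdefault(find(el), []).append(el)
    chromosomes = tuple(
        tuple(sorted(g)) for g in sorted(groups.values(), key=lambda g: sorted(g)[0])
    )
    return ElementConfiguration(chromosomes)


def _zscore_diagonal(sub: np.ndarray) -> np.ndarray:
    n = sub.shape[0]
    z = np.zeros_like(sub)
    for k in range(n):
        i = np.arange(n - k)
        j = i + k
        v = sub[i, j]
        sd = v.std()
        zz = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
        z[i, j] = zz
        z[j, i] = zz
    return z


def _zscore_rows(sub: np.ndarray) -> np.ndarray:
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (sub - mu) / sd


def _zscore_matrix(sub: np.ndarray) -> np.ndarray:
    sd = sub.std()
    if sd == 0:
        return np.zeros_like(sub)
    return (sub - sub.mean()) / sd


def _normalize(sub: np.ndarray, elements_of: np.ndarray, mode: str) -> np.ndarray:
    """Blockwise z-score: intra-element blocks per the chosen mode,
    inter-element blocks as whole blocks."""
    z = np.zeros_like(sub)
    uniq = list(dict.fromkeys(elements_of))
    for a in uniq:
        ia = np.flatnonzero(elements_of == a)
        for b in uniq:
            ib = np.flatnonzero(elements_of == b)
            block = sub[np.ix_(ia, ib)]
            if a == b:
                if mode == "diagonal":
                    zb = _zscore_diagonal(block)
                elif mode == "row":
                    zb = _zscore_rows(block)
                elif mode == "matrix":
                    zb = _zscore_matrix(block)
                else:
                    raise InvalidParameterError(f"unknown zscore mode {mode!r}")
            else:
                zb = _zscore_matrix(block)
            z[np.ix_(ia, ib)] = zb
    return z


def compartment_eigenvector(
    matrix: ContactMatrix,
    scope: str | None = None,
    zscore: str = "diagonal",
    min_bins: int = 10,
) -> CompartmentTrack:
    """Leading eigenvector of the bin-bin Pearson correlation matrix.

    ``scope`` restricts to one element; None uses the whole genome.
    Zero-coverage bins are masked and returned as missing.  The sign is
    arbitrary until :func:`orient_compartments` fixes it.
    """
    if scope is None:
        idx = np.arange(matrix.n_bins)
        scope_name = "genome"
    else:
        idx = matrix.element_bins(scope)
        scope_name = scope
        if idx.size == 0:
            raise InvalidParameterError(f"no bins for element {scope!r}")
    sub = matrix.counts[np.ix_(idx, idx)]
    if idx.size < min_bins:
        raise InvalidParameterError(f"need >= {min_bins} bins in scope")

    coverage = sub.sum(axis=1)
    valid = coverage > 0
    if valid.sum() < min_bins:
        raise DegenerateMatrixError("too few covered bins in scope")
    sub_v = sub[np.ix_(np.flatnonzero(valid), np.flatnonzero(valid))]
    if np.allclose(sub_v, sub_v.flat[0]):
        raise DegenerateMatrixError("constant contact matrix in scope")

    elements_of = matrix.bins["element"].to_numpy()[idx][valid]
    z = _normalize(sub_v, elements_of, zscore)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(z)
    if not np.all(np.isfinite(corr)):
        # rows with zero variance after normalisation: treat as uncorrelated
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)

    w, v = linalg.eigh(corr)
    lead = v[:, -1]
    explained = float(w[-1] / np.trace(corr))

    eigenvector = np.full(idx.size, np.nan)
    eigenvector[valid] = lead
    labels = np.full(idx.size, "", dtype="<U1")
    labels[valid] = np.where(lead < 0, "B", "A")
    return CompartmentTrack(
        bins=matrix.bins.iloc[idx].reset_index(drop=True),
        eigenvector=eigenvector,
        labels=labels,
        explained=explained,
        scope=scope_name,
    )


def orient_compartments(
    track: CompartmentTrack, te_density
) -> CompartmentTrack:
    """Fix the eigenvector sign so repeat-rich bins are negative (= B).

    ``te_density`` is a DensityTrack or plain vector on the same binning
    as the track.  If TE density is constant the input orientation is kept
    and a warning flag set.
    """
    values = te_density.values if isinstance(te_density, DensityTrack) else np.asarray(
        te_density, dtype=float
    )
    if values.size != track.eigenvector.size:
        raise InconsistentInputError("TE track and compartment track binning differ")
    valid = np.isfinite(track.eigenvector)
    ev = track.eigenvector.copy()
    warning = False
    if np.allclose(values, values.flat[0]):
        warning = True
    else:
        median = np.median(values[valid])
        high = valid & (values > median)
        if not high.any():
            warning = True
        elif float(ev[high].mean()) > 0:
            ev = -ev
    labels = np.full(ev.size, "", dtype="<U1")
    labels[valid] = np.where(ev[valid] < 0, "B", "A")
    return CompartmentTrack(
        bins=track.bins,
        eigenvector=ev,
        labels=labels,
        explained=track.explained,
        scope=track.scope,
        oriented=True,
        orientation_warning=warning,
    )
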