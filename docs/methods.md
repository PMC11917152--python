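# Methods

`chromarch` re-implements, as a tested library, the downstream computations
of a comparative study of chromosome architecture across *Drosophila*
genomes: how the six ancestral chromosome arms (Muller elements A–F) are
allocated, oriented and fused into chromosomes; where pericentromeric
heterochromatin lies; how gene order decays by inversion; and how satellite
DNA families diversify.  Every stage is exercised against synthetic genomes
with planted ground truth, so the package's tests measure recovery of known
structure rather than agreement with any particular real assembly.

## Muller element allocation and orientation

A scaffold is allocated to the element whose reference arm (dm6: X, 2L, 2R,
3L, 3R, 4 = A–F) receives the largest summed aligned length across all of
the scaffold's nucleotide-alignment hits.  "Mutual best" is operationalised
as a minimum share of the scaffold's total aligned bp going to the winning
arm (`min_share`, default 0.5); ties and weak winners are UNPLACED.
Aligned length, not alignment score, is aggregated, since the criterion is
overall coverage.

Orientation compares the mean TE density of the first versus last half of
an element.  The reference convention is that A, B and D end in the TE-rich
pericentromere while C and E begin with it; element F has no stated
convention and is always reported `undetermined`, as are exact ties.
Halves, not quartiles, are compared.

## Hi-C: configuration and compartments

Inter-element contact intensity is `raw / sqrt(len_i × len_j)`; element
lengths are the summed bin spans of the matrix, so the statistic is
self-contained.  A pair is called fused when it is the mutual contact
maximum of both elements **and** its normalised value is at least
`fusion_ratio` (default 2.0) times the median of all inter-element values;
fused pairs merge transitively into chromosomes.  The threshold replaces a
visual call in the original analysis and is configurable; at the synthetic
study conditions (junction contacts boosted 10× over background) the fused
pair sits near 2.9× the background median, so the call is stable.

Compartments come from the leading eigenvector of the Pearson correlation
matrix of the normalised contact map, per element or genome-wide.
Normalisation is z-scoring; three modes exist behind the `zscore` switch:

* `diagonal` (default) — z-score each diagonal of the intra-element
  sub-matrix separately, i.e. standardise observed counts within each
  genomic-distance stratum.  This is the observed/expected convention of
  Hi-C compartment analysis: without it, the distance decay dominates all
  row correlations and the leading eigenvector tracks position, not
  compartment.  On planted checkerboards the per-row mode recovers ~60% of
  labels, the per-diagonal mode 93–99%.
* `row` — plain per-row z-score.
* `matrix` — one z-score over the whole sub-matrix.

Zero-coverage bins are masked and reported missing.  The eigenvector sign
is arbitrary until `orient_compartments` fixes it against TE density:
repeat-rich (above-median TE) bins are made negative and labelled B.  A
constant TE track leaves the orientation unchanged and sets a warning flag.

## Heterochromatin segmentation

TE intervals are merged and binned (default 100 kb; the final partial bin
is normalised by its true span).  Heterochromatic blocks are maximal runs
of bins at ≥ 20% TE share, merged across dips of ≤ `max_dip` (2) bins;
merged runs shorter than `min_block` (5) bins survive only within
`min_island_gap` (10) bins of a long block, otherwise they are dismissed as
euchromatic TE islands (the piRNA-cluster case).  The 20%/100-kb rule is
the published one; the dip/island tolerances are quantified here and kept
as configuration keys.  Features are classified eu/het by their midpoint.
Raising the threshold can only shrink blocks (proved by the run-merging
structure and pinned by a property test).

## Synteny blocks and breakpoints

Ortholog anchors between two gene orders are chained left-to-right into
maximal strictly monotone runs (same or inverted), with at most `max_gap`
skipped genes between consecutive anchors in either species; chains below
`min_genes` anchors are dropped.  Defaults (5/5) follow common collinearity
-tool conventions.  With a *dense* one-to-one anchor map — every gene
anchored, as in the synthetic data — `max_gap = 0` and `min_genes = 2` make
breakpoint recovery exact: any positive gap allowance lets a flanking run
absorb the first anchor of an inversion shorter than `max_gap + 1`.

Breakpoints are boundaries between adjacent reference genes assigned to
different blocks (or block vs none), reported as the left gene's index;
element ends are not breakpoints.  Counts are accumulated in bins of 10
reference genes; runs of ≥ 2 zero bins are reported as conserved regions.
Breakpoints are counted once per species pair, without deduplicating
shared ancestral events.  Block-size medians and breaks per Mb are related
to patristic distance, and block size versus distance is fitted as
`size = a·exp(−b·distance)` by nonlinear least squares initialised from the
log-linear fit.

## Satellite DNA

Arrays with monomer consensus < 50 bp are *simple*, ≥ 50 bp *complex*; only
complex consensuses enter the ordination, deliberately without strand
normalisation so that reverse-complemented members of one family form
mirrored clusters.  Arrays are grouped when consensus lengths agree within
1 bp; groups over 5 kb total coverage get a group consensus: members are
multiple-aligned (pluggable backend; the internal fallback is center-star
over exact global pairwise alignments with "once a gap, always a gap"
merging) and the highest-frequency non-gap base is taken per column,
dropping columns that are > 50% gaps.  Base ties break alphabetically.

Two identity conventions are kept explicit. The gap-counting identity
scores a gap opposite a residue as a mismatch (gap–gap columns excluded)
and feeds the distance `d = sqrt(1 − identity)`; the gap-excluding identity
uses only co-residue columns. The former never exceeds the latter.
Distances can be computed on one joint multiple alignment or per pair of
sequences (both modes are provided; the pairwise mode is the default in the
CLI since a joint alignment of heterogeneous monomer lengths is fragile).

PCoA is classical scaling: `B = −½ J D² J`, eigendecomposition, coordinates
`v√λ` for the positive eigenvalues; negative eigenvalues are reported, not
used.  Reverse-complement duplicates are detected per pair — flagged iff
the reverse-complement distance is below `tau` (0.3) while the same-strand
distance is not — and each flagged sequence gets a lexicographic canonical
strand.  For clustering, `collapse_strands` orients all sequences
consistently by a greedy anchor pass (nearest-anchor orientation within an
attachment distance of 0.5, new anchors on the canonical strand); plain
per-sequence lexicographic canonicalisation flips ~7% of members at 5%
divergence because single substitutions near the sequence ends reorder the
comparison, while anchor attachment has a wide margin (within-family
distance ≈ 0.31 versus cross-family ≈ 0.7–0.9).

Family assignment aligns each reference monomer locally (match +2,
mismatch −2, gap −3) against both strands of each array, discards hits
shorter than 50 bp, and requires ≥ 80% reference coverage; the qualifying
hit with the best score assigns the array.  A score-only pass over all
reference/strand combinations precedes the single full alignment.
Abundance sums assigned array spans per (species, element, family),
split eu/het by the midpoint rule — for a correctly assigned tandem array
the span equals the combined matched length.  Known-repeat validation uses
exact matching of any cyclic rotation (both strands; the observed consensus
is doubled so its own rotation is free) for repeats ≤ 12 bp and ≥ 80%
query coverage by local alignment for longer ones.  Higher-order repeat
structure is summarised by a windowed identity matrix (1-kb windows,
identity = identical columns / alignment length of the global alignment of
each window pair).

## Synthetic data

The generator plants exactly the structure the inference stages assume;
its defaults are the study conditions used throughout the tests.

* **Scale.** 6 elements of 3 Mb (30 bins of 100 kb), 4–6 species, 100
  genes per element.  These desk-scale sizes keep the full test suite and
  acceptance script in tens of seconds while leaving every statistic
  well-resolved; real arms are ~8× longer.
* **Tree.** Kingman-coalescent topology, node heights rescaled so every
  root-to-tip path equals `tree_depth` (default 0.3 substitutions/site) —
  rooted, binary, ultrametric by construction.
* **TE layout.** One contiguous heterochromatic block per element
  (`het_fraction` 0.2): terminal for acrocentric singletons, at the joined
  ends of fused pairs, centred for metacentric singletons.  Per-bin TE
  fraction is normal around 0.5 (het) or 0.05 (eu) with *relative* sd
  `density_noise_sd` (0.1), clipped to [0, 1], and emitted as one interval
  per bin covering exactly that fraction.
* **Compartments.** Het bins are B; euchromatin alternates A/B blocks of 5
  bins.  Same-chromosome contacts between same-label bins are boosted by
  `1 + compartment_corr` (0.3).
* **Contacts.** Intra-element expectation `scale·(1+d)^(−α)` (scale 300,
  α 1.0); inter-element background 1.0; fused pairs add
  `background·(fusion_boost−1)·exp(−(d_i+d_j)/junction_scale)` with
  distances to the joined ends and `junction_scale` 15 bins, which reduces
  exactly to the uniform background at `fusion_boost = 1`.  Counts are
  Poisson, symmetrised.  Overdispersion is deliberately not modelled.
* **Gene orders.** Each branch applies Poisson(rate × length) inversions,
  each reversing a uniformly chosen run of ≥ 2 genes within one element;
  no inter-element moves.  The `non_overlapping` mode draws all inversions
  without replacement from pre-tiled disjoint interior intervals separated
  by at least one gene, so every inversion on the path between two species
  contributes exactly two breakpoints and the per-pair truth is exact.
  A `protected` range per element excludes a window from rearrangement
  (used to emulate constrained gene clusters).
* **Satellites.** Each family (defaults: 170/140/250-bp heterochromatic
  families and a 12-bp euchromatic one) has one random ancestral monomer;
  array consensuses add i.i.d. substitutions at `divergence` (0.05), array
  sequences are 10–40 tandem copies each lightly re-mutated (0.01), and
  half the arrays are emitted reverse-complemented.  Heterochromatic
  families are placed only inside het truth, euchromatic only outside,
  non-overlapping with fixed spacing.
* **Randomness.** One stream per logical component, derived from the
  master seed by fixed CRC-labelled `SeedSequence`s; identical parameters
  give bit-identical output, and adding a generator does not perturb the
  others.  The alphabet is uniform ACGT with uniform substitutions.

What the generator does **not** emulate: read-level noise, assembly gaps,
TE sequence content (TE annotations are intervals only), indel evolution
of satellite monomers, Hi-C ligation artefacts and coverage biases,
overdispersed contact counts, gene gain/loss and many-to-many orthology.
Passing tests therefore demonstrate the correctness and calibration of the
*computations*, not robustness to every artefact of real assemblies.

## Numerical choices

* Global alignment: linear gap costs, deterministic tie-break
  (match/mismatch over gap-in-first over gap-in-second), numba-compiled DP;
  scores verified against an independent aligner in the tests.
* Eigendecompositions use symmetric `eigh`; the leading-eigenvalue share
  is reported against the correlation-matrix trace.
* The exponential-decay fit refuses non-positive sizes and reports the fit
  failure rather than guessing; the flat-data limit fits `b ≈ 0`.
* TRASH-style CSVs are 1-based inclusive on disk, 0-based half-open in
  memory; BED is 0-based half-open throughout.
* All table writers pin float formatting and newlines, so a fixed seed
  reproduces byte-identical outputs.

## Known limitations

* The fusion call assumes at most pairwise junctions per chromosome
  arrangement (the catalogue of observed configurations contains none
  with three fused elements meeting at one point).
* Genome-wide compartment scope normalises inter-element blocks as whole
  blocks; per-element scope is the better-behaved default and the one the
  acceptance checks use.
* Manual curation steps of the original pipeline (alignment corrections by
  eye, visually separated unrelated arrays) are inherently irreproducible
  and are not modelled.
* The breakpoint convention counts each species pair independently;
  ancestral breakpoints shared by related species are counted repeatedly.
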