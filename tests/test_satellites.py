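"""Satellite pipeline: grouping, consensus, distances, PCoA, families."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chromarch.alignment import align_pair, revcomp
from chromarch.core import HetBlocks, InvalidParameterError
from chromarch.satellites import (
    FamilyReference,
    assign_families,
    build_group_consensus,
    classify_repeat_class,
    collapse_strands,
    consensus_distance_matrix,
    detect_strand_duplicates,
    group_arrays_by_length,
    identity_heatmap,
    pairwise_distance_matrix,
    pairwise_identity_excluding_gaps,
    partition_satellites,
    pcoa,
    select_for_pcoa,
    validate_known_repeats,
)
from chromarch.synthdata import SimParams, component_rng, _mutate, _random_monomer


def _arrays_frame(rows):
    return pd.DataFrame(
        rows, columns=["array_id", "species", "element", "start", "end", "consensus"]
    )


class TestClassification:
    @pytest.mark.parametrize(
        "length,expected",
        [(12, "simple"), (170, "complex"), (49, "simple"), (50, "complex")],
    )
    def test_fifty_bp_monomer_threshold(self, length, expected):
        assert classify_repeat_class(length) == expected

    def test_pcoa_selection_keeps_only_complex_consensuses(self):
        df = _arrays_frame(
            [
                ("a1", "S01", "A", 0, 300, "A" * 30),
                ("a2", "S01", "A", 400, 900, "C" * 50),
                ("a3", "S01", "A", 1000, 2700, "G" * 170),
            ]
        )
        kept = select_for_pcoa(df)
        assert kept["array_id"].tolist() == ["a2", "a3"]

    def test_empty_input_passes_through(self):
        df = _arrays_frame([])
        assert select_for_pcoa(df).empty


class TestGrouping:
    def test_lengths_within_one_bp_group_together(self):
        df = _arrays_frame(
            [
                ("a1", "S01", "A", 0, 6000, "A" * 170),
                ("a2", "S01", "A", 7000, 13_000, "C" * 170),
                ("a3", "S01", "A", 14_000, 20_000, "G" * 171),
                ("a4", "S01", "A", 21_000, 27_000, "T" * 240),
            ]
        )
        groups = group_arrays_by_length(df)
        assert [g.member_ids for g in groups] == [["a1", "a2", "a3"], ["a4"]]

    def test_low_coverage_group_marked_not_retained(self):
        df = _arrays_frame(
            [
                ("a1", "S01", "A", 0, 1000, "A" * 170),
                ("a2", "S01", "A", 2000, 12_000, "C" * 250),
            ]
        )
        groups = group_arrays_by_length(df)
        assert [g.retained for g in groups] == [False, True]
        assert groups[0].total_coverage == 1000


class TestConsensus:
    def test_identical_members_give_their_sequence(self):
        _, cons = build_group_consensus(["ACGT", "ACGT", "ACGT"])
        assert cons == "ACGT"

    def test_majority_base_wins_per_column(self):
        _, cons = build_group_consensus(["ACGT", "ACGA", "ACGT"])
        assert cons == "ACGT"

    def test_simulated_members_recover_ancestor(self):
        rng = component_rng(42, "consensus-test")
        anc = _random_monomer(rng, 170)
        members = [_mutate(rng, anc, 0.05) for _ in range(20)]
        _, cons = build_group_consensus(members)
        assert cons == anc

    def test_majority_matches_per_site_tally_oracle(self):
        # substitution-only members share coordinates: per-site counts are
        # an exact oracle for the aligned majority
        rng = component_rng(43, "consensus-oracle")
        anc = _random_monomer(rng, 60)
        members = [_mutate(rng, anc, 0.1) for _ in range(15)]
        _, cons = build_group_consensus(members)
        oracle = []
        for col in range(60):
            counts = {}
            for m in members:
                counts[m[col]] = counts.get(m[col], 0) + 1
            top = max(counts.values())
            oracle.append(sorted(c for c, k in counts.items() if k == top)[0])
        assert cons == "".join(oracle)


class TestIdentityConventions:
    def test_gap_counting_distance_pin(self):
        D = consensus_distance_matrix(["AC-GT", "ACCGT"])
        assert D[0, 1] == pytest.approx(np.sqrt(0.2))

    def test_gap_excluding_identity_pin(self):
        ident, defined = pairwise_identity_excluding_gaps(["AC-GT", "ACCGT"])
        assert ident[0, 1] == pytest.approx(1.0)
        assert defined.all()

    def test_total_mismatch_is_distance_one(self):
        D = consensus_distance_matrix(["AAAA", "TTTT"])
        assert D[0, 1] == pytest.approx(1.0)

    def test_disjoint_residues_flagged_undefined(self):
        ident, defined = pairwise_identity_excluding_gaps(["AA--", "--TT"])
        assert not defined[0, 1]
        assert np.isnan(ident[0, 1])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_gap_counting_never_exceeds_gap_excluding(self, seed):
        rng = np.random.default_rng(seed)
        symbols = np.array(list("ACGT-"))
        a = "".join(rng.choice(symbols, 30, p=[0.22, 0.22, 0.22, 0.22, 0.12]))
        b = "".join(rng.choice(symbols, 30, p=[0.22, 0.22, 0.22, 0.22, 0.12]))
        both = [(x, y) for x, y in zip(a, b) if not (x == "-" and y == "-")]
        co = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
        if not both or not co:
            return
        gap_counting = sum(x == y for x, y in both) / len(both)
        gap_excluding = sum(x == y for x, y in co) / len(co)
        assert gap_counting <= gap_excluding + 1e-12


class TestPCoA:
    def test_collinear_points_embed_exactly_in_one_axis(self):
        D = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        res = pcoa(D, k=1)
        coords = res.coordinates[:, 0]
        for i in range(3):
            for j in range(3):
                assert abs(coords[i] - coords[j]) == pytest.approx(D[i, j])

    def test_zero_distance_matrix_embeds_at_origin(self):
        with pytest.warns(UserWarning):  # no positive eigenvalues to keep
            res = pcoa(np.zeros((4, 4)), k=2)
        assert np.allclose(res.coordinates, 0.0)

    def test_matches_scikit_bio_classical_scaling(self, rng):
        import skbio

        for n in (8, 25, 50):
            X = rng.random((n, 4))
            D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
            res = pcoa(D, k=3)
            ref = skbio.stats.ordination.pcoa(
                skbio.DistanceMatrix(D), method="eigh"
            )
            ref_coords = ref.samples.to_numpy()[:, :3]
            for axis in range(3):
                a, b = res.coordinates[:, axis], ref_coords[:, axis]
                assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_embedding_equivariant_under_permutation(self, rng):
        X = rng.random((12, 3))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        perm = rng.permutation(12)
        res = pcoa(D, k=2)
        res_p = pcoa(D[np.ix_(perm, perm)], k=2)
        d1 = np.linalg.norm(
            res.coordinates[:, None] - res.coordinates[None, :], axis=-1
        )
        d2 = np.linalg.norm(
            res_p.coordinates[:, None] - res_p.coordinates[None, :], axis=-1
        )
        assert np.allclose(d1[np.ix_(perm, perm)], d2, atol=1e-8)

    def test_excess_axes_truncated_with_warning(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.warns(UserWarning):
            res = pcoa(D, k=5)
        assert res.coordinates.shape[1] <= 1


class TestStrandHandling:
    def test_exact_reverse_complement_is_flagged(self):
        rng = component_rng(5, "strand")
        x = _random_monomer(rng, 170)
        flagged, canonical = detect_strand_duplicates({"x": x, "y": revcomp(x)})
        assert len(flagged) == 1
        assert flagged[0][2] == pytest.approx(0.0, abs=1e-12)
        assert canonical["x"] == canonical["y"]

    def test_unrelated_monomers_are_not_flagged(self):
        rng = component_rng(6, "strand-null")
        seqs = {f"s{i}": _random_monomer(rng, 170) for i in range(6)}
        flagged, _ = detect_strand_duplicates(seqs)
        assert flagged == []

    def test_collapse_orients_family_members_consistently(self):
        rng = component_rng(7, "collapse")
        anc = _random_monomer(rng, 170)
        cons = {}
        truth = {}
        for i in range(12):
            seq = _mutate(rng, anc, 0.05)
            if i % 2:
                seq = revcomp(seq)
                truth[f"a{i:02d}"] = "-"
            else:
                truth[f"a{i:02d}"] = "+"
            cons[f"a{i:02d}"] = seq
        oriented, strands = collapse_strands(cons)
        # all oriented sequences are close to one strand of the ancestor
        agree = sum(strands[k] == truth[k] for k in cons)
        assert agree in (0, len(cons))  # consistent up to one global flip


class TestFamilies:
    def _refs(self):
        rng = component_rng(8, "refs")
        return [
            FamilyReference("FamA", _random_monomer(rng, 170), 170),
            FamilyReference("FamB", _random_monomer(rng, 250), 250),
        ]

    def test_exact_reference_copy_is_assigned(self):
        refs = self._refs()
        df = _arrays_frame([("a1", "S01", "A", 0, 340, refs[0].consensus)])
        seqs = {"a1": refs[0].consensus * 2}
        assignments, abundance = assign_families(df, seqs, refs)
        assert assignments["family"].tolist() == ["FamA"]
        assert assignments["query_cov"].iloc[0] == pytest.approx(1.0)
        assert abundance["coverage_bp"].sum() == 340

    def test_short_fragment_filtered_by_min_alignment_length(self):
        refs = self._refs()
        fragment = refs[0].consensus[:40]
        df = _arrays_frame([("a1", "S01", "A", 0, 40, fragment)])
        assignments, abundance = assign_families(df, {"a1": fragment}, refs)
        assert assignments["family"].tolist() == [""]
        assert abundance.empty

    def test_no_references_rejected(self):
        df = _arrays_frame([("a1", "S01", "A", 0, 40, "ACGT" * 10)])
        with pytest.raises(InvalidParameterError):
            assign_families(df, {"a1": "ACGT" * 10}, [])

    def test_reference_shorter_than_fifty_bp_rejected(self):
        with pytest.raises(InvalidParameterError):
            FamilyReference("bad", "ACGT" * 10, 40)


class TestKnownRepeatValidation:
    def test_rotated_twelve_mer_matches(self):
        repeat = "ACCTGAATGGAT"
        rotated = repeat[5:] + repeat[:5]
        report = validate_known_repeats([("sat12", repeat)], [rotated])
        assert report["matched"].all()

    def test_absent_twelve_mer_is_unmatched(self):
        report = validate_known_repeats(
            [("sat12", "ACCTGAATGGAT")], ["GGGGCCCCAAAA"]
        )
        assert not report["matched"].any()

    def test_diverged_long_reference_matches_at_coverage(self):
        rng = component_rng(9, "validate")
        ref = _random_monomer(rng, 359)
        observed = _mutate(rng, ref, 0.05)  # ~95% identity, full length
        report = validate_known_repeats([("sat359", ref)], [observed])
        assert report["matched"].all()


class TestIdentityHeatmap:
    def test_homogeneous_tandem_array_is_uniform(self):
        monomer = "ACGTT" * 40  # 200 bp, window multiple of period
        region = monomer * 10  # 2000 bp
        hm = identity_heatmap(region, window=1000)
        assert np.allclose(hm.matrix, 1.0)

    def test_hor_blocks_show_block_structure(self):
        rng = component_rng(10, "hor")
        base = _random_monomer(rng, 500)
        block_a = "".join(_mutate(rng, base, 0.02) for _ in range(4))
        far = _mutate(rng, base, 0.2)
        block_b = "".join(_mutate(rng, far, 0.02) for _ in range(4))
        hm = identity_heatmap(block_a + block_b, window=1000)
        n = hm.matrix.shape[0]
        within = [hm.matrix[i, j] for i in range(2) for j in range(2) if i < j]
        within += [hm.matrix[i, j] for i in range(2, n) for j in range(2, n) if i < j]
        between = [hm.matrix[i, j] for i in range(2) for j in range(2, n)]
        assert np.mean(within) > np.mean(between)

    def test_te_insertion_depresses_identity(self):
        rng = component_rng(11, "te-insert")
        monomer = _random_monomer(rng, 200)
        te = _random_monomer(rng, 1000)
        region = monomer * 10 + te + monomer * 10
        hm = identity_heatmap(region, window=1000)
        te_row = 2  # the TE occupies the third window
        array_cols = [0, 1, 3, 4]
        assert hm.matrix[te_row, array_cols].mean() < 0.8
        assert hm.matrix[0, 1] > 0.95

    def test_too_short_region_rejected(self):
        with pytest.raises(InvalidParameterError):
            identity_heatmap("ACGT" * 100, window=1000)


class TestPartition:
    def _blocks(self):
        return {"A": HetBlocks("A", [(0, 600_000)]), "B": HetBlocks("B", [])}

    def test_all_arrays_in_het_truth_gives_full_het_share(self):
        df = _arrays_frame(
            [
                ("a1", "S01", "A", 0, 5000, "A" * 170),
                ("a2", "S01", "A", 10_000, 18_000, "C" * 170),
            ]
        )
        shares, _ = partition_satellites(df, self._blocks())
        assert shares["compartment"].unique().tolist() == ["het"]
        assert shares["bp"].sum() == 13_000

    def test_empty_array_set_gives_empty_shares(self):
        shares, _ = partition_satellites(_arrays_frame([]), self._blocks())
        assert shares.empty

    def test_planted_het_eu_design_recovers_dichotomy(
        self, small_params, small_layout, one_species_satellites
    ):
        sat = one_species_satellites
        labels = {aid: fam for aid, (fam, _) in sat.family_truth.items()}
        shares, _ = partition_satellites(
            sat.arrays, small_layout.het_truth, labels=labels
        )
        by_fam = {s.name: s.compartment for s in small_params.family_specs}
        for row in shares.itertuples(index=False):
            assert row.compartment == by_fam[row.label]

    def test_density_tracks_use_thirty_kb_bins(self, small_layout,
                                               one_species_satellites):
        shares, tracks = partition_satellites(
            one_species_satellites.arrays,
            small_layout.het_truth,
            element_lengths=small_layout.element_lengths,
        )
        assert set(tracks) == set(small_layout.element_lengths)
        assert tracks["A"].size == 100  # 3 Mb / 30 kb
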