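"""Generator invariants: determinism, planted-truth consistency, rates."""

import numpy as np
import pytest

from chromarch.core import (
    CONFIGURATION_CATALOGUE,
    InvalidParameterError,
    patristic_distances,
)
from chromarch.synthdata import (
    FamilySpec,
    SimParams,
    apply_inversion,
    gen_contact_matrix,
    gen_gene_orders,
    gen_genome_layout,
    gen_satellite_dataset,
    gen_species_tree,
    expected_contacts,
    identity_order,
    simulate,
    tree_newick,
)


class TestSpeciesTree:
    def test_two_species_tree_has_depth_long_branches(self):
        tree = gen_species_tree(1, 2, 0.1)
        leaves = list(tree.leaf_node_iter())
        assert len(leaves) == 2
        for leaf in leaves:
            assert leaf.edge.length == pytest.approx(0.1)

    def test_same_seed_gives_identical_newick(self):
        assert tree_newick(gen_species_tree(1, 8, 0.3)) == tree_newick(
            gen_species_tree(1, 8, 0.3)
        )

    def test_tree_is_ultrametric_with_requested_depth(self):
        tree = gen_species_tree(3, 7, 0.25)
        for leaf in tree.leaf_node_iter():
            assert leaf.distance_from_root() == pytest.approx(0.25, abs=1e-9)

    def test_patristic_distances_bounded_by_twice_depth(self):
        tree = gen_species_tree(2, 8, 0.3)
        dists = patristic_distances(tree)
        assert max(dists.values()) <= 0.6 + 1e-9

    def test_too_few_species_rejected(self):
        with pytest.raises(InvalidParameterError):
            gen_species_tree(1, 1, 0.3)


class TestGenomeLayout:
    def test_zero_noise_bins_hit_their_means_exactly(self):
        p = SimParams(seed=1, density_noise_sd=0.0, te_density_het=0.5,
                      te_density_eu=0.05)
        lay = gen_genome_layout(p)
        for el in lay.elements:
            het = lay.het_truth[el]
            for b, frac in enumerate(lay.bin_fractions[el]):
                mid = b * p.bin_size + p.bin_size // 2
                expected = 0.5 if het.contains(mid) else 0.05
                assert frac == pytest.approx(expected)

    def test_zero_het_fraction_means_no_heterochromatin(self):
        lay = gen_genome_layout(SimParams(seed=1, het_fraction=0.0))
        assert all(not blocks.intervals for blocks in lay.het_truth.values())

    def test_het_fraction_one_rejected(self):
        with pytest.raises(InvalidParameterError):
            SimParams(seed=1, het_fraction=1.0)

    def test_realized_het_density_is_calibrated(self):
        # average realised het-bin TE fraction over seeds stays within two
        # standard errors of the target mean
        means = []
        for seed in range(20):
            p = SimParams(seed=seed)
            lay = gen_genome_layout(p)
            for el in lay.elements:
                het = lay.het_truth[el]
                vals = [
                    f
                    for b, f in enumerate(lay.bin_fractions[el])
                    if het.contains(b * p.bin_size + p.bin_size // 2)
                ]
                means.append(np.mean(vals))
        sem = 0.1 * 0.5 / np.sqrt(len(means) * 6)
        assert abs(np.mean(means) - 0.5) < 2 * sem + 0.01

    def test_metacentric_singletons_get_internal_blocks(self):
        p = SimParams(seed=2, configuration=CONFIGURATION_CATALOGUE["ananassae"])
        lay = gen_genome_layout(p)
        assert lay.het_truth["A"].flavors == ["internal"]
        assert lay.het_truth["F"].flavors == ["internal"]
        # fused pair keeps the junction heterochromatic
        assert lay.het_truth["B"].intervals[0][1] == p.element_length
        assert lay.het_truth["C"].intervals[0][0] == 0

    def test_truth_intervals_stay_inside_elements(self):
        lay = gen_genome_layout(SimParams(seed=3))
        for el, blocks in lay.het_truth.items():
            for a, b in blocks.intervals:
                assert 0 <= a < b <= lay.element_lengths[el]


class TestGeneOrders:
    def test_zero_rate_keeps_all_orders_identical(self):
        tree = gen_species_tree(1, 4, 0.2)
        orders = gen_gene_orders(1, tree, 30, 0.0)
        ref = identity_order("A", 30)
        for sp in orders.species:
            assert orders.orders[sp]["A"] == ref

    def test_single_inversion_truth_breakpoints(self):
        order = identity_order("A", 30)
        inverted = apply_inversion(order, 10, 20)
        assert [g for g, _ in inverted[:10]] == [f"Ag{i:04d}" for i in range(10)]
        assert inverted[10][0] == "Ag0019"
        assert inverted[10][1] == "-"
        assert inverted[19][0] == "Ag0010"

    def test_gene_content_is_conserved(self):
        tree = gen_species_tree(5, 4, 0.3)
        orders = gen_gene_orders(5, tree, 50, 8.0)
        ref_genes = {g for g, _ in identity_order("B", 50)}
        for sp in orders.species:
            assert {g for g, _ in orders.orders[sp]["B"]} == ref_genes

    def test_inversion_rate_matches_poisson_expectation(self):
        # recorded event counts across seeds track rate x total branch length
        rate, depth = 5.0, 0.2
        totals = []
        for seed in range(60):
            tree = gen_species_tree(seed, 4, depth)
            total_blen = sum(
                e.length for e in tree.preorder_edge_iter() if e.length
            )
            orders = gen_gene_orders(seed, tree, 100, rate)
            totals.append(len(orders.events) / total_blen)
        assert abs(np.mean(totals) - rate) / rate < 0.15

    def test_non_overlapping_truth_counts_two_per_inversion(self):
        tree = gen_species_tree(7, 5, 0.25)
        orders = gen_gene_orders(7, tree, 100, 30.0, non_overlapping=True)
        assert orders.events and orders.breakpoint_truth is not None
        # each inversion on the path between two species contributes
        # exactly two breakpoints, so per-pair totals are even and match
        # the recorded event count on the connecting path
        events_by_edge: dict[str, list] = {}
        for edge, el, s, e in orders.events:
            events_by_edge.setdefault(edge, []).append((el, s, e))
        total = 0
        for pair, per_el in orders.breakpoint_truth.items():
            n_bp = sum(len(v) for v in per_el.values())
            assert n_bp % 2 == 0
            total += n_bp
        assert total > 0


class TestSatellites:
    def test_zero_divergence_consensuses_equal_ancestor(self, small_layout):
        p = SimParams(seed=4, divergence=0.0, revcomp_fraction=0.0)
        sat = gen_satellite_dataset(p, small_layout, species=["S01"])
        for row in sat.arrays.itertuples(index=False):
            fam, strand = sat.family_truth[row.array_id]
            assert strand == "+"
            assert row.consensus == sat.ancestral_monomers[fam]

    def test_revcomp_fraction_splits_strands_binomially(self, small_layout):
        p = SimParams(seed=5, revcomp_fraction=0.5)
        sat = gen_satellite_dataset(p, small_layout, species=["S01"])
        strands = [s for _, s in sat.family_truth.values()]
        n_minus = strands.count("-")
        n = len(strands)
        assert abs(n_minus - n / 2) < 2 * np.sqrt(n * 0.25) + 1

    def test_consensus_divergence_matches_rate(self, small_layout):
        p = SimParams(
            seed=6,
            divergence=0.05,
            revcomp_fraction=0.0,
            family_specs=(FamilySpec("FamX", 170, 20, "het"),),
        )
        sat = gen_satellite_dataset(p, small_layout, species=["S01"])
        anc = sat.ancestral_monomers["FamX"]
        hams = [
            sum(a != b for a, b in zip(row.consensus, anc))
            for row in sat.arrays.itertuples(index=False)
        ]
        expected = 0.05 * 170
        sd = np.sqrt(170 * 0.05 * 0.95)
        assert abs(np.mean(hams) - expected) < 2 * sd

    def test_array_count_and_compartment_placement(self, small_params,
                                                   small_layout,
                                                   one_species_satellites):
        sat = one_species_satellites
        expected_n = sum(s.n_arrays for s in small_params.family_specs)
        assert len(sat.arrays) == expected_n
        by_fam = {s.name: s.compartment for s in small_params.family_specs}
        for row in sat.arrays.itertuples(index=False):
            fam, _ = sat.family_truth[row.array_id]
            mid = (row.start + row.end) // 2
            inside = small_layout.het_truth[row.element].contains(mid)
            assert inside == (by_fam[fam] == "het")


class TestContacts:
    def test_no_signal_case_has_uniform_inter_element_rates(self, small_layout):
        p = SimParams(seed=1, fusion_boost=1.0, compartment_corr=0.0)
        E, bins = expected_contacts(
            p, small_layout, p.configuration, small_layout.compartment_labels
        )
        el = bins["element"].to_numpy()
        inter = E[np.ix_(el == "A", el == "B")]
        assert np.allclose(inter, p.contact_background)
        inter2 = E[np.ix_(el == "B", el == "C")]  # fused pair, boost=1
        assert np.allclose(inter2, p.contact_background)

    def test_zero_rate_gives_zero_matrix(self, small_layout):
        p = SimParams(seed=1, contact_scale=0.0, contact_background=0.0)
        cm = gen_contact_matrix(p, small_layout)
        assert not cm.counts.any()

    def test_matrix_is_symmetric_and_deterministic(self, small_layout):
        p = SimParams(seed=9)
        cm1 = gen_contact_matrix(p, small_layout)
        cm2 = gen_contact_matrix(p, small_layout)
        assert np.array_equal(cm1.counts, cm2.counts)
        assert np.array_equal(cm1.counts, cm1.counts.T)


def test_full_simulation_is_deterministic():
    a = simulate(SimParams(seed=11, n_species=3))
    b = simulate(SimParams(seed=11, n_species=3))
    assert tree_newick(a.tree) == tree_newick(b.tree)
    assert a.satellites.arrays.equals(b.satellites.arrays)
    assert np.array_equal(a.contacts.counts, b.contacts.counts)
    assert a.orders.orders == b.orders.orders
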