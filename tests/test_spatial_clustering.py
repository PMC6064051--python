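"""Proximity clustering: pair p-values, single-link components, centroid
selection, radius focusing with recursion, and label propagation — all
cross-checked against an exhaustive reference implementation."""

import numpy as np
import pytest
from oracles import reference_cluster

from druggability.spatial_clustering import (
    LABEL_KNOWN_RESISTANT,
    LABEL_KNOWN_SENSITIVE,
    ProximalPair,
    choose_centroid,
    cluster_structure,
    distance_set_from_coordinates,
    focus_and_recurse,
    pair_pvalue,
    propagate_labels,
    putative_residue_sets,
    significant_pairs,
    single_link_cluster,
)
from druggability.synthetic import SimulationConfig, simulate_structure

import networkx as nx


def line_distance_set(positions):
    """Residues on a line, one per integer id, positions in Angstroms."""
    coords = {i + 1: np.array([p, 0.0, 0.0]) for i, p in enumerate(positions)}
    return distance_set_from_coordinates("S", "G", coords)


class TestPairPvalue:
    def test_four_point_line_brute_force(self):
        dset = line_distance_set([0, 3, 10, 20])
        # pairwise distances: 3,10,20,7,17,10 -> exactly one is <= 3
        assert pair_pvalue(3.0, dset.background) == pytest.approx(1 / 6)

    def test_minimum_element(self):
        dset = line_distance_set([0, 3, 10, 20])
        assert pair_pvalue(min(dset.background), dset.background) == pytest.approx(1 / 6)

    def test_maximum_gives_one(self):
        dset = line_distance_set([0, 3, 10, 20])
        assert pair_pvalue(max(dset.background), dset.background) == 1.0

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            pair_pvalue(1.0, np.array([]))


class TestSignificantPairs:
    def _dset(self):
        # two residues 4.2 apart plus many decoys far away shape the background
        positions = [0, 4.2] + [100 + 20 * i for i in range(48)]
        return line_distance_set(positions)

    def test_both_thresholds_met_retained(self):
        dset = self._dset()
        pairs = significant_pairs([1, 2], dset)
        assert [p.residues for p in pairs] == [(1, 2)]
        assert pairs[0].distance == pytest.approx(4.2)
        assert pairs[0].p_value < 0.05

    def test_insignificant_p_dropped(self):
        # only 4 residues: the 4.2 A pair has p = 1/6 > 0.05
        dset = line_distance_set([0, 4.2, 100, 200])
        assert significant_pairs([1, 2], dset) == []

    def test_distance_limit_strict(self):
        positions = [0, 6.0] + [100 + 20 * i for i in range(48)]
        dset = line_distance_set(positions)
        assert significant_pairs([1, 2], dset) == []


class TestSingleLink:
    def _pair(self, a, b, d=1.0):
        return ProximalPair((a, b), d, 0.01)

    def test_transitive_chain_is_one_cluster(self):
        assert single_link_cluster([self._pair(1, 2), self._pair(2, 3)]) == [{1, 2, 3}]

    def test_disjoint_pairs_two_clusters(self):
        comps = single_link_cluster([self._pair(1, 2), self._pair(3, 4)])
        assert sorted(map(sorted, comps)) == [[1, 2], [3, 4]]

    def test_no_pairs_no_clusters(self):
        assert single_link_cluster([]) == []


class TestCentroid:
    def test_most_recurrent_member_wins(self):
        g = nx.Graph([(600, 601, {"weight": 2.0}), (601, 596, {"weight": 2.0})])
        rec = {600: 40, 601: 2, 596: 1}
        assert choose_centroid({600, 601, 596}, rec, g) == 600

    def test_tie_broken_by_recurrence_weighted_path_sums(self):
        # a - b - c chain, all recurrence equal: b is graph-central
        g = nx.Graph([(1, 2, {"weight": 4.0}), (2, 3, {"weight": 4.0})])
        rec = {1: 2, 2: 2, 3: 2}
        # exhaustive weighted sums: 1 -> 2*4 + 2*8 = 24; 2 -> 16; 3 -> 24
        assert choose_centroid({1, 2, 3}, rec, g) == 2

    def test_singleton_is_its_own_centroid(self):
        g = nx.Graph()
        g.add_node(9)
        assert choose_centroid({9}, {9: 1}, g) == 9


class TestFocusAndRecurse:
    def test_three_node_chain_discards_unreachable_singleton(self):
        pairs = [ProximalPair((1, 2), 4.0, 0.01), ProximalPair((2, 3), 4.0, 0.01)]
        rec = {1: 10, 2: 1, 3: 1}  # centroid is residue 1
        out = focus_and_recurse({1, 2, 3}, pairs, rec)
        assert len(out) == 1
        members, centroid, gen, _g = out[0]
        assert members == {1, 2} and centroid == 1 and gen == 0

    def test_everything_within_radius_single_cluster(self):
        pairs = [ProximalPair((1, 2), 2.0, 0.01), ProximalPair((2, 3), 2.0, 0.01)]
        out = focus_and_recurse({1, 2, 3}, pairs, {1: 5, 2: 1, 3: 1})
        assert len(out) == 1 and out[0][0] == {1, 2, 3}

    def test_two_hotspots_bridged_yield_two_clusters_after_recursion(self):
        pairs = [
            ProximalPair((1, 2), 1.0, 0.01),
            ProximalPair((2, 3), 1.0, 0.01),
            ProximalPair((3, 4), 4.5, 0.02),  # bridge
            ProximalPair((4, 5), 1.0, 0.01),
            ProximalPair((5, 6), 1.0, 0.01),
        ]
        rec = {1: 10, 2: 1, 3: 1, 4: 1, 5: 1, 6: 1}
        out = focus_and_recurse({1, 2, 3, 4, 5, 6}, pairs, rec)
        assert [(m, g) for m, _c, g, _ in out] == [({1, 2, 3}, 0), ({4, 5, 6}, 1)]

    def test_shrinking_radius_never_grows_a_cluster(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            coords = {i: rng.uniform(0, 15, 3) for i in range(1, 11)}
            dset = distance_set_from_coordinates("S", "G", coords)
            rec = {i: int(rng.integers(1, 5)) for i in coords}
            wide = cluster_structure(dset, list(coords), rec, radius_limit=5.0)
            narrow = cluster_structure(dset, list(coords), rec, radius_limit=2.5)
            wide_sizes = {c.centroid: len(c.members) for c in wide if c.generation == 0}
            for c in narrow:
                if c.generation == 0 and c.centroid in wide_sizes:
                    assert len(c.members) <= wide_sizes[c.centroid]


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(15))
    def test_random_structures_match_reference(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 16))
        coords = {i: rng.uniform(0, 12, size=3) for i in range(1, n + 1)}
        dset = distance_set_from_coordinates("S", "G", coords)
        rec = {i: int(rng.integers(1, 6)) for i in coords}
        got = {
            (frozenset(c.members), c.centroid, c.generation)
            for c in cluster_structure(dset, list(coords), rec)
        }
        expected = {
            (m, c, g) for m, c, g in reference_cluster(dset.distances, list(coords), rec)
        }
        assert got == expected

    def test_final_clusters_partition_and_are_connected(self):
        rng = np.random.default_rng(99)
        coords = {i: rng.uniform(0, 10, size=3) for i in range(1, 13)}
        dset = distance_set_from_coordinates("S", "G", coords)
        clusters = cluster_structure(dset, list(coords), {i: 1 for i in coords})
        seen: set[int] = set()
        for c in clusters:
            assert not (set(c.members) & seen)
            seen |= set(c.members)
            if len(c.members) >= 2:
                assert nx.is_connected(c.graph)


class TestPlantedHotspots:
    def test_hotspot_recovered_as_single_cluster(self):
        config = SimulationConfig(seed=3)
        s = simulate_structure("BRAF", config)
        dset = distance_set_from_coordinates(s.structure_id, s.gene, s.coordinates)
        hotspot = set(s.hotspots[0])
        clusters = cluster_structure(dset, sorted(hotspot), {r: 1 for r in hotspot})
        assert len(clusters) == 1
        assert set(clusters[0].members) == hotspot

    def test_two_distant_hotspots_form_two_clusters(self):
        config = SimulationConfig(seed=4)
        config.structures = {"GX": {"hotspots": [[10, 11, 12], [50, 51, 52]], "far_mutated": [], "n_decoys": 40}}
        s = simulate_structure("GX", config)
        dset = distance_set_from_coordinates(s.structure_id, s.gene, s.coordinates)
        mutated = sorted(s.hotspots[0] + s.hotspots[1])
        clusters = cluster_structure(dset, mutated, {r: 1 for r in mutated})
        member_sets = sorted(sorted(c.members) for c in clusters)
        assert member_sets == [[10, 11, 12], [50, 51, 52]]


class TestLabelPropagation:
    def _clusters(self, labels_by_cluster):
        clusters = []
        for i, labels in enumerate(labels_by_cluster):
            members = sorted(labels)
            clusters.append(
                type(
                    "C",
                    (),
                    {
                        "cluster_id": f"c{i}",
                        "gene": "G",
                        "structure_id": "S",
                        "members": members,
                        "centroid": members[0],
                        "generation": 0,
                        "labels": labels,
                        "recurrence": {m: 1 for m in members},
                        "graph": nx.Graph(),
                    },
                )()
            )
        return clusters

    def test_sensitive_cluster_marks_uncatalogued_members_putative_sensitive(self):
        clusters = self._clusters(
            [{600: LABEL_KNOWN_SENSITIVE, 601: "putative", 604: "putative"}]
        )
        table = propagate_labels(clusters)
        putative = table[table.putative_call == "putative_sensitive"].residue.tolist()
        assert putative == [601, 604]

    def test_resistant_cluster_without_overlap_yields_putative_resistant(self):
        clusters = self._clusters(
            [
                {600: LABEL_KNOWN_SENSITIVE, 601: "putative"},
                {29: LABEL_KNOWN_RESISTANT, 18: "putative"},
            ]
        )
        table = propagate_labels(clusters)
        assert table[table.residue == 18].putative_call.iloc[0] == "putative_resistant"
        sens, res = putative_residue_sets(clusters)
        assert ("G", 18) in res and ("G", 29) in res
        assert ("G", 601) in sens

    def test_resistant_cluster_overlapping_sensitive_is_suppressed(self):
        clusters = self._clusters(
            [
                {600: LABEL_KNOWN_SENSITIVE, 601: "putative"},
                {29: LABEL_KNOWN_RESISTANT, 601: "putative"},
            ]
        )
        table = propagate_labels(clusters)
        resistant_calls = table[table.putative_call == "putative_resistant"]
        assert resistant_calls.empty

    def test_cluster_without_known_member_yields_no_calls(self):
        table = propagate_labels(self._clusters([{1: "putative", 2: "putative"}]))
        assert (table.putative_call == "").all()


def test_pdb_route_matches_min_atomic_distance(tmp_path):
    """A structure written with Bio.PDB round-trips through the PDB reader
    with residue distances equal to the minimum inter-atomic distance."""
    from Bio.PDB import StructureBuilder, PDBIO

    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("X")
    builder.init_model(0)
    builder.init_chain("A")
    builder.init_seg(" ")
    atoms = {
        1: [("CA", (0, 0, 0)), ("CB", (1.0, 0, 0))],
        2: [("CA", (4.0, 0, 0))],
        3: [("CA", (10.0, 0, 0))],
    }
    for res_id, res_atoms in atoms.items():
        builder.init_residue("ALA", " ", res_id, " ")
        for name, coord in res_atoms:
            builder.set_line_counter(res_id)
            builder.init_atom(name, np.array(coord, dtype=float), 0.0, 1.0, " ", name, element="C")
    path = tmp_path / "toy.pdb"
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))

    from druggability.spatial_clustering import distance_set_from_pdb

    dset = distance_set_from_pdb(path, "G", chain_id="A")
    assert dset.distance(1, 2) == pytest.approx(3.0)  # CB at x=1 is closest
    assert dset.distance(2, 3) == pytest.approx(6.0)
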