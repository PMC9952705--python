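"""Tests of the condensate-structure observables on hand-built states."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crowdpd.builder import SOLVENT_ID, State
from crowdpd.analysis import (
    contact_graph,
    find_junctions,
    idp_ids,
    junction_separation,
    len_sample,
    network_stats,
    sample_observables,
)
from crowdpd.model import BEAD_INDEX

E = BEAD_INDEX["E"]
B = BEAD_INDEX["B"]
W = BEAD_INDEX["W"]
P = BEAD_INDEX["P"]


def make_state(positions, types, mol_ids, box=(20.0, 20.0, 20.0)):
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    return State(
        positions=positions,
        velocities=np.zeros((n, 3)),
        bead_types=np.asarray(types, dtype=np.int64),
        molecule_ids=np.asarray(mol_ids, dtype=np.int64),
        bonds=np.empty((0, 2), np.int64),
        angles=np.empty((0, 3), np.int64),
        box=np.asarray(box, dtype=float),
    )


def dimer_pair_state(gap):
    """Two 2-bead sticky dimers whose nearest sticky beads sit ``gap`` apart."""
    pos = [[1, 1, 1], [1.5, 1, 1], [1.5 + gap, 1, 1], [2.0 + gap, 1, 1]]
    return make_state(pos, [E, E, E, E], [0, 0, 1, 1])


def random_sticky_state(rng, n_molecules, beads_per_mol=3, box=12.0):
    pos = rng.random((n_molecules * beads_per_mol, 3)) * box
    types = np.tile([E] * beads_per_mol, n_molecules)
    mids = np.repeat(np.arange(n_molecules), beads_per_mol)
    return make_state(pos, types, mids, box=(box, box, box))


def brute_force_contact_edges(state, cutoff):
    """O(n^2 m^2) enumeration over sticky-bead pairs of distinct molecules."""
    sticky = [
        (i, state.molecule_ids[i])
        for i in range(state.n_beads)
        if state.bead_types[i] in (BEAD_INDEX["E"], BEAD_INDEX["F"])
        and state.molecule_ids[i] != SOLVENT_ID
    ]
    box = state.box
    edges = set()
    for (i, mi), (j, mj) in itertools.combinations(sticky, 2):
        if mi == mj:
            continue
        d = state.positions[i] - state.positions[j]
        d -= box * np.rint(d / box)
        if np.linalg.norm(d) < cutoff:
            edges.add(frozenset((int(mi), int(mj))))
    return edges


class TestContactGraph:
    def test_out_of_range_stickers_make_no_edge(self):
        g = contact_graph(dimer_pair_state(1.5), cutoff=1.0)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 2

    def test_coincident_stickers_make_one_edge(self):
        g = contact_graph(dimer_pair_state(0.0), cutoff=1.0)
        assert set(g.edges) == {(0, 1)}

    def test_crowders_and_solvent_excluded(self):
        pos = [[1, 1, 1], [1.2, 1, 1], [1.4, 1, 1], [1.6, 1, 1]]
        state = make_state(pos, [E, W, P, E], [0, SOLVENT_ID, 1, 2])
        g = contact_graph(state, cutoff=1.0)
        assert set(g.nodes) == {0, 2}

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(5):
            state = random_sticky_state(rng, n_molecules=10)
            g = contact_graph(state, cutoff=1.0)
            assert {frozenset(e) for e in g.edges} == brute_force_contact_edges(
                state, 1.0
            )

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            contact_graph(dimer_pair_state(0.5), cutoff=0.0)


class TestLenSample:
    def test_dispersed_gives_singleton(self):
        g = nx.Graph()
        g.add_nodes_from([0, 1, 2])
        assert len(len_sample(g)) == 1

    def test_chain_component(self):
        g = nx.Graph([("A", "B"), ("B", "C")])
        g.add_node("D")
        assert len_sample(g) == {"A", "B", "C"}

    def test_tie_break_is_lowest_id(self):
        g = nx.Graph([(5, 6), (1, 2)])
        assert len_sample(g) == {1, 2}

    def test_matches_exhaustive_component_search(self, rng):
        for _ in range(10):
            n = 12
            g = nx.gnp_random_graph(n, 0.2, seed=int(rng.integers(1 << 30)))
            expected = max(
                (sorted(c) for c in nx.connected_components(g)),
                key=lambda c: (len(c), -min(c)),
            )
            assert len_sample(g) == set(expected)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            len_sample(nx.Graph())


class TestJunctions:
    def test_no_intermolecular_contact_no_junction(self):
        assert find_junctions(dimer_pair_state(1.5), cutoff=1.0) == []

    def test_two_overlapping_endcaps_form_mass_two_junction(self):
        [junction] = find_junctions(dimer_pair_state(0.2), cutoff=1.0)
        assert junction.mass == 2
        assert junction.molecule_ids == frozenset({0, 1})

    def test_five_molecule_star(self):
        # five dimers, one endcap of each packed around one point
        hub = np.array([5.0, 5.0, 5.0])
        pos, types, mids = [], [], []
        for m in range(5):
            jitter = 0.1 * np.array([np.cos(m), np.sin(m), 0.0])
            pos.append(hub + jitter)
            # far endcaps fan out in distinct directions, away from each other
            pos.append(hub + 4.0 * np.array([np.cos(2 * m), np.sin(2 * m), 1.0]))
            types += [E, E]
            mids += [m, m]
        state = make_state(pos, types, mids)
        junctions = find_junctions(state, cutoff=1.0)
        assert len(junctions) == 1
        assert junctions[0].mass == 5

    def test_single_linkage_matches_brute_force(self, rng):
        for _ in range(5):
            state = random_sticky_state(rng, n_molecules=8)
            junctions = find_junctions(state, cutoff=1.0)
            # brute-force single linkage over sticky beads
            n = state.n_beads
            g = nx.Graph()
            g.add_nodes_from(range(n))
            for i, j in itertools.combinations(range(n), 2):
                d = state.positions[i] - state.positions[j]
                d -= state.box * np.rint(d / state.box)
                if np.linalg.norm(d) < 1.0:
                    g.add_edge(i, j)
            expected = sorted(
                tuple(sorted(c))
                for c in nx.connected_components(g)
                if len({int(state.molecule_ids[b]) for b in c}) >= 2
            )
            assert sorted(j.bead_indices for j in junctions) == expected

    def test_centroid_respects_periodic_wrap(self):
        # cluster straddling the boundary: beads at x = 0.1 and x = 19.9
        pos = [[0.1, 5, 5], [19.9, 5, 5]]
        state = make_state(pos, [E, E], [0, 1])
        [junction] = find_junctions(state, cutoff=1.0)
        x = junction.center[0]
        assert min(x, 20.0 - x) < 0.2  # near the seam, not at x = 10


class TestJunctionSeparation:
    def two_junction_state(self, x2=4.0):
        # molecule 0 bridges both junctions; molecules 1 and 2 anchor them
        pos = [[1.0, 1, 1], [x2, 1, 1], [1.0, 1.2, 1], [x2, 1.2, 1]]
        return make_state(pos, [E, E, E, E], [0, 0, 1, 2], box=(48.0, 48, 48))

    def test_bridged_pair_distance(self):
        state = self.two_junction_state(4.0)
        junctions = find_junctions(state, cutoff=1.0)
        assert len(junctions) == 2
        mean, sd = junction_separation(junctions, state)
        assert mean == pytest.approx(3.0, abs=1e-6)

    def test_minimum_image_distance(self):
        pos = [[1.0, 1, 1], [47.0, 1, 1], [1.0, 1.2, 1], [47.0, 1.2, 1]]
        state = make_state(pos, [E, E, E, E], [0, 0, 1, 2], box=(48.0, 48, 48))
        junctions = find_junctions(state, cutoff=1.0)
        mean, _ = junction_separation(junctions, state)
        assert mean == pytest.approx(2.0, abs=1e-6)

    def test_undefined_without_two_junctions(self):
        state = dimer_pair_state(0.2)
        junctions = find_junctions(state, cutoff=1.0)
        mean, sd = junction_separation(junctions, state)
        assert np.isnan(mean) and np.isnan(sd)

    def test_unbridged_junctions_are_undefined(self):
        # two junctions with no molecule in common
        pos = [[1.0, 1, 1], [1.0, 1.2, 1], [9.0, 1, 1], [9.0, 1.2, 1]]
        state = make_state(pos, [E, E, E, E], [0, 1, 2, 3])
        junctions = find_junctions(state, cutoff=1.0)
        assert len(junctions) == 2
        mean, _ = junction_separation(junctions, state)
        assert np.isnan(mean)

    def test_matches_brute_force_over_bridged_pairs(self, rng):
        state = random_sticky_state(rng, n_molecules=12, beads_per_mol=4, box=10.0)
        junctions = find_junctions(state, cutoff=1.0)
        mean, _ = junction_separation(junctions, state)
        dists = []
        for a, b in itertools.combinations(junctions, 2):
            if a.molecule_ids & b.molecule_ids:
                d = np.asarray(a.center) - np.asarray(b.center)
                d -= state.box * np.rint(d / state.box)
                dists.append(np.linalg.norm(d))
        if dists:
            assert mean == pytest.approx(np.mean(dists))
        else:
            assert np.isnan(mean)


class TestNetworkStats:
    class FakeSample:
        def __init__(self, state, phase):
            self.state = state
            self.phase = phase

    def test_repeated_sample_has_zero_sd(self):
        state = dimer_pair_state(0.2)
        samples = [self.FakeSample(state, "production")] * 3
        stats = network_stats(samples)
        assert stats.len_mean == 2.0 and stats.len_sd == 0.0
        assert stats.n_samples == 3

    def test_mean_of_two_len_values(self):
        s_bound = dimer_pair_state(0.2)  # LEN 2
        s_free = dimer_pair_state(3.0)  # LEN 1
        samples = [
            self.FakeSample(s_bound, "production"),
            self.FakeSample(s_free, "production"),
        ]
        stats = network_stats(samples)
        assert stats.len_mean == pytest.approx(1.5)
        assert stats.dense_fraction_mean == pytest.approx(0.75)

    def test_equilibration_samples_excluded(self):
        s_bound = dimer_pair_state(0.2)
        s_free = dimer_pair_state(3.0)
        samples = [
            self.FakeSample(s_free, "equilibration"),
            self.FakeSample(s_bound, "production"),
        ]
        stats = network_stats(samples)
        assert stats.len_mean == 2.0 and stats.n_samples == 1

    def test_no_production_samples_rejected(self):
        with pytest.raises(ValueError):
            network_stats([self.FakeSample(dimer_pair_state(0.2), "equilibration")])

    def test_planted_cluster_trajectory_recovered(self, rng):
        # plant k-molecule clusters; LEN must equal the planted size exactly
        for k in (2, 4, 6):
            hub = np.array([3.0, 3.0, 3.0])
            pos, types, mids = [], [], []
            for m in range(k):
                pos.append(hub + 0.05 * rng.normal(size=3))
                types.append(E)
                mids.append(m)
            for m in range(k, 9):  # isolated molecules well apart
                pos.append([10.0 + 2 * (m - k), 15.0, 15.0])
                types.append(E)
                mids.append(m)
            state = make_state(pos, types, mids, box=(30.0, 30, 30))
            obs = sample_observables(state)
            assert obs["len_size"] == k
            assert obs["n_idps"] == 9


class TestPeriodicInvariance:
    @given(st.floats(min_value=0.0, max_value=19.0))
    @settings(max_examples=15, derandomize=True, deadline=None)
    def test_global_translation_leaves_observables_unchanged(self, shift):
        rng = np.random.default_rng(5)
        state = random_sticky_state(rng, n_molecules=8, box=20.0)
        obs0 = sample_observables(state)
        moved = make_state(
            (state.positions + shift) % 20.0,
            state.bead_types,
            state.molecule_ids,
            box=(20.0, 20.0, 20.0),
        )
        obs1 = sample_observables(moved)
        assert obs1["len_size"] == obs0["len_size"]
        assert obs1["n_junctions"] == obs0["n_junctions"]
        if np.isnan(obs0["junction_separation"]):
            assert np.isnan(obs1["junction_separation"])
        else:
            assert obs1["junction_separation"] == pytest.approx(
                obs0["junction_separation"], abs=1e-8
            )

    def test_dense_fraction_monotone_under_added_edges(self):
        g = nx.Graph()
        g.add_nodes_from(range(6))
        sizes = [len(len_sample(g))]
        for e in [(0, 1), (2, 3), (1, 2), (4, 5), (3, 4)]:
            g.add_edge(*e)
            sizes.append(len(len_sample(g)))
        assert all(b >= a for a, b in zip(sizes, sizes[1:]))


def test_idp_identification(small_mixed_state):
    _, state = small_mixed_state
    ids = idp_ids(state)
    assert len(ids) == 4  # the IDPs, not the 3 crowders
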