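"""Created/destroyed bond deltas and pH-sensitive patch clustering."""

import networkx as nx
import numpy as np
import pytest

from phdelta import (
    FixtureSpec, GeometryParams, assign_model_pkas, assign_states,
    build_patch_graph, detect_all, find_patches, interaction_delta,
    make_motif, shifting_residues,
)

import oracles
from conftest import random_model


def bond_sets(motif, ph_ref, ph_int, **kwargs):
    model, pkas = make_motif(FixtureSpec(motif, **kwargs))
    set_ref = detect_all(model, assign_states(pkas, ph_ref))
    set_int = detect_all(model, assign_states(pkas, ph_int))
    return model, pkas, set_ref, set_int


class TestInteractionDelta:
    def test_identical_sets_give_empty_delta(self):
        _, _, set_ref, set_int = bond_sets("salt_bridge_pair", 7.0, 7.0,
                                           distance=3.0)
        delta = interaction_delta(set_ref, set_int)
        assert delta.created == () and delta.destroyed == ()

    def test_acidification_destroys_the_salt_bridge(self):
        # reference pH 7 (bridge intact) -> pH of interest 2 (Glu neutral)
        _, _, set_ref, set_int = bond_sets("salt_bridge_pair", 7.0, 2.0,
                                           distance=3.0)
        delta = interaction_delta(set_ref, set_int)
        destroyed_kinds = [r.kind for r in delta.destroyed]
        assert "salt_bridge" in destroyed_kinds
        assert all(r.kind != "salt_bridge" for r in delta.created)

    def test_swap_antisymmetry(self):
        _, _, set_ref, set_int = bond_sets("ring_stack", 7.5, 5.5, distance=4.5)
        fwd = interaction_delta(set_ref, set_int)
        rev = interaction_delta(set_int, set_ref)
        assert fwd.created == rev.destroyed and fwd.destroyed == rev.created

    def test_his_recategorization_reports_one_destroyed_one_created(self):
        # one His pinned protonatable, partner pinned neutral: pi-pi at 7.5
        # becomes cation-pi at 5.5 -> one destroyed + one created record
        model, pkas = make_motif(FixtureSpec("ring_stack", distance=4.5,
                                             pka_overrides={10: 4.0}))
        set_ref = detect_all(model, assign_states(pkas, 7.5))
        set_int = detect_all(model, assign_states(pkas, 5.5))
        delta = interaction_delta(set_ref, set_int)
        assert [r.kind for r in delta.destroyed if r.kind == "pi_pi"] == ["pi_pi"]
        assert [r.kind for r in delta.created if r.kind == "cation_pi"] == ["cation_pi"]

    def test_mismatched_geometry_params_rejected(self):
        model, pkas = make_motif(FixtureSpec("salt_bridge_pair", distance=3.0))
        a = detect_all(model, assign_states(pkas, 7.0))
        b = detect_all(model, assign_states(pkas, 2.0),
                       GeometryParams(salt_bridge_max_dist=5.0))
        with pytest.raises(ValueError):
            interaction_delta(a, b)

    def test_changed_records_involve_shifting_residues(self):
        model, pkas, set_ref, set_int = None, None, None, None
        rng = np.random.default_rng(5)
        model = random_model(rng, 10)
        pkas = assign_model_pkas(model)
        set_ref = detect_all(model, assign_states(pkas, 7.5))
        set_int = detect_all(model, assign_states(pkas, 3.5))
        delta = interaction_delta(set_ref, set_int)
        shift_res = {k.residue for k in
                     shifting_residues(pkas, 7.5, 3.5).keys()}
        for rec in delta.created + delta.destroyed:
            assert rec.state_dependent or \
                rec.key_a in shift_res or rec.key_b in shift_res


class TestPatchGraph:
    def test_edge_within_radius(self):
        model, pkas = make_motif(FixtureSpec("shifting_cluster", distance=5.0,
                                             n_members=2))
        shift = shifting_residues(pkas, 5.5, 7.5)
        graph = build_patch_graph(model, shift, radius=8.0)
        assert graph.number_of_edges() == 1

    def test_no_edge_beyond_radius(self):
        model, pkas = make_motif(FixtureSpec("shifting_cluster", distance=5.0,
                                             n_members=2))
        shift = shifting_residues(pkas, 5.5, 7.5)
        graph = build_patch_graph(model, shift, radius=2.0)
        assert graph.number_of_edges() == 0
        assert graph.number_of_nodes() == 2  # nodes stay, only edges vanish

    def test_empty_shift_report_gives_empty_graph(self):
        model, pkas = make_motif(FixtureSpec("shifting_cluster", distance=5.0))
        shift = shifting_residues(pkas, 8.0, 9.0)  # His pKa 6.5 outside (8,9]
        graph = build_patch_graph(model, shift, radius=8.0)
        assert graph.number_of_nodes() == 0

    @pytest.mark.parametrize("mode", ["side_chain", "any_atom", "centroid"])
    @pytest.mark.parametrize("seed", [1, 9, 23])
    def test_adjacency_matches_naive_thresholding(self, seed, mode):
        rng = np.random.default_rng(seed)
        model = random_model(rng, 10, box=18.0)
        pkas = assign_model_pkas(model)
        shift = shifting_residues(pkas, 3.5, 11.5)  # most side chains titrate
        radius = float(rng.uniform(4.0, 10.0))
        graph = build_patch_graph(model, shift, radius, mode)
        residues = [model.residue(k) for k in graph.nodes]
        edges, _ = oracles.patch_components(residues, radius, 2, mode)
        got = {frozenset(e) for e in graph.edges}
        assert got == {e for e in edges if len(e) == 2}

    def test_radius_monotonicity(self):
        rng = np.random.default_rng(13)
        model = random_model(rng, 9, box=16.0)
        pkas = assign_model_pkas(model)
        shift = shifting_residues(pkas, 3.5, 11.5)
        small = build_patch_graph(model, shift, 5.0)
        large = build_patch_graph(model, shift, 9.0)
        assert set(small.edges) <= set(large.edges)


class TestFindPatches:
    def path_graph(self, *nodes):
        g = nx.Graph()
        nx.add_path(g, nodes)
        return g

    def test_path_of_three_is_one_patch(self):
        model, pkas = make_motif(FixtureSpec("shifting_cluster", distance=6.0))
        shift = shifting_residues(pkas, 5.5, 7.5)
        graph = build_patch_graph(model, shift, 8.0)
        result = find_patches(graph, model, 8.0, min_size=3)
        assert len(result.patches) == 1 and result.patches[0].size == 3

    def test_components_below_min_size_reported_separately(self):
        model, pkas = make_motif(FixtureSpec("shifting_cluster", distance=6.0,
                                             n_members=2))
        shift = shifting_residues(pkas, 5.5, 7.5)
        graph = build_patch_graph(model, shift, 8.0)
        result = find_patches(graph, model, 8.0, min_size=3)
        assert result.patches == ()
        assert len(result.near_patch) == 1 and len(result.near_patch[0]) == 2

    def test_min_size_below_two_rejected(self):
        with pytest.raises(ValueError):
            find_patches(nx.Graph(), None, 8.0, min_size=1)

    def test_patch_members_all_shifting(self):
        model, pkas = make_motif(FixtureSpec("shifting_cluster", distance=6.0))
        shift = shifting_residues(pkas, 5.5, 7.5)
        graph = build_patch_graph(model, shift, 8.0)
        result = find_patches(graph, model, 8.0, 3)
        shifting_keys = set(shift.side_chain_keys())
        for patch in result.patches:
            assert set(patch.members) <= shifting_keys

    @pytest.mark.parametrize("seed", [2, 8, 21])
    def test_components_match_bfs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        model = random_model(rng, 12, box=20.0)
        pkas = assign_model_pkas(model)
        shift = shifting_residues(pkas, 3.5, 11.5)
        radius = float(rng.uniform(5.0, 9.0))
        graph = build_patch_graph(model, shift, radius)
        result = find_patches(graph, model, radius, min_size=3)
        residues = [model.residue(k) for k in graph.nodes]
        _, expected = oracles.patch_components(residues, radius, 3)
        assert [p.members for p in result.patches] == expected
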