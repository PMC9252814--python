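"""Interaction detectors: constructed geometries and brute-force oracles."""

import pytest

from phdelta import (
    FixtureSpec, GeometryParams, assign_model_pkas, assign_states, detect_all,
    detect_aromatic, detect_hydrogen_bonds, detect_salt_bridges, make_motif,
)

import oracles


def motif(name, distance, **kwargs):
    return make_motif(FixtureSpec(name, distance=distance, **kwargs))


class TestSaltBridges:
    def test_charged_pair_at_3A_forms_one_bridge(self):
        model, pkas = motif("salt_bridge_pair", 3.0)
        records = detect_salt_bridges(model, assign_states(pkas, 7.0))
        assert len(records) == 1
        rec = records[0]
        assert rec.kind == "salt_bridge" and rec.distance == pytest.approx(3.0, abs=0.01)

    def test_protonated_glu_breaks_the_bridge(self):
        model, pkas = motif("salt_bridge_pair", 3.0)
        # pH 2 < Glu pKa 4.5: carboxyl is neutral -> no charge pair
        assert detect_salt_bridges(model, assign_states(pkas, 2.0)) == []

    def test_distance_beyond_cutoff_rejected(self):
        model, pkas = motif("salt_bridge_pair", 4.5)
        assert detect_salt_bridges(model, assign_states(pkas, 7.0)) == []

    def test_cutoff_is_configurable(self):
        model, pkas = motif("salt_bridge_pair", 4.5)
        params = GeometryParams(salt_bridge_max_dist=5.0)
        assert len(detect_salt_bridges(model, assign_states(pkas, 7.0), params)) == 1

    def test_neutralizing_a_group_never_creates_a_bridge(self):
        """State monotonicity: bridges at low pH are a subset of high-pH
        bridges whenever only acids titrate in between."""
        model, pkas = motif("salt_bridge_pair", 3.5)
        high = {r.identity for r in
                detect_salt_bridges(model, assign_states(pkas, 7.0))}
        low = {r.identity for r in
               detect_salt_bridges(model, assign_states(pkas, 3.0))}
        assert low <= high


class TestHydrogenBonds:
    def test_ser_his_pair_at_2p9A(self):
        model, pkas = motif("hbond_pair", 2.9)
        records = detect_hydrogen_bonds(model, assign_states(pkas, 7.5))
        assert [(r.label_a, r.label_b) for r in records] == [("OG", "NE2")]

    def test_his_state_changes_bond_inventory(self):
        """Neutral His NE2 is donor+acceptor; imidazolium NE2 is donor only.
        The OG-NE2 contact survives either way (Ser OG accepts), but the
        directed capability sets differ; enumerate them."""
        model, pkas = motif("hbond_pair", 2.9)
        neutral = assign_states(pkas, 7.5)
        charged = assign_states(pkas, 5.5)
        from phdelta.pka import GroupKey
        his_key = next(k for k, e in pkas if e.res_name == "HIS")
        assert neutral.get(his_key).acceptor_capable
        assert not charged.get(his_key).acceptor_capable
        # tautomer-agnostic record is retained in both states
        assert len(detect_hydrogen_bonds(model, neutral)) == 1
        assert len(detect_hydrogen_bonds(model, charged)) == 1

    def test_distance_beyond_cutoff_rejected(self):
        model, pkas = motif("hbond_pair", 3.8)
        assert detect_hydrogen_bonds(model, assign_states(pkas, 7.5)) == []

    def test_explicit_hydrogens_enable_angle_filter(self):
        model, pkas = motif("hbond_pair", 2.9, hydrogens=True)
        states = assign_states(pkas, 7.5)
        permissive = GeometryParams(hbond_min_angle=0.0)
        strict = GeometryParams(hbond_min_angle=179.5)
        with_angle = detect_hydrogen_bonds(model, states, permissive)
        assert any(r.angle is not None for r in with_angle)
        assert detect_hydrogen_bonds(model, states, strict) == []


class TestAromatics:
    def test_neutral_his_rings_stack(self):
        model, pkas = motif("ring_stack", 4.5)
        records = detect_aromatic(model, assign_states(pkas, 7.5))
        assert [r.kind for r in records] == ["pi_pi"]
        assert records[0].distance == pytest.approx(4.5, abs=0.01)

    def test_single_protonated_his_recategorizes_to_cation_pi(self):
        # one His titrates at 6.5, the other is pinned far below the pH
        model, pkas = motif("ring_stack", 4.5, pka_overrides={10: 4.0})
        records = detect_aromatic(model, assign_states(pkas, 5.5))
        assert [r.kind for r in records] == ["cation_pi"]
        assert {records[0].label_a, records[0].label_b} == {"ring+", "ring"}

    def test_both_protonated_no_aromatic_contact(self):
        model, pkas = motif("ring_stack", 4.5)
        assert detect_aromatic(model, assign_states(pkas, 5.5)) == []

    def test_arg_his_cation_pi_at_5A(self):
        model, pkas = motif("cation_pi_pair", 5.0)
        records = detect_aromatic(model, assign_states(pkas, 7.0))
        assert [(r.kind, r.label_a, r.label_b) for r in records] == \
            [("cation_pi", "guanidinium", "ring")]
        assert records[0].distance == pytest.approx(5.0, abs=0.01)

    def test_pi_pi_beyond_centroid_cutoff_rejected(self):
        model, pkas = motif("ring_stack", 7.4)
        assert detect_aromatic(model, assign_states(pkas, 7.5)) == []


class TestDetectAll:
    def test_salt_bridge_fixture_composes(self):
        model, pkas = motif("salt_bridge_pair", 3.0)
        states = assign_states(pkas, 7.0)
        combined = detect_all(model, states)
        assert {r.identity for r in combined.by_kind("salt_bridge")} == \
            {r.identity for r in detect_salt_bridges(model, states)}

    def test_salt_bridge_takes_precedence_over_hbond(self):
        model, pkas = motif("salt_bridge_pair", 3.0)
        combined = detect_all(model, assign_states(pkas, 7.0))
        sb_atom_pairs = {frozenset([(r.key_a, r.label_a), (r.key_b, r.label_b)])
                         for r in combined.by_kind("salt_bridge")}
        hb_atom_pairs = {frozenset([(r.key_a, r.label_a), (r.key_b, r.label_b)])
                         for r in combined.by_kind("hydrogen_bond")}
        assert not sb_atom_pairs & hb_atom_pairs

    def test_records_canonicalized_and_unique(self, make_random_system):
        model, pkas, ph = make_random_system(7)
        result = detect_all(model, assign_states(pkas, ph))
        assert len(result.identities()) == len(result.records)
        for r in result.records:
            assert (r.key_a, r.label_a) <= (r.key_b, r.label_b)
            assert r.distance > 0

    def test_determinism(self, make_random_system):
        model, pkas, ph = make_random_system(11)
        a = detect_all(model, assign_states(pkas, ph))
        b = detect_all(model, assign_states(pkas, ph))
        assert a.records == b.records


class TestBruteForceOracle:
    @pytest.mark.parametrize("seed", range(30))
    def test_detection_matches_naive_all_pairs(self, make_random_system, seed):
        model, pkas, ph = make_random_system(seed)
        states = assign_states(pkas, ph)
        got = detect_all(model, states).identities()
        expected = oracles.all_bonds(model, pkas, ph)
        assert got == expected

    @pytest.mark.parametrize("seed", [3, 17])
    def test_per_kind_agreement(self, make_random_system, seed):
        model, pkas, ph = make_random_system(seed)
        states = assign_states(pkas, ph)
        assert {r.identity for r in detect_salt_bridges(model, states)} == \
            oracles.salt_bridges(model, pkas, ph)
        assert {r.identity for r in detect_hydrogen_bonds(model, states)} == \
            oracles.hydrogen_bonds(model, pkas, ph)
        assert {r.identity for r in detect_aromatic(model, states)} == \
            oracles.aromatics(model, pkas, ph)
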