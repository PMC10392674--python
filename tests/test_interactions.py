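"""Geometric interaction detection, networks, persistence and reports."""
import copy

import numpy as np
import pytest

from gpcrforge.core import Atom, Residue, Structure, build_ideal_helix
from gpcrforge.fixtures import make_frames, make_salt_bridge_pair
from gpcrforge.geometry import rotation_about_axis
from gpcrforge.interactions import (anchor_report, detect_hbonds,
                                    detect_salt_bridges, hb_network,
                                    persistence)


def _brute_force_hbonds(structure, d_max, angle_min):
    """Independent all-pairs detector used as the oracle."""
    from gpcrforge import residues as rt
    residues = list(structure.residues)
    found = set()
    for rd in residues:
        for a in rd.atoms:
            heavy = rt.DONOR_OF_HYDROGEN.get(a.name)
            if not heavy or not rd.has_atom(heavy):
                continue
            d_atom = rd.atom(heavy)
            for ra in residues:
                if ra is rd:
                    continue
                for acc in ra.atoms:
                    if acc.element != "O" or acc.name not in rt.ACCEPTOR_NAMES:
                        continue
                    r = np.linalg.norm(acc.coord - d_atom.coord)
                    if r > d_max:
                        continue
                    v1 = d_atom.coord - a.coord
                    v2 = acc.coord - a.coord
                    cosang = v1 @ v2 / (np.linalg.norm(v1)
                                        * np.linalg.norm(v2))
                    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                    if ang >= angle_min:
                        found.add(((rd.chain, rd.index, heavy),
                                   (ra.chain, ra.index, acc.name)))
    return found


class TestHBonds:
    def test_planted_ideal_hbond_detected(self, salt_bridge_pair):
        records = detect_hbonds(salt_bridge_pair)
        assert any(r.partner_a[3] == "NZ" and r.partner_b[3] == "OD1"
                   for r in records)

    def test_far_pair_not_detected(self):
        pair = make_salt_bridge_pair(5.0)
        assert detect_hbonds(pair) == []

    def test_matches_all_pairs_oracle_on_random_fixture(self, rng):
        helix = build_ideal_helix("SKDSYKDS")
        st = Structure(residues=helix.residues)
        for r in st.residues:
            for a in r.atoms:
                a.coord = a.coord + rng.normal(scale=0.4, size=3)
        got = {((r.partner_a[0], r.partner_a[1], r.partner_a[3]),
                (r.partner_b[0], r.partner_b[1], r.partner_b[3]))
               for r in detect_hbonds(st)}
        assert got == _brute_force_hbonds(st, 3.5, 120.0)

    def test_rigid_transform_invariance(self, salt_bridge_pair):
        before = detect_hbonds(salt_bridge_pair)
        moved = copy.deepcopy(salt_bridge_pair)
        R = rotation_about_axis([1.0, 1.0, 0.2], 67.0)
        for r in moved.residues:
            for a in r.atoms:
                a.coord = R @ a.coord + np.array([5.0, -8.0, 2.0])
        after = detect_hbonds(moved)
        assert [(r.partner_a, r.partner_b) for r in before] == \
            [(r.partner_a, r.partner_b) for r in after]


class TestSaltBridges:
    def test_planted_pair_at_3A(self, salt_bridge_pair):
        records = detect_salt_bridges(salt_bridge_pair)
        assert len(records) == 1
        assert records[0].distance == pytest.approx(3.0, abs=1e-6)

    def test_same_pair_at_6A_not_detected(self):
        assert detect_salt_bridges(make_salt_bridge_pair(6.0)) == []

    def test_three_planted_bridges_among_decoys(self):
        residues = []
        # three Lys/Asp pairs 3 A apart, plus far decoys of both types
        for k in range(3):
            pair = make_salt_bridge_pair(3.0)
            for r in pair.residues:
                r.index = r.index + 10 * k
                for a in r.atoms:
                    a.coord = a.coord + np.array([0.0, 0.0, 25.0 * k])
            residues.extend(pair.residues)
        decoys = make_salt_bridge_pair(3.0)
        for r in decoys.residues:
            r.index = r.index + 100
        for a in decoys.residues[0].atoms:
            a.coord = a.coord + np.array([60.0, 0.0, 0.0])
        for a in decoys.residues[1].atoms:
            a.coord = a.coord + np.array([-60.0, 0.0, 0.0])
        residues.extend(decoys.residues)
        records = detect_salt_bridges(Structure(residues=residues))
        pairs = {(r.partner_a[1], r.partner_b[1]) for r in records}
        assert pairs == {(1, 5), (11, 15), (21, 25)}

    def test_ligand_formal_charges_participate(self):
        pair = make_salt_bridge_pair(3.0)
        asp = pair.residues[1]
        cation = Residue(index=90, name="LIG", chain="L", atoms=[
            Atom("NX", "N", asp.atom("OD2").coord + np.array([3.0, 0, 0]),
                 formal_charge=1)])
        st = Structure(residues=pair.residues + [cation])
        records = detect_salt_bridges(st)
        assert any(r.partner_a[2] == "LIG" for r in records)


class TestNetwork:
    def test_chain_of_residues_forms_path(self):
        # four Ser residues in a row, OG...OG within range pairwise
        residues = []
        for k in range(4):
            h = build_ideal_helix("ASA", start_index=1 + 10 * k)
            ser = copy.deepcopy(h.residues[1])
            for a in ser.atoms:
                a.coord = a.coord + np.array([3.0 * k, 0.0, 0.0])
            residues.append(ser)
        st = Structure(residues=residues)
        net = hb_network(st, residues[0], d_max=4.5, angle_min=0.0)
        assert net.number_of_nodes() == 4
        assert net.number_of_edges() >= 3

    def test_water_bridge_edge(self):
        h = build_ideal_helix("SAAAS")
        s1 = copy.deepcopy(h.residues[0])
        s2 = copy.deepcopy(h.residues[4])
        for a in s2.atoms:
            a.coord = a.coord + np.array([20.0, 0.0, 0.0])
        mid = (s1.atom("OG").coord + s2.atom("OG").coord) / 2.0
        water = Residue(index=50, name="HOH", chain="W",
                        atoms=[Atom("O", "O", mid)])
        st = Structure(residues=[s1, s2, water])
        net = hb_network(st, s1, allow_water_bridge=True, d_max=12.0)
        kinds = {d["kind"] for _, _, d in net.edges(data=True)}
        assert kinds == {"water-mediated-HB"}

    def test_isolated_seed_gives_singleton_graph(self):
        h = build_ideal_helix("SAA")
        st = Structure(residues=[h.residues[0]])
        net = hb_network(st, h.residues[0])
        assert net.number_of_nodes() == 1
        assert net.number_of_edges() == 0


class TestPersistence:
    SPEC = {"kind": "SB", "partner_a": 1, "partner_b": 5}

    def test_always_present(self, salt_bridge_pair):
        frames, _ = make_frames(salt_bridge_pair, self.SPEC, 1.0, 20, seed=1)
        assert persistence(frames, self.SPEC).fraction == 1.0

    def test_never_present(self, salt_bridge_pair):
        frames, _ = make_frames(salt_bridge_pair, self.SPEC, 0.0, 20, seed=1)
        assert persistence(frames, self.SPEC).fraction == 0.0

    def test_scheduled_fraction_exact(self, salt_bridge_pair):
        frames, truth = make_frames(salt_bridge_pair, self.SPEC, 0.6, 100,
                                    seed=2)
        series = persistence(frames, self.SPEC)
        assert series.fraction == 0.60
        assert series.present == truth["schedule"]

    def test_monotone_in_added_on_frames(self, salt_bridge_pair):
        frames, _ = make_frames(salt_bridge_pair, self.SPEC, 0.5, 10, seed=3)
        on_frames, _ = make_frames(salt_bridge_pair, self.SPEC, 1.0, 5,
                                   seed=3)
        f1 = persistence(frames, self.SPEC).fraction
        f2 = persistence(frames + on_frames, self.SPEC).fraction
        assert f2 >= f1


class TestAnchorReport:
    def test_planted_anchor_groups(self, salt_bridge_pair):
        report = anchor_report(salt_bridge_pair,
                               {"ICL1": [1], "G_beta": [5], "EMPTY": [99]})
        by_group = report.groupby("group").size().to_dict()
        assert by_group.get("ICL1", 0) >= 1
        assert by_group.get("G_beta", 0) >= 1
        assert "EMPTY" not in by_group

    def test_persistence_column_with_frames(self, salt_bridge_pair):
        frames, _ = make_frames(salt_bridge_pair,
                                {"kind": "SB", "partner_a": 1,
                                 "partner_b": 5}, 0.5, 10, seed=4)
        report = anchor_report(salt_bridge_pair, {"ICL1": [1]},
                               frames=frames)
        assert "persistence" in report.columns
        sb_rows = report[report["kind"] == "SB"]
        assert np.allclose(sb_rows["persistence"], 0.5)
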