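"""Internal-coordinate construction: round trips, locality, ideality, caps."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swaloop import topology as topo
from swaloop.geometry import (Conformation, append_capped_residue, bond_angle,
                              build_from_torsions, dihedral,
                              prepend_capped_residue, set_torsion, wrap_angle)


def scratch_ca_ca_distance():
    """Independent planar computation of the trans-peptide CA-CA distance.

    With omega = 180 the four atoms CA-C-N-CA are coplanar; walk the three
    bonds in 2D, turning by the bond-angle supplements.
    """
    bb = topo.backbone_params()
    pos = np.zeros(2)
    heading = 0.0
    sign = 1.0  # trans peptide: the zigzag alternates turn direction
    for bond, angle in ((bb["bond_CA_C"], bb["angle_CA_C_N"]),
                        (bb["bond_C_N"], bb["angle_C_N_CA"]),
                        (bb["bond_N_CA"], None)):
        pos = pos + bond * np.array([math.cos(heading), math.sin(heading)])
        if angle is not None:
            heading += sign * (math.pi - math.radians(angle))
            sign = -sign
    return float(np.linalg.norm(pos))


def test_poly_ala_ca_spacing_matches_scratch_builder():
    tor = {r: {"phi": -70.0 - 5 * r, "psi": 120.0 + 3 * r, "omega": 180.0}
           for r in range(1, 4)}
    conf = build_from_torsions("AAA", tor)
    cas = np.array([conf.atom(r, "CA") for r in range(1, 4)])
    d = np.linalg.norm(np.diff(cas, axis=0), axis=1)
    expected = scratch_ca_ca_distance()
    assert np.allclose(d, expected, atol=1e-9)
    assert np.allclose(d, d[0])


def test_empty_sequence_builds_zero_atoms():
    conf = build_from_torsions("")
    assert [r for r in conf.residues if r != 0] == []


def test_degenerate_anchor_rejected():
    frame = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
    with pytest.raises(ValueError, match="collinear"):
        build_from_torsions("AA", anchor_frame=frame)


def test_unknown_residue_code_rejected():
    with pytest.raises(KeyError):
        build_from_torsions("AXA")


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.floats(-179.0, 179.0), st.floats(-179.0, 179.0)),
                min_size=2, max_size=5))
def test_torsion_roundtrip_rebuild_reproduces_coordinates(phipsi):
    seq = "ASLG"[: max(2, len(phipsi))].ljust(len(phipsi), "A")
    tor = {r + 1: {"phi": p, "psi": s, "omega": 180.0}
           for r, (p, s) in enumerate(phipsi)}
    conf = build_from_torsions(seq, tor)
    measured = {}
    for r in range(1, len(phipsi) + 1):
        measured[r] = {"phi": conf.measure_phi(r) or tor[r]["phi"],
                       "psi": conf.measure_psi(r), "omega": 180.0}
    rebuilt = build_from_torsions(seq, measured)
    for r in range(1, len(phipsi) + 1):
        for a in conf.residues[r]:
            assert np.linalg.norm(conf.atom(r, a) - rebuilt.atom(r, a)) < 1e-6


def test_ideality_after_edits():
    conf = build_from_torsions("ASA")
    conf.set_torsion(2, "phi", 77.0)
    conf.set_torsion(2, "psi", -33.0)
    bb = topo.backbone_params()
    for r in (2, 3):
        res = conf.residues[r]
        prev = conf.residues[r - 1]
        assert abs(np.linalg.norm(res["N"] - prev["C"]) - bb["bond_C_N"]) < 1e-6
        assert abs(np.linalg.norm(res["CA"] - res["N"]) - bb["bond_N_CA"]) < 1e-6
        assert abs(bond_angle(res["N"], res["CA"], res["C"])
                   - bb["angle_N_CA_C"]) < 1e-6


class TestLoopFragments:
    @pytest.fixture()
    def problem(self, ala_helix):
        conf = ala_helix.copy()
        conf.set_loop(6, 10)
        return conf

    def test_append_creates_cap_and_trans_omega(self, problem):
        grown = append_capped_residue(problem, 6)
        assert grown.nfrag_end == 6
        for cap in ("NT", "HT", "CT"):
            assert grown.has_atom(6, cap)
        assert abs(abs(grown.measure_omega(6)) - 180.0) < 1e-6

    def test_append_nonadjacent_rejected(self, problem):
        with pytest.raises(ValueError, match="not adjacent"):
            append_capped_residue(problem, 8)
        grown = append_capped_residue(problem, 6)
        with pytest.raises(ValueError, match="already built"):
            grown.append_residue(6)

    def test_cap_removed_when_next_residue_appended(self, problem):
        grown = append_capped_residue(problem, 6)
        grown = append_capped_residue(grown, 7)
        assert not grown.has_atom(6, "NT")
        assert grown.has_atom(7, "NT")

    def test_prepend_creates_acetyl_cap(self, problem):
        grown = prepend_capped_residue(problem, 10)
        assert grown.cfrag_start == 10
        for cap in ("CP", "OP", "CMP"):
            assert grown.has_atom(10, cap)

    def test_double_prepend_equals_batch_torsions(self, problem):
        a = prepend_capped_residue(problem, 10, phi=-70, psi=140)
        a = prepend_capped_residue(a, 9, phi=-100, psi=20)
        b = problem.copy()
        b.prepend_residue(10, phi=-70, psi=140)
        b.prepend_residue(9, phi=-100, psi=20)
        for r in (9, 10):
            for at in a.residues[r]:
                assert np.linalg.norm(a.atom(r, at) - b.atom(r, at)) < 1e-9

    def test_set_torsion_roundtrip_and_last_write_wins(self, problem):
        grown = append_capped_residue(problem, 6)
        one = set_torsion(grown, 6, "phi", -97.0)
        assert abs(one.get_torsion(6, "phi") - (-97.0)) < 1e-9
        twice = set_torsion(set_torsion(grown, 6, "phi", 10.0), 6, "phi", -97.0)
        for at in one.residues[6]:
            assert np.linalg.norm(one.atom(6, at) - twice.atom(6, at)) < 1e-12

    def test_scaffold_torsion_is_immovable(self, problem):
        with pytest.raises(ValueError, match="not movable"):
            problem.set_torsion(3, "phi", 10.0)

    def test_locality_upstream_atoms_do_not_move(self, problem):
        grown = problem.copy()
        for r in (6, 7):
            grown.append_residue(r)
        for r in (10, 9):
            grown.prepend_residue(r)
        before_scaffold = {a: grown.atom(5, a).copy() for a in grown.residues[5]}
        before_cfrag = {a: grown.atom(9, a).copy() for a in grown.residues[9]}
        before_n6 = {a: grown.atom(6, a).copy()
                     for a in ("N", "CA", "C", "O", "H")}
        grown.set_torsion(7, "phi", 61.0)
        for a, p in before_scaffold.items():
            assert np.linalg.norm(grown.atom(5, a) - p) == 0.0
        for a, p in before_cfrag.items():
            assert np.linalg.norm(grown.atom(9, a) - p) == 0.0
        for a, p in before_n6.items():
            assert np.linalg.norm(grown.atom(6, a) - p) < 1e-12

    def test_cutpoint_rotation_never_moves_past_cutpoint(self, problem):
        grown = problem.copy()
        for r in (6, 7, 8):
            grown.append_residue(r)
        for r in (10, 9):
            grown.prepend_residue(r)
        grown.mark_closed()
        assert grown.cutpoint == 8
        before = {a: grown.atom(9, a).copy()
                  for a in ("N", "CA", "C")}
        grown.set_torsion(7, "psi", 99.0)  # N-side edit
        for a, p in before.items():
            assert np.linalg.norm(grown.atom(9, a) - p) == 0.0

    def test_proline_phi_pinned_on_append(self, ala_helix):
        seq = ala_helix.sequence[:7] + "P" + ala_helix.sequence[8:]
        conf = build_from_torsions(seq).freeze_as_scaffold()
        conf.set_loop(6, 10)
        conf.append_residue(6)
        conf.append_residue(7)
        conf.append_residue(8, phi=-120.0)
        assert conf.bb[8]["phi"] == -65.0
        assert not conf.has_atom(8, "H")

    def test_virtual_atoms_exist_iff_cutpoint(self, problem):
        grown = problem.copy()
        for r in (6, 7, 8):
            grown.append_residue(r)
        for r in (10, 9):
            grown.prepend_residue(r)
        assert not grown.has_atom(8, "VN")
        grown.mark_closed()
        assert grown.has_atom(8, "VN") and grown.has_atom(8, "VCA")
        assert grown.has_atom(9, "VC")
        assert not grown.has_atom(8, "NT")


def test_wrap_angle_range():
    assert wrap_angle(190.0) == -170.0
    assert wrap_angle(-180.0) == 180.0
    assert wrap_angle(360.0) == 0.0


def test_dihedral_sign_convention():
    a, b, c = np.array([1.0, 1, 0]), np.array([0.0, 0, 0]), np.array([1.0, 0, 0])
    d_up = np.array([2.0, 0.0, 1.0])
    assert dihedral(a, b, c, d_up) < 0 or dihedral(a, b, c, d_up) > 0  # defined
    assert abs(dihedral(a, b, c, np.array([2.0, 1.0, 0.0]))) < 1e-9  # cis = 0
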