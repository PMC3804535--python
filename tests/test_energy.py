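"""Surrogate energy: term oracles, cutoffs, invariances."""

import math

import numpy as np
import pytest

from swaloop import energy as E
from swaloop.geometry import build_from_torsions
from tests.conftest import helix_torsions


@pytest.fixture(scope="module")
def helix():
    conf = build_from_torsions("AASLAAVAASAALAAA", helix_torsions(16))
    return conf.freeze_as_scaffold()


# ------------------------------------------------------------- weights


def test_weight_presets_match_protocol_dialects():
    ws = E.sampling_weights()
    wm = E.minimization_weights()
    assert ws.fa_rep == 0.10 and wm.fa_rep == 0.44
    assert ws.hbond_sc == 3.1 and wm.hbond_sc == 1.1


def test_negative_weight_rejected():
    with pytest.raises(ValueError):
        E.EnergyWeights(fa_rep=-0.1)


def test_breakdown_total_is_weighted_sum(helix):
    bd = E.score(helix, E.minimization_weights())
    expected = sum(bd.weights.as_dict()[t] * v for t, v in bd.terms.items())
    assert abs(bd.total - expected) < 1e-9


def test_weight_linearity(helix):
    w1 = E.minimization_weights()
    w2 = E.EnergyWeights(**{t: 2 * v for t, v in w1.as_dict().items()})
    assert abs(E.score(helix, w2).total - 2 * E.score(helix, w1).total) < 1e-9


# ------------------------------------------------------------- packing term


def scratch_lj(d, r1, r2, eps, cap_frac, cutoff):
    """Independent scalar re-derivation of the split Lennard-Jones."""
    rmin = r1 + r2
    if d >= cutoff:
        return 0.0, 0.0
    if d >= rmin:
        x = rmin / d
        lj = eps * (x ** 12 - 2 * x ** 6)
        if d > cutoff - 1.0:
            lj *= 0.5 * (1 + math.cos(math.pi * (d - (cutoff - 1.0))))
        return lj, 0.0
    d0 = cap_frac * rmin
    if d >= d0:
        x = rmin / d
        return -eps, eps * (x ** 12 - 2 * x ** 6 + 1)
    x0 = 1.0 / cap_frac
    e0 = eps * (x0 ** 12 - 2 * x0 ** 6 + 1)
    slope = eps * (-12 * x0 ** 13 + 12 * x0 ** 7) / rmin
    return -eps, e0 + slope * (d - d0)


def test_split_lj_matches_scalar_oracle_on_five_atom_toy():
    par = E._params()
    eps, cf, co = par["epsilon"], par["rep_cap_fraction"], par["pair_cutoff"]
    dists = np.array([0.0, 1.7, 3.2, 3.6, 5.7])
    radii = np.array([(1.75, 1.75), (1.55, 1.50), (1.75, 1.50),
                      (1.80, 1.75), (1.50, 1.50)])
    rmins = radii.sum(axis=1)
    atr, rep = E._lj_split(dists, rmins, eps, cf, co)
    for i, d in enumerate(dists):
        a0, r0 = scratch_lj(float(d), radii[i][0], radii[i][1], eps, cf, co)
        assert abs(atr[i] - a0) < 1e-9
        assert abs(rep[i] - r0) < 1e-9
    assert np.isfinite(rep[0]) and rep[0] > 100  # clash at finite cap


def test_pair_terms_zero_beyond_cutoff():
    par = E._params()
    atr, rep = E._lj_split(np.array([par["pair_cutoff"] + 0.5]),
                           np.array([3.5]), par["epsilon"],
                           par["rep_cap_fraction"], par["pair_cutoff"])
    assert atr[0] == 0.0 and rep[0] == 0.0


# ------------------------------------------------------------ hydrogen bond


def test_hbond_inside_well_is_negative():
    assert E.hbond_term(2.9, 1.0) < -0.5


def test_hbond_zero_beyond_heavy_cutoff():
    assert E.hbond_term(3.5, 1.0) == 0.0
    assert E.hbond_term(3.2, 1.0) == 0.0


def test_hbond_continuous_at_cutoff():
    assert abs(E.hbond_term(3.2 - 1e-5, 1.0)) < 1e-6


def test_hbond_angle_modulation():
    assert E.hbond_term(2.9, -0.2) == 0.0
    assert E.hbond_term(2.9, 0.5) > E.hbond_term(2.9, 1.0)  # weaker when bent


# ------------------------------------------------------------- rama tables


def test_alanine_helix_passes_filter():
    assert E.rama_score("ALA", -60.0, -45.0) <= 0.8


def test_glycine_table_differs_from_generic():
    assert E.rama_score("GLY", 80.0, 10.0) <= 0.8
    assert E.rama_score("ALA", 80.0, 10.0) > 0.8


def test_bilinear_interpolation_exact_at_grid_node():
    data = E._rama_tables()
    grid = data["grid"]
    table = data["tables"]["generic"]
    i, j = 4, 7
    assert abs(E.rama_score("ALA", float(grid[i]), float(grid[j]))
               - float(table[i, j])) < 1e-12


def test_rama_minimum_nonpositive():
    for cls, table in E._rama_tables()["tables"].items():
        assert table.min() <= 0.0


# ------------------------------------------- chainbreak & fade constraint


@pytest.fixture()
def closed_loop(ala_helix):
    conf = ala_helix.copy()
    conf.set_loop(6, 10)
    tors = {r: {"phi": -63.0, "psi": -43.0, "omega": 180.0} for r in range(6, 11)}
    for r in (6, 7, 8):
        conf.append_residue(r, **tors[r])
    for r in (10, 9):
        conf.prepend_residue(r, **tors[r])
    conf.mark_closed()
    return conf


def test_closed_chain_has_zero_chainbreak(closed_loop):
    assert E.linear_chainbreak(closed_loop) < 1e-9


def test_rigid_translation_gives_three_angstroms(closed_loop):
    conf = closed_loop.copy()
    t = np.array([1.0, 0.0, 0.0])
    c = conf.cutpoint
    for r in list(conf.residues):
        if r > c and r in conf.kind and conf.kind[r] != "scaffold":
            for a in conf.residues[r]:
                conf.residues[r][a] = conf.residues[r][a] + t
    conf.touch()
    assert abs(E.linear_chainbreak(conf) - 3.0) < 1e-9
    # matches a scratch distance computation over the three atom pairs
    direct = (np.linalg.norm(conf.atom(c, "VN") - conf.atom(c + 1, "N"))
              + np.linalg.norm(conf.atom(c, "VCA") - conf.atom(c + 1, "CA"))
              + np.linalg.norm(conf.atom(c + 1, "VC") - conf.atom(c, "C")))
    assert abs(E.linear_chainbreak(conf) - direct) < 1e-12


def test_chainbreak_requires_cutpoint(ala_helix):
    with pytest.raises(ValueError, match="cutpoint"):
        E.linear_chainbreak(ala_helix)


@pytest.mark.parametrize("d,expected", [(1.0, 0.0), (5.0, 10.0), (3.0, 5.0)])
def test_fade_spline_hermite_values(d, expected):
    assert abs(E.ca_fade_constraint(d) - expected) < 1e-12


def test_fade_spline_zero_slope_at_knots():
    eps = 1e-6
    assert E.ca_fade_constraint(2.0 + eps) < 1e-9
    assert 10.0 - E.ca_fade_constraint(4.0 - eps) < 1e-9


def test_fade_spline_rejects_inverted_knots():
    with pytest.raises(ValueError):
        E.ca_fade_constraint(3.0, r_lo=4.0, r_hi=2.0)


# ---------------------------------------------------------------- invariances


def test_rigid_body_invariance(helix, rng):
    from scipy.spatial.transform import Rotation

    bd0 = E.score(helix, E.minimization_weights()).total
    conf = helix.copy()
    R = Rotation.random(random_state=7).as_matrix()
    t = rng.normal(size=3) * 10
    for r in conf.residues:
        for a in conf.residues[r]:
            conf.residues[r][a] = R @ conf.residues[r][a] + t
    conf.touch()
    assert abs(E.score(conf, E.minimization_weights()).total - bd0) < 1e-6


def test_incremental_subset_scoring_consistency(closed_loop):
    w = E.minimization_weights().with_(linear_chainbreak=150.0)
    subset = set(range(6, 11))
    full0 = E.score(closed_loop, w).total
    sub0 = E.score(closed_loop, w, subset=subset).total
    static = full0 - sub0
    moved = closed_loop.copy()
    moved.set_torsion(7, "phi", moved.bb[7]["phi"] + 25.0)
    full1 = E.score(moved, w).total
    sub1 = E.score(moved, w, subset=subset).total
    assert abs((static + sub1) - full1) < 1e-6


def test_nan_coordinates_rejected(helix):
    conf = helix.copy()
    conf.residues[3]["CA"] = np.array([np.nan, 0.0, 0.0])
    conf.touch()
    with pytest.raises(ValueError, match="NaN"):
        E.score(conf, E.minimization_weights())
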