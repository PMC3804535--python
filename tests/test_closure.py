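"""CCD chain closure: analytic updates, screens, recombination."""

import numpy as np
import pytest

from swaloop.buildup import GridSpec, StageEnsemble
from swaloop.closure import (_CcdModel, ccd_close, close_candidates,
                             close_from_stage, merge_fragments,
                             recombine_fragments, reclose)
from swaloop.energy import minimization_weights, sampling_weights, score
from swaloop.geometry import build_from_torsions
from tests.conftest import helix_torsions


@pytest.fixture(scope="module")
def closed_loop():
    conf = build_from_torsions("AAAAAAAAAA", helix_torsions(10)).freeze_as_scaffold()
    conf.set_loop(4, 8)
    tors = {r: {"phi": -63.0, "psi": -43.0, "omega": 180.0} for r in range(4, 9)}
    for r in (4, 5, 6):
        conf.append_residue(r, **tors[r])
    for r in (8, 7):
        conf.prepend_residue(r, **tors[r])
    conf.mark_closed()
    return conf


BRIDGE = [(6, "psi"), (7, "phi"), (7, "psi"), (8, "phi")]


def test_already_closed_chain_is_untouched(closed_loop):
    before = {(r, n): closed_loop.bb[r][n] for r, n in BRIDGE}
    out, dev = ccd_close(closed_loop, BRIDGE)
    assert dev < 1e-9
    for (r, n), v in before.items():
        assert abs(out.bb[r][n] - v) < 1e-9


def test_single_torsion_perturbation_is_recovered(closed_loop):
    conf = closed_loop.copy()
    orig = conf.bb[6]["psi"]
    conf.set_torsion(6, "psi", orig + 15.0)
    assert conf.closure_deviation() > 0.1
    out, dev = ccd_close(conf, [(6, "psi")], tol=1e-5)
    assert dev < 1e-3
    assert abs(out.bb[6]["psi"] - orig) < 0.5


def test_ccd_requires_cutpoint_and_torsions(closed_loop):
    open_conf = build_from_torsions("AAA")
    with pytest.raises(ValueError, match="cutpoint"):
        ccd_close(open_conf, [(2, "psi")])
    with pytest.raises(ValueError, match="empty"):
        ccd_close(closed_loop, [])


def test_analytic_update_matches_fine_grid_scan(closed_loop):
    """One CCD update on one torsion reaches the scan minimum of that
    torsion's deviation profile."""
    conf = closed_loop.copy()
    conf.set_torsion(7, "phi", conf.bb[7]["phi"] + 40.0)
    conf.set_torsion(6, "psi", conf.bb[6]["psi"] - 25.0)
    for r, name in [(6, "psi"), (7, "phi")]:
        base = conf.bb[r][name]
        best_dev, best_v = np.inf, None
        for v in np.arange(-180.0, 180.0, 0.25):
            trial = conf.copy()
            trial.set_torsion(r, name, v)
            d = trial.closure_deviation()
            if d < best_dev:
                best_dev, best_v = d, v
        out, _ = ccd_close(conf, [(r, name)], max_cycles=1)
        assert out.closure_deviation() <= best_dev + 1e-6


def test_per_update_deviation_never_increases(closed_loop):
    conf = closed_loop.copy()
    conf.set_torsion(6, "psi", conf.bb[6]["psi"] + 35.0)
    conf.set_torsion(7, "psi", conf.bb[7]["psi"] - 50.0)
    model = _CcdModel(conf, BRIDGE)
    dev = model.deviation_sq()
    for _cycle in range(5):
        for r, name in BRIDGE:
            model.update(r, name)
            new_dev = model.deviation_sq()
            assert new_dev <= dev + 1e-12
            dev = new_dev


def test_ccd_moves_only_listed_torsions(closed_loop):
    conf = closed_loop.copy()
    conf.set_torsion(6, "psi", conf.bb[6]["psi"] + 30.0)
    out, _ = ccd_close(conf, [(7, "phi"), (7, "psi")])
    for r in (4, 5):
        assert out.bb[r]["phi"] == conf.bb[r]["phi"]
        assert out.bb[r]["psi"] == conf.bb[r]["psi"]
    assert out.bb[6]["psi"] == conf.bb[6]["psi"]


# ----------------------------------------------------------- stage closure


@pytest.fixture(scope="module")
def gapped_stage():
    """Stage (4, 7) on an 5-residue loop: gap residues 5 and 6."""
    conf = build_from_torsions("AAAAAAAAAA", helix_torsions(10)).freeze_as_scaffold()
    conf.set_loop(4, 8)
    conf.append_residue(4, phi=-63.0, psi=-43.0)
    conf.prepend_residue(8, phi=-63.0, psi=-43.0)
    conf.prepend_residue(7, phi=-63.0, psi=-43.0)
    score(conf, minimization_weights())
    return conf


def test_close_candidates_respect_screen(gapped_stage):
    spec = GridSpec(torsion_step=40.0)
    w = sampling_weights().with_(linear_chainbreak=150.0)
    unscreened = close_candidates(gapped_stage, "first", spec, w,
                                  screen=np.inf, max_cycles=100)
    screened = close_candidates(gapped_stage, "first", spec, w,
                                screen=1.5, max_cycles=100)
    # independent re-screen of the saved pre-screen models at 1.5 A
    recount = sum(1 for m, _ in unscreened if m.closure_deviation() < 1.5)
    assert len(screened) == recount
    for m, dev in screened:
        assert dev < 1.5
        assert abs(m.closure_deviation() - dev) < 1e-9


def test_gap_one_variants_coincide():
    conf = build_from_torsions("AAAAAAAAAA", helix_torsions(10)).freeze_as_scaffold()
    conf.set_loop(4, 6)
    conf.append_residue(4, phi=-63.0, psi=-43.0)
    conf.prepend_residue(6, phi=-63.0, psi=-43.0)
    score(conf, minimization_weights())
    spec = GridSpec(torsion_step=60.0)
    w = sampling_weights().with_(linear_chainbreak=150.0)
    a = close_candidates(conf, "first", spec, w, max_cycles=100)
    b = close_candidates(conf, "last", spec, w, max_cycles=100)
    assert len(a) == len(b)
    for (ma, da), (mb, db) in zip(a, b):
        assert abs(da - db) < 1e-12
        assert abs(ma.energy.total - mb.energy.total) < 1e-12


def test_gap_outside_one_to_three_rejected():
    conf = build_from_torsions("AAAAAAAAAAAA", helix_torsions(12)).freeze_as_scaffold()
    conf.set_loop(3, 10)
    score(conf, minimization_weights())
    with pytest.raises(ValueError, match="gap"):
        close_candidates(conf, "first", GridSpec(),
                         sampling_weights().with_(linear_chainbreak=150.0))


def test_lowest_energy_closure_is_well_closed(gapped_stage):
    spec = GridSpec(torsion_step=40.0)
    models = close_from_stage(StageEnsemble([gapped_stage]), "first", spec,
                              rng_seed=0, keep=4, max_cycles=200,
                              minimize_iter=30, rotamer_sweeps=1)
    assert models
    assert models[0].closure_deviation() < 0.01


def test_recombination_matches_exhaustive_pairing_oracle():
    conf = build_from_torsions("AAAAAAAAAA", helix_torsions(10)).freeze_as_scaffold()
    conf.set_loop(4, 8)
    score(conf, minimization_weights())
    spec = GridSpec(torsion_step=60.0)
    wm = minimization_weights()
    n_models, c_models = [], []
    for phi in (-63.0, -100.0):
        n = conf.copy()
        n.append_residue(4, phi=phi, psi=-43.0)
        score(n, wm)
        n_models.append(n)
        c = conf.copy()
        c.prepend_residue(8, phi=phi, psi=-43.0)
        c.prepend_residue(7, phi=phi, psi=-40.0)
        score(c, wm)
        c_models.append(c)
    ens_n = StageEnsemble(sorted(n_models, key=lambda m: m.energy.total))
    ens_c = StageEnsemble(sorted(c_models, key=lambda m: m.energy.total))
    got = recombine_fragments(ens_n, ens_c, spec, rng_seed=0, keep=50,
                              max_cycles=100, minimize_iter=0,
                              rotamer_sweeps=0, fine_radius=1e-9)
    # oracle: enumerate all four pairs through the same closure core
    w_break = sampling_weights().with_(linear_chainbreak=150.0)
    wm_break = wm.with_(linear_chainbreak=150.0)
    best = np.inf
    for a in ens_n.models:
        for b in ens_c.models:
            merged = merge_fragments(a, b)
            for m, _ in close_candidates(merged, "first", spec, w_break,
                                         max_cycles=100):
                m = reclose(m)
                best = min(best, score(m, wm_break).total)
    assert got
    assert abs(got[0].energy.total - best) < 1e-6
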