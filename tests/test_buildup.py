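"""Grid enumeration, rama filtering, fine clustering and the growth move."""

from types import SimpleNamespace

import numpy as np
import pytest

from swaloop.buildup import (GridSpec, SampleSpec, StageEnsemble, backbone_atoms,
                             cluster_fine, enumerate_backbone_grid, grow_step)
from swaloop.energy import minimization_weights, rama_score, sampling_weights, score
from swaloop.geometry import build_from_torsions
from tests.conftest import helix_torsions


def test_twenty_degree_grid_has_eighteen_samples():
    spec = GridSpec(torsion_step=20.0)
    assert spec.n_sample == 18
    grid = spec.grid()
    assert len(grid) == 18
    assert grid[0] == -180.0 and grid[-1] == 160.0  # left-inclusive


def test_step_must_divide_360():
    with pytest.raises(ValueError):
        GridSpec(torsion_step=25.0)


def test_two_residue_unfiltered_product_count():
    spec = GridSpec(torsion_step=20.0, rama_cutoff=1e9)
    residues = [SampleSpec(res=1, restype="ALA"), SampleSpec(res=2, restype="ALA")]
    assignments = enumerate_backbone_grid(spec, residues)
    assert len(assignments) == 18 ** 4


def test_rama_filter_drops_disallowed_assignments():
    spec = GridSpec(torsion_step=20.0, rama_cutoff=0.8)
    out = enumerate_backbone_grid(spec, [SampleSpec(res=1, restype="ALA")])
    assert 0 < len(out) < 18 ** 2
    for assign in out:
        phi, psi = assign[(1, "phi")], assign[(1, "psi")]
        assert rama_score("ALA", phi, psi) <= 0.8


def test_cis_proline_omega_doubles_count():
    spec = GridSpec(torsion_step=20.0, rama_cutoff=1e9)
    plain = enumerate_backbone_grid(
        spec, [SampleSpec(res=2, restype="ALA")])
    doubled = enumerate_backbone_grid(
        spec, [SampleSpec(res=2, restype="ALA", omega_res=2,
                          omega_values=(180.0, 0.0))])
    assert len(doubled) == 2 * len(plain)
    omegas = {a[(2, "omega")] for a in doubled}
    assert omegas == {180.0, 0.0}


# ------------------------------------------------------------- clustering


def _fake_models(rng, n=50):
    """Tiny conformations with synthetic energies for clustering tests."""
    models = []
    for i in range(n):
        tor = {1: {"phi": -120.0, "psi": float(rng.uniform(-180, 180)),
                   "omega": 180.0},
               2: {"phi": float(rng.uniform(-180, 180)), "psi": 120.0,
                   "omega": 180.0}}
        m = build_from_torsions("AA", tor)
        m.energy = SimpleNamespace(total=float(rng.normal()))
        models.append(m)
    return models


def scratch_leader_clustering(models, atoms, radius, keep):
    order = sorted(range(len(models)), key=lambda i: (models[i].energy.total, i))
    kept = []
    for i in order:
        if len(kept) >= keep:
            break
        ci = np.array([models[i].atom(r, a) for r, a in atoms])
        close = False
        for j in kept:
            cj = np.array([models[j].atom(r, a) for r, a in atoms])
            if np.sqrt(((ci - cj) ** 2).sum(axis=1).mean()) < radius:
                close = True
                break
        if not close:
            kept.append(i)
    return [models[i] for i in kept]


def test_leader_clustering_matches_scratch_oracle(rng):
    models = _fake_models(rng)
    atoms = backbone_atoms([1, 2])
    for radius, keep in ((0.5, 10), (2.0, 400), (10.0, 3)):
        got = cluster_fine(models, atoms, radius, keep).models
        want = scratch_leader_clustering(models, atoms, radius, keep)
        assert [id(m) for m in got] == [id(m) for m in want]


def test_identical_models_collapse_to_one(rng):
    m = _fake_models(rng, n=1)[0]
    clones = []
    for e in (3.0, 1.0, 2.0):
        c = m.copy()
        c.energy = SimpleNamespace(total=e)
        clones.append(c)
    out = cluster_fine(clones, backbone_atoms([1, 2]), 0.10, 400).models
    assert len(out) == 1
    assert out[0].energy.total == 1.0


def test_near_duplicates_within_fine_radius_are_discarded(rng):
    a = _fake_models(rng, n=1)[0]
    a.energy = SimpleNamespace(total=-1.0)
    b = a.copy()
    b.set_torsion(2, "phi", b.bb[2]["phi"] + 0.5)  # tiny backbone shift
    b.energy = SimpleNamespace(total=0.0)
    atoms = backbone_atoms([2])
    rms = np.sqrt(np.mean([np.sum((a.atom(r, n) - b.atom(r, n)) ** 2)
                           for r, n in atoms]))
    assert rms < 0.10
    out = cluster_fine([b, a], atoms, 0.10, 400).models
    assert len(out) == 1 and out[0].energy.total == -1.0


def test_empty_selection_rejected(rng):
    models = _fake_models(rng, n=2)
    with pytest.raises(ValueError, match="empty"):
        cluster_fine(models, [], 0.1, 10)


def test_lowest_energy_model_always_retained(rng):
    models = _fake_models(rng, n=20)
    out = cluster_fine(models, backbone_atoms([1, 2]), 100.0, 5).models
    assert out[0].energy.total == min(m.energy.total for m in models)
    assert len(out) == 1  # everything within a huge radius collapses


# ---------------------------------------------------------------- grow step


@pytest.fixture(scope="module")
def one_res_problem():
    conf = build_from_torsions("AAAAAAAA", helix_torsions(8)).freeze_as_scaffold()
    conf.set_loop(4, 4)
    score(conf, minimization_weights())
    return conf


def test_grow_step_empty_parent_gives_empty_output(one_res_problem):
    assert grow_step(StageEnsemble([]), "N", GridSpec()) == []


def test_grow_step_direction_validated(one_res_problem):
    with pytest.raises(ValueError, match="direction"):
        grow_step(StageEnsemble([one_res_problem]), "X", GridSpec())


def test_single_residue_growth_matches_exhaustive_grid_oracle(one_res_problem):
    """Retained-minimum energy equals explicit enumeration of the same grid."""
    spec = GridSpec(torsion_step=60.0)
    wm = minimization_weights()
    out = grow_step(StageEnsemble([one_res_problem]), "N", spec,
                    rng_seed=0, keep=999, fine_radius=1e-6, minimize_iter=0)
    got = min(m.energy.total for m in out)
    # scratch enumeration: place the capped residue at every surviving
    # grid point and score directly
    best = np.inf
    for assign in enumerate_backbone_grid(
            spec, [SampleSpec(res=4, restype="ALA")]):
        work = one_res_problem.copy()
        work.append_residue(4, phi=assign[(4, "phi")], psi=assign[(4, "psi")])
        best = min(best, score(work, wm).total)
    assert abs(got - best) < 1e-9


def test_first_loop_residue_does_not_sample_scaffold(one_res_problem):
    spec = GridSpec(torsion_step=60.0, sample_adjacent=True)
    psi_before = one_res_problem.bb[3]["psi"]
    out = grow_step(StageEnsemble([one_res_problem]), "N", spec,
                    rng_seed=0, keep=5, minimize_iter=0)
    for m in out:
        assert m.bb[3]["psi"] == psi_before


def test_filter_soundness_and_ensemble_contracts(one_res_problem):
    spec = GridSpec(torsion_step=40.0)
    out = grow_step(StageEnsemble([one_res_problem]), "N", spec,
                    rng_seed=0, keep=6, minimize_iter=0)
    assert 0 < len(out) <= 6
    energies = [m.energy.total for m in out]
    assert energies == sorted(energies)
    for m in out:
        assert rama_score("ALA", m.bb[4]["phi"], m.bb[4]["psi"]) <= 0.8
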