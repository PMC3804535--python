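"""Download-free synthetic test problems.

Generates small scaffolds (a beta-hairpin or a helix-turn-helix) whose
designed "native" loop is a strong local optimum of the package's own
surrogate energy function.  Excising the loop (and all side-chains)
produces a recovery problem in the same shape as a crystallographic
loop-rebuilding benchmark input; because the planted answer is an optimum
of the very energy being searched, recovery isolates the sampling problem
from energy-function error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .buildup import movable_bb
from .energy import minimization_weights, sampling_weights, score, _flat, _params, _lj_split
from .geometry import Conformation, build_from_torsions
from .minimize import torsion_minimize
from .rotamers import rotamer_trials

_ALPHABET = list("ASVLTG")
_WEIGHTS = np.array([0.40, 0.18, 0.12, 0.10, 0.08, 0.12])


def _torsion_plan(n: int, topology: str, rng: np.random.Generator
                  ) -> tuple[str, dict[int, dict]]:
    jitter = lambda: float(rng.normal(0.0, 4.0))
    seq = list(rng.choice(_ALPHABET, size=n, p=_WEIGHTS / _WEIGHTS.sum()))
    tors: dict[int, dict] = {}
    if topology == "helix_turn":
        n_turn = 4
        n1 = (n - n_turn) // 2
        turn = [(-60.0, -30.0), (-90.0, 0.0), (-80.0, -20.0), (-70.0, -35.0)]
        for r in range(1, n + 1):
            if r <= n1:
                phi, psi = -63.0, -43.0
            elif r <= n1 + n_turn:
                phi, psi = turn[r - n1 - 1]
            else:
                phi, psi = -63.0, -43.0
            tors[r] = {"phi": phi + jitter(), "psi": psi + jitter(),
                       "omega": 180.0}
    elif topology == "hairpin":
        n_turn = 4
        n1 = (n - n_turn) // 2
        # type-I'-like turn; glycines keep the positive-phi steps allowed
        turn = [(-60.0, -30.0), (60.0, 30.0), (90.0, 0.0), (-90.0, 10.0)]
        for idx, r in enumerate(range(n1 + 1, n1 + n_turn + 1)):
            if turn[idx][0] > 0:
                seq[r - 1] = "G"
        for r in range(1, n + 1):
            if r <= n1:
                phi, psi = -139.0, 135.0
            elif r <= n1 + n_turn:
                phi, psi = turn[r - n1 - 1]
            else:
                phi, psi = -139.0, 135.0
            tors[r] = {"phi": phi + jitter(), "psi": psi + jitter(),
                       "omega": 180.0}
    else:
        raise ValueError("topology must be 'hairpin' or 'helix_turn'")
    return "".join(seq), tors


def max_repulsion(conf: Conformation) -> float:
    """Largest single-pair repulsive energy (clash detector)."""
    from scipy.spatial.distance import cdist

    par = _params()
    flat = _flat(conf)
    hi = flat.heavy_idx
    if hi.size < 2:
        return 0.0
    d = cdist(flat.xyz[hi], flat.xyz[hi])
    iu, ju = np.triu_indices(hi.size, k=1)
    mask = (d[iu, ju] < par["pair_cutoff"]) & ~flat.excluded[hi[iu], hi[ju]]
    iu, ju = iu[mask], ju[mask]
    if not iu.size:
        return 0.0
    rmin = flat.radius[hi[iu]] + flat.radius[hi[ju]]
    _, rep = _lj_split(d[iu, ju], rmin, par["epsilon"],
                       par["rep_cap_fraction"], par["pair_cutoff"])
    return float(rep.max()) if rep.size else 0.0


def make_scaffold(n_residues: int, topology: str = "hairpin",
                  seed: int = 0, relax_iter: int = 60,
                  max_attempts: int = 5) -> Conformation:
    """Generate a closed, clash-free all-atom scaffold.

    Built from canonical torsions with seeded jitter, side-chains packed by
    rotamer trials, then relaxed by full-torsion minimization.  Deterministic
    per seed.  Raises RuntimeError when no clash-free structure is found
    within the retry budget.
    """
    if not 15 <= n_residues <= 60:
        raise ValueError("n_residues must be in [15, 60]")
    wm = minimization_weights()
    for attempt in range(max_attempts):
        rng = np.random.default_rng(seed + 7919 * attempt)
        seq, tors = _torsion_plan(n_residues, topology, rng)
        conf = build_from_torsions(seq, tors)
        conf = rotamer_trials(conf, list(range(1, n_residues + 1)),
                              sampling_weights(), rng_seed=seed, sweeps=2)
        move_set = []
        for r in range(2, n_residues):
            move_set += movable_bb(conf, r, include_omega=False)
        for r in range(1, n_residues + 1):
            move_set += [("chi", r, c) for c in range(conf.topo(r).n_chi)]
        conf = torsion_minimize(conf, move_set, wm, max_iter=relax_iter)
        scaffold = conf.freeze_as_scaffold()
        score(scaffold, wm)
        if np.isfinite(scaffold.energy.total) and max_repulsion(scaffold) < 5.0:
            return scaffold
    raise RuntimeError(f"no clash-free {topology} scaffold found for seed {seed} "
                       f"after {max_attempts} attempts")


@dataclass
class RecoveryProblem:
    """A loop-rebuilding problem plus its planted answer."""

    problem: Conformation     # loop residues and all side-chains stripped
    answer: Conformation      # native: loop closed, polished local optimum
    loop: tuple[int, int]
    sequence: str


def strip_sidechains(conf: Conformation) -> Conformation:
    """Remove all side-chain atoms (benchmark input convention)."""
    new = conf.copy()
    keep = {"N", "CA", "C", "O", "H"}
    for r in list(new.residues):
        new.residues[r] = {n: p for n, p in new.residues[r].items() if n in keep}
        if r in new.chi:
            new.chi[r] = None
    new.touch()
    return new


def make_recovery_problem(scaffold: Conformation, loop_range: tuple[int, int],
                          polish_iters: int = 150, seed: int = 0
                          ) -> RecoveryProblem:
    """Excise a loop and plant its polished native conformation as answer.

    The native loop is minimized (all loop torsions and side-chains, linear
    chainbreak active) until it is a strong local optimum of the
    minimization-dialect energy; the problem conformation has the loop
    residues and every side-chain removed.
    """
    k, l = loop_range
    if k <= 1 or l >= scaffold.n:
        raise ValueError("loop at chain terminus")
    wm = minimization_weights().with_(linear_chainbreak=150.0)

    native = scaffold.copy()
    loop_tors = {r: dict(native.bb[r]) for r in range(k, l + 1)}
    loop_tors = {r: {n: (v if v is not None else
                         (native.measure_phi(r) if n == "phi" else
                          native.measure_psi(r) if n == "psi" else
                          native.measure_omega(r)))
                     for n, v in d.items()} for r, d in loop_tors.items()}
    loop_chi = {r: (list(native.chi[r]) if native.chi[r] is not None else
                    native.measure_chi(r))
                for r in range(k, l + 1)}
    native.set_loop(k, l, strip=True)
    c = (k + l) // 2
    for r in range(k, c + 1):
        native.append_residue(r, **{n: loop_tors[r][n] for n in ("phi", "psi", "omega")})
    for r in range(l, c, -1):
        native.prepend_residue(r, **{n: loop_tors[r][n] for n in ("phi", "psi", "omega")})
    native.mark_closed()
    for r in range(k, l + 1):
        if loop_chi[r]:
            native.set_chi(r, loop_chi[r])
    move_set = []
    for r in range(k, l + 1):
        move_set += movable_bb(native, r)
        move_set += [("chi", r, cc) for cc in range(native.topo(r).n_chi)]
    move_set.append(("bb", c + 1, "omega"))
    move_set = list(dict.fromkeys(move_set))
    native = torsion_minimize(native, move_set, wm, max_iter=polish_iters)
    native = torsion_minimize(native, move_set, wm, max_iter=polish_iters)

    problem = strip_sidechains(scaffold)
    problem.set_loop(k, l, strip=True)
    return RecoveryProblem(problem=problem, answer=native, loop=loop_range,
                           sequence=scaffold.sequence)
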