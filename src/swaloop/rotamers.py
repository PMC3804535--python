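"""Side-chain rotamer library, neighbor detection, rotamer trials, prepacking.

The library is a coarse backbone-independent set: canonical chi combinations
(gauche+/trans/gauche- for sp3 torsions, in-plane candidates for terminal
sp2 torsions) with a per-chi standard deviation, expanded by +/- 1 sigma
shifts of chi1 and chi2.  Side-chain optimization during loop building uses
stochastic one-at-a-time greedy replacement (rotamer trials); the initial
scaffold is prepared by a multi-sweep annealed version followed by
continuous chi minimization (prepacking).
"""

from __future__ import annotations

import functools
import itertools

import numpy as np

from . import topology as topo
from .energy import EnergyWeights, sampling_weights, score
from .geometry import Conformation
from .minimize import torsion_minimize
from .topology import residue_topology


class RotamerLibrary:
    """Per-residue-type chi-angle candidates with +/- 1 sigma expansions."""

    def __init__(self, chi_values: dict[str, list[list[float]]], sigma: float):
        self.chi_values = chi_values
        self.sigma = sigma

    @classmethod
    @functools.lru_cache(maxsize=1)
    def load(cls) -> "RotamerLibrary":
        raw = topo._load_yaml("rotamer_library.yaml")
        return cls({k: [list(map(float, vs)) for vs in v]
                    for k, v in raw["chi_values"].items()},
                   float(raw["sigma_default"]))

    def canonical(self, restype: str) -> list[tuple[float, ...]]:
        """Canonical rotamers; residues without chi yield one empty rotamer."""
        values = self.chi_values.get(restype)
        if not values:
            return [()]
        return [tuple(c) for c in itertools.product(*values)]

    def candidates(self, restype: str, expand: bool = True) -> list[tuple[float, ...]]:
        """Canonical rotamers plus +/- 1 sigma expansions of chi1 and chi2."""
        base = self.canonical(restype)
        if not expand or base == [()]:
            return base
        nchi = len(base[0])
        shifts1 = (-self.sigma, 0.0, self.sigma)
        shifts2 = shifts1 if nchi >= 2 else (0.0,)
        out = []
        seen = set()
        for rot in base:
            for s1 in shifts1:
                for s2 in shifts2:
                    cand = list(rot)
                    cand[0] += s1
                    if nchi >= 2:
                        cand[1] += s2
                    key = tuple(round(c, 3) for c in cand)
                    if key not in seen:
                        seen.add(key)
                        out.append(tuple(cand))
        return out


def _cb_or_ca(conf: Conformation, r: int) -> np.ndarray:
    res = conf.residues[r]
    return res.get("CB", res["CA"])


def neighbor_list(conf: Conformation, focus_residues, cutoff: float = 10.0,
                  repackable_only: bool = False) -> set[int]:
    """Residues whose C-beta (C-alpha for glycine) lies within ``cutoff`` of
    any focus residue's C-beta; always includes the focus residues."""
    focus = [r for r in focus_residues if r in conf.residues]
    out = set(focus)
    if not focus:
        return out
    fpos = np.array([_cb_or_ca(conf, r) for r in focus])
    for r in conf.residues:
        if r == 0 or r not in conf.kind or r in out:
            continue
        if repackable_only and conf.chi.get(r) is None:
            continue
        d = np.linalg.norm(fpos - _cb_or_ca(conf, r), axis=1)
        if (d < cutoff).any():
            out.add(r)
    return out


def _residue_local_energy(conf: Conformation, r: int, weights: EnergyWeights) -> float:
    return score(conf, weights, subset={r}).total


def rotamer_trials(conf: Conformation, residues, weights: EnergyWeights,
                   rng_seed: int | np.random.Generator = 0, sweeps: int = 2,
                   expand: bool = True) -> Conformation:
    """Greedy stochastic one-at-a-time rotamer replacement.

    Visits residues in seeded-random order for ``sweeps`` sweeps; each visit
    installs the candidate rotamer (canonical + expansions) of lowest energy
    in the current context.  Total energy is non-increasing across accepted
    replacements; bit-identical results for identical seeds.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    lib = RotamerLibrary.load()
    new = conf.copy()
    residues = [r for r in residues]
    for r in residues:
        if r not in new.residues:
            raise ValueError(f"residue {r} not built")
        if new.chi.get(r) is None:
            new.chi[r] = [180.0] * new.topo(r).n_chi
            new._build_sidechain(r)
            new.touch()
    packable = [r for r in residues if new.topo(r).n_chi > 0]
    for _ in range(sweeps):
        order = list(packable)
        rng.shuffle(order)
        for r in order:
            cands = lib.candidates(new.restype(r), expand=expand)
            best_chi = tuple(new.chi[r])
            best_e = _residue_local_energy(new, r, weights)
            for cand in cands:
                new.set_chi(r, cand)
                e = _residue_local_energy(new, r, weights)
                if e < best_e - 1e-12:
                    best_e = e
                    best_chi = cand
            new.set_chi(r, best_chi)
    score(new, weights)
    return new


def prepack(conf: Conformation, weights: EnergyWeights | None = None,
            rng_seed: int = 0, sweeps: int = 20,
            minimize_iter: int = 50) -> Conformation:
    """Place and optimize all scaffold side-chains before loop building.

    Missing side-chains are built from ideal geometry; a simulated-annealing
    schedule of stochastic rotamer sweeps (Metropolis acceptance at
    decreasing temperature, then greedy sweeps) optimizes the assignment,
    and a final continuous chi minimization relaxes off-rotamer strain.
    The backbone never moves.
    """
    weights = weights or sampling_weights()
    rng = np.random.default_rng(rng_seed)
    lib = RotamerLibrary.load()
    new = conf.copy()
    residues = [r for r in sorted(new.residues)
                if r != 0 and r in new.kind]
    for r in residues:
        if new.chi.get(r) is None:
            new.chi[r] = [180.0] * new.topo(r).n_chi
            new._build_sidechain(r)
            new.touch()
    packable = [r for r in residues if new.topo(r).n_chi > 0]
    if not packable:
        score(new, weights)
        return new

    n_anneal = max(sweeps - 2, 0)
    temps = np.geomspace(2.0, 0.05, n_anneal) if n_anneal else []
    for it, temp in enumerate(list(temps) + [0.0, 0.0]):
        order = list(packable)
        rng.shuffle(order)
        for r in order:
            cands = lib.candidates(new.restype(r))
            cur_chi = tuple(new.chi[r])
            cur_e = _residue_local_energy(new, r, weights)
            if temp > 0.0:
                cand = cands[rng.integers(len(cands))]
                new.set_chi(r, cand)
                e = _residue_local_energy(new, r, weights)
                if e <= cur_e or rng.random() < np.exp(-(e - cur_e) / temp):
                    continue
                new.set_chi(r, cur_chi)
            else:
                best_chi, best_e = cur_chi, cur_e
                for cand in cands:
                    new.set_chi(r, cand)
                    e = _residue_local_energy(new, r, weights)
                    if e < best_e - 1e-12:
                        best_e, best_chi = e, cand
                new.set_chi(r, best_chi)
    move_set = [("chi", r, k) for r in packable
                for k in range(new.topo(r).n_chi)]
    new = torsion_minimize(new, move_set, weights, max_iter=minimize_iter)
    return new
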