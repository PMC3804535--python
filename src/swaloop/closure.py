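"""Chain closure: bridge the N- and C-terminal fragments into a whole loop.

A stage (i, j) with 1-3 gap residues is closed by appending/prepending the
gap residues, grid-sampling (phi, psi) of one designated end gap residue,
and running cyclic coordinate descent (CCD) on the remaining bridge
torsions.  Each CCD update sets one torsion to the analytic angle minimizing
the summed squared deviation of the three virtual/real closure atom pairs.
Closures whose deviation metric (RMS over the three pairs) reaches 1.5 A or
more are discarded; survivors get full-loop side-chain optimization,
clustering, and full-loop torsional minimization with the linear chainbreak
penalty at weight 150, which typically drives final closure deviations
below 0.01 A.
"""

from __future__ import annotations

import math

import numpy as np

from .buildup import (GridSpec, StageEnsemble, backbone_atoms, cluster_fine,
                      enumerate_backbone_grid, movable_bb, _sample_specs)
from .energy import EnergyWeights, minimization_weights, sampling_weights, score
from .geometry import Conformation
from .minimize import torsion_minimize
from .rotamers import neighbor_list, rotamer_trials

CHAINBREAK_WEIGHT = 150.0


# ----------------------------------------------------------------------- CCD


class _CcdModel:
    """Minimal working model for CCD: backbone (and virtual closure) atoms
    of the gap region as a coordinate table, with per-torsion moving sets.

    Rotating a torsion applies a rigid rotation to its downstream atoms,
    which is exactly what rebuilding from torsions would do, so the final
    torsions can simply be measured back off the table.
    """

    def __init__(self, conf: Conformation, torsions: list[tuple[int, str]]):
        self.c = conf.cutpoint
        self.torsions = torsions
        c = self.c
        n_res = [r for r, _ in torsions if r <= c]
        c_res = [r for r, _ in torsions if r > c]
        lo = min(n_res) - 1 if n_res else c - 1
        hi = max(max(c_res) + 1 if c_res else c + 1, c + 1)
        hi = min(hi, conf.loop[1] + 1)
        self.coords: dict[tuple[int, str], np.ndarray] = {}
        for r in range(lo, hi + 1):
            if r not in conf.residues:
                continue
            for nm in ("N", "CA", "C"):
                if nm in conf.residues[r]:
                    self.coords[(r, nm)] = conf.atom(r, nm).copy()
        self.coords[(c, "VN")] = conf.atom(c, "VN").copy()
        self.coords[(c, "VCA")] = conf.atom(c, "VCA").copy()
        self.coords[(c + 1, "VC")] = conf.atom(c + 1, "VC").copy()

    def _moves(self, key: tuple[int, str], r: int, name: str) -> bool:
        c = self.c
        s, nm = key
        if nm == "VC":
            return r > c and (r > c + 1 or r == c + 1)
        virtual_n = nm in ("VN", "VCA")
        on_n_side = s <= c
        if r <= c:  # N-side torsion
            if not on_n_side:
                return False
            if virtual_n:
                return True
            if s > r:
                return True
            if s == r:
                return name == "phi" and nm == "C"
            return False
        # C-side torsion (downstream = toward the cutpoint / N direction)
        if on_n_side:
            return False
        if s < r:
            return True
        if s == r:
            return name == "psi" and nm == "N"
        return False

    def deviation_sq(self) -> float:
        c = self.c
        d = 0.0
        for a, b in (((c, "VN"), (c + 1, "N")), ((c, "VCA"), (c + 1, "CA")),
                     ((c + 1, "VC"), (c, "C"))):
            diff = self.coords[a] - self.coords[b]
            d += float(diff @ diff)
        return d

    def deviation(self) -> float:
        return math.sqrt(self.deviation_sq() / 3.0)

    def update(self, r: int, name: str) -> None:
        """Set torsion (r, name) to its analytically optimal angle."""
        c = self.c
        if name == "phi":
            p1, p2 = self.coords[(r, "N")], self.coords[(r, "CA")]
        else:
            p1, p2 = self.coords[(r, "CA")], self.coords[(r, "C")]
        u = p2 - p1
        u = u / np.linalg.norm(u)
        pairs = (((c, "VN"), (c + 1, "N")), ((c, "VCA"), (c + 1, "CA")),
                 ((c + 1, "VC"), (c, "C")))
        b_coef = c_coef = 0.0
        for a1, a2 in pairs:
            m1 = self._moves(a1, r, name)
            m2 = self._moves(a2, r, name)
            if m1 == m2:
                continue
            m, f = (a1, a2) if m1 else (a2, a1)
            v = self.coords[m] - p1
            w = self.coords[f] - p1
            v_par = u * float(u @ v)
            v_perp = v - v_par
            t_vec = np.cross(u, v)
            b_coef += 2.0 * float((v_par - w) @ v_perp)
            c_coef += 2.0 * float((v_par - w) @ t_vec)
        if math.hypot(b_coef, c_coef) < 1e-12:
            return
        theta = math.atan2(-c_coef, -b_coef)
        ct, st = math.cos(theta), math.sin(theta)
        for key in self.coords:
            if self._moves(key, r, name):
                v = self.coords[key] - p1
                v_par = u * float(u @ v)
                v_perp = v - v_par
                self.coords[key] = (p1 + v_par + v_perp * ct
                                    + np.cross(u, v_perp) * st)

    def measured_torsions(self) -> dict[tuple[int, str], float]:
        from .geometry import dihedral as _dih

        c = self.c
        out = {}
        for r, name in self.torsions:
            if name == "phi":
                prev_c = self.coords[(r, "VC")] if r == c + 1 \
                    else self.coords[(r - 1, "C")]
                out[(r, name)] = _dih(prev_c, self.coords[(r, "N")],
                                      self.coords[(r, "CA")], self.coords[(r, "C")])
            else:
                next_n = self.coords[(c, "VN")] if r == c \
                    else self.coords[(r + 1, "N")]
                out[(r, name)] = _dih(self.coords[(r, "N")], self.coords[(r, "CA")],
                                      self.coords[(r, "C")], next_n)
        return out


def ccd_close(conf: Conformation, bridge_torsions: list[tuple[int, str]],
              max_cycles: int = 1000, tol: float = 1e-4
              ) -> tuple[Conformation, float]:
    """Cyclic coordinate descent over ``bridge_torsions`` (list of
    (residue, "phi"|"psi")), cycling N-to-C until the closure deviation (RMS
    over the three virtual/real atom pairs) drops below ``tol`` or
    ``max_cycles`` is reached.  Only the listed torsions move; every
    per-torsion update is the analytic optimum, so the deviation never
    increases across an update."""
    if not conf.closed:
        raise ValueError("no cutpoint set")
    if not bridge_torsions:
        raise ValueError("empty bridge torsion list")
    model = _CcdModel(conf, bridge_torsions)
    dev = model.deviation()
    for _cycle in range(max_cycles):
        if dev < tol:
            break
        start_dev = dev
        for r, name in bridge_torsions:
            model.update(r, name)
        dev = model.deviation()
        if start_dev - dev < 1e-9:
            break
    new = conf.copy()
    changed = False
    for (r, name), val in model.measured_torsions().items():
        if abs(val - new.bb[r][name]) > 1e-12:
            new.bb[r][name] = val
            changed = True
    if changed:
        new.rebuild("both")
    return new, new.closure_deviation()


# ------------------------------------------------------------ stage closure


def _build_closed(parent: Conformation, sampling_end: str
                  ) -> tuple[Conformation, int, list[tuple[int, str]]]:
    """Append/prepend gap residues, mark the cutpoint, and return
    (closed conformation, sampled residue, CCD torsion list)."""
    i, j = parent.nfrag_end, parent.cfrag_start
    gap = j - i - 1
    if not 1 <= gap <= 3:
        raise ValueError(f"gap {gap} outside 1-3")
    conf = parent.copy()
    if gap == 1:
        sampling_end = "first"  # the two protocol variants coincide
    if sampling_end == "first":
        conf.append_residue(i + 1)
        for r in range(j - 1, i + 1, -1):
            conf.prepend_residue(r)
        conf.mark_closed()
        c = i + 1
        sampled = i + 1
        ccd_set: list[tuple[int, str]] = [(c, "psi")]
        for r in range(c + 1, j):
            if conf.restype(r) != "PRO":
                ccd_set.append((r, "phi"))
            ccd_set.append((r, "psi"))
        if j <= conf.loop[1] and conf.restype(j) != "PRO":
            ccd_set.append((j, "phi"))
    elif sampling_end == "last":
        conf.prepend_residue(j - 1)
        for r in range(i + 1, j - 1):
            conf.append_residue(r)
        conf.mark_closed()
        sampled = j - 1
        ccd_set = [(i, "psi")] if parent.sample_loop_takeoff or i >= parent.loop[0] else []
        for r in range(i + 1, j - 1):
            if conf.restype(r) != "PRO":
                ccd_set.append((r, "phi"))
            ccd_set.append((r, "psi"))
        if not ccd_set:
            ccd_set = [(i + 1, "psi")]
    else:
        raise ValueError("sampling_end must be 'first' or 'last'")
    return conf, sampled, ccd_set


def close_candidates(parent: Conformation, sampling_end: str, spec: GridSpec,
                     weights: EnergyWeights, screen: float = 1.5,
                     max_cycles: int = 1000, tol: float = 1e-4
                     ) -> list[tuple[Conformation, float]]:
    """Grid-sample the designated end gap residue and CCD-close the rest;
    return (model, deviation) pairs passing the closure screen."""
    base, sampled, ccd_set = _build_closed(parent, sampling_end)
    assignments = enumerate_backbone_grid(spec, _sample_specs(base, [sampled], spec))
    out = []
    for assign in assignments:
        work = base.copy()
        for (r, name), val in assign.items():
            work.bb[r][name] = val
        work.rebuild("both")
        closed, dev = ccd_close(work, ccd_set, max_cycles=max_cycles, tol=tol)
        if dev < screen:
            score(closed, weights)
            out.append((closed, dev))
    return out


def reclose(conf: Conformation, max_cycles: int = 200,
            tol: float = 1e-4) -> Conformation:
    """CCD over every movable loop phi/psi to re-tighten the chainbreak of a
    formally closed model (used before chainbreak-weighted minimization,
    which then maintains closure)."""
    if not conf.closed or conf.closure_deviation() < tol:
        return conf
    c = conf.cutpoint
    k, l = conf.loop
    tors: list[tuple[int, str]] = []
    for r in range(k, l + 1):
        if conf.restype(r) != "PRO":
            tors.append((r, "phi"))
        tors.append((r, "psi"))
    closed, _dev = ccd_close(conf, tors, max_cycles=max_cycles, tol=tol)
    return closed


def optimize_closed(models: list[Conformation], weights_sampling: EnergyWeights,
                    weights_min: EnergyWeights, rng_seed: int = 0,
                    keep: int = 400, fine_radius: float = 0.10,
                    neighbor_cutoff: float = 10.0, rotamer_sweeps: int = 2,
                    minimize_iter: int = 60) -> list[Conformation]:
    """Full-loop side-chain optimization, clustering and torsional
    minimization (chainbreak active) of closed models.

    Raw closed candidates are clustered first so that the expensive
    pack-and-minimize step touches at most 2 x ``keep`` distinct backbones.
    """
    if not models:
        return []
    rng = np.random.default_rng(rng_seed)
    ws = weights_sampling.with_(linear_chainbreak=CHAINBREAK_WEIGHT)
    wm = weights_min.with_(linear_chainbreak=CHAINBREAK_WEIGHT)
    atoms = backbone_atoms(models[0].loop_residues())
    pre = cluster_fine(models, atoms, fine_radius, 2 * keep)
    packed = []
    for m in pre.models:
        loop_res = m.loop_residues()
        pack_set = sorted(neighbor_list(m, loop_res, neighbor_cutoff,
                                        repackable_only=True))
        mm = rotamer_trials(m, pack_set, ws, rng_seed=int(rng.integers(2 ** 31)),
                            sweeps=rotamer_sweeps)
        packed.append(mm)
    out = []
    for m in packed:
        m = reclose(m)
        move_set = []
        for r in m.loop_residues():
            move_set += movable_bb(m, r)
        move_set.append(("bb", m.cutpoint + 1, "omega"))
        pack_set = sorted(neighbor_list(m, m.loop_residues(), neighbor_cutoff,
                                        repackable_only=True))
        for r in pack_set:
            move_set += [("chi", r, c) for c in range(m.topo(r).n_chi)]
        # deduplicate (omega of cutpoint+1 may already be in the loop set)
        move_set = list(dict.fromkeys(move_set))
        mm = torsion_minimize(m, move_set, wm, max_iter=minimize_iter)
        out.append(mm)
    return cluster_fine(out, atoms, fine_radius, keep).models


def close_from_stage(ensemble: StageEnsemble, gap_sampling_end: str = "first",
                     spec: GridSpec | None = None,
                     weights_sampling: EnergyWeights | None = None,
                     weights_min: EnergyWeights | None = None,
                     rng_seed: int = 0, screen: float = 1.5,
                     max_cycles: int = 1000, tol: float = 1e-4,
                     keep: int = 400, max_parents: int | None = None,
                     **opt_kw) -> list[Conformation]:
    """Close every model of a stage ensemble with 1-3 gap residues."""
    spec = spec or GridSpec()
    ws = weights_sampling or sampling_weights()
    wm = weights_min or minimization_weights()
    models = ensemble.models
    if max_parents is not None:
        models = models[:max_parents]
    ws_break = ws.with_(linear_chainbreak=CHAINBREAK_WEIGHT)
    closed: list[Conformation] = []
    for parent in models:
        for m, _dev in close_candidates(parent, gap_sampling_end, spec,
                                        ws_break, screen=screen,
                                        max_cycles=max_cycles, tol=tol):
            closed.append(m)
    return optimize_closed(closed, ws, wm, rng_seed=rng_seed, keep=keep,
                           **opt_kw)


def merge_fragments(na: Conformation, cb: Conformation) -> Conformation:
    """Combine the N-fragment of one model with the C-fragment of another
    (same scaffold); scaffold side-chains are taken from the first."""
    merged = na.copy()
    for r in range(cb.cfrag_start, cb.loop[1] + 1):
        merged.bb[r] = dict(cb.bb[r])
        merged.chi[r] = list(cb.chi[r]) if cb.chi[r] is not None else None
        merged.kind[r] = "cfrag"
    merged.cfrag_start = cb.cfrag_start
    gap = merged.cfrag_start - merged.nfrag_end - 1
    if not 1 <= gap <= 3:
        raise ValueError("incompatible stages: combined gap outside 1-3")
    merged.rebuild("c")
    return merged


def recombine_candidates(ens_n: StageEnsemble, ens_c: StageEnsemble,
                         spec: GridSpec, weights_break: EnergyWeights,
                         max_pairs: int = 10000, screen: float = 1.5,
                         max_cycles: int = 1000, tol: float = 1e-4
                         ) -> list[Conformation]:
    """Screened closure candidates from Cartesian fragment pairing, capped
    at ``max_pairs`` pairs ranked by summed fragment energies."""
    if len(ens_n) == 0 or len(ens_c) == 0:
        return []
    e_n = ens_n.energies()
    e_c = ens_c.energies()
    pairs = [(float(e_n[a] + e_c[b]), a, b)
             for a in range(len(ens_n)) for b in range(len(ens_c))]
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))
    pairs = pairs[:max_pairs]
    closed: list[Conformation] = []
    for _e, a, b in pairs:
        merged = merge_fragments(ens_n.models[a], ens_c.models[b])
        for m, _dev in close_candidates(merged, "first", spec, weights_break,
                                        screen=screen, max_cycles=max_cycles,
                                        tol=tol):
            closed.append(m)
    return closed


def recombine_fragments(ens_n: StageEnsemble, ens_c: StageEnsemble,
                        spec: GridSpec | None = None,
                        weights_sampling: EnergyWeights | None = None,
                        weights_min: EnergyWeights | None = None,
                        rng_seed: int = 0, max_pairs: int = 10000,
                        screen: float = 1.5, max_cycles: int = 1000,
                        tol: float = 1e-4, keep: int = 400,
                        **opt_kw) -> list[Conformation]:
    """Pair pure-N-fragment models with pure-C-fragment models and close
    each merged model through the standard gap-closure machinery."""
    spec = spec or GridSpec()
    ws = weights_sampling or sampling_weights()
    wm = weights_min or minimization_weights()
    ws_break = ws.with_(linear_chainbreak=CHAINBREAK_WEIGHT)
    closed = recombine_candidates(ens_n, ens_c, spec, ws_break,
                                  max_pairs=max_pairs, screen=screen,
                                  max_cycles=max_cycles, tol=tol)
    return optimize_closed(closed, ws, wm, rng_seed=rng_seed, keep=keep,
                           **opt_kw)
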