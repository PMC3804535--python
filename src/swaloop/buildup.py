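"""The core stepwise-assembly move: add one residue, enumerate its backbone.

Each growth step appends (N-fragment) or prepends (C-fragment) a capped
residue, enumerates (phi, psi) for the new residue and its fragment-adjacent
neighbor on a grid (default 20 degrees, 18 samples per torsion), discards
assignments whose backbone-torsion score exceeds the filter threshold
(default 0.8 units), optimizes nearby side-chains by rotamer trials under
the soft sampling weights, fine-clusters at 0.10 A over the rebuilt backbone
atoms, keeps the lowest 400, minimizes each survivor under the standard
weights, and fine-clusters again.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy import EnergyWeights, minimization_weights, rama_score, sampling_weights, score
from .geometry import Conformation
from .minimize import torsion_minimize
from .rotamers import neighbor_list, rotamer_trials


@dataclass(frozen=True)
class GridSpec:
    """Backbone grid-search settings."""

    torsion_step: float = 20.0
    rama_cutoff: float = 0.8
    sample_adjacent: bool = True
    cis_preproline: bool = True

    def __post_init__(self):
        if abs(360.0 / self.torsion_step - round(360.0 / self.torsion_step)) > 1e-9:
            raise ValueError("torsion step must divide 360")

    @property
    def n_sample(self) -> int:
        return int(round(360.0 / self.torsion_step))

    def grid(self) -> np.ndarray:
        """Samples at -180, -180+step, ..., 180-step (left-inclusive)."""
        return np.arange(-180.0, 180.0 - 1e-9, self.torsion_step)


@dataclass(frozen=True)
class SampleSpec:
    """One residue's enumerated degrees of freedom."""

    res: int
    restype: str
    next_is_pro: bool = False
    sample_phi: bool = True
    sample_psi: bool = True
    phi_fixed: float | None = None      # proline: phi pinned near -65
    omega_res: int | None = None        # residue whose omega is enumerated
    omega_values: tuple[float, ...] = (180.0,)


def enumerate_backbone_grid(spec: GridSpec, residues: list[SampleSpec]
                            ) -> list[dict[tuple[int, str], float]]:
    """Rama-filtered Cartesian product of per-residue (phi, psi) grids.

    Returns a deterministic, grid-ordered list of torsion assignments
    {(residue, torsion_name): value}.  Assignments in which any sampled
    residue's (phi, psi) scores above ``rama_cutoff`` are discarded.
    """
    grid = spec.grid()
    per_res: list[list[dict]] = []
    for rs in residues:
        phis = ([rs.phi_fixed] if rs.phi_fixed is not None
                else (grid if rs.sample_phi else [None]))
        psis = grid if rs.sample_psi else [None]
        entries = []
        for phi in phis:
            for psi in psis:
                if phi is not None and psi is not None:
                    if rama_score(rs.restype, phi, psi, rs.next_is_pro) > spec.rama_cutoff:
                        continue
                d = {}
                if phi is not None:
                    d[(rs.res, "phi")] = float(phi)
                if psi is not None:
                    d[(rs.res, "psi")] = float(psi)
                entries.append(d)
        if rs.omega_res is not None and len(rs.omega_values) > 1:
            expanded = []
            for e in entries:
                for om in rs.omega_values:
                    d2 = dict(e)
                    d2[(rs.omega_res, "omega")] = float(om)
                    expanded.append(d2)
            entries = expanded
        per_res.append(entries)
    out: list[dict] = []

    def _recurse(i: int, acc: dict):
        if i == len(per_res):
            out.append(dict(acc))
            return
        for e in per_res[i]:
            acc.update(e)
            _recurse(i + 1, acc)
            for k in e:
                acc.pop(k, None)

    _recurse(0, {})
    return out


@dataclass
class StageEnsemble:
    """Energy-sorted, clustered set of models at one build-up stage."""

    models: list[Conformation] = field(default_factory=list)
    stage: object = None

    def __len__(self) -> int:
        return len(self.models)

    def energies(self) -> np.ndarray:
        return np.array([m.energy.total for m in self.models])


def _model_coords(model: Conformation, atoms: list[tuple[int, str]]) -> np.ndarray:
    return np.array([model.atom(r, n) for r, n in atoms])


def cluster_fine(models: list[Conformation], rmsd_atoms: list[tuple[int, str]],
                 radius: float = 0.10, keep: int = 400,
                 stage=None) -> StageEnsemble:
    """Greedy energy-ordered leader clustering without superposition.

    Models are visited lowest energy first; a model within ``radius`` RMSD
    (over ``rmsd_atoms``, raw coordinates -- the scaffold frame is shared)
    of an already-kept model is discarded, otherwise it seeds a new cluster.
    At most ``keep`` models are returned, energy-sorted; the lowest-energy
    model is always retained.
    """
    if not models:
        return StageEnsemble([], stage)
    if not rmsd_atoms:
        raise ValueError("empty cluster atom selection")
    energies = np.array([m.energy.total for m in models])
    order = np.argsort(energies, kind="stable")
    coords = np.array([_model_coords(models[i], rmsd_atoms) for i in order])
    kept_idx: list[int] = []
    kept_coords: list[np.ndarray] = []
    for pos in range(len(order)):
        if len(kept_idx) >= keep:
            break
        c = coords[pos]
        if kept_coords:
            diffs = np.stack(kept_coords) - c[None]
            rms = np.sqrt((diffs ** 2).sum(axis=2).mean(axis=1))
            if (rms < radius).any():
                continue
        kept_idx.append(int(order[pos]))
        kept_coords.append(c)
    return StageEnsemble([models[i] for i in kept_idx], stage)


def backbone_atoms(residues, names=("N", "C", "CA", "O")) -> list[tuple[int, str]]:
    return [(r, n) for r in residues for n in names]


def movable_bb(conf: Conformation, r: int, include_omega: bool = True
               ) -> list[tuple[str, int, str]]:
    """Backbone move-set entries for one residue (proline phi stays pinned)."""
    names = ["psi"]
    if conf.restype(r) != "PRO":
        names.insert(0, "phi")
    if include_omega:
        names.append("omega")
    return [("bb", r, n) for n in names]


def _sample_specs(conf: Conformation, residues: list[int],
                  grid: GridSpec) -> list[SampleSpec]:
    specs = []
    for r in residues:
        t = conf.restype(r)
        next_is_pro = r < conf.n and conf.sequence[r] == "P"
        omega_res = None
        omega_values: tuple[float, ...] = (180.0,)
        if grid.cis_preproline and t == "PRO":
            omega_res = r          # the peptide bond preceding this proline
            omega_values = (180.0, 0.0)
        specs.append(SampleSpec(
            res=r, restype=t, next_is_pro=next_is_pro,
            phi_fixed=-65.0 if t == "PRO" else None,
            omega_res=omega_res, omega_values=omega_values))
    return specs


def grow_step(ensemble_in: StageEnsemble, direction: str, spec: GridSpec,
              weights_sampling: EnergyWeights | None = None,
              weights_min: EnergyWeights | None = None,
              rng_seed: int = 0, keep: int = 400, fine_radius: float = 0.10,
              neighbor_cutoff: float = 10.0, rotamer_sweeps: int = 2,
              minimize_iter: int = 50) -> list[Conformation]:
    """Grow every parent model by one residue in the given direction.

    ``direction`` is ``"N"`` (append after the N-fragment) or ``"C"``
    (prepend before the C-fragment).  Returns the minimized, fine-clustered
    candidate list for the next stage.
    """
    if direction not in ("N", "C"):
        raise ValueError("direction must be 'N' or 'C'")
    ws = weights_sampling or sampling_weights()
    wm = weights_min or minimization_weights()
    rng = np.random.default_rng(rng_seed)
    if len(ensemble_in) == 0:
        return []

    candidates: list[Conformation] = []
    for parent in ensemble_in.models:
        k, l = parent.loop
        if direction == "N":
            new_res = parent.nfrag_end + 1
            adjacent = new_res - 1 if new_res - 1 >= k else None
        else:
            new_res = parent.cfrag_start - 1
            adjacent = new_res + 1 if new_res + 1 <= l else None
        base = parent.copy()
        if direction == "N":
            base.append_residue(new_res)
        else:
            base.prepend_residue(new_res)
        sampled = [new_res]
        if spec.sample_adjacent and adjacent is not None:
            sampled.append(adjacent)
        assignments = enumerate_backbone_grid(spec, _sample_specs(base, sampled, spec))
        focus = set(sampled)
        for gi, assign in enumerate(assignments):
            work = base.copy()
            for (r, name), val in assign.items():
                work.bb[r][name] = val
            work.rebuild("n" if direction == "N" else "c")
            pack_set = sorted(neighbor_list(work, focus, neighbor_cutoff,
                                            repackable_only=True))
            work = rotamer_trials(work, pack_set, ws,
                                  rng_seed=int(rng.integers(2 ** 31)),
                                  sweeps=rotamer_sweeps)
            candidates.append(work)

    cluster_atoms = None
    out: list[Conformation] = []
    if candidates:
        # cluster over backbone atoms of the residues rebuilt at this step
        first = candidates[0]
        k, l = first.loop
        if direction == "N":
            sampled_res = [first.nfrag_end]
            if spec.sample_adjacent and first.nfrag_end - 1 >= k:
                sampled_res.append(first.nfrag_end - 1)
        else:
            sampled_res = [first.cfrag_start]
            if spec.sample_adjacent and first.cfrag_start + 1 <= l:
                sampled_res.append(first.cfrag_start + 1)
        cluster_atoms = backbone_atoms(sorted(set(sampled_res)))
        pre = cluster_fine(candidates, cluster_atoms, fine_radius, keep)
        for m in pre.models:
            move_set = []
            for r in sampled_res:
                move_set += movable_bb(m, r)
            pack_set = sorted(neighbor_list(m, set(sampled_res), neighbor_cutoff,
                                            repackable_only=True))
            for r in pack_set:
                move_set += [("chi", r, c) for c in range(m.topo(r).n_chi)]
            mm = torsion_minimize(m, move_set, wm, max_iter=minimize_iter)
            out.append(mm)
        out = cluster_fine(out, cluster_atoms, fine_radius, keep).models
    return out
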