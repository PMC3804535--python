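"""Metrics and reference protocols.

RMSD calculators (raw coordinates -- the scaffold frame is shared, so no
superposition is ever applied), loop-environment descriptors, native-loop
optimization baselines, and energy-vs-RMSD reporting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .buildup import StageEnsemble, movable_bb
from .config import RunConfig
from .energy import minimization_weights, sampling_weights, score, _flat
from .geometry import Conformation
from .minimize import torsion_minimize
from .rotamers import neighbor_list, rotamer_trials

_BB_SET = {"N", "C", "CA", "CB", "O"}


def ca_rmsd(model: Conformation, reference: Conformation,
            loop_range: tuple[int, int]) -> float:
    """Root-mean-square C-alpha deviation over the loop, no superposition."""
    k, l = loop_range
    diffs = []
    for r in range(k, l + 1):
        if not model.has_atom(r, "CA"):
            raise ValueError(f"missing CA at residue {r}")
        diffs.append(model.atom(r, "CA") - reference.atom(r, "CA"))
    d = np.array(diffs)
    return float(np.sqrt((d ** 2).sum(axis=1).mean()))


def backbone_rmsd(model: Conformation, reference: Conformation,
                  residues, atoms=("N", "CA", "C", "O")) -> float:
    """Backbone RMSD over the given residues (those built in the model)."""
    diffs = []
    for r in residues:
        for a in atoms:
            if model.has_atom(r, a) and reference.has_atom(r, a):
                diffs.append(model.atom(r, a) - reference.atom(r, a))
    if not diffs:
        return 0.0
    d = np.array(diffs)
    return float(np.sqrt((d ** 2).sum(axis=1).mean()))


def loop_descriptors(conf: Conformation, loop_range: tuple[int, int]) -> dict:
    """Loop-environment statistics, averaged per loop residue.

    Non-hydrogen atoms only; for every loop residue, residues within two
    sequence positions are excluded from its partner set.  N_contact counts
    partner residues with any atom-atom contact closer than 4.0 A; N_out
    restricts partners to non-loop residues; N_SC counts partners whose
    contact involves an atom needing side-chain placement (not N, C, CA,
    CB, O); N_HB counts donor/acceptor pairs closer than 3.2 A.
    """
    k, l = loop_range
    flat = _flat(conf)
    heavy = ~flat.is_h
    donors_h = {d for d, _ in flat.donors}
    acceptors = set(int(a) for a in flat.acceptors)
    loop_res = list(range(k, l + 1))
    n_contact = n_out = n_sc = n_hb = 0
    for lr in loop_res:
        lmask = (flat.res == lr) & heavy
        pmask_res = np.array([abs(rr - lr) > 2 for rr in flat.res])
        pmask = pmask_res & heavy
        li = np.flatnonzero(lmask)
        pi = np.flatnonzero(pmask)
        if li.size == 0 or pi.size == 0:
            continue
        d = np.linalg.norm(flat.xyz[li][:, None] - flat.xyz[pi][None], axis=2)
        contact = d < 4.0
        partners = {}
        for a_idx, b_idx in zip(*np.nonzero(contact)):
            rr = int(flat.res[pi[b_idx]])
            sc = (flat.names[li[a_idx]] not in _BB_SET
                  or flat.names[pi[b_idx]] not in _BB_SET)
            prev = partners.get(rr, False)
            partners[rr] = prev or sc
        n_contact += len(partners)
        n_out += sum(1 for rr in partners if not k <= rr <= l)
        n_sc += sum(1 for rr, sc in partners.items() if sc)
        # hydrogen bonds: donor/acceptor heavy-atom pairs < 3.2 A
        for a_idx in li:
            ai = int(a_idx)
            partner_ok = {int(p) for p in pi}
            if ai in donors_h or ai in acceptors:
                for bi in partner_ok:
                    if bi == ai:
                        continue
                    pair_da = (ai in donors_h and bi in acceptors) or \
                              (ai in acceptors and bi in donors_h)
                    if not pair_da:
                        continue
                    if np.linalg.norm(flat.xyz[ai] - flat.xyz[bi]) < 3.2:
                        n_hb += 1
    n = len(loop_res)
    return {"N_contact": n_contact / n, "N_out": n_out / n,
            "N_SC": n_sc / n, "N_HB": n_hb / n}


# ------------------------------------------------- native-loop optimization


def _graft_native_loop(scaffold_like: Conformation, native: Conformation,
                       loop_range: tuple[int, int], cutpoint: int) -> Conformation:
    """Rebuild the native loop with ideal geometry onto a (pre-packed)
    scaffold, formally broken at ``cutpoint``."""
    k, l = loop_range
    conf = scaffold_like.copy()
    tors = {}
    for r in range(k, l + 1):
        tors[r] = {
            "phi": native.bb[r]["phi"] if native.bb[r]["phi"] is not None
            else native.measure_phi(r),
            "psi": native.bb[r]["psi"] if native.bb[r]["psi"] is not None
            else native.measure_psi(r),
            "omega": native.bb[r]["omega"] if native.bb[r]["omega"] is not None
            else (native.measure_omega(r) or 180.0),
        }
    chis = {r: (list(native.chi[r]) if native.chi[r] else native.measure_chi(r))
            for r in range(k, l + 1)}
    conf.set_loop(k, l, strip=True)
    for r in range(k, cutpoint + 1):
        conf.append_residue(r, **tors[r])
    for r in range(l, cutpoint, -1):
        conf.prepend_residue(r, **tors[r])
    conf.mark_closed()
    for r in range(k, l + 1):
        if chis[r]:
            conf.set_chi(r, chis[r])
    return conf


def optimize_native(conf_native_loop: Conformation, loop_range: tuple[int, int],
                    strategy: str = "idealize_optimize",
                    config: RunConfig | None = None, n_runs: int = 20,
                    scaffold: Conformation | None = None) -> StageEnsemble:
    """Reference protocols estimating the energy of the native loop.

    ``idealize_optimize``: rebuild the native loop with ideal internal
    coordinates, graft it onto the scaffold, repack and fully minimize, for
    every chainbreak placement (before the loop and after each loop residue)
    times ``n_runs`` seeds.  ``native_constrained_swa``: a full stepwise
    run with a 2.0 A backbone-RMSD screen at every retention step and the
    C-alpha fade restraints active.  Both return energy-ranked ensembles.
    """
    config = config or RunConfig()
    k, l = loop_range
    for r in range(k, l + 1):
        if r not in conf_native_loop.residues:
            raise ValueError(f"reference missing loop residue {r}")
    wm = minimization_weights(**config.energy.minimization_overrides) \
        .with_(linear_chainbreak=config.closure.chainbreak_weight)
    ws = sampling_weights(**config.energy.sampling_overrides)
    base = scaffold if scaffold is not None else conf_native_loop

    if strategy == "idealize_optimize":
        models = []
        for c in range(k - 1, l):
            for run_idx in range(n_runs):
                seed = (config.seed * 97 + 131 * c + run_idx) % (2 ** 31)
                m = _graft_native_loop(base, conf_native_loop, loop_range, c)
                pack_set = sorted(neighbor_list(
                    m, m.loop_residues(), config.sampling.neighbor_cutoff,
                    repackable_only=True))
                m = rotamer_trials(m, pack_set, ws, rng_seed=seed,
                                   sweeps=config.sampling.rotamer_sweeps)
                move_set = []
                for r in m.loop_residues():
                    move_set += movable_bb(m, r)
                move_set.append(("bb", m.cutpoint + 1, "omega"))
                for r in pack_set:
                    move_set += [("chi", r, cc) for cc in range(m.topo(r).n_chi)]
                move_set = list(dict.fromkeys(move_set))
                m = torsion_minimize(m, move_set, wm,
                                     max_iter=config.minimize.final_polish_iter)
                models.append(m)
        models.sort(key=lambda m: m.energy.total)
        return StageEnsemble(models, None)

    if strategy == "native_constrained_swa":
        from .dag import run_pipeline

        cfg = config.model_copy(deep=True)
        cfg.native.rmsd_screen = cfg.native.rmsd_screen or 2.0
        cfg.native.constrain_ca = True
        cfg.energy.sampling_overrides = dict(cfg.energy.sampling_overrides,
                                             coordinate_constraint=1.0)
        cfg.energy.minimization_overrides = dict(cfg.energy.minimization_overrides,
                                                 coordinate_constraint=1.0)
        problem = base.copy()
        preds, _report = run_pipeline(problem, loop_range, cfg,
                                      native_ref=conf_native_loop)
        return preds

    raise ValueError(f"unknown strategy {strategy!r}")


def report_energy_vs_rmsd(ensembles: list[tuple[str, StageEnsemble]],
                          reference: Conformation, loop_range: tuple[int, int],
                          plot_path: str | None = None) -> pd.DataFrame:
    """Per-model (label, energy, C-alpha RMSD) table and scatter plot."""
    rows = []
    for label, ens in ensembles:
        for i, m in enumerate(ens.models):
            rows.append({"label": label, "model": i,
                         "energy": float(m.energy.total),
                         "ca_rmsd": ca_rmsd(m, reference, loop_range)})
    df = pd.DataFrame(rows, columns=["label", "model", "energy", "ca_rmsd"])
    if plot_path:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for label, grp in df.groupby("label"):
            ax.scatter(grp["ca_rmsd"], grp["energy"], s=14, label=str(label))
        ax.set_xlabel(r"C$\alpha$ RMSD to reference ($\mathrm{\AA}$)")
        ax.set_ylabel("energy (units)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return df
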