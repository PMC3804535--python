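"""Stage-graph orchestration of a complete loop rebuild.

Every build-up intermediate is indexed by the stage (i, j): N-terminal
fragment built through residue i, C-terminal fragment built back through
residue j.  The full calculation visits all stages reachable by single
residue additions (O(N^2) of them), closing the chain whenever the two
fragments come within 1-3 residues of each other; the simplified linear
calculation grows each fragment alone (O(N) stages) and closes at the end.
Per stage, all incoming models are collated, the 4000 lowest kept,
reclustered at 0.25 A over the rebuilt fragment backbones, and the lowest
400 carried forward.  The final full-length models are reclustered at
1.0 A over loop C-alphas and the five lowest-energy models become the
predictions.  A run is considered converged when the energy gap between the
two lowest final models is at least 1 k_BT; the standard policy runs the
linear calculation first and escalates to the full recursion otherwise.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass, field

import numpy as np

from . import closure as closure_mod
from .buildup import StageEnsemble, backbone_atoms, cluster_fine, grow_step
from .config import RunConfig
from .energy import minimization_weights, sampling_weights, score
from .geometry import Conformation
from .minimize import torsion_minimize
from .rotamers import prepack

logger = logging.getLogger("swaloop")


@dataclass(frozen=True, order=True)
class StageIndex:
    """(i, j): N-fragment built through i, C-fragment built back through j."""

    i: int
    j: int

    def gap(self) -> int:
        return self.j - self.i - 1

    def label(self) -> str:
        return f"({self.i},{self.j})"


@dataclass(frozen=True)
class Edge:
    kind: str  # grow-N | grow-C | close-first | close-last | recombine
    src: tuple[StageIndex, ...]
    dst: StageIndex | None  # None = final (closed full-length loop) pool


@dataclass
class BuildDAG:
    loop: tuple[int, int]
    mode: str
    nodes: set[StageIndex] = field(default_factory=set)
    edges: list[Edge] = field(default_factory=list)

    @property
    def start(self) -> StageIndex:
        k, l = self.loop
        return StageIndex(k - 1, l + 1)

    def open_nodes(self) -> list[StageIndex]:
        return sorted(self.nodes)


def build_dag(loop: tuple[int, int], mode: str = "full", max_gap: int = 3) -> BuildDAG:
    """Construct the stage graph for a loop [k, l] (1-based inclusive)."""
    k, l = loop
    if l < k:
        raise ValueError("inverted loop bounds")
    n = l - k + 1
    dag = BuildDAG(loop=loop, mode=mode)
    start = StageIndex(k - 1, l + 1)

    def is_open(i: int, j: int) -> bool:
        built = (i - (k - 1)) + ((l + 1) - j)
        return k - 1 <= i < j <= l + 1 and j - i - 1 >= 1 and built <= n

    if mode == "full":
        for i in range(k - 1, l + 1):
            for j in range(i + 2, l + 2):
                if is_open(i, j):
                    dag.nodes.add(StageIndex(i, j))
    elif mode == "linear":
        dag.nodes.add(start)
        for i in range(k, l + 1):
            if is_open(i, l + 1):
                dag.nodes.add(StageIndex(i, l + 1))
        for j in range(k, l + 1):
            if is_open(k - 1, j):
                dag.nodes.add(StageIndex(k - 1, j))
    else:
        raise ValueError("mode must be 'full' or 'linear'")

    for node in sorted(dag.nodes):
        src_n = StageIndex(node.i - 1, node.j)
        if node.i >= k and src_n in dag.nodes:
            dag.edges.append(Edge("grow-N", (src_n,), node))
        src_c = StageIndex(node.i, node.j + 1)
        if node.j <= l and src_c in dag.nodes:
            dag.edges.append(Edge("grow-C", (src_c,), node))
        if 1 <= node.gap() <= max_gap:
            dag.edges.append(Edge("close-first", (node,), None))
            if node.gap() > 1:
                dag.edges.append(Edge("close-last", (node,), None))
    # recombination of pure-N and pure-C fragments
    for i in range(k - 1, l + 1):
        ni = StageIndex(i, l + 1)
        if ni not in dag.nodes or i < k:
            continue
        for j in range(k, l + 2):
            cj = StageIndex(k - 1, j)
            if cj not in dag.nodes or j > l:
                continue
            if 1 <= j - i - 1 <= max_gap:
                dag.edges.append(Edge("recombine", (ni, cj), None))
    return dag


def converged(final_ensemble: StageEnsemble) -> bool:
    """True iff the two lowest energies are separated by >= 1 energy unit
    (single-model ensembles count as converged)."""
    if len(final_ensemble) == 0:
        raise ValueError("empty ensemble")
    if len(final_ensemble) == 1:
        return True
    e = final_ensemble.energies()
    return bool(e[1] - e[0] >= 1.0)


def _edge_seed(master: int, edge: Edge) -> int:
    label = edge.kind + ";" + ",".join(s.label() for s in edge.src)
    return (master * 1000003 + zlib.crc32(label.encode())) % (2 ** 31)


def run(dag: BuildDAG, scaffold_conf: Conformation, config: RunConfig | None = None,
        do_prepack: bool = True, native_ref: Conformation | None = None
        ) -> tuple[StageEnsemble, dict]:
    """Execute a stage graph: topological stage execution with collation,
    clustering and retention; returns (final predictions, report).

    When ``native_ref`` is given together with ``config.native``, models
    beyond the backbone-RMSD screen are dropped at every retention step and
    C-alpha fade restraints to the reference are applied.
    """
    config = config or RunConfig()
    k, l = dag.loop
    ws = sampling_weights(**config.energy.sampling_overrides)
    wm = minimization_weights(**config.energy.minimization_overrides)
    spec = config.grid.spec()
    ret = config.retention
    report: dict = {"stages": [], "mode": dag.mode,
                    "config": config.model_dump()}
    logger.info("run %s mode=%s loop=%s config=%s", dag.start.label(),
                dag.mode, dag.loop, config.model_dump())

    base = scaffold_conf.copy()
    if base.loop != dag.loop or base.nfrag_end >= k or base.cfrag_start <= l:
        base.set_loop(k, l)  # strips any existing loop atoms
    base.sample_loop_takeoff = config.sample_loop_takeoff
    if native_ref is not None and config.native.constrain_ca:
        base.ca_restraints = {r: native_ref.atom(r, "CA").copy()
                              for r in range(k, l + 1)}

    def _screen(models: list[Conformation]) -> list[Conformation]:
        if native_ref is None or config.native.rmsd_screen is None:
            return models
        from .evaluate import backbone_rmsd

        out = []
        for m in models:
            built = [r for r in range(k, l + 1) if r in m.residues]
            if backbone_rmsd(m, native_ref, built) < config.native.rmsd_screen:
                out.append(m)
        return out

    if do_prepack:
        t0 = time.time()
        base = prepack(base, ws, rng_seed=config.seed,
                       sweeps=config.sampling.prepack_sweeps)
        logger.info("prepack done in %.1fs (E=%.2f)", time.time() - t0,
                    base.energy.total)
    score(base, wm)

    ensembles: dict[StageIndex, StageEnsemble] = {
        dag.start: StageEnsemble([base], dag.start)}
    incoming: dict[StageIndex, list[Conformation]] = {}
    final_pool: list[Conformation] = []

    grow_edges = [e for e in dag.edges if e.kind.startswith("grow")]
    close_edges = [e for e in dag.edges if e.kind.startswith("close")]
    recombine_edges = [e for e in dag.edges if e.kind == "recombine"]

    def stage_cluster_atoms(node: StageIndex):
        built = [r for r in range(k, node.i + 1)] + \
                [r for r in range(node.j, l + 1)]
        return backbone_atoms(built) if built else None

    # topological order: total built residues ascending
    order = sorted(dag.nodes, key=lambda s: ((s.i - (k - 1)) + ((l + 1) - s.j),
                                             s.i, s.j))
    for node in order:
        if node == dag.start:
            continue
        t0 = time.time()
        pool: list[Conformation] = []
        for edge in grow_edges:
            if edge.dst != node:
                continue
            src = edge.src[0]
            if src not in ensembles or len(ensembles[src]) == 0:
                continue
            direction = "N" if edge.kind == "grow-N" else "C"
            pool += grow_step(
                ensembles[src], direction, spec, ws, wm,
                rng_seed=_edge_seed(config.seed, edge),
                keep=ret.keep, fine_radius=ret.fine_radius,
                neighbor_cutoff=config.sampling.neighbor_cutoff,
                rotamer_sweeps=config.sampling.rotamer_sweeps,
                minimize_iter=config.minimize.grow_max_iter)
        pool = _screen(pool)
        if not pool:
            ensembles[node] = StageEnsemble([], node)
            report["stages"].append({"stage": node.label(), "in": 0, "out": 0})
            continue
        pool.sort(key=lambda m: m.energy.total)
        pool = pool[:ret.collate_max]
        ens = cluster_fine(pool, stage_cluster_atoms(node),
                           ret.stage_radius, ret.keep, stage=node)
        ensembles[node] = ens
        report["stages"].append({
            "stage": node.label(), "in": len(pool), "out": len(ens),
            "min_energy": float(ens.energies().min()) if len(ens) else None,
            "wall_s": round(time.time() - t0, 2)})
        logger.info("stage %s: %d -> %d models (%.1fs)", node.label(),
                    len(pool), len(ens), time.time() - t0)

    # closure: pool screened candidates from every closure/recombination
    # route, then run the expensive pack-and-minimize phase once on the
    # clustered union (the many routes to chain closure are collated anyway)
    opt_kw = dict(fine_radius=ret.fine_radius,
                  neighbor_cutoff=config.sampling.neighbor_cutoff,
                  rotamer_sweeps=config.sampling.rotamer_sweeps,
                  minimize_iter=config.minimize.closure_max_iter)
    ws_break = ws.with_(linear_chainbreak=config.closure.chainbreak_weight)
    for edge in close_edges:
        src = edge.src[0]
        if src not in ensembles or len(ensembles[src]) == 0:
            continue
        t0 = time.time()
        variant = "first" if edge.kind == "close-first" else "last"
        parents = ensembles[src].models
        if config.closure.max_parents is not None:
            parents = parents[:config.closure.max_parents]
        n_before = len(final_pool)
        for parent in parents:
            for m, _dev in closure_mod.close_candidates(
                    parent, variant, spec, ws_break,
                    screen=config.closure.screen,
                    max_cycles=config.closure.max_cycles,
                    tol=config.closure.tol):
                final_pool.append(m)
        logger.info("closure %s from %s: %d candidates (%.1fs)", variant,
                    src.label(), len(final_pool) - n_before, time.time() - t0)
    for edge in recombine_edges:
        ni, cj = edge.src
        if ni not in ensembles or cj not in ensembles:
            continue
        if len(ensembles[ni]) == 0 or len(ensembles[cj]) == 0:
            continue
        t0 = time.time()
        models = closure_mod.recombine_candidates(
            ensembles[ni], ensembles[cj], spec, ws_break,
            max_pairs=config.closure.recombine_max_pairs,
            screen=config.closure.screen, max_cycles=config.closure.max_cycles,
            tol=config.closure.tol)
        final_pool += models
        logger.info("recombine %s x %s: %d candidates (%.1fs)", ni.label(),
                    cj.label(), len(models), time.time() - t0)
    if final_pool:
        t0 = time.time()
        final_pool = closure_mod.optimize_closed(
            final_pool, ws, wm, rng_seed=(config.seed * 31 + 17) % (2 ** 31),
            keep=ret.keep, **opt_kw)
        logger.info("closure optimization: %d models (%.1fs)",
                    len(final_pool), time.time() - t0)

    final_pool = _screen(final_pool)
    report["n_final_pool"] = len(final_pool)
    if not final_pool:
        return StageEnsemble([], None), report

    # final stage: collate, recluster, select five predictions
    final_pool.sort(key=lambda m: m.energy.total)
    final_pool = final_pool[:ret.collate_max]
    loop_bb = backbone_atoms(range(k, l + 1))
    final_ens = cluster_fine(final_pool, loop_bb, ret.stage_radius, ret.keep)
    ca_atoms = [(r, "CA") for r in range(k, l + 1)]
    preds = cluster_fine(final_ens.models, ca_atoms, ret.final_radius,
                         ret.final_keep)

    # polish the predictions with a longer full-loop minimization
    wm_break = wm.with_(linear_chainbreak=config.closure.chainbreak_weight)
    polished = []
    for m in preds.models:
        if m.closed:
            m = closure_mod.reclose(m, max_cycles=config.closure.max_cycles,
                                    tol=config.closure.tol)
        move_set = []
        from .buildup import movable_bb
        for r in m.loop_residues():
            move_set += movable_bb(m, r)
        if m.closed:
            move_set.append(("bb", m.cutpoint + 1, "omega"))
        move_set = list(dict.fromkeys(move_set))
        polished.append(torsion_minimize(m, move_set, wm_break,
                                         max_iter=config.minimize.final_polish_iter))
    polished.sort(key=lambda m: m.energy.total)
    predictions = StageEnsemble(polished, None)
    report["final_energies"] = [float(m.energy.total) for m in polished]
    report["converged"] = converged(predictions) if len(predictions) else False
    report["closure_deviation"] = [
        float(m.closure_deviation()) if m.closed else 0.0 for m in polished]
    report["ensemble"] = final_ens
    return predictions, report


def run_pipeline(scaffold_conf: Conformation, loop: tuple[int, int],
                 config: RunConfig | None = None,
                 native_ref: Conformation | None = None
                 ) -> tuple[StageEnsemble, dict]:
    """Standard policy: linear (O(N)) calculation first, escalate to the
    full (O(N^2)) recursion when the result has not clearly converged."""
    config = config or RunConfig()
    if config.mode in ("linear", "full"):
        dag = build_dag(loop, config.mode, config.max_gap)
        return run(dag, scaffold_conf, config, native_ref=native_ref)
    preds, report = run(build_dag(loop, "linear", config.max_gap),
                        scaffold_conf, config, native_ref=native_ref)
    if len(preds) and converged(preds):
        report["escalated"] = False
        return preds, report
    logger.info("linear run not converged; escalating to full recursion")
    preds_full, report_full = run(build_dag(loop, "full", config.max_gap),
                                  scaffold_conf, config, native_ref=native_ref)
    report_full["escalated"] = True
    report_full["linear_report"] = report
    return preds_full, report_full
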