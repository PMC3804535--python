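"""Surrogate all-atom energy function.

A transparent stand-in for a full molecular-mechanics score, with the term
structure the loop-building protocol needs: a split Lennard-Jones packing
term (``fa_atr``/``fa_rep``), directional hydrogen bonds with a hard 3.2 A
heavy-atom cutoff (``hbond_bb``/``hbond_sc``), a backbone-torsion
(Ramachandran) term, a side-chain torsion preference term, the linear
chainbreak pseudo-energy read off the virtual closure atoms, and an optional
fade-spline C-alpha coordinate restraint.  One energy unit is treated as one
k_BT throughout (retention windows, convergence gaps).

Two weight dialects are shipped: "sampling" (soft repulsion fa_rep = 0.10,
strong side-chain hydrogen bonds hbond_sc = 3.1, forgiving the discreteness
of grid and rotamer sampling) and "minimization" (fa_rep = 0.44,
hbond_sc = 1.1).  Hydrogen-bond strength is never attenuated by burial or
solvent exposure, in either dialect.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from . import topology as topo
from .geometry import Conformation, wrap_angle
from .topology import BACKBONE_LIKE, residue_topology

TERMS = ("fa_atr", "fa_rep", "hbond_bb", "hbond_sc", "rama", "rotamer",
         "linear_chainbreak", "coordinate_constraint")


@dataclass(frozen=True)
class EnergyWeights:
    fa_atr: float = 0.8
    fa_rep: float = 0.44
    hbond_bb: float = 1.17
    hbond_sc: float = 1.1
    rama: float = 0.2
    rotamer: float = 0.4
    linear_chainbreak: float = 0.0
    coordinate_constraint: float = 0.0

    def __post_init__(self):
        for t in TERMS:
            if getattr(self, t) < 0:
                raise ValueError(f"negative weight for {t}")

    def as_dict(self) -> dict[str, float]:
        return {t: getattr(self, t) for t in TERMS}

    def with_(self, **kw) -> "EnergyWeights":
        return replace(self, **kw)


def sampling_weights(**overrides) -> EnergyWeights:
    """Soft-repulsion dialect used during enumerative sampling and packing."""
    return EnergyWeights(fa_rep=0.10, hbond_sc=3.1).with_(**overrides)


def minimization_weights(**overrides) -> EnergyWeights:
    """Standard dialect used for continuous minimization and model ranking."""
    return EnergyWeights(fa_rep=0.44, hbond_sc=1.1).with_(**overrides)


@dataclass
class EnergyBreakdown:
    terms: dict[str, float]
    weights: EnergyWeights
    total: float = field(init=False)

    def __post_init__(self):
        self.total = float(sum(self.weights.as_dict()[t] * v
                               for t, v in self.terms.items()))


# --------------------------------------------------------------- parameters


@functools.lru_cache(maxsize=1)
def _params() -> dict:
    return topo._load_yaml("atom_params.yaml")


def _element(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element for atom {name!r}")


# ------------------------------------------------------- Ramachandran tables


@functools.lru_cache(maxsize=1)
def _rama_tables() -> dict:
    """Build the binned (phi, psi) score tables from the basin mixture data."""
    cfg = topo._load_yaml("rama_basins.yaml")
    step = cfg["grid_step"]
    grid = np.arange(-180.0, 180.0, step)
    pp, ss = np.meshgrid(grid, grid, indexing="ij")
    tables = {}
    for cls, basins in cfg["classes"].items():
        p = np.full_like(pp, cfg["floor"])
        for phi0, psi0, sp, spsi, w in basins:
            dphi = (pp - phi0 + 180.0) % 360.0 - 180.0
            dpsi = (ss - psi0 + 180.0) % 360.0 - 180.0
            p = p + w * np.exp(-0.5 * (dphi / sp) ** 2 - 0.5 * (dpsi / spsi) ** 2)
        score = -np.log(p / p.max())
        score = np.minimum(score, cfg["cap"]) + cfg["shift"]
        tables[cls] = score
    return {"step": step, "grid": grid, "tables": tables}


def rama_class(restype: str, next_is_pro: bool = False) -> str:
    if restype == "GLY":
        return "glycine"
    if restype == "PRO":
        return "proline"
    if next_is_pro:
        return "preproline"
    return "generic"


def rama_score(restype: str, phi: float, psi: float, next_is_pro: bool = False) -> float:
    """Bilinear interpolation on the shipped (phi, psi) table, periodic."""
    data = _rama_tables()
    table = data["tables"][rama_class(restype, next_is_pro)]
    step = data["step"]
    nbin = table.shape[0]
    fi = (wrap_angle(phi) + 180.0) / step
    fj = (wrap_angle(psi) + 180.0) / step
    i0, j0 = int(math.floor(fi)) % nbin, int(math.floor(fj)) % nbin
    i1, j1 = (i0 + 1) % nbin, (j0 + 1) % nbin
    u, v = fi - math.floor(fi), fj - math.floor(fj)
    return float(table[i0, j0] * (1 - u) * (1 - v) + table[i1, j0] * u * (1 - v)
                 + table[i0, j1] * (1 - u) * v + table[i1, j1] * u * v)


# ---------------------------------------------------------------- flat view


class _Flat:
    """Vectorized atom view of a conformation plus bonded-pair exclusions."""

    __slots__ = ("xyz", "res", "names", "is_h", "is_bb", "radius", "heavy_idx",
                 "donors", "acceptors", "excluded")

    def __init__(self, conf: Conformation):
        par = _params()
        radii = par["radius"]
        names, res, xyz = [], [], []
        for r in sorted(conf.residues):
            if r == 0 or r not in conf.kind:
                continue
            for name, pos in conf.residues[r].items():
                if name.startswith("V"):
                    continue  # virtual closure atoms carry no physical energy
                names.append(name)
                res.append(r)
                xyz.append(pos)
        self.names = names
        self.res = np.array(res, dtype=int)
        self.xyz = np.array(xyz, dtype=float) if xyz else np.zeros((0, 3))
        self.is_h = np.array([_element(n) == "H" for n in names])
        self.is_bb = np.array([n in BACKBONE_LIKE for n in names])
        self.radius = np.array([0.0 if h else radii[_element(n)]
                                for n, h in zip(names, self.is_h)])
        self.heavy_idx = np.flatnonzero(~self.is_h)
        self._find_hbond_partners(conf)
        self._build_exclusions(conf)

    def _index(self) -> dict:
        return {(r, n): i for i, (r, n) in enumerate(zip(self.res, self.names))}

    def _bonds(self, conf: Conformation) -> list[tuple[int, int]]:
        idx = self._index()
        bonds = []

        def add(r1, n1, r2, n2):
            a, b = idx.get((r1, n1)), idx.get((r2, n2))
            if a is not None and b is not None:
                bonds.append((a, b))

        ring_closures = {
            "PRO": [("CD", "N")], "PHE": [("CZ", "CE2")], "TYR": [("CZ", "CE2")],
            "HIS": [("CE1", "NE2")], "TRP": [("CE2", "CD2"), ("CH2", "CZ3")],
        }
        built = [r for r in sorted(conf.residues) if r != 0 and r in conf.kind]
        for r in built:
            t = residue_topology(conf.sequence[r - 1])
            add(r, "N", r, "CA"); add(r, "CA", r, "C"); add(r, "C", r, "O")
            add(r, "N", r, "H")
            for a in t.sidechain:
                add(r, a.name, r, a.parents[0])
            for n1, n2 in ring_closures.get(t.name3, []):
                add(r, n1, r, n2)
            # caps
            add(r, "NT", r, "C"); add(r, "HT", r, "NT"); add(r, "CT", r, "NT")
            add(r, "CP", r, "N"); add(r, "OP", r, "CP"); add(r, "CMP", r, "CP")
            # peptide bond to the next built residue; a *closed* cutpoint
            # still counts as bonded for exclusions (the chainbreak term,
            # not sterics, polices the remaining deviation)
            if (r + 1) in conf.residues:
                crossing = (conf.kind.get(r) == "nfrag"
                            and conf.kind.get(r + 1) == "cfrag")
                if not crossing or conf.closed:
                    add(r, "C", r + 1, "N")
        return bonds

    def _build_exclusions(self, conf: Conformation) -> None:
        n = len(self.names)
        adj: list[list[int]] = [[] for _ in range(n)]
        for a, b in self._bonds(conf):
            adj[a].append(b)
            adj[b].append(a)
        # pairs within 4 bonds are excluded: local (torsion-determined)
        # preferences are carried by the rama and rotamer terms, the pair
        # terms measure genuine nonlocal packing and hydrogen bonding
        excl = np.zeros((n, n), dtype=bool)
        for start in range(n):
            seen = {start}
            frontier = [start]
            for _depth in (1, 2, 3, 4):
                nxt = []
                for a in frontier:
                    for b in adj[a]:
                        if b not in seen:
                            seen.add(b)
                            nxt.append(b)
                frontier = nxt
            for b in seen:
                excl[start, b] = True
        self.excluded = excl

    def _find_hbond_partners(self, conf: Conformation) -> None:
        par = _params()
        exceptions = {tuple(x) for x in par["acceptor_exceptions"]}
        idx = {(r, n): i for i, (r, n) in enumerate(zip(self.res, self.names))}
        donors = []  # (heavy_index, h_index)
        h_parent = {"H": "N", "HT": "NT", "HG": "OG", "HG1": "OG1", "HH": "OH",
                    "HE1": "NE1", "HE2": "NE2", "HD21": "ND2", "HD22": "ND2",
                    "HE21": "NE2", "HE22": "NE2", "HZ1": "NZ", "HZ2": "NZ",
                    "HZ3": "NZ", "HE": "NE", "HH11": "NH1", "HH12": "NH1",
                    "HH21": "NH2", "HH22": "NH2"}
        for i, (r, name) in enumerate(zip(self.res, self.names)):
            if not self.is_h[i]:
                continue
            parent = h_parent.get(name)
            j = idx.get((int(r), parent)) if parent else None
            if j is not None:
                donors.append((j, i))
        acceptors = []
        for i, (r, name) in enumerate(zip(self.res, self.names)):
            if self.is_h[i]:
                continue
            if _element(name) == "O":
                acceptors.append(i)
            elif (conf.restype(int(r)), name) in exceptions:
                acceptors.append(i)
        self.donors = donors
        self.acceptors = np.array(acceptors, dtype=int)


def _topo_key(conf: Conformation):
    return tuple((r, tuple(conf.residues[r])) for r in sorted(conf.residues)
                 if r != 0 and r in conf.kind) + (conf.closed,)


def _flat(conf: Conformation) -> _Flat:
    """Flat view; rebuilt only when the atom topology changes (coordinate
    edits refresh the xyz array in place)."""
    cached = getattr(conf, "_flat_cache", None)
    if cached is not None and cached[0] == conf._version:
        return cached[2]
    key = _topo_key(conf)
    if cached is not None and cached[1] == key:
        flat = cached[2]
        flat.xyz = np.array([conf.residues[r][n] for r, n in
                             zip(flat.res, flat.names)], dtype=float) \
            if flat.names else np.zeros((0, 3))
        conf._flat_cache = (conf._version, key, flat)
        return flat
    flat = _Flat(conf)
    conf._flat_cache = (conf._version, key, flat)
    return flat


# -------------------------------------------------------------- pair energies


def _lj_split(d: np.ndarray, rmin: np.ndarray, eps: float,
              cap_frac: float, cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    """Split Lennard-Jones: attractive branch (<= 0) and repulsive (>= 0)."""
    atr = np.zeros_like(d)
    rep = np.zeros_like(d)
    out = (d >= rmin) & (d < cutoff)
    if out.any():
        x = rmin[out] / d[out]
        lj = eps * (x ** 12 - 2.0 * x ** 6)
        # cosine switch to zero over the last Angstrom before the cutoff
        sw = np.ones_like(lj)
        tail = d[out] > cutoff - 1.0
        sw[tail] = 0.5 * (1.0 + np.cos(np.pi * (d[out][tail] - (cutoff - 1.0))))
        atr[out] = lj * sw
    inn = d < rmin
    if inn.any():
        atr[inn] = -eps
        d0 = cap_frac * rmin[inn]
        lin = d[inn] < d0
        x = rmin[inn] / np.maximum(d[inn], 1e-6)
        rep_in = eps * (x ** 12 - 2.0 * x ** 6 + 1.0)
        if lin.any():
            x0 = 1.0 / cap_frac
            e0 = eps * (x0 ** 12 - 2.0 * x0 ** 6 + 1.0)
            slope = eps * (-12.0 * x0 ** 13 + 12.0 * x0 ** 7) / rmin[inn][lin]
            rep_in[lin] = e0 + slope * (d[inn][lin] - d0[lin])
        rep[inn] = rep_in
    return atr, rep


def hbond_term(d_heavy: float, cos_theta: float) -> float:
    """Distance/angle hydrogen-bond energy for one donor-acceptor pair.

    ``d_heavy`` is the donor-heavy-atom to acceptor distance; ``cos_theta``
    the cosine of the deviation of H...A from the D-H direction (1 =
    collinear).  Smooth, <= 0, exactly 0 beyond 3.2 A.
    """
    par = _params()["hbond"]
    if d_heavy >= par["heavy_cutoff"] or cos_theta <= 0.0:
        return 0.0
    t = min((par["heavy_cutoff"] - d_heavy) / par["switch_width"], 1.0)
    sw = t * t * (3.0 - 2.0 * t)
    well = math.exp(-((d_heavy - par["well_center"]) / par["well_sigma"]) ** 2)
    return -sw * well * cos_theta ** 2


def ca_fade_constraint(d: float, r_lo: float = 2.0, r_hi: float = 4.0,
                       max_penalty: float = 10.0) -> float:
    """Fade-spline penalty on a C-alpha deviation ``d`` (Angstrom).

    Zero up to ``r_lo``, ``max_penalty`` beyond ``r_hi``, and the unique
    cubic with zero slope at both knots in between.
    """
    if r_lo >= r_hi:
        raise ValueError("r_lo must be < r_hi")
    if d <= r_lo:
        return 0.0
    if d >= r_hi:
        return max_penalty
    t = (d - r_lo) / (r_hi - r_lo)
    return max_penalty * (3.0 * t ** 2 - 2.0 * t ** 3)


# ------------------------------------------------------------------- scoring


def _term_values(conf: Conformation, subset: set[int] | None = None) -> dict[str, float]:
    """Raw term values; ``subset`` restricts to interactions involving the
    given residues (pair terms with >= 1 atom there, one-body terms there)."""
    par = _params()
    flat = _flat(conf)
    terms = {t: 0.0 for t in TERMS}
    if flat.xyz.shape[0] == 0:
        return terms
    if not np.isfinite(flat.xyz).all():
        raise ValueError("NaN coordinates")
    in_sub = None
    if subset is not None:
        in_sub = np.isin(flat.res, list(subset))

    # packing: heavy-atom pairs within cutoff, excluding near-bonded pairs
    hi = flat.heavy_idx
    dd = rmin = None
    if hi.size:
        if in_sub is None:
            d = cdist(flat.xyz[hi], flat.xyz[hi])
            iu, ju = np.triu_indices(hi.size, k=1)
            mask = (d[iu, ju] < par["pair_cutoff"]) \
                & ~flat.excluded[hi[iu], hi[ju]]
            iu, ju = iu[mask], ju[mask]
            if iu.size:
                dd = d[iu, ju]
                rmin = flat.radius[hi[iu]] + flat.radius[hi[ju]]
        else:
            # only rows touching the subset; count in-subset pairs once
            sub_h = hi[in_sub[hi]]
            if sub_h.size:
                d = cdist(flat.xyz[sub_h], flat.xyz[hi])
                mask = (d < par["pair_cutoff"]) \
                    & ~flat.excluded[np.ix_(sub_h, hi)] \
                    & ((~in_sub[hi])[None, :] | (sub_h[:, None] < hi[None, :]))
                ii, jj = np.nonzero(mask)
                if ii.size:
                    dd = d[ii, jj]
                    rmin = flat.radius[sub_h[ii]] + flat.radius[hi[jj]]
        if dd is not None:
            atr, rep = _lj_split(dd, rmin, par["epsilon"],
                                 par["rep_cap_fraction"], par["pair_cutoff"])
            terms["fa_atr"] = float(atr.sum())
            terms["fa_rep"] = float(rep.sum())

    # hydrogen bonds: vectorized distance prefilter, then per-pair geometry
    if flat.donors and flat.acceptors.size:
        dheavy = np.array([d for d, _ in flat.donors])
        dhyd = np.array([h for _, h in flat.donors])
        acc = flat.acceptors
        dm = cdist(flat.xyz[dheavy], flat.xyz[acc])
        cand = dm < par["hbond"]["heavy_cutoff"]
        cand &= ~flat.excluded[np.ix_(dheavy, acc)]
        cand &= dheavy[:, None] != acc[None, :]
        if in_sub is not None:
            cand &= in_sub[dheavy][:, None] | in_sub[acc][None, :]
        di, ai = np.nonzero(cand)
        if di.size:
            hb = par["hbond"]
            dh, hh, aa = dheavy[di], dhyd[di], acc[ai]
            u = flat.xyz[hh] - flat.xyz[dh]
            v = flat.xyz[aa] - flat.xyz[hh]
            nu = np.sqrt((u * u).sum(1))
            nv = np.sqrt((v * v).sum(1))
            ok = (nu > 1e-6) & (nv > 1e-6)
            cth = np.where(ok, (u * v).sum(1) / np.maximum(nu * nv, 1e-12), 0.0)
            dist = dm[di, ai]
            t = np.clip((hb["heavy_cutoff"] - dist) / hb["switch_width"], 0.0, 1.0)
            sw = t * t * (3.0 - 2.0 * t)
            well = np.exp(-((dist - hb["well_center"]) / hb["well_sigma"]) ** 2)
            e = -sw * well * np.maximum(cth, 0.0) ** 2
            both_bb = flat.is_bb[dh] & flat.is_bb[aa]
            terms["hbond_bb"] = float(e[both_bb].sum())
            terms["hbond_sc"] = float(e[~both_bb].sum())

    # one-body torsion terms: flexible (fragment) residues only; the fixed
    # scaffold backbone contributes a constant that is omitted throughout
    for r in sorted(conf.residues):
        if r == 0 or conf.kind.get(r) in (None, "scaffold"):
            continue
        if subset is not None and r not in subset:
            continue
        phi, psi = conf.bb[r]["phi"], conf.bb[r]["psi"]
        if phi is not None and psi is not None:
            next_is_pro = r < conf.n and conf.sequence[r] == "P"
            terms["rama"] += rama_score(conf.restype(r), phi, psi, next_is_pro)
    for r, chis in conf.chi.items():
        if chis is None or r not in conf.residues:
            continue
        if subset is not None and r not in subset:
            continue
        per = residue_topology(conf.sequence[r - 1]).chi_periodicity
        for x, p in zip(chis, per):
            if p == 3:
                terms["rotamer"] += 0.5 * (1.0 + math.cos(3.0 * math.radians(x)))

    if conf.closed:
        terms["linear_chainbreak"] = float(conf.chainbreak_deviations().sum())

    if conf.ca_restraints:
        tot = 0.0
        for r, ref in conf.ca_restraints.items():
            if conf.has_atom(r, "CA"):
                tot += ca_fade_constraint(float(np.linalg.norm(conf.atom(r, "CA") - ref)))
        terms["coordinate_constraint"] = tot

    return terms


def score(conf: Conformation, weights: EnergyWeights,
          subset: set[int] | None = None) -> EnergyBreakdown:
    """Score a conformation; optionally only interactions touching ``subset``."""
    bd = EnergyBreakdown(_term_values(conf, subset), weights)
    if subset is None:
        conf.energy = bd
    return bd


def linear_chainbreak(conf: Conformation) -> float:
    """Sum of the three virtual/real closure atom-pair deviations (Angstrom)."""
    return float(conf.chainbreak_deviations().sum())
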