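"""All-atom peptide conformations built from internal coordinates.

The only degrees of freedom are torsions (phi/psi/omega per residue, chi per
side-chain); bond lengths and angles are fixed at the ideal values shipped in
``data/ideal_geometry.yaml``.  A :class:`Conformation` carries a fixed
scaffold (backbone coordinates authoritative, never moved) plus loop
fragments grown from the two scaffold anchor residues (torsions
authoritative, coordinates derived by NeRF-style sequential placement).

Conventions
-----------
* residue numbering is 1-based and matches the FASTA position;
* torsions are degrees in all interfaces, wrapped to (-180, 180];
* ``phi_r``   = dihedral(C_{r-1}, N_r, CA_r, C_r)
* ``psi_r``   = dihedral(N_r, CA_r, C_r, N_{r+1}); the carbonyl O sits at
  ``psi_r + 180`` in the same frame;
* ``omega_r`` = dihedral(CA_{r-1}, C_{r-1}, N_r, CA_r) (the peptide bond
  *preceding* residue r);
* a growing N-terminal fragment ends in a methylamide cap (NT/HT/CT), a
  growing C-terminal fragment starts with an acetyl cap (CP/OP/CMP); caps
  model the next peptide unit and disappear automatically once the adjacent
  residue is built;
* a formally closed chain carries a cutpoint with virtual closure atoms
  VN/VCA (on the cutpoint residue) and VC (on the residue after it) that
  overlap their real counterparts iff closure is exact.
"""

from __future__ import annotations

import copy as _copy
import math
from typing import Iterable

import numpy as np

from . import topology as topo
from .topology import AA1TO3, residue_topology

BB_NAMES = ("phi", "psi", "omega")


def wrap_angle(x: float) -> float:
    """Wrap an angle in degrees to (-180, 180]."""
    y = math.fmod(x, 360.0)
    if y <= -180.0:
        y += 360.0
    elif y > 180.0:
        y -= 360.0
    return y


def place_atom(p1, p2, p3, bond: float, angle_deg: float,
               torsion_deg: float) -> np.ndarray:
    """Place an atom at distance ``bond`` from p1, angle atom-p1-p2 and
    dihedral atom-p1-p2-p3 (natural-extension-of-reference-frame placement).

    Scalar arithmetic on purpose: this is the innermost primitive of every
    rebuild and numpy dispatch overhead would dominate.
    """
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    b1x = p1[0] - p2[0]; b1y = p1[1] - p2[1]; b1z = p1[2] - p2[2]
    b2x = p2[0] - p3[0]; b2y = p2[1] - p3[1]; b2z = p2[2] - p3[2]
    # n1 = b2 x b1
    nx = b2y * b1z - b2z * b1y
    ny = b2z * b1x - b2x * b1z
    nz = b2x * b1y - b2y * b1x
    nn = math.sqrt(nx * nx + ny * ny + nz * nz)
    if nn < 1e-10:
        raise ValueError("degenerate (collinear) reference frame")
    lb1 = math.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
    ux, uy, uz = b1x / lb1, b1y / lb1, b1z / lb1
    nx, ny, nz = nx / nn, ny / nn, nz / nn
    # m1 = n1 x u1
    mx = ny * uz - nz * uy
    my = nz * ux - nx * uz
    mz = nx * uy - ny * ux
    d0 = -bond * math.cos(ang)
    s = bond * math.sin(ang)
    d1 = s * math.cos(tor)
    d2 = -s * math.sin(tor)
    return np.array((p1[0] + d0 * ux + d1 * mx + d2 * nx,
                     p1[1] + d0 * uy + d1 * my + d2 * ny,
                     p1[2] + d0 * uz + d1 * mz + d2 * nz))


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Dihedral angle a-b-c-d in degrees, in (-180, 180]."""
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return wrap_angle(math.degrees(math.atan2(float(m1 @ n2), float(n1 @ n2))))


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = a - b
    v = c - b
    cosang = float(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def _default_anchor() -> np.ndarray:
    """Pseudo (C0, CA0, N0) frame used when no anchor is supplied."""
    ca = np.zeros(3)
    c = np.array([1.525, 0.0, 0.0])
    ang = math.radians(111.2)
    n = np.array([1.458 * math.cos(ang), 1.458 * math.sin(ang), 0.0])
    return np.stack([c, ca, n])


class Conformation:
    """Scaffold plus partially built loop.

    ``residues`` maps residue index -> {atom name -> xyz}.  ``kind`` marks
    each built residue as ``scaffold`` / ``nfrag`` / ``cfrag``; loop residues
    not yet built are absent.  Fragment coordinates are always derived from
    the stored torsions; editing a torsion triggers a rebuild of the owning
    fragment only, so scaffold atoms (and the other fragment) never move.
    """

    def __init__(self, sequence: str, loop: tuple[int, int] | None = None):
        for ch in sequence:
            if ch.upper() not in AA1TO3:
                raise KeyError(f"unknown residue code {ch!r}")
        self.sequence = sequence.upper()
        self.n = len(sequence)
        self.loop = loop
        self.residues: dict[int, dict[str, np.ndarray]] = {}
        self.kind: dict[int, str] = {}
        self.bb: dict[int, dict[str, float | None]] = {
            r: {"phi": None, "psi": None, "omega": None} for r in range(0, self.n + 2)
        }
        self.chi: dict[int, list[float] | None] = {r: None for r in range(1, self.n + 1)}
        self.nfrag_end = 0
        self.cfrag_start = self.n + 1
        self.closed = False
        self.cutpoint: int | None = None
        self.sample_loop_takeoff = False
        self.ca_restraints: dict[int, np.ndarray] | None = None
        self.energy = None  # EnergyBreakdown set by scoring
        self._version = 0

    # ------------------------------------------------------------------ util

    def restype(self, r: int) -> str:
        return AA1TO3[self.sequence[r - 1]]

    def topo(self, r: int):
        return residue_topology(self.sequence[r - 1])

    def atom(self, r: int, name: str) -> np.ndarray:
        return self.residues[r][name]

    def has_atom(self, r: int, name: str) -> bool:
        return r in self.residues and name in self.residues[r]

    def built(self) -> list[int]:
        return sorted(self.residues)

    def loop_residues(self) -> list[int]:
        if self.loop is None:
            return []
        k, l = self.loop
        return list(range(k, l + 1))

    def built_mask(self) -> dict[int, str]:
        return dict(self.kind)

    def touch(self) -> None:
        self._version += 1
        self.energy = None

    def copy(self) -> "Conformation":
        new = Conformation.__new__(Conformation)
        new.sequence = self.sequence
        new.n = self.n
        new.loop = self.loop
        new.residues = {r: dict(d) for r, d in self.residues.items()}
        new.kind = dict(self.kind)
        new.bb = {r: dict(d) for r, d in self.bb.items()}
        new.chi = {r: (list(v) if v is not None else None) for r, v in self.chi.items()}
        new.nfrag_end = self.nfrag_end
        new.cfrag_start = self.cfrag_start
        new.closed = self.closed
        new.cutpoint = self.cutpoint
        new.sample_loop_takeoff = self.sample_loop_takeoff
        new.ca_restraints = _copy.deepcopy(self.ca_restraints)
        new.energy = self.energy
        new._version = self._version
        return new

    # ------------------------------------------------------- construction

    @classmethod
    def from_torsions(cls, sequence: str,
                      torsions: dict[int, dict] | None = None,
                      anchor_frame: np.ndarray | None = None,
                      chi: dict[int, list[float]] | None = None) -> "Conformation":
        """Build a full chain forward from an anchor frame.

        ``torsions[r]`` may carry phi/psi/omega (degrees); missing values
        default to an extended chain (phi -120, psi 120, omega 180).
        ``torsions[0]`` may carry the pseudo psi orienting the first residue
        relative to the anchor.  The anchor frame rows are used verbatim as
        the (C, CA, N) positions of a virtual residue 0.
        """
        conf = cls(sequence)
        torsions = torsions or {}
        if anchor_frame is None:
            anchor_frame = _default_anchor()
        anchor_frame = np.asarray(anchor_frame, dtype=float)
        if anchor_frame.shape != (3, 3):
            raise ValueError("anchor frame must be three 3-vectors (C, CA, N)")
        v1 = anchor_frame[0] - anchor_frame[1]
        v2 = anchor_frame[2] - anchor_frame[1]
        if np.linalg.norm(np.cross(v1, v2)) < 1e-8:
            raise ValueError("degenerate (collinear) anchor frame")
        conf.residues[0] = {"C": anchor_frame[0].copy(), "CA": anchor_frame[1].copy(),
                            "N": anchor_frame[2].copy()}
        conf.bb[0]["psi"] = wrap_angle(torsions.get(0, {}).get("psi", 150.0))
        for r in range(1, conf.n + 1):
            t = torsions.get(r, {})
            conf.bb[r]["phi"] = wrap_angle(t.get("phi", -120.0))
            conf.bb[r]["psi"] = wrap_angle(t.get("psi", 120.0))
            conf.bb[r]["omega"] = wrap_angle(t.get("omega", 180.0))
            nchi = conf.topo(r).n_chi
            if chi is not None and r in chi:
                conf.chi[r] = [wrap_angle(x) for x in chi[r]]
            else:
                conf.chi[r] = [180.0] * nchi
        conf.nfrag_end = conf.n
        conf.kind = {r: "nfrag" for r in range(1, conf.n + 1)}
        # residue 0 (the anchor frame) is kept so that phi of residue 1 stays
        # well-defined; it is excluded from scoring and output.
        conf._rebuild_nfrag(start=1, anchor=0, cap=False)
        conf.touch()
        return conf

    def freeze_as_scaffold(self) -> "Conformation":
        """Return a copy whose built residues become a fixed scaffold."""
        new = self.copy()
        new.residues.pop(0, None)
        for r in new.residues:
            new.kind[r] = "scaffold"
        new.nfrag_end = 0
        new.cfrag_start = new.n + 1
        new.closed = False
        new.cutpoint = None
        new.touch()
        return new

    def set_loop(self, k: int, l: int, strip: bool = True) -> None:
        """Declare residues k..l (inclusive) as the loop to be rebuilt."""
        if not (1 <= k <= l <= self.n):
            raise ValueError("inverted or out-of-range loop bounds")
        if k == 1 or l == self.n:
            raise ValueError("loop must be interior to the chain")
        self.loop = (k, l)
        if strip:
            for r in range(k, l + 1):
                self.residues.pop(r, None)
                self.kind.pop(r, None)
                self.chi[r] = None
                self.bb[r] = {"phi": None, "psi": None, "omega": None}
        self.nfrag_end = k - 1
        self.cfrag_start = l + 1
        self.closed = False
        self.cutpoint = None
        # anchor torsions, recovered from scaffold atoms where possible
        a = self.residues[k - 1]
        if "O" in a:
            self.bb[k - 1]["psi"] = wrap_angle(
                dihedral(a["N"], a["CA"], a["C"], a["O"]) + 180.0)
        elif self.bb[k - 1]["psi"] is None:
            self.bb[k - 1]["psi"] = 150.0
        b = self.residues[l + 1]
        if "H" in b:
            self.bb[l + 1]["phi"] = wrap_angle(
                dihedral(b["H"], b["N"], b["CA"], b["C"]) + 180.0)
        elif self.bb[l + 1]["phi"] is None:
            self.bb[l + 1]["phi"] = -120.0
        if self.bb[l + 1]["omega"] is None:
            self.bb[l + 1]["omega"] = 180.0
        self.touch()

    # --------------------------------------------------------- fragment ops

    def append_residue(self, pos: int, phi: float = -120.0, psi: float = 120.0,
                       omega: float = 180.0) -> None:
        """Append residue ``pos`` (with methylamide cap) to the N-fragment."""
        if self.closed:
            raise ValueError("chain already closed")
        if pos in self.residues:
            raise ValueError(f"residue {pos} already built")
        if pos != self.nfrag_end + 1:
            raise ValueError(f"append position {pos} not adjacent to N-fragment "
                             f"end {self.nfrag_end}")
        t = self.topo(pos)
        self.bb[pos]["phi"] = -65.0 if t.name3 == "PRO" else wrap_angle(phi)
        self.bb[pos]["psi"] = wrap_angle(psi)
        self.bb[pos]["omega"] = wrap_angle(omega)
        self.chi[pos] = [180.0] * t.n_chi
        self.kind[pos] = "nfrag"
        self.nfrag_end = pos
        self.rebuild("n")

    def prepend_residue(self, pos: int, phi: float = -120.0, psi: float = 120.0,
                        omega: float = 180.0) -> None:
        """Prepend residue ``pos`` (with acetyl cap) to the C-fragment."""
        if self.closed:
            raise ValueError("chain already closed")
        if pos in self.residues:
            raise ValueError(f"residue {pos} already built")
        if pos != self.cfrag_start - 1:
            raise ValueError(f"prepend position {pos} not adjacent to C-fragment "
                             f"start {self.cfrag_start}")
        t = self.topo(pos)
        self.bb[pos]["phi"] = -65.0 if t.name3 == "PRO" else wrap_angle(phi)
        self.bb[pos]["psi"] = wrap_angle(psi)
        self.bb[pos]["omega"] = wrap_angle(omega)
        self.chi[pos] = [180.0] * t.n_chi
        self.kind[pos] = "cfrag"
        self.cfrag_start = pos
        self.rebuild("c")

    def mark_closed(self) -> None:
        """Declare the chain formally closed at cutpoint = N-fragment end."""
        if self.nfrag_end + 1 != self.cfrag_start:
            raise ValueError("fragments not adjacent; cannot close")
        c = self.nfrag_end
        if not (self.loop and self.loop[0] - 1 <= c <= self.loop[1]):
            raise ValueError("cutpoint must lie inside the loop "
                             "or at either loop boundary")
        self.closed = True
        self.cutpoint = c
        if self.bb[c + 1]["omega"] is None:
            self.bb[c + 1]["omega"] = 180.0
        self.rebuild("both")

    # ------------------------------------------------------------- torsions

    def _owner(self, r: int, name: str) -> str:
        """Which fragment a backbone torsion drives ('n' or 'c')."""
        if name not in BB_NAMES:
            raise ValueError(f"unknown torsion {name!r}")
        k = self.loop[0] if self.loop else 1
        l = self.loop[1] if self.loop else self.n
        if name == "psi" and r == k - 1:
            if not self.sample_loop_takeoff:
                raise ValueError("loop-takeoff psi is fixed (sample_loop_takeoff off)")
            return "n"
        if self.nfrag_end >= k and k <= r <= self.nfrag_end:
            return "n"
        if self.cfrag_start <= l and self.cfrag_start <= r <= l:
            return "c"
        if self.closed and r == self.cutpoint + 1 and name == "omega":
            return "n"  # drives the virtual CA only
        raise ValueError(f"torsion {name} of residue {r} is not movable")

    def set_torsion(self, r: int, name: str, value: float) -> None:
        owner = self._owner(r, name)
        self.bb[r][name] = wrap_angle(value)
        self.rebuild(owner)

    def get_torsion(self, r: int, name: str) -> float | None:
        return self.bb[r][name]

    def set_chi(self, r: int, values: Iterable[float]) -> None:
        if r not in self.residues:
            raise ValueError(f"residue {r} not built")
        values = [wrap_angle(v) for v in values]
        if len(values) != self.topo(r).n_chi:
            raise ValueError("chi count mismatch")
        self.chi[r] = values
        self._build_sidechain(r)
        self.touch()

    # ------------------------------------------------------------- building

    def _build_sidechain(self, r: int) -> None:
        t = self.topo(r)
        res = self.residues[r]
        for name in list(res):
            if name not in ("N", "CA", "C", "O", "H", "NT", "HT", "CT",
                            "CP", "OP", "CMP", "VN", "VCA", "VC"):
                del res[name]
        chis = self.chi[r]
        if chis is None:
            return
        for a in t.sidechain:
            tor = a.torsion if a.torsion is not None else chis[a.chi_index] + a.chi_offset
            res[a.name] = place_atom(res[a.parents[0]], res[a.parents[1]],
                                     res[a.parents[2]], a.bond, a.angle, tor)

    def _place_backbone_h(self, r: int) -> None:
        if self.restype(r) == "PRO":
            return
        bbp = topo.backbone_params()
        res = self.residues[r]
        phi = self.bb[r]["phi"]
        if phi is None:
            return
        res["H"] = place_atom(res["N"], res["CA"], res["C"],
                              bbp["bond_N_H"], bbp["angle_H_N_CA"], phi + 180.0)

    def _rebuild_nfrag(self, start: int | None = None, anchor: int | None = None,
                       cap: bool | None = None) -> None:
        k = self.loop[0] if self.loop else 1
        start = k if start is None else start
        anchor = k - 1 if anchor is None else anchor
        if self.nfrag_end < start:
            return
        bbp = topo.backbone_params()
        prev = self.residues[anchor]
        for r in range(start, self.nfrag_end + 1):
            res: dict[str, np.ndarray] = {}
            res["N"] = place_atom(prev["C"], prev["CA"], prev["N"],
                                  bbp["bond_C_N"], bbp["angle_CA_C_N"],
                                  self.bb[r - 1]["psi"])
            res["CA"] = place_atom(res["N"], prev["C"], prev["CA"],
                                   bbp["bond_N_CA"], bbp["angle_C_N_CA"],
                                   self.bb[r]["omega"])
            res["C"] = place_atom(res["CA"], res["N"], prev["C"],
                                  bbp["bond_CA_C"], bbp["angle_N_CA_C"],
                                  self.bb[r]["phi"])
            res["O"] = place_atom(res["C"], res["CA"], res["N"],
                                  bbp["bond_C_O"], bbp["angle_CA_C_O"],
                                  self.bb[r]["psi"] + 180.0)
            self.residues[r] = res
            self._place_backbone_h(r)
            self._build_sidechain(r)
            prev = res
        end = self.nfrag_end
        do_cap = (not self.closed) if cap is None else cap
        if do_cap and end >= k:
            self._place_cap_methylamide(end)
        if self.closed:
            self._place_virtuals()
        self.touch()

    def _rebuild_cfrag(self) -> None:
        if self.loop is None:
            return
        l = self.loop[1]
        if self.cfrag_start > l:
            return
        bbp = topo.backbone_params()
        nxt = self.residues[l + 1]
        for r in range(l, self.cfrag_start - 1, -1):
            res: dict[str, np.ndarray] = {}
            res["C"] = place_atom(nxt["N"], nxt["CA"], nxt["C"],
                                  bbp["bond_C_N"], bbp["angle_C_N_CA"],
                                  self.bb[r + 1]["phi"])
            res["CA"] = place_atom(res["C"], nxt["N"], nxt["CA"],
                                   bbp["bond_CA_C"], bbp["angle_CA_C_N"],
                                   self.bb[r + 1]["omega"])
            res["N"] = place_atom(res["CA"], res["C"], nxt["N"],
                                  bbp["bond_N_CA"], bbp["angle_N_CA_C"],
                                  self.bb[r]["psi"])
            res["O"] = place_atom(res["C"], res["CA"], res["N"],
                                  bbp["bond_C_O"], bbp["angle_CA_C_O"],
                                  self.bb[r]["psi"] + 180.0)
            self.residues[r] = res
            self._place_backbone_h(r)
            self._build_sidechain(r)
            nxt = res
        if (not self.closed) and self.cfrag_start <= l:
            self._place_cap_acetyl(self.cfrag_start)
        if self.closed:
            self._place_virtuals()
        self.touch()

    def rebuild(self, which: str = "both") -> None:
        if which in ("n", "both"):
            self._rebuild_nfrag()
        if which in ("c", "both"):
            self._rebuild_cfrag()

    def _place_cap_methylamide(self, r: int) -> None:
        res = self.residues[r]
        for name, p1, p2, p3, bond, angle, tor in topo.cap_templates()["methylamide"]:
            t = self.bb[r]["psi"] if tor == "psi" else float(tor)
            res[name] = place_atom(res[p1], res[p2], res[p3], bond, angle, t)

    def _place_cap_acetyl(self, r: int) -> None:
        res = self.residues[r]
        for name, p1, p2, p3, bond, angle, tor in topo.cap_templates()["acetyl"]:
            t = self.bb[r]["phi"] if tor == "phi" else float(tor)
            res[name] = place_atom(res[p1], res[p2], res[p3], bond, angle, t)

    def _place_virtuals(self) -> None:
        c = self.cutpoint
        bbp = topo.backbone_params()
        a = self.residues[c]
        b = self.residues[c + 1]
        for name in ("NT", "HT", "CT"):
            a.pop(name, None)
        for name in ("CP", "OP", "CMP"):
            b.pop(name, None)
        a["VN"] = place_atom(a["C"], a["CA"], a["N"],
                             bbp["bond_C_N"], bbp["angle_CA_C_N"], self.bb[c]["psi"])
        a["VCA"] = place_atom(a["VN"], a["C"], a["CA"],
                              bbp["bond_N_CA"], bbp["angle_C_N_CA"],
                              self.bb[c + 1]["omega"])
        b["VC"] = place_atom(b["N"], b["CA"], b["C"],
                             bbp["bond_C_N"], bbp["angle_C_N_CA"],
                             self.bb[c + 1]["phi"])

    # ------------------------------------------------------------ measuring

    def measure_phi(self, r: int) -> float | None:
        if not (self.has_atom(r - 1, "C") and r in self.residues):
            return None
        a, b = self.residues[r - 1], self.residues[r]
        return dihedral(a["C"], b["N"], b["CA"], b["C"])

    def measure_psi(self, r: int) -> float | None:
        if not (r in self.residues and self.has_atom(r + 1, "N")):
            if r in self.residues and "O" in self.residues[r]:
                res = self.residues[r]
                return wrap_angle(dihedral(res["N"], res["CA"], res["C"], res["O"]) + 180.0)
            return None
        a, b = self.residues[r], self.residues[r + 1]
        return dihedral(a["N"], a["CA"], a["C"], b["N"])

    def measure_omega(self, r: int) -> float | None:
        if not (self.has_atom(r - 1, "CA") and r in self.residues):
            return None
        a, b = self.residues[r - 1], self.residues[r]
        return dihedral(a["CA"], a["C"], b["N"], b["CA"])

    def measure_chi(self, r: int) -> list[float]:
        t = self.topo(r)
        res = self.residues[r]
        out = []
        for quad in t.chi:
            if not all(n in res for n in quad):
                return []
            out.append(dihedral(*(res[n] for n in quad)))
        return out

    def chainbreak_deviations(self) -> np.ndarray:
        """The three virtual/real atom-pair deviations (Angstrom)."""
        if not self.closed:
            raise ValueError("no cutpoint set")
        c = self.cutpoint
        a, b = self.residues[c], self.residues[c + 1]
        return np.array([
            float(np.linalg.norm(a["VN"] - b["N"])),
            float(np.linalg.norm(a["VCA"] - b["CA"])),
            float(np.linalg.norm(b["VC"] - a["C"])),
        ])

    def closure_deviation(self) -> float:
        """RMS of the three closure atom-pair deviations (Angstrom)."""
        d = self.chainbreak_deviations()
        return float(np.sqrt(np.mean(d ** 2)))


# ------------------------------------------------------- functional wrappers


def build_from_torsions(sequence: str, torsions: dict[int, dict] | None = None,
                        anchor_frame: np.ndarray | None = None,
                        chi: dict[int, list[float]] | None = None) -> Conformation:
    """Build a chain from per-residue torsions (see Conformation.from_torsions)."""
    return Conformation.from_torsions(sequence, torsions, anchor_frame, chi)


def append_capped_residue(conf: Conformation, pos: int, **torsions) -> Conformation:
    new = conf.copy()
    new.append_residue(pos, **torsions)
    return new


def prepend_capped_residue(conf: Conformation, pos: int, **torsions) -> Conformation:
    new = conf.copy()
    new.prepend_residue(pos, **torsions)
    return new


def set_torsion(conf: Conformation, residue: int, name: str, value: float) -> Conformation:
    new = conf.copy()
    if name.startswith("chi"):
        idx = int(name[3:]) - 1
        chis = list(new.chi[residue])
        chis[idx] = value
        new.set_chi(residue, chis)
    else:
        new.set_torsion(residue, name, value)
    return new
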