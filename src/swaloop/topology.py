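"""Residue topology: ideal internal coordinates and per-residue templates.

All conformations are built from a single versioned table of ideal bond
lengths, bond angles and reference torsions (``data/ideal_geometry.yaml``).
Bond lengths and angles are fixed throughout: the only degrees of freedom
anywhere in the package are torsion angles.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import yaml

AA1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA3TO1 = {v: k for k, v in AA1TO3.items()}

BACKBONE_ATOMS = ("N", "CA", "C", "O", "H")
#: atoms treated as "backbone-like" when classifying hydrogen bonds;
#: cap atoms present the next peptide unit and count as backbone.
BACKBONE_LIKE = set(BACKBONE_ATOMS) | {"NT", "HT", "CT", "CP", "OP", "CMP", "OXT"}
VIRTUAL_ATOMS = ("VN", "VCA", "VC")


def _load_yaml(name: str) -> dict:
    ref = resources.files("swaloop.data").joinpath(name)
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class SidechainAtom:
    name: str
    parents: tuple[str, str, str]
    bond: float
    angle: float
    torsion: float | None  # fixed value, or None when chi-driven
    chi_index: int | None  # 0-based chi this atom's torsion reads
    chi_offset: float


@dataclass(frozen=True)
class ResidueTopology:
    """Template for one amino-acid type.

    Every non-root atom is placed from three already-defined parent atoms by
    one bond length, one bond angle and one torsion.  ``chi`` holds the
    4-atom dihedral definitions of the side-chain torsions; ``chi_periodicity``
    the local torsional symmetry used by the torsion-preference energy term.
    """

    name3: str
    sidechain: tuple[SidechainAtom, ...]
    chi: tuple[tuple[str, str, str, str], ...]
    chi_periodicity: tuple[int, ...]

    @property
    def n_chi(self) -> int:
        return len(self.chi)

    @property
    def has_cb(self) -> bool:
        return any(a.name == "CB" for a in self.sidechain)


def _parse_torsion(spec) -> tuple[float | None, int | None, float]:
    if isinstance(spec, (int, float)):
        return float(spec), None, 0.0
    s = str(spec)
    if not s.startswith("chi"):
        raise ValueError(f"bad torsion spec {spec!r}")
    body = s[3:]
    for sep in ("+", "-"):
        if sep in body:
            k, off = body.split(sep)
            return None, int(k) - 1, float(sep + off)
    return None, int(body) - 1, 0.0


@functools.lru_cache(maxsize=1)
def _tables() -> dict:
    return _load_yaml("ideal_geometry.yaml")


@functools.lru_cache(maxsize=1)
def backbone_params() -> dict:
    return dict(_tables()["backbone"])


@functools.lru_cache(maxsize=1)
def cap_templates() -> dict:
    return {k: [tuple(rec) for rec in v] for k, v in _tables()["caps"].items()}


@functools.lru_cache(maxsize=None)
def residue_topology(code: str) -> ResidueTopology:
    """Topology for a residue given its 1- or 3-letter code."""
    name3 = AA1TO3.get(code.upper(), code.upper())
    try:
        raw = _tables()["residues"][name3]
    except KeyError:
        raise KeyError(f"unknown residue code {code!r}") from None
    sc = []
    for rec in raw["sidechain"]:
        name, p1, p2, p3, bond, angle, tors = rec
        fixed, chi_idx, chi_off = _parse_torsion(tors)
        sc.append(SidechainAtom(name, (p1, p2, p3), float(bond), float(angle),
                                fixed, chi_idx, chi_off))
    return ResidueTopology(
        name3=name3,
        sidechain=tuple(sc),
        chi=tuple(tuple(c) for c in raw["chi"]),
        chi_periodicity=tuple(raw["chi_periodicity"]),
    )
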