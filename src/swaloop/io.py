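"""Formats: PDB, FASTA, loop files, ensemble archives, fixture bundles.

The PDB reader is tolerant of missing side-chains and missing loop residues
(their absence defines the built mask); author numbering may be offset from
the 1-based FASTA numbering.  Ensemble archives are plain directories with a
multi-model PDB (``models.pdb``) and a tab-separated score table
(``scores.tsv``), inspectable with standard viewers.
"""

from __future__ import annotations

import os
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import yaml

from .buildup import StageEnsemble
from .energy import TERMS
from .geometry import Conformation
from .topology import AA1TO3, AA3TO1

_SKIP_ATOMS = {"NT", "HT", "CT", "CP", "OP", "CMP", "VN", "VCA", "VC"}


def read_fasta(path) -> str:
    """Single-record FASTA -> sequence string."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected one FASTA record, found {len(records)}")
    return str(records[0].seq).upper()


def read_loopfile(path) -> list[tuple[int, int]]:
    """Whitespace-separated ``start end`` per line, 1-based inclusive."""
    loops = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 'start end'")
            start, end = int(parts[0]), int(parts[1])
            if end < start:
                raise ValueError(f"{path}:{ln}: inverted loop bounds")
            loops.append((start, end))
    if not loops:
        raise ValueError(f"{path}: no loop definitions found")
    return loops


def _element_of(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def write_pdb(confs: Conformation | list[Conformation], path) -> None:
    """Write one model or a MODEL/ENDMDL ensemble; chain A, occupancy 1.00,
    element column populated.  Cap and virtual atoms are omitted."""
    if isinstance(confs, Conformation):
        confs = [confs]
    lines = []
    multi = len(confs) > 1
    for mi, conf in enumerate(confs, 1):
        if multi:
            lines.append(f"MODEL     {mi:4d}")
        serial = 1
        for r in sorted(conf.residues):
            if r == 0 or r not in conf.kind:
                continue
            res3 = conf.restype(r)
            for name, pos in conf.residues[r].items():
                if name in _SKIP_ATOMS:
                    continue
                el = _element_of(name)
                nm = name if len(name) >= 4 else f" {name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {nm:<4s}{res3:>4s} A{r:4d}    "
                    f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {el:>2s}")
                serial += 1
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdb(path, sequence: str | None = None, offset: int = 0) -> Conformation:
    """Read a (possibly partial) structure into a Conformation.

    ``offset`` maps author numbering to 1-based FASTA numbering
    (fasta_index = author_index - offset).  With ``sequence`` given, residue
    identities are checked and conflicts are fatal with a diff report;
    otherwise the sequence is inferred (gaps filled with alanine).
    Residues present become scaffold; missing interior residues and missing
    side-chains are simply absent (defining the built mask).
    """
    st = gemmi.read_pdb(str(path))
    st.setup_entities()
    model = st[0]
    found: dict[int, tuple[str, dict[str, np.ndarray]]] = {}
    for chain in model:
        for res in chain:
            idx = res.seqid.num - offset
            atoms = {a.name: np.array([a.pos.x, a.pos.y, a.pos.z])
                     for a in res}
            found[idx] = (res.name, atoms)
    if not found:
        raise ValueError(f"{path}: no ATOM records")
    if sequence is None:
        n = max(found)
        seq = "".join(AA3TO1.get(found[r][0], "A") if r in found else "A"
                      for r in range(1, n + 1))
    else:
        seq = sequence.upper()
        mism = [(r, AA1TO3[seq[r - 1]], name) for r, (name, _) in found.items()
                if 1 <= r <= len(seq) and AA1TO3[seq[r - 1]] != name]
        if mism:
            diff = "; ".join(f"res {r}: FASTA {a} vs PDB {b}" for r, a, b in mism[:10])
            raise ValueError(f"{path}: sequence/structure mismatch: {diff}")
        out_of_range = [r for r in found if not 1 <= r <= len(seq)]
        if out_of_range:
            raise ValueError(f"{path}: residues outside FASTA range "
                             f"(check numbering offset): {out_of_range[:10]}")
    conf = Conformation(seq)
    for r, (_name, atoms) in sorted(found.items()):
        conf.residues[r] = {n: p for n, p in atoms.items()}
        conf.kind[r] = "scaffold"
        chis = conf.measure_chi(r)
        # backbone-only residues get chi None: side-chain awaits prepacking
        conf.chi[r] = chis if chis else (None if conf.topo(r).n_chi else [])
    # record backbone torsions where measurable
    for r in sorted(found):
        conf.bb[r]["phi"] = conf.measure_phi(r)
        conf.bb[r]["psi"] = conf.measure_psi(r)
        conf.bb[r]["omega"] = conf.measure_omega(r)
    conf.touch()
    return conf


# ----------------------------------------------------------------- archives


def archive_write(ensemble: StageEnsemble, out_dir,
                  reference: Conformation | None = None,
                  loop_range: tuple[int, int] | None = None) -> None:
    """Write an ensemble archive: models.pdb + scores.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    models = ensemble.models
    write_pdb(models, out / "models.pdb")
    rows = []
    for i, m in enumerate(models):
        row = {"model": i}
        row.update({t: m.energy.terms[t] for t in TERMS})
        row["total"] = m.energy.total
        row["closure_deviation"] = m.closure_deviation() if m.closed else 0.0
        if reference is not None and loop_range is not None:
            from .evaluate import ca_rmsd

            row["ca_rmsd"] = ca_rmsd(m, reference, loop_range)
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "scores.tsv", sep="\t", index=False)


def archive_read(in_dir) -> tuple[list[dict[int, dict[str, np.ndarray]]], pd.DataFrame]:
    """Read an archive back: per-model atom dictionaries plus score table."""
    in_dir = Path(in_dir)
    scores = pd.read_csv(in_dir / "scores.tsv", sep="\t")
    st = gemmi.read_pdb(str(in_dir / "models.pdb"))
    models = []
    for model in st:
        res: dict[int, dict[str, np.ndarray]] = {}
        for chain in model:
            for r in chain:
                res[r.seqid.num] = {a.name: np.array([a.pos.x, a.pos.y, a.pos.z])
                                    for a in r}
        models.append(res)
    return models, scores


# ---------------------------------------------------------- fixture bundles


def write_fixture_bundle(problem: Conformation, answer: Conformation,
                         loop: tuple[int, int], out_dir, meta: dict | None = None
                         ) -> None:
    """problem.pdb + native.pdb + seq.fasta + loop.txt + meta.yaml."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_pdb(problem, out / "problem.pdb")
    write_pdb(answer, out / "native.pdb")
    (out / "seq.fasta").write_text(f">fixture\n{problem.sequence}\n")
    (out / "loop.txt").write_text(f"{loop[0]} {loop[1]}\n")
    with open(out / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta or {}, fh)


def read_fixture_bundle(in_dir) -> tuple[Conformation, Conformation,
                                         tuple[int, int], dict]:
    in_dir = Path(in_dir)
    seq = read_fasta(in_dir / "seq.fasta")
    loop = read_loopfile(in_dir / "loop.txt")[0]
    problem = read_pdb(in_dir / "problem.pdb", sequence=seq)
    problem.set_loop(*loop)
    answer = read_pdb(in_dir / "native.pdb", sequence=seq)
    meta = {}
    meta_path = in_dir / "meta.yaml"
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or {}
    return problem, answer, loop, meta
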