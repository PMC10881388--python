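"""File formats: PDB models (via gemmi), delimited reflection tables, YAML.

Reflection tables are plain whitespace-delimited text with a header line
``h k l F sigF [phase]`` and ``#``-comment lines carrying the cell and the
resolution range — transparent, diffable, and sufficient at desk scale.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import yaml

from .models import AtomicModel
from .scattering import ReflectionSet


class PDBParseError(ValueError):
    pass


_REQUIRED_FLOAT_COLS = [(30, 38), (38, 46), (46, 54), (54, 60), (60, 66)]


def read_pdb(path: str | Path) -> AtomicModel:
    """Read an AtomicModel from a PDB file.

    ATOM/HETATM records are validated field-by-field first so malformed
    lines are reported with their line number, then the file is parsed with
    gemmi.
    """
    path = Path(path)
    text = path.read_text()
    n_atom_lines = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            n_atom_lines += 1
            if len(line) < 54:
                raise PDBParseError(f"{path}:{lineno}: truncated atom record")
            for lo, hi in _REQUIRED_FLOAT_COLS:
                fieldtxt = line[lo:hi].strip()
                if fieldtxt:
                    try:
                        float(fieldtxt)
                    except ValueError as err:
                        raise PDBParseError(
                            f"{path}:{lineno}: malformed numeric field "
                            f"{fieldtxt!r} in columns {lo + 1}-{hi}") from err
    if n_atom_lines == 0:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")

    st = gemmi.read_pdb_string(text)
    cell = st.cell
    atom_id, element, res_name, res_seq, xyz, b, occ = [], [], [], [], [], [], []
    for model in st:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    atom_id.append(atom.name)
                    element.append(atom.element.name.upper())
                    res_name.append(residue.name)
                    res_seq.append(residue.seqid.num)
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    b.append(atom.b_iso)
                    occ.append(atom.occ)
        break  # first model only
    return AtomicModel(atom_id=np.array(atom_id, dtype=object),
                       element=np.array(element, dtype=object),
                       res_name=np.array(res_name, dtype=object),
                       res_seq=np.array(res_seq, dtype=int),
                       xyz=np.array(xyz, dtype=float),
                       b=np.array(b, dtype=float), occ=np.array(occ, dtype=float),
                       cell=(cell.a, cell.b, cell.c))


def write_pdb(model: AtomicModel, path: str | Path) -> None:
    """Write an AtomicModel as a standard PDB file (P1, orthogonal cell)."""
    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(*model.cell, 90.0, 90.0, 90.0)
    st.spacegroup_hm = "P 1"
    gm = gemmi.Model("1")
    chain = gemmi.Chain("A")
    current = None
    residue = None
    for i in range(model.n_atoms):
        key = (int(model.res_seq[i]), str(model.res_name[i]))
        if key != current:
            residue = gemmi.Residue()
            residue.name = str(model.res_name[i])
            residue.seqid = gemmi.SeqId(int(model.res_seq[i]), " ")
            chain.add_residue(residue)
            current = key
        atom = gemmi.Atom()
        atom.name = str(model.atom_id[i])
        atom.element = gemmi.Element(str(model.element[i]).capitalize())
        atom.pos = gemmi.Position(*model.xyz[i])
        atom.b_iso = float(model.b[i])
        atom.occ = float(model.occ[i])
        chain[-1].add_atom(atom)
    gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def write_reflections(refl: ReflectionSet, path: str | Path) -> None:
    """Write a reflection table as delimited text (h k l F sigF [phase])."""
    path = Path(path)
    cols = {"h": refl.hkl[:, 0], "k": refl.hkl[:, 1], "l": refl.hkl[:, 2],
            "F": refl.f, "sigF": refl.sigma}
    if refl.phase is not None:
        cols["phase"] = refl.phase
    df = pd.DataFrame(cols)
    buf = _io.StringIO()
    a, b, c = refl.cell
    buf.write(f"# cell {a:.6f} {b:.6f} {c:.6f}\n")
    buf.write(f"# resolution {refl.d_min:.6f} {refl.d_max:.6f}\n")
    df.to_csv(buf, sep=" ", index=False, float_format="%.6f")
    path.write_text(buf.getvalue())


def read_reflections(path: str | Path) -> ReflectionSet:
    """Read a reflection table written by :func:`write_reflections`."""
    path = Path(path)
    cell = None
    d_min, d_max = None, None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].split()
            if parts and parts[0] == "cell":
                cell = tuple(float(x) for x in parts[1:4])
            elif parts and parts[0] == "resolution":
                d_min, d_max = float(parts[1]), float(parts[2])
    if cell is None:
        raise ValueError(f"{path}: missing '# cell a b c' header")
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    for col in ("h", "k", "l", "F", "sigF"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    hkl = df[["h", "k", "l"]].to_numpy(dtype=int)
    phase = df["phase"].to_numpy(dtype=float) if "phase" in df.columns else None
    if d_min is None:
        a, b, c = cell
        s2 = (hkl[:, 0] / a) ** 2 + (hkl[:, 1] / b) ** 2 + (hkl[:, 2] / c) ** 2
        d_min, d_max = float(1 / np.sqrt(s2.max())), float(1 / np.sqrt(s2.min()))
    return ReflectionSet(cell, hkl, df["F"].to_numpy(dtype=float), phase,
                         df["sigF"].to_numpy(dtype=float), d_min, d_max)


def write_yaml(obj: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
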