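"""Geometry metrics for haem photolysis intermediates.

Iron out-of-plane displacement, Fe-His distance, porphyrin doming
amplitude, difference-distance (Go) matrices, per-residue displacement
from the haem centre, and radius of gyration. All metrics operate on
:class:`~trsfx.models.AtomicModel` instances with PDB-style atom labels:
the haem core is ``FE``, pyrrole nitrogens ``NA..ND``, alpha/beta ring
carbons ``C1A..C4D``, meso carbons ``CHA..CHD``; the proximal histidine
mimic carries ``NE2``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import AtomicModel, check_same_roster

PYRROLE_N = ["NA", "NB", "NC", "ND"]
ALPHA_C = ["C1A", "C4A", "C1B", "C4B", "C1C", "C4C", "C1D", "C4D"]
BETA_C = ["C2A", "C3A", "C2B", "C3B", "C2C", "C3C", "C2D", "C3D"]
MESO_C = ["CHA", "CHB", "CHC", "CHD"]
HAEM_CORE = ["FE"] + PYRROLE_N + ALPHA_C + BETA_C + MESO_C  # Fe + 24 ring atoms

# Out-of-plane doming mode: Fe and the inner ring (pyrrole N) move toward the
# proximal side while the ring periphery moves the opposite way. The raw
# pattern is normalized to unit Euclidean norm at use, so the reported doming
# amplitude is the length of the displacement projected onto this mode.
_DOMING_RAW = {"FE": 1.0}
_DOMING_RAW.update({n: 0.5 for n in PYRROLE_N})
_DOMING_RAW.update({c: -0.15 for c in ALPHA_C})
_DOMING_RAW.update({c: -0.40 for c in BETA_C})
_DOMING_RAW.update({c: -0.45 for c in MESO_C})


def doming_mode_vector() -> tuple[list[str], np.ndarray]:
    """(labels, unit-norm weights) of the doming mode over the haem core."""
    w = np.array([_DOMING_RAW[lab] for lab in HAEM_CORE])
    return HAEM_CORE, w / np.linalg.norm(w)


def _core_indices(model: AtomicModel, labels: list[str]) -> np.ndarray:
    missing = [lab for lab in labels if not np.any(model.atom_id == lab)]
    if missing:
        raise KeyError(f"model is missing haem atoms: {missing}")
    return np.array([model.index_of(lab) for lab in labels])


def fit_plane(points: np.ndarray, orient_toward: np.ndarray | None = None
              ) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares plane through >= 3 points.

    Returns (unit normal, centroid). With ``orient_toward`` given, the normal
    is flipped if needed so it points from the centroid toward that position.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 3:
        raise ValueError("plane fit requires at least 3 points")
    centroid = points.mean(axis=0)
    centered = points - centroid
    evals, evecs = np.linalg.eigh(centered.T @ centered)
    if evals[1] < 1e-10 * max(evals[2], 1e-30):
        raise ValueError("points are collinear; plane is not defined")
    normal = evecs[:, 0]  # eigenvector of the smallest eigenvalue
    if orient_toward is not None:
        if np.dot(normal, np.asarray(orient_toward) - centroid) < 0:
            normal = -normal
    return normal, centroid


def _haem_frame(model: AtomicModel, proximal: tuple[str, int] = ("NE2", 93)
                ) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares pyrrole-N plane, normal oriented toward the proximal His."""
    n_idx = _core_indices(model, PYRROLE_N)
    his = model.position(*proximal)
    return fit_plane(model.xyz[n_idx], orient_toward=his)


def fe_out_of_plane(model: AtomicModel,
                    proximal: tuple[str, int] = ("NE2", 93)) -> float:
    """Signed Fe displacement from the pyrrole-N plane; positive toward the His."""
    normal, centroid = _haem_frame(model, proximal)
    fe = model.position("FE")
    return float(np.dot(fe - centroid, normal))


def fe_his_distance(model: AtomicModel,
                    proximal: tuple[str, int] = ("NE2", 93)) -> float:
    """Distance between the haem iron and the proximal His nitrogen."""
    return float(np.linalg.norm(model.position("FE") - model.position(*proximal)))


def haem_centroid(model: AtomicModel, reference: str = "nitrogens") -> np.ndarray:
    """Centre of the four pyrrole N ('nitrogens') or of the 25-atom core ('core')."""
    labels = PYRROLE_N if reference == "nitrogens" else HAEM_CORE
    idx = _core_indices(model, labels)
    return model.xyz[idx].mean(axis=0)


def doming_coefficient(model: AtomicModel, reference: AtomicModel,
                       proximal: tuple[str, int] = ("NE2", 93)) -> float:
    """Doming amplitude: out-of-plane displacement projected on the doming mode.

    Displacements (model - reference) of the 25 haem-core atoms are projected
    on the reference haem normal (oriented toward the proximal His) and then
    onto the unit-norm doming mode; in-plane motion contributes nothing.
    """
    labels, weights = doming_mode_vector()
    idx_m = _core_indices(model, labels)
    idx_r = _core_indices(reference, labels)
    if np.any(model.atom_id[idx_m] != reference.atom_id[idx_r]):
        raise ValueError("haem-core labels differ between model and reference")
    normal, _ = _haem_frame(reference, proximal)
    disp = (model.xyz[idx_m] - reference.xyz[idx_r]) @ normal
    return float(np.dot(disp, weights))


def difference_distance_matrix(light: AtomicModel, dark: AtomicModel,
                               selection: str = "CA") -> np.ndarray:
    """Go plot: pairwise-distance change ``d_ij(light) - d_ij(dark)``.

    Computed over the atoms named ``selection`` (default C-alpha), matched by
    residue index. Symmetric with zero diagonal; invariant under rigid-body
    motion of either state.
    """
    ml = light.select(light.atom_id == selection)
    md = dark.select(dark.atom_id == selection)
    if ml.n_atoms != md.n_atoms or np.any(ml.res_seq != md.res_seq):
        raise ValueError(f"{selection} rosters differ between the two models")
    if ml.n_atoms == 0:
        raise ValueError(f"no atoms named {selection!r}")

    def pdist_matrix(xyz):
        delta = xyz[:, None, :] - xyz[None, :, :]
        return np.sqrt((delta ** 2).sum(axis=-1))

    return pdist_matrix(ml.xyz) - pdist_matrix(md.xyz)


BACKBONE = ["N", "CA", "C"]


def displacement_from_haem(models: list[tuple[float, AtomicModel]],
                           dark: AtomicModel) -> pd.DataFrame:
    """Per-residue backbone displacement from the haem centre versus time.

    For each backbone N/CA/C atom, Delta(t) = |r_atom(t) - c(t)| -
    |r_atom(dark) - c(dark)| with c the centroid of the four pyrrole N of
    the same model, so a rigid-body motion of the whole structure cancels.
    Returns a tidy frame (delay_fs, res_seq, atom, delta_A).
    """
    c_dark = haem_centroid(dark)
    rows = []
    for delay, model in models:
        check_same_roster(model, dark)
        c_t = haem_centroid(model)
        for name in BACKBONE:
            sel = model.atom_id == name
            for i in np.flatnonzero(sel):
                d_t = np.linalg.norm(model.xyz[i] - c_t)
                d_0 = np.linalg.norm(dark.xyz[i] - c_dark)
                rows.append({"delay_fs": delay, "res_seq": int(model.res_seq[i]),
                             "atom": name, "delta_A": float(d_t - d_0)})
    return pd.DataFrame(rows)


def radius_of_gyration(model: AtomicModel, mass_weighted: bool = False) -> float:
    """R_g over non-hydrogen atoms, unweighted by default."""
    heavy = model.element != "H"
    if heavy.sum() < 2:
        raise ValueError("radius of gyration requires at least 2 heavy atoms")
    xyz = model.xyz[heavy]
    if mass_weighted:
        # coarse integer masses suffice for a point-atom toolkit
        masses = {"H": 1.0, "C": 12.0, "N": 14.0, "O": 16.0, "S": 32.1, "FE": 55.8}
        w = np.array([masses[e] for e in model.element[heavy]])
    else:
        w = np.ones(heavy.sum())
    center = (w[:, None] * xyz).sum(axis=0) / w.sum()
    return float(np.sqrt((w * ((xyz - center) ** 2).sum(axis=1)).sum() / w.sum()))
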