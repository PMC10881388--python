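"""Atomic models and ground-truth kinetic schedules.

The containers here are deliberately minimal: point atoms with an element,
an isotropic B factor and an occupancy, living in an orthogonal P1 box.
That is all the downstream crystallographic math (structure factors,
difference maps, geometry metrics) needs, and it keeps the synthetic
two-state system fully transparent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# Electron counts for the elements the toy systems use.
ELECTRON_COUNTS: dict[str, int] = {
    "H": 1,
    "C": 6,
    "N": 7,
    "O": 8,
    "S": 16,
    "FE": 26,
}


class GeometryError(ValueError):
    """Raised when an atomic configuration violates a geometric invariant."""


@dataclass
class AtomicModel:
    """A labeled point-atom structure in an orthogonal P1 cell.

    Parameters
    ----------
    atom_id : array of str
        Unique atom labels (PDB-style names, e.g. ``"FE"``, ``"NA"``, ``"CA"``).
    element : array of str
        Element symbols, upper case; must be present in :data:`ELECTRON_COUNTS`.
    res_name, res_seq : arrays
        Residue label and 1-based residue index per atom.
    xyz : (n, 3) float array
        Cartesian coordinates in Angstrom.
    b : (n,) float array
        Isotropic B factors in Angstrom^2; strictly positive.
    occ : (n,) float array
        Occupancies in [0, 1].
    cell : (a, b, c)
        Orthogonal box lengths in Angstrom. Space group is fixed to P1.
    """

    atom_id: np.ndarray
    element: np.ndarray
    res_name: np.ndarray
    res_seq: np.ndarray
    xyz: np.ndarray
    b: np.ndarray
    occ: np.ndarray
    cell: tuple[float, float, float]
    spacegroup: str = "P1"

    def __post_init__(self) -> None:
        self.atom_id = np.asarray(self.atom_id, dtype=object)
        self.element = np.asarray(self.element, dtype=object)
        self.res_name = np.asarray(self.res_name, dtype=object)
        self.res_seq = np.asarray(self.res_seq, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.occ = np.asarray(self.occ, dtype=float)
        self.cell = tuple(float(x) for x in self.cell)

    # -- basic queries -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atom_id)

    @property
    def electrons(self) -> np.ndarray:
        """Electron count per atom."""
        return np.array([ELECTRON_COUNTS[e] for e in self.element], dtype=float)

    def index_of(self, atom_id: str, res_seq: int | None = None) -> int:
        """Index of the (unique) atom with the given label (and residue)."""
        mask = self.atom_id == atom_id
        if res_seq is not None:
            mask &= self.res_seq == res_seq
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise KeyError(f"no atom named {atom_id!r}"
                           + (f" in residue {res_seq}" if res_seq else ""))
        if len(idx) > 1:
            raise KeyError(f"atom label {atom_id!r} is ambiguous; give res_seq")
        return int(idx[0])

    def position(self, atom_id: str, res_seq: int | None = None) -> np.ndarray:
        return self.xyz[self.index_of(atom_id, res_seq)].copy()

    def select(self, mask: np.ndarray) -> "AtomicModel":
        """Sub-model containing the atoms where ``mask`` is True."""
        return AtomicModel(
            atom_id=self.atom_id[mask],
            element=self.element[mask],
            res_name=self.res_name[mask],
            res_seq=self.res_seq[mask],
            xyz=self.xyz[mask],
            b=self.b[mask],
            occ=self.occ[mask],
            cell=self.cell,
        )

    def copy(self) -> "AtomicModel":
        return AtomicModel(
            atom_id=self.atom_id.copy(),
            element=self.element.copy(),
            res_name=self.res_name.copy(),
            res_seq=self.res_seq.copy(),
            xyz=self.xyz.copy(),
            b=self.b.copy(),
            occ=self.occ.copy(),
            cell=self.cell,
        )

    def fractional(self) -> np.ndarray:
        """Fractional coordinates, wrapped into [0, 1)."""
        return np.mod(self.xyz / np.asarray(self.cell), 1.0)

    # -- validation ----------------------------------------------------
    def validate(self, min_separation: float = 0.5) -> None:
        """Check the type invariants; raise on violation."""
        n = self.n_atoms
        for arr, name in [(self.element, "element"), (self.res_name, "res_name"),
                          (self.res_seq, "res_seq"), (self.b, "b"), (self.occ, "occ")]:
            if len(arr) != n:
                raise ValueError(f"field {name} has length {len(arr)}, expected {n}")
        if self.xyz.shape != (n, 3):
            raise ValueError(f"xyz has shape {self.xyz.shape}, expected ({n}, 3)")
        unknown = {e for e in self.element} - set(ELECTRON_COUNTS)
        if unknown:
            raise ValueError(f"elements without tabulated electron count: {unknown}")
        if np.any(self.b <= 0):
            raise ValueError("B factors must be strictly positive")
        if np.any((self.occ < 0) | (self.occ > 1)):
            raise ValueError("occupancies must lie in [0, 1]")
        if any(c <= 0 for c in self.cell):
            raise ValueError("cell lengths must be positive")
        if min_separation > 0 and n > 1:
            frac = self.fractional()
            cart = frac * np.asarray(self.cell)
            delta = cart[:, None, :] - cart[None, :, :]
            # minimum-image in the orthogonal box
            delta -= np.round(delta / np.asarray(self.cell)) * np.asarray(self.cell)
            d = np.sqrt((delta ** 2).sum(axis=-1))
            np.fill_diagonal(d, np.inf)
            if d.min() < min_separation:
                i, j = np.unravel_index(np.argmin(d), d.shape)
                raise GeometryError(
                    f"atoms {self.atom_id[i]}/{self.res_seq[i]} and "
                    f"{self.atom_id[j]}/{self.res_seq[j]} are {d.min():.2f} A apart "
                    f"(< {min_separation} A)")


def rmsd(a: AtomicModel, b: AtomicModel) -> float:
    """Coordinate RMSD between two models with identical atom rosters (no fitting)."""
    check_same_roster(a, b)
    return float(np.sqrt(np.mean(np.sum((a.xyz - b.xyz) ** 2, axis=1))))


def check_same_roster(a: AtomicModel, b: AtomicModel) -> None:
    if a.n_atoms != b.n_atoms or np.any(a.atom_id != b.atom_id) \
            or np.any(a.element != b.element) or np.any(a.res_seq != b.res_seq):
        raise ValueError("atom rosters differ between the two models")


@dataclass
class TwoStateSystem:
    """Dark (CO-bound) and excited (photolysed, CO in docking site) states.

    Both states share one atom roster; they differ only in coordinates and
    B factors. The structural deltas record how the excited state was built.
    """

    dark: AtomicModel
    excited: AtomicModel
    delta_fe: float          # Fe out-of-plane shift toward the proximal His, A
    co_translocation: np.ndarray  # bound CO carbon -> docking-site carbon, A
    helix_shift: float       # F-helix displacement away from the haem, A

    def __post_init__(self) -> None:
        check_same_roster(self.dark, self.excited)
        self.co_translocation = np.asarray(self.co_translocation, dtype=float)


@dataclass
class GroundTruthSchedule:
    """Time dependence of the synthetic photolysis reaction.

    The photolysis event itself is complete at t=0 (a constant true fraction
    ``f_plateau`` of molecules is photolysed); what evolves is the *apparent*,
    map-derived CO* occupancy (rise time ``tau_occ``), the Fe out-of-plane
    displacement (instantaneous fraction ``w_fast`` plus a slow exponential
    phase ``tau_slow``) and a damped porphyrin doming oscillation.

    All times are femtoseconds, amplitudes Angstrom.
    """

    f_plateau: float = 0.5      # true photolysed fraction
    tau_occ: float = 400.0      # apparent-occupancy rise time
    w_fast: float = 0.5         # instantaneous fraction of the FeOOP amplitude
    tau_slow: float = 400.0     # slow FeOOP phase
    doming_amplitude: float = 0.10
    tau_damp: float = 400.0     # doming damping constant
    period: float = 300.0       # doming oscillation period
    jitter_sd: float = 100.0    # pump-probe delay jitter, SD

    def validate(self) -> None:
        for name in ("tau_occ", "tau_slow", "tau_damp", "period"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("f_plateau", "w_fast"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")

    def apparent_occupancy(self, t: float | np.ndarray) -> float | np.ndarray:
        """Scheduled apparent CO* occupancy f(t) = f_plateau * (1 - exp(-t/tau_occ))."""
        t = np.asarray(t, dtype=float)
        out = self.f_plateau * (1.0 - np.exp(-np.maximum(t, 0.0) / self.tau_occ))
        return out if out.ndim else float(out)

    def oop_fraction(self, t: float | np.ndarray) -> float | np.ndarray:
        """Fraction of the full FeOOP amplitude reached at time t."""
        t = np.asarray(t, dtype=float)
        slow = 1.0 - np.exp(-np.maximum(t, 0.0) / self.tau_slow)
        out = self.w_fast + (1.0 - self.w_fast) * slow
        return out if out.ndim else float(out)

    def doming(self, t: float | np.ndarray) -> float | np.ndarray:
        """Damped-cosine doming amplitude at time t."""
        t = np.asarray(t, dtype=float)
        out = (self.doming_amplitude * np.exp(-np.maximum(t, 0.0) / self.tau_damp)
               * np.cos(2.0 * np.pi * t / self.period))
        return out if out.ndim else float(out)
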