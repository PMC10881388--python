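"""Synthetic two-state haem-protein crystal and serial-frame simulator.

This module builds the toy system every downstream stage is benchmarked
against: a ~100-atom haem core (Fe, 24-atom porphyrin ring, CO ligand),
a proximal-histidine mimic embedded in a short "F" helix below the haem,
and a distal helix above it, in an orthogonal P1 box. The excited
(photolysed) state moves the iron out of the ring plane toward the
proximal His, translocates the CO to a docking site, and displaces the
proximal helix away from the haem.

The time-dependent ground truth follows a
:class:`~trsfx.models.GroundTruthSchedule`: the photolysis fraction is
constant (the photoreaction is complete within the time resolution) while
the *apparent* CO* occupancy grows as the initially delocalized ligand
density narrows; the Fe out-of-plane displacement has an instantaneous
plus a slow exponential phase; and the porphyrin rings a damped doming
oscillation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import doming_mode_vector
from .models import (AtomicModel, GeometryError, GroundTruthSchedule,
                     TwoStateSystem)
from .scattering import ReflectionSet
from .timeseries import Frame, FrameSet

PROXIMAL_HIS_SEQ = 93
DISTAL_HIS_SEQ = 64
CO_RES_SEQ = 155
HELIX_F_RANGE = (89, 95)
HELIX_E_RANGE = (59, 65)


@dataclass
class TwoStateConfig:
    """Structural parameters of the synthetic two-state system (Angstrom)."""

    cell: tuple[float, float, float] = (34.0, 30.0, 28.0)
    delta_fe: float = 0.30                # Fe out-of-plane shift toward the His
    co_docking_offset: tuple[float, float, float] = (2.2, 0.9, 1.2)  # from Fe
    co_axis: tuple[float, float, float] = (0.85, 0.35, 0.40)  # docked C->O
    helix_shift: float = 0.25             # F-helix displacement away from haem
    b_iso: float = 15.0                   # common isotropic B
    b_co_star: float = 15.0               # B of the docked (localized) CO*


# per-residue backbone geometry of an ideal helix along +x:
# atom -> (radius from axis, angular offset in deg, offset along axis)
_HELIX_ATOMS = {
    "N": (1.55, -28.0, -0.55),
    "CA": (2.30, 0.0, 0.0),
    "C": (1.65, 22.0, 0.60),
    "O": (2.60, 30.0, 0.75),
    "CB": (3.60, 0.0, -0.25),
}
_RISE = 1.52       # A per residue
_TWIST = 100.0     # deg per residue


def _helix(res_range: tuple[int, int], axis_origin: np.ndarray,
           phase_deg: float, res_name: str = "ALA") -> list[tuple]:
    """Backbone + CB atoms of an ideal helix with its axis along +x."""
    atoms = []
    first, last = res_range
    for i in range(first, last + 1):
        theta0 = phase_deg + (i - first) * _TWIST
        x0 = axis_origin[0] + (i - first) * _RISE
        for name, (radius, dtheta, dx) in _HELIX_ATOMS.items():
            th = np.deg2rad(theta0 + dtheta)
            pos = np.array([x0 + dx,
                            axis_origin[1] + radius * np.cos(th),
                            axis_origin[2] + radius * np.sin(th)])
            elem = "N" if name == "N" else ("O" if name == "O" else "C")
            atoms.append((name, elem, res_name, i, pos))
    return atoms


def build_two_state_system(config: TwoStateConfig | None = None) -> TwoStateSystem:
    """Construct the dark and excited states of the toy crystal.

    Raises :class:`~trsfx.models.GeometryError` if any two atoms end up
    closer than 0.5 Angstrom.
    """
    cfg = config or TwoStateConfig()
    center = np.asarray(cfg.cell) / 2.0          # haem iron position (dark)
    atoms: list[tuple] = []

    # --- haem: Fe + 24-atom porphyrin core in the z = center_z plane
    atoms.append(("FE", "FE", "HEM", 154, center.copy()))
    ring = {"N": (2.01, 0.0), "C1": (3.05, -17.0), "C4": (3.05, 17.0),
            "C2": (4.30, -10.0), "C3": (4.30, 10.0)}
    for pyr, theta in zip("ABCD", (0.0, 90.0, 180.0, 270.0)):
        for stem, (radius, dtheta) in ring.items():
            th = np.deg2rad(theta + dtheta)
            pos = center + radius * np.array([np.cos(th), np.sin(th), 0.0])
            name = f"{stem}{pyr}" if stem != "N" else f"N{pyr}"
            atoms.append((name, "N" if stem == "N" else "C", "HEM", 154, pos))
        th = np.deg2rad(theta + 45.0)
        pos = center + 3.40 * np.array([np.cos(th), np.sin(th), 0.0])
        atoms.append((f"CH{pyr}", "C", "HEM", 154, pos))

    # --- bound CO above the iron (distal side, +z)
    atoms.append(("C", "C", "CMO", CO_RES_SEQ, center + [0.0, 0.0, 1.85]))
    atoms.append(("O", "O", "CMO", CO_RES_SEQ, center + [0.0, 0.0, 2.98]))

    # --- proximal F helix below the haem, His93 under the iron
    # phase chosen so the His93 CA points up toward the haem
    f_origin = center + np.array([-1.5 - 4 * _RISE, 0.0, -4.5])
    phase_f = 90.0 - (PROXIMAL_HIS_SEQ - HELIX_F_RANGE[0]) * _TWIST
    atoms += _helix(HELIX_F_RANGE, f_origin, phase_f)
    # His93 imidazole mimic reaching up to 2.16 A below the iron
    atoms.append(("CG", "C", "HIS", PROXIMAL_HIS_SEQ, center + [-0.5, 0.0, -1.6]))
    atoms.append(("NE2", "N", "HIS", PROXIMAL_HIS_SEQ, center + [0.0, 0.0, -2.16]))

    # --- distal E helix above the haem with a His64 mimic
    e_origin = center + np.array([-2.0 - 3 * _RISE, 1.5, 5.3])
    phase_e = 270.0 - (DISTAL_HIS_SEQ - HELIX_E_RANGE[0]) * _TWIST
    atoms += _helix(HELIX_E_RANGE, e_origin, phase_e)
    atoms.append(("NE2", "N", "HIS", DISTAL_HIS_SEQ, center + [2.5, 1.0, 3.0]))

    def assemble(records) -> AtomicModel:
        return AtomicModel(
            atom_id=np.array([r[0] for r in records], dtype=object),
            element=np.array([r[1] for r in records], dtype=object),
            res_name=np.array([r[2] for r in records], dtype=object),
            res_seq=np.array([r[3] for r in records], dtype=int),
            xyz=np.array([r[4] for r in records], dtype=float),
            b=np.full(len(records), cfg.b_iso),
            occ=np.ones(len(records)),
            cell=cfg.cell,
        )

    dark = assemble(atoms)
    try:
        dark.validate(min_separation=0.5)
    except GeometryError as err:
        raise GeometryError(f"invalid dark-state geometry: {err}") from err

    # --- excited state: Fe toward His, CO to docking site, F-helix away
    excited = dark.copy()
    fe = excited.index_of("FE")
    excited.xyz[fe, 2] -= cfg.delta_fe
    helix_f = (excited.res_seq >= HELIX_F_RANGE[0]) \
        & (excited.res_seq <= HELIX_F_RANGE[1])
    excited.xyz[helix_f, 2] -= cfg.helix_shift
    co_c = excited.index_of("C", CO_RES_SEQ)
    co_o = excited.index_of("O", CO_RES_SEQ)
    dock_c = center + np.asarray(cfg.co_docking_offset)
    co_axis = np.asarray(cfg.co_axis, dtype=float)
    co_axis /= np.linalg.norm(co_axis)
    excited.xyz[co_c] = dock_c
    excited.xyz[co_o] = dock_c + 1.13 * co_axis
    excited.b[[co_c, co_o]] = cfg.b_co_star
    try:
        excited.validate(min_separation=0.5)
    except GeometryError as err:
        raise GeometryError(f"invalid excited-state geometry: {err}") from err

    co_shift = excited.xyz[co_c] - dark.xyz[co_c]
    return TwoStateSystem(dark=dark, excited=excited, delta_fe=cfg.delta_fe,
                          co_translocation=co_shift, helix_shift=cfg.helix_shift)


def co_sites(system: TwoStateSystem) -> tuple[np.ndarray, np.ndarray]:
    """(dark CO carbon, docked CO* carbon) positions in Angstrom."""
    return (system.dark.position("C", CO_RES_SEQ),
            system.excited.position("C", CO_RES_SEQ))


def localized_co_star_fraction(schedule: GroundTruthSchedule, t: float) -> float:
    """Total occupancy of the *localized* (map-visible) CO* at time t.

    The apparent, map-derived occupancy f_app follows the schedule's
    exponential rise; assuming equal per-occupancy peak heights at the dark
    and docked CO sites, the localized CO* occupancy that produces it in a
    peak-height ratio against a dark CO at occupancy (1 - f_plateau) is
    ``u = f_app (1 - f_plateau) / (1 - f_app)``. The remaining photolysed
    CO is delocalized and contributes no localized density.
    """
    f_app = schedule.apparent_occupancy(t)
    fp = schedule.f_plateau
    if fp >= 1.0 - 1e-9:
        return float(f_app)
    u = f_app * (1.0 - fp) / max(1.0 - f_app, 1e-12)
    return float(np.clip(u, 0.0, fp))


def interpolate_state(system: TwoStateSystem, schedule: GroundTruthSchedule,
                      t: float) -> tuple[AtomicModel, float]:
    """Excited-state model at time t plus the (constant) true photolysed fraction.

    Fe and the proximal helix advance along their dark->excited displacement
    with the fast-step + slow-exponential law; the porphyrin core carries the
    damped doming oscillation; the CO sits in its docking site from t = 0 on,
    with an occupancy encoding how much of it is already localized.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    schedule.validate()
    model = system.dark.copy()
    frac = schedule.oop_fraction(t)

    moving = np.flatnonzero(system.dark.atom_id != None)  # all indices
    delta = system.excited.xyz - system.dark.xyz
    co_mask = system.dark.res_seq == CO_RES_SEQ
    # Fe + helix follow the kinetic law; CO jumps to the docking site at once
    model.xyz[~co_mask] += frac * delta[~co_mask]
    model.xyz[co_mask] = system.excited.xyz[co_mask]
    model.b[co_mask] = system.excited.b[co_mask]

    # damped doming of the haem core, along the haem normal toward the His
    labels, weights = doming_mode_vector()
    dome = schedule.doming(t)
    for lab, w in zip(labels, weights):
        model.xyz[model.index_of(lab), 2] -= dome * w  # -z is toward the His

    fp = schedule.f_plateau
    u = localized_co_star_fraction(schedule, t)
    occ_star = u / fp if fp > 1e-9 else 0.0
    model.occ[co_mask] = np.clip(occ_star, 0.0, 1.0)
    return model, fp


# ----------------------------------------------------------------------
# frame simulation
# ----------------------------------------------------------------------

@dataclass
class NoiseConfig:
    """Per-frame noise model for the serial-frame simulator.

    fraction_observed
        Probability that a reflection is recorded on a given frame
        (random orientation -> partial coverage of reciprocal space).
    scale_sigma
        Sigma of the lognormal per-frame scale factor (crystal size, beam).
    partiality_range
        Uniform range of per-observation partiality.
    noise_frac
        SD of the additive Gaussian intensity noise, as a fraction of the
        median true intensity.
    jitter_sd
        SD of the Gaussian timing jitter added to the nominal delay, fs.
    """

    fraction_observed: float = 0.3
    scale_sigma: float = 0.1
    partiality_range: tuple[float, float] = (0.3, 1.0)
    noise_frac: float = 0.05
    jitter_sd: float = 100.0

    def validate(self) -> None:
        if not 0 < self.fraction_observed <= 1:
            raise ValueError("fraction_observed must lie in (0, 1]")
        for name in ("scale_sigma", "noise_frac", "jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.partiality_range
        if not 0 < lo <= hi <= 1:
            raise ValueError("partiality_range must satisfy 0 < lo <= hi <= 1")


def simulate_frames(amplitudes: ReflectionSet, n_frames: int,
                    noise: NoiseConfig | None = None,
                    nominal_delay: float | np.ndarray = 0.0,
                    seed: int | np.random.Generator = 0,
                    first_frame_id: int = 0) -> FrameSet:
    """Simulate serial frames from true mixture amplitudes.

    Each frame records a random subset of reflections with
    ``I = scale * partiality * |F|^2 + eps`` and carries a jittered delay.
    Reproducible for a fixed seed.
    """
    if amplitudes.n_reflections == 0:
        raise ValueError("cannot simulate frames from an empty reflection set")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    cfg = noise or NoiseConfig()
    cfg.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    i_true = amplitudes.f ** 2
    eps_sd = cfg.noise_frac * float(np.median(i_true))
    nominal = np.broadcast_to(np.asarray(nominal_delay, dtype=float), (n_frames,))
    lo, hi = cfg.partiality_range
    frames = []
    for j in range(n_frames):
        obs = np.flatnonzero(rng.random(len(i_true)) < cfg.fraction_observed)
        if len(obs) == 0:       # guarantee a non-empty frame
            obs = np.array([rng.integers(len(i_true))])
        scale = float(np.exp(rng.normal(0.0, cfg.scale_sigma))) if cfg.scale_sigma else 1.0
        part = rng.uniform(lo, hi, size=len(obs)) if hi > lo else np.full(len(obs), hi)
        i_obs = scale * part * i_true[obs]
        if eps_sd > 0:
            i_obs = i_obs + rng.normal(0.0, eps_sd, size=len(obs))
        delay = float(nominal[j] + (rng.normal(0.0, cfg.jitter_sd)
                                    if cfg.jitter_sd else 0.0))
        frames.append(Frame(first_frame_id + j, delay,
                            obs.astype(np.int32), i_obs.astype(float),
                            np.full(len(obs), max(eps_sd, 1e-12))))
    return FrameSet(amplitudes.cell, amplitudes.hkl.copy(), frames,
                    amplitudes.d_min, amplitudes.d_max,
                    metadata={"nominal_delay": nominal_delay})
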