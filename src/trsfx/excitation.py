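"""Photoexcitation-regime arithmetic for pump-probe crystallography.

Beer-Lambert absorption plus Poisson photon statistics: absorbed photons
per chromophore at the crystal front face, peak power density, 1/e
penetration depth, depth-resolved single- versus multi-photon excitation
fractions, and the crystal-averaged photolysis yield that explains why
thick crystals saturate below 100% even at very high fluence.

Physical constants are CODATA values from :mod:`scipy.constants`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.constants import Avogadro, c as SPEED_OF_LIGHT, h as PLANCK

LN10 = float(np.log(10.0))


@dataclass
class ExcitationParams:
    """Pump-pulse and chromophore parameters.

    fluence : mJ cm^-2
    wavelength : nm
    epsilon : molar (decadic) absorption coefficient, M^-1 cm^-1
    pulse_fwhm : pulse duration FWHM, fs
    concentration : chromophore concentration in the crystal, M (optional)
    thickness : crystal thickness along the pump beam, um (optional)
    """

    fluence: float
    wavelength: float = 530.0
    epsilon: float = 11600.0
    pulse_fwhm: float = 60.0
    concentration: float | None = None
    thickness: float | None = None

    def validate(self) -> None:
        for name in ("wavelength", "epsilon", "pulse_fwhm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fluence < 0:
            raise ValueError("fluence must be >= 0")
        for name in ("concentration", "thickness"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when given")


def absorption_cross_section(epsilon: float) -> float:
    """Molecular cross-section sigma = ln(10) * eps * 1000 / N_A, in cm^2."""
    return LN10 * epsilon * 1e3 / Avogadro


def photon_energy(wavelength_nm: float) -> float:
    """Photon energy h c / lambda in joule."""
    return PLANCK * SPEED_OF_LIGHT / (wavelength_nm * 1e-9)


def photons_per_chromophore(p: ExcitationParams) -> float:
    """Nominal absorbed photons per chromophore at the crystal front face.

    n0 = (fluence / E_photon) * sigma — the photon areal density times the
    molecular absorption cross-section; linear in fluence.
    """
    p.validate()
    photon_flux = (p.fluence * 1e-3) / photon_energy(p.wavelength)  # cm^-2
    return photon_flux * absorption_cross_section(p.epsilon)


def peak_power_density(p: ExcitationParams) -> float:
    """Peak power density fluence / FWHM, in GW cm^-2 (flat-top convention)."""
    p.validate()
    return (p.fluence * 1e-3) / (p.pulse_fwhm * 1e-15) / 1e9


def penetration_depth(epsilon: float, concentration: float) -> float:
    """1/e penetration depth 1 / (ln(10) eps c), converted to um."""
    if epsilon <= 0 or concentration <= 0:
        raise ValueError("epsilon and concentration must be positive")
    return 1.0 / (LN10 * epsilon * concentration) * 1e4


def poisson_p_at_least(n_mean: np.ndarray, k: int) -> np.ndarray:
    """P(N >= k) for Poisson-distributed absorbed photon counts."""
    n_mean = np.asarray(n_mean, dtype=float)
    if k == 1:
        return -np.expm1(-n_mean)
    if k == 2:
        return -np.expm1(-n_mean) - n_mean * np.exp(-n_mean)
    # generic complement of the CDF
    from scipy.stats import poisson
    return poisson.sf(k - 1, n_mean)


def depth_profile(p: ExcitationParams, z_um: np.ndarray) -> pd.DataFrame:
    """Absorbed-photon statistics versus depth into the crystal.

    n(z) = n0 exp(-z/d) with d the 1/e penetration depth; P_ge1 and P_ge2
    are the Poisson probabilities of absorbing at least one and at least
    two photons — the single- versus multi-photon excitation bookkeeping.
    """
    p.validate()
    if p.concentration is None:
        raise ValueError("depth profile requires the chromophore concentration")
    z_um = np.atleast_1d(np.asarray(z_um, dtype=float))
    d = penetration_depth(p.epsilon, p.concentration)
    n0 = photons_per_chromophore(p)
    n = n0 * np.exp(-z_um / d)
    return pd.DataFrame({"z_um": z_um, "n_absorbed": n,
                         "p_ge1": poisson_p_at_least(n, 1),
                         "p_ge2": poisson_p_at_least(n, 2)})


def crystal_averaged_yield(p: ExcitationParams,
                           thickness_um: float | np.ndarray | None = None,
                           n_z: int = 256) -> float:
    """Mean single-photon excitation probability over crystal depth.

    Averages P_ge1(z) over the beam path for one thickness or over a
    distribution of thicknesses (plate-thickness polydispersity). Monotone
    and saturating in fluence; for crystals much thicker than the
    penetration depth it plateaus strictly below 1 at any realistic fluence
    — the mechanism limiting the photolysis yield in thick plates.
    """
    p.validate()
    if p.concentration is None:
        raise ValueError("crystal-averaged yield requires the concentration")
    thicknesses = np.atleast_1d(np.asarray(
        p.thickness if thickness_um is None else thickness_um, dtype=float))
    if np.any(thicknesses < 0):
        raise ValueError("thicknesses must be >= 0")
    d = penetration_depth(p.epsilon, p.concentration)
    n0 = photons_per_chromophore(p)
    yields = []
    for L in thicknesses:
        if L <= 0:
            yields.append(float(poisson_p_at_least(np.array([n0]), 1)[0]))
            continue
        z = np.linspace(0.0, L, n_z)
        p1 = poisson_p_at_least(n0 * np.exp(-z / d), 1)
        yields.append(float(np.trapezoid(p1, z) / L))
    return float(np.mean(yields))
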