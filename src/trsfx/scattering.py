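"""Structure factors, map synthesis, scaling and peak readout.

Conventions
-----------
* Point-atom form factor ``Z * exp(-B |s|^2 / 4)`` with ``|s| = 1/d``;
  self-consistent for a simulate-then-analyze toolkit, *not* exchangeable
  with real-data amplitudes (no Cromer-Mann tables, no bulk solvent).
* Structure factors: ``F(h) = sum_i occ_i Z_i exp(-B_i |s|^2/4) exp(2 pi i h.x_i)``
  over fractional coordinates ``x_i``; reflections are stored as a Friedel
  hemisphere (the mate is implied by conjugation for real densities).
* Maps: ``rho(x) = (1/V) sum_h F(h) exp(-2 pi i h.x)`` on a regular grid,
  realized by FFT; F(000) is excluded so difference maps have zero mean.
* Difference maps use dark-model phases (isomorphous-difference convention);
  "mFo-DFc" weights are fixed at m = D = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft
from scipy.optimize import least_squares

from .models import AtomicModel

LOW_RES_LIMIT = 10.0   # A; low-resolution cutoff used for all scaling/differencing
HIGH_RES_LIMIT = 1.4   # A; common high-resolution limit


class ScalingError(RuntimeError):
    """Raised when relative scaling between two reflection sets is degenerate."""


@dataclass
class ReflectionSet:
    """Indexed structure-factor amplitudes (optionally with phases) on one cell.

    Only a Friedel hemisphere is stored; for a real electron density
    ``F(-h) = conj(F(h))`` is implied.
    """

    cell: tuple[float, float, float]
    hkl: np.ndarray            # (n, 3) int
    f: np.ndarray              # (n,) amplitudes, >= 0
    phase: np.ndarray | None   # (n,) degrees, or None for amplitude-only sets
    sigma: np.ndarray          # (n,) >= 0
    d_min: float
    d_max: float = LOW_RES_LIMIT

    def __post_init__(self) -> None:
        self.cell = tuple(float(x) for x in self.cell)
        self.hkl = np.asarray(self.hkl, dtype=int)
        self.f = np.asarray(self.f, dtype=float)
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)

    @property
    def n_reflections(self) -> int:
        return len(self.f)

    @property
    def volume(self) -> float:
        a, b, c = self.cell
        return a * b * c

    def s2(self) -> np.ndarray:
        """|s|^2 = 1/d^2 per reflection."""
        a, b, c = self.cell
        h, k, l = self.hkl.T
        return (h / a) ** 2 + (k / b) ** 2 + (l / c) ** 2

    def d_spacing(self) -> np.ndarray:
        return 1.0 / np.sqrt(self.s2())

    def complex_f(self) -> np.ndarray:
        if self.phase is None:
            raise ValueError("reflection set has no phases")
        return self.f * np.exp(1j * np.deg2rad(self.phase))

    def copy(self) -> "ReflectionSet":
        return ReflectionSet(self.cell, self.hkl.copy(), self.f.copy(),
                             None if self.phase is None else self.phase.copy(),
                             self.sigma.copy(), self.d_min, self.d_max)

    def with_f(self, f: np.ndarray, phase: np.ndarray | None = None) -> "ReflectionSet":
        """Same indices/cell with replaced amplitudes (and optionally phases)."""
        out = self.copy()
        out.f = np.asarray(f, dtype=float)
        if phase is not None:
            out.phase = np.asarray(phase, dtype=float)
        return out

    def with_complex(self, fc: np.ndarray) -> "ReflectionSet":
        return self.with_f(np.abs(fc), np.rad2deg(np.angle(fc)))

    def check_same_index_set(self, other: "ReflectionSet") -> None:
        if self.hkl.shape != other.hkl.shape or np.any(self.hkl != other.hkl):
            raise ValueError("reflection index sets do not match")
        if not np.allclose(self.cell, other.cell):
            raise ValueError("unit cells do not match")


@dataclass
class DensityGrid:
    """Real-space electron density (or difference density) on a regular grid.

    Maps produced by :func:`synthesize_map` keep a reference to their Fourier
    coefficients, which lets :func:`peak_height` evaluate the band-limited
    density exactly between grid nodes.
    """

    cell: tuple[float, float, float]
    values: np.ndarray          # (n1, n2, n3) real, e/A^3
    provenance: str = "Fc map"  # difference map | omit map | Fc map
    coeffs: "ReflectionSet | None" = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        return tuple(c / n for c, n in zip(self.cell, self.values.shape))


# ----------------------------------------------------------------------
# reflection enumeration and structure factors
# ----------------------------------------------------------------------

def hemisphere_indices(cell: tuple[float, float, float], d_min: float,
                       d_max: float = LOW_RES_LIMIT) -> np.ndarray:
    """All Friedel-unique hkl with d_min <= d <= d_max (F(000) excluded).

    Hemisphere convention: l > 0, or (l = 0, k > 0), or (l = k = 0, h > 0).
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    if d_min >= d_max:
        raise ValueError("d_min must be smaller than d_max")
    a, b, c = cell
    hmax = int(np.floor(a / d_min))
    kmax = int(np.floor(b / d_min))
    lmax = int(np.floor(c / d_min))
    h, k, l = np.meshgrid(np.arange(-hmax, hmax + 1),
                          np.arange(-kmax, kmax + 1),
                          np.arange(0, lmax + 1), indexing="ij")
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    s2 = (hkl[:, 0] / a) ** 2 + (hkl[:, 1] / b) ** 2 + (hkl[:, 2] / c) ** 2
    keep = (s2 >= 1.0 / d_max ** 2) & (s2 <= 1.0 / d_min ** 2)
    hemi = (hkl[:, 2] > 0) | ((hkl[:, 2] == 0) & (hkl[:, 1] > 0)) \
        | ((hkl[:, 2] == 0) & (hkl[:, 1] == 0) & (hkl[:, 0] > 0))
    return hkl[keep & hemi]


def structure_factors(model: AtomicModel, d_min: float = HIGH_RES_LIMIT,
                      d_max: float = LOW_RES_LIMIT,
                      hkl: np.ndarray | None = None) -> ReflectionSet:
    """Direct-summation structure factors of a point-atom model.

    Parameters
    ----------
    model : AtomicModel
    d_min, d_max : float
        Resolution range in Angstrom (ignored if ``hkl`` is given).
    hkl : array, optional
        Explicit Friedel-unique index set to evaluate on.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    if hkl is None:
        hkl = hemisphere_indices(model.cell, d_min, d_max)
    hkl = np.asarray(hkl, dtype=int)
    a, b, c = model.cell
    s2 = (hkl[:, 0] / a) ** 2 + (hkl[:, 1] / b) ** 2 + (hkl[:, 2] / c) ** 2
    frac = model.xyz / np.asarray(model.cell)
    # (n_refl, n_atoms) phase matrix; fine at desk scale (~2e6 entries)
    phases = 2.0 * np.pi * (hkl @ frac.T)
    weights = (model.occ * model.electrons)[None, :] \
        * np.exp(-model.b[None, :] * s2[:, None] / 4.0)
    fc = (weights * np.exp(1j * phases)).sum(axis=1)
    return ReflectionSet(model.cell, hkl, np.abs(fc),
                         np.rad2deg(np.angle(fc)), np.zeros(len(fc)),
                         d_min=d_min, d_max=d_max)


def f000(model: AtomicModel) -> float:
    """Zero-frequency term: total (occupancy-weighted) electron count."""
    return float(np.sum(model.occ * model.electrons))


def mix_states(f_dark: ReflectionSet, f_excited: ReflectionSet,
               f: float) -> ReflectionSet:
    """Complex two-state mixture ``(1-f) F_dark + f F_excited``.

    Models the ensemble average over a crystal in which a fraction ``f`` of
    the molecules is in the excited state.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("mixing fraction must lie in [0, 1]")
    f_dark.check_same_index_set(f_excited)
    fc = (1.0 - f) * f_dark.complex_f() + f * f_excited.complex_f()
    return f_dark.with_complex(fc)


# ----------------------------------------------------------------------
# relative (Wilson-type) scaling
# ----------------------------------------------------------------------

def scale_light_to_dark(f_light: ReflectionSet, f_dark: ReflectionSet,
                        d_min: float | None = None,
                        d_max: float = LOW_RES_LIMIT
                        ) -> tuple[ReflectionSet, float, float]:
    """Scale light amplitudes onto dark with an isotropic k, B_rel model.

    Minimizes ``sum (k exp(-B_rel |s|^2/4) F_light - F_dark)^2`` over the
    common resolution range and returns the scaled light set together with
    the fitted ``k`` and ``B_rel``.
    """
    f_light.check_same_index_set(f_dark)
    s2 = f_light.s2()
    lo = d_min if d_min is not None else max(f_light.d_min, f_dark.d_min)
    sel = (s2 >= 1.0 / d_max ** 2) & (s2 <= 1.0 / lo ** 2) \
        & (f_light.f > 0) & (f_dark.f > 0)
    if sel.sum() < 20:
        raise ScalingError(f"only {int(sel.sum())} common reflections; need >= 20")
    if np.ptp(s2[sel]) < 1e-12:
        raise ScalingError("all reflections at one |s|; B_rel unidentifiable")

    # log-linear start:  log(Fd/Fl) = log k - B s^2/4
    x = s2[sel] / 4.0
    y = np.log(f_dark.f[sel] / f_light.f[sel])
    bb, aa = np.polyfit(x, y, 1)       # y = bb*x + aa
    k0, b0 = float(np.exp(aa)), float(-bb)

    def resid(p):
        k, b = p
        return k * np.exp(-b * x) * f_light.f[sel] - f_dark.f[sel]

    sol = least_squares(resid, x0=[k0, b0], method="lm", xtol=1e-14, ftol=1e-14)
    k, b_rel = float(sol.x[0]), float(sol.x[1])
    scaled = f_light.with_f(k * np.exp(-b_rel * s2 / 4.0) * f_light.f)
    scaled.sigma = k * np.exp(-b_rel * s2 / 4.0) * f_light.sigma
    return scaled, k, b_rel


# ----------------------------------------------------------------------
# map synthesis and readout
# ----------------------------------------------------------------------

def default_grid_shape(cell: tuple[float, float, float], d_min: float,
                       oversample: float = 3.0) -> tuple[int, int, int]:
    """Grid dimensions giving a spacing of at most d_min / oversample."""
    return tuple(sp_fft.next_fast_len(int(np.ceil(oversample * c / d_min)))
                 for c in cell)


def synthesize_map(coeffs: ReflectionSet, shape: tuple[int, int, int] | None = None,
                   provenance: str = "Fc map") -> DensityGrid:
    """Fourier synthesis ``rho(x) = (1/V) sum_h F(h) exp(-2 pi i h.x)`` by FFT.

    The stored hemisphere is expanded with Friedel mates so the map is real.
    F(000) is not included: difference and omit maps are zero-mean.
    """
    if coeffs.phase is None:
        raise ValueError("map synthesis requires phases on every reflection")
    if shape is None:
        shape = default_grid_shape(coeffs.cell, coeffs.d_min)
    n1, n2, n3 = shape
    grid = np.zeros(shape, dtype=complex)
    fc = coeffs.complex_f()
    h, k, l = coeffs.hkl.T
    grid[h % n1, k % n2, l % n3] += fc
    grid[(-h) % n1, (-k) % n2, (-l) % n3] += np.conj(fc)
    rho = np.real(sp_fft.fftn(grid)) / coeffs.volume
    return DensityGrid(coeffs.cell, rho, provenance=provenance, coeffs=coeffs)


def _trilinear(grid: DensityGrid, frac: np.ndarray) -> np.ndarray:
    """Periodic trilinear interpolation at fractional coordinates (n, 3)."""
    shape = np.asarray(grid.shape)
    g = np.mod(frac, 1.0) * shape
    i0 = np.floor(g).astype(int)
    t = g - i0
    out = np.zeros(len(g))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (np.where(dx, t[:, 0], 1 - t[:, 0])
                     * np.where(dy, t[:, 1], 1 - t[:, 1])
                     * np.where(dz, t[:, 2], 1 - t[:, 2]))
                idx = (i0 + [dx, dy, dz]) % shape
                out += w * grid.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    return out


def density_at_points(coeffs: ReflectionSet, xyz: np.ndarray) -> np.ndarray:
    """Exact band-limited density at arbitrary Cartesian points (n, 3).

    Direct Fourier sum over the stored hemisphere (Friedel mates folded in):
    ``rho(x) = (2/V) sum_h f_h cos(phi_h - 2 pi h.x)``.
    """
    if coeffs.phase is None:
        raise ValueError("exact density evaluation requires phases")
    frac = np.atleast_2d(xyz) / np.asarray(coeffs.cell)
    ang = np.deg2rad(coeffs.phase)[None, :] - 2.0 * np.pi * (frac @ coeffs.hkl.T)
    return (np.cos(ang) @ coeffs.f) * (2.0 / coeffs.volume)


def _density_on_local_grid(coeffs: ReflectionSet, origin: np.ndarray,
                           offsets: np.ndarray) -> np.ndarray:
    """Exact density on the tensor grid origin + offsets^3 (separable sum)."""
    cell = np.asarray(coeffs.cell)
    phase0 = np.deg2rad(coeffs.phase) \
        - 2.0 * np.pi * (coeffs.hkl @ (np.asarray(origin) / cell))
    c = coeffs.f * np.exp(1j * phase0)
    u, v, w = (np.exp(-2j * np.pi * coeffs.hkl[:, d, None] * (offsets / cell[d]))
               for d in range(3))
    vals = np.einsum("n,np,nq,nr->pqr", c, u, v, w, optimize=True)
    return np.real(vals) * (2.0 / coeffs.volume)


def peak_height(grid: DensityGrid, position: np.ndarray,
                search_radius: float | None = None) -> float:
    """Density at a Cartesian position (A), by periodic trilinear interpolation.

    With ``search_radius`` set, returns instead the local maximum within that
    radius: the best grid node in the sphere is refined — exactly, via the
    band-limited Fourier sum, when the grid carries its coefficients, or by
    a separable three-point parabolic fit otherwise — compensating the
    coarse-grid underestimate of sharp peaks.
    """
    cell = np.asarray(grid.cell)
    frac = np.mod(np.asarray(position, dtype=float) / cell, 1.0)
    if search_radius is None:
        return float(_trilinear(grid, frac[None, :])[0])

    shape = np.asarray(grid.shape)
    spacing = cell / shape
    center = frac * shape
    half = np.ceil(search_radius / spacing).astype(int)
    axes = [np.arange(int(np.floor(center[d])) - half[d],
                      int(np.ceil(center[d])) + half[d] + 1) for d in range(3)]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    # Cartesian offsets of each candidate node from the requested position
    off = np.stack([(ii - center[0]) * spacing[0],
                    (jj - center[1]) * spacing[1],
                    (kk - center[2]) * spacing[2]], axis=-1)
    within = (off ** 2).sum(axis=-1) <= search_radius ** 2
    vals = grid.values[ii % shape[0], jj % shape[1], kk % shape[2]]
    if not within.any():
        return float(_trilinear(grid, frac[None, :])[0])
    masked = np.where(within, vals, -np.inf)
    best = np.unravel_index(np.argmax(masked), masked.shape)
    bi = np.array([axes[0][best[0]], axes[1][best[1]], axes[2][best[2]]])
    peak = vals[best]

    if grid.coeffs is not None:
        # exact two-stage local refinement around the best node
        pt = bi * spacing
        for half, n_side in ((0.5, 5), (0.125, 5)):
            offs = np.linspace(-half, half, n_side)
            rho = _density_on_local_grid(grid.coeffs, pt, offs)
            best3 = np.unravel_index(np.argmax(rho), rho.shape)
            pt = pt + np.array([offs[best3[0]], offs[best3[1]], offs[best3[2]]])
            peak = float(rho.max())
        return peak
    # separable parabolic refinement around the best node
    for d in range(3):
        lo = np.array(bi)
        hi = np.array(bi)
        lo[d] -= 1
        hi[d] += 1
        v_m = grid.values[lo[0] % shape[0], lo[1] % shape[1], lo[2] % shape[2]]
        v_p = grid.values[hi[0] % shape[0], hi[1] % shape[1], hi[2] % shape[2]]
        v_0 = vals[best]
        denom = v_m - 2.0 * v_0 + v_p
        if denom < 0:  # genuine local max along this axis
            delta = 0.5 * (v_m - v_p) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            peak += -0.25 * (v_m - v_p) * delta
    return float(peak)


def map_value_at(grid: DensityGrid, position: np.ndarray) -> float:
    """Plain interpolated map value (no local-maximum search)."""
    return peak_height(grid, position, search_radius=None)
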