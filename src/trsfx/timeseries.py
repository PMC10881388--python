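"""Serial-frame statistics: delay binning, Monte-Carlo merging, kinetics
fits and bootstrap uncertainties.

A :class:`FrameSet` mirrors what a serial crystallography experiment
delivers after indexing: for every frame (one microcrystal, one XFEL
pulse) a set of partial, noisy reflection intensities plus the true
pump-probe delay from the timing tool. The operations here reproduce the
standard treatment of such data: sliding-window binning in true delay,
unweighted Monte-Carlo averaging of intensities, exponential-rise and
damped-cosine fits to metric time series, and sample-with-replacement
bootstrap over frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import lombscargle

from .scattering import ReflectionSet


class MergeError(RuntimeError):
    pass


class FitError(RuntimeError):
    pass


@dataclass
class Frame:
    frame_id: int
    delay: float                # true (jittered) pump-probe delay, fs
    refl_idx: np.ndarray        # indices into the FrameSet reflection table
    i_obs: np.ndarray           # observed intensities (may be negative)
    sigma: np.ndarray           # per-observation sigma, > 0


@dataclass
class FrameSet:
    """Per-frame partial intensities sharing one reflection table."""

    cell: tuple[float, float, float]
    hkl: np.ndarray             # (n_refl, 3) reference reflection indices
    frames: list[Frame]
    d_min: float
    d_max: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def delays(self) -> np.ndarray:
        return np.array([fr.delay for fr in self.frames])

    def subset(self, indices: np.ndarray) -> "FrameSet":
        """FrameSet over the given frame indices (repeats allowed)."""
        return FrameSet(self.cell, self.hkl, [self.frames[i] for i in indices],
                        self.d_min, self.d_max, dict(self.metadata))

    def sorted_by_delay(self) -> "FrameSet":
        order = np.argsort(self.delays, kind="stable")
        return self.subset(order)


# ----------------------------------------------------------------------
# binning and merging
# ----------------------------------------------------------------------

def bin_by_delay(frames: FrameSet, window: int, step: int) -> list[FrameSet]:
    """Sliding-window binning over frames sorted by true delay.

    Windows of ``window`` frames advance by ``step`` frames while they fit
    entirely inside the sorted data, so consecutive bins overlap by
    ``window - step`` frames. Each bin records its mean delay and delay SD
    in ``metadata`` — the SD surfaces the temporal smearing the overlap
    scheme introduces.
    """
    n = frames.n_frames
    if window > n:
        raise ValueError(f"window ({window}) exceeds number of frames ({n})")
    if not 1 <= step <= window:
        raise ValueError("step must satisfy 1 <= step <= window")
    srt = frames.sorted_by_delay()
    bins = []
    for start in range(0, n - window + 1, step):
        b = srt.subset(np.arange(start, start + window))
        d = b.delays
        b.metadata.update({"delay_mean": float(d.mean()),
                           "delay_sd": float(d.std(ddof=1)) if window > 1 else 0.0,
                           "start": start})
        bins.append(b)
    return bins


def merge_frames(bin_frames: FrameSet, n_min: int = 3) -> ReflectionSet:
    """Monte-Carlo merge: unweighted mean intensity per reflection.

    F = sqrt(max(mean I, 0)); sigma is the standard error of the mean
    intensity. Reflections observed fewer than ``n_min`` times are dropped
    (``n_min`` is clamped to the number of frames so that merging a single
    frame is well defined).
    """
    if bin_frames.n_frames == 0:
        raise MergeError("cannot merge an empty frame set")
    n_refl = len(bin_frames.hkl)
    idx = np.concatenate([fr.refl_idx for fr in bin_frames.frames])
    i_obs = np.concatenate([fr.i_obs for fr in bin_frames.frames])
    sig = np.concatenate([fr.sigma for fr in bin_frames.frames])
    count = np.bincount(idx, minlength=n_refl).astype(float)
    s1 = np.bincount(idx, weights=i_obs, minlength=n_refl)
    s2 = np.bincount(idx, weights=i_obs ** 2, minlength=n_refl)
    sig1 = np.bincount(idx, weights=sig, minlength=n_refl)
    n_min = min(n_min, bin_frames.n_frames)
    keep = count >= n_min
    if not keep.any():
        raise MergeError(f"no reflection observed at least {n_min} times")
    cnt = count[keep]
    mean_i = s1[keep] / cnt
    with np.errstate(invalid="ignore"):
        var = np.where(cnt > 1, (s2[keep] - cnt * mean_i ** 2) / np.maximum(cnt - 1, 1),
                       np.nan)
    sem = np.where(cnt > 1, np.sqrt(np.maximum(var, 0.0) / cnt), sig1[keep] / cnt)
    return ReflectionSet(bin_frames.cell, bin_frames.hkl[keep],
                         np.sqrt(np.maximum(mean_i, 0.0)), None, sem,
                         d_min=bin_frames.d_min, d_max=bin_frames.d_max)


# ----------------------------------------------------------------------
# kinetics fits
# ----------------------------------------------------------------------

@dataclass
class KineticsFit:
    """Result of an exponential-rise or damped-cosine fit."""

    model: str                  # "exp_rise" | "damped_cosine"
    params: dict
    sd: dict
    residual_rms: float
    n_points: int
    flags: list[str] = field(default_factory=list)

    def __getitem__(self, key: str) -> float:
        return self.params[key]


def _finish_fit(model: str, names: list[str], sol, n: int) -> KineticsFit:
    resid = sol.fun
    dof = max(n - len(names), 1)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    flags: list[str] = []
    try:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.inv(jtj) * (resid @ resid) / dof
        sds = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        sds = np.full(len(names), np.nan)
        flags.append("singular_covariance")
    params = dict(zip(names, map(float, sol.x)))
    sd = dict(zip(names, map(float, sds)))
    return KineticsFit(model, params, sd, rms, n, flags)


def _amplitude_consistent_with_zero(fit: KineticsFit) -> bool:
    amp = abs(fit.params["amplitude"])
    sda = fit.sd.get("amplitude", float("nan"))
    threshold = 2.0 * sda if np.isfinite(sda) else 2.0 * fit.residual_rms
    return amp <= threshold or amp < 1e-12


def _exp_rise(t, y0, amp, t0, tau):
    rise = 1.0 - np.exp(-np.maximum(t - t0, 0.0) / tau)
    return y0 + amp * rise


def fit_exponential_rise(t: np.ndarray, y: np.ndarray,
                         sigma: np.ndarray | None = None,
                         t0_fixed: float | None = None) -> KineticsFit:
    """Weighted fit of ``y0 + A (1 - exp(-(t - t0)/tau))`` (flat before t0).

    Multi-start over a logarithmic tau grid guards against local minima.
    The amplitude is flagged when consistent with zero (flat data), in
    which case tau is unidentifiable.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 4:
        raise FitError("exponential-rise fit needs at least 4 points")
    span = np.ptp(t)
    if span <= 0:
        raise FitError("time span must be positive")
    w = 1.0 / np.asarray(sigma, dtype=float) if sigma is not None else np.ones_like(y)

    fixed_t0 = t0_fixed is not None

    def resid(p):
        if fixed_t0:
            y0, amp, tau = p
            t0 = t0_fixed
        else:
            y0, amp, t0, tau = p
        return w * (_exp_rise(t, y0, amp, t0, tau) - y)

    y0_init = float(y[np.argmin(t)])
    amp_init = float(y[np.argmax(t)] - y0_init)
    best = None
    for tau0 in np.geomspace(span / 30.0, span * 3.0, 7):
        x0 = [y0_init, amp_init, tau0] if fixed_t0 else [y0_init, amp_init, float(t.min()), tau0]
        lb = [-np.inf, -np.inf, 1e-9] if fixed_t0 \
            else [-np.inf, -np.inf, t.min() - span, 1e-9]
        ub = [np.inf, np.inf, np.inf] if fixed_t0 \
            else [np.inf, np.inf, t.max(), np.inf]
        try:
            sol = least_squares(resid, x0=x0, bounds=(lb, ub),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("exponential-rise fit failed to converge from any start")
    names = ["y0", "amplitude", "tau"] if fixed_t0 else ["y0", "amplitude", "t0", "tau"]
    fit = _finish_fit("exp_rise", names, best, len(t))
    if fixed_t0:
        fit.params["t0"] = float(t0_fixed)
    if _amplitude_consistent_with_zero(fit):
        fit.flags.append("amplitude_consistent_with_zero")
        fit.flags.append("tau_unidentifiable")
    return fit


def _damped_cosine(t, y0, amp, tau_d, period, phi):
    return y0 + amp * np.exp(-t / tau_d) * np.cos(2.0 * np.pi * t / period + phi)


def fit_damped_cosine(t: np.ndarray, y: np.ndarray,
                      sigma: np.ndarray | None = None,
                      baseline: str = "constant",
                      period_init: float | None = None) -> KineticsFit:
    """Fit ``y0 + A exp(-t/tau_d) cos(2 pi t / T + phi)``.

    The period is initialized from the dominant Lomb-Scargle component, with
    multi-starts over phase and nearby periods. ``baseline="exp_rise"`` adds
    a ``B (1 - exp(-t/tau_b))`` term for oscillations riding on a slow rise
    (as doming does on the Fe out-of-plane relaxation).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 6:
        raise FitError("damped-cosine fit needs at least 6 points")
    span = np.ptp(t)
    w = 1.0 / np.asarray(sigma, dtype=float) if sigma is not None else np.ones_like(y)

    # dominant spectral component as the period start (unless supplied)
    yc = y - y.mean()
    if period_init is not None:
        period0 = float(period_init)
    elif np.allclose(yc, 0.0):
        period0 = span / 2.0
    else:
        dt_med = np.median(np.diff(np.sort(t)))
        periods = np.geomspace(max(2.0 * dt_med, span / 50.0), span, 300)
        pgram = lombscargle(t, yc, 2.0 * np.pi / periods)
        period0 = float(periods[np.argmax(pgram)])
    if span < period0:
        raise FitError(
            f"time span ({span:g}) is below one period of the dominant "
            f"component ({period0:g}); period unidentifiable")

    amp0 = float(np.max(np.abs(yc))) or 1.0
    use_rise = baseline == "exp_rise"

    def resid(p):
        if use_rise:
            y0, amp, tau_d, period, phi, b_amp, tau_b = p
            base = y0 + b_amp * (1.0 - np.exp(-t / tau_b))
        else:
            y0, amp, tau_d, period, phi = p
            base = y0
        return w * (base + amp * np.exp(-t / tau_d)
                    * np.cos(2.0 * np.pi * t / period + phi) - y)

    best = None
    for pfac in (0.7, 1.0, 1.4):
        for phi0 in (0.0, np.pi / 2, np.pi, 3 * np.pi / 2):
            x0 = [float(y.mean()), amp0, span, period0 * pfac, phi0]
            lb = [-np.inf, -np.inf, span / 50.0, 2.0 * span / len(t), -2 * np.pi]
            ub = [np.inf, np.inf, 1e9, 3.0 * span, 2 * np.pi]
            if use_rise:
                x0 += [float(y[np.argmax(t)] - y[np.argmin(t)]), span / 2.0]
                lb += [-np.inf, span / 100.0]
                ub += [np.inf, 1e9]
            try:
                sol = least_squares(resid, x0=x0, bounds=(lb, ub),
                                    xtol=1e-14, ftol=1e-14, gtol=1e-14)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise FitError("damped-cosine fit failed to converge from any start")
    names = ["y0", "amplitude", "tau_damp", "period", "phi"]
    if use_rise:
        names += ["rise_amplitude", "tau_rise"]
    fit = _finish_fit("damped_cosine", names, best, len(t))
    if _amplitude_consistent_with_zero(fit):
        fit.flags.append("amplitude_consistent_with_zero")
    return fit


# ----------------------------------------------------------------------
# bootstrap
# ----------------------------------------------------------------------

def bootstrap_metric(frames: FrameSet, pipeline, n_boot: int = 100,
                     seed: int | np.random.Generator = 0
                     ) -> tuple[float, np.ndarray]:
    """Frame-level bootstrap of any frames -> scalar pipeline.

    ``n_boot`` resampled frame sets (same size, drawn with replacement) are
    pushed through ``pipeline``; the SD over replicates estimates the
    uncertainty of the metric. Failing replicates are dropped; more than 20%
    failures raises.
    """
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = frames.n_frames
    values, failures = [], 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            values.append(float(pipeline(frames.subset(idx))))
        except Exception:
            failures += 1
    if failures > 0.2 * n_boot:
        raise RuntimeError(
            f"{failures}/{n_boot} bootstrap replicates failed; result unreliable")
    values = np.asarray(values)
    return float(values.std(ddof=1)), values
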