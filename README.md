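# trsfx

Desk-scale analysis toolkit for pump–probe **time-resolved serial
femtosecond crystallography (TR-SFX)** of ligand photolysis, built around
the carboxymyoglobin (MbCO) photodissociation problem: an optical pump
pulse detaches CO from the haem iron, and X-ray snapshots at femtosecond
delays record the fractional population ("occupancy") of the photolysed
state and the accompanying structural dynamics — iron out-of-plane motion,
haem doming, and correlated helix displacements.

The package is aimed at method development and teaching: it ships a
**synthetic two-state crystal generator** (a ~100-atom haem-core + helix
toy system in a P1 box) with a fully specified kinetic ground truth, so
every estimator in the pipeline can be benchmarked against known answers
— occupancy determination, serial-frame statistics, and geometry metrics
alike. No real diffraction data are required.

## What it computes

**Photoproduct occupancy** from difference electron density, two ways:

- *Peak-height ratio* in a ligand-omit residual map,

  `f = ρ_CO* / (ρ_dark + ρ_CO*)`,

  where `ρ_dark` and `ρ_CO*` are the map peak heights at the bound-CO and
  docked-CO* sites of one mFo−Fc omit map.

- *Occupancy titration* (multicopy-style): for trial occupancies
  `f_trial`, build two-state mixture structure factors
  `F_c = (1−f) F_dark + f F_excited`, record the residual `Fo − Fc`
  density at the bound-CO position, fit a straight line through
  `(f_trial, residual)`, and take its zero crossing.

- *Structure-factor extrapolation* `F_ext = F_dark + (F_light − F_dark)/f`
  as a comparator, with a complex-mode variant that inverts the mixture
  exactly and serves as its oracle.

**Crystallographic math**: direct-summation structure factors for
point atoms (`F(h) = Σ occ·Z·exp(−B|s|²/4)·exp(2πi h·x)`), isotropic
Wilson-type light-to-dark scaling (k, B_rel), FFT map synthesis with
dark-model phases, and exact band-limited peak readout.

**Structural metrics**: signed Fe out-of-plane distance from the
total-least-squares pyrrole-N plane, Fe–His distance, a haem doming
amplitude (projection onto an out-of-plane mode), Cα–Cα
difference-distance (Go) matrices, per-residue displacement from the haem
centre, and radius of gyration.

**Serial statistics**: sliding-window binning of frames by timing-tool
delay (window 20,000 / step 10,000 in the original experiments; scaled
down here), Monte-Carlo merging of partial intensities, exponential-rise
and damped-cosine kinetics fits, and frame-level bootstrap uncertainties
(~100 resamples).

**Photoexcitation arithmetic**: absorbed photons per haem
`n₀ = (fluence/E_photon)·σ` with `σ = ln(10)·ε·10³/N_A`, peak power
density, Beer–Lambert penetration depth, and depth-resolved Poisson
single- vs multi-photon excitation fractions.

## Worked example

```python
from trsfx import (ExcitationParams, photons_per_chromophore, peak_power_density,
                   build_two_state_system, structure_factors, mix_states)
from trsfx.occupancy import estimate_from_amplitudes

# pump-pulse arithmetic for a 101 mJ/cm2, 60 fs pulse at 530 nm
pump = ExcitationParams(fluence=101.0, wavelength=530.0,
                        epsilon=11600.0, pulse_fwhm=60.0)
print(f"photons/haem at 101 mJ/cm2: {photons_per_chromophore(pump):.1f}")
print(f"peak power density:        {peak_power_density(pump):.0f} GW/cm2")

# estimate the photolysed fraction of a simulated 45% mixture
system = build_two_state_system()
f_dark = structure_factors(system.dark, d_min=1.4)
f_exc = structure_factors(system.excited, d_min=1.4, hkl=f_dark.hkl)
f_obs = mix_states(f_dark, f_exc, 0.45).with_f(mix_states(f_dark, f_exc, 0.45).f)
f_obs.phase = None   # amplitudes only, as measured
for method in ("peak_ratio", "titration"):
    est = estimate_from_amplitudes(f_obs, system, method)
    print(f"{method:10s} estimate of f=0.45 mixture: {est.f:.3f}")
```

prints

```
photons/haem at 101 mJ/cm2: 12.0
peak power density:        1683 GW/cm2
peak_ratio estimate of f=0.45 mixture: 0.444
titration  estimate of f=0.45 mixture: 0.448
```

The ~12 absorbed photons/haem places this fluence far outside the linear
(single-photon) excitation regime; both occupancy estimators recover the
simulated mixing fraction to better than 0.01.

A complete synthetic pump–probe time series — simulate frames, bin by
delay, merge, map, estimate occupancy with bootstrap error bars, fit the
kinetics — runs with

```bash
trsfx replay --seed 1 --outdir replay_out
```

and writes `summary.json` (recovered plateau occupancy and time constants
versus the scheduled ground truth), `bins.csv` and diagnostic plots.
Other subcommands: `simulate`, `estimate-occupancy`, `metrics`,
`timeseries`, `excite`.

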