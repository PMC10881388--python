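# Methods

This note records the models, conventions and numerical choices behind
`trsfx`, and what its synthetic benchmarks do and do not demonstrate
about real data.

## The synthetic two-state crystal

`build_two_state_system` constructs a 100-atom mimic of a haem protein in
an orthogonal P1 box (default 34 × 30 × 28 Å): an iron atom, a planar
24-atom porphyrin core (4 pyrrole N, 8 α- and 8 β-ring carbons, 4 meso
carbons), a bound CO above the iron, a proximal "F" helix below the haem
carrying a histidine mimic whose Nε2 sits 2.16 Å under the iron, and a
distal "E" helix above. Space group is fixed to P1 with an orthogonal
cell — every analysis implemented here is symmetry-agnostic, and real
crystal symmetry would only add bookkeeping.

The excited (photolysed) state shares the atom roster and differs only in
coordinates and B factors: the iron moves out of the ring plane toward
the proximal His by `delta_fe` (default 0.30 Å — a conventional
deoxy-like value; the generator parameter is configuration, not a claim
about any particular protein), the CO translocates ~2.5 Å to a docking
site above the ring, and the F helix shifts 0.25 Å away from the haem.
Atom pairs closer than 0.5 Å (minimum-image) are rejected as invalid
geometry.

What the toy system does *not* emulate: real side-chain chemistry,
solvent and bulk-solvent scattering, crystal symmetry, anisotropic
displacement, radiation damage, or realistic completeness. Tests passing
on it show the *estimators* are correct and well-conditioned, not that
any particular real dataset would yield the same numbers.

## Kinetic ground truth

`GroundTruthSchedule` fixes the time dependence (times in fs, amplitudes
in Å):

| parameter | default | meaning |
|---|---|---|
| `f_plateau` | 0.5 | true photolysed fraction (constant: photolysis completes within the time resolution) |
| `tau_occ` | 400 | rise time of the *apparent* CO* occupancy |
| `w_fast` | 0.5 | instantaneous fraction of the Fe out-of-plane amplitude |
| `tau_slow` | 400 | slow FeOOP phase |
| `doming_amplitude` | 0.10 | damped doming oscillation amplitude |
| `tau_damp` | 400 | doming damping constant |
| `period` | 300 | doming oscillation period |
| `jitter_sd` | 100 | Gaussian pump–probe delay jitter |

The functional forms are this package's choice (experiments report time
constants, not fit equations): the FeOOP progress is
`w_fast + (1 − w_fast)(1 − e^{−t/τ_slow})`, the doming is
`A e^{−t/τ_d} cos(2πt/T)` applied along the haem normal with a unit-norm
mode vector in which Fe and the pyrrole N move toward the proximal side
while the ring periphery moves oppositely. Any consistent normalization
of that mode only rescales the reported doming curve.

**Apparent versus true occupancy.** The physically motivated picture is
that the photolysed CO is initially delocalized (a coherently oscillating
wavepacket too fast for the time resolution), so its electron density is
smeared over a large volume and contributes no localized map peak; as the
motion damps, the docked CO "narrows" and the *map-derived* occupancy
rises although the true photolysed fraction never changes. The generator
implements this by scheduling the apparent occupancy
`f̂(t) = f_plateau (1 − e^{−t/τ_occ})` — the curve whose time constant is
the quantity of interest — and back-solving the localized CO* occupancy
`u(t) = f̂ (1 − f_plateau)/(1 − f̂)` that produces it in a peak-height
ratio against a bound CO at occupancy `1 − f_plateau` (assuming equal
per-occupancy peak heights at the two sites; the delocalized remainder is
simply absent from the model). A corollary worth noting: the titration
estimator reads the *depletion of the bound-CO site* and therefore
reports the constant true fraction, while the peak-ratio estimator reads
the *localized CO\* peak* and reports the rising apparent occupancy. The
replay exposes both.

The same mechanism is testable statically: inflating the docked-CO
B factor at fixed true fraction strictly lowers the apparent peak-ratio
occupancy (disorder masquerading as sub-occupancy).

## Crystallographic conventions

- **Form factor**: point atoms, `Z·exp(−B|s|²/4)` with `|s| = 1/d`. This
  is deliberate, self-consistent for a simulate-then-analyze toolkit, and
  *not exchangeable* with real-data amplitudes (no Cromer–Mann tables, no
  bulk solvent, no anomalous terms).
- **Resolution range**: 10 Å low cutoff and 1.4 Å high cutoff by default
  for all scaling and map work.
- **Storage**: a Friedel hemisphere only; `F(−h) = F(h)*` is implied
  (real densities). F(000) is excluded, so difference maps are zero-mean.
- **Scaling**: isotropic `k, B_rel` minimizing
  `Σ(k e^{−B_rel|s|²/4} F_light − F_dark)²`, seeded by a log-linear fit
  and polished by Levenberg–Marquardt. All reflections on a single |s|
  shell → `B_rel` is unidentifiable → error.
- **Maps**: `ρ(x) = (1/V) Σ_h F(h) e^{−2πi h·x}` by FFT on a grid with
  spacing ≤ d_min/3 (dimensions rounded up to fast FFT lengths).
  Difference and omit maps use model phases (isomorphous-difference
  convention) with `m = D = 1` (unweighted Fo−Fc); with synthetic noise
  of known provenance, σ-style weighting would rescale both peak heights
  of the occupancy ratio by a common factor.
- **Peak readout**: periodic trilinear interpolation at a point; the
  local-maximum mode (default radius 0.8 Å) picks the best grid node in
  the sphere and then refines it *exactly* — maps synthesized by this
  package carry their Fourier coefficients, and the band-limited density
  `ρ(x) = (2/V) Σ f_h cos(φ_h − 2πh·x)` is evaluated on two nested local
  grids (half-widths 0.5 and 0.125 Å, 5³ points each, separable tensor
  sum). This removes the coarse-grid underestimate of sharp peaks; grids
  without coefficients fall back to a parabolic node refinement.

## Occupancy estimators

- **Peak ratio** `f = ρ_CO*/(ρ_dark + ρ_CO*)` from one ligand-omit
  residual map. Negative peak heights are clamped to zero before the
  ratio (noise-induced negative density has no occupancy reading); both
  peaks non-positive → undefined-occupancy error. The estimate is
  invariant under any common positive rescaling of the map.
- **Titration**: trial occupancies 0.05…0.95 (step 0.05) by default; for
  each, mixture structure factors are built from the *fixed* dark and
  excited coordinates — refinement inside the loop is intentionally
  omitted at desk scale, a simplification relative to full multicopy
  refinement — and the observed amplitudes are re-scaled (k, B) against
  each trial mixture, exactly as refinement against that mixture would.
  Per-trial scaling makes the zero crossing exact on noise-free data and
  the estimate invariant to a resolution-independent scale error on Fo.
  The residual is read at the bound-CO carbon (averaging C and O is an
  option); a straight line is fitted by unweighted least squares and its
  root, clipped to [0, 1], returned. Near-zero slope → unidentifiable;
  roots beyond [−0.1, 1.1] are flagged before clipping.
- **Extrapolation**: amplitude-level
  `F_ext = F_dark + (F_light − F_dark)/f`, with negative amplitudes
  counted and clamped; the complex-mode variant inverts the two-state
  mixture exactly and quantifies the amplitude approximation.

The benchmark harness perturbs mixture amplitudes with relative Gaussian
noise (default levels 0 and 3%, roughly the amplitude precision of a
well-merged serial dataset) over a grid of true fractions and reports
bias and RMSE per method. On this system the titration, which pools all
reflections into one residual trend, is markedly more precise than the
two-point peak-ratio readout.

## Serial statistics

- **Binning** sorts frames by their true (timing-tool) delay and slides a
  window of W frames in steps of S while the window fits, so consecutive
  bins share W−S frames. Each bin records its delay mean and SD — the SD
  *is* the temporal smearing the overlap scheme introduces, and with a
  150–1300 fs nominal series, 100 fs jitter and W = 2000 of 13,000
  frames it lands in the 40–70 fs band.
- **Merging** is the plain Monte-Carlo estimate: unweighted mean
  intensity per reflection over the frames observing it,
  `F = sqrt(max(Ī, 0))`, σ the standard error of the mean; reflections
  seen fewer than `n_min = 3` times are dropped (`n_min` is clamped to
  the bin size so single-frame merges stay defined).
- **Kinetics fits** use bounded Levenberg–Marquardt with multi-starts:
  the exponential rise `y0 + A(1 − e^{−(t−t0)/τ})` (flat before `t0`)
  over a 7-point logarithmic τ grid; the damped cosine
  `y0 + A e^{−t/τ_d} cos(2πt/T + φ)` with the period seeded from the
  dominant Lomb–Scargle component (or a caller-supplied `period_init`)
  and starts over four phases and three nearby periods. An optional
  exponential-rise baseline term serves series in which an oscillation
  rides on a slow relaxation — the FeOOP series is fit with this combined
  model, seeded with the period measured from the doming series.
  Parameter SDs come from the Gauss–Newton covariance at the optimum;
  amplitudes consistent with zero (≤ 2 SD, or ≤ 2× the residual RMS when
  the covariance is singular) are flagged, and τ flagged unidentifiable
  on flat data.
- **Bootstrap** resamples *frames* (not reflections) with replacement —
  the sampling unit of a serial experiment is the lattice — with 100
  replicates by default; failing replicates are dropped, and more than
  20% failures aborts.

The Monte-Carlo recovery study for the exponential τ uses a replicated
three-level design (baseline, ≈τ, plateau; 3/4/3 of 10 points), the
information-optimal layout for a time-constant estimate, with per-point
noise of 10% of the amplitude and 500 replicates.

## Photoexcitation arithmetic

`n₀ = (fluence/E_photon)·σ` with `E_photon = hc/λ` and
`σ = ln(10)·ε·10³/N_A` (cm²); CODATA constants via `scipy.constants`.
Peak power density uses the flat-top convention fluence/FWHM (no Gaussian
0.94 factor), matching how such numbers are usually quoted. The 1/e
penetration depth is `1/(ln 10·ε·c)`; the chromophore concentration in
the crystal is a required input (for MbCO-like crystals, c ≈ 0.0535 M
reproduces a ≈7 µm depth at ε = 11,600 M⁻¹cm⁻¹). Depth-resolved Poisson
bookkeeping (`P_{≥1} = 1 − e^{−n}`, `P_{≥2} = 1 − e^{−n}(1+n)`) gives the
single- versus multi-photon fractions; averaging `P_{≥1}` over crystal
thickness shows why thick plates saturate below 100% photolysis —
sequential two-photon photophysics beyond this bookkeeping is out of
scope.

## The replay

`replay(RunConfig())` runs the whole chain deterministically from one
seed: structural snapshots every 25 fs feed per-frame intensities
(`I = scale · partiality · |F|² + ε`, with a lognormal frame scale of
σ = 0.1, partiality uniform on 0.3–1, additive noise of 5% of the median
intensity, 30% of reflections per frame); 400 frames at each of ten
nominal delays (150–1300 fs) with 100 fs jitter; windows of 800 frames in
steps of 400; per-bin merging, scaling to the dark model, omit-map
synthesis and both occupancy estimates, with a fast frame-level bootstrap
(100 replicates) for the peak-ratio error bars; geometry metrics on the
ground-truth structures at each bin's mean delay; and the kinetics fits.
These problem sizes are the package defaults chosen to make a complete
run a few minutes on one CPU while keeping per-bin amplitude noise near
the benchmark's 3% level; all of them are configuration.

Recovered quantities and their ground truths are written side by side in
`summary.json`. With the default configuration and seed 1 the apparent
occupancy plateau is recovered to ~0.01, its rise time to ~8%, and the
FeOOP constant and doming period to optimizer precision (the metric
series are evaluated on ground-truth structures; their only distortions
are bin smearing and fit model mismatch).

## Known limitations

- The point-atom form factor and absent bulk solvent mean absolute peak
  heights are not comparable to real refinement programs; only ratios
  and trends are.
- Coordinates are never refined; the titration explores occupancy alone.
  Real multicopy refinement co-refines the photolysed coordinates and
  B factors, which couples occupancy to disorder in ways the toy cannot
  show.
- The equal-peak-height assumption in the apparent-occupancy inversion is
  exact only up to the few-percent difference in band-limited peak shape
  between the two CO sites.
- Frame intensities snap to the nearest 25 fs structural snapshot; this
  adds a quantization jitter small compared to the 100 fs timing jitter.
- The bootstrap treats frames as exchangeable; real serial data have
  drift (jet, beam) that frame resampling only partially captures.
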