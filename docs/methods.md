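# Methods

This note records the physics model behind `minikv`, the parameters that
matter, the numerical choices, and what the synthetic components do and do
not establish about real measurements.

## Source model

**Electron source.** Electrons strike the inner face of the gold
hemisphere in two annular rings, 0.06–0.07 cm radius with selection
weight 1.05 and 0.07–0.08 cm with weight 1.55, uniform in area within the
chosen ring. The kinetic energy is Gaussian with mean equal to the kV
setting (50 keV default) and 5 keV FWHM (σ = FWHM/2.35482), truncated to
(0, mean + 5σ]. The ring "weighting factors" are interpreted as per-ring
selection weights; per-area weighting would differ by the ring-area ratio
(≈ 1.15), well inside the model's fidelity band.

**Photon emission.** Electrons are not transported. Each history emits a
configurable number of photons (default 1, statistical weight 1) from a
depth sampled uniformly through the 1 µm target along the surface normal,
isotropically, with energy drawn from a mixture of

* the Kramers thick-target continuum, N(E) ∝ (E₀ − E)/E on [1 keV, E₀],
  sampled by rejection under a 1/E envelope, and
* the gold L lines (Lα 9.713, Lβ 11.442, Lγ 13.382 keV), with mixture
  weight `line_fraction`.

`line_fraction` defaults to 0.10: electron-impact L-shell ionisation of
gold at ≈ 4× overvoltage, with ω_L ≈ 0.32, puts the L-line share of
emitted photons at the ten-percent level, and materially larger values
make the simulated gold peaks dominate the nickel fluorescence peaks —
the opposite of what measured probe spectra show. Target self-absorption
is not folded into the emission density; it emerges from transporting each
photon through the remaining gold along its actual direction.

**Known fidelity limit.** The Kramers shape is a deliberate, transparent
stand-in for condensed-history bremsstrahlung generation. After
filtration it reproduces the spectral morphology (continuum shape, all
characteristic peaks, the beam-hardening ordering of every device) but
carries a soft bias: simulated surface mean energies come out 6–13 % below
the reference characterisation (probe ≈ 18.5 keV, applicators
≈ 26.8–29.0 keV). Quantities that depend on the spectrum's soft tail
(probe-surface mean energy, near-surface dose gradients) inherit this
bias; orderings, peak positions and relative comparisons do not.

## Cross sections

The shipped table (`data/attenuation.csv`, regenerable with
`scripts/generate_attenuation.py`) holds per-material mass coefficients
for photoelectric, incoherent, coherent, total and energy absorption on a
1–200 keV log grid with points straddling every absorption edge; lookups
are log-log interpolated (exact at nodes, monotone between).

* Incoherent: exact free-electron Klein–Nishina per electron × Z/A·N_A.
  No incoherent scattering function — this overestimates incoherent
  scattering below ≈ 20 keV, where photoelectric absorption dominates the
  attenuation anyway.
* Coherent: a screened power law σ ∝ Z^2.3/E^1.9 calibrated to the water
  coherent coefficient at 30 keV; adequate for a channel that changes
  direction only and contributes ≲ 5 % of the total.
* Photoelectric: per-element power laws τ = τ_a(E_a/E)^p calibrated so
  the **total** matches standard reference attenuation values at two
  anchor energies per element, with multiplicative edge-jump factors
  (Cr/Fe/Ni/Cu/Mo K, Au L₁L₂L₃ and K). Ni, Cr and Ar anchors come from
  log-log interpolation of the atomic cross section in Z between
  calibrated neighbours.
* μ_en: photoelectric (minus mean K-fluorescence escape above K edges)
  plus the Klein–Nishina mean energy-transfer fraction times incoherent.

Accuracy: ≲ 1 % for water across 10–100 keV (the medium that controls the
dosimetry), a few % for the other low-Z media, 10–20 % for the µm-thin
high-Z layers — below the source model's own fidelity band. Compounds use
mass-fraction additivity; the mu-metal composition (Ni 0.77/Fe 0.16/
Cu 0.05/Mo 0.02, 8.7 g/cm³) is a nominal alloy datasheet value, and CrN
(Cr 0.788, 5.9 g/cm³) and NiO (Ni 0.785, 6.67 g/cm³) use handbook
stoichiometry and densities.

## Geometry

Right-handed coordinates, z along the probe axis pointing distally, all
lengths in cm; the origin is the gold-hemisphere centre for bare-probe
scenes and the applicator ball centre for applicator scenes (the probe
isocentre registers to the ball centre; the offset is configurable).
Layer radii at the tip, outside in: CrN/Ni/NiO 2.5 µm each, then the
500 µm wall (beryllium on the distal 1.6 cm, mu-metal on the proximal
8.4 cm), then the 1 µm gold target on the tip's inner face, then vacuum.
The phantom is a 30 × 20 × 30 cm water box centred on the device axis.

Applicator dimensions are not published. The ULTEM shell is 0.25 cm for
the aluminium-filtered (≤ 3 cm) applicators with a 0.1 cm Al layer on the
cavity side; the unfiltered 3.5–5 cm applicators are modelled near-solid
with a fixed 0.45 cm air cavity (shell = R − 0.45 cm), which reproduces
the observed trend of stronger attenuation for larger applicators. The
shank (probe channel 0.2 cm, neck 0.4 cm, 2 cm cone to a 0.7 cm wide
cylinder) only shadows backward-going photons. All of these are
config-overridable estimates, not manufacturer data.

The tracer collects a ray's intersections with every bounding surface
(spheres, cylinders, planes, one cone, the phantom box) and classifies
interval midpoints with the same point-classification function, so path
segments and region lookup cannot disagree. Points exactly on an
interface resolve to the outer region; the geometric epsilon is 1e-7 cm.

## Transport and scoring

Analog, unweighted transport with a 1 keV cutoff. Photoelectric events in
Ni-, Cr- or Au-bearing media re-emit a K line isotropically with the
element's fluorescence yield when the photon energy exceeds the K edge
(the Auger branch deposits locally); Compton scatter uses free-electron
Klein–Nishina sampling by rejection; coherent scatter redirects with the
unscreened Thomson angular law (the forward-peaking form factor is
ignored — the channel is small and deposits nothing).

Electrons deposit at their creation point: the CSDA range of ≤ 50 keV
electrons in water is below the voxel size, so collision kerma = dose.
That identity licenses three estimators of the same quantity:

* **collision** (default): energy deposited at interaction points.
  Energy is conserved exactly per run (entering = deposited + escaped,
  verified to 1e-6 relative); the balance is tracked from collisions in
  every mode.
* **tracklength**: every traversed water segment adds
  E·(μ_en/ρ)·ds/V to the voxels it crosses — unbiased for collision
  kerma at far lower variance.
* **ShellTally**: kerma in spherical shells about the isocentre
  restricted to a 30° forward cone. With near-isotropic emission the
  polar/azimuthal average estimates the central-axis depth dose while
  every photon contributes at every radius it crosses. This is the
  desk-scale PDD estimator: single 0.16 × 0.16 × 0.1 cm axis voxels need
  ~10⁹ histories for fit-quality curves, the cone average needs ~10⁵.
  The Cartesian grid + `extract_pdd` path remains the
  measurement-faithful interface.

Statistical uncertainty uses the batch method (default 10 contiguous
batches): k × standard error of the batch mean, relative to the mean;
zero-dose voxels are flagged NaN, never divided. Dose is per-history
arbitrary units (dose-to-water); all downstream quantities are relative.

## PDD analysis

Curves store depth from the device surface plus the surface-to-isocentre
offset; fits use x = depth + offset, anchoring the 1/x² term at the
isocentre (back-computing the published fit amplitudes confirms that
convention). Default normalisation depths: 0.1992 cm from the isocentre
for the probe (resolvable on fine grids; coarse-grid runs normalise at the
shallowest sampled depth) and 0.2 cm from the surface for applicators.

Fit initialisation is log-linear regression (on ln(y·x²) for eq3; tail
then residual head for eq2), with B, D bounded ≥ 0. The `weighting`
parameter selects the residual scale: `relative` (default — correct for
multiplicative MC/film noise, and necessary for the decay rates to be
determined by more than the steep head), `uncertainty` (per-point batch
uncertainties), or `none` (plain least squares, the convention of the
published fit tables; used when comparing R² against them, over depths at
and beyond the normalisation depth, since the reference curves are
normalised at their shallowest measured point). R² = 1 − SS_res/SS_tot is
always reported on unweighted residuals. In eq3, A and C enter only
through A·e^C; the fit reports the amplitude in A with C = 0.

Curve comparison evaluates 100 × (test − model)/model at shifted depths;
the shift search optionally fits a free scale per shift, needed when the
test curve was normalised at its own (possibly misregistered) reference
depth, which turns a pure spatial shift into shift + scale.

## Dose-rate protocol and uncertainty

The chamber dose rate is the literal six-factor product
N_k·Q̄·(T/T0)·(P0/P)·k_Q·k_{kA→Dw} with Q̄ the mean of repeat readings;
reference conditions default to 293.15 K / 1013.25 hPa and should be set
from the calibration certificate. Uncertainty components combine in
quadrature at k = 1 (each rescaled from its stated coverage first), then
expand by the requested k. σ_rep is the standard deviation of the mean of
the readings; σ_pos converts a positioning bound δr to dose via the local
PDD gradient, σ_pos = |d ln D/dr|·δr.

## Synthetic film

The forward model emulates a stabilised (24 h) radiochromic film scanned
at 48-bit/300 dpi: dose → netOD through D = a·netOD + b·netOD^n
(defaults a = 10 Gy, b = 40 Gy, n = 2.5 — the standard radiochromic
calibration form, synthetic, not a fit to any real batch), red channel
PV = PV₀·10^(−netOD) with PV₀ = 42000, reduced green/blue sensitivity,
additive Gaussian pixel noise, values clipped to [0, 65535], and a
hemisphere or circle cut-out whose pixels carry no dose information. The
calibrated range is 0–16 Gy, covering the 0.25–16 Gy exposure levels the
analysis chain is exercised on.

The inverse chain follows the measurement procedure: red channel, average
of the central five pixel rows along the axis, 1-D median filter (window
5, configurable), calibration inversion, normalisation; per-depth
uncertainty is the five-row standard deviation, and the film-set
uncertainty is the standard deviation of those per-slice vectors across
repeat slices. Axis registration comes from the scan's sidecar metadata
(centroid of the cut-out mask and sub-pixel shift search are available as
refinements).

What passing film tests show: the analysis chain is the exact inverse of
the forward model up to quantisation and noise (round trip ≤ 0.5 %
noiseless), robust to single-pixel artefacts, and able to recover
injected misregistrations. What they do not show: real-film behaviour —
lateral scanner response, Callier effect, darkening kinetics, batch
calibration drift are all outside the model.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen so
the whole suite completes in minutes on one core: 1.1 × 10⁶ histories for
the bare-probe phase space (≥ 2 × 10⁵ surface photons; the reference runs
used ≥ 10⁹), the full scored phase space through each applicator
(≥ 5 × 10⁴ surface photons each), 10⁵–10⁶ draws for sampler statistics,
and shell-tally PDDs for fit-quality curves. At these sizes the
stochastic error on mean energies is ≈ 0.03 keV — negligible against the
source model's fidelity band — and fit R² values are statistics-limited
at the third decimal.
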