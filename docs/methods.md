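# Methods

`crystaldiff` models, renders and analyses the optical signature of guest
molecules diffusing into and out of a single faceted porous crystal — the
setting of colorimetric MOF-based sensing, where an intensely coloured guest
(here cobalamin in a colourless Tb-mesoMOF crystal) makes its own
concentration field visible under a bright-field microscope.  This note
records the models, the numerical choices, and the design decisions that
were genuinely open, in enough detail to re-derive every default.

## 1. Diffusion model and solver

The fractional guest occupancy `c(x, t) ∈ [0, 1]` obeys the diffusion
equation on an axis-aligned voxelized crystal (isotropic pitch `h`, µm).
The solver is an explicit forward-time centred-space (FTCS) scheme with
interface-averaged diffusivity.

**Boundaries.** Faces in contact with the bath carry a Dirichlet condition
(`c = 1` for uptake from saturated solution, `c = 0` for release into pure
solvent) imposed through *mirror ghost cells*, `ghost = 2·b − c_surface`,
which places the boundary exactly on the crystal surface and is second-order
accurate.  The first-order alternative (bath value at the ghost-cell centre)
shifts the boundary half a voxel outward; at desk resolutions that error is
visible as a spurious short-time uptake exponent (measured ≈ 0.55–0.64
instead of ½), which is why the mirror form is used.  Sealed faces are
zero-flux (reflected ghosts), under which total occupancy is conserved to
floating-point rounding.

**Stability.** The update is a convex combination of neighbour values —
hence `c` stays in [0, 1] with no clamping — provided
`dt ≤ h² / ((6 + k)·max D)`, where `k` is the largest number of exposed
faces meeting at one voxel (each mirror ghost doubles that voxel's coupling
to the bath; a fully exposed corner has `k = 3`).  The solver refuses a
larger `dt` rather than produce out-of-range values; when no `dt` is given
it uses 90 % of the bound.  Requested snapshot times are hit exactly by
subdividing each interval into uniform steps.

**Face-dependent ingress.** Single crystals take up guests at different
speeds through different faces.  Lacking a quantitative anisotropy model,
this is realised minimally: each exposed face may carry its own diffusivity,
applied in a two-voxel near-surface layer, with the interior at the fastest
face value.  Defaults are isotropic; anisotropy must be requested
explicitly.  Surface defects (chips, bumps, scratches) are modelled as extra
bath-contact voxels pinned to the bath occupancy — their real effect is
guest intake from multiple directions.

**Validation oracles** (all in the test suite): the 1-D half-space closed
form `c = erfc(x / 2√(Dt))` for one-face uptake (< 2 % RMS at 64
voxels/axis); exact mass conservation when sealed; √t scaling of total
early uptake (log–log slope 0.5 ± 0.05 over the first 1 % of the saturation
timescale); and the corner < edge-midpoint < face-centre < body-centre
ordering of half-saturation times on an all-faces-exposed cube.

## 2. Optical model

Frames are rendered by Beer–Lambert attenuation of the background
illumination along the viewing axis: per-pixel absorbance is
`extinction × channel weight × occupancy column (µm)`.  The guest is red,
so green and blue carry weight 1; the red channel carries a small weight
(default 0.2) representing the overlap of the camera's red passband with
the short-wavelength edge of the guest's absorption band.  That weak red
response is essential, not cosmetic: the analysis pipeline reads the *red
channel* of reference-subtracted frames, and a perfectly transparent red
channel would make that differential identically zero for any concentration
history.  The default extinction (0.039 µm⁻¹ at unit occupancy) makes a
fully loaded 100 µm crystal transmit ≈ 2 % in green/blue — an intensely red
crystal — while its red channel retains ≈ 46 % of background.

Rendering adds seeded Gaussian read noise (default SD 2 counts) and
quantizes to 8 bits.  Noisy rendering without a seed is refused; frame `k`
of a sequence uses `seed + k`, so one seed reproduces a whole sequence
bit-for-bit.  Spectrally resolved optics, scattering and polarisation are
out of scope.

## 3. Image-analysis pipeline

The pipeline follows the histogram procedure used for single-crystal
time-lapse microscopy: (1) the first frame is the reference, subtracted
(per-channel absolute difference) from every later frame, cancelling
everything static; (2) the red channel of the differential image is kept as
an 8-bit grayscale; (3) its mean (the histogram mean) per frame, against
time, is the kinetic trace.  Absolute differencing keeps uptake (growing
red) and release (fading red) on one code path.  The mean is taken over the
full frame by default — a crystal mask derived by thresholding the
reference against its border colour is available, since full-frame means
dilute the signal with background; both choices are recorded in the output.

**Spot change ω.** The characteristic linear scale fed to the spot
estimator is derived from the region whose differential red intensity
exceeds half of its frame maximum ("changed region").  Two summaries are
implemented:

* `changed` — equivalent-circle diameter of the changed region itself.
  For transport through the crystal's side faces that region is a thin
  annular band, whose equivalent-circle diameter grows like
  √(perimeter × front depth) — a geometric mean of crystal size and
  diffusion length.  It is a useful descriptive statistic but, fed into
  `D = ω²/(4 t_D)`, it systematically overestimates D (measured ≈ 2.7–3.8×
  across schedules, masks, face sets and resolutions in this package's
  validation runs).
* `remaining` — equivalent-circle diameter of the still-unchanged part of
  the crystal footprint.  In release micrographs the compact visible
  feature is the shrinking loaded core; its diameter change is a direct
  linear measure of front progression, which is the length scale a
  spot-equilibration estimator presumes.  The end-to-end estimator uses
  this policy; with it, parameter recovery lands within a factor of two of
  truth (measured 0.85–0.90×) across a tenfold range of D.

ω is the magnitude of the diameter change between the first post-reference
frame and the frame nearest `t_D`, so a protocol should start sampling
early relative to `t_D` (the bundled protocols start at ≈ 1 %).

## 4. Release kinetics and diffusion estimators

The release trace is summarised by a capped saturating-logarithm model
`I(t) = min(A·ln(1 + t/τ), P)` — logarithmic at intermediate times with a
hard plateau, matching the observed rise-then-stop shape.  The exact
functional form behind "logarithmic diffusion" fits in the literature is
not standardised; this one was chosen for boundedness and a closed-form
half-signal time, and every result records the model form and residual RMSE
so alternatives can be compared.  Fitting is damped least squares from
several τ starting points; parameter covariance comes from the Jacobian at
the optimum.  The characteristic time is
`t_D = τ·(exp(P/2A) − 1)`, the earliest time the *fitted* curve reaches half
its plateau — defined against the fitted asymptote rather than the last
sample.  The plateau (and hence `t_D`) is only identified when the
observation window actually covers the plateau; the bundled validation
protocols therefore extend the monitoring cadence until the trace flattens.

Two estimators convert observables to a diffusion coefficient (always SI,
m²/s; unit conversion is centralised in `crystaldiff.units`):

* **Spot (FRAP-style):** `D = ω²/(4·t_D)`, with ω in µm and t_D in min
  converted internally.  This is a characteristic-scale estimator for
  effectively two-dimensional transport, not an exact solution for a
  faceted crystal; the package-level accuracy target for the full
  image-to-coefficient chain is a factor of two.
* **MSD:** `D = ⟨x²⟩/(q_i·t)` with `q_i = 2, 4, 6` for 1-, 2-, 3-D
  diffusion, validated against seeded Brownian ensembles whose increments
  have per-axis variance `2·D·dt` (estimator standard error
  `D·√(2/(dim·n))`).

## 5. What the synthetic generator does and does not emulate

The generator reproduces the features the analysis depends on: a faceted
~100 µm crystal at ≈ 1 µm/px and 8-bit RGB; corner-before-edge-before-face
uptake ordering; saturating, plateauing traces; read noise.  It does not
emulate: guest trapping or framework–guest binding (real release stops with
colour still present; simulated release runs to completion, so simulated
plateaus come later), crystal-to-crystal shape variability, illumination
drift, refraction and scattering at facets, or molecular-scale pore
transport (pore access is a geometric gate in the sensing module).  Passing
tests therefore demonstrate the correctness of the algorithms under the
stated optical model, not the photometric realism of any particular
microscope.

## 6. Sensing design calculations

Literature constants of the Tb-mesoMOF/cobalamin system ship as a versioned
JSON file (saturation load 0.33 mg/mg, initial uptake 11.2 %/hr, detection
limit 10 ng/mL, cage diameters 3.9/4.7 nm, window diameters 1.3/1.7 nm,
guest bounding box 1.41 × 1.83 × 1.14 nm, full-infusion 780 min and
substantial-release 3000 min durations).  They are design inputs only and
never calibrate the simulator.  Derived rules:

* **Capacity** is exactly linear in MOF mass.
* **Window accessibility**: a rigid box passes a circular aperture when the
  larger of its two smallest dimensions does not exceed the aperture
  diameter (inclusive at equality) — the minimal rule consistent with the
  guest demonstrably entering through 1.7 nm windows while 1.3 nm windows
  are sub-molecular.  It is monotone in the aperture.
* **Initial uptake rate**: least-squares slope of the trace over a short
  window, normalised by saturation, per hour.  Early uptake follows
  `F(t) = 6·√(Dt/π)/a` for a cube of half-width `a`, so short windows
  approximate it linearly and longer windows can only lower the estimate
  (concavity); at fixed D the rate falls with crystal size, which bounds
  the usable crystal size of a timed sensing readout.
* **Saturation ordering**: half-saturation times of four probe voxels
  (literal grid corner, edge midpoint, face centre, body centre, placed on
  an exposed face) with linear interpolation between snapshots.

## 7. Problem sizes and defaults

The bundled validation runs use 64 voxels per 100 µm axis (1.5625 µm
voxels, matching ≈ 1 µm/px microscopy), 16-frame log-spaced schedules, and
release through the four side faces with the viewing axis sealed (a crystal
resting on the slide; the spot estimator is explicitly two-dimensional).
Unit tests use the same lateral resolution on a thin slab — lateral
transport is depth-uniform, so a 64×64×8 slab with extinction scaled by the
thickness ratio reproduces the full crystal's image sequence at an eighth
of the cost.  At coarse resolution (≈ 32 voxels across a crystal) the
one-pixel surface rim consumes a sizeable fraction of ω and the recovery
degrades; 64 voxels across is the supported minimum for quantitative spot
work.

## 8. Known limitations

* The spot estimator is order-of-magnitude by construction; its factor-two
  validated accuracy holds for the bundled lateral-release protocol and
  should not be assumed for arbitrary geometries.
* The capped-log release model is phenomenological; a mechanistic series
  solution would be better-founded but has no closed-form half-signal time.
* No registration or flat-fielding: frames are assumed aligned and evenly
  illuminated.
* Uptake and release need not share one D in real crystals; the simulator
  accepts separate parameter sets per run rather than enforcing equality.
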