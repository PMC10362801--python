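# Methods

`drdifc` simulates diffuse in-vivo flow cytometry (DiFC) with the
dual-ratio (DR) measurement scheme: fluorescence sensing of labeled cells
flowing through vessels a few millimetres below the tissue surface, where
the detection limit is set by tissue autofluorescence (AF) background and
by coupling noise. This note describes the models, their assumptions, the
numerical choices, and what the desk-scale defaults do and do not show.

## Photon transport

The forward model is built from continuous-wave fluence-rate Green's
functions Φ (mm⁻², per unit source power) computed by a native voxel
Monte-Carlo kernel in a homogeneous slab:

* **Medium.** Absorption μa = 0.002 mm⁻¹, scattering μs = 7 mm⁻¹,
  Henyey–Greenstein anisotropy g = 0.9, interior index n = 1.37 against
  air — tissue-like properties at λ ≈ 810 nm. Only g is physically
  specified; Henyey–Greenstein is the standard voxel-MC phase function.
* **Geometry.** Surface at z = 0, z positive into the medium. The top face
  applies unpolarized Fresnel reflection/refraction; the other five faces
  absorb (photons crossing them are terminated and tallied). Lateral
  boundary behaviour is a documented convention, not a physical claim.
* **Sources.** Sources are normally incident pencil beams. Detectors are
  represented, through the adjoint/reciprocity argument, as cone-beam
  sources: launch directions uniform in solid angle within the exterior
  acceptance half-angle asin(NA/n_out) (NA = 0.5, the fiber convention of
  an externally defined numerical aperture), refracted into the medium.
  The pencil-vs-cone distinction matters at these millimetre scales: it
  produces the asymmetric two-lobe transit signature discussed below.
* **Scoring.** Absorption-weight deposition: each interaction deposits
  w·μa/μt into its voxel and the fluence is `deposited/(N·μa·V)`. Scoring
  is time-gated (10 uniform gates to 10 ns by default, stored per unit
  time); the CW grid is the gate-width-weighted sum. Photons outliving the
  last gate are dropped. Russian roulette below weight 10⁻⁴ with survival
  factor 10.
* **Determinism.** A single-threaded xorshift64* stream (SplitMix64-
  scrambled seed) makes every grid bit-reproducible for a fixed seed.

A semi-infinite diffusion-theory closed form (isotropic point source at
one transport mean free path, extrapolated-boundary image source with the
Groenhuis/Egan internal-reflection parameter) serves as fallback and as an
independent oracle. At 10⁷ photons the MC agrees with it to ~10–15 % at
ρ = 5 mm; the discrepancy is largest below ~2 mm (diffusion theory is not
valid in the near field) and grows again beyond ~4 mm in the finite
absorbing box (truncation), so validation compares inside that window.
The per-voxel standard error scales as 1/√N as expected.

## Fluorescence model

The fluorescence Jacobian for a source–detector pair is
`W(r) = Φ_src(r)·Φ_det(r)·V` (mm⁻¹). A point target with absorption ×
quantum-efficiency product μa,t·η_t contributes reflectance
`Psrc·W(r_t)·μa,t·η_t`; a distributed AF background contributes
`R0 = Psrc·Σ_r W(r)·μa,AF(r)·η_AF(r)`. Excitation and emission optical
properties are taken equal. Two AF distributions are modeled: homogeneous,
and surface-weighted with profile 2^(−z/0.1 mm) (halving every 0.1 mm of
depth), evaluated at voxel-centre depths. Targets map to their nearest
voxel (the grid convention of the MC); trilinear interpolation is
available for smooth traces.

Default coefficients are the phantom-calibrated values μa,t·η_t =
43.3×10⁻⁶ mm⁻¹, surface-weighted AF prefactor 228×10⁻⁹ mm⁻¹, homogeneous
AF 6.81×10⁻⁹ mm⁻¹. **Caveat:** those values were originally fitted against
a 10⁹-photon, 0.1 mm-voxel sensitivity grid. Applied to this package's
desk-scale grids they inflate absolute SNR, so maximum measurable depths
come out systematically deeper than the reference values (e.g. DR ≈ 7.4 mm
rather than ≈ 4 mm). All depth outputs are therefore labeled with the
photon budget and seed, and conclusions are drawn from *orderings*
(which data type reaches deepest, and at what non-cancelable noise
fraction the ranking flips), which are stable at the desk budget.

## Measurements and noise

Single-distance (SD) is the raw pair intensity; the single ratio (SR) is
long-ρ over short-ρ; the dual ratio is the geometric mean of two
symmetric SRs, `DR = sqrt((I_l,I·I_l,II)/(I_s,I·I_s,II))`. The default
layout (detectors at ±3.5 mm, sources at ±0.5 mm on the x axis) gives two
3 mm and two 4 mm pairs; the layout validator checks that every optode
appears once at short and once at long ρ (tolerance 10⁻⁶ mm, configurable)
and returns the canonical quartet assignment (s,I = A1; l,I = A2;
s,II = B2; l,II = B1).

Measured intensities are the theoretical reflectances times Gaussian
coupling factors of mean 1: one per optode (variance popt·σrel²), shared
by both pairs containing that optode, plus one independent non-cancelable
(NC) factor per pair (variance pNC·σrel²), with 2·popt + pNC = 1 so every
single intensity has relative noise σrel regardless of the split. Defaults
σrel = 0.031 and pNC = 0.05 come from the phantom noise calibration.
Factors are drawn untruncated in a fixed documented order from one seeded
generator; a guard rejects σrel > 0.2, where the mean-1 Gaussian model
stops being a sensible intensity distribution. DR cancels the per-optode
factors algebraically (exactly, draw by draw), leaving only the NC
factors; to first order its relative noise is sqrt(pNC)·σrel.

**SNR convention.** SNR is the expected background-subtracted signal (ΔSD
or ΔDR) divided by the baseline (target-absent) standard deviation of the
same data type, sign retained — a DR excursion below baseline is as
detectable as one above. SD baseline noise is σrel·R0 analytically. DR
baseline noise is estimated either by sampling the coupling model (10⁴
draws by default; the reference method) or by the delta-method closed form
sqrt(pNC)·σrel·DR0; the two agree to a few per cent at the default σrel,
and the deterministic closed form is used inside the pNC sweeps. At
pNC = 0 the DR noise is exactly zero and the SNR is undefined by
construction; sweep grids therefore start above zero.

## Calibration from traces

Traces are PMT currents (nA) at 2 kHz. Background is the median of 1 s
moving means after removing outliers (beyond 3 scaled MADs, consistency
constant 1.4826, from the trace median); noise is the median of 1 s moving
standard deviations with the same outlier rule. Windows truncate at the
trace ends; outliers are excluded rather than interpolated. A 5 s moving-
median subtraction and a single-long-window noise variant are available as
the peak-display conventions. Peaks are local maxima of the background-
subtracted trace at least 5× the noise and 1 s apart; a short 2.5 ms
moving mean (well under the ~10 ms transit width) suppresses the
max-of-noise amplitude bias, and can be disabled.

Currents convert to reflectance with a fixed 271×10⁻¹⁵ W mm⁻² nA⁻¹ factor
(folding detector gain 10⁴, area 0.565 mm², λ 810 nm); it cancels in every
unit-less quantity, so it is treated as a supplied constant. The
coefficient fits are exact algebraic inverses of the forward model:
AF prefactor = R0/(Psrc·ΣW·profile), target coefficient =
(Rpeak − R0)/(Psrc·max W) under the assumption that the peak occurred at
the most sensitive voxel.

## Synthetic data

The trace generator emulates a phantom flow experiment: samples are
`baseline·(1 + N(0, σrel))` — multiplicative *relative* noise, matching
σrel = σI/R, not additive absolute noise — plus scheduled transient peaks
(Gaussian of ~10 ms width by default, or a two-lobe transit waveform).
Default conditions: 170 nA background, σrel = 0.031, 47.3 nA peaks,
60 s at 2 kHz. It does not model PMT dark current, drift, shot noise, or
motion artifacts, so passing recovery tests demonstrates correctness of
the estimators under the stated noise model, not robustness to every real
instrument effect. Toy fluence/sensitivity grids (uniform, single-point,
axis-separable) with closed-form sums support oracle tests.

## Desk-scale study conditions

The reference computation used 10⁹ photons on a GPU with 0.1 mm voxels in
a 30 mm cube. This package's experiment-level default is 4×10⁶ photons per
optode on 0.25 mm voxels in a 30×30×15 mm box (the absorbing bottom face
mostly affects paths that would not return to the top few mm), ~70 s per
optode on one CPU core; the transport-validation runs use 10⁷ photons.
0.25 mm resolution is the coarsest that preserves the DR trace's
triphasic sign structure, which depends on resolving the 1 mm source
separation in the near field; at 0.5 mm it is lost. Maps evaluate the
y = 0 voxel plane; depth scans run below the mean x of each data type's
participating optodes (−2.0 mm for the A1 pair, 0 for DR), located by
linear interpolation of |SNR| = 1 between grid depths.

## Known limitations

* Homogeneous optical properties only; no distinct excitation/emission
  wavelength properties, saturation, photobleaching or lifetime effects.
* Absolute depth values are photon-budget- and voxel-size-dependent (see
  the coefficient caveat above); orderings and crossover fractions are the
  robust outputs.
* Shot noise and correlated drift are outside the coupling-factor noise
  model.
* The adjoint cone-beam representation of a detector is an approximation
  whose accuracy is only probed qualitatively (through the transit-shape
  asymmetry), not independently verified.
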