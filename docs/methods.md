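# Methods

This note documents the physical model behind `mammodose`, the default
parameters and why they were chosen, the synthetic-data generators and
what they do and do not emulate, and the numerical choices that affect
results.

## Irradiation geometry

Distances are in mm in a right-handed frame: origin at the chest-wall
edge on the detector midline, x lateral, y chest wall → nipple, z upward
from the support-table top.  Defaults model a clinical digital
mammography unit:

| parameter | default | note |
|---|---|---|
| source height | 655.5 mm above the detector plane | isotropic point source |
| collimated field | 300 × 240 mm at the detector | x centered, y from the chest wall |
| compression paddle | 3.0 mm PET | resting on the phantom top unless a height is given |
| support table | 1.7 mm carbon fiber | phantom rests on it |
| heel model | HE(d) = a + b·d² + c·d⁴ per axis, d in cm | y: a=1.0176, b=−8×10⁻⁴, c=−4.8146×10⁻⁷; x: a=0.9971, b=−2×10⁻⁴, c=−3.939×10⁻⁷ |

The default heel coefficients are surface-fit parameters measured on the
modelled unit at 28 kV W/Rh; `fit_heel_model` refits them from any
air-kerma grid (ordinary least squares in d² and d⁴ per axis, rank
checked, r² reported).  The two 1D fits are combined multiplicatively;
all normalization cancels between the rejection sampler and the analytic
kerma integral, so the product is used unnormalized.

## Beam model

The tube spectrum is a Kramers-law bremsstrahlung shape (differential
energy fluence ∝ kVp − E, 0.25 keV bins from 1 keV) with two inherent
filtration terms: a 0.69 mm beryllium window and an effective 5 µm
tungsten anode self-filtration path.  The pure Kramers shape is well
known to be too soft because it ignores absorption of the beam inside the
target; the 5 µm W default was calibrated once so that tuning the rhodium
filter to the measured beam quality (first HVL 0.55 mm Al at 28 kV)
returns the clinical nominal ~50 µm Rh.  No tungsten characteristic lines
are modelled: K lines are unexcited at 28 kV and L lines are removed by
the Rh+Be filtration; this affects only the spectrum below ~12 keV, which
the rhodium filter suppresses anyway.

Filter tuning supports two targets: a measured aluminium attenuation
curve (bounded scalar minimization of the summed squared transmission
residuals, tolerance 10⁻⁷ mm) or a target first HVL (bisection, monotone
by beam hardening, tolerance 10⁻⁶ mm, thickness bracket 5–150 µm with
20–80 µm used for the clinical case).  A monoenergetic spectrum makes the
attenuation-curve objective flat in filter thickness and is rejected as
degenerate.  The HVL itself is found by bisection of the air-kerma
transmission curve on [0.01, 5] mm to 10⁻⁴ mm.

## Photon cross sections

No cross-section library is assumed at run time: elemental tables
(total, photoelectric, coherent, incoherent and mass energy-absorption
coefficients, 1–50 keV, 19 elements) are bundled as TSV and produced by
the committed generator `tools/make_element_tables.py`.  The generator is
an analytic reconstruction:

* coherent/incoherent angular-integrated cross sections from a
  screened-hydrogenic shell model (Slater effective charges), with the
  coherent magnitude calibrated per element by a smooth correction so
  that anchored energy-absorption values are reproduced;
* photoelectric cross sections as the residual of anchored totals, with
  log-Z interpolation of atomic cross sections for unanchored elements
  and a parameterized K-edge jump;
* anchors are hand-transcribed published values for H, C, Al, Cu plus
  compound identities: oxygen is pinned so liquid water reproduces its
  reference curve and argon so dry air does;
* µen/ρ = PE·(1 − K-fluorescence escape) + incoherent · f_tr(E), with
  f_tr the Klein–Nishina mean energy-transfer fraction, pinned to the
  same anchors.

Accuracy is ~1% for air, water and tissue constituents at mammographic
energies, degrading to ~10–20% for Cu, Rh and W.  That is acceptable
because the filter metals enter only through *tuned* thicknesses: an
error in the Rh coefficient moves the tuned thickness, not the resulting
beam quality.  Interpolation is log-log linear with no extrapolation;
out-of-range energies raise.

Materials are mass-fraction compositions (compound formulas such as LiF
expanded stoichiometrically); mixtures use mass-weighted coefficients and
the volume-conserving harmonic-mean density, which conserves total mass
exactly under homogenization.  Tissue compositions are Hammerstein-style
adipose (ρ 0.93) and glandular (ρ 1.04) and ICRU-44 skin (ρ 1.09); the
50/50 slab material is their equal-mass mixture.  The TLD chip is
LiF:Mg,Cu,P (99.5/0.2/0.004/0.296% by mass, ρ 2.48).

## Phantoms

Voxel phantoms are uint8 label grids (label 0 = air) with a label →
material map, cubic voxels (default pitch 0.273 mm, read as a side
length; coarser grids are used where speed matters since the homogeneous
phantom has no sub-voxel structure), serialized as raw + JSON sidecar.

The homogeneous phantom is a semicylinder, flat face at the chest wall,
default radius 100 mm and thickness 5 cm.  The 30-dosimeter layout is
configuration-driven with a documented default of 5 rows
(y = 20, 45, 70, 95, 120 mm) × 6 columns (x = ±8, ±24, ±40 mm); because
the default rows reach y = 120 mm, the measurement configuration used in
tests and the acceptance script builds the phantom with radius 130 mm so
every chip clears the footprint by at least half a chip.  Chips are
3.2 × 3.2 × 0.38 mm³ and sit with their upper face at the requested depth
below the entrance surface.

The synthetic anthropomorphic phantom is a trinary
(skin/adipose/glandular) semicylinder, default 4.5 cm thick with a 1.5 mm
skin shell on the lateral rim and the top/bottom faces.  Glandular tissue
is laid down by thresholding a smoothed Gaussian random field
(correlation length 3 mm → ~6 mm structures) plus additive central
envelopes in depth (σ_z = 0.25 × thickness) and laterally; the threshold
is solved by bisection so the glandular *mass* fraction matches the
target (default 10.9%) within ±0.5 percentage points.  The defaults were
chosen for a plausible compressed-breast depth profile: in every seed the
middle third of the thickness holds ~50–65% of the glandular mass, with
glandular tissue present at all depths.  What the generator does *not*
emulate: connected ductal architecture, Cooper ligaments, pectoral
muscle, breast curvature between paddle and table, and the
tissue-equivalent-material approximations of physical phantoms.  Tests
that pass on it therefore validate the dose *methodology* (tallying,
normalization, homogenization, glandular-dose accounting), not anatomical
realism.

`homogenize` replaces the adipose+glandular compartment by its
equal-composition mixture at the compartment's overall glandular mass
fraction, leaving skin and air untouched; glandular mass fraction and
total tissue mass are conserved (the former to <10⁻³, the latter exactly
up to float rounding).

## Transport

One history is one primary photon; the kerma approximation deposits
transferred energy at the interaction point (no electron transport, no
fluorescence), justified because secondary-electron CSDA ranges at
≤28 keV are far below the voxel size, and fluorescence yields of tissue
constituents are negligible (chip-material fluorescence is ignored and
noted as a limitation).  Interactions: photoelectric (full local
deposition), incoherent via free-electron Klein–Nishina with Kahn's
rejection sampling, coherent via the Thomson angular law without form
factors.  Both angular simplifications are accuracy-limiting and
swappable; they bias the scatter field in opposite directions (free KN
oversamples forward incoherent scatter, form-factor-free Thomson
oversamples wide-angle coherent scatter).  Photons below 1 keV deposit
locally and stop.

Voxel traversal uses Woodcock (delta) tracking: per-energy majorant
attenuation over all materials present, fictitious collisions resolved by
the local-to-majorant ratio.  Cross sections are pre-binned on a 0.1 keV
grid; the same binned values feed the majorant and the acceptance test,
so the discretization is self-consistent and unbiased.  Equivalence with
an explicit layer-walk reference implementation is tested bin-by-bin at
3σ on a two-material slab.

The source sampler draws a uniform point on the detector field and
accepts with probability ∝ HE(x, y) · cosθ / r² (isotropic emission into
the collimation, heel-modulated); energies follow the spectrum's photon
fluence.  The 600 mm air column above the paddle is handled as analytic
primary attenuation with a kill (air-scattered photons are treated as
lost — a sub-percent effect on phantom dose); the identical air
transmission enters the analytic incident-air-kerma integral so the scale
factor stays consistent.  Photons are then tracked through paddle,
phantom and support table as explicit slabs/voxels, so scattered photons
see all structures.

Estimators:

* **Chip tallies** use a track-length collision-kerma estimator —
  fluence × E × (µen/ρ) of the chip material — with the chips *not*
  physically present.  Rationale: analog deposition in a 0.38 mm chip is
  starved for events at desk-scale history counts, and virtual chips at
  five depths cannot shadow each other (the physical experiment exposed
  one depth at a time).  An analog collision estimator is available as an
  option and is used in the closed-form and cross-code tests.
* **2D maps** embed a physical TLD-material layer (default
  0.38 mm × 12 × 20 cm, 1 mm pixels) and score analog deposition with
  per-pixel history-by-history statistics.  Note that contrast in such a
  layer under a heterogeneous phantom reflects *upstream attenuation*
  (less dose under glandular columns); the factor-of-~2 glandular/adipose
  contrast of local dose refers to dose in the tissue voxels themselves,
  which the per-voxel estimator scores.
* **Per-voxel deposition** accumulates energy per voxel for
  glandular-dose analysis, with a per-history scalar accumulator for the
  glandular energy so the AGD carries a Sempau uncertainty.

Statistical uncertainties follow the history-by-history scheme:
σ²_mean = (1/N)[S₂/N − (S₁/N)²] from per-history sums S₁, S₂; a
zero-mean tally flags its relative uncertainty as undefined.  Runs
require an explicit integer seed and are bit-reproducible.

Absolute normalization: the incident air kerma per history is computed
analytically (primary only) over a 3 × 3 cm² region laterally centered,
4 cm from the chest wall, at the bottom surface of the compression paddle
(the exact scoring height is not standardized; the paddle bottom is the
documented default), including inverse square, heel amplitude, paddle
slant transmission and air attenuation.  The scale factor is the measured
kerma divided by this per-history value.

## Dose to air and glandular dose

Chip doses scored in TLD material convert to dose in air by the ratio of
spectrum-averaged mass energy-absorption coefficients, the average taken
over the *depth-hardened* spectrum (the incident spectrum attenuated by
the overlying phantom material); the ratio changes measurably between 0
and 4 cm, which is why depth-specific dosimeter calibration is enforced.

The average glandular dose is the mass-weighted mean dose to glandular
tissue.  In a heterogeneous phantom only glandular-labelled voxels count.
In a homogenized phantom the energy deposited in a mixture voxel is
partitioned to its glandular component by
G = s · ⟨µen/ρ⟩_glandular / ⟨µen/ρ⟩_mixture (s the glandular mass share,
averages weighted by the irradiating spectrum's energy fluence) — the
standard glandular-dosimetry convention; without it, dose-to-mixture
understates glandular dose by the µen ratio and the
homogeneous-vs-heterogeneous comparison inverts.  With it, the
heterogeneous AGD of the synthetic phantom is 5–25% (realization-
dependent) below its homogenized counterpart: homogenization spreads
glandular mass into the high-dose entrance layers that centrally
concentrated tissue avoids.

## Dosimeter models

Film: dose(x) = a + b·x/ln x (x = net reflectance change in (0,1); x = 1
is a domain error), fitted by linear least squares in (a, b); percent
uncertainty u%(D) = a + b·e^(−D/c), monotone decreasing to the asymptote
a — uncertainty grows toward low dose, i.e. with depth.  TLD:
D = Q·K_calib/S with per-chip sensitivities, positions averaged over
three chips.  MOSFET: D = mean(ΔV/CF), negative signals warn.  Combined
standard uncertainty (k = 1) is the quadrature sum of Type A components
and rectangular Type B half-widths converted by /√3.  Calibrations are
depth-specific and refuse to apply across depths without an explicit
override.  A synthetic-reading generator inverts each calibration and
adds seeded Gaussian noise for end-to-end tests; the round trip is exact
at zero noise and unbiased.

## Problem sizes and tolerances used in the shipped checks

The depth-dose configuration (radius 130 mm homogeneous phantom, 30 chips
per depth, heel and paddle on) runs 6 × 10⁶ histories in the test suite
and 1.2 × 10⁷ in `scripts/acceptance.py` (statistical uncertainty on the
entrance→4 cm percentage decrease ≈ 0.15–0.2 points); the AGD comparison
uses 2 mm voxels and 5 × 10⁵ histories per phantom (AGD uncertainty
≈ 1.5%); the cross-code slab check uses 2.5 × 10⁵ engine and 2.5 × 10⁴
reference histories at 3σ per bin.  Voxel pitches coarser than 0.273 mm
are used wherever the phantom has no sub-voxel structure.

## Known limitations

* Free-electron incoherent and form-factor-free coherent angular
  distributions; no Doppler broadening or binding effects.
* No electron transport or fluorescence; chip self-absorption and cavity
  perturbation are neglected (virtual chips).
* The spectrum model is semi-analytic, not a measured or published
  clinical spectrum; beam quality is matched through filter tuning only.
* Mid/high-Z cross sections (Cu, Rh, W) are order-10% reconstructions.
* Detector backscatter below the support table is not modelled.
* The synthetic breast is statistically, not anatomically, realistic.
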