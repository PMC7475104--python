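# Methods

## Decay chain

Activities follow the two-member Bateman solution with half-lives
18.7 d (²²⁷Th) and 11.4 d (²²³Ra):

    A_Th(t) = A_Th(0) e^{−λ_Th t}
    A_Ra(t) = A_Th(0) λ_Ra/(λ_Ra−λ_Th) (e^{−λ_Th t} − e^{−λ_Ra t}) + A_Ra(0) e^{−λ_Ra t}

²²³Ra's daughters (²¹⁹Rn 4.0 s, ²¹⁵Po 1.8 ms, ²¹¹Pb 36.1 min, ²¹¹Bi
2.1 min, ²⁰⁷Tl 4.8 min) are treated as in secular equilibrium with
²²³Ra: imaging happens hours to days after filling, far beyond their
half-lives, so their photon lines are folded into a single
`Ra223chain` emission spectrum with branching taken as unity along the
main chain. The emission table ships as plain text
(`data/emission_lines.tsv`, lines with abundance > 1%) and can be
overridden to accommodate revised intensity evaluations. The time
origin is the fill time; any purification-to-fill interval is the
caller's responsibility via the initial activities.

Cumulated activity uses the trapezoid rule over the sampled curve with
no extrapolation. Over the 13-point, 29-day schedule the trapezoid
error against the closed-form exponential integral is < 0.5% (the
largest gap is 6 days; λ_Th·6 ≈ 0.22 and the per-interval relative
error ≈ (λh)²/12).

## Camera forward model

The geometric-mean primary count-rate density per unit activity is

    C_GM(E) = 10⁶ · n(E) · η_G · η_ε(E) · e^{−μ(E)x/2}

on a 1 keV grid spanning 20–600 keV. Lines below 20 keV are retained in
the data table but excluded from the forward model by a configurable
cutoff: they cannot traverse high-energy collimation and lie outside
all acquisition windows.

* `η_G = [kD²/(L(D+T))]²` with the hexagonal-hole shape factor
  k = 0.26 (standard value; configurable), D = 0.4 cm, L = 5.97 cm,
  T = 0.2 cm. No septal-penetration term: penetration varies with
  source–detector distance and is absorbed empirically into the scatter
  scale/ν coefficients; an HE collimator keeps the residual bias small.
* `η_ε(E) = 1 − e^{−τ_NaI(E)·t}` with t = 0.95 cm and the photoelectric
  coefficient of NaI(Tl) tabulated in plain text (iodine K-edge at
  33.2 keV represented by a closely spaced sample pair), log–log
  interpolated.
* `μ(E)` is the narrow-beam attenuation coefficient of water with
  coherent scattering excluded, tabulated at 40 energies over
  20–600 keV, log–log interpolated.
* Energy resolution: Gaussian kernel with fractional FWHM
  `w·√(140/E)`, w = 0.09 (9% at 140 keV, Siemens Intevo). Each line's
  kernel is renormalized over the grid, so blurring conserves counts to
  machine precision.

Window integrals sum the bins whose centers fall in the half-open
interval [lo, hi). The modeled unattenuated sensitivities
(≈7.3 cps/MBq for ²²⁷Th in 215–260 keV, ≈66 cps/MBq for ²²³Ra in
75–100 keV) agree with reported observations (~10 and ~70) to well
within a factor of two; the remaining gap is consistent with omitting
septal penetration and partial energy deposition.

## Scatter model

Scatter enters as a fixed unit-integral spectral *shape* per isotope,
times the fitted scale B·A, times per-window coefficients ν. Two shape
sources are supported:

* a loader for externally tabulated spectra (two-column text,
  linearly resampled onto the grid), e.g. full Monte Carlo output of
  the acquisition geometry;
* a bundled parametric stand-in: for each emission line a
  single-Compton-scatter continuum between the backscatter limit
  E₀/(1+2E₀/511) and E₀ with the Klein–Nishina scattered-photon energy
  distribution, weighted by line intensity and the water scatter
  fraction 1−e^{−μ_C(E₀)x/2} (μ_C from the Klein–Nishina total cross
  section times water's electron density), blurred with the detector
  resolution and normalized.

ν calibration solves, per window, the linear relation between modeled
and measured counts given known activities: parent-dominant data
determine ν_Th, daughter-grown data determine ν_Ra, and the two stages
are alternated to a fixed point so that a small daughter admixture in
the parent-dominant set (as in a real fill) does not bias the result.
B and ν enter only as a product, so calibration conventionally fixes
B = 1; at quantification time B is free and absorbs any overall scale
(tests confirm estimates are invariant to rescaling the shapes).

Identifiability caveat: in windows where the expected scatter counts
are small against the Poisson noise of the total window counts (for
20-min phantom-level acquisitions, notably 260–285 keV), individual ν
coefficients are statistically ill-determined — their per-seed spread
exceeds the coefficient itself. The test suite asserts the 10% median
recovery only where the expected scatter counts exceed twice the count
noise, and unbiasedness elsewhere. This mirrors the observation that ν
stabilizes only once sufficient scatter material surrounds the source.

## Unmixing

The objective is the unweighted sum over the four windows of squared
differences between measured geometric-mean counts and the model;
an optional approximate-Poisson weighting (1/√counts) exists but is off
by default, matching the reference procedure. The 3-parameter problem
is mildly nonconvex through the B·A product, so the trust-region
bounded least-squares solver is run from four deterministic starts
(primary-only nonnegative seed with B = 0 and B = 1, a full linear seed
at B = 1, and a daughter-only seed); ties break toward the lowest
residual, then the lowest B. Estimates within 10⁻⁹ of the bound are
snapped to exact zeros, so boundary solutions (e.g. a ²²³Ra-only
source) report A_Th = 0 exactly. All-zero measurements return
(0, 0, B = 1) with zero residual. Negative background-corrected counts
must be clipped to zero upstream (the geometric mean is otherwise
undefined); clip events are logged.

Pixelwise decomposition applies the same solve per pixel of the
conjugate-geometric-mean window images; pixels whose four-window summed
counts fall below a floor (default 5) are masked, since near-zero-count
fits are unstable. An anterior-only mode exists for single-view data;
conjugate is the default.

## Planar processing

The portable image format is a delimited text matrix plus a JSON
sidecar (duration, view, window bounds, pixel size, timestamp); DICOM
NM planar read/write via pydicom is optional. Room background is
subtracted scaled by the duration ratio and clipped at zero. ROI counts
use an oversized main ROI (captures spill-out) minus an identically
sized background ROI (removes under/overlying activity); the package
validates equal area and non-overlap but leaves placement to the user.
Scout-based water-equivalent thickness ships as a calibration
*procedure* (default linear fit to user-supplied pixel-value/thickness
pairs, couch effect folded into the coefficients) rather than fixed
numbers, with the calibrated range enforced.

## Synthetic phantom simulator

The simulator emulates a torso-representative phantom: compartments
(discs/rectangles in the 64×64, 9.59 mm-pixel image plane) with fill
activities decayed per Bateman, forward-modeled window counts, uniform
in-compartment count distribution, an optional Gaussian spatial blur
(default FWHM 15 mm) standing in for partial-volume spill-out, a room
background rate per window, and independent Poisson draws per pixel,
window and view. Seeds derive deterministically from a master seed and
the (time, window, view) indices, so any single image is reproducible
in isolation.

Anterior and posterior views attenuate the primary spectra through
d_ant = f·x and d_post = (1−f)·x (default f = 0.5, configurable to test
depth independence); scatter window counts are split between views by
the window's primary-derived factor g_j = √(ant_j/post_j), which makes
the geometric mean of the two simulated views equal the conjugate model
exactly — the noise-free pipeline is an inverse crime by construction
and recovers truth to < 0.01%.

The `jaszczak_torso` preset encodes the two-sphere torso phantom
(0.54 MBq ²²⁷Th + 0.014 MBq ²²³Ra in the 83 mL sphere, 0.15 MBq ²²³Ra
in the 14.6 mL sphere, 0.98 MBq/0.025 MBq in the warm background for a
≈40:1 concentration ratio, 20 cm water, 20-min acquisitions at days
0, 1, 2, 3, 4, 7, 9, 11, 14, 16, 22, 24, 29). The background
compartment is modeled as a rectangle (projection of the cylinder) so
that identically sized background ROIs placed inferior to the spheres
lie fully over it; the room-background rate defaults to 0.5 cps per
window over the field of view, a typical low-count-room level.

What the simulator does *not* emulate — and what passing tests
therefore do not demonstrate about real data: depth-dependent
collimator response, septal penetration, backscatter from the
photomultiplier stack, dead time, mis-modeled scatter shapes (the
simulator and the fit share the parametric basis unless a mismatch is
injected via ν_true/B_true), registration errors, and anatomical
backgrounds that overlap the target. The Poisson statistics, count
levels, decay dynamics, cross-talk pattern and the ROI/background
bookkeeping are faithful, which is what the recovery bounds exercise.

## Problem sizes in the tests

Statistical tests run at sizes chosen to keep the default suite quick
while leaving comfortable statistical margins: 150 seeded acquisitions
for the law-of-large-numbers and dispersion checks (the dispersion
statistic is averaged over all pixels with expectation ≥ 20, giving a
standard error ≪ the ±0.1 band), 100 seeds for median-bias checks, 8–10
replicate studies for the cumulated-activity bound (observed margins
are ~0.2–2% against the 10% bound), and a 200³ grid for the solver
oracle.
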