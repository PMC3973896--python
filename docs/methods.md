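# Methods

## Microplate forward model

The simulator treats the cell and the cantilever as two springs in
series. At commanded base displacement D (um) the cell deformation
δ_c and cantilever deflection δ_b satisfy

    D = δ_c + δ_b,        k·δ_b = E·(δ_c/h₀)·A_c / 1000,

with k the spring constant (nN/um), E the phase modulus (Pa), h₀ the
initial height (um) and A_c the contact area (um²); the factor 1000
converts Pa·um² to nN. With A_c fixed at π·d₀²/4 (the default
*constant-area* policy) the force is the closed form
F(D) = D / (1/k + 1000·h₀/(E·A_c)), which doubles as the analytic
oracle in the tests. The optional *volume-conserving* policy updates
d = d₀·√(h₀/h) and solves the balance per frame with Brent's method;
cell volume is then exactly conserved.

Compression runs to the commanded amplitude (default 5 um at
0.42 um/s); tension continues until the tensile force reaches the
cell's adhesion force, at which point the cell releases within a
single frame: the cantilever snaps straight (δ_b = 0) and subsequent
frames are labeled post-detachment. Detachment is checked only during
tension — compression loads the adhesive bond in compression, so the
pull-off criterion cannot trigger there. Strain uses the same Hookean
law in both phases with the phase's modulus, so CS and TS are both
positive modulus estimates.

Frames are rendered with the image origin top-left and the
compression axis vertical: a dark slide band at the bottom, the cell
as an ellipse standing on the slide surface, and the cantilever as a
full-width dark bar whose lower edge sits at row
`slide_surface_row − round(tip·scale)` — exact by construction, which
the rendering-fidelity test asserts. Noise is additive Gaussian on
the 8-bit intensities (default sd 4); an optional Gaussian PSF is off
by default. All generators take explicit seeds and are bit-for-bit
reproducible; there is no global random state.

### Default parameters

| parameter | default | why |
| --- | --- | --- |
| scale | 4.8 px/um | the instrument calibration under the 40× objective |
| spring constant k | 9.6 nN/um | chosen so a one-pixel deflection equals the stated 2 nN force resolution |
| piezo travel / speed | 5 um, 0.42 um/s | the stated compression protocol |
| frame interval | 0.25 s | 4 fps CCD-class imaging; ~49 compression frames, force increments ≲1 nN |
| h₀, d₀ | 15, 18 um | adherent tumor-cell scale under gentle spreading |
| intensity levels | slide/bar 40, cell 120, background 200 | phase-contrast-like contrast ordering |
| image | 128×224 px | fits the cell plus the cantilever at maximum pull travel |

## Measurement chain

Tracking follows the instrument's image pipeline: 3×3 mean filter,
histogram equalization, horizontal-edge (Sobel) filter, then edge
detection. Full-width edges are found as local maxima of the
column-averaged edge response above half the strongest response; the
bottom-most such edge is the slide surface, the topmost is the bar's
upper edge, and the tip is the strongest edge below the bar top within
the plausible bar thickness, ties broken toward the previous frame's
tip row (temporal continuity). Deflection is |tip motion − commanded
base motion| from the sidecar metadata; force reduction is Hooke's
law, F = k·δ_b. Frames without a detectable edge become missing
values; more than 20% missing is an error.

Cell geometry is segmented by Otsu thresholding of the mean-filtered
image. Thresholding deliberately precedes the histogram equalization
used for edge detection: Otsu's criterion is not invariant under that
rank transform, and equalized background noise inflated segmented
diameters by several pixels. Full-width dark rows (bar, slide) are
excluded; the largest remaining dark component is the cell. Two small
geometric corrections keep extents pixel-accurate: the cell apex hides
under the bar's lower edge while in contact, so an adjacent component
top is snapped to it, and the 3×3 mean filter erodes a dark boundary
by one pixel per side, which is compensated on the free apex and both
lateral edges. h₀ and d₀ are taken from the first frame, which the
protocol captures before any compression.

Stiffness is the slope of stress versus strain over each phase's
loading frames, restricted to strains in (0, 0.20] (the linear
window). The default regression carries a free intercept: the
deflection reference (the frame-0 tip row) is pixel-quantized, which
puts a constant offset on the force trace; a through-origin slope
folds that offset into the modulus (±6–10% on synthetic noise-free
cells), while a free intercept absorbs it (median error 2.6%). The
origin-constrained slope and a literal single-point σ/ε ratio remain
available via `MeasurementConfig`. R² below 0.9 flags `poor_fit`.

Pull-off detection: scanning the tension-phase force, detachment is
the first frame whose force has dropped by more than 50% of the
running peak and stays below 20% of that peak; the adhesion force is
the running peak before that frame. Both fractions are
config-exposed; no instrument convention is published, and these
defaults tolerate partial slips while catching the terminal drop.
Cells that detach before five tensile frames were collected are
flagged `early_detachment` and their TS/AF are excluded — mirroring
the study's exclusion of cells that released from the cantilever
backplate before the tensile protocol completed. A record with no
drop is flagged `no_detachment` (AF invalid, TS still estimated).

Under these defaults the end-to-end chain on 50 synthetic cells with
E ∈ [200, 800] Pa and AF ∈ [10, 60] nN recovers moduli with ~2.6%
(noise-free) and ~4% (default noise) median relative error and the
adhesion force within 2 nN in 100% of cells; the acceptance tests
assert the looser 5% / 15% / 90% bounds.

## AFM force-volume analysis

Curves are approach segments F(z). The contact point is first located
with the windowed ratio-of-variances statistic on the
baseline-corrected force (variance ahead over variance behind a
sliding split), which is sample-accurate on clean curves; because the
indentation force near contact is quadratic and buried in noise, the
modulus fit then refines z₀ by profile least squares — the modulus is
linear in the model, so it is solved in closed form for every
candidate contact position and the residual-minimizing z₀ is kept.
The default contact model is Bilodeau's four-sided pyramid,
F = 0.7453·tanθ·E/(1−ν²)·δ², with θ = 35° and ν = 0.5
(incompressible soft tissue); a Hertz sphere is available for rounded
tips. The instrument names only a pyramidal tip, so the half-angle
and depth are documented package defaults. Fits are capped at 2 um
indentation — 10% of a 20-um cryosection — to limit substrate
stiffening; loading-rate effects are not modeled (quasi-static fit).
Per-point fit failures are masked and map statistics run over valid
points only.

## Subpopulations

Quadrant gating assigns each event by two log-scale thresholds
(strictly-greater-than is positive; ties negative). Control-derived
gates use the 99.5th percentile of negative-control intensities.
Mixtures are univariate Gaussians fitted by EM for k = 1..6 with 20
restarts each, selected by BIC, with component variances floored at
10⁻³ of the data variance; peak counting evaluates the *fitted*
density (not the histogram) on a regular grid over the data range
(1 Pa for stiffness) and merges local maxima closer than 25 Pa
(2 nN for force). Band fractions use closed intervals. Group
comparisons run Shapiro–Wilk per group, one-way ANOVA and Tukey HSD
at α = 0.05.

A note on peak counts at realistic sample sizes: the analytic
four-component recurrence-group CS density (subgroup means/spreads
weighted by the quadrant proportions 0.632/0.011/0.273/0.083) has
exactly four modes, and the tests assert this against a direct grid
evaluation. Resampling n = 98 cells from that mixture, however, gives
the 1.1%-weight component an expected single cell, and BIC (penalty
3·ln n per component) rarely supports a dedicated component for it:
over 50 seeds the modal recovered peak count is 3, not 4. The
four-mode structure is a property of the density; recovering it from
a sample of this size is not guaranteed, and the acceptance suite
reports this honestly.

## Cohort generator

Per-animal vectors (mean CS, TS, AF, TV, TW, BWG) are drawn through a
Gaussian copula with a target correlation matrix: the mechanics ×
indicator block holds the study's correlations, the within-block
entries are package defaults (mechanics co-vary at 0.3–0.5; TV–TW
0.5; weak negative couplings to BWG), and the matrix is validated
symmetric, unit-diagonal and positive semidefinite (the error names
the offending eigenvalue). Marginals are normal except tumor volume,
which is log-normal (moment-matched) since its printed dispersion
would put substantial normal mass below zero. Group marginals come
from the per-group summary tables; BWG defaults to 0.15 ± 0.06 in
both groups — the groups did not differ — as a realistic gain for
young tumor-bearing mice. Tumor length/width series use a per-animal
aspect ratio in [1.1, 1.5] with W = (TV/a)^{1/3}, so TV recomputed
from the day-14 calipers reproduces the drawn value exactly, and
weight series ramp linearly to the drawn BWG; the recurrence group
regrows exponentially from day 21. Copula marginals pass a
Kolmogorov–Smirnov check at distance < 0.05 for n = 10⁴, and the
nonlinear (log-normal) marginal attenuates target correlations by
under 0.01 at the printed dispersions — inside the ±0.05 recovery
tolerance asserted in the tests.

## Printed-dispersion ambiguity

Summary tables report mean ± spread without naming the statistic. The
group-level spreads behave like standard errors (the subgroup
structure implies group SDs near 250–320 Pa, not 23–33), while the
subgroup spreads behave like SDs (the double-negative subgroup's
±165/±265 Pa are described as large standard deviations). The
generators default to treating a printed spread as the component SD
(`spread_is="sd"`) and expose `spread_is="sem"` to scale it by √n
instead; analyses that prescribe the printed values use them as
printed.

## Known limitations

* The renderer draws hard-edged, noise-free-geometry scenes; real
  phase-contrast halos, debris and drift are not emulated, so passing
  recovery tests bound algorithmic error, not instrument artifacts.
* One cell per sequence; no viscoelasticity, creep or motility during
  the run; detachment is instantaneous.
* Flow channels are independent log-normals per marker state — no
  spectral overlap or compensation modeling.
* Vessel masks are inputs; the package computes area fractions only.
* The copula cohort draws mechanics and indicators jointly per
  animal; it does not simulate per-cell variation within an animal.
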