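# Methods

## Scope and coordinate conventions

The package measures three inner retinal bands — RNFL, combined GCL/IPL,
and INL — on radial macular OCT scan sets: 6 B-scans through the foveal
center, 4.5 mm long, rotated in 30° steps, i.e. 12 radial half-lines.
Thickness is sampled at 3 eccentricities (0.75, 1.5, 2.25 mm) per
half-line, 36 points per eye; the points nearest the fovea are excluded
because the inner layers converge there and their boundaries are not
separable.

Image coordinates: row 0 is the vitreous, depth increases downward;
boundary depth is a fractional pixel at each column center, 0-based.
Default calibration is 3.9 µm/px axial and `4500/ascan_count` µm/px
lateral (2.93 µm at the native 1536 A-scans); both are config fields.

Line numbering: everything is expressed on a right-eye template (left
eyes are mirrored laterally before sampling). Line 1 is the temporal
horizontal; numbering increases counterclockwise, so line *l* points at
(l−1)·30°. Slice *k* (0-based) carries lines k+1 and k+7. Quadrants are
90° sectors starting at the temporal horizontal; the nasal hemifield is
lines 5–9 (120°–240°). This makes topographic statements ("cysts on the
nasal lines") reproducible.

## Synthetic OCT generator

**Phantom geometry.** Each phantom is a stack of smooth boundary depth
curves per slice. The outer interfaces (INL/OPL, OPL/ONL, ONL/RPE, RPE
base) are flat; the inner boundaries are stacked upward from the INL/OPL
interface by per-layer thickness fields. Inner-layer thickness thins
smoothly to ~0 inside the foveal pit (quartic-exponential radial profile,
default pit radius 450 µm, floor 2 %), which produces the pit in the ILM.
A small seeded sinusoidal undulation (3 % amplitude, 1.1 mm period) adds
lateral texture. After construction, each measured layer's field is
rescaled so its mean over the 36 grid points equals the requested target
exactly. Optional per-line scale factors modulate thickness by radial
line; they are blended across the fovea with a 120 µm sigmoid so the
curves stay smooth, and are how topographically structured cohorts
(nasal-only loss) are built. Infeasible stacks (inner layers pushing the
ILM above a 60 µm top margin, or the outer retina below the depth budget)
are rejected naming the offending layer.

**Rendering.** Bands are filled with base reflectivities (vitreous 0.05,
RNFL 0.80, GCL/IPL 0.42, INL 0.26, OPL 0.55, ONL 0.14, RPE 0.85) using
exact partial-volume coverage at fractional boundaries, blurred axially
by a Gaussian PSF (σ = 4 µm), attenuated per column by vessel shadows
(rectangular, attenuation in (0,1]), and multiplied by gamma speckle with
mean 1. The speckle shape parameter stands in for frame averaging; the
default of 100 (≈10 % residual relative SD) represents a heavily averaged
acquisition. Rendering is pure given (phantom, acquisition, seed).

**Microcysts.** A cyst plan draws count (default 3–10 per affected eye),
nasal line (default lines 5–9), eccentricity (cyst fully inside
0.75–2.0 mm), and extents (axial 28–42 µm × lateral 14–28 µm, axial >
lateral, i.e. elongated perpendicular to the layers). Cysts are stamped
into the clean image as ellipses strictly inside the INL band at 40 % of
the INL reflectivity (drop 0.6), with a boolean truth mask. Cystic change
is modelled as edema: the INL also swells locally around each cyst
(Gaussian lateral bump, σ = 250 µm, amplitude ≈ 0.35 × axial extent,
min 6 µm), so an eye rendered with cysts is genuinely thicker in the INL
than the same eye rendered without. A cyst that cannot fit inside the
INL anywhere allowed is skipped and logged, never misplaced.

**Cohorts.** Per-eye layer targets are drawn from group-specific
multivariate normals truncated at 1 µm. Defaults encode a healthy-control
group (RNFL 32.2 ± 2, GCL/IPL 98.1 ± 5, INL 39.6 ± 3 µm; corr(GCL/IPL,
INL) = 0.65, corr(RNFL, ·) ≈ 0) and an affected group (27.8 ± 4,
69.3 ± 14, 42.9 ± 6 µm; corr(RNFL, GCL/IPL) = 0.80, corr(RNFL, INL) =
−0.61, corr(GCL/IPL, INL) = −0.44). Affected/fellow pairs are coupled by
one of two models: *shared-latent* (both eyes share a fraction ρ of their
latent variance; ρ defaults to 0.7 — fellow-eye statistics are not
constrained by published data, so this is a free parameter) or *delta*
(affected = fellow + correlated difference, used when the asymmetry
correlation itself, e.g. −0.75, is the generative target). Exactly
`round(prevalence × n)` affected eyes receive cysts (assignment random
under the seed); cyst-designated eyes are redrawn from a severe stratum
(RNFL 22.7 ± 4, GCL/IPL 54.2 ± 6, INL 53.8 ± 6 µm) so cysts always fit
and the cyst subgroup has the expected contrast. Durations (ON→OCT,
MS duration) are gamma-shaped with mean ≈ 51–52 and SD 44 months,
independent of the layer draws.

**What the generator does not emulate:** interferometric physics and
depth-dependent signal decay, motion/blink artifacts, real vessel
geometry (shadows are rectangular columns), curvature/tilt of the retina,
pathology other than diffuse thinning + INL cysts, and raster/volume
protocols. Passing tests therefore demonstrate correctness of the
measurement chain under controlled conditions, not clinical performance.

## Segmentation

Chain per B-scan: quality gate → vessel detection/removal → sequential
median filtering → Canny edges → dynamic-programming boundary tracing.

*Quality gate.* SNR = 10·log₁₀(signal power / background power) with the
signal band 350 µm below a coarse ILM estimate and the background the
vitreous above it (zero background variance ⇒ +∞, passes); pass requires
SNR > 25 dB, pit centration within 500 µm of the image center, and
left/right brightness ratio in [0.8, 1.25].

*Vessels.* Column means are taken over the **outer** retina (190–350 µm
below the ILM): a vessel shadow attenuates the whole column down to the
RPE, whereas an INL microcyst darkens only the inner retina — banding
deep separates the two. A column is flagged when its mean drops more
than 2.5 robust SDs (1.4826·MAD) below a 61-column rolling median; runs
narrower than 20 µm are discarded (isolated speckle dips), surviving
runs are dilated by 2 columns. The statistic is scale-free (gain
invariant). Flagged columns are replaced by per-row linear interpolation
(nearest-neighbor at the edges) and marked `interpolated` in the output.

*Filtering.* Sequential 2-D medians with windows (3×3), (3×7), (3×15)
(axial × lateral). Windows are axially narrow deliberately: a square
median taller than a band erases it (the thin ON RNFL is ~6–7 px), while
wide lateral windows exploit the lateral smoothness of the layers.
Square sizes remain supported.

*Edges.* Standard Canny with σ = 2 px and hysteresis thresholds set from
the gradient-magnitude distribution (high = 0.90 quantile, low = 0.5 ×
high) for gain invariance. A constant image yields an empty edge map.

*Tracing.* Each boundary is the minimum-cost lateral path through a
signed axial-gradient field (σ = 1.2 px for localization), cost
−max(0, sign·∂I/∂z) minus a small bonus on Canny pixels, with a
smoothness penalty λ = 0.15 per pixel of jump (max ±3 px/column) on a
gradient field normalized by its 0.995 |quantile| (gain invariance).
Order of tracing: ILM (coarse intensity crossing refined by DP); the
strong ONL/RPE step as a deep anchor; INL/OPL in a band 90–165 µm above
that anchor — anchoring deep keeps the weak GCL-IPL/INL edge from being
confused with the much stronger OPL/ONL edge in severely thinned eyes;
then RNFL/GCL-IPL in [ILM, min(ILM + 85 µm, INL/OPL − 2 px)] and
GCL-IPL/INL in [RNFL/GCL-IPL + 12 µm, INL/OPL − 1 px]. Bands collapse
gracefully at the fovea, pinning converged boundaries; ordering holds at
every column by construction. Sub-pixel refinement fits a parabola to
the gradient around the path (+0.5 px pixel-center offset). A boundary
with no admissible band is flagged failed together with all deeper
boundaries; results are never fabricated.

Accuracy is evaluated outside a 600 µm foveal exclusion zone, mirroring
the protocol's exclusion of the central points where layers converge
(the 36-point grid starts at 750 µm regardless).

## Thickness grid and summaries

At each grid point, thickness = boundary separation × axial calibration,
averaged over a 5-column window to suppress single-column jitter. The
outermost eccentricity (2.25 mm) sits exactly at the scan edge; its
window is clamped inside the image by at most one window width —
without this the default protocol would invalidate a third of the grid.
Points over failed boundaries or farther off-scan are invalid, never
extrapolated. An eye with fewer than 30 of 36 valid points is flagged
unanalyzable. Eye summaries are per-layer means over valid points.

## Microcyst detection

Within the traced INL band (0.5 px margins, vessel-flagged columns ± 2
excluded), pixels darker than (1 − 0.35) × a local INL median (per-column
medians smoothed by a 201-column rolling median — robust to lateral
shading) are candidates. Connected components are kept if area ≥ 6 px²,
axial extent ≥ 0.8 × lateral extent in µm (admits near-round cysts while
favoring the perpendicular elongation), and rim/interior intensity ratio
≥ 1.3 ("well-circumscribed"). Each kept cyst is localized by centroid →
signed eccentricity and radial line (mirrored for left eyes). Cohort
prevalence is eyes-with-≥1-cyst / eyes analyzed, to the nearest integer
percent; topography is a quadrant histogram. Detection thresholds are
package defaults, not literature constants: the clinical definition of a
countable cyst is qualitative.

## Statistics

Group comparisons use the two-sided pooled-variance Student t-test
(Welch available by option); identical zero-variance groups report
t = 0, p = 1 by convention. Pearson r carries a two-sided p from the t
transform with n−2 df; zero-variance input is an explicit error, never a
silent NaN. No multiple-testing correction by default (a Holm option
exists). The asymmetry analysis takes affected-minus-fellow differences
per subject (binocular subjects excluded; missing fellow eyes dropped
with a count) and correlates ΔGCL/IPL with ΔINL; all-zero differences
are reported as undefined. The 36-point deviation map uses control −
affected for RNFL and GCL/IPL (thinning positive) and affected − control
for the INL (increase positive) — the convention is stamped into every
output — and correlates GCL/IPL thinning with INL increase over the
grid points using signed differences (config-exposed choice); points
with fewer than 2 valid eyes in either group are dropped and counted.
Subgroup analyses (cyst-positive vs negative) reuse the same immutable
measurement table for the "with" and "without" re-runs, so repeated
analyses are bit-identical; a subgroup of size 1 is refused.

Implementation note: t and r are computed via scipy.stats; the test
suite cross-checks both against hand-written textbook formulas on random
fixtures to 1e-10 relative error.

## Problem sizes and numerical choices

Cohort-scale experiments and the test suite render at 384 A-scans ×
176 depth px (full 4.5 mm × ~686 µm geometry, coarser sampling) so a
36-eye cohort (216 B-scans) simulates, segments and analyzes in a few
minutes on one CPU; unit accuracy checks that need per-column
specificity (vessel flagging) use the native 1536-column width. The
segmentation-recovery suite uses 20 seeded phantoms spanning healthy to
severely thinned anatomy; the cyst sensitivity/specificity suite uses 6
seeded severe eyes with 3–10 cysts each. Determinism: every stochastic
component takes a numpy Generator seed; repeated runs are bit-identical,
and the 16-bit TIFF round trip changes layer means by < 0.01 µm.

## Known limitations

- The segmenter is tuned to the generator's contrast ordering (bright
  RNFL/OPL/RPE, darker GCL/IPL, dark INL/ONL). Real scans with different
  contrast or pathology outside this family (drusen, detachments, large
  edema) are out of scope.
- Only 4 inner boundaries are reported; the outer retina is traced once
  as an anchor, not sub-segmented.
- GCL and IPL are measured as one band end-to-end (their reflectivities
  are too similar to separate reliably).
- The topographic deviation correlation reflects whatever topography the
  generator imposes; the default cohort has none, so its r is ≈ 0 by
  construction unless per-line structure is configured.
- Prevalence arithmetic assumes one designated study eye per affected
  subject; per-subject vs per-eye prevalence coincide here.
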