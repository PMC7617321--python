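# Methods

This note documents the models, conventions, parameter defaults and
numerical choices behind `epipolarity`, and what the synthetic-data
generators do and do not emulate.

## Coordinate and angle conventions

Label maps use pixel-centered, 0-based coordinates with x rightward and
y downward. Angles are measured counterclockwise on screen from +x, so
the direction vector of angle t is (cos t, −sin t) in image
coordinates. All tissue-scale orientations are axial (period 180°).
Raw angles are normalized against the image-frame angle of the sensory
organ precursor (SOP) cell line; after normalization 0° is the
proximodistal (PD) axis and 90° the anteroposterior (AP) axis.
Junctions and event axes with normalized angle in [45°, 135°) are
classified AP, the rest PD; the bounds are lower-inclusive so the
classification partitions [0, 180°) exactly.

## Tissue model

A `SegmentedTissue` wraps one frame's integer label map (0 =
background). Cells carry pixel centroids, areas, boundary pixels
(pixels with a 4-neighbor of a different label, ordered by polar angle
around the centroid) and the central second-moment tensor of their
interior pixels. Cell elongation is the principal axis of that tensor
with magnitude (λ₁−λ₂)/(λ₁+λ₂).

`build_junction_graph` emits one junction per 4-adjacent label pair.
The junction chord joins the two extremal interface midpoints (extremes
of the projection onto the interface's principal direction); its angle
is the end-to-end chord angle, matching the manual convention of
drawing a line along a junction, rather than averaged per-pixel
tangents. Junction intensity is averaged over a band of member-cell
pixels hugging the interface. The band width defaults to 3 px
(~0.6 µm at the 0.21 µm pixel size typical of these recordings, about
the width of the junctional signal); it is exposed as a parameter
because segmentation pipelines differ in how much signal spills off the
skeleton. Pixels 4-adjacent to any third cell are excluded so vertices
do not contaminate junctional means.

The tracking table (frame, cell_id, lineage_id, parent_lineage_id) is
the single source of lineage truth; label maps are per-frame only. A
division appears as two child lineages naming the same parent in their
first frame.

## PCA polarity

For each cell the boundary point set is whitened (multiplied by the
inverse principal square root of its centered second-moment tensor),
which maps the cell to an isotropic shape and is what makes the score
insensitive to cell eccentricity. Boundary intensities are divided by
their own mean, removing per-cell illumination differences and making
the score invariant to intensity scaling. The polarity angle is the
principal axis of the intensity-weighted second-moment matrix of
whitened boundary displacements; the magnitude is its eigenvalue
anisotropy (λ₁−λ₂)/(λ₁+λ₂), a bounded, scale-free number in [0, 1]
chosen so magnitudes are comparable across cells and samples. Apolar
cells (magnitude below 1e−9) report angle 0 by convention rather than
NaN so downstream tables stay numeric.

Whitening centers displacements at the boundary-point mean rather than
the pixel centroid; for the convex, roughly star-shaped cells this
pipeline targets the two differ negligibly, and the choice keeps the
whitening and the weighting consistent on one point set.

Coarse-graining averages cell polarities as nematic tensors
Q = mean(m·(cos 2θ, sin 2θ)) over square spatial tiles whose side is
`block_cells` (default 3) median cell diameters — an approximation to
"3×3 cells" that is well defined in irregular tissues. Naive averaging
of axial angles is wrong (0° and 179° would average to 89.5°); the
double-angle representation handles the wrap-around.

Weighted angle histograms use 18 bins of 10°. Two weighting modes are
provided because the two natural readings of magnitude weighting —
summing magnitudes per bin versus averaging them — answer different
questions (total vs typical polarity strength per orientation);
`magnitude_sum` is the default.

## Division and T1 extraction

Divisions are read from the tracking table: one event per lineage
replaced by exactly two children in one frame. The new-junction angle
is the orientation of the daughter–daughter junction in their first
shared frame (daughters without a shared junction are kept, flagged
`no_shared_junction`, with an undefined angle — flagged retention
rather than silent dropping keeps event counts honest). The division
axis is the new-junction angle + 90° (mod 180°).

T1 detection treats junctions shorter than a bond cutoff (default 4 px
of chord length, the conventional four-way-vertex threshold) as
contracted vertices, i.e. as no contact. An event is emitted at the
first frame where a previously effectively-adjacent pair has lost
contact while a pair of their common neighbors has gained a junction at
least as long as the cutoff. Candidate events involving a cell that
divides within ±1 frame are excluded and logged: division
neighborhoods transiently look like exchanges, and the ±1-frame window
is this package's explicit, deterministic version of the manual
curation such data normally receive. Detection operates on lineage
ids, so it is invariant to per-frame relabeling of cells.

## FRAP

Acquisition schedule (the default): 3 pre-bleach frames, an immediate
post-bleach frame, then 5 frames every 5 s, 10 every 10 s, 10 every
15 s and 7 every 30 s (33 post-bleach timepoints over 515 s). Each
bleached ROI is paired with an unbleached control ROI and a scalar
background.

Quality gates: initial bleaching 100 − 100·(Ī₀/Ī₋₁) must lie in
[50, 75] %; acquisition bleaching 100·(Ū₋₁−Ū_end)/(Ū₋₁−bg) must be
below 25 %. Failing traces are excluded with a warning, not an error,
so batch runs complete.

Correction: A_n = [(Ū₋₁−bg)/(U_n−bg)]·[(I_n−bg)/(Ī₋₁−bg)]. The
reference denominator is the pre-bleach mean of the bleached ROI: this
is the only reading under which pre-bleach intensities map to 1 and the
subsequent normalization N(n) = (A_n−A₀)/(1−A₀) spans 0 to 1 (dividing
by the first post-bleach intensity instead makes A₀ ≡ 1 and N
degenerate). The literal post-bleach reference is available via
`reference="post_bleach"` for comparison. The correction exactly
cancels any multiplicative bleaching profile shared by both channels
and is invariant to rescaling all intensities and the background by a
common factor.

One-phase model: y = y_max·(1 − e^(−αt)), with y(0) = 0 by
construction. Starting values: y_max from the last observation, α from
the time to half-plateau; bounds y_max ∈ (0, 1.5], α ∈ (0, 10] s⁻¹;
tolerances 1e−10, at most 10⁴ evaluations. 95 % confidence intervals
come from the asymptotic covariance of the NLS estimate with
t-quantiles. Under the fit's own noise model (independent Gaussian
noise on the normalized curve) these CIs are well calibrated (~94 %
coverage at σ = 0.05 on the default schedule). A caveat the tests make
explicit: when noise enters the *raw* traces, normalizing each ROI by
its own noisy A₀ injects a shared offset per ROI that an iid-residual
CI cannot represent, and per-pupa CI coverage drops well below nominal.
This is a property of the standard normalization formula itself;
plateau *comparisons* are unaffected (the per-pupa t-test does not use
the curve-fit CIs) and plateau estimates stay unbiased to < 0.01.

Two-phase model: y = A₁(1−e^(−α₁t)) + A₂(1−e^(−α₂t)) with α₁ > α₂
enforced by reordering. On one-phase data the model collapses (A₂ ≈ 0
or α₁ ≈ α₂); near-equal rates leave parameters poorly defined and the
confidence intervals are then reported as NA rather than fabricated.

Aggregation follows the replicate structure of the assay: ROIs are
technical replicates (each ROI is corrected and normalized
individually, then the typically four same-orientation ROIs of a pupa
are averaged into one curve), pupae are biological replicates. Group
plateaus are compared with an unpaired Student's t-test on per-pupa
y_max values; groups with a single pupa are refused. When comparing
genotypes rather than junction orientations, all eight ROIs of a pupa
enter its single average curve.

## Ablation recoil

Wound-edge vertices are fitted per frame with a direct least-squares
ellipse (algebraic conic fit constrained to an ellipse); full axis
lengths are reported with a ≥ b and the major-axis orientation
SOP-normalized (circles report 0° by convention). Axis dynamics follow
L(t) = L∞ − (L∞−L0)·e^(−t/τ). The functional form is a choice: a
saturating exponential is the standard Kelvin–Voigt-type relaxation for
post-ablation recoil and matches the plateauing curves these assays
produce; the fitting routine is pluggable if another form is wanted.
The initial recoil velocity is deliberately *not* the fitted curve's
derivative at 0 but the OLS slope of axis length over frames
t = 1..6 s at 1 frame/s — the operational "first 5 s" definition —
because that is robust to the model choice. Flat series are flagged
`no_recoil` instead of fitting a meaningless τ. Major and minor
velocities are compared per group with an unpaired Student's t-test
across pupae (identical constant samples report t = 0, p = 1 rather
than a 0/0). The default cut geometry is a 24.3 µm diameter circle.

## Statistics

Angle distributions are compared with a two-sample Kolmogorov–Smirnov
test on the raw angles treated as linear data on [0, 180°). A caveat:
for circular data the KS statistic depends on the origin; here the
origin is pinned to the SOP axis, which makes D well defined and
comparable across samples, but it is not a rotation-invariant circular
test (Kuiper's test would be; it is out of scope). Exact p-values are
used when n₁·n₂ ≤ 10⁴ and no ties are present (the exact distribution
is unavailable with ties); otherwise the asymptotic approximation —
appropriate at the hundreds-to-thousands of events this pipeline
targets. Scalar group comparisons use an unpaired t-test for two groups
and one-way ANOVA with Tukey–Kramer-adjusted pairwise p-values for
three or more; raw pairwise p-values use the pooled ANOVA error
variance so adjusted ≥ raw holds exactly.

## Synthetic data

The generators emulate a segmented pupal-wing field and the paired
physiological recordings; they are the package's accuracy oracle, since
every analysis stage can be run against known truth.

- **Tissue**: seeds on a jittered triangular lattice (epithelial
  packings are near-hexagonal; jitter sd 0.15 of the lattice spacing)
  rasterized as a nearest-seed label map with 2 Lloyd relaxation
  iterations. Defaults: 1000 cells, 4 µm mean diameter, 0.21 µm
  pixels. Mean cell-shape anisotropy of interior cells is ~0.11–0.16
  depending on field size. An optional global stretch elongates cells
  along a chosen axis. There is no background/skeleton between cells;
  junctions are label-pair interfaces.
- **Polarity painting**: junction intensity
  base·(1 + c·cos 2(θ−axis)) + Gaussian noise, painted on interface
  pixels. With the enrichment axis at 0° (PD junctions bright), per-cell
  PCA polarity concentrates at 90° — the geometric inversion between
  junctional enrichment axis and cellular polarity axis.
- **Time-lapse events**: divisions split a cell's pixels along the
  line through its centroid at the sampled new-junction angle; T1s
  rewire a quartet by reassigning a small pixel band so the losing pair
  separates and the gaining pair meets along the target angle. Event
  orientations are drawn from an axial von Mises distribution (sampled
  on the doubled circle and halved; default mean 90°, κ = 4). Each
  event uses a disjoint set of interior cells, so planted T1s never
  share cells with divisions; the detector's ±1-frame division
  exclusion can therefore be tested for false positives without
  sacrificing recall. Default 13 frames (2 h at 10-min intervals).
- **FRAP**: recovery R(t) = pre·[(1−d) + d·y_max·(1−e^(−αt))] with the
  bleach depth d set from the requested initial-bleaching percentage
  (default 60 %); both channels decay geometrically per frame,
  calibrated so measured acquisition bleaching equals the request
  (default 15 %); background (default 50 at pre = 1000) is added, then
  Gaussian noise. Defaults y_max 0.8, α 0.02 s⁻¹.
- **Recoil**: axis lengths follow the relaxation model with L∞ chosen
  per axis so the frames-1..6 OLS slope equals the requested velocity
  exactly; 12 vertices are sampled on the ellipse with jittered polar
  angles, plus optional Gaussian position noise. Defaults: L0 =
  24.3 µm, τ = 20 s, v_major = 0.2 and v_minor = 0.1 µm/s (a PD-biased,
  post-hinge-contraction-like state; set them equal for the
  early-stage isotropic state). Simulation studies in the tests use
  0.05 µm vertex noise, a realistic tracking jitter of a fraction of a
  pixel.

Every generator draws from its own deterministic sub-stream of the
master seed, so outputs are pure functions of their parameters and
adding a generator never perturbs existing fixtures.

What the generators do **not** emulate: point-spread functions, shot
noise and imaging artifacts; curved or moving tissue; cell growth,
extrusions and rosettes; mechanically realistic vertex-model dynamics;
diffusion-limited FRAP recovery; wound-healing ring mechanics. Passing
tests therefore certify the *analysis* chain — geometry, corrections,
estimators, statistics — not robustness to raw-microscopy nuisances or
segmentation error.

## Problem sizes used in the validation suite

The test and acceptance runs use: 1000-cell fields for the end-to-end
polarity and event checks (13 frames, 60 divisions + 30 T1s); 200
replicates for FRAP calibration and for each recoil simulation (7-pupa
null, 11-pupa anisotropic design, 8 frames — only the first six enter
the velocity); 1000 null replicates at n = 100 for KS calibration; 500
random 3-group datasets for the Tukey–Kramer ordering check; and an
exhaustive sweep of all ~10⁵ pairs of samples of size ≤ 6 over a
5-angle alphabet against the brute-force ECDF oracle.

## Known limitations

- Junction chords understate the length of strongly curved junctions;
  orientation is end-to-end by design.
- The coarse-graining tiles are square and axis-aligned; block
  membership near tile borders is arbitrary at the half-cell scale.
- T1 detection assumes clean tracking; it does not attempt rosette
  decomposition or recovery from tracking gaps.
- The recoil model assumes a single relaxation timescale per axis.
- KS on [0, 180°) is origin-dependent (see above).
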