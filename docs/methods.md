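# Methods

This note documents the models, parameter choices and numerical
conventions behind `hepcyto`, and what the synthetic benchmarks do and do
not establish about real microscopy.

## Image operators

**Spot enhancement.** The spot-enhancing filter is the sign-flipped,
scale-normalised Laplacian of Gaussian, implemented as convolution with
the analytic kernel `K = −σ²∇²G_σ` sampled at pixel centres, truncated at
5σ and recentred so a constant image maps exactly to zero. Boundaries are
handled by reflection. Scale-normalisation (×σ²) makes peak response
roughly independent of σ; the sign flip makes bright blobs positive. The
default scale is **σ = 2.0 µm**. The matched filter for a disk of radius
r is σ ≈ r/√2 ≈ 3.2 µm for the 4.5 µm nuclei simulated here, but at
1200 cells/mm² nuclei sit only a few µm apart and that scale blurs
neighbours into single components (detection recall drops to ~0.90);
σ = 2 µm keeps per-nucleus response well separated at a modest cost in
peak signal-to-noise. σ is an exposed parameter, as is the enhancement
mode: the time-lapse variant of the assay uses plain smoothing
(normalised box convolution, default 2 µm kernel) instead of the spot
filter.

**Triangle threshold.** The histogram is integer-exact for integer
images and 256 equal bins over the observed range for float images. A
chord runs from the histogram peak to the farthest nonzero bin on the
longer-tail side (equal tails → right tail). Each interior bin's
perpendicular distance to the chord is computed in normalised coordinates
(peak→tail span and peak count both scaled to 1) and the threshold is the
centre of the maximising bin. Ties take the median of the tied bins,
rounded toward the peak, so two equal spikes separated by an empty
plateau threshold at the plateau midpoint. These rules pin the behaviour
deterministically; no attempt is made to reproduce any particular
legacy implementation's variant.

**Background mode.** The most frequent integer pixel value, ties to the
smallest value. With a Poisson background of rate λ the sample mode sits
at ⌊λ⌋ (occasionally ⌊λ⌋−1), so mode subtraction can under-correct by
~1 count; the anion channel is therefore corrected by a vehicle-control
*mean* instead (see below).

## Segmentation and shape

Enhanced images are thresholded and labelled with 8-connectivity. No
size or shape filtering happens at segmentation time — noise specks and
merged objects are deliberately passed through and removed later by the
quantitative exclusion rules, which is how the assay design separates
detection from quality control. A blank field (flat enhanced response or
single-bin histogram) yields zero nuclei with a warning rather than an
error.

Shape metrics per component: area = pixel count × (pixel size)²; maximum
Feret diameter = largest pairwise distance between boundary-pixel centres,
computed exactly via the convex hull (with a brute-force fallback for
degenerate masks); circularity = 4πA/P² with the 4-direction Crofton
perimeter estimator. Crofton was chosen because its bias vanishes for
large disks (circularity 0.99 at r = 50 px, 0.94 at r = 10 px), which a
0.6 circularity cutoff requires; the naive pixel-edge perimeter saturates
disk circularity near 0.91 regardless of size. Circularity may slightly
exceed 1 on small discrete masks.

## The cellular (cytosolic) ROI

The "cytosol" of a cell is the annulus from its nuclear border to 3 µm
beyond it (the band width is a parameter). Distances are Euclidean
between pixel centres, 0-based (row, col) with the origin at top-left.
Pixels within the band of two or more nuclei are assigned to the nucleus
whose mask is nearest; squared pixel-grid distances are integers, so ties
are exact and resolved to the lower label. Pixels inside any nucleus are
never cytosol. The band is purely geometric — with no membrane channel it
can include a geometrically closer neighbour's cytoplasm, a known
property of the ROI design rather than a defect.

## Measurement and background correction

Per channel per ROI: mean, sample SD (n−1; 0 for single-pixel ROIs),
integrated intensity (= mean × pixel count) and pixel count, all on raw
counts. Corrections: the anion channel subtracts the mean cytosolic
intensity of a vehicle (no-anion) condition; Hoechst, Lysotracker and
propidium iodide subtract the field's image mode. Negative corrected
values are retained — clamping would bias condition means near zero.
The FBA/Hoechst ratio uses corrected values and is undefined (record
flagged and excluded) when corrected Hoechst is non-positive.

## Exclusion rulesets

Three named declarative rulesets carry the assay's thresholds:

* `accumulation_assay` — cytosolic anion SD outside mean ×15/÷15,
  cytosolic Lysotracker SD outside ×10/÷5, nuclear Hoechst SD outside
  ×2.5/÷5, nuclear Lysotracker mean > ×1.5, nuclear area < 47 or
  > 360 µm², circularity < 0.6.
* `viability_assay` — qualifying nuclear area 36–468 µm², nuclear
  propidium iodide mean < 200 a.u., nuclear Hoechst SD within ×2/÷2,
  circularity ≥ 0.6.
* `timelapse_assay` — nuclear area 36–252 µm², circularity ≥ 0.05.

Two readings of "mean ×k" are possible: a cell's statistic against the
population mean of that statistic, or against the same cell's own mean
intensity. The population reading is the default (the per-statistic
reference is the mean over all candidate records, computed once before
any flagging, which makes flagging idempotent and order-free); the
rulesets are data, so the alternative is expressible by overriding
bounds. SD rules attach to each dye's target compartment: anion and
Lysotracker in the cytosol, Hoechst in the nucleus. All relations are
strict inequalities; a record is retained iff it trips no rule. Condition
means at or below 75 a.u. are annotated as too dim for robust scoring at
the report level; no per-cell filter is applied at that level.

## Time-lapse death calling

ROIs are frozen at frame 1 — no re-segmentation or tracking — because
hepatocytes are essentially non-motile over a 30-h movie and
re-segmentation after death is unreliable (nuclei fragment). "Cell
fluorescence" for the PI death rule defaults to the cytosolic annulus
(the cellular ROI), configurable to the nuclear ROI. Per frame, the
frame's own image mode is subtracted from PI (and from FBA, since a
frame-matched vehicle arm is rarely available in a movie). A cell is
called dead at the first frame with PI excess > 100 a.u. (1-based frame
index); appending later frames can never change an existing call. Cells
already above threshold at frame 1 are excluded from stratification —
only cells viable at the start are informative about subsequent death.

## Population statistics

Tertile stratification sorts ascending by initial (frame-1) FBA with a
stable sort (ties keep input order) and cuts into three contiguous
groups; remainders go to the low then the mid group, so sizes differ by
at most one. Death fractions are plain percentages within groups; the
high-vs-whole contrast is reported both in percentage points and as a
relative ratio, since either convention is found in practice. CV uses
the sample (n−1) SD. The power law *y = a·x^b* is fitted by least
squares on log y vs log x — deterministic, exact on noiseless power-law
data, and the conventional way plotted power trends are produced — with
an optional nonlinear refinement on the raw scale. Time-course summaries
treat experiments, not cells, as the unit of replication (mean of
per-experiment means, SEM = SD/√n_experiments) and compare conditions by
two-sided, equal-variance Student's t-tests; no multiple-testing
correction is applied.

## The synthetic-field generator

The generator emulates the statistical structure the analysis assumes,
not optics. Geometry: nucleus centres by dart throwing at the configured
plating density (1200 cells/mm² default; the count is Poisson in the
field area), radii normal (4.5 ± 0.5 µm, truncated to a plausible
window), minimum centre distance r_i + r_j + 1 µm with an optional extra
clearance, and an opt-in `allow_touching` stress mode. Nuclei render as
soft-edged disks (±0.65 µm linear edge). Cytoplasm is an annular profile
(flat from 1 µm inside the nuclear border to 5.5 µm outside, tapering to
zero at 7 µm) painted over **nearest-nucleus territories**, so confluent
cells tile space instead of summing — the flat span comfortably covers
the 3 µm measurement band even when the segmented boundary misses the
true one by a pixel. Intensities: per-cell true FBA is lognormal
(default mean 500 a.u., CV 15%, the scale of cell-to-cell heterogeneity
such assays report); Lysotracker lognormal (CV 20%, optionally
log-correlated with FBA to emulate an immunofluorescence marker);
Hoechst normal with ~2% CV. Signal = background (100 a.u.) + object
profile, optional Poisson shot noise, Gaussian read noise (σ = 3) added
last, clipped and quantised to 16-bit. Identical config and seed give
bit-identical output.

Dead cells (fraction configurable) render with 400 a.u. nuclear and
300 a.u. cellular PI excess, a fragmented nucleus (three off-centre
sub-disks with strongly varying amplitude) and reduced circularity, so
each viability rule has real violations to catch; debris are sub-nuclear
bright specks flagged non-cell in the ground truth. The ground-truth
table carries one row per rendered object: position, true per-channel
cytosolic intensity, viability at t0, death frame and true tertile.

**Death hazard.** In time-lapse mode each cell viable at frame 1 dies
with per-frame probability `expit(α + β·log F)` where F is its true FBA
and β (`death_coupling_beta`, default 3.0) is the log-odds of death per
unit log FBA. α is not exposed: it is calibrated by 64-node
Gauss–Hermite quadrature over the lognormal FBA law so that the marginal
death probability over the movie equals `death_marginal_p` (default 0.4,
a bile-acid-arm-like level). With the default CV this yields roughly
26/39/54% death in the low/whole/high tertiles — a high-vs-whole excess
of ~15 percentage points, the magnitude at which tertile stratification
is informative. Death frames are drawn geometrically (first lethal
inter-frame step), which is distributionally identical to per-frame
Bernoulli draws; the test suite verifies this against an independent
frame-by-frame simulation. `simulate_death_cohort` exposes exactly this
sampling path without pixel rendering, which is how cohort-scale
(n = 1500) stratification analyses are run at desk scale; full pixel
rendering of movies is exercised on small fields (256 px, ~25 cells,
13 frames).

**What the benchmarks do not show.** The generator has no PSF, no
collagen-layer scattering, no focus drift, no photobleaching, no cell
migration, and its nuclei never touch unless asked to; the standard
clean benchmark additionally keeps enough clearance (7 µm extra) that
every annulus lies inside its own cell's cytoplasm territory, so
intensity recovery there measures the ROI machinery, not robustness to
confluence. Passing these benchmarks therefore establishes correctness
of the measurement chain under the stated statistical model, not
segmentation performance on dense real tissue — which the assay's own
exclusion rules, not the segmenter, are designed to police.

## Problem sizes and numerical conventions

Benchmarks run at: one 768×768 px field (0.25 mm², ~300 cells) for
segmentation/intensity recovery; n = 1500 cohorts (with a 200 000-cell
Monte-Carlo reference) for stratification; n = 1000–1150 samples and 200
replicates for the statistic checks — sizes at which the statistical
contrasts of interest are resolvable in seconds on one CPU. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; derived seeds stay below 2³¹. Strict
inequalities throughout the rules; distances in µm; times internally in
minutes (manifests accept hours for culture age); frames are 1-based.
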