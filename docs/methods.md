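# Methods

## Regions and ratios

Both pipelines start from two binary masks on the fluorescence image grid:
the macroscopic tumor and the complete bread loaf, rasterized from
polygons drawn on the co-registered white-light image. The tumor mask is
intersected with the loaf mask at load time (both pipelines assume
tumor ⊆ loaf; any clipped area is logged). Multiple tumor polygons for one
loaf should be unioned into a single mask before region construction.

**Dilation in physical units.** `dilate_mm(mask, d, p)` returns every
pixel whose Euclidean distance (between pixel centers) to the mask is at
most `d / p` pixels, by thresholding the exact Euclidean distance
transform at the *real-valued* radius (e.g. 35.294… px for 3 mm at
0.085 mm/px) with a `<=` comparison. No structuring-element approximation
and no integer rounding are used: the operation is exact up to
pixel-center discretization, reproducible across implementations, and
monotone in both the mask and the radius.

**Non-targeted (rim) pipeline.**
signal region = (dilate(tumor, 3 mm) \ tumor) ∩ loaf;
background region = loaf \ dilate(tumor, 5 mm);
SBR = MFI(signal) / MFI(background). The signal halo is clipped to the
loaf so that zero-intensity pixels outside the specimen never enter the
mean. With the default 3/5 mm parameters, tumor, signal and background are
pairwise disjoint subsets of the loaf. The same dilation operator is used
for both the 3 mm and the 5 mm step.

**Targeted pipeline.**
signal region = tumor; background region =
(dilate(tumor, 5 mm) \ tumor) ∩ loaf; TBR = MFI(tumor) / MFI(background).
The background margin is configurable (`--background-mm`), e.g. 10 or
15 mm for other tissue types or dyes; widening it weakly shrinks the
non-targeted background and weakly grows the targeted one.

**MFI.** Intensities are binned into half-open intervals
`[i·w, (i+1)·w)` anchored at zero with `w = 0.001` a.u.; the MFI is the
count-weighted mean of bin centers. Whether an implementation uses bin
centers or lower edges changes the result by at most `w/2`, and the
histogram MFI always agrees with the direct arithmetic mean to `w/2`; this
bound propagates into the ratios as roughly `w/2 · (1/MFI_sig + 1/MFI_bg)`
relative error. A constant region whose level falls exactly on a bin edge
realizes the full `w/2` error; smoothly varying regions average it away.
Intensities are treated as opaque arbitrary units — the imager does not
auto-gain, and no calibration or normalization is applied.

## Agreement statistics

**DSC schedule.** The evaluation design is 3 observers × 2 delineation
sessions per loaf. Interobserver overlap is computed for the three
observer pairs crossed with all four session combinations (I-I, I-II,
II-I, II-II): 12 records per loaf per ROI kind. Intraobserver overlap is
session I vs session II per observer: 3 records. ROI kinds are the
tumor/signal region and the derived background region of the selected
pipeline. Incomplete designs are rejected with the missing combinations
listed.

**ICC.** The "two-way mixed-effects, absolute-agreement, mean-rating"
model is operationalized as McGraw & Wong's ICC(A,k):
`(MSR − MSE) / (MSR + (MSC − MSE)/n)` from the two-way ANOVA mean squares
(subjects, raters, residual). The confidence interval is the F-based
interval for ICC(A,1) with Satterthwaite denominator degrees of freedom,
stepped up to k raters by the Spearman–Brown relation — the same
convention as the common statistical packages (verified against pingouin's
ICC2k in the test suite). Negative estimates are reported as computed and
flagged, never truncated to zero, so degenerate simulations stay visible.
A matrix with zero residual *and* zero subject variance is rejected as
degenerate; perfect absolute agreement (zero residual and rater variance,
positive subject variance) returns 1.0 with a collapsed interval.

**Subject stacking.** The design does not uniquely determine the ICC
subject structure, so it is fixed here as: interobserver — subjects =
loaf × session (n = 2 × loaves), raters = the 3 observers; intraobserver —
subjects = loaf × observer (n = 3 × loaves), raters = the 2 sessions.
These are the only complete-design readings consistent with k = 3 and
k = 2 mean-rating models computed "over both sessions" / "once for all
measurements".

**Ratings and comparisons.** Point estimates and CI endpoints are rated
poor (< 0.5), moderate ([0.5, 0.75]), good ((0.75, 0.9]), excellent
(> 0.9). The published band wording is ambiguous at 0.75 and 0.9; both
interior boundaries are assigned to the lower band, matching the strict
inequalities that define poor and excellent. Two ICCs are reported as
significantly different iff their confidence intervals are disjoint.

## Synthetic phantoms

The generator emulates the closed-box imager's output geometry (default
1300 × 964 px at 0.085 mm/px; tests and the acceptance script use a
400 × 300 px field — 34 × 25.5 mm — which leaves room for the 5 mm margin
while keeping runtimes in seconds). A phantom is an elliptical loaf on a
black field with a circular (optionally lobulated) tumor, plus:

* **rim pattern** (non-targeted dye): intensity `b` inside the loaf plus
  `a · exp(−dist_mm / d)` outside the tumor, with distance measured to the
  tumor boundary. The exponential form and the default decay `d = 1.5 mm`
  are modeling choices — only the qualitative rim shape is established —
  and are recorded in every dataset manifest. Defaults `b = 0.10`,
  `a = 1.25` a.u. give SBR ≈ 5–6, in the range reported for rim dyes in
  liver specimens.
* **filled pattern** (targeted dye): tumor interior set to `t`
  (default 0.15 a.u.) over background `b = 0.05` a.u., TBR ≈ 3.
* **background heterogeneity**: a smooth zero-mean field (sum of four
  fixed-seed random-phase sinusoids, normalized to ±1) scaled to 10 % of
  `b` by default, emulating heterogeneous dye distribution in liver.
* **noise**: additive Gaussian, clipped at zero, applied inside the loaf
  (the field outside the specimen stays exactly zero). The real imager's
  noise model is unpublished, so σ is a free parameter; intensity levels
  are nominal arbitrary units.

The ground truth carries the **analytic ratio**: the noiseless profile
integrated numerically (direct pixel-grid means) over the exact pipeline
regions built from the true masks. On noiseless phantoms the pipelines
recover it to well within 2 % (the residual is pure histogram binning);
with noise, recovery is unbiased within Monte-Carlo error because the
ratio of region means is insensitive to zero-mean noise at these levels.

**Simulated observers** redraw a mask by resampling its boundary contour
to ~64 vertices (96 for the loaf) and displacing each vertex radially from
the mask centroid by `bias_px + N(0, jitter_sd_px)`. Zero jitter and bias
reproduce the mask after rasterization (DSC ≥ 0.99 — the residual is
polygonization of the discrete boundary); a pure bias of +5 px on a disk
of radius 50 px scales the area by ≈ (55/50)². Self-intersecting draws are
retried with fresh noise up to 10 times. Default jitter is 2 px (~0.2 mm),
a plausible tracing error at this resolution; loaf outlines get half the
tumor jitter since the specimen boundary is far easier to follow.

**Evaluation datasets** contain `n_loaves` phantoms × 3 observers × 2
sessions of GeoJSON delineations plus OME-TIFF image pairs, truth files
and a manifest, all derived from one seed (byte-identical on re-runs).
Tumor radius and dye level vary by ±20 % across loaves so the true ratios
differ between subjects — without that variance the reliability analysis
would be degenerate.

## What the phantoms do and do not show

Passing recovery and agreement tests on phantoms demonstrates that the
region algebra, the histogram quantification and the reliability
statistics are implemented correctly and respond monotonically to
delineation error. Phantoms do not model real tissue: no light transport,
no fixation or inking artifacts, no irregular loaf shapes with multiple
fragments, no correlated observer errors (human observers disagree
systematically at ambiguous boundaries, not isotropically), and nominal —
not calibrated — intensity scales. Agreement levels measured on phantoms
therefore characterize the software, not clinical interobserver
variability.

## Numerical choices and edge cases

* Rasterization: pixel-center-in-polygon, even-odd rule, 0-based top-left
  origin, x right / y down; polygons are clipped to the frame and must
  cover at least one pixel center.
* Delineation exchange: GeoJSON polygons in pixel coordinates (the common
  annotation-tool export) or binary mask TIFFs, normalized internally.
* Missing pixel-size metadata falls back to 0.085 mm with a warning; a
  CLI flag overrides.
* Degenerate inputs raise early with parameter-specific messages: empty
  masks, tumor filling the loaf (no signal region), loaves entirely within
  the background margin of the tumor (no background region), incomplete
  observer designs, zero-variance rater matrices.
* Dilation by 0 mm is the identity; DSC of two empty masks is undefined
  and rejected.

## Known limitations

* Strictly 2-D, per-slice analysis; no 3-D dilation across loaves.
* One tumor mask per loaf (union multifocal lesions beforehand).
* The ICC subject-stacking convention above is a declared choice; other
  complete-design stackings would give slightly different interobserver
  intervals.
* The CI-overlap rule is conservative relative to a formal test of ICC
  equality; it is provided because it is the convention this workflow
  reports.
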