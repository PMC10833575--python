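# fluoroquant

Standardized, semi-automatic quantification of fluorescent-dye performance
in resected tumor specimens.

## The problem

In fluorescence-guided surgery, the performance of a dye is summarized by
how brightly it marks tumor tissue relative to surrounding healthy tissue.
Resected specimens are sliced into ~5 mm "bread loaves" and imaged in a
closed-box NIR system (standardized illumination and distance, 85 µm pixel
pitch, 1300 × 964 px frames) that acquires a white-light and a fluorescence
image of each slice. Manually outlining a "signal" and a "background"
region on the fluorescence image is subjective and poorly reproducible;
this package instead derives those regions automatically from two
anatomical outlines drawn on the *white-light* image — the macroscopic
tumor and the complete bread loaf — using morphological dilation in
physical units:

* **Non-targeted dyes** (e.g. ICG, which accumulates in a peritumoral rim):
  signal = mean fluorescence intensity (MFI) in the halo obtained by
  dilating the tumor mask 3 mm and removing the tumor, clipped to the loaf;
  background = MFI of loaf tissue beyond a 5 mm dilation of the tumor.
  The **signal-to-background ratio** is SBR = MFI_signal / MFI_background.
* **Tumor-targeted dyes** (e.g. CEA-targeted conjugates that fill the
  tumor): signal = MFI inside the tumor mask; background = MFI of the 5 mm
  halo around the tumor inside the loaf, giving the
  **tumor-to-background ratio** TBR = MFI_tumor / MFI_background.

MFIs are computed from fixed-width intensity histograms (bin 0.001 a.u.),
and dilation thresholds the exact Euclidean distance transform at the
real-valued radius in pixels, so results are reproducible to the pixel.

The package also ships the evaluation machinery used to compare such
pipelines against conventional manual selection:

* **Dice similarity coefficients** (DSC = 2|A∩B| / (|A|+|B|)) on the fixed
  3-observer × 2-session schedule: 12 interobserver and 3 intraobserver
  comparisons per loaf per ROI kind;
* **Intraclass correlation** of the resulting SBR/TBR values — the
  two-way, absolute-agreement, mean-of-k-raters model ICC(A,k) of McGraw &
  Wong, with F-based 95 % confidence intervals, qualitative ratings
  (poor < 0.5 ≤ moderate ≤ 0.75 < good ≤ 0.9 < excellent) and the
  CI-overlap rule for significant method differences;
* a **synthetic phantom generator** that emulates the imager's output —
  elliptical loaves, rim-shaped or filled fluorescence patterns with known
  analytic ratios, heterogeneous background, noise, and simulated
  observers with controllable delineation jitter — so the whole stack is
  testable without clinical data.

## Worked example

```python
from fluoroquant import PhantomSpec, generate_phantom, compute_sbr

spec = PhantomSpec(width=400, height=300, pattern="rim", noise_sd=0.01, seed=42)
white, fluor, truth = generate_phantom(spec)
result = compute_sbr(fluor, truth.tumor_mask, truth.loaf_mask)
print(f"signal MFI     {result.signal_mfi:.4f} a.u. over {result.signal_area_px} px")
print(f"background MFI {result.background_mfi:.4f} a.u. over {result.background_area_px} px")
print(f"SBR            {result.ratio:.3f}  (ground truth {truth.analytic_ratio:.3f})")
```

prints

```
signal MFI     0.5788 a.u. over 11468 px
background MFI 0.1204 a.u. over 16230 px
SBR            4.809  (ground truth 4.803)
```

i.e. the 3 mm peritumoral halo of this rim phantom is ~4.8× brighter than
loaf tissue beyond the 5 mm margin, and the pipeline recovers the
generator's analytic ratio to ~0.1 %.

The same workflow is available from the shell:

```bash
fluoroquant simulate --out ds --n-loaves 10 --pattern rim --jitter-px 2 --seed 1
fluoroquant analyze ds --pipeline nontargeted --out results_analyze
fluoroquant agreement ds --pipeline nontargeted --out results_agreement
```

`analyze` writes a quantification CSV (one row per loaf × observer ×
session) and per-loaf PNG overlays of the tumor/signal/background regions;
`agreement` writes the DSC schedule and the ICC report with ratings and
confidence intervals (add `--compare-with OTHER_DS` to test two methods
against each other by CI overlap). Every run snapshots its configuration
to `config.json` so it can be repeated exactly.

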