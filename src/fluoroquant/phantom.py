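"""Synthetic bread-loaf phantoms with known ground truth.

No clinical specimens ship with this package, so every downstream module
is exercised on synthetic "bread loaves": an elliptical specimen slice on
a dark field, a circular (optionally lobulated) tumor inside it, and a
fluorescence field that emulates either of two dye classes:

* ``rim`` — a non-targeted dye accumulating in a peritumoral rim (ICG-like):
  intensity ``b`` inside the loaf plus ``a * exp(-dist_mm / d)`` outside
  the tumor, where ``dist_mm`` is the Euclidean distance to the tumor
  boundary and ``d`` the decay length in mm;
* ``filled`` — a tumor-targeted dye (SGM-101-like): background ``b`` in
  the loaf, constant level ``t`` inside the tumor.

Background heterogeneity is a smooth low-frequency field (a fixed-seed sum
of sinusoids) scaled to a fraction of ``b``; measurement noise is additive
Gaussian clipped at zero.  The ground truth carries the analytic SBR/TBR
of the noiseless field, obtained by integrating the generating profile
numerically over the exact pipeline regions.

Observer variability is emulated by resampling the true boundary contour
to a polygon and perturbing each vertex radially (systematic bias plus
Gaussian jitter, in pixels), which mimics a human re-drawing the outline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import measure

from .imaging_io import (
    DEFAULT_FRAME_SHAPE,
    DEFAULT_PIXEL_SIZE_MM,
    DelineationSet,
    FluorescenceImage,
    write_delineations,
    write_image,
)
from .quantification import compute_sbr, compute_tbr
from .roi_masks import (
    HaloParams,
    background_region_nontargeted,
    background_region_targeted,
    signal_region_nontargeted,
)

logger = logging.getLogger(__name__)


@dataclass
class PhantomSpec:
    """Full parameterization of one synthetic specimen slice.

    Geometry is in pixels on a grid of ``height x width`` with physical
    pitch ``pixel_size_mm`` (defaults follow the imager: 1300 x 964 px at
    0.085 mm).  Intensity levels are nominal arbitrary units chosen to
    resemble ex-vivo liver-metastasis imaging: rim phantoms default to
    background 0.10 a.u. with rim amplitude 1.25 a.u. decaying over 1.5 mm
    (SBR around 6); filled phantoms default to tumor 0.15 over background
    0.05 a.u. (TBR around 3).
    """

    width: int = DEFAULT_FRAME_SHAPE[1]
    height: int = DEFAULT_FRAME_SHAPE[0]
    pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM
    loaf_center: tuple[float, float] | None = None  # (x, y) px; default image center
    loaf_axes: tuple[float, float] | None = None  # semi-axes (x, y) px
    tumor_center: tuple[float, float] | None = None  # (x, y) px; default loaf center
    tumor_radius_px: float | None = None
    tumor_lobularity: float = 0.0  # fractional radial modulation of the tumor outline
    pattern: str = "rim"
    background_level: float | None = None  # b, a.u.
    tumor_level: float | None = None  # t, a.u. (filled only)
    rim_amplitude: float | None = None  # a, a.u. (rim only)
    rim_decay_mm: float = 1.5  # d, mm
    heterogeneity_frac: float = 0.10  # amplitude of background field, fraction of b
    noise_sd: float = 0.0  # sigma, a.u.
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in ("rim", "filled"):
            raise ValueError(f"pattern must be 'rim' or 'filled', got {self.pattern!r}")
        if self.loaf_center is None:
            self.loaf_center = (self.width / 2.0, self.height / 2.0)
        if self.loaf_axes is None:
            self.loaf_axes = (0.35 * self.width, 0.33 * self.height)
        if self.tumor_center is None:
            self.tumor_center = self.loaf_center
        if self.tumor_radius_px is None:
            self.tumor_radius_px = 0.35 * min(self.loaf_axes)
        if self.background_level is None:
            self.background_level = 0.10 if self.pattern == "rim" else 0.05
        if self.tumor_level is None:
            self.tumor_level = 0.15
        if self.rim_amplitude is None:
            self.rim_amplitude = 1.25
        for name in ("background_level", "tumor_level", "rim_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.rim_decay_mm > 0:
            raise ValueError("rim_decay_mm must be positive")
        if self.noise_sd < 0 or self.heterogeneity_frac < 0:
            raise ValueError("noise_sd and heterogeneity_frac must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PhantomTruth:
    """Ground truth of a generated phantom: masks and analytic ratio."""

    tumor_mask: np.ndarray
    loaf_mask: np.ndarray
    analytic_ratio: float
    signal_mfi: float
    background_mfi: float
    spec: PhantomSpec


def _tumor_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    cx, cy = spec.tumor_center
    dx = xx - cx
    dy = yy - cy
    r = np.hypot(dx, dy)
    radius = np.full_like(r, float(spec.tumor_radius_px))
    if spec.tumor_lobularity > 0:
        theta = np.arctan2(dy, dx)
        # low-order harmonics give a smooth, blob-like outline
        phases = rng.uniform(0, 2 * np.pi, size=3)
        weights = rng.uniform(0.3, 1.0, size=3)
        weights *= spec.tumor_lobularity / weights.sum()
        mod = sum(w * np.cos(m * theta + p) for m, (w, p) in zip((2, 3, 5), zip(weights, phases)))
        radius = radius * (1.0 + mod)
    return r <= radius


def _heterogeneity_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth zero-mean field in [-1, 1], from a few random-phase sinusoids."""
    if spec.heterogeneity_frac == 0:
        return np.zeros((spec.height, spec.width))
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    u = xx / spec.width
    v = yy / spec.height
    fields = []
    for _ in range(4):
        fx, fy = rng.uniform(0.5, 2.5, size=2)  # cycles across the frame
        px, py = rng.uniform(0, 2 * np.pi, size=2)
        fields.append(np.sin(2 * np.pi * fx * u + px) * np.sin(2 * np.pi * fy * v + py))
    f = np.sum(fields, axis=0)
    return f / np.max(np.abs(f))


def noiseless_fluorescence(
    spec: PhantomSpec,
    tumor: np.ndarray,
    loaf: np.ndarray,
    het: np.ndarray,
) -> np.ndarray:
    """The generating intensity profile before noise, zero outside the loaf."""
    b = spec.background_level
    base = b * (1.0 + spec.heterogeneity_frac * het)
    pixels = np.where(loaf, base, 0.0)
    if spec.pattern == "rim":
        dist_mm = ndimage.distance_transform_edt(~tumor) * spec.pixel_size_mm
        rim = spec.rim_amplitude * np.exp(-dist_mm / spec.rim_decay_mm)
        pixels = np.where(loaf & ~tumor, pixels + rim, pixels)
    else:
        pixels = np.where(tumor, spec.tumor_level, pixels)
    return pixels


def _analytic_ratio(
    spec: PhantomSpec, clean: np.ndarray, tumor: np.ndarray, loaf: np.ndarray
) -> tuple[float, float, float]:
    """Ground-truth ratio: direct means of the noiseless profile over the
    exact pipeline regions (numeric integration on the pixel grid)."""
    params = HaloParams()
    if spec.pattern == "rim":
        sig_region = signal_region_nontargeted(tumor, loaf, params, spec.pixel_size_mm)
        bg_region = background_region_nontargeted(tumor, loaf, params, spec.pixel_size_mm)
    else:
        sig_region = tumor
        bg_region = background_region_targeted(tumor, loaf, params, spec.pixel_size_mm)
    signal = float(clean[sig_region].mean())
    background = float(clean[bg_region].mean())
    return signal / background, signal, background


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[FluorescenceImage, FluorescenceImage, PhantomTruth]:
    """Generate one phantom: (white-light image, fluorescence image, truth).

    Bit-reproducible for a fixed spec (including its seed).  The white
    image is a flat gray loaf on black — enough for the delineation
    simulator, which only needs the loaf silhouette.
    """
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    lcx, lcy = spec.loaf_center
    lax, lay = spec.loaf_axes
    loaf = ((xx - lcx) / lax) ** 2 + ((yy - lcy) / lay) ** 2 <= 1.0
    tumor = _tumor_mask(spec, rng)
    if np.any(tumor & ~loaf):
        raise ValueError("tumor geometry extends outside the loaf")
    if not tumor.any():
        raise ValueError("tumor geometry is empty")

    het = _heterogeneity_field(spec, rng)
    clean = noiseless_fluorescence(spec, tumor, loaf, het)
    ratio, signal, background = _analytic_ratio(spec, clean, tumor, loaf)

    pixels = clean.copy()
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=pixels.shape)
        pixels = np.where(loaf, np.clip(pixels + noise, 0.0, None), pixels)

    white = np.where(loaf, 0.6, 0.0)
    fluor_img = FluorescenceImage(pixels, spec.pixel_size_mm)
    white_img = FluorescenceImage(white, spec.pixel_size_mm)
    truth = PhantomTruth(
        tumor_mask=tumor,
        loaf_mask=loaf,
        analytic_ratio=ratio,
        signal_mfi=signal,
        background_mfi=background,
        spec=spec,
    )
    return white_img, fluor_img, truth


# ---------------------------------------------------------------------------
# Observer simulation
# ---------------------------------------------------------------------------


def _boundary_vertices(mask: np.ndarray, n_vertices: int) -> np.ndarray:
    """Resample the longest 0.5-level contour of a mask to ``n_vertices``
    points, returned as (x, y) pixel coordinates."""
    padded = np.pad(np.asarray(mask, dtype=float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("mask has no boundary contour")
    contour = max(contours, key=len)  # (row, col), closed
    xy = np.stack([contour[:, 1] - 1.0, contour[:, 0] - 1.0], axis=1)
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    targets = np.linspace(0.0, total, n_vertices, endpoint=False)
    resampled = np.stack(
        [np.interp(targets, arclen, xy[:, 0]), np.interp(targets, arclen, xy[:, 1])],
        axis=1,
    )
    return resampled


def simulate_observer(
    truth_mask: np.ndarray,
    jitter_sd_px: float = 0.0,
    bias_px: float = 0.0,
    seed: int | np.random.Generator = 0,
    n_vertices: int = 64,
    max_attempts: int = 10,
) -> Polygon:
    """Simulate a human delineation of a (simply connected) truth mask.

    The boundary contour is resampled to about ``n_vertices`` vertices and
    each vertex is displaced radially from the mask centroid by
    ``bias_px + N(0, jitter_sd_px)`` pixels.  With zero bias and jitter the
    rasterized polygon reproduces the mask (Dice >= 0.99).  Draws that
    self-intersect are retried with fresh noise up to ``max_attempts``
    times before raising.
    """
    if jitter_sd_px < 0:
        raise ValueError("jitter_sd_px must be non-negative")
    mask = np.asarray(truth_mask, dtype=bool)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    verts = _boundary_vertices(mask, n_vertices)
    rr, cc = np.nonzero(mask)
    centroid = np.array([cc.mean(), rr.mean()])
    rel = verts - centroid
    radius = np.linalg.norm(rel, axis=1)
    radius = np.where(radius == 0, 1e-9, radius)
    unit = rel / radius[:, None]
    for _ in range(max_attempts):
        delta = bias_px + rng.normal(0.0, jitter_sd_px, size=len(verts))
        new_r = np.clip(radius + delta, 0.5, None)
        poly = Polygon(centroid + unit * new_r[:, None])
        if poly.is_valid and poly.area > 0:
            return poly
    raise RuntimeError(
        f"could not draw a simple polygon in {max_attempts} attempts "
        f"(jitter_sd_px={jitter_sd_px})"
    )


# ---------------------------------------------------------------------------
# Evaluation dataset
# ---------------------------------------------------------------------------

DEFAULT_OBSERVERS = ("observer1", "observer2", "observer3")
DEFAULT_SESSIONS = ("session1", "session2")


def generate_evaluation_dataset(
    out_dir: str | Path,
    n_loaves: int = 10,
    pattern: str = "rim",
    jitter_sd_px: float | dict[str, float] = 2.0,
    bias_px: float | dict[str, float] = 0.0,
    loaf_jitter_sd_px: float | dict[str, float] | None = None,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
    observers: tuple[str, ...] = DEFAULT_OBSERVERS,
    sessions: tuple[str, ...] = DEFAULT_SESSIONS,
    method: str = "automatic",
) -> Path:
    """Write a reproducible multi-loaf evaluation dataset to disk.

    Emulates the evaluation design: ``n_loaves`` specimen slices, each
    delineated by 3 observers in 2 sessions.  Per-loaf tumor size and dye
    level are varied (about +/-20%) so the true ratios differ across
    loaves, giving the between-subject variance the reliability analysis
    needs.  Observer jitter/bias may be a scalar or a per-observer dict;
    loaf delineations default to half the tumor jitter.

    Layout::

        out_dir/manifest.json
        out_dir/loaf_XX/white.tiff
        out_dir/loaf_XX/fluor.ome.tiff
        out_dir/loaf_XX/truth.json
        out_dir/loaf_XX/delineations/<observer>_<session>.geojson

    Returns the manifest path.
    """
    if n_loaves < 2:
        raise ValueError("need at least 2 loaves for an agreement analysis")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = base_spec or PhantomSpec(pattern=pattern)
    rng = np.random.default_rng(seed)

    def _per_observer(value, obs):
        return value[obs] if isinstance(value, dict) else float(value)

    if loaf_jitter_sd_px is None:
        loaf_jitter_sd_px = (
            {k: v / 2 for k, v in jitter_sd_px.items()}
            if isinstance(jitter_sd_px, dict)
            else jitter_sd_px / 2
        )

    manifest: dict = {
        "pattern": pattern,
        "n_loaves": n_loaves,
        "observers": list(observers),
        "sessions": list(sessions),
        "method": method,
        "seed": seed,
        "base_spec": base.to_dict(),
        "jitter_sd_px": jitter_sd_px,
        "bias_px": bias_px,
        "loaf_jitter_sd_px": loaf_jitter_sd_px,
        "loaves": [],
    }

    for i in range(n_loaves):
        loaf_id = f"loaf_{i:02d}"
        loaf_dir = out_dir / loaf_id
        (loaf_dir / "delineations").mkdir(parents=True, exist_ok=True)
        # per-loaf biological variation: tumor size and dye level
        size_f = float(rng.uniform(0.8, 1.2))
        level_f = float(rng.uniform(0.8, 1.2))
        spec = PhantomSpec(
            width=base.width,
            height=base.height,
            pixel_size_mm=base.pixel_size_mm,
            loaf_center=base.loaf_center,
            loaf_axes=base.loaf_axes,
            tumor_center=base.tumor_center,
            tumor_radius_px=base.tumor_radius_px * size_f,
            tumor_lobularity=base.tumor_lobularity,
            pattern=base.pattern,
            background_level=base.background_level,
            tumor_level=base.tumor_level * level_f,
            rim_amplitude=base.rim_amplitude * level_f,
            rim_decay_mm=base.rim_decay_mm,
            heterogeneity_frac=base.heterogeneity_frac,
            noise_sd=base.noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        white, fluor, truth = generate_phantom(spec)
        write_image(white, loaf_dir / "white.tiff")
        write_image(fluor, loaf_dir / "fluor.ome.tiff", ome=True)
        (loaf_dir / "truth.json").write_text(
            json.dumps(
                {
                    "loaf_id": loaf_id,
                    "analytic_ratio": truth.analytic_ratio,
                    "signal_mfi": truth.signal_mfi,
                    "background_mfi": truth.background_mfi,
                    "spec": spec.to_dict(),
                },
                sort_keys=True,
            )
        )
        for obs in observers:
            for ses in sessions:
                obs_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
                tumor_poly = simulate_observer(
                    truth.tumor_mask,
                    jitter_sd_px=_per_observer(jitter_sd_px, obs),
                    bias_px=_per_observer(bias_px, obs),
                    seed=obs_rng,
                )
                loaf_poly = simulate_observer(
                    truth.loaf_mask,
                    jitter_sd_px=_per_observer(loaf_jitter_sd_px, obs),
                    bias_px=0.0,
                    seed=obs_rng,
                    n_vertices=96,
                )
                dset = DelineationSet(
                    tumor_roi=tumor_poly,
                    loaf_roi=loaf_poly,
                    observer_id=obs,
                    session_id=ses,
                    method=method,
                    loaf_id=loaf_id,
                )
                write_delineations(dset, loaf_dir / "delineations" / f"{obs}_{ses}.geojson")
        manifest["loaves"].append(
            {"loaf_id": loaf_id, "analytic_ratio": truth.analytic_ratio, "spec": spec.to_dict()}
        )

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest_path


def quantify_truth(
    spec: PhantomSpec, bin_width: float = 0.001
):
    """Run the matching pipeline on a phantom with its *true* masks.

    Convenience for recovery checks: returns ``(QuantResult, PhantomTruth)``
    using the non-targeted pipeline for rim phantoms and the targeted
    pipeline for filled phantoms.
    """
    white, fluor, truth = generate_phantom(spec)
    if spec.pattern == "rim":
        qr = compute_sbr(fluor, truth.tumor_mask, truth.loaf_mask, bin_width=bin_width)
    else:
        qr = compute_tbr(fluor, truth.tumor_mask, truth.loaf_mask, bin_width=bin_width)
    return qr, truth
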