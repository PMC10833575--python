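"""Signal and background region construction by physical-unit dilation.

The two quantification pipelines derive their regions from the tumor and
bread-loaf masks by morphological dilation parameterized in millimetres:

* non-targeted dyes (rim-accumulating, e.g. ICG): the *signal* region is
  the halo of the tumor dilated by ``signal_halo_mm`` (default 3 mm) minus
  the tumor, clipped to the loaf; the *background* region is the loaf minus
  the tumor dilated by ``background_margin_mm`` (default 5 mm);
* tumor-targeted dyes (e.g. anti-CEA conjugates): the signal region is the
  tumor itself; the background region is the 5 mm halo around the tumor,
  clipped to the loaf.

Dilation thresholds the exact Euclidean distance transform at the
real-valued radius ``distance_mm / pixel_size_mm`` (``<=`` comparison, no
integer rounding), so it is exact up to pixel-center discretization and
reproducible across implementations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


class EmptyRegionError(ValueError):
    """A derived region contains no pixels."""


@dataclass
class HaloParams:
    """Millimetre-parameterized dilation distances for region construction.

    ``signal_halo_mm`` applies to the non-targeted pipeline only; both
    pipelines use ``background_margin_mm``.  For the non-targeted pipeline
    the signal halo must not exceed the background margin, otherwise signal
    and background regions would overlap.
    """

    signal_halo_mm: float = 3.0
    background_margin_mm: float = 5.0

    def __post_init__(self) -> None:
        if not self.signal_halo_mm > 0:
            raise ValueError("signal_halo_mm must be positive")
        if not self.background_margin_mm > 0:
            raise ValueError("background_margin_mm must be positive")

    def validate_nontargeted(self) -> None:
        if self.signal_halo_mm > self.background_margin_mm:
            raise ValueError(
                "signal_halo_mm must not exceed background_margin_mm "
                f"({self.signal_halo_mm} > {self.background_margin_mm}): "
                "signal and background regions would overlap"
            )


def dilate_mm(mask: np.ndarray, distance_mm: float, pixel_size_mm: float) -> np.ndarray:
    """Dilate a boolean mask by a physical distance.

    Returns ``{p : d_euclid(p, mask) <= distance_mm / pixel_size_mm}`` where
    the distance is measured between pixel centers.  The input is always a
    subset of the output.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyRegionError("cannot dilate empty mask")
    if distance_mm < 0:
        raise ValueError("distance_mm must be non-negative")
    if not pixel_size_mm > 0:
        raise ValueError("pixel_size_mm must be positive")
    if distance_mm == 0:
        return mask.copy()
    radius_px = distance_mm / pixel_size_mm
    dist = ndimage.distance_transform_edt(~mask)
    return dist <= radius_px


def _require_tumor_in_loaf(tumor: np.ndarray, loaf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    tumor = np.asarray(tumor, dtype=bool)
    loaf = np.asarray(loaf, dtype=bool)
    if tumor.shape != loaf.shape:
        raise ValueError(f"tumor shape {tumor.shape} != loaf shape {loaf.shape}")
    if not tumor.any():
        raise EmptyRegionError("tumor mask is empty")
    if np.any(tumor & ~loaf):
        raise ValueError("tumor mask extends outside the loaf mask")
    return tumor, loaf


def signal_region_nontargeted(
    tumor: np.ndarray,
    loaf: np.ndarray,
    params: HaloParams | None = None,
    pixel_size_mm: float = 0.085,
) -> np.ndarray:
    """Peritumoral signal halo for the non-targeted pipeline.

    ``(dilate(tumor, signal_halo_mm) \\ tumor) ∩ loaf`` — the 3 mm rim just
    outside the tumor, restricted to the specimen so that zero-intensity
    pixels outside the loaf never enter the mean.
    """
    params = params or HaloParams()
    params.validate_nontargeted()
    tumor, loaf = _require_tumor_in_loaf(tumor, loaf)
    halo = dilate_mm(tumor, params.signal_halo_mm, pixel_size_mm) & ~tumor & loaf
    if not halo.any():
        raise EmptyRegionError("no signal region: tumor fills the loaf")
    return halo


def background_region_nontargeted(
    tumor: np.ndarray,
    loaf: np.ndarray,
    params: HaloParams | None = None,
    pixel_size_mm: float = 0.085,
) -> np.ndarray:
    """Distant-background region for the non-targeted pipeline.

    ``loaf \\ dilate(tumor, background_margin_mm)`` — specimen tissue more
    than 5 mm (by default) from the tumor.
    """
    params = params or HaloParams()
    tumor, loaf = _require_tumor_in_loaf(tumor, loaf)
    bg = loaf & ~dilate_mm(tumor, params.background_margin_mm, pixel_size_mm)
    if not bg.any():
        raise EmptyRegionError(
            "no background region: the whole loaf lies within "
            f"{params.background_margin_mm} mm of the tumor (background_margin_mm)"
        )
    return bg


def background_region_targeted(
    tumor: np.ndarray,
    loaf: np.ndarray,
    params: HaloParams | None = None,
    pixel_size_mm: float = 0.085,
) -> np.ndarray:
    """Peritumoral background region for the targeted pipeline.

    ``(dilate(tumor, background_margin_mm) \\ tumor) ∩ loaf`` — the 5 mm
    (by default) halo surrounding the tumor, inside the specimen.
    """
    params = params or HaloParams()
    tumor, loaf = _require_tumor_in_loaf(tumor, loaf)
    bg = dilate_mm(tumor, params.background_margin_mm, pixel_size_mm) & ~tumor & loaf
    if not bg.any():
        raise EmptyRegionError("no background region: tumor fills the loaf")
    return bg
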