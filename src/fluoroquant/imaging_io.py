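"""Image and ROI input/output.

Reads paired white-light / near-infrared fluorescence TIFF (or OME-TIFF)
images of specimen slices ("bread loaves"), converts polygon delineations
(GeoJSON, pixel coordinates) or binary mask TIFFs into boolean masks on the
image grid, and writes quantification results to CSV.

Coordinate convention
---------------------
Pixel coordinates are 0-based with the origin at the top-left corner;
``x`` increases to the right (columns) and ``y`` downwards (rows).  The
*center* of pixel ``(row=j, col=i)`` is at ``(x=i, y=j)``.  A pixel belongs
to a rasterized polygon iff its center lies strictly inside the polygon
(even-odd rule).  Dice coefficients between rasterizations depend on this
rule, so it is fixed here and used everywhere.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import Polygon, shape as shapely_shape

logger = logging.getLogger(__name__)

#: Pixel pitch of the closed-box specimen imager (85 um).
DEFAULT_PIXEL_SIZE_MM = 0.085
#: Native frame geometry of the imager (width x height in pixels).
DEFAULT_FRAME_SHAPE = (964, 1300)  # (rows, cols)

#: Columns of the quantification CSV, in output order.
QUANT_CSV_COLUMNS = [
    "loaf_id",
    "lesion_id",
    "observer",
    "session",
    "method",
    "pipeline",
    "signal_mfi",
    "background_mfi",
    "ratio",
    "signal_area_px",
    "background_area_px",
    "signal_halo_mm",
    "background_margin_mm",
]


class UnpairedImagesError(ValueError):
    """White-light and fluorescence frames do not share a pixel grid."""


class EmptyROIError(ValueError):
    """A delineation rasterizes to zero pixels on the image grid."""


@dataclass
class FluorescenceImage:
    """A single 2-D intensity frame in arbitrary units (a.u.).

    Parameters
    ----------
    pixels : ndarray
        2-D array of non-negative, finite intensities.
    pixel_size_mm : float
        Physical edge length of one (square) pixel in millimetres.
    """

    pixels: np.ndarray
    pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite intensities")
        if np.any(self.pixels < 0):
            raise ValueError("image contains negative intensities")
        if not self.pixel_size_mm > 0:
            raise ValueError("pixel_size_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def _pixel_size_from_tiff(tf: tifffile.TiffFile) -> float | None:
    """Try to recover the physical pixel size (mm) from TIFF/OME metadata."""
    try:
        if tf.ome_metadata:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tf.ome_metadata)
            for el in root.iter():
                if el.tag.endswith("Pixels"):
                    size = el.attrib.get("PhysicalSizeX")
                    unit = el.attrib.get("PhysicalSizeXUnit", "µm")
                    if size is not None:
                        value = float(size)
                        scale = {"mm": 1.0, "µm": 1e-3, "um": 1e-3, "nm": 1e-6}.get(unit)
                        if scale is not None:
                            return value * scale
    except Exception:  # malformed metadata: fall through to resolution tags
        pass
    try:
        page = tf.pages[0]
        xres = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if xres is not None and unit is not None:
            num, den = xres.value
            if num and den:
                px_per_unit = num / den
                unit_mm = {2: 25.4, 3: 10.0}.get(int(getattr(unit.value, "value", unit.value)))
                if unit_mm is not None and px_per_unit > 0:
                    return unit_mm / px_per_unit
    except Exception:
        pass
    return None


def read_image(path: str | Path, pixel_size_mm: float | None = None) -> FluorescenceImage:
    """Read one TIFF/OME-TIFF frame.

    ``pixel_size_mm`` overrides metadata; when neither is available the
    imager default of 0.085 mm is used with a warning.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        pixels = tf.asarray()
        meta_size = _pixel_size_from_tiff(tf)
    if pixels.ndim == 3 and pixels.shape[-1] in (3, 4):
        # RGB white-light frame: collapse to luminance for mask work
        pixels = pixels[..., :3].mean(axis=-1)
    if pixel_size_mm is None:
        if meta_size is not None:
            pixel_size_mm = meta_size
        else:
            warnings.warn(
                f"{path.name}: no pixel-size metadata; assuming "
                f"{DEFAULT_PIXEL_SIZE_MM} mm/px",
                stacklevel=2,
            )
            pixel_size_mm = DEFAULT_PIXEL_SIZE_MM
    return FluorescenceImage(np.asarray(pixels, dtype=np.float64), pixel_size_mm)


def read_image_pair(
    white_path: str | Path,
    fluor_path: str | Path,
    pixel_size_mm: float | None = None,
) -> tuple[FluorescenceImage, FluorescenceImage]:
    """Read a sequentially acquired white-light / fluorescence frame pair.

    Both frames must share the same pixel grid; a shape mismatch raises
    :class:`UnpairedImagesError`.
    """
    white = read_image(white_path, pixel_size_mm)
    fluor = read_image(fluor_path, pixel_size_mm)
    if white.shape != fluor.shape:
        raise UnpairedImagesError(
            f"unpaired images: white {white.shape} vs fluorescence {fluor.shape}"
        )
    return white, fluor


def write_image(
    image: FluorescenceImage, path: str | Path, ome: bool | None = None
) -> Path:
    """Write a frame to (OME-)TIFF, embedding the physical pixel size."""
    path = Path(path)
    if ome is None:
        ome = "".join(path.suffixes).lower().endswith(".ome.tiff") or path.name.lower().endswith(
            ".ome.tif"
        )
    um = image.pixel_size_mm * 1000.0
    if ome:
        tifffile.imwrite(
            path,
            image.pixels,
            ome=True,
            metadata={
                "axes": "YX",
                "PhysicalSizeX": um,
                "PhysicalSizeXUnit": "µm",
                "PhysicalSizeY": um,
                "PhysicalSizeYUnit": "µm",
            },
        )
    else:
        # resolution in pixels per cm (ResolutionUnit 3)
        px_per_cm = 10.0 / image.pixel_size_mm
        tifffile.imwrite(path, image.pixels, resolution=(px_per_cm, px_per_cm), resolutionunit=3)
    return path


# ---------------------------------------------------------------------------
# Polygon rasterization
# ---------------------------------------------------------------------------


def _as_polygon(roi) -> Polygon:
    """Normalize supported ROI encodings to a shapely Polygon."""
    if isinstance(roi, Polygon):
        poly = roi
    elif isinstance(roi, Mapping):  # GeoJSON geometry or feature
        geom = roi.get("geometry", roi)
        poly = shapely_shape(geom)
        if not isinstance(poly, Polygon):
            raise ValueError(f"unsupported ROI geometry type {poly.geom_type!r}")
    else:
        coords = np.asarray(roi, dtype=float)
        if coords.ndim != 2 or coords.shape[0] < 3 or coords.shape[1] != 2:
            raise ValueError("polygon must be an (N>=3, 2) array of (x, y) vertices")
        poly = Polygon(coords)
    if not poly.is_valid:
        poly = poly.buffer(0)
    if poly.is_empty or poly.area == 0:
        raise EmptyROIError("empty ROI: polygon has zero area")
    return poly


def rasterize_roi(roi, grid_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed polygon onto an image grid.

    A pixel is set iff its center ``(x=col, y=row)`` lies strictly inside
    the polygon (even-odd rule).  The polygon is clipped to the grid; a
    polygon whose interior covers no pixel center raises
    :class:`EmptyROIError`.

    Parameters
    ----------
    roi
        Shapely Polygon, GeoJSON geometry/feature mapping, or an (N, 2)
        vertex array in pixel coordinates.
    grid_shape
        ``(rows, cols)`` of the target grid.
    """
    poly = _as_polygon(roi)
    rows, cols = grid_shape
    minx, miny, maxx, maxy = poly.bounds
    c0 = max(int(np.floor(minx)), 0)
    c1 = min(int(np.ceil(maxx)) + 1, cols)
    r0 = max(int(np.floor(miny)), 0)
    r1 = min(int(np.ceil(maxy)) + 1, rows)
    mask = np.zeros((rows, cols), dtype=bool)
    if c0 >= c1 or r0 >= r1:
        raise EmptyROIError("empty ROI: polygon lies outside the image")
    xs, ys = np.meshgrid(np.arange(c0, c1, dtype=float), np.arange(r0, r1, dtype=float))
    inside = shapely.contains_xy(poly, xs.ravel(), ys.ravel()).reshape(xs.shape)
    mask[r0:r1, c0:c1] = inside
    if not mask.any():
        raise EmptyROIError("empty ROI: no pixel center falls inside the polygon")
    return mask


def mask_to_polygon(mask: np.ndarray) -> Polygon:
    """Trace the boundary of a mask as a polygon in pixel coordinates.

    For an axis-aligned rectangular mask the result rasterizes back to the
    identical mask (vertices sit half a pixel outside the outermost pixel
    centers).  General masks are approximated by their marching-squares
    contour at the 0.5 level.
    """
    from skimage import measure

    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyROIError("empty ROI: mask has no pixels")
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    contour = max(contours, key=len)
    # (row, col) in padded coords -> (x, y) in image coords
    xy = np.stack([contour[:, 1] - 1.0, contour[:, 0] - 1.0], axis=1)
    poly = Polygon(xy)
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


# ---------------------------------------------------------------------------
# Delineations
# ---------------------------------------------------------------------------


@dataclass
class DelineationSet:
    """One observer/session's tumor and bread-loaf ROIs for one loaf.

    ``tumor_roi`` and ``loaf_roi`` are polygons (any encoding accepted by
    :func:`rasterize_roi`) or boolean masks.  ``rasterize`` enforces the
    pipeline assumption that the tumor lies inside the loaf by intersecting
    the tumor mask with the loaf mask, logging any clipped area.
    """

    tumor_roi: object
    loaf_roi: object
    observer_id: str
    session_id: str
    method: str = "automatic"
    loaf_id: str = ""

    def __post_init__(self) -> None:
        if self.method not in ("automatic", "manual"):
            raise ValueError(f"method must be 'automatic' or 'manual', got {self.method!r}")

    def _roi_mask(self, roi, grid_shape: tuple[int, int]) -> np.ndarray:
        if isinstance(roi, np.ndarray) and roi.dtype == bool:
            if roi.shape != tuple(grid_shape):
                raise ValueError(f"mask shape {roi.shape} does not match grid {grid_shape}")
            if not roi.any():
                raise EmptyROIError("empty ROI: mask has no pixels")
            return roi
        return rasterize_roi(roi, grid_shape)

    def rasterize(self, grid_shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(tumor_mask, loaf_mask)`` with tumor clipped to the loaf."""
        loaf = self._roi_mask(self.loaf_roi, grid_shape)
        tumor = self._roi_mask(self.tumor_roi, grid_shape)
        clipped = tumor & ~loaf
        if clipped.any():
            logger.info(
                "observer=%s session=%s: clipped %d tumor px outside the loaf",
                self.observer_id,
                self.session_id,
                int(clipped.sum()),
            )
            tumor = tumor & loaf
        if not tumor.any():
            raise EmptyROIError("empty ROI: tumor has no pixels inside the loaf")
        return tumor, loaf


def write_delineations(dset: DelineationSet, path: str | Path) -> Path:
    """Write a delineation set as a GeoJSON FeatureCollection (pixel coords)."""
    path = Path(path)
    features = []
    for kind, roi in (("tumor", dset.tumor_roi), ("loaf", dset.loaf_roi)):
        poly = _as_polygon(roi)
        features.append(
            {
                "type": "Feature",
                "geometry": json.loads(shapely.to_geojson(poly)),
                "properties": {
                    "roi": kind,
                    "observer_id": dset.observer_id,
                    "session_id": dset.session_id,
                    "method": dset.method,
                    "loaf_id": dset.loaf_id,
                },
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    path.write_text(json.dumps(doc, sort_keys=True))
    return path


def read_delineations(path: str | Path) -> DelineationSet:
    """Read a delineation set from a GeoJSON FeatureCollection."""
    path = Path(path)
    doc = json.loads(path.read_text())
    rois: dict[str, Polygon] = {}
    props: dict = {}
    for feat in doc.get("features", []):
        kind = feat.get("properties", {}).get("roi")
        if kind in ("tumor", "loaf"):
            rois[kind] = shapely_shape(feat["geometry"])
            props = feat.get("properties", {})
    missing = {"tumor", "loaf"} - set(rois)
    if missing:
        raise ValueError(f"{path.name}: missing ROI feature(s): {sorted(missing)}")
    return DelineationSet(
        tumor_roi=rois["tumor"],
        loaf_roi=rois["loaf"],
        observer_id=str(props.get("observer_id", "")),
        session_id=str(props.get("session_id", "")),
        method=str(props.get("method", "automatic")),
        loaf_id=str(props.get("loaf_id", "")),
    )


# ---------------------------------------------------------------------------
# Quantification CSV
# ---------------------------------------------------------------------------


def write_quantification_csv(records: Iterable[Mapping], path: str | Path) -> Path:
    """Write quantification records to CSV with a fixed column order.

    Each record must provide the keys in :data:`QUANT_CSV_COLUMNS`.  An
    empty record list produces a header-only file with a warning.
    """
    path = Path(path)
    records = list(records)
    if not records:
        warnings.warn(f"{path.name}: writing header-only CSV (no records)", stacklevel=2)
        df = pd.DataFrame(columns=QUANT_CSV_COLUMNS)
    else:
        df = pd.DataFrame.from_records(records)
        missing = set(QUANT_CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"records missing required fields: {sorted(missing)}")
        df = df[QUANT_CSV_COLUMNS]
    df.to_csv(path, index=False)
    return path


def read_quantification_csv(path: str | Path) -> pd.DataFrame:
    """Read a quantification CSV back into a DataFrame."""
    df = pd.read_csv(
        path,
        dtype={c: str for c in ("loaf_id", "lesion_id", "observer", "session", "method", "pipeline")},
    )
    missing = set(QUANT_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
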