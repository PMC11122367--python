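"""Reading en-face OCTA angiograms and building physical-coordinate region masks.

An en-face angiogram is a 2D grayscale projection of an OCTA volume slab
(superficial or deep capillary plexus) over a fovea-centered square scan,
nominally 586 x 585 pixels covering 3 x 3 mm (one pixel ~ 5.13 x 5.13 um).
All downstream quantification works on an 8-bit representation of that image
plus its physical scan geometry.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from PIL import Image
import tifffile

log = logging.getLogger(__name__)

PLEXUS_LABELS = ("SCP", "DCP")
REGIONS = ("foveal", "parafoveal", "whole")

#: default Topcon Quality Index cut-off below which scans are excluded
DEFAULT_MIN_QUALITY = 45


class FormatError(ValueError):
    """Raised for images that are not single-channel 2D rasters."""


class MetadataError(ValueError):
    """Raised when required sidecar metadata is missing or invalid."""


@dataclass(frozen=True)
class EnFaceImage:
    """An 8-bit en-face angiogram plus its physical scan geometry.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (height_px, width_px)
        Intensities in [0, 255].
    extent_mm : (float, float)
        Physical scan size as (height_mm, width_mm); both > 0.
    plexus : str
        ``"SCP"`` or ``"DCP"``.
    quality_score : int or None
        Device quality index in [0, 100]; ``None`` if not reported.
    eye_id, visit : str
        Free-form identifiers used when tabulating output.
    """

    pixels: np.ndarray
    extent_mm: tuple[float, float] = (3.0, 3.0)
    plexus: str = "SCP"
    quality_score: Optional[int] = None
    eye_id: str = ""
    visit: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise FormatError(f"expected a 2D grid, got ndim={px.ndim}")
        if px.dtype != np.uint8:
            if not np.issubdtype(px.dtype, np.integer):
                raise FormatError(
                    "pixels must be 8-bit integers; convert raw data with to_8bit()"
                )
            if px.min() < 0 or px.max() > 255:
                raise FormatError("integer pixels outside [0, 255]; use to_8bit()")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        h_mm, w_mm = self.extent_mm
        if not (h_mm > 0 and w_mm > 0):
            raise MetadataError(f"extent_mm components must be > 0, got {self.extent_mm}")
        if self.plexus not in PLEXUS_LABELS:
            raise MetadataError(f"plexus must be one of {PLEXUS_LABELS}, got {self.plexus!r}")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def pixel_pitch_um(self) -> tuple[float, float]:
        """Per-axis pitch (row_um, col_um). The two axes may differ slightly
        (586 vs 585 px over the same 3 mm), so they are kept separate."""
        return (
            pixel_scale_um(self.extent_mm[0], self.height_px),
            pixel_scale_um(self.extent_mm[1], self.width_px),
        )

    @property
    def pixel_pitch_um_mean(self) -> float:
        """Geometric mean pitch; the single number quoted for the nominal scan."""
        r, c = self.pixel_pitch_um
        return float(np.sqrt(r * c))


@dataclass(frozen=True)
class RegionSpec:
    """ETDRS-style circular region around the fovea center.

    ``foveal`` is a central disc of ``inner_diameter_mm``; ``parafoveal`` is
    the annulus between the inner and outer diameters; ``whole`` is the full
    scan.  ``center_px`` is the fovea center in 0-based (row, col) pixel
    coordinates; ``None`` means the image center (scans are fovea-centered).
    """

    region: str
    center_px: Optional[tuple[float, float]] = None
    inner_diameter_mm: float = 1.0
    outer_diameter_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}, got {self.region!r}")
        if not self.inner_diameter_mm < self.outer_diameter_mm:
            raise ValueError("inner diameter must be smaller than outer diameter")


@dataclass(frozen=True)
class RoiMask:
    """Boolean region-of-interest mask congruent with its parent image."""

    mask: np.ndarray
    region: str


def to_8bit(raw_grid: np.ndarray) -> np.ndarray:
    """Linearly rescale a raw intensity grid to 8 bits.

    Min-max rescale to [0, 255], rounded to nearest integer.  A constant
    input (no dynamic range) maps to all zeros.  Raises ``ValueError`` on
    NaN or negative intensities.
    """
    raw = np.asarray(raw_grid, dtype=np.float64)
    if raw.ndim != 2:
        raise FormatError(f"expected a 2D grid, got ndim={raw.ndim}")
    if not np.isfinite(raw).all():
        raise ValueError("raw intensities contain NaN or infinity")
    if (raw < 0).any():
        raise ValueError("raw intensities must be non-negative")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros(raw.shape, dtype=np.uint8)
    # half-up rounding (floor(x + 0.5)), so 127.5 -> 128; multiply before
    # dividing so exact midpoints stay exact in floating point
    scaled = np.floor((raw - lo) * 255.0 / (hi - lo) + 0.5)
    return scaled.astype(np.uint8)


def pixel_scale_um(extent_mm: float, n_pixels: int) -> float:
    """Physical pixel pitch in micrometres for one axis.

    ``1000 * extent_mm / n_pixels``; e.g. a 3 mm axis sampled at 585 px
    gives 5.13 um per pixel.
    """
    if n_pixels < 1:
        raise ValueError(f"n_pixels must be >= 1, got {n_pixels}")
    if not extent_mm > 0:
        raise ValueError(f"extent_mm must be > 0, got {extent_mm}")
    return 1000.0 * float(extent_mm) / float(n_pixels)


def load_enface(image_path: str | Path, metadata: Mapping | str | Path) -> EnFaceImage:
    """Load a single-channel 8-bit PNG/TIFF en-face image with its metadata.

    ``metadata`` is a mapping, a JSON sidecar path, or a CSV manifest path
    (columns eye_id, visit, plexus, extent_mm_h, extent_mm_w, quality_score;
    an optional ``image`` column selects the row matching the image file
    name, otherwise the first row is used).  It must supply
    ``extent_mm_h``/``extent_mm_w`` (or ``extent_mm`` as a 2-list) and
    ``plexus``; ``quality_score``, ``eye_id`` and ``visit`` are optional.
    Pixels are taken as stored — no rescaling of already-8-bit data.  Higher
    bit depths are rejected with a pointer to :func:`to_8bit`.
    """
    image_path = Path(image_path)
    if isinstance(metadata, (str, Path)):
        meta_path = Path(metadata)
        if meta_path.suffix.lower() == ".csv":
            import pandas as pd

            manifest = pd.read_csv(meta_path)
            if "image" in manifest.columns:
                rows = manifest[manifest["image"] == image_path.name]
                if rows.empty:
                    raise MetadataError(f"no manifest row for {image_path.name}")
                metadata = rows.iloc[0].to_dict()
            else:
                metadata = manifest.iloc[0].to_dict()
            metadata = {k: (None if pd.isna(v) else v) for k, v in metadata.items()}
        else:
            with open(meta_path) as fh:
                metadata = json.load(fh)

    suffix = image_path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(image_path)
    else:
        arr = np.asarray(Image.open(image_path))
    if arr.ndim == 3:
        raise FormatError(
            f"{image_path.name}: multi-channel image; en-face angiograms are single-channel"
        )
    if arr.ndim != 2:
        raise FormatError(f"{image_path.name}: expected 2D raster, got ndim={arr.ndim}")
    if arr.dtype != np.uint8:
        raise FormatError(
            f"{image_path.name}: {arr.dtype} data; convert to 8 bits with to_8bit() first"
        )

    if "extent_mm" in metadata:
        extent = tuple(float(v) for v in metadata["extent_mm"])
    elif "extent_mm_h" in metadata and "extent_mm_w" in metadata:
        extent = (float(metadata["extent_mm_h"]), float(metadata["extent_mm_w"]))
    else:
        raise MetadataError("metadata must supply extent_mm (or extent_mm_h/extent_mm_w)")
    if "plexus" not in metadata:
        raise MetadataError("metadata must supply plexus (SCP or DCP)")

    q = metadata.get("quality_score")
    return EnFaceImage(
        pixels=arr,
        extent_mm=extent,
        plexus=str(metadata["plexus"]),
        quality_score=None if q is None else int(q),
        eye_id=str(metadata.get("eye_id", "")),
        visit=str(metadata.get("visit", "")),
    )


def make_region_mask(image: EnFaceImage, region_spec: RegionSpec) -> RoiMask:
    """Build a boolean ROI mask for a circular/annular region in mm units.

    Distances are measured from pixel centers using the per-axis pitch, so
    the foveal disc is truly circular in physical coordinates even when the
    pixel grid is slightly anisotropic.  foveal: distance <= inner radius;
    parafoveal: inner < distance <= outer; whole: all pixels.
    """
    h, w = image.pixels.shape
    if region_spec.region == "whole":
        return RoiMask(mask=np.ones((h, w), dtype=bool), region="whole")

    center = region_spec.center_px
    if center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
    cr, cc = center
    if not (0 <= cr < h and 0 <= cc < w):
        raise ValueError(f"center_px {center} lies outside the image")

    pitch_r_mm = image.extent_mm[0] / h
    pitch_c_mm = image.extent_mm[1] / w
    rows = (np.arange(h)[:, None] - cr) * pitch_r_mm
    cols = (np.arange(w)[None, :] - cc) * pitch_c_mm
    dist_mm = np.hypot(rows, cols)

    r_in = region_spec.inner_diameter_mm / 2.0
    r_out = region_spec.outer_diameter_mm / 2.0
    # warn if the outer circle spills past the scan; the mask is clipped
    max_extent = min(cr * pitch_r_mm, (h - 1 - cr) * pitch_r_mm,
                     cc * pitch_c_mm, (w - 1 - cc) * pitch_c_mm)
    if region_spec.region == "parafoveal" and r_out > max_extent + max(pitch_r_mm, pitch_c_mm):
        log.warning(
            "outer circle (r=%.2f mm) exceeds image bounds (%.2f mm); mask clipped",
            r_out, max_extent,
        )

    if region_spec.region == "foveal":
        mask = dist_mm <= r_in
    else:
        mask = (dist_mm > r_in) & (dist_mm <= r_out)
    return RoiMask(mask=mask, region=region_spec.region)


def quality_filter(records: Iterable, min_quality: int = DEFAULT_MIN_QUALITY) -> list:
    """Drop records whose device quality index falls below ``min_quality``.

    Each record must expose ``quality_score`` (attribute or mapping key);
    an absent score excludes the record, with the reason logged.  Returns
    the retained records in input order.
    """
    retained = []
    for rec in records:
        if isinstance(rec, Mapping):
            score = rec.get("quality_score")
            ident = rec.get("eye_id", "?")
        else:
            score = getattr(rec, "quality_score", None)
            ident = getattr(rec, "eye_id", "?")
        if score is None:
            log.info("excluding record %s: missing quality score", ident)
            continue
        if score < min_quality:
            log.info("excluding record %s: quality %s < %s", ident, score, min_quality)
            continue
        retained.append(rec)
    return retained
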