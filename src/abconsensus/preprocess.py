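"""Tile-level preprocessing: color normalization, tiling, candidate detection.

The pipeline mirrors standard immunohistochemistry patch extraction:

1. color-normalize the slide raster to a reference (Reinhard statistics
   transfer in the Ruderman lαβ opponent space),
2. tile it into non-overlapping 1536×1536 tiles,
3. detect candidate deposits per tile with a stain-specific HSV range filter,
   mask smoothing and connected components,
4. center-crop a 256×256 patch around each candidate centroid.

HSV uses the 8-bit OpenCV convention (H on 0–179, S and V on 0–255), which is
the scale the stain ranges are defined on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color as skcolor

from .data_model import BoundingBox, logger

TILE_SIZE = 1536
CROP_SIZE = 256

# stain-specific HSV detection ranges: (h_lo, h_hi), (s_lo, s_hi), (v_lo, v_hi)
STAIN_HSV_RANGES = {
    "4G8": ((0, 40), (10, 255), (0, 220)),
    "6E10": ((0, 40), (10, 255), (0, 220)),
    "NAB228": ((0, 100), (1, 255), (0, 250)),
}


@dataclass(frozen=True)
class HsvRange:
    """Inclusive HSV bounds on the 8-bit scale (H 0–179, S/V 0–255)."""

    h_lo: int
    h_hi: int
    s_lo: int
    s_hi: int
    v_lo: int
    v_hi: int

    def __post_init__(self):
        for lo, hi in ((self.h_lo, self.h_hi), (self.s_lo, self.s_hi), (self.v_lo, self.v_hi)):
            if lo > hi:
                raise ValueError(f"HSV bound lo={lo} > hi={hi}")

    @classmethod
    def for_stain(cls, stain: str) -> "HsvRange":
        (h0, h1), (s0, s1), (v0, v1) = STAIN_HSV_RANGES[stain]
        return cls(h0, h1, s0, s1, v0, v1)

    def mask(self, rgb: np.ndarray) -> np.ndarray:
        """Boolean in-range mask for an 8-bit RGB image."""
        hsv = skcolor.rgb2hsv(rgb.astype(np.float64) / 255.0)
        h = hsv[..., 0] * 180.0  # half-degree OpenCV scale
        s = hsv[..., 1] * 255.0
        v = hsv[..., 2] * 255.0
        return (
            (h >= self.h_lo) & (h <= self.h_hi)
            & (s >= self.s_lo) & (s <= self.s_hi)
            & (v >= self.v_lo) & (v <= self.v_hi)
        )


@dataclass
class Tile:
    """One grid-aligned square tile of a larger slide raster."""

    pixels: np.ndarray  # uint8, (size, size, 3)
    tile_origin: tuple[int, int] = (0, 0)  # (x, y) in the source-image frame
    stain: str = "4G8"
    wsi_id: str = ""
    size: int = TILE_SIZE

    def __post_init__(self):
        h, w = self.pixels.shape[:2]
        if h != self.size or w != self.size or self.pixels.shape[2] != 3:
            raise ValueError(
                f"tile must be {self.size}x{self.size}x3, got {self.pixels.shape}"
            )

    @property
    def tile_id(self) -> str:
        return f"{self.wsi_id}_t{self.tile_origin[0]}_{self.tile_origin[1]}"


@dataclass
class PlaqueCandidate:
    """A detected blob (candidate deposit) inside one tile."""

    centroid: tuple[float, float]  # (x, y), tile frame
    blob_box: BoundingBox
    source_tile: Tile | None = None
    area: int = 0


# ---------------------------------------------------------------------------
# Reinhard statistics transfer
# ---------------------------------------------------------------------------

# Ruderman opponent-space matrices (RGB -> LMS, log-LMS -> lαβ)
_RGB2LMS = np.array(
    [[0.3811, 0.5783, 0.0402],
     [0.1967, 0.7244, 0.0782],
     [0.0241, 0.1288, 0.8444]]
)
_LOGLMS2LAB = (
    np.diag([1 / np.sqrt(3), 1 / np.sqrt(6), 1 / np.sqrt(2)])
    @ np.array([[1, 1, 1], [1, 1, -2], [1, -1, 0]], dtype=float)
)
_LAB2LOGLMS = np.linalg.inv(_LOGLMS2LAB)
_LMS2RGB = np.linalg.inv(_RGB2LMS)
_EPS = 1e-6


def rgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    """8-bit RGB -> Ruderman lαβ (float), pixelwise."""
    flat = rgb.reshape(-1, 3).astype(np.float64) / 255.0
    lms = np.clip(flat @ _RGB2LMS.T, _EPS, None)
    lab = np.log10(lms) @ _LOGLMS2LAB.T
    return lab.reshape(rgb.shape)


def lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    """Ruderman lαβ -> 8-bit RGB, inverse of :func:`rgb_to_lab`."""
    flat = lab.reshape(-1, 3)
    lms = np.power(10.0, flat @ _LAB2LOGLMS.T)
    rgb = np.clip(lms @ _LMS2RGB.T, 0.0, 1.0)
    return np.round(rgb.reshape(lab.shape) * 255.0).astype(np.uint8)


def lab_stats(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel (mean, std) of an 8-bit RGB image in lαβ space."""
    lab = rgb_to_lab(image).reshape(-1, 3)
    return lab.mean(axis=0), lab.std(axis=0)


def reinhard_normalize(
    image: np.ndarray,
    reference_stats: tuple[np.ndarray, np.ndarray],
) -> np.ndarray:
    """Match an image's lαβ channel statistics to reference (mean, std).

    Channels with (near-)zero standard deviation are shifted but not scaled
    (scale guard of 1), so constant images map to the reference mean.
    """
    ref_mean, ref_std = (np.asarray(a, dtype=float) for a in reference_stats)
    lab = rgb_to_lab(image)
    mean = lab.reshape(-1, 3).mean(axis=0)
    std = lab.reshape(-1, 3).std(axis=0)
    scale = np.where(
        (std > 1e-8) & (ref_std > 1e-8), ref_std / np.maximum(std, 1e-8), 1.0
    )
    out = (lab - mean) * scale + ref_mean
    return lab_to_rgb(out)


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------


def tile_image(
    image: np.ndarray, stain: str = "4G8", wsi_id: str = "", size: int = TILE_SIZE
) -> list[Tile]:
    """Uniformly tile an RGB raster into non-overlapping ``size``² tiles.

    The grid is anchored at the origin; remainder rows/columns that do not
    fill a whole tile are discarded.
    """
    h, w = image.shape[:2]
    tiles = []
    for ty in range(h // size):
        for tx in range(w // size):
            y0, x0 = ty * size, tx * size
            tiles.append(
                Tile(
                    pixels=np.ascontiguousarray(image[y0 : y0 + size, x0 : x0 + size]),
                    tile_origin=(x0, y0),
                    stain=stain,
                    wsi_id=wsi_id,
                    size=size,
                )
            )
    return tiles


# ---------------------------------------------------------------------------
# candidate detection
# ---------------------------------------------------------------------------


def smooth_mask(mask: np.ndarray, sigma: float = 2.0, truncate_kernel: int = 9) -> np.ndarray:
    """Gaussian-smooth a binary mask and re-threshold at 0.5 (speck removal)."""
    radius = truncate_kernel // 2
    sm = ndimage.gaussian_filter(
        mask.astype(np.float32), sigma=sigma, truncate=radius / sigma
    )
    return sm >= 0.5


def detect_candidates(
    tile: Tile,
    hsv_range: HsvRange | None = None,
    min_area: int = 100,
    sigma: float = 2.0,
) -> list[PlaqueCandidate]:
    """Detect candidate deposits in a tile by HSV filtering.

    The in-range mask is smoothed, connected components below ``min_area``
    pixels are discarded, and one candidate per surviving component is
    returned with its center of mass and tight bounding box.  Ordering is
    deterministic: row-major by centroid (y, then x).
    """
    if hsv_range is None:
        hsv_range = HsvRange.for_stain(tile.stain)
    mask = smooth_mask(hsv_range.mask(tile.pixels), sigma=sigma)
    labeled, n = ndimage.label(mask)
    if n == 0:
        return []
    candidates = []
    slices = ndimage.find_objects(labeled)
    for idx, sl in enumerate(slices, start=1):
        component = labeled[sl] == idx
        area = int(component.sum())
        if area < min_area:
            continue
        cy, cx = ndimage.center_of_mass(component)
        y_off, x_off = sl[0].start, sl[1].start
        box = BoundingBox(x_off, y_off, sl[1].stop, sl[0].stop)
        candidates.append(
            PlaqueCandidate(
                centroid=(cx + x_off, cy + y_off),
                blob_box=box,
                source_tile=tile,
                area=area,
            )
        )
    candidates.sort(key=lambda c: (c.centroid[1], c.centroid[0]))
    logger.debug("tile %s: %d candidates", tile.tile_id, len(candidates))
    return candidates


def crop_window(
    centroid: tuple[float, float], tile_size: int, crop_size: int = CROP_SIZE
) -> tuple[int, int, int, int]:
    """Half-open (x0, x1, y0, y1) crop window centered on a candidate.

    Windows that would fall off the tile edge are slid inward so the output
    is always exactly ``crop_size`` square.
    """
    half = crop_size // 2
    cx, cy = int(round(centroid[0])), int(round(centroid[1]))
    x0 = min(max(cx - half, 0), tile_size - crop_size)
    y0 = min(max(cy - half, 0), tile_size - crop_size)
    return x0, x0 + crop_size, y0, y0 + crop_size


def center_crop(
    tile: Tile, candidate: PlaqueCandidate, crop_size: int = CROP_SIZE
) -> np.ndarray:
    """Extract the ``crop_size``² RGB patch centered on a candidate."""
    x0, x1, y0, y1 = crop_window(candidate.centroid, tile.size, crop_size)
    return np.ascontiguousarray(tile.pixels[y0:y1, x0:x1])
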