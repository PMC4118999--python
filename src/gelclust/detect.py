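"""Spot detection on grayscale 2DE gel images.

Blob detection by scale-normalized Laplacian of Gaussian: the image is
polarity-corrected so spots are bright, filtered with ``sigma**2 *
gaussian_laplace`` over a geometric ladder of scales, and local maxima of
the 3-D (scale, y, x) response stack above a relative threshold become
spots.  Overlaps are suppressed greedily by descending response.  A spot's
intensity is the plain sum of polarity-corrected pixel values over its
region — a disk of radius sqrt(2)*sigma, the zero-crossing radius of the
LoG kernel at the detected scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "GelImage",
    "Spot",
    "SpotList",
    "detect_spots",
    "measure_spot_intensity",
    "normalize_intensities",
    "disk_region",
]

_POLARITIES = ("dark-on-light", "light-on-dark")


@dataclass
class GelImage:
    """A grayscale gel scan plus acquisition metadata.

    ``stain_polarity`` records whether spots are darker than the
    background (silver stain on a densitometer scan, the default) or
    brighter; polarity correction for detection and intensity measurement
    inverts dark-on-light images around their observed maximum.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    sample_id: str = ""
    replicate_id: str = ""
    stain_polarity: str = "dark-on-light"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("gel image must be a 2-D grayscale array")
        if min(self.pixels.shape) < 32:
            raise ValueError("gel image must be at least 32x32 pixels")
        if np.any(self.pixels < 0):
            raise ValueError("gel image intensities must be nonnegative")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.stain_polarity not in _POLARITIES:
            raise ValueError(f"stain_polarity must be one of {_POLARITIES}")

    def corrected(self) -> np.ndarray:
        """Pixels with spots bright and the background anchored at zero.

        Dark-on-light images are inverted around the observed maximum
        (``max - pixel``); light-on-dark images have the observed
        minimum subtracted.  Anchoring both polarities at the observed
        baseline makes inversion an exact involution and keeps raw
        intensities equivariant under rescaling.
        """
        if self.stain_polarity == "dark-on-light":
            return self.pixels.max() - self.pixels
        return self.pixels - self.pixels.min()


@dataclass
class Spot:
    spot_id: int
    x: float  # column, 0-based pixel center
    y: float  # row, 0-based pixel center
    sigma: float  # detection scale in pixels
    region: np.ndarray  # (n, 2) array of (row, col) pixel coordinates
    raw_intensity: float
    normalized_intensity: float | None = None


@dataclass
class SpotList:
    gel_id: str
    spots: list[Spot] = field(default_factory=list)
    detection_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.spot_id for s in self.spots]
        if len(ids) != len(set(ids)):
            raise ValueError("spot_ids must be unique within a SpotList")

    def __len__(self) -> int:
        return len(self.spots)

    def ids(self) -> list[int]:
        return [s.spot_id for s in self.spots]

    def coords(self) -> np.ndarray:
        """(n, 2) array of x, y centers."""
        if not self.spots:
            return np.empty((0, 2))
        return np.array([[s.x, s.y] for s in self.spots])


def disk_region(
    x: float, y: float, radius: float, shape: tuple[int, int]
) -> np.ndarray:
    """Pixel coordinates (row, col) of a disk clipped to image bounds."""
    h, w = shape
    r = int(np.ceil(radius))
    r0 = max(int(np.floor(y)) - r, 0)
    r1 = min(int(np.ceil(y)) + r, h - 1)
    c0 = max(int(np.floor(x)) - r, 0)
    c1 = min(int(np.ceil(x)) + r, w - 1)
    rows, cols = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    inside = (rows - y) ** 2 + (cols - x) ** 2 <= radius**2
    return np.column_stack([rows[inside], cols[inside]])


def detect_spots(
    image: GelImage,
    sigma_min: float = 2.0,
    sigma_max: float = 10.0,
    n_scales: int = 8,
    threshold_rel: float = 0.1,
) -> SpotList:
    """Detect spots as scale-space maxima of the LoG response.

    A candidate is a strict local maximum of the (scale, y, x) response
    stack whose value exceeds ``threshold_rel`` times the global maximum
    response.  Candidates are accepted greedily by descending response;
    a candidate whose center falls within ``sqrt(2) * sigma`` of an
    already accepted spot is discarded.  Deterministic for fixed inputs.
    """
    if not sigma_min < sigma_max:
        raise ValueError("require sigma_min < sigma_max")
    if not 0.0 < threshold_rel < 1.0:
        raise ValueError("threshold_rel must be in (0, 1)")
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")
    support = int(np.ceil(8 * sigma_max)) + 1
    if min(image.pixels.shape) < support:
        raise ValueError(
            f"image smaller than the largest filter support ({support} px)"
        )
    img = image.corrected()
    sigmas = np.geomspace(sigma_min, sigma_max, n_scales)
    stack = np.stack(
        [-(s**2) * ndi.gaussian_laplace(img, s, mode="reflect") for s in sigmas]
    )
    global_max = stack.max()
    params = {
        "sigma_min": sigma_min,
        "sigma_max": sigma_max,
        "n_scales": n_scales,
        "threshold_rel": threshold_rel,
    }
    # guard against the numerical noise floor of the separable filter:
    # a (near-)constant image must yield no spots
    scale = float(img.max() - img.min())
    if scale == 0 or global_max <= 1e-9 * scale:
        return SpotList(gel_id=image.sample_id, spots=[], detection_params=params)
    thr = threshold_rel * global_max
    # local maxima over the 3x3x3 (scale, y, x) neighborhood
    footprint = np.ones((3, 3, 3) if n_scales > 1 else (1, 3, 3), dtype=bool)
    maxed = ndi.maximum_filter(stack, footprint=footprint, mode="nearest")
    peaks = (stack == maxed) & (stack > thr)
    sidx, rows, cols = np.nonzero(peaks)
    responses = stack[sidx, rows, cols]
    # descending response; ties broken by ascending (row, col, scale)
    order = np.lexsort((sidx, cols, rows, -responses))
    accepted: list[tuple[float, float, float, float]] = []  # x, y, sigma, resp
    for k in order:
        x, y, s = float(cols[k]), float(rows[k]), float(sigmas[sidx[k]])
        too_close = any(
            (x - ax) ** 2 + (y - ay) ** 2 <= 2 * asig**2 for ax, ay, asig, _ in accepted
        )
        if too_close:
            continue
        accepted.append((x, y, s, float(responses[k])))
    spots = []
    for i, (x, y, s, _resp) in enumerate(accepted):
        region = disk_region(x, y, np.sqrt(2) * s, img.shape)
        raw = float(img[region[:, 0], region[:, 1]].sum())
        if raw <= 0:
            continue
        spots.append(
            Spot(spot_id=i, x=x, y=y, sigma=s, region=region, raw_intensity=raw)
        )
    return SpotList(gel_id=image.sample_id, spots=spots, detection_params=params)


def measure_spot_intensity(image: GelImage, spot: Spot) -> float:
    """Sum of polarity-corrected pixel values over the spot region."""
    region = np.asarray(spot.region)
    if region.size == 0:
        raise ValueError("spot region is empty")
    h, w = image.pixels.shape
    if (
        region[:, 0].min() < 0
        or region[:, 1].min() < 0
        or region[:, 0].max() >= h
        or region[:, 1].max() >= w
    ):
        raise ValueError("spot region extends outside the image")
    img = image.corrected()
    return float(img[region[:, 0], region[:, 1]].sum())


def normalize_intensities(spots: SpotList, matched_ids: set[int]) -> SpotList:
    """Fill normalized intensities: each matched spot's raw intensity
    divided by the total raw intensity of matched spots on this gel.

    Unmatched spots keep ``normalized_intensity = None``.
    """
    matched_ids = set(matched_ids)
    if not matched_ids:
        raise ValueError("matched_ids is empty")
    present = set(spots.ids())
    missing = matched_ids - present
    if missing:
        raise ValueError(f"matched ids not in spot list: {sorted(missing)}")
    total = sum(s.raw_intensity for s in spots.spots if s.spot_id in matched_ids)
    if total <= 0:
        raise ValueError("total intensity over matched spots is zero")
    new_spots = []
    for s in spots.spots:
        norm = s.raw_intensity / total if s.spot_id in matched_ids else None
        new_spots.append(
            Spot(
                spot_id=s.spot_id,
                x=s.x,
                y=s.y,
                sigma=s.sigma,
                region=s.region,
                raw_intensity=s.raw_intensity,
                normalized_intensity=norm,
            )
        )
    return SpotList(
        gel_id=spots.gel_id, spots=new_spots, detection_params=dict(spots.detection_params)
    )
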