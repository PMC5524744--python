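"""Leaf segmentation: band-ratio image, binarization/cleaning, region
growing and ROI extraction.

The chain isolates each leaf lying on the dark scan stage:

1. divide two band images (default NIR 800 nm over red 680 nm — vegetation
   is bright in the NIR and dark in the red, the background is spectrally
   flat so its ratio is ~1);
2. rescale the float ratio to 8-bit gray, threshold (Otsu by default),
   then a morphological opening with a horizontal 1 x k line element to cut
   thin bridges and specks;
3. drop connected components above an area ceiling (calibration panels,
   stage edges) and below an area floor (noise);
4. grow each surviving component on the ratio image, accepting 4-connected
   neighbors within a tolerance of the region's running mean, and emit one
   labeled, cropped ROI per leaf ordered by image position.

All steps are deterministic given the parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import opening

from hyperleaf.cube import HyperCube

log = logging.getLogger(__name__)

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class SegmentationParams:
    numerator_nm: float = 800.0
    denominator_nm: float = 680.0
    threshold_mode: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: float | None = None  # on the 8-bit gray scale
    opening_length: int = 5  # horizontal line element, pixels
    area_floor: int = 64  # components smaller than this are noise
    area_ceiling_frac: float = 0.30  # of total image area
    grow_tolerance: float = 0.2  # on the ratio scale
    #: display range of the float->8-bit conversion. The ratio image is
    #: clipped here before rescaling: a flat background sits at ratio ~1
    #: while vegetation NIR/red ratios exceed 2 and saturate, so the gray
    #: histogram is cleanly bimodal regardless of pigment level.
    gray_range: tuple[float, float] = (0.0, 2.0)

    def validate(self) -> None:
        if self.opening_length < 1:
            raise ValueError("opening length must be >= 1")
        if self.gray_range[1] <= self.gray_range[0]:
            raise ValueError("gray range must be increasing")
        if not 0 < self.area_ceiling_frac <= 1:
            raise ValueError("area ceiling fraction must be in (0, 1]")
        if self.threshold_mode not in ("otsu", "fixed"):
            raise ValueError("threshold mode must be 'otsu' or 'fixed'")
        if self.threshold_mode == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold mode requires a value")
        if self.grow_tolerance < 0:
            raise ValueError("region-growing tolerance must be nonnegative")


@dataclass
class LeafROI:
    """One segmented leaf: label, full-frame mask, bounding box, area."""

    label: int
    mask: np.ndarray  # boolean, full (columns, frames) raster
    bbox: tuple[int, int, int, int]  # (col, frame, width, height)
    area: int

    def crop(self, raster: np.ndarray) -> np.ndarray:
        c, f, w, h = self.bbox
        return raster[c : c + w, f : f + h]


def ratio_image(
    cube: HyperCube, params: SegmentationParams | None = None, eps: float = 1e-6
) -> np.ndarray:
    """Element-wise numerator-band / denominator-band image.

    Division is guarded (denominator floored at ``eps``) so the output is
    always finite. If a requested wavelength is farther from the nearest
    band center than one band spacing, the substitution is logged.
    """
    params = params or SegmentationParams()
    if cube.state != "reflectance":
        raise ValueError("ratio image requires a reflectance-calibrated cube")
    grid = cube.grid
    spacing = float(np.median(np.diff(grid.centers))) if grid.n_bands > 1 else np.inf
    for wl in (params.numerator_nm, params.denominator_nm):
        resolved = grid.centers[grid.nearest(wl)]
        if abs(resolved - wl) > spacing:
            log.warning("band %.1f nm not on grid; using nearest center %.1f nm", wl, resolved)
    num = cube.band(params.numerator_nm).astype(float)
    den = cube.band(params.denominator_nm).astype(float)
    return num / np.maximum(den, eps)


def binarize_and_clean(ratio: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Threshold the ratio image and clean it morphologically.

    8-bit linear rescale over the configured display range (values outside
    saturate) -> threshold (Otsu default; or a fixed gray level) -> opening
    with a horizontal 1 x k line element -> removal of connected components
    above the area ceiling or below the area floor. An all-background
    result is legal and yields an empty mask.
    """
    params = params or SegmentationParams()
    params.validate()
    ratio = np.asarray(ratio, dtype=float)
    if not np.all(np.isfinite(ratio)):
        raise ValueError("ratio image must be finite")
    lo, hi = params.gray_range
    gray = np.round((np.clip(ratio, lo, hi) - lo) / (hi - lo) * 255.0).astype(np.uint8)
    if gray.max() == gray.min():
        return np.zeros(ratio.shape, dtype=bool)
    if params.threshold_mode == "otsu":
        thr = threshold_otsu(gray)
    else:
        thr = params.fixed_threshold
    mask = gray > thr
    # horizontal = column axis (axis 0 of the (columns, frames) raster)
    mask = opening(mask, footprint=np.ones((params.opening_length, 1), dtype=bool))

    labels, n = ndi.label(mask, structure=_STRUCT4)
    if n == 0:
        return mask
    areas = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
    ceiling = params.area_ceiling_frac * mask.size
    keep = (areas >= params.area_floor) & (areas <= ceiling)
    return keep[labels - 1] & (labels > 0)


def _grow_region(
    seed: np.ndarray, ratio: np.ndarray, tolerance: float, max_iter: int = 10_000
) -> np.ndarray:
    """Grow a seed mask on the ratio image.

    4-connected neighbors are accepted while they lie within ``tolerance``
    of the region's running mean (recomputed after each accretion sweep).
    """
    region = seed.copy()
    if tolerance <= 0:
        return region
    for _ in range(max_iter):
        mean = ratio[region].mean()
        frontier = ndi.binary_dilation(region, structure=_STRUCT4) & ~region
        accept = frontier & (np.abs(ratio - mean) <= tolerance)
        if not accept.any():
            break
        region |= accept
    return region


def extract_rois(
    cube: HyperCube,
    cleaned_mask: np.ndarray,
    params: SegmentationParams | None = None,
    ratio: np.ndarray | None = None,
) -> list[LeafROI]:
    """Region-grow each cleaned component and return labeled leaf ROIs.

    Grown regions that overlap are merged into a single ROI (logged).
    ROIs are ordered by bounding-box position (column, then frame) and
    relabeled 1..k in that order.
    """
    params = params or SegmentationParams()
    params.validate()
    cleaned_mask = np.asarray(cleaned_mask, dtype=bool)
    if cleaned_mask.shape != cube.data.shape[1:]:
        raise ValueError("mask shape does not match cube spatial dims")
    if ratio is None:
        ratio = ratio_image(cube, params)

    labels, n = ndi.label(cleaned_mask, structure=_STRUCT4)
    grown: list[np.ndarray] = []
    for k in range(1, n + 1):
        region = _grow_region(labels == k, ratio, params.grow_tolerance)
        merged = False
        for g in grown:
            if (g & region).any():
                g |= region
                log.warning("grown regions overlap; merged into one ROI")
                merged = True
                break
        if not merged:
            grown.append(region)

    rois: list[LeafROI] = []
    for region in grown:
        cols = np.nonzero(region.any(axis=1))[0]
        frames = np.nonzero(region.any(axis=0))[0]
        bbox = (
            int(cols[0]),
            int(frames[0]),
            int(cols[-1] - cols[0] + 1),
            int(frames[-1] - frames[0] + 1),
        )
        rois.append(LeafROI(0, region, bbox, int(region.sum())))
    rois.sort(key=lambda r: (r.bbox[0], r.bbox[1]))
    for k, roi in enumerate(rois, start=1):
        roi.label = k
    return rois


def write_roi_table(rois: list[LeafROI], path: str, sep: str = "\t") -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "label": [r.label for r in rois],
            "col": [r.bbox[0] for r in rois],
            "frame": [r.bbox[1] for r in rois],
            "width": [r.bbox[2] for r in rois],
            "height": [r.bbox[3] for r in rois],
            "area": [r.area for r in rois],
        }
    ).to_csv(path, sep=sep, index=False)


def write_label_image(rois: list[LeafROI], shape: tuple[int, int], path: str) -> None:
    import tifffile

    labels = np.zeros(shape, dtype=np.uint16)
    for roi in rois:
        labels[roi.mask] = roi.label
    tifffile.imwrite(path, labels)
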