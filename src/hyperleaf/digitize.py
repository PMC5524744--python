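"""Per-pixel pigment digitization and pseudo-color rendering.

A fitted (or published preset) model plus its predictor index are applied
to every pixel spectrum of a leaf ROI, producing a pigment raster at the
native pixel pitch of the instrument (0.11 mm/pixel by default). Pixels
whose index value falls outside the model's domain (logarithm of a
non-positive value, guarded denominators) become flagged no-data (NaN) and
are excluded from stretch computation and summary statistics.

Rendering maps stored values linearly onto a colormap between a (vmin,
vmax) stretch; a shared stretch across maps makes cross-sample comparisons
valid. Rendering never alters the stored values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from hyperleaf.cube import HyperCube
from hyperleaf.grid import SpectralGrid
from hyperleaf.indices import IndexDescriptor, IndexRegistry, evaluate_all
from hyperleaf.segmentation import LeafROI

DEFAULT_PIXEL_PITCH_MM = 0.11


@dataclass
class PigmentMap:
    """Per-pixel pigment raster (mg/m^2) over one leaf ROI."""

    values: np.ndarray  # (columns, frames); NaN outside ROI / no-data
    roi: LeafROI
    model: object  # FittedModel or PublishedModelPreset provenance
    descriptor: IndexDescriptor
    pixel_pitch_mm: float = DEFAULT_PIXEL_PITCH_MM
    stretch: tuple[float, float] | None = None

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)

    def summary(self) -> dict[str, float]:
        v = self.values[self.valid]
        if v.size == 0:
            return {"mean": float("nan"), "median": float("nan"), "sd": float("nan"), "n": 0}
        return {
            "mean": float(v.mean()),
            "median": float(np.median(v)),
            "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            "n": int(v.size),
        }


def predict_pixelwise(
    cube: HyperCube,
    roi: LeafROI,
    model,
    descriptor: IndexDescriptor,
    registry: IndexRegistry | None = None,
    median_filter: bool = False,
) -> PigmentMap:
    """Evaluate the predictor index on every ROI pixel and apply the model.

    ``model`` must expose ``predict`` (a FittedModel or a PublishedModelPreset).
    ``median_filter`` optionally applies a 3x3 spatial median to the index
    raster before prediction (off by default).
    """
    if cube.state != "reflectance":
        raise ValueError("digitization requires a reflectance-calibrated cube")
    if not hasattr(model, "predict"):
        raise ValueError("model must expose a predict() method")
    pred_desc = getattr(model, "predictor", None)
    if isinstance(pred_desc, IndexDescriptor) and pred_desc != descriptor:
        raise ValueError("descriptor does not match the model's predictor")
    mask = roi.mask
    spectra = cube.data[:, mask].T  # (n_px, n_bands)
    table = evaluate_all(spectra, cube.grid, descriptors=[descriptor], registry=registry)
    x = table.values[:, 0]
    if median_filter:
        raster_x = np.full(mask.shape, np.nan)
        raster_x[mask] = x
        filtered = ndi.median_filter(np.nan_to_num(raster_x), size=3)
        x = filtered[mask]
    with np.errstate(invalid="ignore"):
        yhat = np.asarray(model.predict(x), dtype=float)
    values = np.full(mask.shape, np.nan)
    values[mask] = yhat
    return PigmentMap(values=values, roi=roi, model=model, descriptor=descriptor)


def compute_stretch(maps: list[PigmentMap]) -> tuple[float, float]:
    """(vmin, vmax) over the valid pixels of all maps."""
    vals = np.concatenate([m.values[m.valid].ravel() for m in maps if m.valid.any()])
    if vals.size == 0:
        return (0.0, 1.0)
    return (float(vals.min()), float(vals.max()))


def render_map(
    maps: list[PigmentMap],
    shared_stretch: bool = True,
    stretch: tuple[float, float] | None = None,
    cmap: str = "viridis",
    grayscale: bool = False,
) -> list[np.ndarray]:
    """Pseudo-color (or gray-stretch) RGBA images of pigment maps.

    With ``shared_stretch`` one (vmin, vmax) is computed over all maps and
    applied to each, so colors are comparable across samples. No-data
    pixels render fully transparent. A degenerate stretch (vmin == vmax)
    renders mid-scale with a warning.
    """
    if not maps:
        raise ValueError("no maps to render")
    import matplotlib

    colormap = matplotlib.colormaps["gray" if grayscale else cmap]
    if stretch is not None:
        stretches = [stretch] * len(maps)
    elif shared_stretch:
        stretches = [compute_stretch(maps)] * len(maps)
    else:
        stretches = [compute_stretch([m]) for m in maps]

    images = []
    for m, (vmin, vmax) in zip(maps, stretches):
        m.stretch = (vmin, vmax)
        if vmax <= vmin:
            warnings.warn("degenerate stretch (vmin == vmax); rendering mid-scale")
            norm = np.full(m.values.shape, 0.5)
        else:
            norm = np.clip((m.values - vmin) / (vmax - vmin), 0.0, 1.0)
        rgba = colormap(np.nan_to_num(norm, nan=0.0))
        rgba[..., 3] = np.where(m.valid, 1.0, 0.0)
        images.append((rgba * 255).astype(np.uint8))
    return images


def save_map_tiff(pmap: PigmentMap, path: str) -> None:
    """32-bit float single-band TIFF; NaN marks no-data."""
    import tifffile

    tifffile.imwrite(path, pmap.values.astype(np.float32))


def save_render_png(image: np.ndarray, path: str) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, image)


def write_map_summaries(maps: list[PigmentMap], path: str, sep: str = "\t") -> None:
    import pandas as pd

    rows = []
    for m in maps:
        row = {"label": m.roi.label, **m.summary()}
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
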