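"""Synthetic leaf scenes with known per-pixel pigment fields.

Every downstream stage (segmentation, index extraction, screening, model
fitting, digitization) is exercised against scenes whose ground truth is
known exactly. The generative model is a deliberately simple Beer-Lambert
style reflectance law, not a radiative-transfer simulation:

    R(lambda) = B(lambda) * exp(-(ka*Ca + kb*Cb + kx*Cxc) / K0) + eta

with

* ``B`` a logistic red-edge baseline (visible shoulder ~0.44, NIR plateau
  ~0.50, inflection at 710 nm),
* ``ka``, ``kb``, ``kx`` Gaussian specific-absorption profiles centered at
  the pigment absorption peaks 665, 649 and 470 nm,
* ``K0`` a scale constant chosen so that the 665 nm reflectance spans
  roughly [0.05, 0.35] over the chlorophyll-a range 61-574 mg/m^2 (the
  tillering-stage range of rice leaves), reproducing the qualitative
  inversion: the more chlorophyll, the lower the red reflectance,
* ``eta`` i.i.d. Gaussian sensor noise.

Leaves are rendered as elongated super-ellipses with a central low-pigment
vein stripe; chlorophyll b and carotenoid track chlorophyll a (Cb ~ Ca/3,
Cxc ~ Ca/5 plus small noise), which reproduces the strong inter-pigment
correlations seen in real leaves (r > 0.88).

The background is dark and spectrally flat so that the segmentation ratio
step has signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from hyperleaf.cube import HyperCube
from hyperleaf.grid import SpectralGrid
from hyperleaf.pigments import ARNON_AB, CAROT_CA, CAROT_CB, CAROT_DEN, arnon_pigments

# --- generative-model constants -------------------------------------------
BASELINE_LO = 0.44  # visible shoulder of the pigment-free baseline
BASELINE_HI = 0.50  # NIR plateau
RED_EDGE_NM = 710.0  # logistic inflection
RED_EDGE_SCALE_NM = 10.0
ABS_CENTER_A = 665.0
ABS_CENTER_B = 649.0
ABS_CENTER_X = 470.0
ABS_SIGMA_A = 30.0
ABS_SIGMA_BX = 25.0
K0 = 335.0  # mg/m^2; sets the depth of the 665 nm absorption feature

#: chlorophyll-a range (mg/m^2) of rice leaves at the tillering stage
DEFAULT_PIGMENT_RANGE = (61.24, 573.63)


@dataclass
class SceneParams:
    """Parameters of one synthetic scene."""

    n_leaves: int = 3
    shape: tuple[int, int] = (128, 96)  # (columns, frames)
    pigment_range: tuple[float, float] = DEFAULT_PIGMENT_RANGE
    corr_targets: tuple[float, float] = (0.95, 0.95)  # Ca-Cb, Ca-Cxc (documented aim)
    noise_sd: float = 0.005
    background_reflectance: float = 0.03
    seed: int = 0
    grid: SpectralGrid = field(default_factory=SpectralGrid.default)
    within_leaf_cv: float = 0.06  # relative sd of the smooth within-leaf field
    vein_factor: float = 0.80  # pigment multiplier on the central vein stripe

    def validate(self) -> None:
        lo, hi = self.pigment_range
        if not lo < hi:
            raise ValueError("pigment range min must be < max")
        if self.n_leaves < 1:
            raise ValueError("n_leaves must be >= 1")
        if self.shape[0] < 32 or self.shape[1] < 32:
            raise ValueError("scene must be at least 32x32 pixels")
        if not 0 <= self.noise_sd < 0.1:
            raise ValueError("noise sd must be in [0, 0.1)")
        if not 0 <= self.background_reflectance < 1:
            raise ValueError("background reflectance must be in [0, 1)")


@dataclass
class GroundTruth:
    """Per-leaf and per-pixel truth accompanying a synthetic cube."""

    leaf_ids: list[int]
    ca: np.ndarray  # per-leaf mean chlorophyll a, mg/m^2
    cb: np.ndarray
    cxc: np.ndarray
    c: np.ndarray
    absorbances: np.ndarray  # (n_leaves, 3): A665, A649, A470 of the means
    masks: list[np.ndarray]  # boolean (columns, frames), pairwise disjoint
    ca_raster: np.ndarray  # per-pixel rasters, 0 outside leaves
    cb_raster: np.ndarray
    cxc_raster: np.ndarray

    @property
    def c_raster(self) -> np.ndarray:
        return self.ca_raster + self.cb_raster


def baseline(centers: np.ndarray) -> np.ndarray:
    """Pigment-free logistic red-edge baseline B(lambda)."""
    return BASELINE_LO + (BASELINE_HI - BASELINE_LO) / (
        1.0 + np.exp(-(centers - RED_EDGE_NM) / RED_EDGE_SCALE_NM)
    )


def absorption_profiles(centers: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian specific-absorption profiles (ka, kb, kx), unit peak."""
    ka = np.exp(-((centers - ABS_CENTER_A) ** 2) / (2 * ABS_SIGMA_A**2))
    kb = np.exp(-((centers - ABS_CENTER_B) ** 2) / (2 * ABS_SIGMA_BX**2))
    kx = np.exp(-((centers - ABS_CENTER_X) ** 2) / (2 * ABS_SIGMA_BX**2))
    return ka, kb, kx


def leaf_spectrum(
    ca: float, cb: float, cxc: float, grid: SpectralGrid | None = None
) -> np.ndarray:
    """Noiseless reflectance spectrum of a homogeneous leaf pixel."""
    grid = grid or SpectralGrid.default()
    ka, kb, kx = absorption_profiles(grid.centers)
    load = ka * ca + kb * cb + kx * cxc
    return baseline(grid.centers) * np.exp(-load / K0)


def invert_arnon(ca: float, cb: float, cxc: float) -> tuple[float, float, float]:
    """Absorbance triple (A665, A649, A470) reproducing the given pigments.

    Algebraic inverse of the Arnon system; feeding the result into
    :func:`hyperleaf.pigments.arnon_pigments` reproduces the inputs to
    floating tolerance.
    """
    vals = np.array([ca, cb, cxc], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("pigment contents must be finite")
    a665, a649 = np.linalg.solve(ARNON_AB, np.array([ca, cb], dtype=float))
    a470 = (CAROT_DEN * cxc + CAROT_CA * ca + CAROT_CB * cb) / 1000.0
    return float(a665), float(a649), float(a470)


def _super_ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    half_len: float,
    half_wid: float,
    angle_rad: float,
    power: float = 3.0,
) -> np.ndarray:
    cols, frames = shape
    cc, ff = np.meshgrid(np.arange(cols), np.arange(frames), indexing="ij")
    dc = cc - center[0]
    df = ff - center[1]
    u = dc * np.cos(angle_rad) + df * np.sin(angle_rad)
    v = -dc * np.sin(angle_rad) + df * np.cos(angle_rad)
    return (np.abs(u / half_len) ** power + np.abs(v / half_wid) ** power) <= 1.0


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float = 6.0) -> np.ndarray:
    """Blurred white noise, rescaled to zero mean / unit sd, clipped at 2.5 sd."""
    raw = gaussian_filter(rng.standard_normal(shape), sigma)
    sd = raw.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return np.clip((raw - raw.mean()) / sd, -2.5, 2.5)


def generate_scene(params: SceneParams) -> tuple[HyperCube, GroundTruth]:
    """Render a reflectance cube plus ground truth for one synthetic scene.

    Leaves are laid out in non-overlapping horizontal rows (elongated along
    the column axis), each with its own mean chlorophyll-a drawn from a
    stratified partition of the configured range so that a multi-leaf scene
    spans the range. The seed fully determines the output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    cols, frames = params.shape
    n = params.n_leaves
    grid = params.grid

    lo, hi = params.pigment_range
    # stratified means: one draw per equal sub-interval, order shuffled
    edges = np.linspace(lo, hi, n + 1)
    ca_means = rng.uniform(edges[:-1], edges[1:])
    rng.shuffle(ca_means)

    row_height = frames / n
    half_wid = min(row_height * 0.32, cols * 0.2)
    half_len = cols * 0.42

    masks: list[np.ndarray] = []
    ca_raster = np.zeros(params.shape)
    cb_raster = np.zeros(params.shape)
    cxc_raster = np.zeros(params.shape)

    for k in range(n):
        center_f = row_height * (k + 0.5) + rng.uniform(-0.05, 0.05) * row_height
        center_c = cols / 2 + rng.uniform(-0.03, 0.03) * cols
        angle = rng.uniform(-0.05, 0.05)  # nearly horizontal
        mask = _super_ellipse_mask(
            params.shape, (center_c, center_f), half_len, half_wid, angle
        )
        # keep leaves disjoint even with jitter
        for prev in masks:
            mask &= ~prev
        if not mask.any():  # degenerate geometry; should not happen at >=32px
            raise RuntimeError("generated an empty leaf mask; enlarge the scene")

        field_ = 1.0 + params.within_leaf_cv * _smooth_field(rng, params.shape)
        ca_px = ca_means[k] * field_
        # central vein stripe: lower pigment, hence brighter
        cc, ff = np.meshgrid(np.arange(cols), np.arange(frames), indexing="ij")
        u = (cc - center_c) * np.cos(angle) + (ff - center_f) * np.sin(angle)
        v = -(cc - center_c) * np.sin(angle) + (ff - center_f) * np.cos(angle)
        vein = np.abs(v) <= max(1.0, half_wid * 0.12)
        ca_px = np.where(vein, ca_px * params.vein_factor, ca_px)

        cb_px = ca_px / 3.0 + rng.normal(0.0, 3.0)
        cxc_px = ca_px / 5.0 + rng.normal(0.0, 2.0)
        ca_raster[mask] = np.clip(ca_px[mask], 0.0, None)
        cb_raster[mask] = np.clip(cb_px[mask], 0.0, None)
        cxc_raster[mask] = np.clip(cxc_px[mask], 0.0, None)
        masks.append(mask)

    # render reflectance
    centers = grid.centers
    ka, kb, kx = absorption_profiles(centers)
    b = baseline(centers)
    data = np.full((grid.n_bands, cols, frames), params.background_reflectance)
    leaf_any = np.zeros(params.shape, dtype=bool)
    for mask in masks:
        leaf_any |= mask
    load = (
        ka[:, None] * ca_raster[leaf_any][None, :]
        + kb[:, None] * cb_raster[leaf_any][None, :]
        + kx[:, None] * cxc_raster[leaf_any][None, :]
    )
    data[:, leaf_any] = b[:, None] * np.exp(-load / K0)
    if params.noise_sd > 0:
        data = data + rng.normal(0.0, params.noise_sd, size=data.shape)
    data = np.clip(data, 0.0, 1.0)

    ca_mean = np.array([ca_raster[m].mean() for m in masks])
    cb_mean = np.array([cb_raster[m].mean() for m in masks])
    cxc_mean = np.array([cxc_raster[m].mean() for m in masks])
    absorb = np.array([invert_arnon(a, bb, x) for a, bb, x in zip(ca_mean, cb_mean, cxc_mean)])

    cube = HyperCube(data=data, grid=grid, state="reflectance")
    truth = GroundTruth(
        leaf_ids=list(range(1, n + 1)),
        ca=ca_mean,
        cb=cb_mean,
        cxc=cxc_mean,
        c=ca_mean + cb_mean,
        absorbances=absorb,
        masks=masks,
        ca_raster=ca_raster,
        cb_raster=cb_raster,
        cxc_raster=cxc_raster,
    )
    return cube, truth


def simulate_samples(
    n_samples: int,
    seed: int = 0,
    noise_sd: float = 0.005,
    leaves_per_scene: int = 3,
    shape: tuple[int, int] = (128, 96),
    grid: SpectralGrid | None = None,
) -> tuple[np.ndarray, "pd.DataFrame"]:
    """Generate leaf-level samples for screening/modeling experiments.

    Runs as many independent scenes as needed (each with its own derived
    seed) and extracts one mean spectrum per leaf using the ground-truth
    masks. Returns ``(spectra, pigments)`` where ``spectra`` has shape
    (n_samples, n_bands) and ``pigments`` columns Ca, Cb, Cxc, C.
    """
    import pandas as pd

    grid = grid or SpectralGrid.default()
    n_scenes = -(-n_samples // leaves_per_scene)
    seeds = np.random.SeedSequence(seed).generate_state(n_scenes) % (2**31)
    spectra = []
    rows = []
    for s in range(n_scenes):
        params = SceneParams(
            n_leaves=leaves_per_scene,
            shape=shape,
            noise_sd=noise_sd,
            seed=int(seeds[s]),
            grid=grid,
        )
        cube, truth = generate_scene(params)
        for k, mask in enumerate(truth.masks):
            spectra.append(cube.data[:, mask].mean(axis=1))
            rows.append(
                {
                    "scene": s,
                    "leaf": truth.leaf_ids[k],
                    "Ca": truth.ca[k],
                    "Cb": truth.cb[k],
                    "Cxc": truth.cxc[k],
                    "C": truth.c[k],
                }
            )
            if len(spectra) == n_samples:
                break
        if len(spectra) == n_samples:
            break
    return np.array(spectra), pd.DataFrame(rows)


def write_ground_truth(truth: GroundTruth, path: str, sep: str = "\t") -> None:
    """Ground-truth table: one row per leaf with pigments and absorbances."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "leaf_id": truth.leaf_ids,
            "Ca": truth.ca,
            "Cb": truth.cb,
            "Cxc": truth.cxc,
            "C": truth.c,
            "A665": truth.absorbances[:, 0],
            "A649": truth.absorbances[:, 1],
            "A470": truth.absorbances[:, 2],
        }
    )
    df.to_csv(path, sep=sep, index=False)


def write_truth_rasters(truth: GroundTruth, prefix: str) -> None:
    """Per-pixel pigment rasters as single-band TIFF; masks as 8-bit TIFF."""
    import tifffile

    tifffile.imwrite(f"{prefix}_Ca.tif", truth.ca_raster.astype(np.float32))
    tifffile.imwrite(f"{prefix}_Cb.tif", truth.cb_raster.astype(np.float32))
    tifffile.imwrite(f"{prefix}_Cxc.tif", truth.cxc_raster.astype(np.float32))
    for i, mask in enumerate(truth.masks, start=1):
        tifffile.imwrite(f"{prefix}_mask{i}.tif", (mask * 255).astype(np.uint8))
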