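"""End-to-end pipeline orchestration with a config file and a manifest.

A run executes the stages in order — scene simulation (or cube loading),
leaf segmentation, ROI spectrum extraction, exhaustive index screening,
model fitting with k-fold cross-validation, and per-pixel digitization of
the winning model — writing per-stage artifacts plus a machine-readable
``manifest.json`` (versions, seeds, censuses, the selected index, fitted
models, per-stage timings) into the run directory. Two runs with the same
config and seed produce identical manifests up to timings.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

import hyperleaf
from hyperleaf.cube import write_bil
from hyperleaf.digitize import predict_pixelwise, render_map, save_map_tiff, save_render_png
from hyperleaf.grid import SpectralGrid
from hyperleaf.indices import census, default_registry, primary_subset, enumerate_indices
from hyperleaf.modeling import MODEL_FORMS, fit_form, kfold_cv
from hyperleaf.screening import best_index, screen_exhaustive
from hyperleaf.segmentation import SegmentationParams, binarize_and_clean, extract_rois, ratio_image
from hyperleaf.indices import spectrum_from_roi
from hyperleaf.synthetic import SceneParams, generate_scene, write_ground_truth

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "hyperleaf_run"
    n_scenes: int = 10
    leaves_per_scene: int = 3
    shape: tuple[int, int] = (128, 96)
    noise_sd: float = 0.005
    seed: int = 0
    target: str = "Ca"
    registry_counts: tuple[int, int] = (20, 95)
    screening_window: tuple[float, float] | None = None  # e.g. (700, 760)
    model_forms: tuple[str, ...] = MODEL_FORMS
    cv_k: int = 5
    write_cubes: bool = False  # BIL export of simulated scenes
    render: bool = True

    def to_yaml(self, path: str) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("shape", "registry_counts", "screening_window", "model_forms"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest: dict = {
        "package_version": hyperleaf.__version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
    }

    grid = SpectralGrid.default()
    registry = default_registry(*config.registry_counts)
    manifest["census"] = census(grid.n_bands, *registry.counts)

    # --- stage 1-2: scenes + segmentation + spectra -----------------------
    t0 = time.perf_counter()
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_scenes) % (2**31)
    seg_params = SegmentationParams()
    spectra, targets, roi_counts = [], [], []
    first_cube = first_roi = None
    for s in range(config.n_scenes):
        params = SceneParams(
            n_leaves=config.leaves_per_scene,
            shape=config.shape,
            noise_sd=config.noise_sd,
            seed=int(seeds[s]),
            grid=grid,
        )
        cube, truth = generate_scene(params)
        scene_dir = out / "scenes"
        scene_dir.mkdir(exist_ok=True)
        write_ground_truth(truth, str(scene_dir / f"scene{s:03d}_truth.tsv"))
        if config.write_cubes:
            write_bil(cube, str(scene_dir / f"scene{s:03d}.bil"))

        ratio = ratio_image(cube, seg_params)
        mask = binarize_and_clean(ratio, seg_params)
        rois = extract_rois(cube, mask, seg_params, ratio=ratio)
        roi_counts.append(len(rois))
        if first_cube is None and rois:
            first_cube, first_roi = cube, rois[0]
        for roi in rois:
            # match ROI to the ground-truth leaf with maximal overlap
            overlaps = [int((roi.mask & m).sum()) for m in truth.masks]
            k = int(np.argmax(overlaps))
            if overlaps[k] == 0:
                raise RuntimeError(f"scene {s}: ROI {roi.label} matches no ground-truth leaf")
            spectra.append(spectrum_from_roi(cube, roi))
            targets.append({"Ca": truth.ca, "Cb": truth.cb, "Cxc": truth.cxc, "C": truth.c}[config.target][k])
    spectra = np.array(spectra)
    y = np.array(targets)
    timings["simulate_segment"] = time.perf_counter() - t0
    manifest["n_samples"] = int(len(y))
    manifest["roi_counts"] = roi_counts

    # --- stage 3: exhaustive screening ------------------------------------
    t0 = time.perf_counter()
    result = screen_exhaustive(spectra, y, grid, registry, target=config.target)
    if config.screening_window is not None:
        descriptors = enumerate_indices(grid, registry)
        subset = primary_subset(descriptors, grid, config.screening_window)
        result.descriptors = descriptors
        winner, r = best_index(result, restrict=subset)
    else:
        winner, r = best_index(result)
    timings["screening"] = time.perf_counter() - t0
    manifest["best_index"] = {"name": winner.name(grid), "r": r}

    # --- stage 4: model fitting + CV --------------------------------------
    t0 = time.perf_counter()
    from hyperleaf.indices import evaluate_all

    x = evaluate_all(spectra, grid, descriptors=[winner], registry=registry).values[:, 0]
    models = {}
    for form in config.model_forms:
        try:
            m = fit_form(x, y, form, predictor=winner, target=config.target)
        except ValueError as exc:
            log.warning("form %s not fittable on this predictor: %s", form, exc)
            continue
        models[form] = m
    if not models:
        raise RuntimeError("no model form could be fitted")
    best_form = max(models, key=lambda f: models[f].metrics.r2)
    cv = kfold_cv(x, y, best_form, k=config.cv_k, seed=config.seed)
    manifest["models"] = {f: m.to_card() for f, m in models.items()}
    manifest["best_form"] = best_form
    manifest["cv"] = {
        "k": cv.k,
        "seed": cv.seed,
        "mean_modeling": cv.mean_modeling._asdict(),
        "mean_validation": cv.mean_validation._asdict(),
    }
    timings["modeling"] = time.perf_counter() - t0

    # --- stage 5: digitization --------------------------------------------
    t0 = time.perf_counter()
    if first_roi is not None:
        pmap = predict_pixelwise(first_cube, first_roi, models[best_form], winner, registry=registry)
        save_map_tiff(pmap, str(out / f"{config.target}_map.tif"))
        if config.render:
            img = render_map([pmap])[0]
            save_render_png(img, str(out / f"{config.target}_map.png"))
        manifest["map_summary"] = pmap.summary()
    timings["digitize"] = time.perf_counter() - t0

    manifest["timings_s"] = timings
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest
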