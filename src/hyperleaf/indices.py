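"""Exhaustive enumeration and evaluation of two-band spectral indices.

Seven index families are generated from a reflectance spectrum R over an
n-band grid:

==========================  =========  =======================================
family                      count      members
==========================  =========  =======================================
original reflectance        n          R_i
pseudo-absorption           2n         lg(R_i), lg(1/R_i)
first derivative            3n         d(R_i), d(lg R_i), d(lg 1/R_i)
second derivative           3n         dd(R_i), dd(lg R_i), dd(lg 1/R_i)
ratio                       9 n(n-1)   T_i/T_j for all 9 transforms T, i != j
normalized                  9 n(n-1)   (T_i-T_j)/(T_i+T_j), i != j
spectral position & area    registry   red-edge position, band areas, ...
published                   registry   named vegetation indices
==========================  =========  =======================================

so the census is 9n + 18 n(n-1) + |registry|; at n = 188 with a 20 + 95
registry this totals 634,615 indices per sample.

Conventions (fixed so the family counts above hold exactly):

* lg is log base 10;
* derivatives are central differences divided by the local wavelength
  spacing (units nm^-1), one-sided at the two grid ends, so each derivative
  transform preserves length n — ``numpy.gradient`` semantics;
* ratio/normalized families use ordered pairs (i, j), i != j, which yields
  the 9 n(n-1) counts; the restricted "primary" subset (see
  :func:`primary_subset`) instead counts unordered pairs;
* requested wavelengths resolve to the nearest band center.

Guarded arithmetic: denominators with magnitude below 1e-12 produce NaN
("flagged") values rather than infinities; screening excludes flagged
columns from rankings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, NamedTuple, Sequence

import numpy as np

from hyperleaf.cube import REFLECTANCE_EPS, HyperCube
from hyperleaf.grid import SpectralGrid

# transform tags in their canonical (enumeration) order
TRANSFORMS = ("R", "lgR", "lg1R", "dR", "dlgR", "dlg1R", "ddR", "ddlgR", "ddlg1R")

# family tags in Table-order; also the tie-break order for rankings
FAMILIES = (
    "original",
    "pseudo_absorption",
    "first_derivative",
    "second_derivative",
    "ratio",
    "normalized",
    "position",
    "published",
)

DENOM_GUARD = 1e-12

# single-band families and the transforms they enumerate, in order
_SINGLE_FAMILIES = (
    ("original", ("R",)),
    ("pseudo_absorption", ("lgR", "lg1R")),
    ("first_derivative", ("dR", "dlgR", "dlg1R")),
    ("second_derivative", ("ddR", "ddlgR", "ddlg1R")),
)

#: transforms whose ratio/normalized combinations are "primary" (kept in the
#: red-edge-restricted subset), together with the primary single families
PRIMARY_SINGLE = {("original", "R"), ("first_derivative", "dR"), ("second_derivative", "ddR")}
PRIMARY_PAIR_TRANSFORM = "R"


class IndexDescriptor(NamedTuple):
    """One spectral index: a family, a transform and band position(s).

    ``i``/``j`` are band indices on the evaluation grid; ``j`` is None for
    single-band families. Registry (position/published) entries carry a
    ``label`` instead of band indices.
    """

    family: str
    transform: str | None
    i: int | None
    j: int | None = None
    label: str | None = None

    def name(self, grid: SpectralGrid | None = None) -> str:
        if self.family in ("position", "published"):
            return f"{self.family}:{self.label}"
        if grid is not None:
            wi = f"{grid.centers[self.i]:.1f}"
            wj = f":{grid.centers[self.j]:.1f}" if self.j is not None else ""
        else:
            wi = str(self.i)
            wj = f":{self.j}" if self.j is not None else ""
        return f"{self.family}:{self.transform}:{wi}{wj}"


@dataclass
class RegistryEntry:
    """A named closed-form index evaluated on (spectrum, grid)."""

    label: str
    fn: Callable[[np.ndarray, SpectralGrid], float]


@dataclass
class IndexRegistry:
    """Pluggable spectral-position and published index definitions."""

    position: list[RegistryEntry] = field(default_factory=list)
    published: list[RegistryEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [e.label for e in self.position + self.published]
        if len(labels) != len(set(labels)):
            raise ValueError("registry labels must be unique")

    @property
    def counts(self) -> tuple[int, int]:
        return (len(self.position), len(self.published))

    def lookup(self, label: str) -> RegistryEntry:
        for entry in self.position + self.published:
            if entry.label == label:
                return entry
        raise KeyError(label)


EMPTY_REGISTRY = IndexRegistry()


# ---------------------------------------------------------------------------
# census / enumeration
# ---------------------------------------------------------------------------

def census(
    n_bands: int, n_position: int = 0, n_published: int = 0
) -> dict[str, int]:
    """Family-by-family descriptor counts plus the total."""
    n = int(n_bands)
    pairs = n * (n - 1) if n >= 2 else 0
    counts = {
        "original": n,
        "pseudo_absorption": 2 * n,
        "first_derivative": 3 * n,
        "second_derivative": 3 * n,
        "ratio": 9 * pairs,
        "normalized": 9 * pairs,
        "position": int(n_position),
        "published": int(n_published),
    }
    counts["total"] = sum(counts.values())
    return counts


def enumerate_indices(
    grid: SpectralGrid, registry: IndexRegistry | None = None
) -> list[IndexDescriptor]:
    """All descriptors for a grid, in canonical (column) order."""
    registry = registry if registry is not None else EMPTY_REGISTRY
    n = grid.n_bands
    out: list[IndexDescriptor] = []
    for family, transforms in _SINGLE_FAMILIES:
        for t in transforms:
            out.extend(IndexDescriptor(family, t, i) for i in range(n))
    for family in ("ratio", "normalized"):
        for t in TRANSFORMS:
            for i in range(n):
                for j in range(n):
                    if j != i:
                        out.append(IndexDescriptor(family, t, i, j))
    out.extend(
        IndexDescriptor("position", None, None, label=e.label) for e in registry.position
    )
    out.extend(
        IndexDescriptor("published", None, None, label=e.label) for e in registry.published
    )
    return out


def descriptor_at(
    position: int, grid: SpectralGrid, registry: IndexRegistry | None = None
) -> IndexDescriptor:
    """Descriptor at a flat position of the canonical enumeration.

    Avoids materializing the full descriptor list when only a handful of
    positions (e.g. screening winners) are needed.
    """
    registry = registry if registry is not None else EMPTY_REGISTRY
    n = grid.n_bands
    k = int(position)
    if k < 0:
        raise IndexError(position)
    for family, transforms in _SINGLE_FAMILIES:
        for t in transforms:
            if k < n:
                return IndexDescriptor(family, t, k)
            k -= n
    pairs = n * (n - 1)
    for family in ("ratio", "normalized"):
        for t in TRANSFORMS:
            if k < pairs:
                i, r = divmod(k, n - 1)
                j = r if r < i else r + 1
                return IndexDescriptor(family, t, i, j)
            k -= pairs
    for family, entries in (("position", registry.position), ("published", registry.published)):
        if k < len(entries):
            return IndexDescriptor(family, None, None, label=entries[k].label)
        k -= len(entries)
    raise IndexError(position)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def transform_stack(
    spectra: np.ndarray, grid: SpectralGrid, eps: float = REFLECTANCE_EPS
) -> np.ndarray:
    """Stack of the 9 spectral transforms, shape (9, n_samples, n_bands).

    Spectra are floored at ``eps`` before logarithms. For a single-band
    grid the derivative transforms are zero by convention.
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    r = np.clip(spectra, eps, None)
    lg = np.log10(r)
    if grid.n_bands >= 2:
        d = lambda a: np.gradient(a, grid.centers, axis=1)
    else:
        d = lambda a: np.zeros_like(a)
    dr, dlg = d(r), d(lg)
    stack = np.empty((9,) + r.shape, dtype=float)
    stack[0] = r
    stack[1] = lg
    stack[2] = -lg  # lg(1/R)
    stack[3] = dr
    stack[4] = dlg
    stack[5] = -dlg  # d(lg(1/R))
    stack[6] = d(dr)
    stack[7] = d(dlg)
    stack[8] = -stack[7]  # dd(lg(1/R))
    return stack


def _guard(den: np.ndarray) -> np.ndarray:
    return np.where(np.abs(den) < DENOM_GUARD, np.nan, den)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class IndexTable:
    """Samples x indices value matrix with descriptor provenance."""

    values: np.ndarray  # (n_samples, n_indices)
    descriptors: list[IndexDescriptor]
    grid: SpectralGrid

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(self.descriptors):
            raise ValueError("value matrix shape does not match descriptor count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def column_names(self) -> list[str]:
        return [d.name(self.grid) for d in self.descriptors]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, columns=self.column_names())

    def select(self, descriptors: Sequence[IndexDescriptor]) -> "IndexTable":
        pos = {d: k for k, d in enumerate(self.descriptors)}
        idx = [pos[d] for d in descriptors]
        return IndexTable(self.values[:, idx], list(descriptors), self.grid)


def _eval_block(stack: np.ndarray, d: IndexDescriptor) -> np.ndarray:
    """Vectorized evaluation of one non-registry descriptor over samples."""
    t = TRANSFORMS.index(d.transform)
    a = stack[t]
    if d.family in ("original", "pseudo_absorption", "first_derivative", "second_derivative"):
        return a[:, d.i]
    if d.family == "ratio":
        return a[:, d.i] / _guard(a[:, d.j])
    if d.family == "normalized":
        return (a[:, d.i] - a[:, d.j]) / _guard(a[:, d.i] + a[:, d.j])
    raise ValueError(f"unknown family {d.family!r}")


def evaluate_index(
    spectrum: np.ndarray,
    descriptor: IndexDescriptor,
    grid: SpectralGrid,
    registry: IndexRegistry | None = None,
) -> float:
    """Evaluate one descriptor on one spectrum."""
    spectrum = np.asarray(spectrum, dtype=float)
    if descriptor.family in ("position", "published"):
        registry = registry if registry is not None else EMPTY_REGISTRY
        return float(registry.lookup(descriptor.label).fn(spectrum, grid))
    stack = transform_stack(spectrum[None, :], grid)
    return float(_eval_block(stack, descriptor)[0])


def evaluate_all(
    spectra: np.ndarray,
    grid: SpectralGrid,
    descriptors: Sequence[IndexDescriptor] | None = None,
    registry: IndexRegistry | None = None,
    dtype=np.float64,
) -> IndexTable:
    """Evaluate descriptors on a spectra matrix (n_samples, n_bands).

    With ``descriptors=None`` the full canonical enumeration is evaluated
    with family-blocked vectorized arithmetic; the column order matches
    :func:`enumerate_indices` exactly. Flagged (guarded) cells are NaN.
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    registry = registry if registry is not None else EMPTY_REGISTRY
    ns, n = spectra.shape
    if n != grid.n_bands:
        raise ValueError("spectra band count does not match grid")
    stack = transform_stack(spectra, grid)

    if descriptors is None:
        descriptors = enumerate_indices(grid, registry)
        blocks: list[np.ndarray] = []
        for _, transforms in _SINGLE_FAMILIES:
            for t in transforms:
                blocks.append(stack[TRANSFORMS.index(t)])
        if n >= 2:
            offdiag = ~np.eye(n, dtype=bool).ravel()
            for t in range(9):
                a = stack[t]
                q = a[:, :, None] / _guard(a[:, None, :])
                blocks.append(q.reshape(ns, -1)[:, offdiag].astype(dtype, copy=False))
            for t in range(9):
                a = stack[t]
                q = (a[:, :, None] - a[:, None, :]) / _guard(a[:, :, None] + a[:, None, :])
                blocks.append(q.reshape(ns, -1)[:, offdiag].astype(dtype, copy=False))
        for entry in registry.position + registry.published:
            col = np.array([entry.fn(spectra[s], grid) for s in range(ns)], dtype=float)
            blocks.append(col[:, None])
        values = np.concatenate([b.astype(dtype, copy=False) for b in blocks], axis=1)
        return IndexTable(values, descriptors, grid)

    values = np.empty((ns, len(descriptors)), dtype=dtype)
    for c, d in enumerate(descriptors):
        if d.family in ("position", "published"):
            entry = registry.lookup(d.label)
            values[:, c] = [entry.fn(spectra[s], grid) for s in range(ns)]
        else:
            values[:, c] = _eval_block(stack, d)
    return IndexTable(values, list(descriptors), grid)


def spectrum_from_roi(cube: HyperCube, roi) -> np.ndarray:
    """Per-band arithmetic mean reflectance over the ROI mask pixels."""
    if cube.state != "reflectance":
        raise ValueError("cube must be calibrated to reflectance")
    mask = np.asarray(roi.mask if hasattr(roi, "mask") else roi, dtype=bool)
    if not mask.any():
        raise ValueError("ROI mask is empty")
    return cube.data[:, mask].mean(axis=1)


# ---------------------------------------------------------------------------
# primary (red-edge restricted) subset
# ---------------------------------------------------------------------------

def primary_subset(
    descriptors: Iterable[IndexDescriptor],
    grid: SpectralGrid,
    window: tuple[float, float] = (700.0, 760.0),
) -> list[IndexDescriptor]:
    """Primary indices with all band centers inside the wavelength window.

    Primary families are R_i, d(R_i), dd(R_i), the plain-reflectance ratio
    R_i/R_j and the plain-reflectance normalized difference. In this
    restricted mode paired families are counted over *unordered* pairs
    (only i < j retained), giving a census of 3m + m(m-1) for m window
    bands.
    """
    lo, hi = window
    if hi < lo:
        raise ValueError("window must satisfy lo <= hi")
    centers = grid.centers

    def inside(idx: int) -> bool:
        return lo <= centers[idx] <= hi

    out: list[IndexDescriptor] = []
    for d in descriptors:
        if (d.family, d.transform) in PRIMARY_SINGLE:
            if inside(d.i):
                out.append(d)
        elif d.family in ("ratio", "normalized") and d.transform == PRIMARY_PAIR_TRANSFORM:
            if d.i < d.j and inside(d.i) and inside(d.j):
                out.append(d)
    return out


def primary_census(m_bands: int) -> int:
    """Primary-subset size for m bands inside the window: 3m + m(m-1)."""
    m = int(m_bands)
    return 3 * m + m * (m - 1)


# ---------------------------------------------------------------------------
# default registry
# ---------------------------------------------------------------------------

def _r(spectrum: np.ndarray, grid: SpectralGrid, wl: float) -> float:
    return float(spectrum[grid.nearest(wl)])


def _safe(num: float, den: float) -> float:
    return num / den if abs(den) >= DENOM_GUARD else float("nan")


def _deriv(spectrum: np.ndarray, grid: SpectralGrid) -> np.ndarray:
    return np.gradient(np.asarray(spectrum, dtype=float), grid.centers)


def _area(spectrum: np.ndarray, grid: SpectralGrid, lo: float, hi: float) -> float:
    idx = grid.window(lo, hi)
    if idx.size < 2:
        return float("nan")
    return float(np.trapezoid(spectrum[idx], grid.centers[idx]))


def _argext(spectrum, grid, lo, hi, which) -> float:
    idx = grid.window(lo, hi)
    if idx.size == 0:
        return float("nan")
    sub = spectrum[idx]
    k = int(np.argmax(sub) if which == "max" else np.argmin(sub))
    return float(grid.centers[idx[k]])


def _ext(spectrum, grid, lo, hi, which) -> float:
    idx = grid.window(lo, hi)
    if idx.size == 0:
        return float("nan")
    sub = spectrum[idx]
    return float(sub.max() if which == "max" else sub.min())


def default_registry(n_position: int = 20, n_published: int = 95) -> IndexRegistry:
    """Registry with spectral-position/area indices and published indices.

    The position group holds red-edge/green-peak/red-well descriptors plus
    band-area integrals over contiguous 50 nm windows. The published group
    ships classic two-band vegetation indices (NDVI, PSSR, SIPI, PRI,
    Vogelmann, Gitelson, MCARI/TCARI/OSAVI, mND705, ...) topped up with
    simple-ratio and normalized-difference variants against the 800 nm NIR
    reference across the visible/red-edge range. Both group sizes are
    configurable; they only pad or truncate the generated lists.
    """
    position: list[RegistryEntry] = [
        RegistryEntry(
            "REP_linear",
            lambda s, g: 700.0
            + 40.0
            * _safe((_r(s, g, 670) + _r(s, g, 780)) / 2.0 - _r(s, g, 700), _r(s, g, 740) - _r(s, g, 700)),
        ),
        RegistryEntry("REP_maxdR", lambda s, g: _argext(_deriv(s, g), g, 680, 760, "max")),
        RegistryEntry("red_edge_amplitude", lambda s, g: _ext(_deriv(s, g), g, 680, 760, "max")),
        RegistryEntry("red_edge_area", lambda s, g: _area(np.abs(_deriv(s, g)), g, 680, 760)),
        RegistryEntry("green_peak_position", lambda s, g: _argext(s, g, 500, 600, "max")),
        RegistryEntry("green_peak_height", lambda s, g: _ext(s, g, 500, 600, "max")),
        RegistryEntry("red_well_position", lambda s, g: _argext(s, g, 640, 700, "min")),
        RegistryEntry("red_well_depth", lambda s, g: _ext(s, g, 640, 700, "min")),
    ]
    for lo in range(400, 1000, 50):  # 12 windows of 50 nm
        position.append(
            RegistryEntry(f"area_{lo}_{lo + 50}", lambda s, g, lo=lo: _area(s, g, lo, lo + 50))
        )

    def nd(w1: float, w2: float):
        return lambda s, g: _safe(_r(s, g, w1) - _r(s, g, w2), _r(s, g, w1) + _r(s, g, w2))

    def sr(w1: float, w2: float):
        return lambda s, g: _safe(_r(s, g, w1), _r(s, g, w2))

    published: list[RegistryEntry] = [
        RegistryEntry("NDVI_800_670", nd(800, 670)),
        RegistryEntry("SR_800_670", sr(800, 670)),
        RegistryEntry("GNDVI_800_550", nd(800, 550)),
        RegistryEntry("PSSRa_800_675", sr(800, 675)),
        RegistryEntry("PSSRb_800_650", sr(800, 650)),
        RegistryEntry("PSNDa_800_675", nd(800, 675)),
        RegistryEntry("PSNDb_800_650", nd(800, 650)),
        RegistryEntry(
            "SIPI", lambda s, g: _safe(_r(s, g, 800) - _r(s, g, 445), _r(s, g, 800) - _r(s, g, 680))
        ),
        RegistryEntry("PRI_531_570", nd(531, 570)),
        RegistryEntry("ZM_750_710", sr(750, 710)),
        RegistryEntry("VOG1_740_720", sr(740, 720)),
        RegistryEntry(
            "VOG2",
            lambda s, g: _safe(_r(s, g, 734) - _r(s, g, 747), _r(s, g, 715) + _r(s, g, 726)),
        ),
        RegistryEntry("GM1_750_550", sr(750, 550)),
        RegistryEntry("GM2_750_700", sr(750, 700)),
        RegistryEntry(
            "Datt_850_710_680",
            lambda s, g: _safe(_r(s, g, 850) - _r(s, g, 710), _r(s, g, 850) - _r(s, g, 680)),
        ),
        RegistryEntry("Carter_695_760", sr(695, 760)),
        RegistryEntry("Lichtenthaler_440_690", sr(440, 690)),
        RegistryEntry(
            "mND705",
            lambda s, g: _safe(
                _r(s, g, 750) - _r(s, g, 705), _r(s, g, 750) + _r(s, g, 705) - 2 * _r(s, g, 445)
            ),
        ),
        RegistryEntry(
            "mSR705",
            lambda s, g: _safe(_r(s, g, 750) - _r(s, g, 445), _r(s, g, 705) - _r(s, g, 445)),
        ),
        RegistryEntry("NDRE_790_720", nd(790, 720)),
        RegistryEntry("CIrededge_780_710", lambda s, g: _safe(_r(s, g, 780), _r(s, g, 710)) - 1.0),
        RegistryEntry("CIgreen_780_550", lambda s, g: _safe(_r(s, g, 780), _r(s, g, 550)) - 1.0),
        RegistryEntry(
            "MCARI",
            lambda s, g: ((_r(s, g, 700) - _r(s, g, 670)) - 0.2 * (_r(s, g, 700) - _r(s, g, 550)))
            * _safe(_r(s, g, 700), _r(s, g, 670)),
        ),
        RegistryEntry(
            "TCARI",
            lambda s, g: 3.0
            * (
                (_r(s, g, 700) - _r(s, g, 670))
                - 0.2 * (_r(s, g, 700) - _r(s, g, 550)) * _safe(_r(s, g, 700), _r(s, g, 670))
            ),
        ),
        RegistryEntry(
            "OSAVI",
            lambda s, g: 1.16 * _safe(_r(s, g, 800) - _r(s, g, 670), _r(s, g, 800) + _r(s, g, 670) + 0.16),
        ),
        RegistryEntry(
            "MTCI", lambda s, g: _safe(_r(s, g, 754) - _r(s, g, 709), _r(s, g, 709) - _r(s, g, 681))
        ),
        RegistryEntry("Chappelle_675_700", sr(675, 700)),
        RegistryEntry(
            "D705_D702",
            lambda s, g: _safe(
                _deriv(s, g)[g.nearest(705)], _deriv(s, g)[g.nearest(702)]
            ),
        ),
        RegistryEntry("NPCI_680_430", nd(680, 430)),
        RegistryEntry("NPQI_415_435", nd(415, 435)),
        RegistryEntry(
            "CUR_675_690_683",
            lambda s, g: _safe(_r(s, g, 675) * _r(s, g, 690), _r(s, g, 683) ** 2),
        ),
        RegistryEntry("LIC1_800_680", nd(800, 680)),
        RegistryEntry("LIC3_440_740", sr(440, 740)),
        RegistryEntry(
            "LeMaire_728_720_434",
            lambda s, g: _safe(_r(s, g, 728) - _r(s, g, 434), _r(s, g, 720) - _r(s, g, 434)),
        ),
    ]
    wl = 430
    while len(published) < n_published:
        published.append(RegistryEntry(f"SR_{wl}_800", sr(wl, 800)))
        if len(published) < n_published:
            published.append(RegistryEntry(f"ND_{wl}_800", nd(wl, 800)))
        wl += 10
    return IndexRegistry(position=position[:n_position], published=published[:n_published])
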