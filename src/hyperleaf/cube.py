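"""Hypercube container plus raw BIL stream I/O and reflectance calibration.

On-disk layout is band-interleaved-by-line (BIL): the stream holds one
frame-block after another, and within each frame-block one full line of
pixels per band, in band order. In memory the cube uses the fixed axis
convention ``(band, column, frame)``, where *frame* is the scan line along
the translation stage; every module in the package shares this convention.

A plain-text sidecar header with ENVI-compatible field names (``samples``,
``lines``, ``bands``, ``data type``, ``interleave``, ``wavelength``)
accompanies each ``.bil`` file so cubes are self-describing.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from typing import BinaryIO, Union

import numpy as np

from hyperleaf.grid import SpectralGrid

#: smallest reflectance kept after clipping, so downstream logs are finite
REFLECTANCE_EPS = 1e-6

# ENVI numeric data-type codes for the dtypes this package writes/reads.
_ENVI_DTYPE = {
    np.dtype("uint8"): 1,
    np.dtype("int16"): 2,
    np.dtype("int32"): 3,
    np.dtype("float32"): 4,
    np.dtype("float64"): 5,
    np.dtype("uint16"): 12,
}
_DTYPE_FROM_ENVI = {v: k for k, v in _ENVI_DTYPE.items()}

DEFAULT_RAW_DTYPE = np.dtype("<u2")  # little-endian unsigned 16-bit counts
DEFAULT_FLOAT_DTYPE = np.dtype("<f4")


@dataclass
class HyperCube:
    """3-D reflectance/count raster with axes (band, column, frame).

    ``state`` is either ``"raw"`` (instrument counts) or ``"reflectance"``
    (calibrated, clipped to [0, 1]).
    """

    data: np.ndarray
    grid: SpectralGrid
    state: str = "raw"

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError("cube data must be 3-D (band, column, frame)")
        if data.shape[0] != self.grid.n_bands:
            raise ValueError(
                f"cube has {data.shape[0]} bands but grid has {self.grid.n_bands}"
            )
        if self.state not in ("raw", "reflectance"):
            raise ValueError(f"unknown calibration state {self.state!r}")
        self.data = data

    @property
    def n_bands(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        """Number of columns (pixels across the slit)."""
        return self.data.shape[1]

    @property
    def n_frames(self) -> int:
        """Number of scan lines along the translation stage."""
        return self.data.shape[2]

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape

    def band(self, wavelength_nm: float) -> np.ndarray:
        """2-D image (column, frame) of the band nearest the wavelength."""
        return self.data[self.grid.nearest(wavelength_nm)]

    def band_image(self, index: int) -> np.ndarray:
        return self.data[index]


def _as_bytes(source: Union[str, os.PathLike, bytes, BinaryIO]) -> bytes:
    if isinstance(source, (bytes, bytearray)):
        return bytes(source)
    if hasattr(source, "read"):
        return source.read()
    with open(source, "rb") as fh:
        return fh.read()


def read_bil(
    source: Union[str, os.PathLike, bytes, BinaryIO],
    dims: tuple[int, int, int] | None = None,
    dtype: Union[str, np.dtype, None] = None,
    grid: SpectralGrid | None = None,
    state: str = "raw",
) -> HyperCube:
    """Read a band-interleaved-by-line binary stream into a HyperCube.

    Parameters
    ----------
    source
        Path, open binary file, or bytes. When a path is given and ``dims``
        is omitted, the sidecar ``.hdr`` written by :func:`write_bil` is
        consulted for dims, dtype and wavelengths.
    dims
        ``(n_bands, width, n_frames)``.
    dtype
        Sample dtype of the stream; default little-endian uint16.
    grid
        Band-center grid; defaults to the instrument grid when the band
        count matches, else an index grid is synthesized.

    Raises
    ------
    ValueError
        If the stream length does not equal bands*width*frames*itemsize;
        the message names expected vs actual byte counts and no partial
        cube is returned.
    """
    if dims is None and isinstance(source, (str, os.PathLike)):
        header = read_header(os.fspath(source) + ".hdr")
        dims = (header["bands"], header["samples"], header["lines"])
        dtype = dtype or header["dtype"]
        state = header.get("state", state)
        if grid is None and header.get("wavelength") is not None:
            grid = SpectralGrid(header["wavelength"])
    if dims is None:
        raise ValueError("dims must be given when no sidecar header is available")
    dtype = np.dtype(dtype if dtype is not None else DEFAULT_RAW_DTYPE)
    n_bands, width, n_frames = dims

    raw = _as_bytes(source)
    expected = n_bands * width * n_frames * dtype.itemsize
    if len(raw) != expected:
        raise ValueError(
            f"BIL stream size mismatch: expected {expected} bytes "
            f"({n_bands}x{width}x{n_frames} @ {dtype.itemsize} B/sample), got {len(raw)}"
        )
    # stream order is (frame, band, column); cube axes are (band, column, frame)
    arr = np.frombuffer(raw, dtype=dtype).reshape(n_frames, n_bands, width)
    data = np.ascontiguousarray(arr.transpose(1, 2, 0))
    if grid is None:
        grid = (
            SpectralGrid.default()
            if n_bands == 188
            else SpectralGrid(np.arange(n_bands, dtype=float) + 1.0)
        )
    return HyperCube(data=data, grid=grid, state=state)


def write_bil(
    cube: HyperCube,
    target: Union[str, os.PathLike, BinaryIO],
    dtype: Union[str, np.dtype, None] = None,
) -> None:
    """Write a cube as a BIL stream; paths also get a sidecar ``.hdr``."""
    if dtype is None:
        dtype = cube.data.dtype
    dtype = np.dtype(dtype)
    # (band, column, frame) -> stream order (frame, band, column)
    stream = np.ascontiguousarray(cube.data.transpose(2, 0, 1)).astype(dtype, copy=False)
    if hasattr(target, "write"):
        target.write(stream.tobytes())
        return
    path = os.fspath(target)
    with open(path, "wb") as fh:
        fh.write(stream.tobytes())
    write_header(path + ".hdr", cube, dtype)


def write_header(path: str, cube: HyperCube, dtype: np.dtype) -> None:
    code = _ENVI_DTYPE[np.dtype(dtype).newbyteorder("=")]
    wl = ", ".join(f"{w:.4f}" for w in cube.grid.centers)
    lines = [
        "ENVI",
        f"samples = {cube.width}",
        f"lines = {cube.n_frames}",
        f"bands = {cube.n_bands}",
        f"data type = {code}",
        "interleave = bil",
        "byte order = 0",
        f"state = {cube.state}",
        f"wavelength = {{ {wl} }}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_header(path: str) -> dict:
    fields: dict = {}
    with open(path) as fh:
        text = fh.read()
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    out: dict = {}
    for key in ("samples", "lines", "bands"):
        out[key] = int(fields[key])
    code = int(fields["data type"])
    out["dtype"] = _DTYPE_FROM_ENVI[code]
    out["state"] = fields.get("state", "raw")
    wl = fields.get("wavelength")
    if wl:
        wl = wl.strip().lstrip("{").rstrip("}")
        out["wavelength"] = np.array([float(v) for v in wl.split(",") if v.strip()])
    else:
        out["wavelength"] = None
    return out


def calibrate_reflectance(
    raw: HyperCube,
    white: np.ndarray,
    dark: np.ndarray | float = 0.0,
    eps: float = REFLECTANCE_EPS,
) -> HyperCube:
    """Convert raw counts to reflectance: (raw - dark) / (white - dark).

    ``white`` and ``dark`` may be per-band vectors (length ``n_bands``,
    broadcast over the spatial axes), full cubes, or scalars (dark only).
    The result is clipped to [eps, 1] so that downstream logarithms stay
    finite.

    Raises
    ------
    ValueError
        If ``white <= dark`` anywhere it is used (zero or negative dynamic
        range cannot be divided out).
    """
    white = np.asarray(white, dtype=float)
    dark = np.asarray(dark, dtype=float)

    def _broadcast(arr: np.ndarray) -> np.ndarray:
        if arr.ndim == 1:
            if arr.shape[0] != raw.n_bands:
                raise ValueError("per-band reference length must equal n_bands")
            return arr[:, None, None]
        return arr

    w = _broadcast(white)
    d = _broadcast(dark)
    denom = w - d
    if np.any(denom <= 0):
        raise ValueError("white reference must exceed dark reference everywhere")
    refl = (raw.data.astype(float) - d) / denom
    refl = np.clip(refl, eps, 1.0)
    return HyperCube(data=refl, grid=raw.grid, state="reflectance")


def export_band_tiff(cube: HyperCube, wavelength_nm: float, path: str) -> None:
    """Write the single band nearest ``wavelength_nm`` as a float TIFF."""
    import tifffile

    tifffile.imwrite(path, cube.band(wavelength_nm).astype(np.float32))
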