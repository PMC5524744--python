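"""Spectral band grid of the line-scan imaging spectrograph.

The reference instrument resolves 188 bands over 400-1000 nm (about 3.2 nm
spectral resolution). Band centers are stored explicitly so that non-uniform
grids and sub-sampled toy grids work everywhere a wavelength is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_N_BANDS = 188
DEFAULT_RANGE_NM = (400.0, 1000.0)


@dataclass(frozen=True)
class SpectralGrid:
    """Monotone band-center wavelengths, in nm."""

    centers: np.ndarray

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        if centers.ndim != 1 or centers.size < 1:
            raise ValueError("band centers must be a non-empty 1-D array")
        if centers.size > 1 and not np.all(np.diff(centers) > 0):
            raise ValueError("band centers must be strictly increasing")
        object.__setattr__(self, "centers", centers)

    @classmethod
    def default(cls) -> "SpectralGrid":
        """The 188-band 400-1000 nm instrument grid (evenly spaced centers)."""
        return cls(np.linspace(*DEFAULT_RANGE_NM, DEFAULT_N_BANDS))

    @classmethod
    def linear(cls, lo: float, hi: float, n: int) -> "SpectralGrid":
        return cls(np.linspace(lo, hi, n))

    @property
    def n_bands(self) -> int:
        return int(self.centers.size)

    def nearest(self, wavelength_nm: float) -> int:
        """Band index whose center is nearest to the requested wavelength."""
        return int(np.argmin(np.abs(self.centers - float(wavelength_nm))))

    def window(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Indices of bands whose centers fall inside [lo, hi] inclusive."""
        c = self.centers
        return np.nonzero((c >= lo_nm) & (c <= hi_nm))[0]

    def __len__(self) -> int:
        return self.n_bands

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralGrid):
            return NotImplemented
        return self.centers.shape == other.centers.shape and bool(
            np.allclose(self.centers, other.centers)
        )

    def __hash__(self) -> int:
        return hash((self.centers.size, float(self.centers[0]), float(self.centers[-1])))
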