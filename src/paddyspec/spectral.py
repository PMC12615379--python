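"""Spectral band grids shared by cubes and indices.

The reference push-broom sensor delivers 304 bands at 2 nm resolution across
the visible to near-infrared range (399–1006 nm).  A uniform 2 nm grid
starting at 399 nm cannot end exactly at 1006 nm; the band count (304) is
honoured and the last band centre falls at 1005 nm.  Wavelength references
such as "1006 nm" are resolved by nearest-band lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpectralGrid", "default_grid", "SENSOR_RANGE_NM"]

#: Nominal sensor coverage in nm.
SENSOR_RANGE_NM = (399.0, 1006.0)

#: How far (nm) a requested wavelength may sit from the nearest band centre.
BAND_LOOKUP_TOLERANCE_NM = 5.0


@dataclass(frozen=True)
class SpectralGrid:
    """Ordered band centres, in nanometres, shared by all cubes and indices.

    Parameters
    ----------
    wavelengths
        Strictly increasing band centres in nm, all within [300, 1100].
    """

    wavelengths: np.ndarray = field()

    def __init__(self, wavelengths) -> None:
        wl = np.asarray(wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("a spectral grid needs at least two band centres")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("band centres must be strictly increasing")
        if wl[0] < 300.0 or wl[-1] > 1100.0:
            raise ValueError("band centres must lie within 300–1100 nm")
        wl.setflags(write=False)
        object.__setattr__(self, "wavelengths", wl)

    @property
    def n_bands(self) -> int:
        return int(self.wavelengths.size)

    def __len__(self) -> int:
        return self.n_bands

    def nearest_band(self, target_nm: float) -> int:
        """Index of the band centre closest to ``target_nm``.

        Ties break toward the lower wavelength.  Targets further than
        5 nm from any centre raise ``ValueError`` rather than silently
        snapping to a distant band.
        """
        wl = self.wavelengths
        dist = np.abs(wl - float(target_nm))
        idx = int(np.argmin(dist))  # argmin returns the first (lower-wl) tie
        if dist[idx] > BAND_LOOKUP_TOLERANCE_NM:
            raise ValueError(
                f"{target_nm} nm is {dist[idx]:.1f} nm from the nearest band "
                f"centre (tolerance {BAND_LOOKUP_TOLERANCE_NM} nm)"
            )
        return idx

    def band_at(self, target_nm: float) -> float:
        """Band centre (nm) closest to ``target_nm``."""
        return float(self.wavelengths[self.nearest_band(target_nm)])

    def __eq__(self, other) -> bool:  # value semantics for grid sharing checks
        return isinstance(other, SpectralGrid) and np.array_equal(
            self.wavelengths, other.wavelengths
        )

    def __hash__(self) -> int:
        return hash(self.wavelengths.tobytes())


def default_grid() -> SpectralGrid:
    """The 304-band, 2 nm sensor grid: 399, 401, …, 1005 nm."""
    return SpectralGrid(399.0 + 2.0 * np.arange(304))
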