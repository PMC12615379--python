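"""Dual-temporal spectral difference indices for stressed rice canopy.

Three index families compare a pixel's reflectance spectrum between an early
(T1) and a late (T2) acquisition:

DSRI
    per-band normalized difference, (R_late − R_early)/(R_late + R_early).
    Ratioing makes it robust to a common illumination gain on both dates.
DSDI
    the raw difference spectrum R_late − R_early, min–max normalized to
    [0, 1] *per pixel* over all bands.  Normalizing per pixel removes the
    sunlit/shaded magnitude difference while keeping the shape of the
    change.
DSDI-SL
    a scalar combining one short-wavelength (399–750 nm) and one
    long-wavelength (750–1006 nm) DSDI value.  Planthopper stress raises
    the normalized difference spectrum on the short-wave side and lowers it
    on the long-wave side, so the normalized contrast
    (D_short − D_long)/(D_short + D_long) increases as infestation worsens.

Undefined values (zero denominators, constant difference spectra) propagate
as NaN and are never silently coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PixelPairs
from .spectral import SpectralGrid

__all__ = [
    "DifferencePair",
    "dsri",
    "dsdi",
    "dsdi_sl",
    "DsdiSlSpec",
    "build_candidates",
    "candidate_matrix",
    "SHORT_WAVE_MAX_NM",
]

#: Boundary between the short-wave (visible / red-edge) and long-wave
#: (NIR plateau) regions, in nm.
SHORT_WAVE_MAX_NM = 750.0


@dataclass
class DifferencePair:
    """A pixel's spectra at the two dates, on a shared grid."""

    r_early: np.ndarray
    r_late: np.ndarray
    grid: SpectralGrid

    def __post_init__(self) -> None:
        self.r_early = np.asarray(self.r_early, dtype=float)
        self.r_late = np.asarray(self.r_late, dtype=float)
        if self.r_early.shape != self.r_late.shape:
            raise ValueError("T1/T2 spectra must have equal length")
        if self.r_early.shape[-1] != self.grid.n_bands:
            raise ValueError("spectrum length does not match the grid")


def _as_2d(a: np.ndarray) -> tuple[np.ndarray, bool]:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        return a[None, :], True
    return a, False


def dsri(r_early, r_late) -> np.ndarray:
    """Per-band normalized difference between the two dates.

    Accepts single spectra (B,) or stacks (n, B).  Bands where
    R_late + R_early == 0 come back NaN.
    """
    early, squeeze_e = _as_2d(r_early)
    late, _ = _as_2d(r_late)
    denom = late + early
    out = np.full_like(denom, np.nan)
    ok = denom != 0
    out[ok] = (late - early)[ok] / denom[ok]
    return out[0] if squeeze_e else out


def dsdi(r_early, r_late, return_degenerate: bool = False):
    """Per-pixel min–max normalized difference spectrum.

    For each pixel the difference d = R_late − R_early is rescaled over that
    pixel's bands so its minimum maps to 0 and its maximum to 1.  A pixel
    whose difference spectrum is constant has no spread to normalize: its
    values are returned as 0 and it is flagged degenerate.

    Returns the (n, B) (or (B,)) normalized array; with
    ``return_degenerate=True`` also a boolean mask of degenerate pixels.
    """
    early, squeeze = _as_2d(r_early)
    late, _ = _as_2d(r_late)
    if early.shape[1] < 2:
        raise ValueError("min-max normalization needs at least two bands")
    d = late - early
    lo = d.min(axis=1, keepdims=True)
    hi = d.max(axis=1, keepdims=True)
    span = hi - lo
    degenerate = span[:, 0] == 0
    span_safe = np.where(span == 0, 1.0, span)
    out = (d - lo) / span_safe
    out[degenerate] = 0.0
    if squeeze:
        out, degenerate = out[0], bool(degenerate[0])
    if return_degenerate:
        return out, degenerate
    return out


@dataclass(frozen=True)
class DsdiSlSpec:
    """One short-wave / long-wave band pairing for DSDI-SL.

    ``short_nm`` must fall in [399, 750) and ``long_nm`` in [750, 1006];
    both are resolved to grid bands by nearest-band lookup.
    """

    short_nm: float
    long_nm: float

    def __post_init__(self) -> None:
        if not (self.short_nm < SHORT_WAVE_MAX_NM <= self.long_nm):
            raise ValueError(
                "DSDI-SL needs a short-wave band (< 750 nm) and a long-wave "
                "band (>= 750 nm)"
            )

    def name(self, grid: SpectralGrid | None = None) -> str:
        s, l = self.short_nm, self.long_nm
        return f"DSDI-SL_{s:g}-{l:g}"


def dsdi_sl(dsdi_values, grid: SpectralGrid, spec: DsdiSlSpec) -> np.ndarray:
    """Normalized short/long contrast of the DSDI spectrum.

    (D_short − D_long)/(D_short + D_long), oriented so the value rises as
    infestation severity worsens (short-wave DSDI increases, long-wave DSDI
    decreases under stress).  Since DSDI ∈ [0, 1], the result lies in
    [−1, 1] where defined; a zero denominator yields NaN.
    """
    vals, squeeze = _as_2d(dsdi_values)
    d_short = vals[:, grid.nearest_band(spec.short_nm)]
    d_long = vals[:, grid.nearest_band(spec.long_nm)]
    denom = d_short + d_long
    out = np.full(vals.shape[0], np.nan)
    ok = denom != 0
    out[ok] = (d_short[ok] - d_long[ok]) / denom[ok]
    return float(out[0]) if squeeze else out


def build_candidates(
    grid: SpectralGrid,
    short_bands_nm,
    long_bands_nm,
) -> list[str]:
    """Canonical names of the full dual-temporal candidate feature set.

    One DSRI and one DSDI per grid band, plus one DSDI-SL per
    (short-wave, long-wave) pairing of the selected bands: with the default
    304-band grid, 6 short and 4 long picks, 304 + 304 + 24 = 632
    candidates.  Names encode the band-centre wavelength(s), e.g.
    ``DSRI_525`` or ``DSDI-SL_399-817``.
    """
    names = [f"DSRI_{w:g}" for w in grid.wavelengths]
    names += [f"DSDI_{w:g}" for w in grid.wavelengths]
    for s in short_bands_nm:
        for l in long_bands_nm:
            names.append(DsdiSlSpec(float(s), float(l)).name())
    if len(set(names)) != len(names):
        raise ValueError("duplicate candidate feature names")
    return names


def candidate_matrix(
    pairs: PixelPairs,
    short_bands_nm,
    long_bands_nm,
) -> pd.DataFrame:
    """Full candidate feature matrix for extracted pixel pairs.

    Columns: ``plot_id`` then every candidate from :func:`build_candidates`.
    Degenerate or undefined values appear as NaN so callers can drop (and
    count) affected pixels before modelling.
    """
    grid = pairs.grid
    names = build_candidates(grid, short_bands_nm, long_bands_nm)
    dsri_vals = dsri(pairs.r_early, pairs.r_late)
    dsdi_vals, degen = dsdi(pairs.r_early, pairs.r_late, return_degenerate=True)
    dsdi_out = dsdi_vals.copy()
    dsdi_out[degen] = np.nan  # degenerate pixels carry no usable DSDI
    blocks = [dsri_vals, dsdi_out]
    sl_cols = []
    for s in short_bands_nm:
        for l in long_bands_nm:
            spec = DsdiSlSpec(float(s), float(l))
            col = dsdi_sl(dsdi_vals, grid, spec)
            col = np.where(degen, np.nan, col)
            sl_cols.append(col)
    blocks.append(np.column_stack(sl_cols) if sl_cols else np.empty((len(pairs), 0)))
    data = np.hstack(blocks)
    df = pd.DataFrame(data, columns=names)
    df.insert(0, "plot_id", pairs.plot_id)
    return df
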