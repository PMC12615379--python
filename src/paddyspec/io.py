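"""Cube and plot-vector input/output.

Hyperspectral cubes travel as ENVI-style rasters: a raw binary payload
(``.dat``) plus a small text header (``.hdr``) declaring dimensions,
interleave, data type and the per-band wavelength list.  Plot vectors are a
CSV table of square footprints.  Classified severity maps are single-band
byte rasters in the same ENVI dialect.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .spectral import SpectralGrid

__all__ = [
    "ReflectanceCube",
    "PlotFootprint",
    "PixelPairs",
    "read_cube",
    "write_cube",
    "calibrate_dn",
    "extract_plot_pixels",
    "write_severity_map",
    "read_severity_map",
    "read_plot_table",
    "write_plot_table",
    "SEVERITY_CODES",
]

# ENVI data-type codes we understand.
_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_DTYPE_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}

#: label -> integer code used in classified severity rasters
SEVERITY_CODES = {"unassessed": 0, "mild": 1, "moderate": 2, "severe": 3}
_CODE_LABELS = {v: k for k, v in SEVERITY_CODES.items()}


@dataclass
class ReflectanceCube:
    """A dated raster of per-pixel reflectance spectra.

    ``values`` has shape (rows, cols, bands) and is unitless reflectance;
    ``grid`` carries the band-centre wavelengths.  T1/T2 pairs must share
    grid and dimensions.
    """

    values: np.ndarray
    grid: SpectralGrid
    date: str = "T1"

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ValueError("cube values must be rows x cols x bands")
        if v.shape[2] != self.grid.n_bands:
            raise ValueError(
                f"cube has {v.shape[2]} bands but grid declares {self.grid.n_bands}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("cube contains non-finite reflectance")
        self.values = v

    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class PlotFootprint:
    """A square observation plot: top-left pixel and side length in pixels.

    Coordinates are 0-based (row, col); the footprint covers
    ``side`` x ``side`` pixels, so a 1 m plot at ~5 cm ground sampling
    distance is the canonical side=21 (441 pixels).
    """

    plot_id: int
    row0: int
    col0: int
    side: int = 21

    def __post_init__(self) -> None:
        if self.side < 1:
            raise ValueError("side must be >= 1")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("footprint origin must be non-negative")

    @property
    def n_pixels(self) -> int:
        return self.side * self.side

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row0, self.row0 + self.side),
            slice(self.col0, self.col0 + self.side),
        )


# ---------------------------------------------------------------------------
# ENVI header handling
# ---------------------------------------------------------------------------

def _parse_envi_header(text: str) -> dict:
    """Parse an ENVI header into a {lowercased key: str | list} dict."""
    if not text.lstrip().lower().startswith("envi"):
        raise ValueError("not an ENVI header (missing 'ENVI' magic line)")
    body = text.lstrip()[4:]
    fields: dict = {}
    i = 0
    lines = body.splitlines()
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or "=" not in line:
            continue
        key, _, rest = line.partition("=")
        key = key.strip().lower()
        rest = rest.strip()
        if rest.startswith("{"):
            chunk = rest[1:]
            while "}" not in chunk and i < len(lines):
                chunk += "\n" + lines[i]
                i += 1
            chunk = chunk.split("}")[0]
            fields[key] = [item.strip() for item in chunk.replace("\n", " ").split(",") if item.strip()]
        else:
            fields[key] = rest
    return fields


def _format_envi_header(
    rows: int, cols: int, bands: int, dtype_code: int, interleave: str,
    wavelengths=None, description: str = "paddyspec cube", classes: dict | None = None,
) -> str:
    parts = [
        "ENVI",
        f"description = {{{description}}}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {dtype_code}",
        f"interleave = {interleave}",
        "byte order = 0",
    ]
    if wavelengths is not None:
        wl = ", ".join(f"{w:.1f}" for w in wavelengths)
        parts.append("wavelength units = Nanometers")
        parts.append(f"wavelength = {{{wl}}}")
    if classes:
        names = ", ".join(name for name, _ in sorted(classes.items(), key=lambda kv: kv[1]))
        parts.append(f"classes = {len(classes)}")
        parts.append(f"class names = {{{names}}}")
    return "\n".join(parts) + "\n"


def _payload_to_cube(raw: np.ndarray, rows: int, cols: int, bands: int, interleave: str) -> np.ndarray:
    if interleave == "bsq":
        return raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    if interleave == "bil":
        return raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    if interleave == "bip":
        return raw.reshape(rows, cols, bands)
    raise ValueError(f"unsupported interleave {interleave!r}")


def read_cube(path, header_path=None, date: str = "T1") -> ReflectanceCube:
    """Read an ENVI raster + header into a :class:`ReflectanceCube`.

    The header must declare ``samples``/``lines``/``bands``, ``data type``,
    ``interleave`` and a ``wavelength`` list; the payload size must match.
    """
    path = Path(path)
    if header_path is None:
        header_path = path.with_suffix(".hdr")
    fields = _parse_envi_header(Path(header_path).read_text())
    try:
        cols = int(fields["samples"])
        rows = int(fields["lines"])
        bands = int(fields["bands"])
        dtype = _DTYPES[int(fields["data type"])]
    except KeyError as exc:
        raise ValueError(f"ENVI header missing required field: {exc}") from exc
    interleave = str(fields.get("interleave", "bsq")).lower()
    if "wavelength" not in fields:
        raise ValueError("ENVI header declares no wavelength list")
    wavelengths = np.array([float(w) for w in fields["wavelength"]])
    if wavelengths.size != bands:
        raise ValueError(
            f"header lists {wavelengths.size} wavelengths for {bands} bands"
        )
    raw = np.fromfile(path, dtype=dtype)
    if raw.size != rows * cols * bands:
        raise ValueError(
            f"payload holds {raw.size} values; header implies {rows * cols * bands}"
        )
    values = _payload_to_cube(raw, rows, cols, bands, interleave).astype(np.float64)
    return ReflectanceCube(values=values, grid=SpectralGrid(wavelengths), date=date)


def write_cube(cube: ReflectanceCube, path, header_path=None) -> None:
    """Write a cube as BSQ float32 ENVI raster + text header."""
    path = Path(path)
    if header_path is None:
        header_path = path.with_suffix(".hdr")
    values = cube.values.astype(np.float32)
    bsq = values.transpose(2, 0, 1)  # bands, rows, cols
    bsq.tofile(path)
    hdr = _format_envi_header(
        cube.rows, cube.cols, cube.grid.n_bands,
        _DTYPE_CODES[np.dtype(np.float32)], "bsq",
        wavelengths=cube.grid.wavelengths,
        description=f"reflectance cube {cube.date}",
    )
    Path(header_path).write_text(hdr)


# ---------------------------------------------------------------------------
# Radiometric scaling
# ---------------------------------------------------------------------------

def calibrate_dn(
    dn: np.ndarray,
    whiteboard_dn: np.ndarray,
    whiteboard_reflectance: np.ndarray,
    grid: SpectralGrid,
    date: str = "T1",
) -> ReflectanceCube:
    """Convert digital numbers to reflectance against a reference panel.

    Per band: ``reflectance = DN * panel_reflectance / panel_DN``, the
    standard ratio against a near-Lambertian whiteboard of known reflectance.
    """
    dn = np.asarray(dn, dtype=float)
    wb_dn = np.asarray(whiteboard_dn, dtype=float)
    wb_refl = np.asarray(whiteboard_reflectance, dtype=float)
    if np.any(wb_dn <= 0):
        raise ValueError("whiteboard DN must be positive in every band")
    values = dn * (wb_refl / wb_dn)
    return ReflectanceCube(values=values, grid=grid, date=date)


# ---------------------------------------------------------------------------
# Plot extraction
# ---------------------------------------------------------------------------

def _check_inside(fp: PlotFootprint, cube: ReflectanceCube) -> None:
    if fp.row0 + fp.side > cube.rows or fp.col0 + fp.side > cube.cols:
        raise ValueError(f"plot {fp.plot_id} footprint extends outside the cube")


@dataclass
class PixelPairs:
    """Per-pixel (T1, T2) spectrum pairs extracted from a cube pair.

    ``r_early`` / ``r_late`` are (n_pixels, n_bands) reflectance arrays in a
    stable row-major order within each plot; ``plot_id``/``row``/``col``
    locate each pixel.
    """

    plot_id: np.ndarray
    row: np.ndarray
    col: np.ndarray
    r_early: np.ndarray
    r_late: np.ndarray
    grid: SpectralGrid

    def __len__(self) -> int:
        return int(self.plot_id.size)


def extract_plot_pixels(
    cube_t1: ReflectanceCube,
    cube_t2: ReflectanceCube,
    footprints,
) -> PixelPairs:
    """Extract per-pixel (T1, T2) spectrum pairs for every footprint.

    Each side-``s`` plot contributes exactly s*s pixel pairs (441 for the
    canonical 21 px plot), ordered row-major and stable across calls.
    """
    if cube_t1.grid != cube_t2.grid:
        raise ValueError("T1/T2 cubes must share a spectral grid")
    if cube_t1.values.shape != cube_t2.values.shape:
        raise ValueError("T1/T2 cubes must share dimensions")
    ids, rows_out, cols_out, early, late = [], [], [], [], []
    for fp in footprints:
        _check_inside(fp, cube_t1)
        rs, cs = fp.slices()
        early.append(cube_t1.values[rs, cs].reshape(fp.n_pixels, -1))
        late.append(cube_t2.values[rs, cs].reshape(fp.n_pixels, -1))
        rr, cc = np.meshgrid(
            np.arange(fp.row0, fp.row0 + fp.side),
            np.arange(fp.col0, fp.col0 + fp.side),
            indexing="ij",
        )
        rows_out.append(rr.ravel())
        cols_out.append(cc.ravel())
        ids.append(np.full(fp.n_pixels, fp.plot_id, dtype=int))
    return PixelPairs(
        plot_id=np.concatenate(ids),
        row=np.concatenate(rows_out),
        col=np.concatenate(cols_out),
        r_early=np.vstack(early),
        r_late=np.vstack(late),
        grid=cube_t1.grid,
    )


# ---------------------------------------------------------------------------
# Classified severity maps
# ---------------------------------------------------------------------------

def write_severity_map(labels, dims: tuple[int, int], path, header_path=None) -> None:
    """Write per-pixel severity labels as a single-band ENVI byte raster.

    ``labels`` is a (rows*cols,) or (rows, cols) array of strings from
    {unassessed, mild, moderate, severe}; codes follow
    :data:`SEVERITY_CODES`.
    """
    rows, cols = dims
    labels = np.asarray(labels).reshape(rows, cols)
    codes = np.zeros((rows, cols), dtype=np.uint8)
    for r in range(rows):
        for c in range(cols):
            lab = str(labels[r, c])
            if lab not in SEVERITY_CODES:
                raise ValueError(f"unknown severity label {lab!r}")
            codes[r, c] = SEVERITY_CODES[lab]
    path = Path(path)
    if header_path is None:
        header_path = path.with_suffix(".hdr")
    codes.tofile(path)
    hdr = _format_envi_header(
        rows, cols, 1, _DTYPE_CODES[np.dtype(np.uint8)], "bsq",
        description="classified BPH severity map", classes=SEVERITY_CODES,
    )
    Path(header_path).write_text(hdr)


def read_severity_map(path, header_path=None) -> np.ndarray:
    """Read a classified severity raster back into a (rows, cols) label array."""
    path = Path(path)
    if header_path is None:
        header_path = path.with_suffix(".hdr")
    fields = _parse_envi_header(Path(header_path).read_text())
    rows, cols = int(fields["lines"]), int(fields["samples"])
    codes = np.fromfile(path, dtype=_DTYPES[int(fields["data type"])]).reshape(rows, cols)
    labels = np.empty((rows, cols), dtype=object)
    for code, lab in _CODE_LABELS.items():
        labels[codes == code] = lab
    if (labels == None).any():  # noqa: E711 — object-array comparison
        raise ValueError("raster contains codes outside the severity table")
    return labels


# ---------------------------------------------------------------------------
# Plot tables
# ---------------------------------------------------------------------------

_PLOT_COLUMNS = ["plot_id", "row0", "col0", "side", "count_t1", "count_t2"]


def write_plot_table(footprints, counts_t1, counts_t2, path) -> None:
    """Write plot footprints and per-date mean BPH counts as CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PLOT_COLUMNS)
        for fp, c1, c2 in zip(footprints, counts_t1, counts_t2):
            writer.writerow([fp.plot_id, fp.row0, fp.col0, fp.side, c1, c2])


def read_plot_table(path) -> pd.DataFrame:
    """Read the plot CSV; returns columns plot_id,row0,col0,side,count_t1,count_t2."""
    df = pd.read_csv(path)
    missing = set(_PLOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plot table missing columns: {sorted(missing)}")
    return df


def footprints_from_table(df: pd.DataFrame) -> list[PlotFootprint]:
    return [
        PlotFootprint(int(r.plot_id), int(r.row0), int(r.col0), int(r.side))
        for r in df.itertuples()
    ]
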