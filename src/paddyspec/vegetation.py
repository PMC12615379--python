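"""Mono-temporal vegetation-index bank.

Twenty-four pigment- and structure-sensitive vegetation indices serve as the
single-date baseline feature set.  Definitions are shipped as data — a
(name, expression) table using a small grammar — so a user can inspect,
override or extend them:

* ``R<nm>`` — canopy reflectance at the band centre nearest <nm> (5 nm
  lookup tolerance), e.g. ``R865``;
* numeric literals, ``+ - * /``, parentheses.

A few formulas circulate in typographically corrupted variants; the forms
here follow the originally published definitions (REIP is the Guyot
linear-interpolation form; CSI and LICI are the red-edge ratio/contrast
forms).  Singular denominators yield NaN, never a silent 0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ReflectanceCube
from .spectral import SpectralGrid

__all__ = ["ViDefinition", "VI_TABLE", "compute_vi", "compute_vi_matrix"]

_TOKEN_RE = re.compile(r"R(\d+)")
_ALLOWED_RE = re.compile(r"^[\sRv_0-9+\-*/().]+$")


@dataclass(frozen=True)
class ViDefinition:
    """A named vegetation index: required wavelengths plus a formula string."""

    name: str
    expression: str
    wavelengths: tuple = field(init=False)

    def __post_init__(self) -> None:
        wl = tuple(sorted({int(m) for m in _TOKEN_RE.findall(self.expression)}))
        if not wl:
            raise ValueError(f"{self.name}: expression references no R<nm> band")
        if not _ALLOWED_RE.match(self.expression):
            raise ValueError(f"{self.name}: expression contains unsupported tokens")
        object.__setattr__(self, "wavelengths", wl)


_VI_EXPRESSIONS = [
    ("PRI", "(R531-R570)/(R531+R570)"),
    ("NGRDI", "(R550-R665)/(R550+R665)"),
    ("GLI", "((R550-R665)+(R550-R490))/((R550+R665)+(R550+R490))"),
    ("CIG", "R865/R550-1"),
    ("NDVI", "(R865-R680)/(R865+R680)"),
    ("CVI", "(R865*R705)/(R550*R550)"),
    ("ARI1", "1/R550-1/R700"),
    ("ARI2", "R800*(1/R550-1/R700)"),
    ("GNDVI", "(R780-R550)/(R780+R550)"),
    ("NDRE", "(R790-R720)/(R790+R720)"),
    ("REIP", "700+40*((R670+R780)/2-R700)/(R740-R700)"),
    ("MCARI", "((R700-R670)-0.2*(R700-R550))*(R700/R670)"),
    ("MRENDVI", "(R750-R705)/(R750+R705-2*R445)"),
    ("MRESR", "(R750-R445)/(R705-R445)"),
    ("MTVI", "1.2*(1.2*(R800-R550)-2.5*(R670-R550))"),
    ("TVI", "60*(R750-R550)-100*(R670-R550)"),
    ("VREI1", "R740/R720"),
    ("VREI2", "(R734-R747)/(R715+R726)"),
    ("SIPI", "(R800-R445)/(R800-R680)"),
    ("PSRI", "(R680-R500)/R750"),
    ("CRI1", "1/R510-1/R550"),
    ("CRI2", "1/R510-1/R700"),
    ("CSI", "2.5*(R490/R705)*(R865-R705)/(R865+R705)"),
    ("LICI", "(R735/R720)-((R573-R680)/(R573+R680))"),
]

#: The default 24-index bank.
VI_TABLE: tuple[ViDefinition, ...] = tuple(
    ViDefinition(name, expr) for name, expr in _VI_EXPRESSIONS
)


def _compile(definition: ViDefinition):
    """Turn an expression string into a function of a {nm: value} mapping."""
    expr = _TOKEN_RE.sub(lambda m: f"v_{m.group(1)}", definition.expression)
    code = compile(expr, f"<VI {definition.name}>", "eval")

    def fn(bands: dict):
        env = {f"v_{nm}": bands[nm] for nm in definition.wavelengths}
        with np.errstate(divide="ignore", invalid="ignore"):
            out = eval(code, {"__builtins__": {}}, env)  # noqa: S307 — grammar-validated
        return out

    return fn


def compute_vi(spectrum, grid: SpectralGrid, definition: ViDefinition):
    """Evaluate one vegetation index on a spectrum (or an (n, B) stack).

    Wavelengths resolve by nearest-band lookup; divisions by zero come back
    NaN (flagged undefined).
    """
    arr = np.asarray(spectrum, dtype=float)
    vec = arr.ndim == 1
    mat = arr[None, :] if vec else arr
    bands = {nm: mat[:, grid.nearest_band(nm)] for nm in definition.wavelengths}
    out = np.asarray(_compile(definition)(bands), dtype=float)
    out = np.where(np.isfinite(out), out, np.nan)
    return float(out[0]) if vec else out


def compute_vi_matrix(
    cube: ReflectanceCube,
    footprints,
    table: tuple[ViDefinition, ...] = VI_TABLE,
) -> pd.DataFrame:
    """Per-pixel VI features for every footprint of a single-date cube.

    Returns ``plot_id`` plus one named column per index in ``table``
    (24 with the default bank), pixel order matching
    :func:`paddyspec.io.extract_plot_pixels`.
    """
    from .io import extract_plot_pixels

    pairs = extract_plot_pixels(cube, cube, footprints)
    spectra = pairs.r_early
    cols = {d.name: compute_vi(spectra, cube.grid, d) for d in table}
    df = pd.DataFrame(cols)
    df.insert(0, "plot_id", pairs.plot_id)
    return df
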