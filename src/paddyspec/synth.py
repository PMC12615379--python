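"""Synthetic dual-date paddy-field scenes with known ground truth.

No UAV hyperspectral imagery is publicly deposited for early
brown-planthopper (BPH) monitoring at plot scale, so every downstream stage
is exercised on simulated scenes built from two field-motivated
assumptions:

1. healthy rice canopy reflectance changes predictably between two nearby
   dates — essentially a wavelength-dependent multiplicative growth gain,
   largest on the NIR plateau;
2. BPH feeding perturbs the magnitude of that change: the T2−T1 difference
   spectrum is pushed up in the 399–750 nm region and down in the
   750–1006 nm region, proportionally to severity.

On top of the clean signal the generator layers per-pixel multiplicative
illumination gain (sunlit/shaded leaves, independent per date), additive
sensor noise, water/soil mixing on plot-edge pixels, within-plot
heterogeneity (only a fraction of a stressed plot's pixels carry the full
effect — five-point count sampling leaves real pixel-level label noise),
and plot-count drift between the two survey dates so that some plots cross
severity boundaries from one date to the next.

The configuration's seed fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grading import SEVERITY_LEVELS, SEVERITY_RANK, PlotSurvey, grade
from .io import PlotFootprint, ReflectanceCube
from .spectral import SpectralGrid, default_grid

__all__ = ["SynthConfig", "GroundTruth", "SyntheticScene", "make_endmembers", "simulate_scene"]


@dataclass(frozen=True)
class Endmembers:
    """Pure-material spectra on a grid: healthy canopy at T1, water, soil."""

    canopy: np.ndarray
    water: np.ndarray
    soil: np.ndarray
    grid: SpectralGrid


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic scene.

    Defaults mirror the field layout: 52 one-metre observation plots of
    21 px side on a ~5 cm ground-sampling-distance mosaic, with the
    moderate class dominant (6/42/4 mild/moderate/severe plots) and an
    8-day gap between surveys over which per-plot BPH counts drift.
    """

    grid: SpectralGrid = field(default_factory=default_grid)
    rows: int = 150
    cols: int = 240
    plot_side: int = 21
    n_plots: int = 52
    #: mild/moderate/severe plot proportions; must sum to 1
    class_mix: tuple = (6 / 52, 42 / 52, 4 / 52)
    #: multiplicative healthy growth gain in the visible and on the NIR plateau
    growth_gain_vis: float = 1.02
    growth_gain_nir: float = 1.18
    #: severity effect size: reflectance-difference shift per severity rank
    delta: float = 0.02
    #: fraction of the severity effect already imprinted on the T1 spectrum
    #: (infestation predates the first flight; single-date signal is weaker
    #: and less consistent than the between-date change)
    t1_effect: float = 0.4
    #: fraction of a stressed plot's pixels carrying the full effect
    stressed_fraction: float = 0.8
    #: sd of the log-normal per-pixel, per-date illumination gain
    illum_sigma: float = 0.02
    #: probability that a plot-edge pixel mixes with water/soil background
    edge_mix_prob: float = 0.15
    #: range of the background mixing coefficient on affected edge pixels
    mix_range: tuple = (0.1, 0.4)
    #: sd of the between-date per-plot count drift (individuals per clump)
    drift_sd: float = 3.0
    #: additive Gaussian sensor noise sd (reflectance units)
    noise_sd: float = 0.005
    #: gap (pixels) kept between neighbouring plot footprints
    plot_gap: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_mix) != len(SEVERITY_LEVELS):
            raise ValueError("class_mix needs one proportion per severity level")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if min(self.class_mix) < 0:
            raise ValueError("class proportions must be non-negative")

    def with_(self, **kw) -> "SynthConfig":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """What the generator knows: per-plot severity and per-pixel labels."""

    plot_severity: dict  # plot_id -> dual-date severity label
    counts_t1: dict  # plot_id -> plot-mean count at T1
    counts_t2: dict
    label_map: np.ndarray  # (rows, cols) str labels, 'unassessed' off-plot
    stressed_mask: np.ndarray  # (rows, cols) bool: pixel carries the effect


@dataclass
class SyntheticScene:
    """A simulated T1/T2 cube pair with plots, surveys and ground truth."""

    cube_t1: ReflectanceCube
    cube_t2: ReflectanceCube
    footprints: list
    surveys: list
    truth: GroundTruth
    config: SynthConfig


# ---------------------------------------------------------------------------
# Endmembers
# ---------------------------------------------------------------------------

def make_endmembers(grid: SpectralGrid, seed: int = 0) -> Endmembers:
    """Healthy-canopy, water and soil spectra on ``grid``.

    The canopy curve shows the classic vegetation shape: a green peak near
    550 nm, chlorophyll absorption near 670 nm, the red-edge rise over
    680–750 nm and a NIR plateau well above the visible.  Water is dark and
    nearly opaque in the NIR (< 0.05); soil is a brightening linear ramp.
    A small smooth seeded perturbation individualizes repeated draws.
    """
    wl = grid.wavelengths
    if wl[0] > 420 or wl[-1] < 900:
        raise ValueError("endmembers need a grid covering the visible and NIR plateau")
    rng = np.random.default_rng(seed)

    canopy = (
        0.035
        + 0.055 * np.exp(-(((wl - 550.0) / 30.0) ** 2))
        + (0.45 - 0.035) / (1.0 + np.exp(-(wl - 715.0) / 12.0))
    )
    water = 0.05 * np.exp(-(wl - wl[0]) / 250.0)
    soil = 0.12 + 0.20 * (wl - wl[0]) / (wl[-1] - wl[0])

    # smooth, small random individuality (single low-frequency cosine)
    phase = rng.uniform(0, 2 * np.pi)
    wiggle = 0.003 * np.cos(2 * np.pi * (wl - wl[0]) / (wl[-1] - wl[0]) + phase)
    canopy = canopy * (1.0 + rng.normal(0, 0.02)) + wiggle
    return Endmembers(canopy=canopy, water=water, soil=soil, grid=grid)


# ---------------------------------------------------------------------------
# Scene assembly
# ---------------------------------------------------------------------------

def _place_footprints(cfg: SynthConfig) -> list:
    """Disjoint square footprints on a regular raster with a small gap."""
    pitch = cfg.plot_side + cfg.plot_gap
    per_row = (cfg.cols - cfg.plot_gap) // pitch
    per_col = (cfg.rows - cfg.plot_gap) // pitch
    if per_row * per_col < cfg.n_plots:
        raise ValueError(
            f"scene {cfg.rows}x{cfg.cols} holds at most {per_row * per_col} "
            f"disjoint plots of side {cfg.plot_side}; {cfg.n_plots} requested"
        )
    fps = []
    for k in range(cfg.n_plots):
        r, c = divmod(k, per_row)
        fps.append(
            PlotFootprint(
                plot_id=k + 1,
                row0=cfg.plot_gap + r * pitch,
                col0=cfg.plot_gap + c * pitch,
                side=cfg.plot_side,
            )
        )
    return fps


def _allocate_classes(cfg: SynthConfig, rng) -> list:
    """Largest-remainder allocation of plots to severity classes, shuffled."""
    quotas = np.array(cfg.class_mix) * cfg.n_plots
    counts = np.floor(quotas).astype(int)
    for i in np.argsort(-(quotas - counts)):
        if counts.sum() >= cfg.n_plots:
            break
        counts[i] += 1
    labels = [lab for lab, n in zip(SEVERITY_LEVELS, counts) for _ in range(n)]
    rng.shuffle(labels)
    return labels


#: dual-date-mean sampling windows per class, kept off the 5/10 boundaries
_MEAN_WINDOWS = {"mild": (0.8, 4.4), "moderate": (5.4, 9.6), "severe": (10.8, 24.0)}


def _draw_counts(label: str, cfg: SynthConfig, rng) -> tuple[float, float]:
    """Plot-mean counts at the two dates whose average grades to ``label``.

    Counts are quantized to 0.2 (means of five integer clump counts); the
    drift between dates has sd ``cfg.drift_sd``, so single-date grades may
    disagree with the dual-date grade.
    """
    lo, hi = _MEAN_WINDOWS[label]
    for _ in range(200):
        m = rng.uniform(lo, hi)
        d = rng.normal(0.0, cfg.drift_sd)
        d = float(np.clip(d, -2 * m, 2 * m))  # both dates stay non-negative
        t1 = round((m + d / 2) / 0.2) * 0.2
        t2 = round((m - d / 2) / 0.2) * 0.2
        t1, t2 = max(t1, 0.0), max(t2, 0.0)
        if grade((t1 + t2) / 2.0) == label:
            return t1, t2
    raise RuntimeError("could not draw counts consistent with the class label")


def simulate_scene(config: SynthConfig | None = None) -> SyntheticScene:
    """Simulate a co-registered T1/T2 reflectance cube pair with ground truth.

    Healthy pixels follow ``R_T2 = g(λ) · R_T1`` (plus noise) with the
    growth gain largest in the NIR.  Pixels carrying stress have the T2−T1
    difference shifted by ``rank · δ`` upward below 750 nm and downward
    above it, where rank is 1/2/3 for mild/moderate/severe.  Emitted counts
    always re-grade to the emitted severity label.
    """
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.grid
    wl = grid.wavelengths
    B = grid.n_bands

    em = make_endmembers(grid, seed=int(rng.integers(2**31)))
    fps = _place_footprints(cfg)
    labels = _allocate_classes(cfg, rng)

    # growth gain: logistic blend from the visible gain to the NIR gain
    blend = 1.0 / (1.0 + np.exp(-(wl - 725.0) / 15.0))
    g = cfg.growth_gain_vis + (cfg.growth_gain_nir - cfg.growth_gain_vis) * blend
    # stress shape: +1 short-wave, −1 long-wave, smooth hand-off near 750 nm
    u = np.tanh((750.0 - wl) / 20.0)
    # T1 imprint shape: chlorosis-like visible rise, mild NIR rise (severe
    # plots showed slightly elevated NIR even on the first date)
    u1 = 0.3 + 0.7 * (1.0 + np.tanh((750.0 - wl) / 20.0)) / 2.0

    shape = (cfg.rows, cfg.cols)
    base_t1 = np.empty(shape + (B,), dtype=np.float32)
    clean_t2 = np.empty_like(base_t1)

    # background: healthy canopy everywhere outside the plots
    bg_gain = rng.normal(1.0, 0.04, size=shape).astype(np.float32)
    base_t1[:] = bg_gain[..., None] * em.canopy.astype(np.float32)
    clean_t2[:] = base_t1 * g.astype(np.float32)

    label_map = np.full(shape, "unassessed", dtype=object)
    stressed_mask = np.zeros(shape, dtype=bool)
    surveys, counts_t1, counts_t2, severities = [], {}, {}, {}

    for fp, label in zip(fps, labels):
        t1c, t2c = _draw_counts(label, cfg, rng)
        label = grade((t1c + t2c) / 2.0)  # by construction equals the draw target
        rs, cs = fp.slices()
        rank = SEVERITY_RANK[label]

        plot_gain = rng.normal(1.0, 0.03)
        pix_gain = rng.normal(1.0, 0.02, size=(fp.side, fp.side, 1))
        plot_base = (plot_gain * pix_gain * em.canopy).astype(np.float32)

        # edge pixels occasionally mix with water or soil (same on both dates)
        edge = np.zeros((fp.side, fp.side), dtype=bool)
        edge[[0, -1], :] = True
        edge[:, [0, -1]] = True
        mixing = edge & (rng.random((fp.side, fp.side)) < cfg.edge_mix_prob)
        alpha = rng.uniform(*cfg.mix_range, size=(fp.side, fp.side, 1))
        bg_spec = np.where(
            rng.random((fp.side, fp.side, 1)) < 0.5, em.water, em.soil
        ).astype(np.float32)
        mixed = np.where(
            mixing[..., None], (1 - alpha) * plot_base + alpha * bg_spec, plot_base
        ).astype(np.float32)

        stressed = rng.random((fp.side, fp.side)) < cfg.stressed_fraction
        imprint = (rank * cfg.delta * cfg.t1_effect) * u1.astype(np.float32)
        t1_clean = mixed + stressed[..., None] * imprint
        effect = (rank * cfg.delta) * u.astype(np.float32)
        t2_clean = t1_clean * g.astype(np.float32) + stressed[..., None] * effect

        base_t1[rs, cs] = t1_clean
        clean_t2[rs, cs] = t2_clean
        label_map[rs, cs] = label
        stressed_mask[rs, cs] = stressed

        surveys.append(PlotSurvey(plot_id=fp.plot_id, mean_t1=t1c, mean_t2=t2c))
        counts_t1[fp.plot_id], counts_t2[fp.plot_id] = t1c, t2c
        severities[fp.plot_id] = label

    # independent per-date illumination and sensor noise
    def observe(clean: np.ndarray) -> np.ndarray:
        gain = np.exp(rng.normal(0.0, cfg.illum_sigma, size=shape)).astype(np.float32)
        noisy = gain[..., None] * clean + rng.normal(
            0.0, cfg.noise_sd, size=clean.shape
        ).astype(np.float32)
        return np.clip(noisy, 0.0, 1.2)

    cube_t1 = ReflectanceCube(values=observe(base_t1), grid=grid, date="T1")
    cube_t2 = ReflectanceCube(values=observe(clean_t2), grid=grid, date="T2")

    truth = GroundTruth(
        plot_severity=severities,
        counts_t1=counts_t1,
        counts_t2=counts_t2,
        label_map=label_map,
        stressed_mask=stressed_mask,
    )
    return SyntheticScene(
        cube_t1=cube_t1,
        cube_t2=cube_t2,
        footprints=fps,
        surveys=surveys,
        truth=truth,
        config=cfg,
    )
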