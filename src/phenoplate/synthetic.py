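"""Synthetic colony-array data: plate images, growth-curve panels and
multi-plate fitness experiments.

Everything downstream — segmentation, slope extraction, normalisation, QC
and differential testing — is exercised on data from this module, with full
knowledge of the ground truth.  The generative model is deliberately close
to how arrayed screens actually behave:

* colony values are **multiplicative**: base x strain effect x smooth
  spatial gradient x lognormal noise (colony sizes are positive and noise
  scales with the mean, hence the CV parameterisation);
* the spatial gradient is a separable cosine surface, a smooth low-order
  stand-in for temperature/moisture/nutrient gradients across a plate;
* growth curves are logistic with strain- and position-specific rates,
  sampled every 20 minutes over 48 hours by default (the standard
  timecourse imaging schedule);
* plate images render colonies as anti-aliased disks (radius proportional
  to sqrt(size)); RGB images mix a cream colony colour with the red of a
  phloxine B-stained colony in proportion to each strain's dead-cell
  fraction.

All outputs are pure functions of the configuration (seeded).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DimensionMismatchError
from .imaging import (
    REFLECTIVE_RGB,
    TRANSMISSION_GREY,
    GridSpec,
    PlateImage,
    TimecourseTable,
)
from .normalise import EMPTY_STRAIN, PlateLayout, make_layout


@dataclass
class SimulationConfig:
    """Knobs of the generative model.

    ``gradient_amplitude`` is the peak-to-trough fraction of the
    multiplicative spatial surface (0.2 = ±10% around 1).  ``noise_cv`` is
    the coefficient of variation of the lognormal observation noise.
    ``strain_effects`` maps strain name to relative fitness (unlisted
    strains default to ``default_effect``; set ``default_effect=None`` to
    make unknown strains an error).  ``dead_fraction`` maps strain name to
    the fraction of dead cells driving colony redness.
    """

    format: int = 384
    gradient_amplitude: float = 0.2
    noise_cv: float = 0.05
    strain_effects: dict = field(default_factory=dict)
    default_effect: float | None = 1.0
    dead_fraction: dict = field(default_factory=dict)
    default_dead_fraction: float = 0.05
    seed: int = 0
    base_value: float = 100.0
    # image rendering
    image_colony_radius: float = 8.0
    image_pitch: int = 24
    image_margin: int = 24
    axis_ratio: float = 1.0  # >1 renders ellipses (low circularity)
    # logistic growth
    growth_k: float = 100.0
    growth_r_mean: float = 0.5
    growth_r_sd: float = 0.1
    growth_t0_mean: float = 10.0
    growth_t0_sd: float = 1.0
    sampling_interval: float = 1.0 / 3.0  # hours (20 min)
    duration: float = 48.0  # hours

    def __post_init__(self) -> None:
        if self.gradient_amplitude < 0 or self.noise_cv < 0:
            raise ConfigurationError("gradient_amplitude and noise_cv must be >= 0")
        for strain, frac in self.dead_fraction.items():
            if not 0 <= frac <= 1:
                raise ConfigurationError(f"dead_fraction[{strain!r}] must lie in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def gradient_surface(n_rows: int, n_cols: int, amplitude: float) -> np.ndarray:
    """Separable cosine surface with the requested peak-to-trough span."""
    r = np.arange(n_rows) / max(n_rows - 1, 1)
    c = np.arange(n_cols) / max(n_cols - 1, 1)
    surf = np.cos(np.pi * r)[:, None] * np.cos(np.pi * c)[None, :]
    return 1.0 + (amplitude / 2.0) * surf


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Unit-mean multiplicative noise with the given coefficient of variation."""
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=shape)


def _effect_of(config: SimulationConfig, strain: str) -> float:
    if strain in config.strain_effects:
        return float(config.strain_effects[strain])
    if config.default_effect is None:
        raise ConfigurationError(f"strain {strain!r} has no configured effect")
    return float(config.default_effect)


def simulate_fitness_plate(
    config: SimulationConfig, layout: PlateLayout
) -> tuple[np.ndarray, pd.DataFrame]:
    """One plate of endpoint colony values plus its ground-truth table.

    value(r, c) = base x strain_effect x gradient(r, c) x lognormal noise.
    Positions whose layout strain is ``"empty"`` come out missing.
    Returns (observed matrix, truth table with per-position expectation).
    """
    shape = {96: (8, 12), 384: (16, 24), 1536: (32, 48)}.get(config.format)
    if shape is not None and (layout.n_rows, layout.n_cols) != shape:
        raise ConfigurationError(
            f"layout {(layout.n_rows, layout.n_cols)} does not match format {config.format}"
        )
    rng = config.rng()
    grad = gradient_surface(layout.n_rows, layout.n_cols, config.gradient_amplitude)
    effects = np.vectorize(lambda s: np.nan if s == EMPTY_STRAIN else _effect_of(config, s))(
        layout.strain
    ).astype(float)
    expected = config.base_value * effects * grad
    observed = expected * _lognormal_noise(rng, config.noise_cv, expected.shape)
    rr, cc = np.meshgrid(np.arange(layout.n_rows), np.arange(layout.n_cols), indexing="ij")
    truth = pd.DataFrame(
        {
            "row": rr.ravel(),
            "col": cc.ravel(),
            "strain": layout.strain.ravel(),
            "is_grid": layout.is_grid.ravel(),
            "effect": effects.ravel(),
            "gradient": grad.ravel(),
            "expected": expected.ravel(),
        }
    )
    return observed, truth


# ---------------------------------------------------------------------------
# image rendering

_GREY_BACKGROUND = 0.85
_GREY_COLONY = 0.25
_RGB_BACKGROUND = np.array([0.92, 0.92, 0.92])
_RGB_COLONY = np.array([0.80, 0.72, 0.55])  # healthy, unstained colony
_RGB_STAIN = np.array([0.75, 0.12, 0.15])  # fully phloxine B-stained colony


def simulate_plate_image(
    config: SimulationConfig,
    layout: PlateLayout,
    sizes: np.ndarray,
    mode: str = "grey",
) -> PlateImage:
    """Render a plate image with one anti-aliased disk per non-zero size.

    Disk radius is ``image_colony_radius * sqrt(size / base_value)``; grey
    mode renders dark colonies on a light background (transmission-style),
    RGB mode colours each colony by mixing the base colony colour with the
    stain colour in proportion to the strain's dead-cell fraction.
    """
    sizes = np.asarray(sizes, dtype=float)
    if sizes.shape != (layout.n_rows, layout.n_cols):
        raise DimensionMismatchError(
            f"sizes {sizes.shape} do not match layout {(layout.n_rows, layout.n_cols)}"
        )
    if mode not in ("grey", "rgb"):
        raise ConfigurationError(f"unknown image mode {mode!r}")
    pitch, margin = config.image_pitch, config.image_margin
    height = max(64, 2 * margin + pitch * (layout.n_rows - 1) + 1)
    width = max(64, 2 * margin + pitch * (layout.n_cols - 1) + 1)
    if mode == "grey":
        canvas = np.full((height, width), _GREY_BACKGROUND)
    else:
        canvas = np.tile(_RGB_BACKGROUND, (height, width, 1))

    for r in range(layout.n_rows):
        for c in range(layout.n_cols):
            size = sizes[r, c]
            if not np.isfinite(size) or size <= 0:
                continue
            radius = config.image_colony_radius * np.sqrt(size / config.base_value)
            if radius < 0.5:
                continue
            cy = margin + r * pitch
            cx = margin + c * pitch
            half = int(np.ceil(radius * max(config.axis_ratio, 1.0))) + 2
            y0, y1 = max(cy - half, 0), min(cy + half + 1, height)
            x0, x1 = max(cx - half, 0), min(cx + half + 1, width)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            dist = np.hypot(yy - cy, (xx - cx) / config.axis_ratio)
            alpha = np.clip(radius + 0.5 - dist, 0.0, 1.0)
            if mode == "grey":
                canvas[y0:y1, x0:x1] = canvas[y0:y1, x0:x1] + alpha * (
                    _GREY_COLONY - canvas[y0:y1, x0:x1]
                )
            else:
                strain = layout.strain[r, c]
                dead = float(config.dead_fraction.get(strain, config.default_dead_fraction))
                colour = (1 - dead) * _RGB_COLONY + dead * _RGB_STAIN
                canvas[y0:y1, x0:x1] = canvas[y0:y1, x0:x1] + alpha[..., None] * (
                    colour - canvas[y0:y1, x0:x1]
                )
    image_mode = TRANSMISSION_GREY if mode == "grey" else REFLECTIVE_RGB
    return PlateImage(np.clip(canvas, 0, 1), image_mode, source_path="<synthetic>")


def simulate_growth_panel(
    config: SimulationConfig, layout: PlateLayout
) -> tuple[TimecourseTable, pd.DataFrame]:
    """Logistic growth curves for every non-empty position plus the truth.

    Each position grows as K / (1 + exp(-r (t - t0))) with r drawn from
    N(growth_r_mean, growth_r_sd) scaled by the strain effect and the
    spatial gradient; observations carry multiplicative lognormal noise.
    The truth table records each position's analytic maximum slope rK/4.
    """
    if config.growth_k <= 0:
        raise ConfigurationError("carrying capacity K must be positive")
    if config.sampling_interval <= 0:
        raise ConfigurationError("sampling interval must be positive")
    rng = config.rng()
    t = np.arange(0.0, config.duration + 1e-9, config.sampling_interval)
    grad = gradient_surface(layout.n_rows, layout.n_cols, config.gradient_amplitude)
    columns, curves, truth_rows = [], [], []
    for r in range(layout.n_rows):
        for c in range(layout.n_cols):
            strain = layout.strain[r, c]
            if strain == EMPTY_STRAIN:
                continue
            rate = max(rng.normal(config.growth_r_mean, config.growth_r_sd), 0.01)
            rate *= _effect_of(config, strain) * grad[r, c]
            t0 = rng.normal(config.growth_t0_mean, config.growth_t0_sd)
            y = config.growth_k / (1.0 + np.exp(-rate * (t - t0)))
            y = y * _lognormal_noise(rng, config.noise_cv, y.shape)
            columns.append(f"{r}-{c}")
            curves.append(y)
            truth_rows.append(
                {
                    "position": f"{r}-{c}",
                    "row": r,
                    "col": c,
                    "strain": strain,
                    "r": rate,
                    "t0": t0,
                    "max_slope_true": rate * config.growth_k / 4.0,
                }
            )
    table = TimecourseTable(pd.DataFrame(np.column_stack(curves), index=t, columns=columns))
    return table, pd.DataFrame(truth_rows)


def simulate_wild_strain_plate(
    seed: int,
    fmt: int = 1536,
    gradient_amplitude: float = 0.8,
    effect_sigma: float = 0.25,
    noise_cv: float = 0.05,
) -> tuple[PlateLayout, np.ndarray, pd.DataFrame]:
    """A dense array of wild isolates under a strong plate gradient.

    Wild strains span a broad fitness range (lognormal spread
    ``effect_sigma`` = 0.25, i.e. roughly 4-fold between the extremes, so
    biological signal dominates control noise), and the plate carries a
    strong smooth spatial gradient (peak-to-trough ``gradient_amplitude`` =
    0.8) of the kind that dominates uncorrected readouts of high-density
    arrays.  This is the standard scenario for spatial-bias diagnostics:
    uncorrected values show strong neighbour correlation, which grid
    normalisation must remove without over-correcting.
    """
    layout = make_layout(fmt, grid_scheme="topleft96")
    rng = np.random.default_rng(seed)
    effects = {
        s: float(rng.lognormal(0.0, effect_sigma))
        for s in np.unique(layout.strain)
        if s not in ("grid", EMPTY_STRAIN)
    }
    effects["grid"] = 1.0
    config = SimulationConfig(
        format=fmt,
        gradient_amplitude=gradient_amplitude,
        noise_cv=noise_cv,
        strain_effects=effects,
        seed=seed,
    )
    values, truth = simulate_fitness_plate(config, layout)
    return layout, values, truth


def simulate_screen_table(
    config: SimulationConfig,
    strains: list[str],
    conditions: list[str],
    n_replicates: int = 3,
    condition_effects: dict | None = None,
) -> pd.DataFrame:
    """Long replicate table for statistical calibration studies.

    One corrected-fitness value per (strain, condition, replicate), drawn
    around strain_effect x condition modifier with lognormal noise of the
    configured CV — i.e. post-normalisation data with no plate structure.
    """
    rng = config.rng()
    condition_effects = condition_effects or {}
    rows = []
    for condition in conditions:
        mods = condition_effects.get(condition, {})
        for strain in strains:
            level = _effect_of(config, strain) * float(mods.get(strain, 1.0))
            vals = level * _lognormal_noise(rng, config.noise_cv, n_replicates)
            for i, v in enumerate(vals):
                rows.append(
                    {
                        "strain": strain,
                        "condition": condition,
                        "replicate": i,
                        "is_grid": False,
                        "corrected_value": v,
                    }
                )
    return pd.DataFrame(rows)


def simulate_experiment(
    config: SimulationConfig,
    out_dir: str | os.PathLike,
    conditions: list[str],
    n_replicates: int = 3,
    n_strains: int = 238,
    condition_effects: dict | None = None,
    filler_strain: str = "wt-control",
    affected_fraction: float = 0.3,
    effect_sigma: float = 0.25,
) -> str:
    """Write a complete multi-plate experiment to disk; returns the EDT path.

    A 384-format layout with the top-left 96 reference grid carries
    ``n_strains`` mutant strains (plus a neutral filler strain on leftover
    positions).  Per-strain effects come from ``config.strain_effects``;
    strains absent there are drawn once from a spike-and-slab mixture —
    neutral (exactly 1.0) with probability ``1 - affected_fraction``,
    otherwise lognormal with spread ``effect_sigma``.  The neutral majority
    mirrors a knock-out collection, the setting in which row/column median
    normalisation is valid.  Each (condition, replicate) pair becomes
    one plate: per-plate data CSV (long format with circularity), a shared
    layout CSV and grid-flag CSV, and one EDT row; the first condition is
    flagged as the control.  The analyse -> qc -> interpret pipeline runs on
    the written files unmodified.
    """
    if n_replicates < 1 or not conditions:
        raise ConfigurationError("need >= 1 replicate and >= 1 condition")
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rng = config.rng()
    condition_effects = condition_effects or {}

    layout = make_layout(384, grid_scheme="topleft96")
    strain_names = [f"mut{i:03d}" for i in range(n_strains)]
    free = np.argwhere(~layout.is_grid)
    if n_strains > len(free):
        raise ConfigurationError(f"{n_strains} strains do not fit on {len(free)} free positions")
    for i, (r, c) in enumerate(free):
        layout.strain[r, c] = strain_names[i] if i < n_strains else filler_strain
    layout_path = os.path.join(out_dir, "layout.csv")
    grid_path = os.path.join(out_dir, "layout_grid.csv")
    layout.to_csv(layout_path, grid_path)

    effects = dict(config.strain_effects)
    for name in strain_names:
        if name not in effects:
            affected = rng.uniform() < affected_fraction
            effects[name] = float(rng.lognormal(0.0, effect_sigma)) if affected else 1.0
    effects.setdefault("grid", 1.0)
    effects.setdefault(filler_strain, 1.0)

    edt_rows = []
    plate_seed = config.seed
    for condition in conditions:
        mods = condition_effects.get(condition, {})
        cond_effects = {s: e * float(mods.get(s, 1.0)) for s, e in effects.items()}
        for rep in range(n_replicates):
            plate_seed = (plate_seed + 9973) % (2**31)
            plate_cfg = SimulationConfig(
                format=384,
                gradient_amplitude=config.gradient_amplitude,
                noise_cv=config.noise_cv,
                strain_effects=cond_effects,
                seed=plate_seed,
                base_value=config.base_value,
            )
            values, _ = simulate_fitness_plate(plate_cfg, layout)
            plate_id = f"{condition}_rep{rep}"
            rr, cc = np.meshgrid(np.arange(layout.n_rows), np.arange(layout.n_cols), indexing="ij")
            circ_rng = np.random.default_rng(plate_seed + 1)
            data = pd.DataFrame(
                {
                    "row": rr.ravel(),
                    "col": cc.ravel(),
                    "strain": layout.strain.ravel(),
                    "value": values.ravel(),
                    "circularity": np.clip(
                        circ_rng.normal(0.97, 0.015, values.size), 0.0, 1.2
                    ),
                }
            )
            data_path = os.path.join(out_dir, f"{plate_id}.csv")
            data.to_csv(data_path, index=False)
            edt_rows.append(
                {
                    "plate_id": plate_id,
                    "data_path": os.path.basename(data_path),
                    "layout_path": os.path.basename(layout_path),
                    "grid_path": os.path.basename(grid_path),
                    "condition": condition,
                    "control": int(condition == conditions[0]),
                    "batch": rep,
                }
            )
    edt_path = os.path.join(out_dir, "edt.csv")
    pd.DataFrame(edt_rows).to_csv(edt_path, index=False)
    truth = pd.DataFrame(
        {"strain": list(effects), "effect": [effects[s] for s in effects]}
    )
    truth.to_csv(os.path.join(out_dir, "truth_effects.csv"), index=False)
    return edt_path
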