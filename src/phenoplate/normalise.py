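"""Spatial and batch-effect normalisation of colony-array plates.

Two complementary corrections are provided:

* **Reference-grid normalisation** — a control strain pinned at known grid
  positions defines the expected local growth; an interpolated reference
  surface over those controls divides every measurement, so a corrected
  value of 1 means "grows like the control here".
* **Row/column median normalisation** — every value is divided by its row
  median and then by the recomputed column median, assuming most strains in
  each row/column are phenotypically neutral.  This also removes the
  secondary edge effect that grid correction can leave in the first inward
  row/column.

When both are requested, the grid correction is applied first.
:func:`aggregate_experiment` drives the whole thing from an Experimental
Design Table (EDT, one row per plate) and emits one long table with one row
per colony across the entire experiment.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator, RegularGridInterpolator
from scipy.spatial import QhullError

from .exceptions import (
    ConfigurationError,
    DegenerateGridError,
    DimensionMismatchError,
    SchemaError,
    ZeroMedianError,
)

log = logging.getLogger(__name__)

_FORMAT_SHAPES = {96: (8, 12), 384: (16, 24), 1536: (32, 48)}

#: Placeholder strain name for positions that carry no colony by design.
EMPTY_STRAIN = "empty"


@dataclass
class PlateLayout:
    """Strain identity and reference-grid flag per (row, col) position."""

    strain: np.ndarray  # 2-D object array of strain names
    is_grid: np.ndarray  # 2-D boolean array

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=object)
        self.is_grid = np.asarray(self.is_grid, dtype=bool)
        if self.strain.shape != self.is_grid.shape or self.strain.ndim != 2:
            raise DimensionMismatchError("strain and is_grid must be equal-shape 2-D arrays")

    @property
    def n_rows(self) -> int:
        return self.strain.shape[0]

    @property
    def n_cols(self) -> int:
        return self.strain.shape[1]

    @classmethod
    def from_csv(cls, strain_path, grid_path=None, grid_strain: str | None = None) -> "PlateLayout":
        """Read a strain-name matrix CSV; grid flags come from a parallel
        0/1 matrix CSV or from all positions matching ``grid_strain``."""
        strain = pd.read_csv(strain_path, header=None).to_numpy(dtype=object)
        strain = np.vectorize(lambda s: str(s).strip())(strain).astype(object)
        if grid_path is not None:
            flags = pd.read_csv(grid_path, header=None)
            try:
                is_grid = flags.to_numpy(dtype=float).astype(bool)
            except (TypeError, ValueError) as exc:
                raise SchemaError(f"grid-flag file {grid_path} is not a 0/1 matrix") from exc
        elif grid_strain is not None:
            is_grid = strain == grid_strain
        else:
            is_grid = np.zeros(strain.shape, dtype=bool)
        return cls(strain, is_grid)

    def to_csv(self, strain_path, grid_path=None) -> None:
        pd.DataFrame(self.strain).to_csv(strain_path, header=False, index=False)
        if grid_path is not None:
            pd.DataFrame(self.is_grid.astype(int)).to_csv(grid_path, header=False, index=False)


def make_layout(fmt: int, grid_scheme: str = "topleft96", custom_grid_path=None) -> PlateLayout:
    """Standard plate layouts with a 96-position reference grid.

    ``topleft96`` in 384 format marks the top-left position of every 2x2
    block (one control in every fourth position).  In 1536 format the 96
    grid positions are spread as evenly as 8x12 positions allow in 32x48,
    with controls present in all four border rows/columns so the reference
    surface never extrapolates far beyond its support.  ``none`` marks no
    grid; ``custom`` reads flags from a 0/1 matrix CSV.
    """
    if fmt not in _FORMAT_SHAPES:
        raise ConfigurationError(f"unknown format {fmt}; use 96, 384 or 1536")
    n_rows, n_cols = _FORMAT_SHAPES[fmt]
    is_grid = np.zeros((n_rows, n_cols), dtype=bool)
    if grid_scheme == "none":
        pass
    elif grid_scheme == "topleft96":
        if fmt == 96:
            is_grid[:, :] = True
        elif fmt == 384:
            is_grid[::2, ::2] = True
        else:  # 1536: even spread with grid colonies on every border
            rows = np.round(np.linspace(0, n_rows - 1, 8)).astype(int)
            cols = np.round(np.linspace(0, n_cols - 1, 12)).astype(int)
            is_grid[np.ix_(rows, cols)] = True
    elif grid_scheme == "custom":
        if custom_grid_path is None:
            raise ConfigurationError("custom grid scheme needs custom_grid_path")
        flags = pd.read_csv(custom_grid_path, header=None)
        try:
            is_grid = flags.to_numpy(dtype=float).astype(bool)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"grid-flag file {custom_grid_path} is not a 0/1 matrix") from exc
        if is_grid.shape != (n_rows, n_cols):
            raise DimensionMismatchError(
                f"custom grid is {is_grid.shape}, format {fmt} is {(n_rows, n_cols)}"
            )
    else:
        raise ConfigurationError(f"unknown grid scheme {grid_scheme!r}")
    strain = np.empty((n_rows, n_cols), dtype=object)
    for r in range(n_rows):
        for c in range(n_cols):
            strain[r, c] = "grid" if is_grid[r, c] else f"strain_{r:02d}_{c:02d}"
    return PlateLayout(strain, is_grid)


@dataclass
class ReferenceSurface:
    """Expected colony value per position, interpolated from grid controls."""

    expected: np.ndarray
    n_grid_used: int
    flags: list[str] = field(default_factory=list)


def _smooth_grid_nodes(ur: np.ndarray, uc: np.ndarray, node_values: np.ndarray) -> np.ndarray:
    """Local quadratic regression (5x5 node neighbourhood) over the grid.

    Each reference colony is replaced by the value at its position of a
    least-squares quadratic surface fitted through itself and its
    neighbouring reference colonies (a 2-D Savitzky-Golay filter of order
    2).  This damps measurement noise of individual controls — which would
    otherwise propagate into every nearby corrected colony as a shared
    error, inducing spurious positive neighbour correlation — while
    reproducing any constant, plane or quadratic surface exactly, even at
    truncated border windows.
    """
    n_r, n_c = node_values.shape
    half = 2
    out = np.empty_like(node_values)
    for i in range(n_r):
        ii = slice(max(i - half, 0), min(i + half + 1, n_r))
        for j in range(n_c):
            jj = slice(max(j - half, 0), min(j + half + 1, n_c))
            # centre coordinates for numerical conditioning
            rr, cc = np.meshgrid(
                ur[ii].astype(float) - ur[i], uc[jj].astype(float) - uc[j], indexing="ij"
            )
            r1, c1 = rr.ravel(), cc.ravel()
            z = node_values[ii, jj].ravel()
            A = np.column_stack([np.ones(z.size), r1, c1, r1**2, r1 * c1, c1**2])
            coef, *_ = np.linalg.lstsq(A, z, rcond=None)
            out[i, j] = coef[0]
    return out


def build_reference_surface(
    plate_values: np.ndarray, layout: PlateLayout, smooth: bool = True
) -> ReferenceSurface:
    """Interpolate the expected value at every position from grid colonies.

    Grid colonies that are missing or non-positive are excluded and
    flagged.  When the usable controls form a complete regular sublattice
    (the common case), their values are first smoothed by a local plane
    regression (``smooth=True``; see :func:`_smooth_grid_nodes`), then
    bilinearly interpolated with linear extrapolation at the borders, which
    reproduces any plane exactly at every position.  Otherwise
    piecewise-linear (Delaunay) interpolation is used inside the convex
    hull of the controls, with nearest-control fill outside.  Positions
    whose expectation comes out non-positive are flagged as artefacts (and
    excluded downstream).
    """
    values = np.asarray(plate_values, dtype=float)
    if values.shape != layout.strain.shape:
        raise DimensionMismatchError(
            f"plate values {values.shape} do not match layout {layout.strain.shape}"
        )
    flags: list[str] = []
    usable = layout.is_grid & np.isfinite(values) & (values > 0)
    for r, c in np.argwhere(layout.is_grid & ~usable):
        flags.append(f"missing grid colony at ({r}, {c})")
    n_used = int(usable.sum())
    if n_used < 3:
        raise DegenerateGridError(f"only {n_used} usable grid colonies (need >= 3)")

    rows = np.arange(layout.n_rows)
    cols = np.arange(layout.n_cols)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")

    ur = np.unique(np.nonzero(usable.any(axis=1))[0])
    uc = np.unique(np.nonzero(usable.any(axis=0))[0])
    regular = len(ur) >= 2 and len(uc) >= 2 and usable[np.ix_(ur, uc)].all()
    if regular:
        node_values = values[np.ix_(ur, uc)]
        if smooth:
            node_values = _smooth_grid_nodes(ur, uc, node_values)
        interp = RegularGridInterpolator(
            (ur.astype(float), uc.astype(float)),
            node_values,
            method="linear",
            bounds_error=False,
            fill_value=None,  # linear extrapolation beyond the outermost controls
        )
        expected = interp(np.column_stack([rr.ravel(), cc.ravel()])).reshape(values.shape)
    else:
        pts = np.argwhere(usable).astype(float)
        vals = values[usable]
        try:
            lin = LinearNDInterpolator(pts, vals)
        except QhullError as exc:
            raise DegenerateGridError("usable grid colonies are collinear") from exc
        expected = lin(rr, cc)
        nn = NearestNDInterpolator(pts, vals)
        hole = ~np.isfinite(expected)
        if hole.any():
            expected[hole] = nn(rr[hole], cc[hole])
    bad = ~np.isfinite(expected) | (expected <= 0)
    for r, c in np.argwhere(bad):
        flags.append(f"artefact expectation at ({r}, {c})")
    expected = np.where(bad, np.nan, expected)
    return ReferenceSurface(expected=expected, n_grid_used=n_used, flags=flags)


def grid_normalise(plate_values: np.ndarray, layout: PlateLayout) -> np.ndarray:
    """Divide every measurement by the local reference-surface expectation.

    A corrected value of 1 means fitness equal to the grid strain at that
    position.  Positions with artefact expectations or empty layout
    positions come out missing (NaN).
    """
    values = np.asarray(plate_values, dtype=float)
    surface = build_reference_surface(values, layout)
    with np.errstate(invalid="ignore", divide="ignore"):
        corrected = values / surface.expected
    corrected = np.where(layout.strain == EMPTY_STRAIN, np.nan, corrected)
    return corrected


def rowcol_median_normalise(plate_values: np.ndarray) -> np.ndarray:
    """Divide by row medians, then by the recomputed column medians.

    Rows/columns that are entirely missing propagate missing values; a zero
    row or column median raises :class:`ZeroMedianError` because the ratio
    would be undefined for the whole row/column.
    """
    values = np.asarray(plate_values, dtype=float)
    if values.ndim != 2:
        raise DimensionMismatchError("plate values must be a 2-D matrix")
    import warnings

    with warnings.catch_warnings():
        # all-NaN rows/columns legitimately yield NaN medians (propagated)
        warnings.simplefilter("ignore", RuntimeWarning)
        row_med = np.nanmedian(values, axis=1)
    zero_rows = np.nonzero(row_med == 0)[0]
    if zero_rows.size:
        raise ZeroMedianError(f"row {zero_rows[0]} has median 0")
    out = values / row_med[:, None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_med = np.nanmedian(out, axis=0)
    zero_cols = np.nonzero(col_med == 0)[0]
    if zero_cols.size:
        raise ZeroMedianError(f"column {zero_cols[0]} has median 0")
    return out / col_med[None, :]


NORMALISATION_METHODS = ("grid", "rowcol", "grid+rowcol", "none")


def _normalise_plate(values: np.ndarray, layout: PlateLayout, method: str):
    """Apply one normalisation method; returns (corrected, reference, flags)."""
    if method not in NORMALISATION_METHODS:
        raise ConfigurationError(f"unknown normalisation method {method!r}")
    flags: list[str] = []
    if method == "none":
        corrected = values.copy()
    elif method == "rowcol":
        corrected = rowcol_median_normalise(values)
    else:
        surface = build_reference_surface(values, layout)
        flags.extend(surface.flags)
        with np.errstate(invalid="ignore", divide="ignore"):
            corrected = values / surface.expected
        if method == "grid+rowcol":
            corrected = rowcol_median_normalise(corrected)
    corrected = np.where(layout.strain == EMPTY_STRAIN, np.nan, corrected)
    with np.errstate(invalid="ignore", divide="ignore"):
        reference = np.where(np.isfinite(corrected) & (corrected != 0), values / corrected, np.nan)
    return corrected, reference, flags


# ---------------------------------------------------------------------------
# experiment aggregation


_EDT_REQUIRED = ("plate_id", "data_path")
_EDT_KNOWN = {
    "plate_id", "data_path", "layout_path", "grid_path", "grid_scheme",
    "condition", "control", "batch", "method",
}


def _load_plate_values(path: str, data_format: str, value_column: str, shape=None):
    """Load one plate's measurements as a matrix plus per-colony extras."""
    if data_format == "matrix":
        values = pd.read_csv(path, header=None).to_numpy(dtype=float)
        return values, None
    if data_format != "long":
        raise ConfigurationError(f"unknown data format {data_format!r}")
    df = pd.read_csv(path)
    for col in ("row", "col", value_column):
        if col not in df.columns:
            raise SchemaError(f"data file {path} lacks required column {col!r}")
    n_rows = shape[0] if shape else int(df["row"].max()) + 1
    n_cols = shape[1] if shape else int(df["col"].max()) + 1
    rows = df["row"].to_numpy(int)
    cols = df["col"].to_numpy(int)
    if rows.min() < 0 or cols.min() < 0 or rows.max() >= n_rows or cols.max() >= n_cols:
        raise DimensionMismatchError(
            f"data file {path} has positions outside the {n_rows}x{n_cols} layout"
        )
    values = np.full((n_rows, n_cols), np.nan)
    values[rows, cols] = df[value_column].to_numpy(float)
    extras = df.drop(columns=[value_column]).set_index(["row", "col"])
    extras = extras[[c for c in extras.columns if c != "strain"]]
    return values, (extras if len(extras.columns) else None)


def aggregate_experiment(
    edt,
    method: str = "grid",
    data_format: str = "long",
    value_column: str = "value",
    qc_dir: str | os.PathLike | None = None,
) -> pd.DataFrame:
    """Normalise and concatenate a whole experiment into one long table.

    ``edt`` is an Experimental Design Table (path to a CSV or a DataFrame)
    with one row per plate: required columns ``plate_id`` and ``data_path``;
    optional ``layout_path``, ``grid_path``, ``grid_scheme``, ``condition``,
    ``control``, ``batch`` and ``method`` (per-plate override of the global
    normalisation method); unknown columns are passed through to the output.
    Relative paths are resolved against the EDT's own location.

    Zero measurements are treated as missing (failed pinnings) before any
    normalisation.  The output has one row per (plate, row, col) with
    ``raw_value``, ``reference_value``, ``corrected_value``,
    ``normalisation_method`` and ``qc_flags`` columns; every value that
    normalisation turned missing carries an explanatory flag.
    """
    if isinstance(edt, (str, os.PathLike)):
        base = os.path.dirname(os.path.abspath(edt))
        edt_df = pd.read_csv(edt)
    else:
        base = os.getcwd()
        edt_df = edt.copy()
    for col in _EDT_REQUIRED:
        if col not in edt_df.columns:
            raise SchemaError(f"EDT lacks required column {col!r}")
    if edt_df["plate_id"].duplicated().any():
        raise SchemaError("EDT plate_id values must be unique")

    def _resolve(p):
        return p if os.path.isabs(str(p)) else os.path.join(base, str(p))

    pieces = []
    for _, plate in edt_df.iterrows():
        plate_id = plate["plate_id"]
        data_path = _resolve(plate["data_path"])
        if not os.path.exists(data_path):
            raise FileNotFoundError(f"plate {plate_id!r}: data file {data_path} not found")

        layout = None
        if "layout_path" in plate.index and pd.notna(plate.get("layout_path")):
            grid_path = (
                _resolve(plate["grid_path"])
                if "grid_path" in plate.index and pd.notna(plate.get("grid_path"))
                else None
            )
            layout = PlateLayout.from_csv(_resolve(plate["layout_path"]), grid_path=grid_path)

        shape = (layout.n_rows, layout.n_cols) if layout is not None else None
        values, extras = _load_plate_values(data_path, data_format, value_column, shape)
        if layout is None:
            if "grid_scheme" in plate.index and pd.notna(plate.get("grid_scheme")):
                layout = make_layout(values.size, grid_scheme=str(plate["grid_scheme"]))
            else:
                strain = np.empty(values.shape, dtype=object)
                strain[:, :] = "unknown"
                layout = PlateLayout(strain, np.zeros(values.shape, dtype=bool))
        if values.shape != (layout.n_rows, layout.n_cols):
            raise DimensionMismatchError(
                f"plate {plate_id!r}: data is {values.shape}, layout is "
                f"{(layout.n_rows, layout.n_cols)}"
            )

        plate_method = (
            str(plate["method"])
            if "method" in plate.index and pd.notna(plate.get("method"))
            else method
        )
        raw = np.asarray(values, dtype=float)
        zero = raw == 0
        clean = np.where(zero, np.nan, raw)
        corrected, reference, surface_flags = _normalise_plate(clean, layout, plate_method)

        n_rows, n_cols = clean.shape
        rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
        qc_flags = np.empty(clean.shape, dtype=object)
        qc_flags[:, :] = ""
        for flag in surface_flags:
            # flags are per-position: "… at (r, c)"
            loc = flag[flag.rindex("(") + 1 : flag.rindex(")")]
            r, c = (int(x) for x in loc.split(","))
            qc_flags[r, c] = _append_flag(qc_flags[r, c], flag.rsplit(" at ", 1)[0])
        for r, c in np.argwhere(zero):
            qc_flags[r, c] = _append_flag(qc_flags[r, c], "zero-size")
        for r, c in np.argwhere(layout.strain == EMPTY_STRAIN):
            qc_flags[r, c] = _append_flag(qc_flags[r, c], "empty-position")
        newly_missing = np.isfinite(clean) & ~np.isfinite(corrected)
        for r, c in np.argwhere(newly_missing):
            if not qc_flags[r, c]:
                qc_flags[r, c] = "normalisation-undefined"

        out = pd.DataFrame(
            {
                "plate_id": plate_id,
                "row": rr.ravel(),
                "col": cc.ravel(),
                "strain": layout.strain.ravel(),
                "is_grid": layout.is_grid.ravel(),
                "condition": plate.get("condition", ""),
                "batch": plate.get("batch", ""),
                "raw_value": raw.ravel(),
                "reference_value": reference.ravel(),
                "corrected_value": corrected.ravel(),
                "normalisation_method": plate_method,
                "qc_flags": qc_flags.ravel(),
            }
        )
        for col in edt_df.columns:
            if col not in _EDT_KNOWN:
                out[col] = plate[col]
        if extras is not None:
            out = out.merge(extras, left_on=["row", "col"], right_index=True, how="left")
        pieces.append(out)
        if qc_dir is not None:
            _plate_qc_plot(qc_dir, plate_id, raw, corrected)
    return pd.concat(pieces, ignore_index=True)


def _append_flag(existing: str, flag: str) -> str:
    return flag if not existing else f"{existing};{flag}"


def _plate_qc_plot(qc_dir, plate_id, raw: np.ndarray, corrected: np.ndarray) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(qc_dir, exist_ok=True)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2))
    for ax, mat, title in zip(axes, (raw, corrected), ("raw", "corrected")):
        im = ax.imshow(mat, aspect="auto", interpolation="nearest")
        ax.set_title(f"{plate_id} {title}")
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(os.path.join(qc_dir, f"{plate_id}_heatmaps.png"), dpi=100)
    plt.close(fig)
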