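"""Quality-control statistics for colony-array screens.

* **CV** — coefficient of variation (sample SD / mean) of the replicate
  control colonies; measures precision.
* **FUV** — fraction of unexplained variance, var(controls)/var(all
  colonies); measures noise relative to the biological signal.
* **Neighbour-sum bias** — correlation of each colony's fitness with the
  summed fitness of its 8 neighbours.  Positive values indicate regional
  plate effects (temperature/moisture/nutrient gradients); negative values
  would indicate competition artefacts introduced by over-correction.
* **Timepoint correlation matrix** — pairwise Pearson correlations of
  strain-averaged values across timepoints, to judge how sensitive a screen
  is to the exact imaging time.

:func:`plate_quality_filter` applies the standard screen filters: colonies
with zero size or circularity below 0.85 are set missing, and plates whose
control CV exceeds 0.2 or FUV exceeds 1 are dropped entirely.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    InsufficientDataError,
    SampleSizeError,
    SchemaError,
    UndefinedStatError,
)

log = logging.getLogger(__name__)

DEFAULT_CV_MAX = 0.2
DEFAULT_FUV_MAX = 1.0
DEFAULT_CIRC_MIN = 0.85


def compute_cv(values) -> float:
    """Sample coefficient of variation: sd (n-1 denominator) / mean."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise SampleSizeError(f"CV needs >= 2 values, got {arr.size}")
    mean = arr.mean()
    if mean == 0:
        raise UndefinedStatError("CV undefined: mean is 0")
    return float(arr.std(ddof=1) / mean)


def compute_fuv(controls, all_values) -> float:
    """Fraction of unexplained variance: var(controls) / var(all values)."""
    ctrl = np.asarray(controls, dtype=float)
    ctrl = ctrl[np.isfinite(ctrl)]
    full = np.asarray(all_values, dtype=float)
    full = full[np.isfinite(full)]
    if ctrl.size < 2 or full.size < 2:
        raise SampleSizeError("FUV needs >= 2 values in both lists")
    denom = full.var(ddof=1)
    if denom == 0:
        raise UndefinedStatError("FUV undefined: total variance is 0")
    return float(ctrl.var(ddof=1) / denom)


def neighbour_bias(plate_values) -> tuple[float, pd.DataFrame]:
    """Correlation of colony values with the sum of their 8 neighbours.

    Only interior positions whose value and all 8 neighbours are non-missing
    contribute; border positions are excluded so the statistic is comparable
    across plates.  Returns the Pearson correlation and the paired table.
    """
    values = np.asarray(plate_values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 3 or values.shape[1] < 3:
        raise InsufficientDataError("neighbour bias needs a plate of at least 3x3")
    center = values[1:-1, 1:-1]
    window_sum = sum(
        values[1 + dr : values.shape[0] - 1 + dr, 1 + dc : values.shape[1] - 1 + dc]
        for dr in (-1, 0, 1)
        for dc in (-1, 0, 1)
    )
    neigh = window_sum - center
    complete = np.isfinite(center) & np.isfinite(neigh)
    if complete.sum() < 3:
        raise InsufficientDataError("no complete interior positions")
    rr, cc = np.nonzero(complete)
    table = pd.DataFrame(
        {
            "row": rr + 1,
            "col": cc + 1,
            "value": center[complete],
            "neighbour_sum": neigh[complete],
        }
    )
    if table["value"].std() == 0 or table["neighbour_sum"].std() == 0:
        return float("nan"), table
    r, _ = stats.pearsonr(table["value"], table["neighbour_sum"])
    return float(r), table


def timepoint_correlation_matrix(per_timepoint_values) -> np.ndarray:
    """Symmetric Pearson correlation matrix across timepoints.

    Each element of ``per_timepoint_values`` is one strain-averaged vector
    (all of equal length).  Timepoints with constant vectors yield NaN
    correlations (flagged column) but keep a diagonal of 1.
    """
    mat = np.asarray([np.asarray(v, dtype=float) for v in per_timepoint_values])
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise InsufficientDataError("need >= 2 equal-length timepoint vectors")
    sd = mat.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat)
    constant = sd == 0
    if constant.any():
        log.warning("constant vectors at timepoints %s", np.nonzero(constant)[0].tolist())
        corr[constant, :] = np.nan
        corr[:, constant] = np.nan
    np.fill_diagonal(corr, 1.0)
    return corr


def compute_plate_qc(
    table: pd.DataFrame,
    cv_max: float = DEFAULT_CV_MAX,
    fuv_max: float = DEFAULT_FUV_MAX,
    value_col: str = "corrected_value",
) -> pd.DataFrame:
    """Per-plate CV/FUV summary over the grid-control colonies.

    Plates lacking enough controls get NaN statistics and pass by default
    (nothing to judge them on); they are flagged in the ``note`` column.
    """
    for col in ("plate_id", "is_grid", value_col):
        if col not in table.columns:
            raise SchemaError(f"table lacks required column {col!r}")
    rows = []
    for plate_id, sub in table.groupby("plate_id", sort=True):
        controls = sub.loc[sub["is_grid"].astype(bool), value_col].to_numpy(dtype=float)
        everything = sub[value_col].to_numpy(dtype=float)
        note = ""
        try:
            cv = compute_cv(controls)
            fuv = compute_fuv(controls, everything)
            passed = bool(cv <= cv_max and fuv <= fuv_max)
        except (SampleSizeError, UndefinedStatError) as exc:
            cv = fuv = float("nan")
            passed = True
            note = f"statistics unavailable: {exc}"
        rows.append(
            {
                "plate_id": plate_id,
                "cv": cv,
                "fuv": fuv,
                "n_controls": int(np.isfinite(controls).sum()),
                "n_total": int(np.isfinite(everything).sum()),
                "pass": passed,
                "note": note,
            }
        )
    return pd.DataFrame(rows)


def plate_quality_filter(
    table: pd.DataFrame,
    cv_max: float = DEFAULT_CV_MAX,
    fuv_max: float = DEFAULT_FUV_MAX,
    circ_min: float | None = DEFAULT_CIRC_MIN,
) -> pd.DataFrame:
    """Apply colony- and plate-level quality filters to an experiment table.

    Colony level: zero-size colonies and colonies with circularity below
    ``circ_min`` have their values set missing with a qc flag.  Plate level:
    plates whose control CV exceeds ``cv_max`` or FUV exceeds ``fuv_max``
    are removed entirely.  Surviving numeric values are never altered.
    """
    out = table.copy()
    if "corrected_value" not in out.columns:
        raise SchemaError("table lacks required column 'corrected_value'")
    if "qc_flags" not in out.columns:
        out["qc_flags"] = ""
    out["qc_flags"] = out["qc_flags"].fillna("")

    def _flag(mask: pd.Series, flag: str) -> None:
        out.loc[mask, "corrected_value"] = np.nan
        out.loc[mask, "qc_flags"] = out.loc[mask, "qc_flags"].map(
            lambda s: flag if not s else f"{s};{flag}"
        )

    if "raw_value" in out.columns:
        zero = (out["raw_value"] == 0) & out["corrected_value"].notna()
        _flag(zero, "zero-size")
    if circ_min is not None:
        if "circularity" not in out.columns:
            raise SchemaError("circularity filter requested but column 'circularity' missing")
        low = (out["circularity"] < circ_min) & out["circularity"].notna()
        low &= out["corrected_value"].notna()
        _flag(low, "low-circularity")

    plate_qc = compute_plate_qc(out, cv_max=cv_max, fuv_max=fuv_max)
    failed = plate_qc.loc[~plate_qc["pass"], "plate_id"].tolist()
    for plate_id in failed:
        row = plate_qc.set_index("plate_id").loc[plate_id]
        log.warning(
            "removing plate %r: CV=%.3f FUV=%.3f exceeds limits", plate_id, row["cv"], row["fuv"]
        )
    return out[~out["plate_id"].isin(failed)].reset_index(drop=True)
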