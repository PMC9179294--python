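"""Mammogram risk scores (MRSs) from thresholded density measures.

An MRS is the standardized residual of a normality-transformed density
measure after ordinary-least-squares adjustment for age and the inverse of
BMI.  The transformation power is selected per measure by maximizing the
Box-Cox profile log-likelihood over a grid of interpretable powers
(-1, -1/2, 0 [log], 1/3, 1/2, 1); a continuous maximum-likelihood mode is
available behind a flag.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: interpretable powers: reciprocal, inverse sqrt, log, cube root, sqrt, identity
DEFAULT_LAMBDA_GRID = (-1.0, -0.5, 0.0, 1.0 / 3.0, 0.5, 1.0)

#: density measure -> risk-score column
MRS_COLUMNS = {
    "cumulus": "cumulus_mrs",
    "cumulus_percent": "percent_mrs",
    "altocumulus": "alto_mrs",
    "cirrocumulus": "cirro_mrs",
    "cumulus_white": "white_mrs",
}

MEASURES = tuple(MRS_COLUMNS)


def derive_measures(table: pd.DataFrame) -> pd.DataFrame:
    """Populate the derived percent and white-area density columns.

    ``cumulus_percent = 100 * cumulus / total_area`` and ``cumulus_white =
    cumulus - altocumulus``.  The nesting invariant (brightest <= bright <=
    dense <= total) is validated and violations are reported by row.
    """
    need = ["cumulus", "altocumulus", "cirrocumulus", "total_area"]
    missing = [c for c in need if c not in table.columns]
    if missing:
        raise ValueError(f"density table missing columns: {missing}")
    out = table.copy()
    for upper, lower in (("total_area", "cumulus"), ("cumulus", "altocumulus"),
                         ("altocumulus", "cirrocumulus")):
        bad = out[lower] > out[upper]
        if bad.any():
            row = out.index[bad][0]
            raise ValueError(
                f"nesting violated at row {row}: {lower}="
                f"{out.loc[row, lower]:g} > {upper}={out.loc[row, upper]:g}")
    out["cumulus_percent"] = 100.0 * out["cumulus"] / out["total_area"]
    out["cumulus_white"] = out["cumulus"] - out["altocumulus"]
    return out


def boxcox_transform(values: np.ndarray, lam: float) -> np.ndarray:
    """Box-Cox power transform; ``lam = 0`` means the natural log."""
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    if lam == 0.0:
        return np.log(values)
    return (values ** lam - 1.0) / lam


def boxcox_select(values: np.ndarray,
                  lambda_grid=DEFAULT_LAMBDA_GRID) -> float:
    """Select the Box-Cox power maximizing the profile log-likelihood.

    ``lambda_grid=None`` returns the continuous maximum-likelihood estimate
    instead of snapping to the interpretable grid.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("values must be positive (apply an offset to zeros)")
    if np.ptp(values) == 0:
        raise ValueError("degenerate distribution: constant input")
    if lambda_grid is None:
        _, lam = stats.boxcox(values)
        return float(lam)
    grid = list(lambda_grid)
    if not grid:
        raise ValueError("lambda grid must be non-empty")
    llf = [stats.boxcox_llf(lam, values) for lam in grid]
    return float(grid[int(np.argmax(llf))])


def zero_offset(values: np.ndarray) -> float:
    """Offset for measures that can be exactly zero (log transforms).

    Half the smallest positive value of the column; zero when the column is
    already strictly positive.
    """
    values = np.asarray(values, dtype=float)
    pos = values[values > 0]
    if pos.size == 0:
        raise ValueError("no positive values in column")
    if np.all(values > 0):
        return 0.0
    return float(pos.min() / 2.0)


def compute_mrs(values: np.ndarray, lam: float, age: np.ndarray,
                bmi: np.ndarray, return_coefficients: bool = False):
    """Standardized residuals of the transformed measure on age and 1/BMI.

    Ordinary least squares of the Box-Cox-transformed values on an
    intercept, age and inverse BMI; residuals are divided by their sample
    (n-1) standard deviation, so the score has mean 0 and SD 1 over the
    estimation sample.
    """
    values = np.asarray(values, dtype=float)
    age = np.asarray(age, dtype=float)
    bmi = np.asarray(bmi, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 observations (insufficient df)")
    if np.any(bmi <= 0):
        raise ValueError("bmi must be positive")
    if np.any(np.isnan(age)) or np.any(np.isnan(bmi)):
        raise ValueError("missing covariates are not allowed here; "
                         "exclude those rows upstream")
    y = boxcox_transform(values, lam)
    X = np.column_stack([np.ones_like(y), age, 1.0 / bmi])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    score = resid / resid.std(ddof=1)
    if return_coefficients:
        return score, beta
    return score


def build_mrs_table(table: pd.DataFrame, lambda_grid=DEFAULT_LAMBDA_GRID,
                    metadata_path=None) -> tuple[pd.DataFrame, dict]:
    """Derive the five risk scores for a cohort density table.

    Expects the cohort columns (``id``, ``age``, ``bmi``) merged with the
    density areas.  Rows with missing BMI or age are excluded from the
    estimation sample (counted in the log and metadata).  Returns the MRS
    table (id + five score columns) and per-measure fit metadata
    (selected power, zero offset, adjustment coefficients), optionally
    written to JSON.
    """
    tab = derive_measures(table)
    complete = tab["age"].notna() & tab["bmi"].notna()
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("excluded %d rows with missing age/BMI", n_dropped)
    tab = tab.loc[complete].reset_index(drop=True)

    out = pd.DataFrame({"id": tab["id"]})
    meta: dict = {"n": int(len(tab)), "n_excluded_missing_covariates": n_dropped,
                  "measures": {}}
    age = tab["age"].to_numpy(dtype=float)
    bmi = tab["bmi"].to_numpy(dtype=float)
    for measure, col in MRS_COLUMNS.items():
        raw = tab[measure].to_numpy(dtype=float)
        offset = zero_offset(raw)
        vals = raw + offset
        lam = boxcox_select(vals, lambda_grid)
        score, beta = compute_mrs(vals, lam, age, bmi,
                                  return_coefficients=True)
        out[col] = score
        meta["measures"][measure] = {
            "mrs_column": col, "lambda": lam, "zero_offset": offset,
            "coefficients": {"intercept": beta[0], "age": beta[1],
                             "inverse_bmi": beta[2]},
        }
    if metadata_path is not None:
        with open(metadata_path, "w") as fh:
            json.dump(meta, fh, indent=2)
    return out, meta
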