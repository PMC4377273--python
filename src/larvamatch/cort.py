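"""Preparation of baseline corticosterone (CORT) samples.

Baseline CORT (ng/mL, plasma drawn within 3 minutes of capture) is floored
at the assay detection limit of 1.21 ng/mL, log10-transformed, and joined
to the trailing 7-day prey-exposure covariates anchored on each sample's
capture day.  Rows with missing CORT or an incomplete exposure window are
flagged and excluded from model fits with a logged count, never silently
dropped.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "DETECTION_LIMIT",
    "apply_detection_floor",
    "log10_transform",
    "prepare_samples",
    "join_exposures",
]

logger = logging.getLogger(__name__)

#: Assay detection limit (ng/mL); lower concentrations are assigned this
#: value, as in the source assay protocol.
DETECTION_LIMIT = 1.21

#: Columns expected in a bird-sample table.
SAMPLE_COLUMNS = ["pair_id", "bird_id", "sex", "year", "phase", "capture_day", "cort"]


def apply_detection_floor(cort, limit: float = DETECTION_LIMIT):
    """Floor CORT values at the assay detection limit.

    Returns ``(values, flagged)`` where ``flagged`` marks values that were
    below the limit and got assigned it.  Missing values stay missing and
    are never flagged; negative concentrations are rejected.  Flooring is
    idempotent.  Accepts scalars or arrays.
    """
    arr = np.asarray(cort, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError("CORT concentrations cannot be negative")
    flagged = np.isfinite(arr) & (arr < limit)
    floored = np.where(flagged, limit, arr)
    if np.isscalar(cort) or arr.ndim == 0:
        return float(floored), bool(flagged)
    return floored, flagged


def log10_transform(cort):
    """Base-10 log of CORT (applied after detection-limit flooring)."""
    arr = np.asarray(cort, dtype=float)
    if np.any(arr[np.isfinite(arr)] <= 0):
        raise ValueError("log10 requires positive concentrations")
    out = np.log10(arr)
    if np.isscalar(cort) or arr.ndim == 0:
        return float(out)
    return out


def prepare_samples(samples: pd.DataFrame, limit: float = DETECTION_LIMIT) -> pd.DataFrame:
    """Apply the detection floor and the log10 transform to a bird-sample
    table, flagging floored rows and excluding missing CORT from analysis.

    Adds ``cort_floored`` (bool), ``log10_cort``, and ``usable`` columns.
    Raises if the table already carries ``log10_cort`` so the floor/log
    transform cannot be applied twice in one pipeline run.
    """
    if "log10_cort" in samples.columns:
        raise ValueError("samples already transformed (log10_cort present)")
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    out = samples.copy()
    floored, flagged = apply_detection_floor(out["cort"].to_numpy(), limit)
    out["cort"] = floored
    out["cort_floored"] = flagged
    usable = np.isfinite(floored)
    out["usable"] = usable
    out["log10_cort"] = np.where(usable, np.log10(np.where(usable, floored, 1.0)), np.nan)
    n_miss = int((~usable).sum())
    if n_miss:
        logger.info("prepare_samples: %d rows with missing CORT excluded from fits", n_miss)
    logger.info("prepare_samples: %d of %d values floored at %.2f ng/mL",
                int(np.sum(flagged)), len(out), limit)
    return out


def join_exposures(samples: pd.DataFrame, exposures: pd.DataFrame) -> pd.DataFrame:
    """Attach each sample's trailing-window covariates by capture day.

    ``exposures`` is an exposure table (columns ``day``, ``larvae_S``,
    ``larvae_N``, ``sst``; optionally ``year`` when windows differ between
    years).  Samples whose capture day has no window are kept but flagged
    (``has_exposure`` False) and excluded from fits; the count is logged.
    The result is sorted on (pair_id, bird_id, year, phase) so the output
    is invariant to input row order.
    """
    keys = ["day"]
    if "year" in exposures.columns and "year" in samples.columns:
        keys = ["year", "day"]
    exp = exposures.rename(columns={"day": "capture_day"})
    keys = [k if k != "day" else "capture_day" for k in keys]
    merged = samples.merge(exp, on=keys, how="left", validate="many_to_one")
    merged["has_exposure"] = np.isfinite(merged["larvae_S"].to_numpy(dtype=float))
    n_missing = int((~merged["has_exposure"]).sum())
    if n_missing:
        logger.info("join_exposures: %d samples lack a complete exposure window", n_missing)
    merged = merged.sort_values(["pair_id", "bird_id", "year", "phase"]).reset_index(drop=True)
    return merged
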