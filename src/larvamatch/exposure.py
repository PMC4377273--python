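"""Prey-availability covariates from particle histories.

Turns daily particle trajectories into the covariates the corticosterone
analysis uses: daily per-ground counts of larvae inside the 100x100 km
colony box, southern (grounds 4-11) and northern (grounds 1-2) aggregates
with mean larval mass per group, box-mean SST, trailing 7-day exposure
windows anchored on capture dates, and the larval biomass index (mean mass
times abundance).  Ground 3 belongs to neither aggregate but is still
counted and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .drift import NORTHERN_GROUNDS, SOUTHERN_GROUNDS, LARVA_STAGE, ParticleHistory
from .ocean import OceanFields

__all__ = [
    "ColonyBox",
    "ExposureWindow",
    "DEFAULT_BOX",
    "count_in_box",
    "daily_abundance",
    "trailing_window",
    "exposure_table",
    "biomass",
    "series_correlation",
    "pulse_strength",
    "standardize_within",
    "WINDOW_DAYS",
]

#: Trailing exposure window length: the 7 days up to and including the day
#: of CORT measurement.
WINDOW_DAYS = 7


@dataclass(frozen=True)
class ColonyBox:
    """The 100 x 100 km square around the colony approximating the adult
    foraging range; membership uses closed intervals on both edges."""

    center_x: float = 50.0
    center_y: float = 1850.0
    side: float = 100.0

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ValueError("box side must be positive")

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        h = self.side / 2.0
        return (self.center_x - h, self.center_x + h, self.center_y - h, self.center_y + h)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x0, x1, y0, y1 = self.bounds
        return (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)


DEFAULT_BOX = ColonyBox()


def count_in_box(
    history: ParticleHistory,
    box: ColonyBox,
    day: int,
    include_eggs: bool = False,
) -> dict[int, int]:
    """Per-ground counts of particles inside the closed box on ``day``.

    By default only larvae are counted (eggs are not guillemot prey); set
    ``include_eggs`` to count all particles.  Raises KeyError if the day is
    absent from the history.
    """
    k = history.day_index(day)
    sel = history.stage_mask(day, LARVA_STAGE)
    if include_eggs:
        sel = history.alive_mask(day)
    inside = sel & box.contains(history.x[k], history.y[k])
    grounds = np.unique(history.origin_ground)
    counts = {int(g): int(np.sum(inside & (history.origin_ground == g))) for g in grounds}
    return counts


def daily_abundance(
    history: ParticleHistory,
    box: ColonyBox,
    fields: OceanFields | None = None,
    days=None,
    include_eggs: bool = False,
) -> pd.DataFrame:
    """Daily in-box abundance table.

    One row per day with per-ground counts (``count_g{id}``), the southern
    (4-11) and northern (1-2) aggregates, mean larval mass (mg) per group,
    and, when fields are given, the mean SST over box grid cells.
    """
    days = history.days if days is None else np.asarray(days, dtype=np.int64)
    grounds = np.unique(history.origin_ground)
    sst_box = None
    if fields is not None:
        g = fields.grid
        xs = g.x_centers
        ys = g.y_centers
        x0, x1, y0, y1 = box.bounds
        cols = (xs >= x0) & (xs <= x1) & (xs >= 0.0)
        rows = (ys >= y0) & (ys <= y1)
        cells = np.ix_(rows, cols)
        sst_box = np.array([float(np.mean(fields.sst[d][cells])) for d in days])

    south = np.asarray(SOUTHERN_GROUNDS)
    north = np.asarray(NORTHERN_GROUNDS)
    is_south = np.isin(history.origin_ground, south)
    is_north = np.isin(history.origin_ground, north)

    recs = []
    for i, d in enumerate(days):
        k = history.day_index(int(d))
        sel = history.alive_mask(int(d)) if include_eggs else history.stage_mask(int(d), LARVA_STAGE)
        inside = sel & box.contains(history.x[k], history.y[k])
        rec = {"day": int(d)}
        for gid in grounds:
            rec[f"count_g{int(gid)}"] = int(np.sum(inside & (history.origin_ground == gid)))
        rec["total"] = int(inside.sum())
        rec["southern"] = int(np.sum(inside & is_south))
        rec["northern"] = int(np.sum(inside & is_north))
        for label, mask in (("southern", is_south), ("northern", is_north)):
            m = history.mass[k][inside & mask]
            m = m[np.isfinite(m)]
            rec[f"mean_mass_{label}"] = float(m.mean()) if m.size else np.nan
        if sst_box is not None:
            rec["sst_box"] = sst_box[i]
        recs.append(rec)
    return pd.DataFrame.from_records(recs)


@dataclass(frozen=True)
class ExposureWindow:
    """7-day trailing exposure: summed counts over anchor-6 .. anchor
    (inclusive) and SST averaged over the same days."""

    anchor_day: int
    length: int
    larvae_S: float
    larvae_N: float
    sst_mean: float
    total: float


def trailing_window(
    abundance: pd.DataFrame, anchor_day: int, length: int = WINDOW_DAYS
) -> ExposureWindow:
    """Sum counts and average SST over the ``length`` days up to and
    including ``anchor_day``.  Raises if the window is not fully covered."""
    lo = anchor_day - length + 1
    win = abundance[(abundance["day"] >= lo) & (abundance["day"] <= anchor_day)]
    if len(win) != length or set(win["day"]) != set(range(lo, anchor_day + 1)):
        raise ValueError(
            f"abundance series does not cover days {lo}..{anchor_day}"
        )
    sst = float(win["sst_box"].mean()) if "sst_box" in win else np.nan
    return ExposureWindow(
        anchor_day=int(anchor_day),
        length=int(length),
        larvae_S=float(win["southern"].sum()),
        larvae_N=float(win["northern"].sum()),
        sst_mean=sst,
        total=float(win["total"].sum()),
    )


def exposure_table(
    abundance: pd.DataFrame, anchor_days, length: int = WINDOW_DAYS
) -> pd.DataFrame:
    """Trailing-window exposures for a set of anchor (capture) days."""
    rows = []
    for d in anchor_days:
        w = trailing_window(abundance, int(d), length)
        rows.append({
            "day": w.anchor_day,
            "larvae_S": w.larvae_S,
            "larvae_N": w.larvae_N,
            "sst": w.sst_mean,
            "total": w.total,
        })
    return pd.DataFrame(rows)


def standardize_within(
    df: pd.DataFrame, cols, by: str | None = "year", suffix: str = "_std"
) -> pd.DataFrame:
    """Append standardized (mean 0, SD 1 within ``by`` groups) copies of
    ``cols``; a zero-variance group standardizes to 0."""
    out = df.copy()
    for c in cols:
        if by is None:
            grouped = out[c]
            mu, sd = grouped.mean(), grouped.std(ddof=0)
            out[c + suffix] = 0.0 if sd == 0 else (grouped - mu) / sd
        else:
            def _z(s: pd.Series) -> pd.Series:
                sd = s.std(ddof=0)
                if sd == 0:
                    return s * 0.0
                return (s - s.mean()) / sd
            out[c + suffix] = out.groupby(by, group_keys=False)[c].apply(_z)
    return out


def biomass(mean_mass: float, abundance_index: float) -> float:
    """Larval biomass index: the product of larval size and the abundance
    index."""
    if mean_mass < 0 or abundance_index < 0:
        raise ValueError("mass and abundance must be non-negative")
    return float(mean_mass) * float(abundance_index)


def series_correlation(a, b) -> float:
    """Pearson product-moment correlation of two equal-length daily series;
    returns NaN (undefined) when either series has zero variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if a.size < 3:
        raise ValueError("need at least 3 points")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def pulse_strength(series) -> float:
    """Peakedness of a daily count series: max over median, with the median
    floored at one particle so a season of near-zero counts compares
    finitely."""
    s = np.asarray(series, dtype=float)
    return float(s.max() / max(np.median(s), 1.0))
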