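"""Single-cell MMP-ratio trajectory filtering and statistics.

A trajectory is one mother cell's time series of division count and the
two reporter signals: MMP_s (membrane-potential-sensitive, matrix-imported
fluorophore) and MMP_i (potential-insensitive inner-membrane tag). Their
ratio MMP_s/MMP_i reads out import capacity normalized to mitochondrial
mass. This module implements the standard quality filter (start at time
zero, stop before a terminal index, both signals above a floor), per-cell
mean-centering, the early-life mean ratio, its Pearson correlation with
replicative lifespan, binned mean trajectories, and windowed group
summaries with a cell-level bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CellTrajectory:
    cell_id: str
    experiment: str
    time: np.ndarray  # hours, strictly increasing
    divisions: np.ndarray  # non-decreasing integers
    mmp_s: np.ndarray
    mmp_i: np.ndarray
    died: bool
    divisions_at_death: Optional[int] = None

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (len(self.divisions) == len(self.mmp_s) == len(self.mmp_i) == n):
            raise ValueError("trajectory arrays must share a length")
        if n > 1:
            if not (np.diff(self.time) > 0).all():
                raise ValueError("times must be strictly increasing")
            if (np.diff(self.divisions) < 0).any():
                raise ValueError("division counts must be non-decreasing")
        if self.died and self.divisions_at_death is None:
            raise ValueError("a dead cell needs divisions_at_death")

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class TrajectorySet:
    cells: list[CellTrajectory]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for c in self.cells:
            key = (c.experiment, c.cell_id)
            if key in seen:
                raise ValueError(f"duplicate cell id {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            rows.append(pd.DataFrame({
                "cell_id": c.cell_id, "experiment": c.experiment,
                "time_h": c.time, "divisions": c.divisions,
                "mmp_s": c.mmp_s, "mmp_i": c.mmp_i, "died": c.died,
                "divisions_at_death": c.divisions_at_death
                if c.divisions_at_death is not None else np.nan,
            }))
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrajectorySet":
        cells = []
        for (exp, cid), g in df.groupby(["experiment", "cell_id"], sort=False):
            g = g.sort_values("time_h")
            dad = g["divisions_at_death"].iloc[0]
            cells.append(CellTrajectory(
                cell_id=str(cid), experiment=str(exp),
                time=g["time_h"].to_numpy(float),
                divisions=g["divisions"].to_numpy(int),
                mmp_s=g["mmp_s"].to_numpy(float),
                mmp_i=g["mmp_i"].to_numpy(float),
                died=bool(g["died"].iloc[0]),
                divisions_at_death=None if pd.isna(dad) else int(dad)))
        return cls(cells=cells)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrajectorySet":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class FilterReport:
    kept: TrajectorySet
    n_input: int
    n_removed_start: int
    n_removed_late_stop: int
    n_removed_low_signal: int


def filter_trajectories(tset: TrajectorySet, *, start_time: float = 0.0,
                        max_timepoint: int = 300,
                        min_signal: float = 50.0) -> FilterReport:
    """Keep trajectories that start at time zero, stop before a terminal
    sampling index, and keep both reporter signals above ``min_signal``.

    The stop rule is an index bound on the fluorescence sampling grid (the
    grid interval is inferred from each trajectory), guarding against false
    event calls at the end of a run. A trajectory failing several rules is
    attributed to the first one checked (start, then stop, then signal).
    Filtering is a pure selection: kept trajectories are unmodified.
    """
    kept = []
    n_start = n_stop = n_signal = 0
    for c in tset:
        if len(c) == 0 or c.time[0] != start_time:
            n_start += 1
            continue
        dt = float(np.min(np.diff(c.time))) if len(c) > 1 else 1.0
        last_index = int(round((c.time[-1] - start_time) / dt))
        if last_index >= max_timepoint:
            n_stop += 1
            continue
        if (c.mmp_s <= min_signal).any() or (c.mmp_i <= min_signal).any():
            n_signal += 1
            continue
        kept.append(c)
    return FilterReport(kept=TrajectorySet(cells=kept, metadata=tset.metadata),
                        n_input=len(tset), n_removed_start=n_start,
                        n_removed_late_stop=n_stop, n_removed_low_signal=n_signal)


def mmp_ratio(traj: CellTrajectory) -> np.ndarray:
    """Per-sample MMP ratio MMP_s / MMP_i (time base unchanged)."""
    if (traj.mmp_i <= 0).any():
        raise ValueError("mmp_i must be positive at every sample")
    return traj.mmp_s / traj.mmp_i


def center_trajectory(series: np.ndarray) -> np.ndarray:
    """Divide a ratio series by its mean, so the centered mean is 1."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    m = series.mean()
    if m <= 0:
        raise ValueError("series mean must be positive")
    return series / m


def early_life_mean(traj: CellTrajectory,
                    max_divisions: int = 5) -> Optional[float]:
    """Mean MMP ratio over samples taken at 0..max_divisions (inclusive).

    Returns None when the trajectory has no qualifying sample; such cells
    are excluded from the lifespan correlation.
    """
    mask = traj.divisions <= max_divisions
    if not mask.any():
        return None
    return float(np.mean(mmp_ratio(traj)[mask]))


def lifespan_correlation(tset: TrajectorySet,
                         max_divisions: int = 5) -> CorrelationResult:
    """Pearson correlation of early-life mean MMP ratio with replicative
    lifespan, over cells observed to die.

    Censored cells, and cells with no sample inside the early-life window,
    are excluded. Raw (uncentered) ratios are used: centering by the
    lifetime mean would leak lifespan information into the predictor.
    """
    early, life = [], []
    for c in tset:
        if not c.died or c.divisions_at_death is None:
            continue
        e = early_life_mean(c, max_divisions)
        if e is None:
            continue
        early.append(e)
        life.append(c.divisions_at_death)
    n = len(early)
    if n < 3:
        raise ValueError(f"need at least 3 dead cells with early-life data, "
                         f"got {n}")
    r, p = stats.pearsonr(early, life)
    return CorrelationResult(r=float(r), p=float(p), n=n)


def mean_trajectory(tset: TrajectorySet, axis: str = "time",
                    bin_width: float = 2.0, center: bool = True) -> pd.DataFrame:
    """Binned population mean (+/- 2 SEM) of per-cell MMP-ratio series.

    ``axis`` is "time" (hours) or "divisions". Each cell contributes its
    (optionally mean-centered) ratio samples to the bins its samples fall
    in; bins touched by fewer than two cells are flagged.
    """
    if axis not in ("time", "divisions"):
        raise ValueError("axis must be 'time' or 'divisions'")
    if len(tset) == 0:
        raise ValueError("empty trajectory set")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    xs, ys, cells = [], [], []
    for i, c in enumerate(tset):
        ratio = mmp_ratio(c)
        if center:
            ratio = center_trajectory(ratio)
        x = c.time if axis == "time" else c.divisions
        xs.append(np.asarray(x, float))
        ys.append(ratio)
        cells.append(np.full(len(c), i))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    cell = np.concatenate(cells)
    bins = np.floor(x / bin_width).astype(int)
    rows = []
    for b in np.unique(bins):
        sel = bins == b
        # mean of per-cell means so heavily sampled cells do not dominate
        per_cell = pd.Series(y[sel]).groupby(cell[sel]).mean()
        m = per_cell.mean()
        sem = per_cell.std(ddof=1) / np.sqrt(len(per_cell)) \
            if len(per_cell) > 1 else np.nan
        rows.append({"bin_start": b * bin_width, "mean": m,
                     "sem": sem, "two_sem": 2 * sem, "n_cells": len(per_cell),
                     "n_samples": int(sel.sum()),
                     "underpopulated": len(per_cell) < 2})
    return pd.DataFrame(rows)


def window_mean(tset: TrajectorySet, t0: float = 21.5, t1: float = 26.5, *,
                group_by: Callable[[CellTrajectory], str] = lambda c: c.experiment,
                n_boot: int = 1000, ci: float = 0.95,
                seed: int = 0) -> pd.DataFrame:
    """Group mean of log10 MMP ratio over samples in the age window [t0, t1].

    The confidence interval is a nonparametric bootstrap over cells (cells,
    not samples, are the independent units). Groups with no sample in the
    window are reported empty and flagged.
    """
    if not t1 > t0:
        raise ValueError("window must be non-degenerate (t1 > t0)")
    rng = np.random.default_rng(seed)
    per_group: dict[str, list[float]] = {}
    for c in tset:
        mask = (c.time >= t0) & (c.time <= t1)
        g = group_by(c)
        per_group.setdefault(g, [])
        if mask.any():
            per_group[g].append(float(np.mean(np.log10(mmp_ratio(c)[mask]))))
    alpha = (1 - ci) / 2
    rows = []
    for g, vals in sorted(per_group.items()):
        if not vals:
            rows.append({"group": g, "n_cells": 0, "mean_log10_ratio": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "empty": True})
            continue
        arr = np.asarray(vals)
        boots = np.array([
            arr[rng.integers(0, len(arr), len(arr))].mean()
            for _ in range(n_boot)])
        lo, hi = np.quantile(boots, [alpha, 1 - alpha])
        rows.append({"group": g, "n_cells": len(arr),
                     "mean_log10_ratio": float(arr.mean()),
                     "ci_low": float(lo), "ci_high": float(hi), "empty": False})
    return pd.DataFrame(rows)
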