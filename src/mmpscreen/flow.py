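"""Signal corrections for flow-cytometry and plate-reader assays.

TMRM (and similar dyes) leak out of cells during analysis, so the measured
mean signal of a sample decays exponentially with time on the instrument.
Measuring each sample in several passes identifies the decay rate; the
corrected signal is the fitted value at t = 0. The module also provides
the background-subtracted 572/546 excitation ratio for isolated
mitochondria, the mitochondrial-mass adjustment of reporter signals, and
the antimycin-difference mitochondrial oxygen consumption rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DecaySeries:
    """Repeated passes of one sample: strictly increasing times (minutes)
    and the mean signal measured at each pass."""

    sample: str
    group: str
    times: np.ndarray
    signals: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        s = np.asarray(self.signals, float)
        if len(t) != len(s):
            raise ValueError("times and signals must have equal length")
        if len(t) < 2:
            raise ValueError("at least 2 passes are required")
        if not (np.diff(t) > 0).all():
            raise ValueError("pass times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample": self.sample, "group": self.group,
                             "time_min": self.times, "mean_signal": self.signals})


@dataclass(frozen=True)
class CorrectedSignal:
    sample: str
    rate_constant: float  # per minute
    signal_t0: float
    r_squared: float


@dataclass(frozen=True)
class MassAdjustment:
    d: float  # fractional change of MMP_i vs WT
    adjusted_mmps: float


def _loglinear(t: np.ndarray, logs: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope/intercept of log-signal on time, plus R^2."""
    slope, intercept = np.polyfit(t, logs, 1)
    fitted = intercept + slope * t
    ss_res = float(np.sum((logs - fitted) ** 2))
    ss_tot = float(np.sum((logs - logs.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def fit_decay(series: Sequence[DecaySeries] | DecaySeries,
              pooled: bool = False) -> list[CorrectedSignal]:
    """Exponential decay correction by log-linear least squares.

    Per sample, log(signal) is regressed on pass time; the decay rate is
    the negated slope and the corrected signal is the intercept
    exponentiated (the signal at t = 0). With ``pooled=True`` all samples
    in a group share one decay rate (a common slope with per-sample
    intercepts), mirroring replicate sets measured together.
    """
    if isinstance(series, DecaySeries):
        series = [series]
    if not series:
        raise ValueError("no decay series given")
    for s in series:
        if (np.asarray(s.signals) <= 0).any():
            raise ValueError(f"sample {s.sample!r} has non-positive signals; "
                             "log-linear decay fit is undefined")
    if not pooled:
        out = []
        for s in series:
            slope, intercept, r2 = _loglinear(np.asarray(s.times, float),
                                              np.log(np.asarray(s.signals, float)))
            out.append(CorrectedSignal(sample=s.sample, rate_constant=-slope,
                                       signal_t0=float(np.exp(intercept)),
                                       r_squared=r2))
        return out

    out = []
    groups: dict[str, list[DecaySeries]] = {}
    for s in series:
        groups.setdefault(s.group, []).append(s)
    for gname, members in groups.items():
        # common slope, per-sample intercept: center times/logs per sample
        t_all, y_all = [], []
        for s in members:
            t = np.asarray(s.times, float)
            y = np.log(np.asarray(s.signals, float))
            t_all.append(t - t.mean())
            y_all.append(y - y.mean())
        t_c = np.concatenate(t_all)
        y_c = np.concatenate(y_all)
        denom = float(np.sum(t_c ** 2))
        if denom == 0:
            raise ValueError(f"group {gname!r} has no time spread")
        slope = float(np.sum(t_c * y_c) / denom)
        for s in members:
            t = np.asarray(s.times, float)
            y = np.log(np.asarray(s.signals, float))
            intercept = float(y.mean() - slope * t.mean())
            fitted = intercept + slope * t
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            r2 = 1.0 if ss_tot == 0 else \
                1 - float(np.sum((y - fitted) ** 2)) / ss_tot
            out.append(CorrectedSignal(sample=s.sample, rate_constant=-slope,
                                       signal_t0=float(np.exp(intercept)),
                                       r_squared=r2))
    return out


@dataclass(frozen=True)
class PlateWellPair:
    """One signal well and its paired DMSO background well, each with
    per-timepoint emission-605 readings under 546- and 572-nm excitation."""

    signal_ex546: np.ndarray
    signal_ex572: np.ndarray
    background_ex546: np.ndarray
    background_ex572: np.ndarray

    def __post_init__(self) -> None:
        if len(self.signal_ex546) != len(self.signal_ex572):
            raise ValueError("signal channels must share timepoints")


@dataclass(frozen=True)
class TmrmRatioResult:
    ratios: np.ndarray  # per-timepoint, NaN where invalid
    mean_ratio: float
    n_invalid: int


def tmrm_ratio(pair: PlateWellPair) -> TmrmRatioResult:
    """Background-subtracted 572/546 excitation ratio, averaged over time.

    The background of each excitation wavelength is averaged over that
    condition's background wells, subtracted from the signal well, and the
    ratio formed per timepoint before averaging. Timepoints whose
    background-subtracted denominator is non-positive are flagged invalid
    and excluded; if every timepoint is invalid the measurement fails.
    """
    bg546 = float(np.mean(pair.background_ex546))
    bg572 = float(np.mean(pair.background_ex572))
    num = np.asarray(pair.signal_ex572, float) - bg572
    den = np.asarray(pair.signal_ex546, float) - bg546
    valid = den > 0
    ratios = np.where(valid, num / np.where(valid, den, 1.0), np.nan)
    if not valid.any():
        raise ValueError("all timepoints have non-positive background-"
                         "subtracted 546 signal")
    return TmrmRatioResult(ratios=ratios,
                           mean_ratio=float(np.nanmean(ratios)),
                           n_invalid=int((~valid).sum()))


def mass_adjust(mmps_mutant: float, mmpi_mutant_mean: float,
                mmpi_wt_mean: float,
                direction: Literal["multiply", "divide"] = "multiply",
                ) -> MassAdjustment:
    """Adjust a mutant's MMP_s signal for its mitochondrial mass.

    The fractional change of the mass proxy is d = MMP_i_mutant /
    MMP_i_WT - 1; the mutant's MMP_s is then multiplied by (1 + d)
    (``direction="multiply"``, the default) or divided by it
    (``direction="divide"``, reading the adjustment as a per-mass
    normalization). WT itself has d = 0 and is unchanged either way.
    """
    if mmps_mutant <= 0 or mmpi_mutant_mean <= 0 or mmpi_wt_mean <= 0:
        raise ValueError("signals must be positive")
    d = mmpi_mutant_mean / mmpi_wt_mean - 1.0
    if d <= -1:
        raise ValueError("fractional change d must exceed -1")
    if direction == "multiply":
        adjusted = mmps_mutant * (1.0 + d)
    elif direction == "divide":
        adjusted = mmps_mutant / (1.0 + d)
    else:
        raise ValueError("direction must be 'multiply' or 'divide'")
    return MassAdjustment(d=float(d), adjusted_mmps=float(adjusted))


def mito_ocr(before: Sequence[float], after: Sequence[float]) -> float:
    """Mitochondrial oxygen consumption rate from an antimycin injection.

    The complex-III inhibitor abolishes mitochondrial respiration, so the
    mitochondrial OCR is mean(before) - mean(after injection).
    """
    before = np.asarray(before, float)
    after = np.asarray(after, float)
    if before.size == 0 or after.size == 0:
        raise ValueError("each phase needs at least one measurement")
    return float(before.mean() - after.mean())
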