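"""Ranking strains by enrichment in high- vs low-MMP sorted bins.

Counts from the sequenced low/medium/high FACS bins are pooled over
technical replicates; each strain gets a pseudocounted log2 fold change
(high vs low), a conditional exact binomial p-value, and a
Benjamini-Hochberg q-value. A closed-form Deming (errors-in-variables)
regression supports cross-experiment concordance checks where both axes
are measured with error.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class BinCountMatrix:
    """Strain x sample counts plus per-sample bin/timepoint/replicate labels."""

    counts: pd.DataFrame  # index strain_id, columns sample
    samples: pd.DataFrame  # index sample; columns include bin, timepoint

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)}")
        if "bin" not in self.samples.columns:
            raise ValueError("sample sheet must have a 'bin' column")
        if self.samples.loc[list(self.counts.columns), "bin"].isna().any():
            raise ValueError("every sample needs a bin label")

    def pooled(self, bin_name: str) -> pd.Series:
        """Counts summed over all samples in one bin (replicates pooled)."""
        cols = [s for s in self.counts.columns
                if self.samples.loc[s, "bin"] == bin_name]
        if not cols:
            raise ValueError(f"no samples in bin {bin_name!r}")
        return self.counts[cols].sum(axis=1)

    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "BinCountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t").set_index("sample")
        return cls(counts, samples)

    def to_tsv(self, counts_path, samples_path=None) -> None:
        self.counts.to_csv(counts_path, sep="\t")
        if samples_path is not None:
            self.samples.to_csv(samples_path, sep="\t")


@dataclass(frozen=True)
class DemingFit:
    slope: float
    intercept: float
    variance_ratio: float

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x)


def log2_enrichment(counts: BinCountMatrix,
                    pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.Series:
    """Per-strain log2 fold change of high- vs low-bin relative frequency.

    Frequencies use a pseudocount of ``pseudocount`` per strain per bin:
    log2((c_h + a) / (N_h + S a)) - log2((c_l + a) / (N_l + S a)) with
    replicate-pooled counts c, library sizes N, and S strains, so zero
    counts stay finite.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    c_high = counts.pooled("high")
    c_low = counts.pooled("low")
    n_high, n_low = c_high.sum(), c_low.sum()
    if n_high == 0 or n_low == 0:
        raise ValueError("a bin has an all-zero library; cannot form frequencies")
    s = len(c_high)
    f_high = (c_high + pseudocount) / (n_high + s * pseudocount)
    f_low = (c_low + pseudocount) / (n_low + s * pseudocount)
    return pd.Series(np.log2(f_high / f_low), index=c_high.index, name="log2fc")


def enrichment_test(counts: BinCountMatrix) -> pd.Series:
    """Conditional exact binomial p-value per strain, high vs low bin.

    Conditions on each strain's total n = c_high + c_low and tests
    c_high ~ Binomial(n, p0) with p0 = N_high / (N_high + N_low); two-sided
    by the minimal-likelihood rule (sum of outcome probabilities no larger
    than the observed one). Strains with n = 0 get p = 1 by convention.
    """
    c_high = counts.pooled("high")
    c_low = counts.pooled("low")
    n_high, n_low = int(c_high.sum()), int(c_low.sum())
    if n_high + n_low == 0:
        raise ValueError("all-zero libraries")
    p0 = n_high / (n_high + n_low)
    pvals = np.ones(len(c_high))
    for i, (ch, cl) in enumerate(zip(c_high.to_numpy(), c_low.to_numpy())):
        n = int(ch) + int(cl)
        if n == 0:
            continue
        pvals[i] = stats.binomtest(int(ch), n, p0).pvalue
    return pd.Series(pvals, index=c_high.index, name="p_value")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, monotone and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def enrich(counts: BinCountMatrix,
           pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Full per-strain enrichment table: counts, log2fc, p, q."""
    lfc = log2_enrichment(counts, pseudocount)
    p = enrichment_test(counts)
    return pd.DataFrame({
        "counts_high": counts.pooled("high"),
        "counts_low": counts.pooled("low"),
        "log2fc": lfc,
        "p_value": p,
        "q_value": bh_adjust(p.to_numpy()),
    })


def select_top(results: pd.DataFrame, n: int) -> pd.DataFrame:
    """Top-n strains by (q ascending, log2fc descending, strain_id).

    The strain_id tiebreak makes the ranking a total order, so the output
    is invariant to input permutation. Requesting more strains than exist
    returns everything with a warning.
    """
    if len(results) == 0:
        raise ValueError("empty results")
    if n < 0:
        raise ValueError("n must be non-negative")
    ranked = results.copy()
    ranked["_id"] = ranked.index.astype(str)
    ranked = ranked.sort_values(["q_value", "log2fc", "_id"],
                                ascending=[True, False, True]).drop(columns="_id")
    if n > len(ranked):
        import warnings
        warnings.warn(f"requested top {n} but only {len(ranked)} strains exist")
        n = len(ranked)
    return ranked.head(n)


def deming_fit(x, y, lam: float = 1.0) -> DemingFit:
    """Closed-form Deming (errors-in-variables) regression.

    Minimizes the sum of squared perpendicular distances weighted by the
    error-variance ratio ``lam`` = var(y errors) / var(x errors):

        slope = (s_yy - lam s_xx + sqrt((s_yy - lam s_xx)^2 + 4 lam s_xy^2))
                / (2 s_xy)

    At lam = 1 this is orthogonal regression; swapping the axes inverts
    the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam <= 0:
        raise ValueError("variance ratio lambda must be positive")
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if len(np.unique(np.column_stack([x, y]), axis=0)) < 2:
        raise ValueError("need at least 2 distinct points")
    xbar, ybar = x.mean(), y.mean()
    s_xx = np.mean((x - xbar) ** 2)
    s_yy = np.mean((y - ybar) ** 2)
    s_xy = np.mean((x - xbar) * (y - ybar))
    if s_xy == 0:
        if np.isclose(s_yy, lam * s_xx):
            raise ValueError("degenerate data: orientation of the Deming "
                             "line is undefined (s_xy = 0, s_yy = lam*s_xx)")
        if s_yy > lam * s_xx:
            raise ValueError("degenerate data: best-fit Deming line is "
                             "vertical (s_xy = 0, s_yy > lam*s_xx)")
        slope = 0.0
    else:
        d = s_yy - lam * s_xx
        slope = (d + np.sqrt(d * d + 4 * lam * s_xy ** 2)) / (2 * s_xy)
    return DemingFit(slope=float(slope),
                     intercept=float(ybar - slope * xbar),
                     variance_ratio=float(lam))
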