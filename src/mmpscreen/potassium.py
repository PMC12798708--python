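"""Internal-potassium estimation for young and aged yeast cultures.

Young, exponentially growing cultures are morphologically uniform, so
their internal concentration is simply total measured potassium divided by
(cell count x mean spherical cell volume). Aged cultures harvested
without fixation are contaminated with newly budded daughters, so the
Coulter diameter distribution is deconvolved as a three-component Gaussian
mixture: the smallest-mean component is the daughter class, the two
larger components together are the old mothers. Old-cell potassium is
then bounded two ways: assuming daughters hold the young-culture
concentration (point estimate) and assuming they hold none (upper bound).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
from scipy import stats

VARIANCE_FLOOR = 1e-4  # um^2
EM_TOL = 1e-8
EM_MAX_ITER = 500
N_STARTS = 10


@dataclass(frozen=True)
class SizeDistribution:
    diameters: np.ndarray  # um
    total_cell_count: float
    culture: str = "culture"

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters, float)
        if (d <= 0).any():
            raise ValueError("diameters must be positive")
        if self.total_cell_count <= 0:
            raise ValueError("total_cell_count must be positive")


@dataclass(frozen=True)
class MixtureFit:
    """Three-component univariate Gaussian mixture, components sorted by
    ascending mean so the daughter class is always index 0."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    converged: bool
    log_likelihood: float
    n_iter: int
    loglik_trace: np.ndarray  # per-iteration log-likelihood of the best start
    variance_floored: bool = False

    @property
    def daughter_index(self) -> int:
        return int(np.argmin(self.means))  # 0 after relabeling


@dataclass(frozen=True)
class PopulationSplit:
    n_daughter: float
    n_old: float
    mean_volume_daughter: float  # fL
    mean_volume_old: float  # fL


@dataclass(frozen=True)
class PotassiumMeasurement:
    """Blank-subtracted total potassium of one filtered culture sample."""

    total_potassium_mol: float
    n_cells_sampled: float
    blank_potassium_mol: float = 0.0


@dataclass(frozen=True)
class PotassiumEstimate:
    estimate_young_daughters: float  # mM
    upper_bound: float  # mM
    negative_estimate: bool


def volume_from_diameter(d) -> np.ndarray | float:
    """Spherical volume of a cell of diameter ``d`` um, in fL (= um^3)."""
    d = np.asarray(d, dtype=float)
    if (d <= 0).any():
        raise ValueError("diameter must be positive")
    v = np.pi / 6.0 * d ** 3
    return float(v) if v.ndim == 0 else v


def internal_concentration(meas: PotassiumMeasurement,
                           mean_volume_fl: float) -> float:
    """Internal potassium concentration in mM.

    concentration = (total - blank) / (n_cells x volume). A negative
    blank-subtracted total is reported as 0 mM with a warning rather than
    a negative concentration.
    """
    if meas.n_cells_sampled <= 0 or mean_volume_fl <= 0:
        raise ValueError("cell count and mean volume must be positive")
    net = meas.total_potassium_mol - meas.blank_potassium_mol
    if net < 0:
        warnings.warn("blank exceeds measured potassium; reporting 0 mM")
        return 0.0
    # mol / (cells * fL): fL -> L is 1e-15, M -> mM is 1e3
    return net / (meas.n_cells_sampled * mean_volume_fl * 1e-15) * 1e3


# ---------------------------------------------------------------------------
# three-component Gaussian mixture by EM
# ---------------------------------------------------------------------------


def _kmeanspp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ style seeding: spread initial centers over the data."""
    centers = [x[rng.integers(len(x))]]
    for _ in range(k - 1):
        d2 = np.min([(x - c) ** 2 for c in centers], axis=0)
        total = d2.sum()
        if total == 0:
            centers.append(x[rng.integers(len(x))])
        else:
            centers.append(x[rng.choice(len(x), p=d2 / total)])
    return np.asarray(centers)


def _em_once(x: np.ndarray, rng: np.random.Generator, max_iter: int,
             tol: float, var_floor: float
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float], bool, bool]:
    n, k = len(x), 3
    means = _kmeanspp_init(x, k, rng)
    sds = np.full(k, max(x.std(), np.sqrt(var_floor)))
    weights = np.full(k, 1.0 / k)
    trace: list[float] = []
    floored = False
    converged = False
    for _ in range(max_iter):
        # E step
        logpdf = stats.norm.logpdf(x[:, None], means[None, :], sds[None, :]) \
            + np.log(weights[None, :])
        m = logpdf.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logpdf - m).sum(axis=1))
        ll = float(lse.sum())
        resp = np.exp(logpdf - lse[:, None])
        if trace and abs(ll - trace[-1]) < tol * max(1.0, abs(trace[-1])):
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        if (var < var_floor).any():
            floored = True
            var = np.maximum(var, var_floor)
        sds = np.sqrt(var)
    return means, sds, weights, trace, converged, floored


def fit_gmm3(sizes: SizeDistribution, n_starts: int = N_STARTS, seed: int = 0,
             *, max_iter: int = EM_MAX_ITER, tol: float = EM_TOL,
             variance_floor: float = VARIANCE_FLOOR) -> MixtureFit:
    """Maximum-likelihood three-Gaussian fit of a diameter distribution.

    Runs ``n_starts`` seeded EM restarts with k-means++-style center
    seeding and keeps the best log-likelihood. Components are relabeled by
    ascending mean, so results do not depend on initialization order and
    the daughter class is index 0. Components collapsing below the
    variance floor are floored and flagged rather than allowed to
    degenerate; a fit that never reaches the tolerance in any start is
    returned with ``converged=False``.
    """
    x = np.asarray(sizes.diameters, dtype=float)
    if len(x) < 30:
        raise ValueError("need at least 30 diameter observations")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        means, sds, weights, trace, converged, floored = \
            _em_once(x, rng, max_iter, tol, variance_floor)
        if best is None or trace[-1] > best[3][-1]:
            best = (means, sds, weights, trace, converged, floored)
    means, sds, weights, trace, converged, floored = best
    order = np.argsort(means)
    return MixtureFit(means=means[order], sds=sds[order], weights=weights[order],
                      converged=converged, log_likelihood=float(trace[-1]),
                      n_iter=len(trace), loglik_trace=np.asarray(trace),
                      variance_floored=floored)


def split_population(fit: MixtureFit, total_cell_count: float,
                     moment_correct: bool = False) -> PopulationSplit:
    """Apportion a culture's cells between daughters and old mothers.

    Counts follow the fitted weights; per-class mean volumes use the
    sphere of the component mean diameter (``moment_correct=True`` instead
    uses E[d^3] = mu^3 + 3 mu sigma^2 for Gaussian diameters, removing the
    Jensen bias). The old class pools the two larger components,
    volume-weighted by their fitted weights.
    """
    if not fit.converged:
        raise ValueError("mixture fit did not converge; refuse to split")
    if total_cell_count <= 0:
        raise ValueError("total_cell_count must be positive")

    def comp_vol(mu: float, sd: float) -> float:
        if moment_correct:
            return float(np.pi / 6.0 * (mu ** 3 + 3 * mu * sd ** 2))
        return float(volume_from_diameter(mu))

    w = fit.weights
    vols = np.array([comp_vol(m, s) for m, s in zip(fit.means, fit.sds)])
    n_d = float(w[0] * total_cell_count)
    n_o = float((w[1] + w[2]) * total_cell_count)
    v_old = float((w[1] * vols[1] + w[2] * vols[2]) / (w[1] + w[2]))
    return PopulationSplit(n_daughter=n_d, n_old=n_o,
                           mean_volume_daughter=float(vols[0]),
                           mean_volume_old=v_old)


def old_cell_potassium(split: PopulationSplit, meas: PotassiumMeasurement,
                       c_young_mm: float) -> PotassiumEstimate:
    """Bound the internal potassium concentration of old mother cells.

    Point estimate: daughters hold the young-culture concentration
    ``c_young_mm``, so their share is subtracted before dividing by the
    old-cell volume. Upper bound: daughters hold no potassium, so all
    measured potassium is attributed to old cells. A negative point
    estimate (daughter correction exceeding the measurement) is reported
    with a warning, never silently clipped.
    """
    if split.n_old <= 0:
        raise ValueError("no old cells in the split")
    net = meas.total_potassium_mol - meas.blank_potassium_mol
    old_litres = split.n_old * split.mean_volume_old * 1e-15
    daughter_mol = split.n_daughter * split.mean_volume_daughter * 1e-15 \
        * c_young_mm * 1e-3
    estimate = (net - daughter_mol) / old_litres * 1e3
    upper = net / old_litres * 1e3
    negative = estimate < 0
    if negative:
        warnings.warn("daughter correction exceeds measured potassium; "
                      "old-cell estimate is negative")
    return PotassiumEstimate(estimate_young_daughters=float(estimate),
                             upper_bound=float(upper),
                             negative_estimate=bool(negative))
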