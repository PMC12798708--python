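"""Synthetic inputs with the statistical structure the pipeline assumes.

Five generators emulate the data the analysis consumes:

* a barcoded deletion-collection catalog (~4,700 strains, unique 20-nt
  barcodes between constant flanks),
* a pooled FACS screen in which each strain's cells carry a log-normal
  MMP ratio, the pooled distribution is split into low/medium/high thirds,
  and per-bin barcode reads are sequenced as error-bearing paired ends,
* single-cell MMP-ratio trajectories declining with replicative age, with
  a planted correlation between early-life MMP and lifespan,
* exponentially decaying repeated-pass fluorescence signals, and
* three-Gaussian cell-diameter mixtures with class-specific potassium
  content (daughter contamination of an aged culture).

Every generator is a pure function of its config, including the seed, and
emits a truth table alongside the data so downstream recovery tests always
compare against the generating parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._seq import BASES, phred_to_string
from .barcodes import BarcodeCatalog

# Constant regions bordering the variable barcode; same role as the
# universal priming sites around the deletion-collection UPTAGs.
DEFAULT_FLANK_UP = "GATGTCCACGAGGTCTCT"
DEFAULT_FLANK_DOWN = "CGTACGCTGCAGGTCGAC"

BIN_NAMES = ("low", "medium", "high")


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class ScreenSimConfig:
    """Design of a simulated pooled MMP sorting screen.

    ``hit_effect`` shifts a hit strain's mean log MMP ratio upward, in
    units of the within-strain (cell-level) standard deviation. Strain
    abundances are log-normal with sd ``abundance_dispersion`` to emulate
    pool skew (some mutants are underrepresented in real pools).
    """

    n_strains: int = 4700
    barcode_length: int = 20
    min_pairwise_hamming: int = 5
    flank_up: str = DEFAULT_FLANK_UP
    flank_down: str = DEFAULT_FLANK_DOWN
    substitution_rate: float = 0.005
    flank_mismatch_rate: float = 0.01
    junk_read_fraction: float = 0.01
    read_depth: int = 200_000
    n_hit_strains: int = 35
    hit_effect: float = 2.0
    abundance_dispersion: float = 0.5
    seed: int = 0
    # secondary knobs (not part of the screen design proper)
    n_replicates: int = 2
    timepoint: str = "T24"
    #: cells sorted into bins; None = infinite-pool limit (analytic tertile
    #: masses, read sampling the only noise source)
    n_pool_cells: Optional[int] = 300_000
    cell_sd: float = 1.0  # within-strain sd of log MMP ratio

    def __post_init__(self) -> None:
        if self.n_strains <= 0 or self.barcode_length <= 0:
            raise ValueError("n_strains and barcode_length must be positive")
        if self.n_hit_strains > self.n_strains:
            raise ValueError("n_hit_strains cannot exceed n_strains")
        if self.min_pairwise_hamming > self.barcode_length:
            raise ValueError("min_pairwise_hamming cannot exceed barcode_length")
        if self.min_pairwise_hamming < 0:
            raise ValueError("min_pairwise_hamming must be non-negative")
        for name in ("substitution_rate", "flank_mismatch_rate", "junk_read_fraction"):
            _check_prob(name, getattr(self, name))
        if self.read_depth < 0:
            raise ValueError("read_depth must be non-negative")
        if self.abundance_dispersion <= 0 or self.cell_sd <= 0:
            raise ValueError("dispersions must be positive")


@dataclass(frozen=True)
class TrajectorySimConfig:
    """Design of simulated single-cell MMP-ratio trajectories.

    Fluorescence is sampled every ``sample_interval_h`` (the 2-h imaging
    cadence); divisions accrue uniformly at one per ``division_interval_h``
    (1.5 h nominal budding rate). ``target_correlation`` is the planted
    Pearson correlation between a cell's early-life mean MMP ratio and the
    number of divisions it completes before death.
    """

    n_cells: int = 1000
    target_correlation: float = 0.55
    decline_per_division: float = 0.05
    noise_sd: float = 0.05
    censor_fraction: float = 0.1
    seed: int = 0
    sample_interval_h: float = 2.0
    division_interval_h: float = 1.5
    mean_lifespan: float = 25.0
    sd_lifespan: float = 8.0
    initial_ratio_sd: float = 0.15  # sd of log initial MMP ratio across cells
    base_mmp_s: float = 800.0
    base_mmp_i: float = 400.0
    experiment: str = "sim"

    def __post_init__(self) -> None:
        if not -1.0 < self.target_correlation < 1.0:
            raise ValueError("target_correlation must lie strictly in (-1, 1)")
        _check_prob("censor_fraction", self.censor_fraction)
        if self.decline_per_division <= 0 or not self.decline_per_division < 1:
            raise ValueError("decline_per_division must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class SizeSimConfig:
    """Three-Gaussian cell-diameter mixture for an aged culture.

    The smallest-mean component plays the daughter class; the two larger
    components are old mothers. Default geometry mimics a 48-h aged yeast
    culture with heavy daughter contamination.
    """

    component_means: tuple[float, float, float] = (3.0, 5.0, 6.5)
    component_sds: tuple[float, float, float] = (0.3, 0.3, 0.3)
    component_weights: tuple[float, float, float] = (0.5, 0.3, 0.2)
    n_cells: int = 50_000
    daughter_concentration: float = 200.0  # mM
    old_concentration: float = 150.0  # mM
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.component_means) != 3 or len(self.component_sds) != 3 \
                or len(self.component_weights) != 3:
            raise ValueError("exactly three mixture components are required")
        if any(m <= 0 for m in self.component_means):
            raise ValueError("component means must be strictly positive")
        if any(s <= 0 for s in self.component_sds):
            raise ValueError("component sds must be strictly positive")
        if abs(sum(self.component_weights) - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------


def make_catalog(cfg: ScreenSimConfig) -> BarcodeCatalog:
    """Random barcode catalog with a guaranteed pairwise Hamming separation.

    Candidates are drawn uniformly and accepted only when at least
    ``cfg.min_pairwise_hamming`` mismatches from every accepted barcode;
    after a bounded number of rejections the separation is declared
    infeasible.
    """
    rng = np.random.default_rng(cfg.seed)
    L, n = cfg.barcode_length, cfg.n_strains
    max_attempts = 200 * n + 1000
    accepted = np.empty((n, L), dtype=np.uint8)
    n_acc = 0
    attempts = 0
    while n_acc < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n} barcodes of length {L} at pairwise "
                f"Hamming >= {cfg.min_pairwise_hamming} within {max_attempts} "
                "attempts; relax the separation constraint")
        cand = rng.integers(0, 4, size=L, dtype=np.uint8)
        if n_acc and int((accepted[:n_acc] != cand).sum(axis=1).min()) \
                < cfg.min_pairwise_hamming:
            continue
        accepted[n_acc] = cand
        n_acc += 1
    barcodes = ["".join(BASES[b] for b in row) for row in accepted]
    records = pd.DataFrame({
        "strain_id": [f"strain{i:05d}" for i in range(n)],
        "gene": [f"GENE{i:05d}" for i in range(n)],
        "barcode": barcodes,
    })
    return BarcodeCatalog(records, cfg.flank_up, cfg.flank_down)


# ---------------------------------------------------------------------------
# screen simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedRead:
    read_id: str
    seq1: str
    qual1: np.ndarray
    seq2: str
    qual2: np.ndarray


@dataclass
class ScreenData:
    """Everything the screen generator emits, plus writers."""

    reads: dict[str, list[SimulatedRead]]  # sample -> read pairs
    true_counts: pd.DataFrame  # strain x sample emitted-read counts
    sample_sheet: pd.DataFrame
    truth_hits: pd.DataFrame  # strain_id, is_hit, hit_effect
    bin_probs: pd.DataFrame  # strain x bin membership probabilities

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sample, pairs in self.reads.items():
            with open(outdir / f"{sample}_R1.fastq", "w") as f1, \
                    open(outdir / f"{sample}_R2.fastq", "w") as f2:
                for r in pairs:
                    f1.write(f"@{r.read_id}/1\n{r.seq1}\n+\n"
                             f"{phred_to_string(r.qual1)}\n")
                    f2.write(f"@{r.read_id}/2\n{r.seq2}\n+\n"
                             f"{phred_to_string(r.qual2)}\n")
        self.true_counts.to_csv(outdir / "truth_counts.tsv", sep="\t")
        self.sample_sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
        self.truth_hits.to_csv(outdir / "truth_hits.tsv", sep="\t", index=False)


def _mutate(rng: np.random.Generator, seq: np.ndarray, positions: np.ndarray) -> None:
    """Substitute the given positions with a uniformly different base (in place)."""
    if len(positions) == 0:
        return
    shift = rng.integers(1, 4, size=len(positions)).astype(np.uint8)
    seq[positions] = (seq[positions] + shift) % 4


def simulate_bin_counts(catalog: BarcodeCatalog, cfg: ScreenSimConfig
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame,
                                   pd.DataFrame]:
    """Sort a simulated pool into MMP-ratio thirds and sequence each bin.

    Returns (true_counts, sample_sheet, truth_hits, bin_probs). Cells are
    drawn per strain according to log-normal abundances; each cell's log
    MMP ratio is Normal(mu_strain, cell_sd) with hit strains shifted up by
    ``hit_effect * cell_sd``; bins are the empirical tertiles of the pooled
    ratio; per-bin read counts are multinomial over the bin's strain
    composition.

    With ``n_pool_cells=None`` the infinite-pool limit is used instead:
    tertile cut points come from the analytic pooled mixture CDF and the
    per-bin composition from exact normal tail masses, so read sampling is
    the only stochastic step. A finite pool adds sorting noise on top of
    read sampling (as a real FACS experiment does), which overdisperses
    counts relative to the read-multinomial model.
    """
    from scipy import stats as _stats
    from scipy.optimize import brentq

    rng = np.random.default_rng(cfg.seed)
    n = len(catalog)
    strains = catalog.strain_ids

    abundance = rng.lognormal(mean=0.0, sigma=cfg.abundance_dispersion, size=n)
    abundance /= abundance.sum()
    hit_idx = rng.choice(n, size=cfg.n_hit_strains, replace=False)
    mu = np.zeros(n)
    mu[hit_idx] = cfg.hit_effect * cfg.cell_sd

    comp = np.zeros((3, n))
    if cfg.n_pool_cells is not None:
        # pooled cells: strain identity then a cell-level log-ratio
        cell_strain = rng.choice(n, size=cfg.n_pool_cells, p=abundance)
        log_ratio = mu[cell_strain] \
            + cfg.cell_sd * rng.standard_normal(cfg.n_pool_cells)
        q1, q2 = np.quantile(log_ratio, [1 / 3, 2 / 3])
        cell_bin = np.digitize(log_ratio, [q1, q2])  # 0=low, 1=medium, 2=high
        for b in range(3):
            comp[b] = np.bincount(cell_strain[cell_bin == b], minlength=n)
    else:
        def mixture_cdf(x: float) -> float:
            return float(np.sum(abundance * _stats.norm.cdf(
                (x - mu) / cfg.cell_sd)))

        lo = float(mu.min() - 10 * cfg.cell_sd)
        hi = float(mu.max() + 10 * cfg.cell_sd)
        q1 = brentq(lambda x: mixture_cdf(x) - 1 / 3, lo, hi)
        q2 = brentq(lambda x: mixture_cdf(x) - 2 / 3, lo, hi)
        z1 = (q1 - mu) / cfg.cell_sd
        z2 = (q2 - mu) / cfg.cell_sd
        comp[0] = abundance * _stats.norm.cdf(z1)
        comp[1] = abundance * (_stats.norm.cdf(z2) - _stats.norm.cdf(z1))
        comp[2] = abundance * _stats.norm.sf(z2)
    # per-strain bin membership P(bin | strain)
    strain_tot = np.maximum(comp.sum(axis=0, keepdims=True), 1e-300)
    bin_probs = pd.DataFrame(
        (comp / strain_tot).T,
        index=pd.Index(strains, name="strain_id"), columns=list(BIN_NAMES))

    samples, counts = [], {}
    for b, bin_name in enumerate(BIN_NAMES):
        p = comp[b] / comp[b].sum()
        for rep in range(1, cfg.n_replicates + 1):
            sample = f"{cfg.timepoint}_{bin_name}_rep{rep}"
            n_junk = rng.binomial(cfg.read_depth, cfg.junk_read_fraction) \
                if cfg.read_depth else 0
            counts[sample] = rng.multinomial(cfg.read_depth - n_junk, p)
            samples.append({"sample": sample, "bin": bin_name,
                            "timepoint": cfg.timepoint, "replicate": rep,
                            "experiment": "sim", "n_junk_reads": n_junk})
    true_counts = pd.DataFrame(counts, index=pd.Index(strains, name="strain_id"))
    sample_sheet = pd.DataFrame(samples)
    truth_hits = pd.DataFrame({
        "strain_id": strains,
        "is_hit": np.isin(np.arange(n), hit_idx),
        "hit_effect": mu,
    })
    return true_counts, sample_sheet, truth_hits, bin_probs


def simulate_screen(catalog: BarcodeCatalog, cfg: ScreenSimConfig) -> ScreenData:
    """Full screen simulation: bin counts plus error-bearing paired FASTQ.

    Each counted read becomes a sense/antisense pair (the antisense mate is
    the reverse complement of the sense construct); substitution errors are
    drawn independently per mate at ``substitution_rate`` per base, whole
    flanks are corrupted (1-3 extra substitutions) at ``flank_mismatch_rate``
    per flank, and ``junk_read_fraction`` of the depth is uniform random
    sequence. Error-free bases carry high Phred scores; substituted bases
    carry low ones, so quality-aware merging is informative.
    """
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    true_counts, sample_sheet, truth_hits, bin_probs = \
        simulate_bin_counts(catalog, cfg)
    rng = np.random.default_rng(np.random.default_rng(cfg.seed).integers(2 ** 31))

    from ._seq import encode, decode
    fu, fd = encode(cfg.flank_up), encode(cfg.flank_down)
    bc_arrs = [encode(b) for b in catalog.barcodes]
    construct_len = len(fu) + cfg.barcode_length + len(fd)
    up_span = (0, len(fu))
    down_span = (len(fu) + cfg.barcode_length, construct_len)

    def emit(template: np.ndarray, rid: str) -> SimulatedRead:
        out = {}
        # reverse complement on the encoded alphabet: base -> 3 - base
        rc_template = (3 - template[::-1]).astype(np.uint8)
        for mate, arr in (("1", template.copy()), ("2", rc_template)):
            err = np.flatnonzero(rng.random(construct_len) < cfg.substitution_rate)
            for span in (up_span, down_span):
                lo, hi = span if mate == "1" else \
                    (construct_len - span[1], construct_len - span[0])
                if rng.random() < cfg.flank_mismatch_rate:
                    extra = rng.choice(np.arange(lo, hi),
                                       size=rng.integers(1, 4), replace=False)
                    err = np.union1d(err, extra)
            _mutate(rng, arr, err)
            qual = rng.integers(33, 41, size=construct_len)
            qual[err] = rng.integers(2, 25, size=len(err))
            out[mate] = (decode(arr), qual)
        return SimulatedRead(rid, out["1"][0], out["1"][1],
                             out["2"][0], out["2"][1])

    reads: dict[str, list[SimulatedRead]] = {}
    for sample in true_counts.columns:
        pairs: list[SimulatedRead] = []
        cnt = true_counts[sample].to_numpy()
        strain_of_read = np.repeat(np.arange(len(catalog)), cnt)
        rng.shuffle(strain_of_read)
        for i, s in enumerate(strain_of_read):
            template = np.concatenate([fu, bc_arrs[s], fd])
            pairs.append(emit(template, f"{sample}:read{i:07d}"))
        n_junk = int(sample_sheet.set_index("sample").loc[sample, "n_junk_reads"])
        for j in range(n_junk):
            junk = rng.integers(0, 4, size=construct_len, dtype=np.uint8)
            pairs.append(emit(junk, f"{sample}:junk{j:07d}"))
        reads[sample] = pairs
    return ScreenData(reads=reads, true_counts=true_counts,
                      sample_sheet=sample_sheet, truth_hits=truth_hits,
                      bin_probs=bin_probs)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def simulate_trajectories(cfg: TrajectorySimConfig) -> "TrajectorySet":
    """Age-declining MMP-ratio trajectories with a planted lifespan correlation.

    Each cell draws a latent pair (z1, z2) from a standard bivariate normal
    with correlation ``target_correlation``; z1 sets the cell's initial MMP
    ratio (log-normal across cells) and z2 its lifespan in divisions
    (normal, rounded, floored at 6 so the early-life window is always
    observed). The MMP-sensitive signal loses ``decline_per_division`` of
    its value per division; the MMP-insensitive signal stays flat. Both
    carry multiplicative log-normal measurement noise of sd ``noise_sd``.
    """
    from .trajectories import CellTrajectory, TrajectorySet

    rng = np.random.default_rng(cfg.seed)
    rho = cfg.target_correlation
    z1 = rng.standard_normal(cfg.n_cells)
    z2 = rho * z1 + math.sqrt(1 - rho ** 2) * rng.standard_normal(cfg.n_cells)

    r0 = np.exp(cfg.initial_ratio_sd * z1)
    lifespan = np.maximum(6, np.rint(cfg.mean_lifespan + cfg.sd_lifespan * z2)
                          ).astype(int)
    censored = rng.random(cfg.n_cells) < cfg.censor_fraction

    cells = []
    for i in range(cfg.n_cells):
        death_time = lifespan[i] * cfg.division_interval_h
        if censored[i]:
            end_time = rng.uniform(cfg.sample_interval_h, death_time)
        else:
            end_time = death_time
        n_samples = int(end_time // cfg.sample_interval_h) + 1
        t = np.arange(n_samples) * cfg.sample_interval_h
        div = np.minimum(np.floor(t / cfg.division_interval_h),
                         lifespan[i]).astype(int)
        noise_s = np.exp(cfg.noise_sd * rng.standard_normal(n_samples)) \
            if cfg.noise_sd else 1.0
        noise_i = np.exp(cfg.noise_sd * rng.standard_normal(n_samples)) \
            if cfg.noise_sd else 1.0
        mmp_s = cfg.base_mmp_s * r0[i] \
            * (1 - cfg.decline_per_division) ** div * noise_s
        mmp_i = cfg.base_mmp_i * np.ones(n_samples) * noise_i
        cells.append(CellTrajectory(
            cell_id=f"cell{i:05d}", experiment=cfg.experiment,
            time=t, divisions=div, mmp_s=mmp_s, mmp_i=mmp_i,
            died=not censored[i],
            divisions_at_death=int(lifespan[i]) if not censored[i] else None))
    return TrajectorySet(cells=cells)


# ---------------------------------------------------------------------------
# decay
# ---------------------------------------------------------------------------


def simulate_decay(n_passes: int, rate: float, initial: float,
                   noise_cv: float = 0.0, seed: int = 0, *,
                   pass_interval_min: float = 5.0,
                   sample: str = "sample", group: str = "group") -> "DecaySeries":
    """Repeated-pass mean signals decaying exponentially with analysis time.

    Signal at pass time t is ``initial * exp(-rate * t) * (1 + eps)`` with
    mean-zero Gaussian ``eps`` of sd ``noise_cv``.
    """
    from .flow import DecaySeries

    if n_passes < 2:
        raise ValueError("at least 2 passes are required; decay is "
                         "unidentifiable from a single pass")
    if rate < 0 or initial <= 0 or noise_cv < 0:
        raise ValueError("rate and noise_cv must be >= 0 and initial > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(n_passes) * pass_interval_min
    signal = initial * np.exp(-rate * t)
    if noise_cv:
        signal = signal * (1 + noise_cv * rng.standard_normal(n_passes))
    return DecaySeries(sample=sample, group=group, times=t, signals=signal)


# ---------------------------------------------------------------------------
# sizes
# ---------------------------------------------------------------------------


@dataclass
class SizeSimResult:
    diameters: np.ndarray  # um
    components: np.ndarray  # generating component index per cell
    total_potassium_mol: float
    n_rejected: int
    truth: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"diameter_um": self.diameters,
                             "component": self.components})


def simulate_sizes(cfg: SizeSimConfig) -> SizeSimResult:
    """Draw diameters from a three-Gaussian mixture and total up potassium.

    Each cell's potassium content is its spherical volume times the
    concentration of its generating class (the smallest-mean component is
    the daughter class). Negative draws are rejected and resampled; the
    rejection count is reported.
    """
    from .potassium import volume_from_diameter

    rng = np.random.default_rng(cfg.seed)
    means = np.asarray(cfg.component_means)
    sds = np.asarray(cfg.component_sds)
    weights = np.asarray(cfg.component_weights)

    comp = rng.choice(3, size=cfg.n_cells, p=weights)
    d = rng.normal(means[comp], sds[comp])
    n_rejected = 0
    bad = d <= 0
    while bad.any():
        n_rejected += int(bad.sum())
        d[bad] = rng.normal(means[comp[bad]], sds[comp[bad]])
        bad = d <= 0

    daughter = int(np.argmin(means))
    conc_mm = np.where(comp == daughter, cfg.daughter_concentration,
                       cfg.old_concentration)
    vol_fl = volume_from_diameter(d)
    # mM * fL -> mol: 1e-3 mol/L * 1e-15 L
    total_mol = float(np.sum(conc_mm * vol_fl) * 1e-18)
    truth = {
        "means": means, "sds": sds, "weights": weights,
        "daughter_component": daughter,
        "daughter_concentration_mm": cfg.daughter_concentration,
        "old_concentration_mm": cfg.old_concentration,
    }
    return SizeSimResult(diameters=d, components=comp,
                         total_potassium_mol=total_mol,
                         n_rejected=n_rejected, truth=truth)
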