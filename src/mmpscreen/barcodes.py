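"""Paired-end barcode calling for pooled deletion-collection screens.

Each amplicon read carries a variable strain barcode between two constant
flanking sequences. The caller locates the flanks in both mates with a
bounded-mismatch scan, extracts the enclosed barcode, reconciles the two
mates into a single consensus (preferring the higher-quality base where
they disagree), and assigns the consensus to a catalog strain by cosine
similarity of k-mer count vectors. The cosine score doubles as the
confidence of the assignment; calls below the score threshold, or tied
between two catalog entries, are not counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from ._seq import encode, phred_from_string, reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_K = 3
DEFAULT_MAX_MISMATCH = 2
DEFAULT_MIN_SCORE = 0.8

#: score ties closer than this are reported as ambiguous
TIE_TOL = 1e-12


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BarcodeCatalog:
    """Known strain barcodes plus the constant sequences flanking them."""

    records: pd.DataFrame  # columns: strain_id, gene, barcode
    flank_up: str
    flank_down: str

    def __post_init__(self) -> None:
        req = {"strain_id", "gene", "barcode"}
        if not req.issubset(self.records.columns):
            raise ValueError(f"catalog requires columns {sorted(req)}")
        if self.records["strain_id"].duplicated().any():
            raise ValueError("strain_ids must be unique")
        if self.records["barcode"].duplicated().any():
            raise ValueError("barcodes must be unique")
        if not self.flank_up or not self.flank_down:
            raise ValueError("flank sequences must be nonempty")
        bad = ~self.records["barcode"].str.fullmatch("[ACGT]+")
        if bad.any():
            raise ValueError("catalog barcodes must be over the ACGT alphabet")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def strain_ids(self) -> np.ndarray:
        return self.records["strain_id"].to_numpy()

    @property
    def barcodes(self) -> np.ndarray:
        return self.records["barcode"].to_numpy()

    @classmethod
    def from_tsv(cls, path, flank_up: str, flank_down: str) -> "BarcodeCatalog":
        return cls(pd.read_csv(path, sep="\t", dtype=str), flank_up, flank_down)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    sense_seq: str
    sense_qual: np.ndarray
    antisense_seq: str
    antisense_qual: np.ndarray

    def __post_init__(self) -> None:
        if len(self.sense_seq) != len(self.sense_qual):
            raise ValueError("sense sequence/quality length mismatch")
        if len(self.antisense_seq) != len(self.antisense_qual):
            raise ValueError("antisense sequence/quality length mismatch")


@dataclass(frozen=True)
class FlankMatch:
    """0-based half-open barcode interval and per-flank mismatch counts."""

    start: int
    end: int
    up_mismatches: int
    down_mismatches: int


@dataclass(frozen=True)
class Extraction:
    barcode: str
    qualities: np.ndarray
    flanks: FlankMatch


@dataclass(frozen=True)
class BarcodeCall:
    read_id: str
    barcode: Optional[str]
    provenance: str  # both-identical | sense-only | antisense-only | quality-merged | none
    matched_id: Optional[str]
    confidence: Optional[float]
    passes_threshold: bool
    ambiguous: bool


@dataclass(frozen=True)
class CallSummary:
    n_reads: int
    fraction_flank_identified: float
    fraction_barcode_recovered: float
    fraction_above_threshold: float
    n_malformed: int = 0


# ---------------------------------------------------------------------------
# flank location and extraction
# ---------------------------------------------------------------------------


def _best_window(seq_arr: np.ndarray, flank_arr: np.ndarray, offset: int,
                 max_mismatch: int) -> Optional[tuple[int, int]]:
    """Leftmost minimal-mismatch placement of ``flank_arr`` within budget.

    Returns (start, mismatches) in coordinates of the full read (``offset``
    is where ``seq_arr`` begins), or None if no window fits the budget.
    """
    L = len(flank_arr)
    if len(seq_arr) < L:
        return None
    windows = sliding_window_view(seq_arr, L)
    mism = (windows != flank_arr).sum(axis=1)
    i = int(np.argmin(mism))  # argmin takes the leftmost minimum
    if mism[i] > max_mismatch:
        return None
    return offset + i, int(mism[i])


def find_flanks(seq: str, flank_up: str, flank_down: str,
                max_mismatch: int = DEFAULT_MAX_MISMATCH) -> Optional[FlankMatch]:
    """Locate both constant flanks in a read; absence is a value, not an error.

    The mismatch budget applies to each flank separately. Among candidate
    placements within budget the minimal-mismatch, leftmost window wins;
    the downstream flank is searched to the right of the upstream one. N
    bases never match and therefore count as mismatches.
    """
    arr = encode(seq)
    up = _best_window(arr, encode(flank_up), 0, max_mismatch)
    if up is None:
        return None
    up_start, up_mm = up
    bc_start = up_start + len(flank_up)
    down = _best_window(arr[bc_start:], encode(flank_down), bc_start, max_mismatch)
    if down is None:
        return None
    down_start, down_mm = down
    return FlankMatch(start=bc_start, end=down_start,
                      up_mismatches=up_mm, down_mismatches=down_mm)


def extract_barcode(seq: str, qual: np.ndarray, flank_up: str, flank_down: str,
                    max_mismatch: int = DEFAULT_MAX_MISMATCH) -> Optional[Extraction]:
    """Pull the barcode (and its quality slice) out of one mate.

    A zero-length interval (adjacent flanks) yields an empty barcode, which
    downstream matching treats as unassignable.
    """
    fm = find_flanks(seq, flank_up, flank_down, max_mismatch)
    if fm is None:
        return None
    return Extraction(barcode=seq[fm.start:fm.end],
                      qualities=np.asarray(qual[fm.start:fm.end]),
                      flanks=fm)


def extract_barcode_antisense(seq: str, qual: np.ndarray, flank_up: str,
                              flank_down: str,
                              max_mismatch: int = DEFAULT_MAX_MISMATCH,
                              ) -> Optional[Extraction]:
    """Extract from an antisense mate by reverse-complementing it first.

    The returned barcode is in sense orientation so that the two mates can
    be compared base-by-base.
    """
    return extract_barcode(reverse_complement(seq), np.asarray(qual)[::-1],
                           flank_up, flank_down, max_mismatch)


def reconcile_pair(sense: Optional[Extraction],
                   antisense: Optional[Extraction]) -> tuple[Optional[str], str]:
    """Merge the two mates' extractions into one barcode.

    Identical sequences (or a single recovered direction) pass through.
    Equal-length disagreements are resolved per position by the higher
    Phred score, ties going to the sense base. Unequal-length
    disagreements have no per-base merge, so the mate with fewer total
    flank mismatches wins (tie: higher mean barcode quality, then sense).
    """
    if sense is None and antisense is None:
        return None, "none"
    if antisense is None:
        return sense.barcode, "sense-only"
    if sense is None:
        return antisense.barcode, "antisense-only"
    if sense.barcode == antisense.barcode:
        return sense.barcode, "both-identical"
    if len(sense.barcode) == len(antisense.barcode):
        take_anti = antisense.qualities > sense.qualities
        merged = "".join(a if t else s for s, a, t in
                         zip(sense.barcode, antisense.barcode, take_anti))
        return merged, "quality-merged"
    # unequal lengths: pick a whole mate
    s_mm = sense.flanks.up_mismatches + sense.flanks.down_mismatches
    a_mm = antisense.flanks.up_mismatches + antisense.flanks.down_mismatches
    if s_mm != a_mm:
        winner = sense if s_mm < a_mm else antisense
    else:
        s_q = float(np.mean(sense.qualities)) if len(sense.qualities) else -np.inf
        a_q = float(np.mean(antisense.qualities)) if len(antisense.qualities) else -np.inf
        winner = antisense if a_q > s_q else sense
    return winner.barcode, "quality-merged"


# ---------------------------------------------------------------------------
# k-mer cosine matching
# ---------------------------------------------------------------------------


def kmer_vector(seq: str, k: int) -> dict[str, int]:
    """Overlapping k-mer counts of ``seq``; k-mers containing N are skipped."""
    if k <= 0:
        raise ValueError("k must be positive")
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k={k}")
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if "N" in kmer:
            continue
        counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def _kmer_count_array(seq: str, k: int) -> np.ndarray:
    """Dense 4**k count vector of a sequence; N-containing k-mers skipped."""
    arr = encode(seq)
    n = len(arr) - k + 1
    if n <= 0:
        return np.zeros(4 ** k, dtype=np.float64)
    windows = sliding_window_view(arr, k)
    valid = (windows < 4).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1)
    idx = (windows[valid].astype(np.int64) * powers).sum(axis=1)
    out = np.zeros(4 ** k, dtype=np.float64)
    np.add.at(out, idx, 1.0)
    return out


class CatalogMatcher:
    """Cosine-similarity nearest neighbour over a barcode catalog.

    Precomputes the L2-normalized k-mer count matrix of the catalog once so
    that per-read matching is a dense dot product.
    """

    def __init__(self, catalog: BarcodeCatalog, k: int = DEFAULT_K):
        if len(catalog) == 0:
            raise ValueError("catalog is empty")
        self.catalog = catalog
        self.k = k
        mat = np.stack([_kmer_count_array(b, k) for b in catalog.barcodes])
        norms = np.linalg.norm(mat, axis=1)
        if (norms == 0).any():
            raise ValueError("catalog contains a barcode shorter than k")
        self._matrix = mat / norms[:, None]
        self._ids = catalog.strain_ids

    def match(self, barcode: str) -> tuple[Optional[str], Optional[float], bool]:
        """Best catalog entry for one barcode: (strain_id, score, ambiguous)."""
        sid, score, amb = self.match_many([barcode])
        return sid[0], (None if np.isnan(score[0]) else float(score[0])), bool(amb[0])

    def match_many(self, barcodes: Sequence[str]
                   ) -> tuple[list[Optional[str]], np.ndarray, np.ndarray]:
        n = len(barcodes)
        ids: list[Optional[str]] = [None] * n
        scores = np.full(n, np.nan)
        ambiguous = np.zeros(n, dtype=bool)
        vecs = np.zeros((n, 4 ** self.k))
        usable = np.zeros(n, dtype=bool)
        for i, b in enumerate(barcodes):
            if b is None or len(b) < self.k:
                continue
            v = _kmer_count_array(b, self.k)
            nv = np.linalg.norm(v)
            if nv == 0:  # all-N barcode
                continue
            vecs[i] = v / nv
            usable[i] = True
        idx = np.flatnonzero(usable)
        for lo in range(0, len(idx), 4096):
            sel = idx[lo:lo + 4096]
            sim = vecs[sel] @ self._matrix.T
            best = sim.argmax(axis=1)
            best_score = sim[np.arange(len(sel)), best]
            # cosine of non-negative count vectors is <= 1; snap float
            # round-off so an exact barcode match scores exactly 1.0
            best_score[best_score > 1.0 - TIE_TOL] = 1.0
            ties = (sim >= best_score[:, None] - TIE_TOL).sum(axis=1) > 1
            for j, row in enumerate(sel):
                ids[row] = str(self._ids[best[j]])
                scores[row] = best_score[j]
                ambiguous[row] = ties[j]
        return ids, scores, ambiguous


def cosine_match(barcode: str, catalog: BarcodeCatalog, k: int = DEFAULT_K
                 ) -> tuple[Optional[str], Optional[float], bool]:
    """One-shot cosine assignment of a barcode against a catalog.

    For repeated queries build a :class:`CatalogMatcher` once instead.
    """
    if len(barcode) < k:
        raise ValueError(f"barcode length {len(barcode)} < k={k}")
    return CatalogMatcher(catalog, k).match(barcode)


# ---------------------------------------------------------------------------
# full composition
# ---------------------------------------------------------------------------


def call_reads(pairs: Iterable[ReadPair], catalog: BarcodeCatalog, *,
               k: int = DEFAULT_K,
               max_mismatch: int = DEFAULT_MAX_MISMATCH,
               min_score: float = DEFAULT_MIN_SCORE,
               ) -> tuple[list[BarcodeCall], CallSummary]:
    """Run find -> extract -> reconcile -> cosine-match over read pairs.

    Returns one call per pair plus summary fractions (flank identified in
    at least one direction; barcode recovered; call above threshold).
    Ambiguous best matches never pass the threshold.
    """
    matcher = CatalogMatcher(catalog, k)
    fu, fd = catalog.flank_up, catalog.flank_down

    read_ids: list[str] = []
    barcodes: list[Optional[str]] = []
    provenances: list[str] = []
    n_flank = 0
    for pair in pairs:
        s = extract_barcode(pair.sense_seq, pair.sense_qual, fu, fd, max_mismatch)
        a = extract_barcode_antisense(pair.antisense_seq, pair.antisense_qual,
                                      fu, fd, max_mismatch)
        if s is not None or a is not None:
            n_flank += 1
        bc, prov = reconcile_pair(s, a)
        read_ids.append(pair.read_id)
        barcodes.append(bc)
        provenances.append(prov)

    n = len(read_ids)
    ids, scores, ambiguous = matcher.match_many(
        [b if b is not None else "" for b in barcodes])

    calls: list[BarcodeCall] = []
    n_recovered = 0
    n_pass = 0
    for i in range(n):
        bc = barcodes[i]
        matched = ids[i] if bc is not None else None
        conf = None
        if matched is not None and not np.isnan(scores[i]):
            conf = float(scores[i])
        else:
            matched = None
        if bc is not None and len(bc) > 0:
            n_recovered += 1
        passes = (conf is not None and conf >= min_score and not ambiguous[i])
        if passes:
            n_pass += 1
        calls.append(BarcodeCall(read_id=read_ids[i], barcode=bc,
                                 provenance=provenances[i], matched_id=matched,
                                 confidence=conf, passes_threshold=passes,
                                 ambiguous=bool(ambiguous[i]) if conf is not None else False))
    summary = CallSummary(
        n_reads=n,
        fraction_flank_identified=n_flank / n if n else 0.0,
        fraction_barcode_recovered=n_recovered / n if n else 0.0,
        fraction_above_threshold=n_pass / n if n else 0.0,
    )
    return calls, summary


def count_barcodes(calls_by_sample: dict[str, Sequence[BarcodeCall]],
                   catalog: BarcodeCatalog,
                   sample_sheet: pd.DataFrame) -> "BinCountMatrix":
    """Tally passing, unambiguous calls into a strain x sample count matrix.

    ``sample_sheet`` must carry one row per sample with at least ``sample``
    and ``bin`` columns (``timepoint``/``replicate``/``experiment`` are
    carried through when present). Rows are the full catalog, zero-filled.
    """
    from .enrichment import BinCountMatrix  # local import to avoid a cycle

    sheet = sample_sheet.set_index("sample") if "sample" in sample_sheet.columns \
        else sample_sheet
    for sample in calls_by_sample:
        if sample not in sheet.index:
            raise ValueError(f"sample {sample!r} missing from sample sheet")
        if "bin" not in sheet.columns or pd.isna(sheet.loc[sample, "bin"]):
            raise ValueError(f"sample {sample!r} has no bin label")

    strains = list(catalog.strain_ids)
    counts = pd.DataFrame(0, index=pd.Index(strains, name="strain_id"),
                          columns=list(calls_by_sample), dtype=np.int64)
    for sample, calls in calls_by_sample.items():
        hits = [c.matched_id for c in calls
                if c.passes_threshold and not c.ambiguous]
        if hits:
            vc = pd.Series(hits).value_counts()
            counts.loc[vc.index, sample] = vc.to_numpy()
    return BinCountMatrix(counts=counts, samples=sheet.loc[list(calls_by_sample)])


# ---------------------------------------------------------------------------
# FASTQ I/O
# ---------------------------------------------------------------------------


def read_fastq_pairs(r1_path, r2_path) -> Iterator[ReadPair]:
    """Stream order-matched mates from two Phred+33 FASTQ files.

    Malformed records (length mismatches) are skipped with a logged warning.
    """
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(r1_path) as f1, open(r2_path) as f2:
        for (id1, seq1, q1), (id2, seq2, q2) in zip(
                FastqGeneralIterator(f1), FastqGeneralIterator(f2)):
            rid = id1.split()[0].removesuffix("/1")
            try:
                yield ReadPair(read_id=rid,
                               sense_seq=seq1, sense_qual=phred_from_string(q1),
                               antisense_seq=seq2, antisense_qual=phred_from_string(q2))
            except ValueError as exc:  # pragma: no cover - defensive
                logger.warning("skipping malformed record %s: %s", rid, exc)


def calls_to_frame(calls: Sequence[BarcodeCall]) -> pd.DataFrame:
    return pd.DataFrame({
        "read_id": [c.read_id for c in calls],
        "barcode": [c.barcode or "" for c in calls],
        "provenance": [c.provenance for c in calls],
        "strain_id": [c.matched_id or "" for c in calls],
        "confidence": [c.confidence if c.confidence is not None else np.nan
                       for c in calls],
        "pass": [c.passes_threshold for c in calls],
    })
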