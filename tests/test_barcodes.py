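"""Barcode caller: flank scan, extraction, reconciliation, cosine matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmpscreen._seq import reverse_complement
from mmpscreen.barcodes import (
    BarcodeCall,
    CatalogMatcher,
    ReadPair,
    call_reads,
    cosine_match,
    count_barcodes,
    extract_barcode,
    extract_barcode_antisense,
    find_flanks,
    kmer_vector,
    reconcile_pair,
    read_fastq_pairs,
)
from conftest import FLANK_DOWN, FLANK_UP, embed

BARCODE = "ACGTACGTACGTACGTACGT"


def _sub(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestFindFlanks:
    def test_exact_embedding_located_with_zero_mismatches(self):
        read = embed(BARCODE)
        fm = find_flanks(read, FLANK_UP, FLANK_DOWN, max_mismatch=2)
        assert fm is not None
        assert read[fm.start:fm.end] == BARCODE
        assert fm.up_mismatches == 0 and fm.down_mismatches == 0

    def test_two_mismatches_in_flank_still_found(self):
        read = "AA" + _sub(FLANK_UP, [2, 7]) + BARCODE + FLANK_DOWN + "TT"
        fm = find_flanks(read, FLANK_UP, FLANK_DOWN, max_mismatch=2)
        assert fm is not None
        assert fm.up_mismatches == 2
        assert read[fm.start:fm.end] == BARCODE

    def test_three_mismatches_exceed_budget(self):
        read = "AA" + _sub(FLANK_UP, [2, 7, 11]) + BARCODE + FLANK_DOWN + "TT"
        assert find_flanks(read, FLANK_UP, FLANK_DOWN, max_mismatch=2) is None

    def test_n_bases_count_as_mismatches(self):
        corrupted = "NNN" + FLANK_UP[3:]
        read = "AA" + corrupted + BARCODE + FLANK_DOWN + "TT"
        assert find_flanks(read, FLANK_UP, FLANK_DOWN, max_mismatch=2) is None


class TestExtractBarcode:
    def test_extracts_barcode_and_aligned_qualities(self):
        read = embed(BARCODE)
        qual = np.arange(len(read))
        ext = extract_barcode(read, qual, FLANK_UP, FLANK_DOWN)
        assert ext.barcode == BARCODE
        start = 2 + len(FLANK_UP)
        np.testing.assert_array_equal(
            ext.qualities, np.arange(start, start + len(BARCODE)))

    def test_no_flanks_returns_absent(self):
        read = "A" * 80
        assert extract_barcode(read, np.zeros(80), FLANK_UP, FLANK_DOWN) is None

    def test_adjacent_flanks_give_zero_length_barcode(self):
        read = "AA" + FLANK_UP + FLANK_DOWN + "TT"
        ext = extract_barcode(read, np.zeros(len(read)), FLANK_UP, FLANK_DOWN)
        assert ext is not None and ext.barcode == ""

    def test_antisense_extraction_matches_sense_on_error_free_pair(self):
        sense = embed(BARCODE)
        anti = reverse_complement(sense)
        q = np.full(len(sense), 35)
        e_sense = extract_barcode(sense, q, FLANK_UP, FLANK_DOWN)
        e_anti = extract_barcode_antisense(anti, q, FLANK_UP, FLANK_DOWN)
        assert e_anti.barcode == e_sense.barcode == BARCODE


class TestReconcilePair:
    def _ext(self, barcode, quals):
        from mmpscreen.barcodes import Extraction, FlankMatch
        return Extraction(barcode=barcode, qualities=np.asarray(quals),
                          flanks=FlankMatch(0, len(barcode), 0, 0))

    def test_identical_sequences(self):
        e = self._ext("ACGT", [30] * 4)
        bc, prov = reconcile_pair(e, self._ext("ACGT", [10] * 4))
        assert (bc, prov) == ("ACGT", "both-identical")

    def test_single_direction_passthrough(self):
        e = self._ext("ACGT", [30] * 4)
        assert reconcile_pair(e, None) == ("ACGT", "sense-only")
        assert reconcile_pair(None, e) == ("ACGT", "antisense-only")
        assert reconcile_pair(None, None) == (None, "none")

    def test_quality_merge_takes_higher_phred_base(self):
        sense = self._ext("ACGTAG", [30, 30, 30, 30, 30, 30])
        anti = self._ext("ACGTAT", [30, 30, 30, 30, 30, 38])
        bc, prov = reconcile_pair(sense, anti)
        assert bc == "ACGTAT" and prov == "quality-merged"

    def test_quality_tie_takes_sense_base(self):
        sense = self._ext("AAAA", [30] * 4)
        anti = self._ext("AAAC", [30] * 4)
        bc, _ = reconcile_pair(sense, anti)
        assert bc == "AAAA"

    def test_merging_identical_inputs_is_idempotent(self):
        e = self._ext("ACGTACGT", [20] * 8)
        bc, _ = reconcile_pair(e, e)
        assert bc == e.barcode

    def test_unequal_lengths_prefer_fewer_flank_mismatches(self):
        from mmpscreen.barcodes import Extraction, FlankMatch
        clean = Extraction("ACGTA", np.full(5, 20), FlankMatch(0, 5, 0, 0))
        noisy = Extraction("ACGT", np.full(4, 40), FlankMatch(0, 4, 2, 1))
        bc, prov = reconcile_pair(clean, noisy)
        assert bc == "ACGTA" and prov == "quality-merged"


class TestKmerVector:
    def test_homopolymer(self):
        assert kmer_vector("AAAA", 2) == {"AA": 3}

    def test_full_length_kmer(self):
        assert kmer_vector("ACGT", 4) == {"ACGT": 1}

    def test_n_kmers_skipped(self):
        assert kmer_vector("ANA", 2) == {}

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            kmer_vector("AC", 3)

    @given(st.text(alphabet="ACGT", min_size=3, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_count_conservation(self, seq):
        counts = kmer_vector(seq, 3)
        assert sum(counts.values()) == len(seq) - 2


class TestCosineMatch:
    def test_identical_barcode_scores_exactly_one(self, tiny_catalog):
        sid, score, amb = cosine_match("ACGTACGTACGTACGTACGT", tiny_catalog)
        assert sid == "s1" and score == 1.0 and not amb

    def test_single_substitution_scores_fifteen_eighteenths(self, tiny_catalog):
        # frozen oracle: all 18 3-mers of the original are distinct and a
        # substitution at position 3 replaces exactly 3 of them
        original = "AGGATGCAATAGTTCACTGA"
        mutated = "AGGGTGCAATAGTTCACTGA"
        v_orig = kmer_vector(original, 3)
        v_mut = kmer_vector(mutated, 3)
        assert len(v_orig) == 18 and set(v_orig.values()) == {1}
        assert len(set(v_orig) & set(v_mut)) == 15

        import pandas as pd
        from mmpscreen.barcodes import BarcodeCatalog
        cat = BarcodeCatalog(
            pd.DataFrame({"strain_id": ["s1"], "gene": ["G1"],
                          "barcode": [original]}), FLANK_UP, FLANK_DOWN)
        sid, score, amb = cosine_match(mutated, cat)
        assert sid == "s1"
        assert score == pytest.approx(15 / 18, abs=1e-12)

    def test_matches_naive_nearest_neighbour_oracle(self, catalog100):
        """Cosine assignment must agree with an exhaustive double loop."""
        rng = np.random.default_rng(42)
        matcher = CatalogMatcher(catalog100, k=3)

        def naive(query):
            best_id, best_score = None, -1.0
            for sid, bc in zip(catalog100.strain_ids, catalog100.barcodes):
                va, vb = kmer_vector(query, 3), kmer_vector(bc, 3)
                dot = sum(va[k] * vb.get(k, 0) for k in va)
                na = np.sqrt(sum(v * v for v in va.values()))
                nb = np.sqrt(sum(v * v for v in vb.values()))
                score = dot / (na * nb)
                if score > best_score:
                    best_id, best_score = sid, score
            return best_id, best_score

        for _ in range(50):
            base = catalog100.barcodes[rng.integers(100)]
            # corrupt up to 3 positions
            pos = rng.choice(20, size=rng.integers(0, 4), replace=False)
            query = _sub(base, pos)
            sid, score, amb = matcher.match(query)
            oid, oscore = naive(query)
            if not amb:
                assert sid == oid
            assert score == pytest.approx(min(oscore, 1.0), abs=1e-9)

    def test_all_n_barcode_is_unmatchable(self, tiny_catalog):
        matcher = CatalogMatcher(tiny_catalog, k=3)
        sid, score, amb = matcher.match("NNNNNNNNNN")
        assert sid is None and score is None


class TestCallReads:
    def _pairs(self, catalog, barcodes):
        pairs = []
        for i, bc in enumerate(barcodes):
            sense = embed(bc)
            anti = reverse_complement(sense)
            q = np.full(len(sense), 35)
            pairs.append(ReadPair(f"r{i}", sense, q, anti, q.copy()))
        return pairs

    def test_error_free_reads_all_recovered_with_full_confidence(self, small_catalog):
        pairs = self._pairs(small_catalog, small_catalog.barcodes)
        calls, summary = call_reads(pairs, small_catalog)
        assert summary.fraction_barcode_recovered == 1.0
        assert all(c.confidence == 1.0 for c in calls)
        assert [c.matched_id for c in calls] == list(small_catalog.strain_ids)
        assert all(c.provenance == "both-identical" for c in calls)

    def test_junk_reads_produce_no_passing_calls(self, small_catalog):
        rng = np.random.default_rng(0)
        pairs = []
        for i in range(200):
            seq = "".join(rng.choice(list("ACGT"), 58))
            q = np.full(58, 35)
            pairs.append(ReadPair(f"j{i}", seq, q,
                                  reverse_complement(seq), q.copy()))
        calls, summary = call_reads(pairs, small_catalog)
        assert all(not c.passes_threshold for c in calls)
        # random 58-mers essentially never contain both 18-nt flanks
        assert summary.fraction_flank_identified < 0.05

    def test_lower_threshold_is_superset(self, small_catalog):
        rng = np.random.default_rng(1)
        pairs = []
        for i, bc in enumerate(small_catalog.barcodes):
            pos = rng.choice(20, size=rng.integers(0, 5), replace=False)
            sense = embed(_sub(bc, pos))
            q = np.full(len(sense), 35)
            pairs.append(ReadPair(f"r{i}", sense, q,
                                  reverse_complement(sense), q.copy()))
        strict, _ = call_reads(pairs, small_catalog, min_score=0.8)
        loose, _ = call_reads(pairs, small_catalog, min_score=0.5)
        passed_strict = {c.read_id for c in strict if c.passes_threshold}
        passed_loose = {c.read_id for c in loose if c.passes_threshold}
        assert passed_strict <= passed_loose


class TestCountBarcodes:
    def _call(self, rid, sid, passes=True, ambiguous=False):
        return BarcodeCall(read_id=rid, barcode="X" * 20, provenance="both-identical",
                           matched_id=sid, confidence=0.9,
                           passes_threshold=passes, ambiguous=ambiguous)

    def _sheet(self):
        import pandas as pd
        return pd.DataFrame({"sample": ["A", "B"], "bin": ["high", "low"],
                             "timepoint": ["T24", "T24"], "replicate": [1, 1]})

    def test_simple_tally(self, small_catalog):
        sid = small_catalog.strain_ids[0]
        calls = {"A": [self._call(f"r{i}", sid) for i in range(3)],
                 "B": []}
        bcm = count_barcodes(calls, small_catalog, self._sheet())
        assert bcm.counts.loc[sid, "A"] == 3
        assert bcm.counts["B"].sum() == 0

    def test_ambiguous_and_failing_calls_excluded(self, small_catalog):
        sid = small_catalog.strain_ids[0]
        calls = {"A": [self._call("r0", sid, ambiguous=True, passes=False),
                       self._call("r1", sid, passes=False)],
                 "B": [self._call("r2", sid)]}
        bcm = count_barcodes(calls, small_catalog, self._sheet())
        assert bcm.counts["A"].sum() == 0
        assert bcm.counts.loc[sid, "B"] == 1

    def test_column_sums_conserve_passing_calls(self, small_catalog):
        ids = small_catalog.strain_ids
        calls = {"A": [self._call(f"r{i}", ids[i % 3]) for i in range(7)],
                 "B": [self._call(f"q{i}", ids[0]) for i in range(2)]}
        bcm = count_barcodes(calls, small_catalog, self._sheet())
        assert bcm.counts["A"].sum() == 7
        assert bcm.counts["B"].sum() == 2

    def test_missing_bin_label_fails(self, small_catalog):
        import pandas as pd
        sheet = pd.DataFrame({"sample": ["A"], "bin": [np.nan]})
        with pytest.raises(ValueError, match="bin"):
            count_barcodes({"A": []}, small_catalog, sheet)


class TestFastqRoundTrip:
    def test_simulated_screen_survives_fastq_round_trip(self, tmp_path):
        from mmpscreen.synthetic import ScreenSimConfig, make_catalog, simulate_screen

        cfg = ScreenSimConfig(n_strains=8, read_depth=50, n_replicates=1,
                              substitution_rate=0.0, flank_mismatch_rate=0.0,
                              junk_read_fraction=0.0, seed=2, n_hit_strains=0,
                              n_pool_cells=2000)
        cat = make_catalog(cfg)
        data = simulate_screen(cat, cfg)
        data.write(tmp_path)
        sample = data.sample_sheet["sample"].iloc[0]
        pairs = list(read_fastq_pairs(tmp_path / f"{sample}_R1.fastq",
                                      tmp_path / f"{sample}_R2.fastq"))
        assert len(pairs) == len(data.reads[sample])
        calls, summary = call_reads(pairs, cat)
        assert summary.fraction_barcode_recovered == 1.0
        assert all(c.confidence == 1.0 for c in calls)
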