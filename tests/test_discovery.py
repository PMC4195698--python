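"""Repeat discovery: seeded aligner, filters and conserved-region calls."""

import numpy as np
import pandas as pd
import pytest

from erenorm import (
    ScanParams,
    SequenceDesign,
    SequenceHit,
    Thresholds,
    conservation_rate,
    conserved_region,
    copy_number,
    expressed_hits,
    filter_candidates,
    generate_repeat_sequences,
    scan_sequences,
)
from erenorm.discovery import DiscoveryError, hits_from_tabular

RC = str.maketrans("ACGT", "TGCA")


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(123)


class TestScanSequences:
    def test_verbatim_planting_yields_one_exact_hit(self, rng):
        cons = _random_dna(rng, 120)
        subject = _random_dna(rng, 300) + cons + _random_dna(rng, 300)
        hits = scan_sequences(cons, {"s1": subject})
        assert len(hits) == 1
        h = hits[0]
        assert (h.subject_start, h.subject_end) == (300, 420)
        assert (h.consensus_start, h.consensus_end) == (0, 120)
        assert h.identity == 100.0 and h.strand == "+"

    def test_reverse_complement_subject_reports_minus_strand(self, rng):
        cons = _random_dna(rng, 100)
        subject = cons.translate(RC)[::-1]
        hits = scan_sequences(cons, {"s1": subject})
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert (hits[0].subject_start, hits[0].subject_end) == (0, 100)

    def test_planted_copies_recovered_with_identity_close_to_truth(self):
        design = SequenceDesign(genome_length=60_000, consensus_length=250, n_copies=100,
                                substitution_rate=0.05, n_transcripts=0,
                                fraction_with_repeat=0.0, seed=21)
        genome, _, truth = generate_repeat_sequences(design)
        hits = scan_sequences(truth.consensus, genome)
        assert len(hits) == 100
        for row in truth.genome_copies.itertuples():
            # max-scoring-segment trimming may shave a few mutated end bases,
            # so match planted copies to hits by overlap, not exact coords
            overlapping = [
                h for h in hits
                if min(h.subject_end, row.end) - max(h.subject_start, row.start)
                >= 0.9 * (row.end - row.start)
            ]
            assert len(overlapping) == 1, f"planted copy at {row.start} missed"
            h = overlapping[0]
            assert h.strand == row.strand
            assert abs(h.identity - row.identity) <= 2.0

    def test_short_or_diverged_matches_are_discarded(self, rng):
        cons = _random_dna(rng, 200)
        # 30 bp fragment is below the 50 bp length floor
        subject = _random_dna(rng, 200) + cons[50:80] + _random_dna(rng, 200)
        assert scan_sequences(cons, {"s1": subject}) == []

    def test_invalid_parameters_raise(self):
        with pytest.raises(DiscoveryError):
            scan_sequences("A" * 100, {}, ScanParams(k=4))
        with pytest.raises(DiscoveryError):
            scan_sequences("A" * 100, {}, ScanParams(min_identity=40.0))


class TestCopyNumber:
    def test_zero_copies(self, rng):
        cons = _random_dna(rng, 150)
        assert copy_number(cons, {"chr1": _random_dna(rng, 5000)}) == 0

    def test_overlapping_hits_are_merged(self, rng):
        # a tandem-duplicated consensus matches one genomic block twice on
        # different diagonals; the two hits cover the same interval and merge
        block = _random_dna(rng, 100)
        cons = block + block
        subject = _random_dna(rng, 300) + block + _random_dna(rng, 300)
        assert copy_number(cons, {"chr1": subject}) == 1

    def test_monotone_in_planted_copy_count(self):
        counts = []
        for n in (5, 20, 50):
            design = SequenceDesign(genome_length=40_000, consensus_length=200, n_copies=n,
                                    substitution_rate=0.05, n_transcripts=0,
                                    fraction_with_repeat=0.0, seed=3)
            genome, _, truth = generate_repeat_sequences(design)
            counts.append(copy_number(truth.consensus, genome))
        assert counts == sorted(counts)
        assert counts == [5, 20, 50]

    def test_empty_genome_raises(self, rng):
        with pytest.raises(DiscoveryError, match="non-empty"):
            copy_number(_random_dna(rng, 100), {})


class TestExpressedHits:
    def test_counts_transcripts_not_segments(self, rng):
        cons = _random_dna(rng, 100)
        carrier = cons + _random_dna(rng, 200) + cons  # two hit segments
        plain = _random_dna(rng, 400)
        res = expressed_hits(cons, {"refseq": {"tx1": carrier, "tx2": plain}})
        assert res.per_collection == {"refseq": 1}
        assert res.combined == 1

    def test_designed_carrier_fraction_is_recovered(self):
        design = SequenceDesign(genome_length=20_000, consensus_length=150, n_copies=10,
                                substitution_rate=0.03, n_transcripts=100,
                                transcript_length=500, fraction_with_repeat=0.4, seed=17)
        _, transcripts, truth = generate_repeat_sequences(design)
        res = expressed_hits(truth.consensus, {"refseq": transcripts})
        assert res.combined == 40

    def test_combined_sums_over_collections(self, rng):
        cons = _random_dna(rng, 100)
        mk = lambda: cons + _random_dna(rng, 100)
        res = expressed_hits(
            cons,
            {"refseq": {"a": mk(), "b": _random_dna(rng, 300)}, "other": {"c": mk()}},
        )
        assert res.per_collection == {"refseq": 1, "other": 1}
        assert res.combined == 2


class TestConservationRate:
    def _hit(self, ident, start=0, end=100):
        return SequenceHit("s", start, end, "+", start, end, ident, end - start)

    def test_mean_of_identities(self):
        assert conservation_rate([self._hit(80.0), self._hit(90.0)]) == pytest.approx(85.0)
        assert conservation_rate([self._hit(100.0)] * 3) == 100.0

    def test_empty_hits_undefined(self):
        with pytest.raises(DiscoveryError):
            conservation_rate([])

    def test_tracks_designed_substitution_rate(self):
        design = SequenceDesign(genome_length=80_000, consensus_length=300, n_copies=150,
                                substitution_rate=0.1, n_transcripts=0,
                                fraction_with_repeat=0.0, seed=6)
        genome, _, truth = generate_repeat_sequences(design)
        hits = scan_sequences(truth.consensus, genome)
        assert conservation_rate(hits) == pytest.approx(90.0, abs=1.5)


class TestConservedRegion:
    def _hit(self, cs, ce, ident=100.0):
        return SequenceHit("s", 0, ce - cs, "+", cs, ce, ident, ce - cs)

    def test_window_restricted_to_hit_support(self):
        hits = [self._hit(100, 250)] * 5
        start, end = conserved_region(hits, 400, 100)
        assert 100 <= start and end <= 250

    def test_uniform_coverage_ties_resolve_to_earliest_window(self):
        hits = [self._hit(0, 400)]
        assert conserved_region(hits, 400, 150) == (0, 150)

    def test_high_coverage_block_wins(self):
        hits = [self._hit(0, 400, ident=90.0)] + [self._hit(200, 320)] * 10
        start, end = conserved_region(hits, 400, 100)
        assert 200 <= start and end <= 320

    def test_window_larger_than_consensus_raises(self):
        with pytest.raises(DiscoveryError):
            conserved_region([self._hit(0, 100)], 100, 200)


class TestFilterCandidates:
    def test_strict_inequalities_at_the_thresholds(self, rng):
        cons = _random_dna(rng, 150)
        spacer = lambda: _random_dna(rng, 60)
        genome5 = {"chr1": "".join(spacer() + cons for _ in range(5)) + spacer()}
        genome6 = {"chr1": "".join(spacer() + cons for _ in range(6)) + spacer()}
        carriers = {f"tx{i}": cons + _random_dna(rng, 100) for i in range(4)}
        thr = Thresholds(min_copies=5, min_combined_hits=3, min_conservation=85.0)
        at_threshold = filter_candidates({"rep": cons}, genome5, {"refseq": carriers}, thr)[0]
        above = filter_candidates({"rep": cons}, genome6, {"refseq": carriers}, thr)[0]
        assert at_threshold.copy_count == 5 and not at_threshold.passes["copy_number"]
        assert not at_threshold.passed
        assert above.copy_count == 6 and above.passed

    def test_pass_set_invariant_to_library_ordering(self, rng):
        cons_a, cons_b = _random_dna(rng, 150), _random_dna(rng, 150)
        spacer = lambda: _random_dna(rng, 60)
        genome = {"chr1": "".join(spacer() + cons_a for _ in range(4)) + spacer()}
        tx = {"tx1": cons_a + _random_dna(rng, 100)}
        thr = Thresholds(min_copies=3, min_combined_hits=0.5, min_conservation=85.0)
        fwd = filter_candidates({"a": cons_a, "b": cons_b}, genome, {"r": tx}, thr)
        rev = filter_candidates({"b": cons_b, "a": cons_a}, genome, {"r": tx}, thr)
        assert {c.repeat_id: c.passed for c in fwd} == {c.repeat_id: c.passed for c in rev}

    def test_region_is_within_consensus_and_overlaps_a_hit(self, rng):
        cons = _random_dna(rng, 200)
        tx = {f"tx{i}": _random_dna(rng, 50) + cons + _random_dna(rng, 50) for i in range(3)}
        cand = filter_candidates(
            {"rep": cons},
            {"chr1": cons + _random_dna(rng, 500)},
            {"r": tx},
            Thresholds(1, 1, 50.0),
        )[0]
        start, end = cand.region
        assert 0 <= start < end <= 200


class TestTabularAdapter:
    def test_round_trip_including_minus_strand(self):
        df = pd.DataFrame(
            [
                ["rep", "chrA", 97.5, 200, 5, 0, 1, 200, 1001, 1200, 1e-50, 350.0],
                ["rep", "chrA", 92.0, 150, 12, 0, 21, 170, 5400, 5251, 1e-30, 220.0],
            ]
        )
        hits = hits_from_tabular(df)
        assert len(hits) == 2
        plus = [h for h in hits if h.strand == "+"][0]
        minus = [h for h in hits if h.strand == "-"][0]
        assert (plus.subject_start, plus.subject_end) == (1000, 1200)
        assert (minus.subject_start, minus.subject_end) == (5250, 5400)
        assert minus.consensus_start == 20
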