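"""Tandem detection: wraparound DP scores, calling, filtering, invariants."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fessurvey.motifs import reverse_complement
from fessurvey.tandem import (
    DetectorParams,
    TandemArray,
    call_tandem_arrays,
    filter_by_purity,
    find_candidate_periods,
    mask_tandem_arrays,
    wraparound_align,
)
from conftest import random_dna, unrolled_dp_score


class TestWraparoundAlign:
    def test_perfect_array(self):
        score, purity, indels, span = wraparound_align("AGAGAG", "AG")
        assert (score, purity, indels) == (12, 1.0, 0.0)
        assert span == (0, 6)

    def test_one_mismatch(self):
        score, purity, _, _ = wraparound_align("AGAGCG", "AG")
        assert score == 7  # 5 matches x2 - 1 mismatch x3
        assert purity == pytest.approx(5 / 6)

    def test_phase_free_entry(self):
        # starting mid-unit costs nothing against a cyclic pattern
        assert wraparound_align("GAGAGA", "AG")[0] == 12

    def test_empty_motif_rejected(self):
        with pytest.raises(ValueError):
            wraparound_align("ACGT", "")

    def test_matches_unrolled_oracle_random(self, wdp_oracle, rng):
        """Cyclic DP equals the brute-force unrolled semi-global DP."""
        for _ in range(120):
            seg = random_dna(rng, int(rng.integers(5, 31)))
            m = int(rng.integers(2, 7))
            motif = random_dna(rng, m)
            got = wraparound_align(seg, motif)[0]
            assert got == wdp_oracle(seg, motif), (seg, motif)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        seg=st.text(alphabet="ACGT", min_size=1, max_size=40),
        motif=st.text(alphabet="ACGT", min_size=1, max_size=6),
    )
    def test_matches_unrolled_oracle_property(self, seg, motif, wdp_oracle):
        assert wraparound_align(seg, motif)[0] == wdp_oracle(seg, motif)


class TestCandidates:
    def test_perfect_embedded_array(self, rng):
        seq = random_dna(rng, 50) + "ACGT" * 10 + random_dna(rng, 50)
        cands = find_candidate_periods(seq)
        covering = [
            (iv, d) for iv, d in cands if d == 4 and iv[0] <= 52 and iv[1] >= 88
        ]
        assert covering

    def test_homopolymer(self):
        cands = find_candidate_periods("C" * 20 + "A" * 60 + "G" * 20)
        assert any(d == 1 and iv[0] <= 21 and iv[1] >= 79 for iv, d in cands)

    def test_invalid_characters(self):
        with pytest.raises(ValueError):
            find_candidate_periods("ACGTQ")

    def test_n_runs_never_candidates(self):
        seq = "A" * 20 + "NN" + "A" * 20
        for (s, e), d in find_candidate_periods(seq):
            assert not (s <= 20 and e >= 22), "candidate crossed an NN run"

    def test_every_planted_perfect_array_has_covering_candidate(self, rng):
        """Seeded sequences with planted perfect arrays >=12 bp."""
        misses = 0
        for _ in range(300):
            unit_len = int(rng.integers(1, 7))
            unit = random_dna(rng, unit_len)
            copies = max(2, int(np.ceil(12 / unit_len)) + int(rng.integers(0, 4)))
            array = (unit * copies)[: max(12, unit_len * copies)]
            left = random_dna(rng, int(rng.integers(10, 60)))
            seq = left + array + random_dna(rng, int(rng.integers(10, 60)))
            s, e = len(left), len(left) + len(array)
            cands = find_candidate_periods(seq)
            if not any(
                iv[0] <= s + d and iv[1] >= e - d
                for iv, d in cands
            ):
                misses += 1
        assert misses == 0


class TestCallArrays:
    def test_perfect_ag_thirty_copies(self):
        arrays = call_tandem_arrays("AG" * 30)
        assert len(arrays) == 1
        a = arrays[0]
        assert (a.period, a.score, a.purity, a.copy_number) == (2, 120, 1.0, 30.0)
        assert a.canonical_motif == "AG"

    def test_score_floor_excludes_short_perfect_array(self):
        # 24 bp perfect dinucleotide scores 48 < 50 under default weights
        assert call_tandem_arrays("AG" * 12) == []
        relaxed = DetectorParams(min_score=24)
        assert len(call_tandem_arrays("AG" * 12, relaxed)) == 1

    def test_planted_mutated_arrays_detected(self, rng):
        """Every planted >=50 bp array at up to 10% substitutions is found
        (right motif class, >=80% span overlap); most boundaries land
        within one unit of the planted interval.

        Exact-boundary recovery at high divergence is limited by the
        ambiguity of mutated terminal units against chance-matching flank;
        the aggregate boundary-accuracy property lives in the acceptance
        suite at its stated level.
        """
        from fessurvey.motifs import canonical_motif

        detected = sharp = total = 0
        for _ in range(120):
            unit = str(rng.choice(["AG", "AC", "AAT", "ATC"]))
            copies = int(rng.integers(30, 60))
            rate = float(rng.uniform(0.0, 0.10))
            array = list(unit * copies)
            for i in range(len(array)):
                if rng.random() < rate:
                    array[i] = str(rng.choice([b for b in "ACGT" if b != array[i]]))
            left = random_dna(rng, int(rng.integers(20, 80)))
            seq = left + "".join(array) + random_dna(rng, int(rng.integers(20, 80)))
            s, e = len(left), len(left) + len(array)
            total += 1
            for a in call_tandem_arrays(seq):
                if a.canonical_motif != canonical_motif(unit).label:
                    continue
                overlap = min(a.end, e) - max(a.start, s)
                if overlap >= 0.8 * (e - s):
                    detected += 1
                    if abs(a.start - s) <= a.period and abs(a.end - e) <= a.period:
                        sharp += 1
                    break
        assert detected / total >= 0.95
        assert sharp / total >= 0.80

    def test_reported_scores_rescore_identically(self, rng):
        seq = random_dna(rng, 80) + "AAT" * 25 + random_dna(rng, 40) + "AG" * 30
        for a in call_tandem_arrays(seq):
            score, purity, _, _ = wraparound_align(seq[a.start : a.end], a.motif)
            assert score == a.score
            assert purity == pytest.approx(a.purity)

    def test_min_score_monotonicity(self, rng):
        seq = random_dna(rng, 60) + "AG" * 20 + random_dna(rng, 30) + "AAAT" * 15
        counts = [
            len(call_tandem_arrays(seq, DetectorParams(min_score=s)))
            for s in (24, 50, 80, 120, 200)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_strand_symmetry(self, rng):
        seq = (
            random_dna(rng, 40) + "AG" * 30 + random_dna(rng, 50)
            + "AACCT" * 12 + random_dna(rng, 40)
        )
        fwd = call_tandem_arrays(seq)
        rev = call_tandem_arrays(reverse_complement(seq))
        n = len(seq)
        mirrored = sorted(
            (n - a.end, n - a.start, a.period, a.canonical_motif, a.score) for a in rev
        )
        direct = sorted(
            (a.start, a.end, a.period, a.canonical_motif, a.score) for a in fwd
        )
        assert direct == mirrored

    def test_same_period_arrays_overlap_at_most_one_unit(self, rng):
        seq = random_dna(rng, 30) + "CT" * 25 + "CA" * 20 + random_dna(rng, 30)
        arrays = call_tandem_arrays(seq)
        for i, a in enumerate(arrays):
            for b in arrays[i + 1:]:
                if a.period == b.period:
                    overlap = min(a.end, b.end) - max(a.start, b.start)
                    assert overlap <= a.period

    def test_compound_repeat_reported_as_two_arrays(self):
        # adjacent distinct-motif arrays, never merged
        seq = "CT" * 38 + "ATTGCATCGCAT" + "CA" * 14
        arrays = call_tandem_arrays(seq)
        motifs = {a.canonical_motif for a in arrays}
        assert motifs == {"AG", "AC"}


class TestPurityFilter:
    def _array(self, purity):
        return TandemArray("r", 0, 60, 2, "AG", "AG", 30.0, 60, purity, 0.0)

    def test_boundary_at_55_percent(self):
        removed = filter_by_purity([self._array(0.55)])
        assert removed == []
        kept = filter_by_purity([self._array(0.551)])
        assert len(kept) == 1

    def test_filter_preserves_order(self):
        arrays = [self._array(p) for p in (0.9, 0.3, 0.8, 0.55, 0.7)]
        out = filter_by_purity(arrays)
        assert [a.purity for a in out] == [0.9, 0.8, 0.7]


def test_mask_tandem_arrays_replaces_spans_with_n():
    reads = {"r1": "ACGT" + "AG" * 10 + "TTTT"}
    arrays = [TandemArray("r1", 4, 24, 2, "AG", "AG", 10.0, 40, 1.0, 0.0)]
    masked = mask_tandem_arrays(reads, arrays)
    assert masked["r1"] == "ACGT" + "N" * 20 + "TTTT"
    assert reads["r1"][4] == "A"  # input untouched
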