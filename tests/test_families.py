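"""De novo repeat-family discovery: hits, elements, clustering, consensus,
curation, screening and accounting."""

import numpy as np
import pytest

from fessurvey.families import (
    FamilyParams,
    PairwiseHit,
    RepeatElement,
    RepeatFamily,
    allpairs_search,
    build_consensus,
    category_totals,
    cluster_families,
    curate_families,
    define_elements,
    discover_families,
    family_accounting,
    filter_families,
    internal_tandem_scan,
    pairwise_local_hits,
    screen_exclusion,
)
from fessurvey.motifs import reverse_complement
from fessurvey.simulate import FamilyPlant, SimulationConfig, simulate_reads
from conftest import random_dna


def _mutate(seq, rate, rng):
    out = []
    for b in seq:
        if rng.random() < rate:
            out.append(str(rng.choice([c for c in "ACGT" if c != b])))
        else:
            out.append(b)
    return "".join(out)


class TestAllPairs:
    def test_shared_element_is_hit(self, rng):
        element = random_dna(rng, 500)
        reads = {
            "a": random_dna(rng, 100) + _mutate(element, 0.05, rng) + random_dna(rng, 80),
            "b": random_dna(rng, 60) + _mutate(element, 0.05, rng) + random_dna(rng, 120),
        }
        hits = [h for h in allpairs_search(reads) if h.read_a == "a"]
        assert hits
        best = max(hits, key=lambda h: h.interval_a[1] - h.interval_a[0])
        covered = min(best.interval_a[1], 600) - max(best.interval_a[0], 100)
        assert covered >= 0.8 * 500

    def test_identical_reads_full_span_cross_pair_no_self(self, rng):
        seq = random_dna(rng, 400)
        hits = allpairs_search({"a": seq, "b": seq})
        assert all(h.read_a != h.read_b for h in hits)
        fwd = [h for h in hits if h.read_a == "a" and h.orientation == "same"]
        assert any(
            h.interval_a[1] - h.interval_a[0] >= 0.95 * 400 for h in fwd
        )

    def test_reverse_complement_hit_orientation(self, rng):
        element = random_dna(rng, 300)
        reads = {
            "a": random_dna(rng, 50) + element + random_dna(rng, 50),
            "b": random_dna(rng, 70) + reverse_complement(element) + random_dna(rng, 30),
        }
        hits = [h for h in allpairs_search(reads) if h.read_a == "a"]
        assert hits and all(h.orientation == "opposite" for h in hits)
        # interval_b is reported on the forward strand of read b
        assert hits[0].interval_b[0] >= 40 and hits[0].interval_b[1] <= 380

    def test_random_background_produces_no_hits(self, rng):
        for _ in range(60):
            reads = {"a": random_dna(rng, 500), "b": random_dna(rng, 500)}
            assert allpairs_search(reads) == []

    def test_symmetry(self, rng):
        element = random_dna(rng, 300)
        reads = {
            "a": random_dna(rng, 50) + element + random_dna(rng, 50),
            "b": element + random_dna(rng, 100),
        }
        hits = allpairs_search(reads)
        keys = {(h.read_a, h.read_b, h.interval_a, h.interval_b) for h in hits}
        assert all(
            (h.read_b, h.read_a, h.interval_b, h.interval_a) in keys for h in hits
        )


class TestElements:
    def test_agreeing_hits_aggregate(self):
        hits = [
            PairwiseHit("r", f"o{i}", (100 + d, 400 + d), (0, 300), "same", 0.9, 270)
            for i, d in enumerate((0, 5, -8))
        ]
        els = define_elements(hits)
        mine = [e for e in els if e.read_id == "r"]
        assert len(mine) == 1
        assert abs(mine[0].start - 100) <= 10 and abs(mine[0].end - 400) <= 10

    def test_disagreeing_endpoints_stay_separate(self):
        hits = [
            PairwiseHit("r", "o1", (100, 400), (0, 300), "same", 0.9, 270),
            PairwiseHit("r", "o2", (380, 700), (0, 320), "same", 0.9, 290),
        ]
        els = [e for e in els if e.read_id == "r"] if False else [
            e for e in define_elements(hits) if e.read_id == "r"
        ]
        assert len(els) == 2
        assert els[0].end <= els[1].start  # trimmed, no double-counted bp

    def test_contained_fragment_absorbed(self):
        hits = [
            PairwiseHit("r", "o1", (100, 400), (0, 300), "same", 0.9, 270),
            PairwiseHit("r", "o2", (150, 300), (0, 150), "same", 0.9, 130),
        ]
        els = [e for e in define_elements(hits) if e.read_id == "r"]
        assert len(els) == 1

    def test_truncated_copy_lengths_correlate(self, rng):
        cfg = SimulationConfig(
            n_reads=120, seed=21, length_min=400, length_mean=550, length_max=861,
            planted_families=(
                FamilyPlant("fam", 300, 30, divergence=0.03, truncation_fraction=0.4),
            ),
        )
        reads, truth = simulate_reads(cfg)
        hits = allpairs_search(reads)
        els = define_elements(hits)
        planted, found = [], []
        for rec in (r for r in truth.records if r.kind == "family"):
            for e in els:
                ov = min(e.end, rec.end) - max(e.start, rec.start)
                if e.read_id == rec.read_id and ov > 0.5 * (rec.end - rec.start):
                    planted.append(rec.end - rec.start)
                    found.append(e.length)
                    break
        assert len(planted) >= 25
        assert np.corrcoef(planted, found)[0, 1] > 0.9


class TestClustering:
    def _planted(self, seed, plants, n_reads=150):
        cfg = SimulationConfig(
            n_reads=n_reads, seed=seed, length_min=400, length_mean=550,
            length_max=861, planted_families=tuple(plants),
        )
        return simulate_reads(cfg)

    def test_planted_family_single_cluster(self):
        reads, truth = self._planted(22, [FamilyPlant("f", 300, 25, 0.05)])
        hits = allpairs_search(reads)
        fams = cluster_families(define_elements(hits), hits)
        big = max(fams, key=lambda f: f.count)
        assert big.count >= 23

    def test_distant_families_never_merge(self):
        reads, truth = self._planted(
            23,
            [FamilyPlant("f1", 250, 22, 0.02), FamilyPlant("f2", 250, 22, 0.02)],
            n_reads=200,
        )
        fams = discover_families(reads)
        # two independent random consensi are ~75% mutually divergent
        assert len([f for f in fams if f.count >= 20]) == 2

    def test_count_filter_boundary(self):
        fams = [
            RepeatFamily("a", [RepeatElement("r", 0, 100)] * 20),
            RepeatFamily("b", [RepeatElement("r", 0, 100)] * 19),
        ]
        kept = filter_families(fams)
        assert [f.family_id for f in kept] == ["a"]
        assert filter_families([]) == []
        stricter = filter_families(fams, FamilyParams(min_family_count=21))
        assert {f.family_id for f in stricter} <= {f.family_id for f in kept}

    def test_order_invariance(self):
        reads, _ = self._planted(24, [FamilyPlant("f", 300, 24, 0.05)])
        fams1 = discover_families(reads)
        shuffled = dict(reversed(list(reads.items())))
        fams2 = discover_families(shuffled)
        sig1 = sorted((f.count, f.total_length) for f in fams1)
        sig2 = sorted((f.count, f.total_length) for f in fams2)
        assert sig1 == sig2


class TestConsensus:
    def test_identical_copies_exact(self, rng):
        seq = random_dna(rng, 300)
        reads = {f"r{i}": seq for i in range(4)}
        fam = RepeatFamily(
            "f", [RepeatElement(f"r{i}", 0, 300) for i in range(4)]
        )
        assert build_consensus(fam, reads) == seq

    def test_single_element_returns_element(self, rng):
        seq = random_dna(rng, 200)
        fam = RepeatFamily("f", [RepeatElement("r", 10, 110)])
        assert build_consensus(fam, {"r": seq}) == seq[10:110]

    def test_tie_breaks_alphabetical(self):
        reads = {"r1": "AAGG", "r2": "AAGG", "r3": "TAGG", "r4": "TAGG"}
        fam = RepeatFamily("f", [RepeatElement(f"r{i}", 0, 4) for i in (1, 2, 3, 4)])
        # column 0 splits 2/2 between A and T -> A wins alphabetically
        assert build_consensus(fam, reads)[0] == "A"

    def test_diverged_copies_recover_consensus(self, rng):
        truth = random_dna(rng, 400)
        reads = {}
        els = []
        for i in range(25):
            copy = _mutate(truth, 0.05, rng)
            reads[f"r{i}"] = copy
            els.append(RepeatElement(f"r{i}", 0, 400))
        got = build_consensus(RepeatFamily("f", els), reads)
        mismatches = sum(1 for a, b in zip(got, truth) if a != b)
        assert mismatches / len(truth) <= 0.02


class TestCuration:
    def test_presplit_family_merged(self, rng):
        consensus = random_dna(rng, 300)
        reads, els = {}, []
        for i in range(30):
            reads[f"r{i}"] = _mutate(consensus, 0.05, rng)
            els.append(RepeatElement(f"r{i}", 0, 300))
        half_a = RepeatFamily("a", els[:15])
        half_b = RepeatFamily("b", els[15:])
        out = curate_families([half_a, half_b], reads)
        assert len(out) == 1
        assert out[0].count == 30

    def test_unrelated_families_untouched_and_idempotent(self, rng):
        reads, fams = {}, []
        for k in range(2):
            consensus = random_dna(rng, 300)
            els = []
            for i in range(20):
                rid = f"f{k}r{i}"
                reads[rid] = _mutate(consensus, 0.05, rng)
                els.append(RepeatElement(rid, 0, 300))
            fams.append(RepeatFamily(f"f{k}", els))
        once = curate_families(fams, reads)
        assert len(once) == 2
        twice = curate_families(once, reads)
        assert sorted(f.count for f in twice) == sorted(f.count for f in once)


class TestScreening:
    def test_exact_exclusion_fragment(self, rng):
        rrna = random_dna(rng, 800)
        fam = RepeatFamily("f", [RepeatElement("r", 0, 200)] * 2)
        fam.consensus = rrna[100:300]
        kept, excluded = screen_exclusion([fam], {"rRNA": rrna})
        assert excluded and not kept

    def test_no_exclusion_set_keeps_all(self):
        fam = RepeatFamily("f", [])
        kept, excluded = screen_exclusion([fam], None)
        assert kept == [fam] and excluded == []

    def test_unrelated_consensus_kept(self, rng):
        fam = RepeatFamily("f", [RepeatElement("r", 0, 200)] * 2)
        fam.consensus = random_dna(rng, 200)
        kept, excluded = screen_exclusion([fam], {"rRNA": random_dna(rng, 800)})
        assert kept and not excluded


class TestInternalTandems:
    def test_long_unit_array_reported(self, rng):
        unit = random_dna(rng, 21)
        consensus = random_dna(rng, 30) + unit * 19 + unit[:8] + random_dna(rng, 30)
        found = internal_tandem_scan(consensus)
        assert any(p == 21 and 18.5 <= c <= 20 for p, c in found)

    def test_unit_repeated_twice(self, rng):
        unit = random_dna(rng, 15)
        consensus = random_dna(rng, 40) + unit * 2 + random_dna(rng, 40)
        found = internal_tandem_scan(consensus)
        assert any(p == 15 and abs(c - 2.0) <= 0.2 for p, c in found)

    def test_tandem_free_consensus_empty(self, rng):
        for _ in range(10):
            assert internal_tandem_scan(random_dna(rng, 200)) == []

    def test_short_consensus_rejected(self):
        with pytest.raises(ValueError):
            internal_tandem_scan("ACGTACGTACGT")


class TestAccounting:
    def test_copy_number_extrapolation(self):
        fam = RepeatFamily("f", [RepeatElement("r", 0, 100)] * 400)
        table = family_accounting([fam], surveyed_bp=11_114_786, sampling_fraction=0.0045)
        copies = table.iloc[0]["extrapolated_genome_copies"]
        assert copies == pytest.approx(400 / 0.0045, rel=1e-9)
        assert copies > 80_000

    def test_category_grand_totals(self):
        # summing the survey's repeat-category lengths over the surveyed bp
        cats = {
            "retro_non_ltr": 643_931,
            "retro_penelope": 378_442,
            "retro_ltr": 157_441,
            "dna_transposon": 14_817,
            "wssv_like": 2_399_849,
            "unannotated": 1_285_643,
            "microsatellite": 807_927,
        }
        table = category_totals(cats, 11_114_786).set_index("category")
        assert table.loc["TOTAL", "length_bp"] == 5_688_050
        assert round(table.loc["TOTAL", "pct"], 2) == 51.18
        assert round(table.loc["wssv_like", "pct"], 2) == 21.59

    def test_full_survey_fraction(self):
        fam = RepeatFamily("f", [RepeatElement("r", 0, 1000)])
        table = family_accounting([fam], surveyed_bp=1000, sampling_fraction=0.5)
        assert table.iloc[0]["genome_fraction_pct"] == pytest.approx(100.0)

    def test_invalid_sampling_fraction(self):
        with pytest.raises(ValueError):
            family_accounting([], 1000, 0.0)


class TestPlantedRecovery:
    def test_planted_families_recovered_with_consensus_identity(self):
        """Families planted at >=20 copies and <=15% pairwise divergence
        come back with counts within 10% and consensi >=95% identical."""
        import edlib

        cfg = SimulationConfig(
            n_reads=150, seed=31, length_min=400, length_mean=550, length_max=861,
            planted_families=(
                FamilyPlant("famA", 300, 25, divergence=0.05),
                FamilyPlant("famB", 400, 30, divergence=0.075),
            ),
        )
        reads, truth = simulate_reads(cfg)
        fams = discover_families(reads)
        matched = {}
        for fam in fams:
            for fid, cons in truth.family_consensi.items():
                d = min(
                    edlib.align(fam.consensus, cons, mode="NW")["editDistance"],
                    edlib.align(
                        reverse_complement(fam.consensus), cons, mode="NW"
                    )["editDistance"],
                )
                ident = 1 - d / max(len(cons), len(fam.consensus))
                if ident >= 0.95:
                    matched[fid] = fam
        assert set(matched) == {"famA", "famB"}
        assert abs(matched["famA"].count - 25) <= 2.5
        assert abs(matched["famB"].count - 30) <= 3

    def test_element_bp_never_exceeds_surveyed_bp(self):
        cfg = SimulationConfig(
            n_reads=100, seed=32, length_min=400, length_mean=500, length_max=700,
            planted_families=(FamilyPlant("f", 250, 24, 0.05),),
        )
        reads, _ = simulate_reads(cfg)
        fams = discover_families(reads)
        surveyed = sum(len(s) for s in reads.values())
        assert sum(f.total_length for f in fams) <= surveyed
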