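import itertools

import numpy as np
import pytest

from tescope.io import AlignmentHit, AnnotationLabel, SequenceRecord
from tescope.landscape import (
    AbundanceVector,
    DivergenceHistogram,
    RepeatLibrary,
    classify_activity,
    cluster_contigs,
    divergence_histogram,
    diversity_indices,
    genome_proportions,
    mask_reads,
    pairwise_identity,
)
from tescope.simulate import random_sequence

GYPSY = AnnotationLabel("I", "LTR", "Gypsy")
L1 = AnnotationLabel("I", "LINE", "L1")


def _library(seqs, labels=None, min_length=100):
    records = [SequenceRecord(f"c{i}", s) for i, s in enumerate(seqs)]
    labels = labels or [GYPSY] * len(records)
    return RepeatLibrary(records, labels, min_length=min_length)


class TestLibrary:
    def test_short_contigs_rejected_and_reported(self, rng):
        lib = _library([random_sequence(rng, 150), random_sequence(rng, 99)])
        assert len(lib) == 1 and lib.rejected == ["c1"]

    def test_duplicate_ids_rejected(self):
        recs = [SequenceRecord("x", "A" * 120), SequenceRecord("x", "C" * 120)]
        with pytest.raises(ValueError):
            RepeatLibrary(recs, [GYPSY, GYPSY])


class TestClustering:
    def test_identical_sequences_merge(self, rng):
        s = random_sequence(rng, 120)
        cs = cluster_contigs(_library([s, s]), identity=0.95)
        assert len(cs.clusters) == 1
        # equal lengths: representative is the later id
        assert cs.representatives == ["c1"]

    def test_identity_threshold_separates_90pct_pair(self, rng):
        a = random_sequence(rng, 100)
        b = list(a)
        for pos in range(0, 100, 10):  # exactly 10 mismatches in 100 bp
            b[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[pos]]
        lib = _library([a, "".join(b)])
        assert len(cluster_contigs(lib, identity=0.95).clusters) == 2
        assert len(cluster_contigs(lib, identity=0.80).clusters) == 1

    def test_representative_is_longest_member(self, rng):
        long = random_sequence(rng, 200)
        short = long[20:140]  # contained, identity 1.0
        cs = cluster_contigs(_library([short, long]), identity=0.95)
        assert cs.clusters == [["c1", "c0"]] and cs.representatives == ["c1"]

    def test_exact_duplicate_classes_match_brute_force(self, rng):
        base = [random_sequence(rng, 110) for _ in range(8)]
        seqs = [base[int(i)] for i in rng.integers(0, 8, size=30)]
        lib = _library(seqs)
        cs = cluster_contigs(lib, identity=1.0)
        # brute-force equivalence classes by exact sequence equality
        records = lib.records
        expected = {}
        for r in records:
            expected.setdefault(r.seq, set()).add(r.id)
        got = {frozenset(c) for c in cs.clusters}
        assert got == {frozenset(v) for v in expected.values()}

    def test_pairwise_identity_best_offset(self):
        assert pairwise_identity("ACGT" * 30, "ACGT" * 30) == 1.0
        assert pairwise_identity("AAAA" * 30, "TTTT" * 30) <= 0.25
        # contained substring at a nonzero offset
        long = "G" * 40 + "ACGTACGT" * 15 + "G" * 40
        assert pairwise_identity("ACGTACGT" * 15, long) == 1.0

    def test_empty_library(self):
        cs = cluster_contigs(_library([]), identity=0.95)
        assert cs.clusters == [] and cs.representatives == []

    def test_bad_identity(self, rng):
        with pytest.raises(ValueError):
            cluster_contigs(_library([random_sequence(rng, 120)]), identity=0.0)


class TestMasking:
    def test_exact_substring_hit_zero_divergence(self, rng):
        lib = _library([random_sequence(rng, 500)])
        read = SequenceRecord("r0", lib.records[0].seq[100:200])
        (hit,) = mask_reads([read], lib)
        assert hit.pct_div == 0.0
        assert (hit.read_start, hit.read_end) == (0, 100)
        assert (hit.cons_start, hit.cons_end) == (100, 200)

    def test_two_substitutions_give_two_percent(self, rng):
        lib = _library([random_sequence(rng, 500)])
        frag = list(lib.records[0].seq[100:200])
        for pos in (30, 60):
            frag[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[frag[pos]]
        (hit,) = mask_reads([SequenceRecord("r0", "".join(frag))], lib)
        assert hit.pct_div == pytest.approx(2.0)

    def test_minus_strand_hit_normalized(self, rng):
        from tescope.io import revcomp

        lib = _library([random_sequence(rng, 500)])
        read = SequenceRecord("r0", revcomp(lib.records[0].seq[100:200]))
        (hit,) = mask_reads([read], lib)
        assert hit.strand == "-" and hit.pct_div == 0.0
        assert (hit.cons_start, hit.cons_end) == (100, 200)

    def test_random_read_not_masked(self, rng):
        lib = _library([random_sequence(rng, 500)])
        assert mask_reads([SequenceRecord("r0", random_sequence(rng, 100))], lib) == []

    def test_empty_library_errors(self):
        with pytest.raises(ValueError):
            mask_reads([SequenceRecord("r0", "ACGT" * 30)], _library([]))


class TestGenomeProportions:
    def test_single_hit_percent(self):
        hits = [AlignmentHit("r0", "c0", 0, 50, 0, 50, "+", 0.0, 50.0)]
        ab = genome_proportions(hits, {"c0": GYPSY}, total_bp=100)
        assert ab.percent_of_genome == {"Gypsy": 50.0}

    def test_overlapping_intervals_merged(self):
        hits = [
            AlignmentHit("r0", "c0", 0, 10, 0, 10, "+", 0.0, 10.0),
            AlignmentHit("r0", "c0", 5, 15, 5, 15, "+", 0.0, 10.0),
        ]
        ab = genome_proportions(hits, {"c0": GYPSY}, total_bp=100)
        assert ab.counts["Gypsy"] == 15

    def test_hit_beyond_read_bounds_errors(self):
        hits = [AlignmentHit("r0", "c0", 0, 50, 0, 50, "+", 0.0, 50.0)]
        with pytest.raises(ValueError):
            genome_proportions(hits, {"c0": GYPSY}, total_bp=100, read_lengths={"r0": 40})

    def test_including_vs_excluding_unknown_library_pair(self, rng):
        """Masking under libraries with and without unknown entries yields a
        per-superfamily [incl, excl] percent pair, the named superfamilies
        gaining coverage when unknown entries are absent."""
        from tescope.simulate import (
            Exponential,
            GenomeSimConfig,
            SuperfamilySpec,
            simulate_repeat_genome,
        )

        cfg = GenomeSimConfig(
            superfamilies=[SuperfamilySpec(GYPSY, 2000, 0.4, Exponential(3.0))],
            unknown_proportion=0.3,
            read_length=150,
            total_bp=400 * 150,
            seed=99,
        )
        sim = simulate_repeat_genome(cfg)
        full = sim.library
        known_only = RepeatLibrary(
            [r for r, lab in full.entries if lab.superfamily != "unknown"],
            [lab for _, lab in full.entries if lab.superfamily != "unknown"],
        )
        pct = {}
        for tag, lib in (("incl", full), ("excl", known_only)):
            hits = mask_reads(sim.reads, lib)
            ab = genome_proportions(hits, lib.annotation, total_bp=cfg.total_bp)
            pct[tag] = ab.percent_of_genome
        assert "unknown" in pct["incl"] and "unknown" not in pct["excl"]
        assert pct["excl"]["Gypsy"] >= pct["incl"]["Gypsy"] - 0.5
        assert abs(pct["incl"]["Gypsy"] - 40.0) < 3.0


class TestDiversity:
    def test_single_label_degenerate(self):
        res = diversity_indices(AbundanceVector({"A": 100}))
        assert res.gini_simpson == pytest.approx(0.0)
        assert res.H == pytest.approx(0.0)

    def test_two_equal_labels_closed_form(self):
        res = diversity_indices(AbundanceVector({"A": 50, "B": 50}))
        assert res.H == pytest.approx(np.log(2), abs=1e-9)
        assert res.D == pytest.approx(2 * (50 * 49) / (100 * 99))
        assert res.gini_simpson == pytest.approx(1 - 0.494949494949, abs=1e-9)

    def test_n_below_two_errors(self):
        with pytest.raises(ValueError):
            diversity_indices(AbundanceVector({"A": 1}))
        with pytest.raises(ValueError):
            diversity_indices(AbundanceVector({}))

    def test_shannon_bounded_by_log_k(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 12))
            counts = {f"L{i}": float(rng.integers(1, 1000)) for i in range(k)}
            res = diversity_indices(AbundanceVector(counts))
            assert 0.0 <= res.H <= np.log(k) + 1e-12

    def test_equal_proportions_attain_log_k(self):
        res = diversity_indices(AbundanceVector({f"L{i}": 1e6 for i in range(5)}))
        assert res.H == pytest.approx(np.log(5), abs=1e-9)

    def test_rescaling_invariance_large_n(self):
        counts = {"A": 5e6, "B": 3e6, "C": 2e6}
        r1 = diversity_indices(AbundanceVector(counts))
        r2 = diversity_indices(AbundanceVector({k: 10 * v for k, v in counts.items()}))
        assert r1.H == pytest.approx(r2.H, abs=1e-12)
        assert r1.gini_simpson == pytest.approx(r2.gini_simpson, abs=1e-4)


class TestDivergenceHistogram:
    def _hits(self, divs, sf="Gypsy"):
        lab = {"c0": GYPSY if sf == "Gypsy" else L1}
        return (
            [
                AlignmentHit(f"r{i}", "c0", 0, 100, 0, 100, "+", d, 100.0)
                for i, d in enumerate(divs)
            ],
            lab,
        )

    def test_one_percent_binning(self):
        hits, ann = self._hits([0.2, 1.5, 2.5, 2.7])
        hist = divergence_histogram(hits, ann)["Gypsy"]
        assert hist.counts.tolist() == [1, 1, 2]
        assert hist.n_reads == 4

    def test_least_divergent_hit_counted_once(self):
        ann = {"cX": GYPSY, "cY": GYPSY}
        hits = [
            AlignmentHit("r0", "cX", 0, 100, 0, 100, "+", 3.0, 50.0),
            AlignmentHit("r0", "cY", 0, 100, 0, 100, "+", 1.2, 60.0),
        ]
        hist = divergence_histogram(hits, ann)["Gypsy"]
        assert hist.counts.tolist() == [0, 1]

    def test_per_superfamily_split(self):
        ann = {"c0": GYPSY, "c1": L1}
        hits = [
            AlignmentHit("r0", "c0", 0, 100, 0, 100, "+", 0.5, 50.0),
            AlignmentHit("r1", "c1", 0, 100, 0, 100, "+", 4.5, 50.0),
        ]
        hists = divergence_histogram(hits, ann)
        assert set(hists) == {"Gypsy", "L1"}
        assert hists["L1"].counts.tolist() == [0, 0, 0, 0, 1]


class TestActivityClassification:
    def test_monotone_decreasing_is_recent_peak(self):
        call = classify_activity(DivergenceHistogram("x", np.array([10, 7, 4, 2, 1])))
        assert call.ongoing and call.shape == "recent-peak-decreasing"

    def test_interior_peak_is_past_unimodal(self):
        call = classify_activity(DivergenceHistogram("x", np.array([3, 5, 9, 12, 6, 2])))
        assert call.ongoing and call.shape == "past-peak-unimodal" and call.argmax_bin == 3

    def test_empty_first_bin_not_ongoing(self):
        call = classify_activity(DivergenceHistogram("x", np.array([0, 4, 8, 3])))
        assert not call.ongoing

    def test_two_separated_peaks_multimodal(self):
        call = classify_activity(
            DivergenceHistogram("x", np.array([1, 10, 14, 10, 1, 1, 10, 14, 10, 1]))
        )
        assert call.shape == "past-peak-multimodal"

    def test_empty_histogram_errors(self):
        with pytest.raises(ValueError):
            classify_activity(DivergenceHistogram("x", np.array([0, 0])))
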