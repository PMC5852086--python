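"""Coverage statistics, confidence ranking, merging, summaries."""

import numpy as np
import pytest

from eccseq.alignment_io import AlignedRead, GenomeIndex, GenomicInterval
from eccseq.circle_calling import (
    CircleCall,
    CoverageStats,
    DepthTrack,
    annotate_genes,
    assign_confidence,
    call_circles,
    coverage_stats,
    merge_calls,
    per_sample_average,
    reciprocal_overlap,
    summarize_sample,
)
from eccseq.config import DetectionConfig
from eccseq.sv_evidence import JunctionEvidence, cluster_evidence


def _depth_from_array(arr, chrom="chr1"):
    """DepthTrack with an explicit per-base depth array."""
    genome = GenomeIndex({chrom: len(arr)})
    track = DepthTrack(genome)
    track._depth[chrom][:] = arr
    return track, genome


class TestCoverageStats:
    def test_uniform_inside_zero_outside(self):
        arr = np.zeros(3000, dtype=np.int32)
        arr[1000:2000] = 10
        track, genome = _depth_from_array(arr)
        st = coverage_stats(GenomicInterval("chr1", 1000, 2000), track, genome)
        assert st.mean_cov == 10 and st.fraction_covered == 1.0 and st.flank_sum == 0

    def test_zero_depth_everywhere(self):
        track, genome = _depth_from_array(np.zeros(1000, dtype=np.int32))
        st = coverage_stats(GenomicInterval("chr1", 100, 200), track, genome)
        assert st.mean_cov == 0 and st.fraction_covered == 0

    def test_matches_brute_force_pileup_from_reads(self):
        """Depth built from aligned blocks equals a per-base counter."""
        rng = np.random.default_rng(13)
        genome = GenomeIndex({"chr1": 5000})
        reads = []
        for i in range(300):
            start = int(rng.integers(0, 4900))
            length = int(rng.integers(20, 100))
            end = min(start + length, 5000)
            reads.append(
                AlignedRead(f"r{i}", "chr1", start, end, "+", [("M", end - start)])
            )
        track = DepthTrack.from_reads(reads, genome)
        brute = np.zeros(5000, dtype=int)
        for r in reads:
            brute[r.start : r.end] += 1
        assert np.array_equal(track.depth("chr1", 0, 5000), brute)

    def test_truncated_flank_uses_available_bases(self):
        arr = np.zeros(1000, dtype=np.int32)
        arr[:400] = 4  # covers the interval and the partial upstream flank
        track, genome = _depth_from_array(arr)
        # interval [100, 400): upstream flank truncated to [0, 100)
        st = coverage_stats(GenomicInterval("chr1", 100, 400), track, genome)
        assert st.flank_truncated
        assert st.flank_up_mean == 4.0

    def test_fully_unavailable_flank_doubles_the_other(self):
        arr = np.full(900, 2, dtype=np.int32)
        track, genome = _depth_from_array(arr)
        # interval [0, 450): no upstream flank at all
        st = coverage_stats(GenomicInterval("chr1", 0, 450), track, genome)
        assert st.flank_up_mean == st.flank_down_mean == 2.0
        assert st.flank_sum == 4.0

    def test_interval_outside_genome_raises(self):
        track, genome = _depth_from_array(np.zeros(100, dtype=np.int32))
        with pytest.raises(ValueError):
            coverage_stats(GenomicInterval("chr1", 50, 200), track, genome)


class TestAssignConfidence:
    def _stats(self, frac, mean, flank_each):
        return CoverageStats(mean, frac, flank_each, flank_each)

    def test_high_fold_is_hconf(self, cfg):
        assert assign_confidence(3, self._stats(0.99, 40, 5), cfg) == "hconf"

    def test_low_fold_is_conf(self, cfg):
        assert assign_confidence(3, self._stats(0.99, 15, 5), cfg) == "conf"

    def test_low_fraction_is_lowq_regardless_of_coverage(self, cfg):
        assert assign_confidence(3, self._stats(0.90, 1000, 0), cfg) == "lowq"

    def test_fraction_boundary_is_exclusive(self, cfg):
        """Exactly 95% covered stays lowq; just above is not."""
        assert assign_confidence(2, self._stats(0.95, 40, 5), cfg) == "lowq"
        assert assign_confidence(2, self._stats(0.9501, 40, 5), cfg) == "hconf"

    def test_fold_boundary_is_exclusive(self, cfg):
        # flank_sum = 10; mean exactly 2x stays conf
        assert assign_confidence(2, self._stats(0.99, 20.0, 5), cfg) == "conf"
        assert assign_confidence(2, self._stats(0.99, 20.01, 5), cfg) == "hconf"

    def test_flank_mean_mode_halves_the_bar(self, cfg):
        alt = cfg.replace(flank_mode="mean")
        stats = self._stats(0.99, 15, 5)  # sum=10, mean=5
        assert assign_confidence(3, stats, cfg) == "conf"
        assert assign_confidence(3, stats, alt) == "hconf"

    def test_below_variant_minimum_is_an_error(self, cfg):
        with pytest.raises(ValueError):
            assign_confidence(1, self._stats(0.99, 40, 5), cfg)

    def test_confidence_monotonicity(self, cfg):
        """Raising flank coverage never upgrades; raising covered fraction
        never downgrades."""
        rank = {"hconf": 2, "conf": 1, "lowq": 0}
        rng = np.random.default_rng(31)
        for _ in range(200):
            frac = float(rng.uniform(0.5, 1.0))
            mean = float(rng.uniform(0, 50))
            flank = float(rng.uniform(0, 20))
            base = rank[assign_confidence(2, self._stats(frac, mean, flank), cfg)]
            worse_flank = rank[
                assign_confidence(2, self._stats(frac, mean, flank + 5), cfg)
            ]
            better_frac = rank[
                assign_confidence(2, self._stats(min(1.0, frac + 0.2), mean, flank), cfg)
            ]
            assert worse_flank <= base
            assert better_frac >= base


class TestCallCircles:
    def _cluster(self, s, e, read_names):
        ev = [
            JunctionEvidence("split", "chr1", s, e, True, True, n, "left_clip")
            for n in read_names
        ]
        return cluster_evidence(ev, DetectionConfig())

    def test_single_read_cluster_is_not_called(self, cfg):
        arr = np.zeros(5000, dtype=np.int32)
        arr[1000:2000] = 20
        track, genome = _depth_from_array(arr)
        calls, counters = call_circles(self._cluster(1000, 2000, ["a"]), track, cfg)
        assert calls == [] and counters["dropped_few_reads"] == 1

    def test_two_reads_full_coverage_high_fold_is_hconf(self, cfg):
        arr = np.zeros(5000, dtype=np.int32)
        arr[1000:2000] = 20
        track, genome = _depth_from_array(arr)
        (call,), _ = call_circles(self._cluster(1000, 2000, ["a", "b"]), track, cfg)
        assert call.confidence == "hconf"
        assert (call.interval.start, call.interval.end) == (1000, 2000)

    def test_simulator_truth_recovered_exactly(self, clean_sample):
        """Every planted circle is called at its exact coordinates (split
        reads exist for all of them)."""
        truth = {
            (c.interval.chrom, c.interval.start, c.interval.end)
            for c in clean_sample["truth"].circles
        }
        called = {
            (c.interval.chrom, c.interval.start, c.interval.end)
            for c in clean_sample["calls"]
        }
        assert truth == called


class TestReciprocalOverlap:
    def test_identical_intervals(self):
        a = GenomicInterval("chr1", 0, 100)
        assert reciprocal_overlap(a, a) == 1.0

    def test_half_overlap_analytic(self):
        a = GenomicInterval("chr1", 0, 100)
        b = GenomicInterval("chr1", 50, 150)
        assert reciprocal_overlap(a, b) == 0.5

    def test_disjoint_and_cross_chromosome(self):
        a = GenomicInterval("chr1", 0, 100)
        assert reciprocal_overlap(a, GenomicInterval("chr1", 100, 200)) == 0.0
        assert reciprocal_overlap(a, GenomicInterval("chr2", 0, 100)) == 0.0

    def test_matches_brute_force_base_by_base(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            s1 = int(rng.integers(0, 9000))
            e1 = s1 + int(rng.integers(1, 1000))
            s2 = int(rng.integers(0, 9000))
            e2 = s2 + int(rng.integers(1, 1000))
            a, b = GenomicInterval("chr1", s1, e1), GenomicInterval("chr1", s2, e2)
            shared = len(set(range(s1, e1)) & set(range(s2, e2)))
            expected = min(shared / a.size, shared / b.size) if shared else 0.0
            assert reciprocal_overlap(a, b) == pytest.approx(expected)
            assert reciprocal_overlap(a, b) == reciprocal_overlap(b, a)


def _call(s, e, n_reads=2, frac=0.99, chrom="chr1"):
    return CircleCall(
        interval=GenomicInterval(chrom, s, e),
        confidence="conf",
        evidence={"split": n_reads, "softclip": 0, "discordant": 0},
        n_distinct_reads=n_reads,
        coverage=CoverageStats(10.0, frac, 1.0, 1.0),
    )


class TestMergeCalls:
    def test_below_threshold_both_kept(self, cfg):
        merged = merge_calls([_call(0, 100), _call(51, 151)], cfg)  # RO 0.49
        assert len(merged) == 2

    def test_above_threshold_representative_by_evidence(self, cfg):
        a, b = _call(0, 100, n_reads=5), _call(5, 105, n_reads=2)  # RO 0.95
        (m,) = merge_calls([a, b], cfg)
        assert m.n_distinct_reads == 5
        assert len(m.merged_members) == 2

    def test_idempotent_on_fuzzed_call_sets(self, cfg):
        rng = np.random.default_rng(19)
        for _ in range(20):
            calls = []
            for _ in range(int(rng.integers(2, 25))):
                s = int(rng.integers(0, 20_000))
                calls.append(_call(s, s + int(rng.integers(100, 5000)),
                                   n_reads=int(rng.integers(2, 9))))
            once = merge_calls(calls, cfg)
            twice = merge_calls(once, cfg)
            key = lambda cs: [
                (c.interval.start, c.interval.end, c.n_distinct_reads) for c in cs
            ]
            assert key(once) == key(twice)

    def test_order_invariance(self, cfg):
        calls = [_call(0, 100, 3), _call(10, 110, 4), _call(500, 900, 2)]
        a = merge_calls(calls, cfg)
        b = merge_calls(calls[::-1], cfg)
        assert [(c.interval.start, c.interval.end) for c in a] == [
            (c.interval.start, c.interval.end) for c in b
        ]


class TestAnnotateGenes:
    def test_spanning_two_genes_lists_both(self):
        call = _call(1000, 5000)
        genes = [
            GenomicInterval("chr1", 1200, 2000, "S100A3"),
            GenomicInterval("chr1", 3000, 4000, "S100A4"),
        ]
        annotate_genes([call], genes)
        assert call.genes == ["S100A3", "S100A4"]

    def test_unannotated_region_empty(self):
        call = _call(1000, 5000)
        annotate_genes([call], [GenomicInterval("chr2", 0, 100, "X")])
        assert call.genes == []

    def test_single_base_overlap_counts(self):
        call = _call(1000, 5000)
        annotate_genes([call], [GenomicInterval("chr1", 4999, 6000, "EDGE")])
        assert call.genes == ["EDGE"]


class TestSummaries:
    def test_per_100_nuclei_frequency(self):
        """8,469 circles from 1e6 nuclei is 0.85 per 100 nuclei (2 dp)."""
        calls = [_call(i, i + 500) for i in range(0, 8469 * 10, 10)]
        summary = summarize_sample(calls, 1e6)
        assert round(summary.per_100_nuclei, 2) == 0.85

    def test_zero_calls_all_zero(self):
        s = summarize_sample([], 1e6)
        assert (s.n_total, s.n_hconf, s.per_100_nuclei) == (0, 0, 0.0)
        assert s.size_hist == {}

    def test_size_histogram_bins_tenth_of_log10kb(self):
        # 100 bp -> log10(0.1 kb) = -1.0; 5000 bp -> log10(5) ~ 0.69897 -> bin 0.6
        s = summarize_sample([_call(0, 100), _call(0, 5000)], 1e6)
        assert set(s.size_hist) == {-1.0, 0.6}

    def test_invalid_nuclei_count(self):
        with pytest.raises(ValueError):
            summarize_sample([], 0)

    def test_summary_report_written(self, tmp_path):
        s = summarize_sample([_call(0, 100), _call(0, 5000)], 1e6)
        path = tmp_path / "summary.tsv"
        s.write_tsv(str(path))
        lines = dict(l.split("\t") for l in path.read_text().splitlines()[1:])
        assert lines["n_total"] == "2" and lines["per_100_nuclei"] == "0.00"

    def test_cohort_per_sample_average(self):
        avg = per_sample_average({"hconf": 43_960, "conf": 81_066, "lowq": 13_655}, 16)
        assert avg == {"hconf": 2748, "conf": 5067, "lowq": 853}
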