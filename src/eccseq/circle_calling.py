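"""Confidence-ranked circle calls from junction clusters plus coverage.

A cluster becomes a call when it is supported by at least two independent
structural-read variants and implies a circle of at most 1 Mb.  Calls are
ranked by internal read coverage against the flanking background:

* ``hconf`` — >95% of internal positions covered *and* mean internal
  coverage more than two-fold the summed means of the two equal-length
  flanks;
* ``conf``  — >95% coverage but failing the fold test;
* ``lowq``  — coverage <=95%; the call rests on the structural reads alone.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .alignment_io import AlignedRead, GenomeIndex, GenomicInterval
from .config import DetectionConfig
from .sv_evidence import JunctionCluster

__all__ = [
    "CoverageStats",
    "CircleCall",
    "DepthTrack",
    "coverage_stats",
    "assign_confidence",
    "call_circles",
    "reciprocal_overlap",
    "merge_calls",
    "annotate_genes",
    "SampleSummary",
    "summarize_sample",
    "per_sample_average",
]

CONFIDENCE_LEVELS = ("hconf", "conf", "lowq")


@dataclass
class CoverageStats:
    """Per-call coverage summary.

    Flank means are taken over windows of the circle's own length immediately
    up- and downstream; a flank truncated by a chromosome end uses only its
    available bases, and a fully unavailable flank contributes the other
    flank's mean (doubling it).
    """

    mean_cov: float
    fraction_covered: float
    flank_up_mean: float
    flank_down_mean: float
    flank_truncated: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_covered <= 1.0:
            raise ValueError("fraction_covered must be in [0, 1]")
        if min(self.mean_cov, self.flank_up_mean, self.flank_down_mean) < 0:
            raise ValueError("coverage means must be non-negative")

    @property
    def flank_sum(self) -> float:
        return self.flank_up_mean + self.flank_down_mean


@dataclass
class CircleCall:
    """A detected eccDNA with evidence counts, coverage and gene overlaps."""

    interval: GenomicInterval
    confidence: str
    evidence: dict[str, int]
    n_distinct_reads: int
    coverage: Optional[CoverageStats] = None
    genes: list[str] = field(default_factory=list)
    merged_members: list["CircleCall"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.confidence not in CONFIDENCE_LEVELS:
            raise ValueError(f"unknown confidence {self.confidence!r}")


class DepthTrack:
    """Per-base read depth from primary, non-duplicate alignments."""

    def __init__(self, genome: GenomeIndex):
        self.genome = genome
        self._depth = {c: np.zeros(l, dtype=np.int32) for c, l in genome.items()}

    @classmethod
    def from_reads(
        cls, reads: Iterable[AlignedRead], genome: GenomeIndex, cfg: Optional[DetectionConfig] = None
    ) -> "DepthTrack":
        track = cls(genome)
        use_dup = bool(cfg and cfg.use_duplicates)
        for r in reads:
            if not r.is_primary or (r.is_duplicate and not use_dup):
                continue
            arr = track._depth.get(r.chrom)
            if arr is None:
                continue
            for a, b in r.aligned_blocks():
                arr[a : min(b, len(arr))] += 1
        return track

    def depth(self, chrom: str, start: int, end: int) -> np.ndarray:
        return self._depth[chrom][start:end]


def coverage_stats(
    interval: GenomicInterval, depth: DepthTrack, genome: GenomeIndex
) -> CoverageStats:
    """Coverage statistics of a candidate circle and its two flanks."""
    interval.validate(genome)
    inside = depth.depth(interval.chrom, interval.start, interval.end)
    mean_cov = float(inside.mean())
    fraction = float((inside > 0).mean())
    L = interval.size
    clen = genome[interval.chrom]
    up = depth.depth(interval.chrom, max(0, interval.start - L), interval.start)
    down = depth.depth(interval.chrom, interval.end, min(clen, interval.end + L))
    truncated = len(up) < L or len(down) < L
    up_mean = float(up.mean()) if len(up) else None
    down_mean = float(down.mean()) if len(down) else None
    if up_mean is None and down_mean is None:
        up_mean = down_mean = 0.0
    elif up_mean is None:
        up_mean = down_mean  # fully unavailable flank doubles the other
    elif down_mean is None:
        down_mean = up_mean
    return CoverageStats(
        mean_cov=mean_cov,
        fraction_covered=fraction,
        flank_up_mean=up_mean,
        flank_down_mean=down_mean,
        flank_truncated=truncated,
    )


def assign_confidence(
    n_variants: int, stats: CoverageStats, cfg: DetectionConfig
) -> str:
    """Deterministic confidence rank from coverage statistics.

    ``lowq`` when the covered fraction is at or below the threshold; else
    ``conf``; upgraded to ``hconf`` when mean coverage exceeds
    ``coverage_fold_threshold`` times the flank statistic (the summed flank
    means by default, their average with ``flank_mode='mean'``).
    """
    if n_variants < cfg.min_structural_variants:
        raise ValueError("no call exists below the structural-variant minimum")
    if stats.fraction_covered <= cfg.coverage_fraction_threshold:
        return "lowq"
    flank_stat = stats.flank_sum if cfg.flank_mode == "sum" else stats.flank_sum / 2.0
    if stats.mean_cov > cfg.coverage_fold_threshold * flank_stat:
        return "hconf"
    return "conf"


def call_circles(
    clusters: Sequence[JunctionCluster],
    depth: DepthTrack,
    cfg: DetectionConfig,
    genome: Optional[GenomeIndex] = None,
) -> tuple[list[CircleCall], dict[str, int]]:
    """Clusters with >=2 distinct supporting reads and a valid <=1 Mb span
    become confidence-ranked calls; everything else is counted and dropped."""
    genome = genome if genome is not None else depth.genome
    calls: list[CircleCall] = []
    counters = {
        "clusters_in": len(clusters),
        "dropped_few_reads": 0,
        "dropped_no_span": 0,
        "dropped_too_large": 0,
    }
    for cl in clusters:
        if cl.consensus_start is None or cl.consensus_end is None:
            counters["dropped_no_span"] += 1
            continue
        if cl.n_distinct_reads < cfg.min_structural_variants:
            counters["dropped_few_reads"] += 1
            continue
        if cl.size > cfg.max_circle_size:
            counters["dropped_too_large"] += 1
            continue
        end = min(cl.consensus_end, genome[cl.chrom])
        start = max(0, cl.consensus_start)
        interval = GenomicInterval(cl.chrom, start, end)
        stats = coverage_stats(interval, depth, genome)
        conf = assign_confidence(cl.n_distinct_reads, stats, cfg)
        calls.append(
            CircleCall(
                interval=interval,
                confidence=conf,
                evidence=cl.kind_counts,
                n_distinct_reads=cl.n_distinct_reads,
                coverage=stats,
            )
        )
    counters["calls"] = len(calls)
    return calls, counters


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(overlap/|a|, overlap/|b|); 0 when disjoint or on different
    chromosomes.  Symmetric."""
    if a.chrom != b.chrom:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return min(ov / a.size, ov / b.size)


def _call_rank_key(call: CircleCall):
    frac = call.coverage.fraction_covered if call.coverage else 0.0
    return (-call.n_distinct_reads, -frac, call.interval.start, call.interval.end)


def merge_calls(calls: Sequence[CircleCall], cfg: DetectionConfig) -> list[CircleCall]:
    """Collapse calls with reciprocal overlap >= the merge threshold
    (transitive closure).

    The representative is the member with the most distinct evidence reads
    (ties: larger covered fraction, then leftmost); constituents are kept in
    ``merged_members``.  Calls below the threshold stay separate — nearby
    circles of clearly different sizes may be genuinely distinct.
    """
    items = sorted(calls, key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
    parent = list(range(len(items)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            a, b = items[i].interval, items[j].interval
            if b.chrom != a.chrom or b.start >= a.end:
                break
            if reciprocal_overlap(a, b) >= cfg.merge_reciprocal_overlap:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list[CircleCall]] = defaultdict(list)
    for i, call in enumerate(items):
        groups[find(i)].append(call)
    merged: list[CircleCall] = []
    for members in groups.values():
        if len(members) == 1:
            merged.append(members[0])
            continue
        rep = min(members, key=_call_rank_key)
        merged.append(
            CircleCall(
                interval=rep.interval,
                confidence=rep.confidence,
                evidence=rep.evidence,
                n_distinct_reads=rep.n_distinct_reads,
                coverage=rep.coverage,
                genes=rep.genes,
                merged_members=list(members),
            )
        )
    merged.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
    return merged


def annotate_genes(
    calls: Sequence[CircleCall], annotation: Sequence[GenomicInterval]
) -> list[CircleCall]:
    """Attach the names of all annotation intervals with any positive overlap
    (sorted, deduplicated).  Returns the same call objects, annotated."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for iv in annotation:
        trees[iv.chrom].addi(iv.start, iv.end, iv.name or f"{iv.chrom}:{iv.start}-{iv.end}")
    for call in calls:
        hits = trees[call.interval.chrom].overlap(call.interval.start, call.interval.end)
        call.genes = sorted({h.data for h in hits})
    return list(calls)


# ---------------------------------------------------------------------------
# Per-sample summaries
# ---------------------------------------------------------------------------


@dataclass
class SampleSummary:
    n_hconf: int
    n_conf: int
    n_lowq: int
    nuclei_count: float
    size_hist: dict[float, int]  # bin lower edge in log10(kb) -> count

    @property
    def n_total(self) -> int:
        return self.n_hconf + self.n_conf + self.n_lowq

    @property
    def per_100_nuclei(self) -> float:
        return self.n_total / self.nuclei_count * 100.0

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            fh.write(f"n_hconf\t{self.n_hconf}\n")
            fh.write(f"n_conf\t{self.n_conf}\n")
            fh.write(f"n_lowq\t{self.n_lowq}\n")
            fh.write(f"n_total\t{self.n_total}\n")
            fh.write(f"nuclei_count\t{self.nuclei_count:g}\n")
            fh.write(f"per_100_nuclei\t{self.per_100_nuclei:.2f}\n")
            for edge, count in self.size_hist.items():
                fh.write(f"size_bin_log10kb_{edge:g}\t{count}\n")


def summarize_sample(calls: Sequence[CircleCall], nuclei_count: float) -> SampleSummary:
    """Counts by confidence, frequency per 100 nuclei, and a size histogram
    in 0.1 log10-kb bins."""
    if nuclei_count <= 0:
        raise ValueError("nuclei_count must be positive")
    counts = Counter(c.confidence for c in calls)
    hist: Counter = Counter()
    for c in calls:
        kb = c.interval.size / 1000.0
        edge = round(math.floor(math.log10(kb) / 0.1) * 0.1, 10)
        hist[edge] += 1
    return SampleSummary(
        n_hconf=counts.get("hconf", 0),
        n_conf=counts.get("conf", 0),
        n_lowq=counts.get("lowq", 0),
        nuclei_count=nuclei_count,
        size_hist=dict(sorted(hist.items())),
    )


def per_sample_average(total_counts: dict[str, int], n_samples: int) -> dict[str, int]:
    """Cohort bookkeeping: rounded per-sample averages from cohort totals."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    return {
        k: int(round(v / n_samples)) for k, v in total_counts.items()
    }
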