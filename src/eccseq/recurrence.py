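"""Cross-sample recurrence of circle calls and variant-database co-occurrence.

Two calls from different samples are "the same" circle when their reciprocal
overlap reaches the recurrence threshold (90% by default).  Grouping is
single-linkage followed by a pairwise check — pure single-linkage can chain
intervals that never meet the threshold pairwise, so failing groups are split
greedily.  A seeded Monte Carlo null quantifies how often such agreement
would arise from random interval placement.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .alignment_io import GenomeIndex, GenomicInterval
from .circle_calling import CircleCall, reciprocal_overlap
from .config import DetectionConfig

__all__ = [
    "RecurrenceRecord",
    "recurrent_circles",
    "intersect_variant_db",
    "recurrence_null_probability",
    "analytic_pair_bound",
    "LARGE_CIRCLE_MIN_BP",
]

#: Size floor for "large" circles intersected with external variant databases.
LARGE_CIRCLE_MIN_BP = 25_000


@dataclass
class RecurrenceRecord:
    """A circle observed in two or more samples at high reciprocal overlap."""

    representative: GenomicInterval
    hits: list[tuple[str, GenomicInterval, str]]  # (sample_id, interval, confidence)
    min_pairwise_ro: float

    @property
    def n_samples(self) -> int:
        return len({s for s, _, _ in self.hits})


def _pairwise_ok(intervals: Sequence[GenomicInterval], threshold: float) -> float:
    """Minimum pairwise reciprocal overlap, or -1 below threshold."""
    lo = 1.0
    for i in range(len(intervals)):
        for j in range(i + 1, len(intervals)):
            ro = reciprocal_overlap(intervals[i], intervals[j])
            if ro < threshold:
                return -1.0
            lo = min(lo, ro)
    return lo


def recurrent_circles(
    samples: dict[str, Sequence[CircleCall]], cfg: DetectionConfig
) -> list[RecurrenceRecord]:
    """Groups of calls from distinct samples with pairwise reciprocal overlap
    at or above ``cfg.recurrence_reciprocal_overlap``.

    Output is independent of sample ordering and sorted by the number of
    supporting samples, descending.
    """
    if len(samples) < 2:
        raise ValueError("recurrence needs at least two samples")
    tagged: list[tuple[str, CircleCall]] = []
    for sid in sorted(samples):
        for call in samples[sid]:
            tagged.append((sid, call))
    tagged.sort(key=lambda t: (t[1].interval.chrom, t[1].interval.start, t[1].interval.end, t[0]))
    thr = cfg.recurrence_reciprocal_overlap

    parent = list(range(len(tagged)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(tagged)):
        a = tagged[i][1].interval
        for j in range(i + 1, len(tagged)):
            b = tagged[j][1].interval
            if b.chrom != a.chrom or b.start >= a.end:
                break
            if reciprocal_overlap(a, b) >= thr:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    groups: dict[int, list[tuple[str, CircleCall]]] = defaultdict(list)
    for i, item in enumerate(tagged):
        groups[find(i)].append(item)

    records: list[RecurrenceRecord] = []
    for members in groups.values():
        for sub in _verified_subgroups(members, thr):
            samples_in = {s for s, _ in sub}
            if len(samples_in) < 2:
                continue
            ivs = [c.interval for _, c in sub]
            min_ro = _pairwise_ok(ivs, thr)
            rep = _medoid(ivs)
            records.append(
                RecurrenceRecord(
                    representative=rep,
                    hits=[(s, c.interval, c.confidence) for s, c in sub],
                    min_pairwise_ro=min_ro,
                )
            )
    records.sort(
        key=lambda r: (
            -r.n_samples,
            r.representative.chrom,
            r.representative.start,
            r.representative.end,
        )
    )
    return records


def _verified_subgroups(members, threshold):
    """Split a single-linkage group greedily until every subgroup passes the
    pairwise check."""
    ivs = [c.interval for _, c in members]
    if _pairwise_ok(ivs, threshold) >= 0:
        yield members
        return
    remaining = list(members)
    while remaining:
        seed_item = remaining.pop(0)
        sub = [seed_item]
        rest = []
        for item in remaining:
            if all(
                reciprocal_overlap(item[1].interval, s[1].interval) >= threshold
                for s in sub
            ):
                sub.append(item)
            else:
                rest.append(item)
        remaining = rest
        yield sub


def _medoid(intervals: Sequence[GenomicInterval]) -> GenomicInterval:
    """The member interval with the greatest total reciprocal overlap to the
    others (ties: leftmost)."""
    best, best_score = None, (-1.0, None)
    for iv in sorted(intervals, key=lambda v: (v.chrom, v.start, v.end)):
        score = sum(reciprocal_overlap(iv, other) for other in intervals)
        if score > best_score[0] + 1e-12:
            best, best_score = iv, (score, iv)
    return best


def intersect_variant_db(
    calls: Sequence[CircleCall],
    db_intervals: Sequence[GenomicInterval],
    cfg: DetectionConfig,
    min_size: int = LARGE_CIRCLE_MIN_BP,
) -> list[tuple[CircleCall, GenomicInterval, float]]:
    """(call, database interval, RO) pairs at the variant-database threshold,
    restricted to calls larger than ``min_size`` bp."""
    large = [c for c in calls if c.interval.size > min_size]
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in db_intervals:
        by_chrom[iv.chrom].append(iv)
    hits = []
    for call in large:
        for iv in by_chrom.get(call.interval.chrom, ()):
            ro = reciprocal_overlap(call.interval, iv)
            if ro >= cfg.variantdb_reciprocal_overlap:
                hits.append((call, iv, ro))
    return hits


# ---------------------------------------------------------------------------
# Monte Carlo null for recurrence
# ---------------------------------------------------------------------------


def _place_uniform(
    rng: np.random.Generator, genome: GenomeIndex, length: int, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """(chrom index, start) of n length-preserving uniform placements;
    chromosomes chosen proportional to length, intervals wholly inside."""
    chroms = [c for c in genome.chroms if genome[c] >= length]
    if not chroms:
        raise ValueError(f"no chromosome can hold an interval of {length} bp")
    weights = np.array([genome[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    idx = rng.choice(len(chroms), size=n, p=weights)
    starts = np.empty(n, dtype=np.int64)
    for i, ci in enumerate(idx):
        starts[i] = rng.integers(0, genome[chroms[ci]] - length + 1)
    return idx, starts


def recurrence_null_probability(
    observed: RecurrenceRecord,
    genome: GenomeIndex,
    n_samples_total: int,
    calls_per_sample: int,
    cfg: DetectionConfig,
    seed: int,
    ro_threshold: float = 0.95,
    n_replicates: Optional[int] = None,
) -> float:
    """Empirical probability of a cross-sample pair reaching the overlap
    threshold under random placement.

    Each replicate places ``calls_per_sample`` intervals of the observed
    length per sample uniformly on the genome; a replicate is a hit when any
    cross-sample pair achieves reciprocal overlap >= ``ro_threshold``.
    The add-one estimator (hits + 1) / (replicates + 1) keeps the probability
    in [1/(n+1), 1].
    """
    n_rep = cfg.mc_randomizations if n_replicates is None else n_replicates
    if n_rep < 1:
        raise ValueError("at least one replicate is required")
    L = observed.representative.size
    tol = int(L * (1.0 - ro_threshold))  # equal lengths: RO>=t iff |ds|<=L(1-t)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_rep):
        chrom_ids = []
        starts = []
        sample_ids = []
        for s in range(n_samples_total):
            ci, st = _place_uniform(rng, genome, L, calls_per_sample)
            chrom_ids.append(ci)
            starts.append(st)
            sample_ids.append(np.full(calls_per_sample, s))
        ci = np.concatenate(chrom_ids)
        st = np.concatenate(starts)
        sid = np.concatenate(sample_ids)
        order = np.lexsort((st, ci))
        ci, st, sid = ci[order], st[order], sid[order]
        hit = False
        for i in range(len(st)):
            j = i + 1
            while j < len(st) and ci[j] == ci[i] and st[j] - st[i] <= tol:
                if sid[j] != sid[i]:
                    hit = True
                    break
                j += 1
            if hit:
                break
        hits += hit
    return (hits + 1) / (n_rep + 1)


def analytic_pair_bound(length_bp: int, genome_bp: int) -> float:
    """Closed-form upper bound on the probability that two uniformly placed
    intervals of the given length overlap at all: ~2L/G per pair."""
    return min(1.0, 2.0 * length_bp / genome_bp)
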