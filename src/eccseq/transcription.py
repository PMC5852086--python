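"""Transcription across eccDNA junctions from RNA split-read alignments.

An RNA read transcribed across a circle junction aligns in back-splice
geometry: its left (query-first) part maps downstream, near the circle end,
and its right part maps upstream, at the circle start.  The interval implied
by such a read — right-part start to left-part end — must lie entirely
within a detected circle, and its start may deviate at most 20 nt from the
circle start (trans-splicing products fail this).  Only circles with an
exactly known junction (soft-clip or split evidence) are eligible.

Significance of the circle/transcript co-location is tested by randomizing
both interval sets on the genome and counting overlaps (empirical p-value,
add-one estimator).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .alignment_io import (
    AlignedRead,
    AlignmentSet,
    GenomeIndex,
    GenomicInterval,
)
from .circle_calling import CircleCall
from .config import DetectionConfig
from .sv_evidence import _best_ungapped_loci, _chrom_seq

__all__ = [
    "SplitTranscriptRead",
    "TranscribedCircle",
    "read_split_transcripts_table",
    "split_transcripts_from_alignments",
    "count_genomic_loci",
    "detect_junction_transcripts",
    "rank_transcribed_circle",
    "monte_carlo_overlap_p",
]

MITO_NAMES = {"chrM", "MT", "chrMT", "M"}


@dataclass
class SplitTranscriptRead:
    """An RNA read split across a circle junction (back-splice geometry)."""

    read_name: str
    chrom: str
    left_part: tuple[int, int]  # aligns downstream (3'): higher coordinates
    right_part: tuple[int, int]  # aligns upstream (5'): lower coordinates
    n_genomic_loci: int = 1

    def __post_init__(self) -> None:
        ls, le = self.left_part
        rs, re = self.right_part
        if not (0 <= ls < le and 0 <= rs < re):
            raise ValueError(f"read {self.read_name}: invalid part intervals")
        if not rs < ls:
            raise ValueError(
                f"read {self.read_name}: left part must align downstream of "
                "the right part (back-splice geometry)"
            )

    @property
    def implied_interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.right_part[0], self.left_part[1])


@dataclass
class TranscribedCircle:
    """A circle call with junction-spanning transcript support."""

    circle: CircleCall
    supporting_reads: list[SplitTranscriptRead]
    rank: str


# ---------------------------------------------------------------------------
# Input parsing
# ---------------------------------------------------------------------------

TABLE_COLUMNS = ["read_name", "chrom", "left_start", "left_end", "right_start", "right_end"]


def read_split_transcripts_table(path: str) -> list[SplitTranscriptRead]:
    """Read split-transcript reads from a 6-column tab-separated table:
    read_name, chrom, left_start, left_end, right_start, right_end
    (coordinates 0-based half-open; optional 7th column: genomic locus
    count).  Mitochondrial records are excluded."""
    out: list[SplitTranscriptRead] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("read_name\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}: expected >=6 columns, got {len(parts)}")
            name, chrom = parts[0], parts[1]
            if chrom in MITO_NAMES:
                continue
            ls, le, rs, re = (int(x) for x in parts[2:6])
            n_loci = int(parts[6]) if len(parts) > 6 else 1
            out.append(
                SplitTranscriptRead(
                    read_name=name,
                    chrom=chrom,
                    left_part=(ls, le),
                    right_part=(rs, re),
                    n_genomic_loci=n_loci,
                )
            )
    return out


def split_transcripts_from_alignments(
    alignments: AlignmentSet | Sequence[AlignedRead],
    reference=None,
    cfg: Optional[DetectionConfig] = None,
) -> list[SplitTranscriptRead]:
    """Reconstruct split-transcript reads from SAM records (primary +
    supplementary-locus annotation).

    The primary record holds one read half with the other half soft-clipped;
    the supplementary locus places the clipped half.  Back-splice geometry
    requires the query-first half to map downstream of the query-second half;
    reads in normal (forward-splice) geometry are skipped, as are
    mitochondrial alignments.  When a reference is given, the genomic locus
    count of each half is computed with the clipped-fragment realigner.
    """
    reads = alignments.reads if isinstance(alignments, AlignmentSet) else alignments
    cfg = cfg or DetectionConfig()
    out: list[SplitTranscriptRead] = []
    for r in reads:
        if not r.is_primary or r.chrom in MITO_NAMES:
            continue
        if r.supplementary_locus is None:
            continue
        sup_chrom, sup_start, sup_strand = r.supplementary_locus
        if sup_chrom != r.chrom or sup_strand != r.strand or sup_chrom in MITO_NAMES:
            continue
        if r.right_clip_len > 0 and r.left_clip_len == 0:
            # primary is the query-first half; clipped (query-second) half at sup
            first = (r.start, r.end)
            second = (sup_start, sup_start + r.right_clip_len)
            clip_seq = r.clipped_seq_right
        elif r.left_clip_len > 0 and r.right_clip_len == 0:
            second = (r.start, r.end)
            first = (sup_start, sup_start + r.left_clip_len)
            clip_seq = r.clipped_seq_left
        else:
            continue
        if first[0] <= second[0]:
            continue  # forward-splice order; not a junction transcript
        n_loci = 1
        if reference is not None:
            n_loci = count_genomic_loci(r, first, second, reference, cfg)
        out.append(
            SplitTranscriptRead(
                read_name=r.read_name,
                chrom=r.chrom,
                left_part=first,
                right_part=second,
                n_genomic_loci=n_loci,
            )
        )
    return out


def count_genomic_loci(
    read: AlignedRead,
    left_part: tuple[int, int],
    right_part: tuple[int, int],
    reference,
    cfg: DetectionConfig,
) -> int:
    """Multi-mapping count of a junction-spanning sequence.

    Each read half is realigned over every chromosome with the same k-mer
    seeding / ungapped extension used for clipped DNA fragments; the count is
    the larger of the halves' acceptable-locus counts (the junction sequence
    itself is not genomically contiguous).
    """
    chroms = (
        list(reference.keys()) if isinstance(reference, dict) else list(reference.keys())
    )
    counts = []
    for a, b in (left_part, right_part):
        frag = _chrom_seq(reference, read.chrom)[a:b]
        if len(frag) < cfg.realign_kmer:
            counts.append(1)
            continue
        n = 0
        for chrom in chroms:
            loci, _ = _best_ungapped_loci(
                frag,
                _chrom_seq(reference, chrom),
                0,
                cfg.realign_kmer,
                cfg.realign_min_identity,
            )
            n += len(loci)
        counts.append(max(1, n))
    return max(counts)


# ---------------------------------------------------------------------------
# Detection and ranking
# ---------------------------------------------------------------------------


def _has_exact_junction(circle: CircleCall) -> bool:
    ev = circle.evidence or {}
    return ev.get("split", 0) + ev.get("softclip", 0) > 0


def detect_junction_transcripts(
    rna_reads: Sequence[SplitTranscriptRead],
    circles: Sequence[CircleCall],
    cfg: DetectionConfig,
) -> list[TranscribedCircle]:
    """Match split-transcript reads to detected circles.

    A read supports a circle when its implied interval lies entirely within
    the circle and its start deviates at most ``cfg.rna_max_start_deviation``
    nt from the circle start.  Circles detected from discordant pairs alone
    (no exact junction coordinate) are not eligible.
    """
    eligible = [c for c in circles if _has_exact_junction(c)]
    by_chrom: dict[str, list[CircleCall]] = defaultdict(list)
    for c in eligible:
        by_chrom[c.interval.chrom].append(c)
    support: dict[int, list[SplitTranscriptRead]] = defaultdict(list)
    for read in rna_reads:
        iv = read.implied_interval
        for ci, circle in enumerate(eligible):
            cv = circle.interval
            if cv.chrom != iv.chrom:
                continue
            contained = cv.start <= iv.start and iv.end <= cv.end
            if contained and abs(iv.start - cv.start) <= cfg.rna_max_start_deviation:
                support[ci].append(read)
    out: list[TranscribedCircle] = []
    for ci in sorted(support):
        circle = eligible[ci]
        reads = support[ci]
        tc = TranscribedCircle(circle=circle, supporting_reads=reads, rank="lowq")
        tc.rank = rank_transcribed_circle(tc)
        out.append(tc)
    return out


def rank_transcribed_circle(tc: TranscribedCircle) -> str:
    """Three-tier rank of transcript support.

    ``hconf``: some read matches both circle coordinates perfectly and its
    junction sequence is unique in the genome; ``conf``: a perfect match
    exists but only from multi-mapping reads; ``lowq``: only one coordinate
    matches.  Adding a perfectly matching unique read never lowers the rank.
    """
    cv = tc.circle.interval
    best = "lowq"
    for read in tc.supporting_reads:
        iv = read.implied_interval
        perfect = iv.start == cv.start and iv.end == cv.end
        if perfect and read.n_genomic_loci == 1:
            return "hconf"
        if perfect:
            best = "conf"
    return best


# ---------------------------------------------------------------------------
# Monte Carlo overlap test
# ---------------------------------------------------------------------------


def _count_overlaps(a: list[tuple[int, int, int]], b: list[tuple[int, int, int]]) -> int:
    """Number of overlapping pairs between two (chrom_id, start, end) lists."""
    by_chrom: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for c, s, e in b:
        by_chrom[c].append((s, e))
    n = 0
    for c, s, e in a:
        for bs, be in by_chrom.get(c, ()):
            if min(e, be) > max(s, bs):
                n += 1
    return n


def monte_carlo_overlap_p(
    circles: Sequence[GenomicInterval],
    transcript_intervals: Sequence[GenomicInterval],
    genome: GenomeIndex,
    cfg: DetectionConfig,
    seed: int,
    n_randomizations: Optional[int] = None,
) -> tuple[float, int]:
    """Empirical p-value for the observed circle/transcript overlap count.

    Both interval sets are re-placed uniformly on the genome (lengths
    preserved, chromosome weighted by length) ``n`` times; p is the add-one
    fraction of replicates whose overlap count reaches the observed one.
    Returns (p, observed overlap count).  Empty input sets give p = 1.
    """
    n = cfg.mc_randomizations if n_randomizations is None else n_randomizations
    if n < 1:
        raise ValueError("at least one randomization is required")
    if not circles or not transcript_intervals:
        import warnings

        warnings.warn("empty interval set: overlap p-value is 1 by definition")
        return 1.0, 0
    chrom_id = {c: i for i, c in enumerate(genome.chroms)}
    obs_a = [(chrom_id[iv.chrom], iv.start, iv.end) for iv in circles]
    obs_b = [(chrom_id[iv.chrom], iv.start, iv.end) for iv in transcript_intervals]
    observed = _count_overlaps(obs_a, obs_b)
    if observed == 0:
        return 1.0, 0
    rng = np.random.default_rng(seed)
    lengths = np.array([genome[c] for c in genome.chroms], dtype=float)
    weights = lengths / lengths.sum()

    def randomize(intervals) -> list[tuple[int, int, int]]:
        out = []
        for _, s, e in intervals:
            L = e - s
            while True:
                ci = rng.choice(len(lengths), p=weights)
                if lengths[ci] >= L:
                    break
            st = int(rng.integers(0, int(lengths[ci]) - L + 1))
            out.append((ci, st, st + L))
        return out

    hits = 0
    for _ in range(n):
        if _count_overlaps(randomize(obs_a), randomize(obs_b)) >= observed:
            hits += 1
    return (hits + 1) / (n + 1), observed
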