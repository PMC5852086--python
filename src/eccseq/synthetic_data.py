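"""Synthetic Circle-Seq data with exactly the read geometry the detector consumes.

The generator emits *post-alignment* records (SAM dialect) directly, modelling
what an ideal aligner would report for reads from a circular template:

* a read crossing the circle junction aligns its longer portion as the
  primary record with the shorter portion soft-clipped (clipped sequence
  included) plus a supplementary-alignment locus — soft-clip and split
  evidence;
* a fragment straddling the junction with neither read crossing it yields a
  reverse-forward discordant pair;
* fragments internal to the circle yield concordant forward-reverse pairs
  (internal coverage), and the linear genome contributes background pairs.

Circle sizes follow a bimodal log-normal mixture (peaks near 0.1 kb and
5 kb); copy numbers can follow a phenomenological rolling-circle
amplification bias (small circles amplified more).  Every emitted read
carries a source tag in its name, and the ground truth is recorded so
detector output can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pysam

from .alignment_io import (
    AlignedRead,
    AlignmentSet,
    GenomeIndex,
    GenomicInterval,
    aligned_read_from_pysam,
)
from .config import SpikeInControl

__all__ = [
    "SimTruth",
    "PlantedCircle",
    "SimReads",
    "simulate_genome",
    "write_fasta",
    "plant_circles",
    "simulate_dna_reads",
    "simulate_rna_junction_reads",
    "simulate_class_reads",
    "bimodal_size_model",
    "fixed_size_model",
    "phi29_copy_model",
    "uniform_copy_model",
    "write_split_transcript_table",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


def simulate_genome(
    lengths: dict[str, int] | Sequence[int],
    gc_content: float = 0.5,
    seed: int = 0,
    repeat_tract: Optional[tuple[str, int, int]] = None,
) -> tuple[dict[str, str], GenomeIndex]:
    """Reproducible pseudo-random genome.

    ``lengths`` is either a chrom->length mapping or a list of lengths
    (chromosomes named chr1, chr2, ...).  ``repeat_tract`` optionally embeds
    a tandem repeat (unit sequence, copies, insert position on the first
    chromosome) to exercise ambiguity handling.
    """
    if not isinstance(lengths, dict):
        lengths = {f"chr{i + 1}": int(l) for i, l in enumerate(lengths)}
    if not 0.0 < gc_content < 1.0:
        raise ValueError("gc_content must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p_gc = gc_content / 2.0
    p_at = (1.0 - gc_content) / 2.0
    probs = np.array([p_at, p_gc, p_gc, p_at])  # A C G T
    genome: dict[str, str] = {}
    for chrom, length in lengths.items():
        idx = rng.choice(4, size=length, p=probs)
        genome[chrom] = _BASES[idx].tobytes().decode()
    if repeat_tract is not None:
        unit, copies, pos = repeat_tract
        first = next(iter(genome))
        tract = unit * copies
        seq = genome[first]
        genome[first] = (seq[:pos] + tract + seq[pos + len(tract) :])[: len(seq)]
    index = GenomeIndex({c: len(s) for c, s in genome.items()})
    return genome, index


def write_fasta(genome: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Size and copy-number models
# ---------------------------------------------------------------------------


def bimodal_size_model(
    modes: tuple[float, float] = (100.0, 5000.0),
    sigmas_log10: tuple[float, float] = (0.15, 0.25),
    weights: tuple[float, float] = (0.5, 0.5),
    min_size: int = 100,
    max_size: int = 1_000_000,
) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Mixture of two log-normal components with modes near 0.1 kb and 5 kb."""
    w = np.array(weights, dtype=float)
    w /= w.sum()

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        comp = rng.choice(2, size=n, p=w)
        log10_sizes = rng.normal(
            np.log10(np.array(modes))[comp], np.array(sigmas_log10)[comp]
        )
        sizes = np.round(10.0 ** log10_sizes).astype(int)
        return np.clip(sizes, min_size, max_size)

    return sample


def fixed_size_model(size: int) -> Callable[[np.random.Generator, int], np.ndarray]:
    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        return np.full(n, int(size))

    return sample


def phi29_copy_model(
    alpha: float = 1.0, scale: float = 1000.0, sigma: float = 0.5
) -> Callable[[np.random.Generator, np.ndarray], np.ndarray]:
    """Rolling-circle amplification bias: expected copy number proportional
    to (scale / size)^alpha with log-normal scatter, floored at 1."""

    def sample(rng: np.random.Generator, sizes: np.ndarray) -> np.ndarray:
        mean = (scale / sizes.astype(float)) ** alpha
        copies = rng.lognormal(np.log(np.maximum(mean, 1e-9)), sigma)
        return np.maximum(1, np.round(copies)).astype(int)

    return sample


def uniform_copy_model(copies: int = 1) -> Callable:
    def sample(rng: np.random.Generator, sizes: np.ndarray) -> np.ndarray:
        return np.full(len(sizes), int(copies))

    return sample


# ---------------------------------------------------------------------------
# Truth containers
# ---------------------------------------------------------------------------


@dataclass
class PlantedCircle:
    interval: GenomicInterval
    copy_number: int = 1
    reads_emitted: dict[str, int] = field(default_factory=dict)


@dataclass
class SimTruth:
    """Ground truth of one simulated sample."""

    genome: dict[str, str]
    index: GenomeIndex
    circles: list[PlantedCircle]
    spike_ins: list[SpikeInControl] = field(default_factory=list)
    background_depth: float = 0.0
    seed: int = 0

    def truth_intervals(self) -> list[GenomicInterval]:
        return [c.interval for c in self.circles]

    def write_truth_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for i, c in enumerate(self.circles):
                iv = c.interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tcircle_{i}\t{c.copy_number}\n")

    def write_truth_table(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("circle\tchrom\tstart\tend\tsize_bp\tcopy_number\treads_emitted\n")
            for i, c in enumerate(self.circles):
                iv = c.interval
                emitted = ",".join(f"{k}={v}" for k, v in sorted(c.reads_emitted.items()))
                fh.write(
                    f"circle_{i}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.size}\t"
                    f"{c.copy_number}\t{emitted or '.'}\n"
                )


def plant_circles(
    genome: dict[str, str],
    index: GenomeIndex,
    n: int,
    size_model: Optional[Callable] = None,
    copy_model: Optional[Callable] = None,
    seed: int = 0,
    min_gap: int = 1000,
    max_retries_per_circle: int = 200,
) -> SimTruth:
    """Place ``n`` non-overlapping circles on the genome.

    Circles are separated by at least ``max(min_gap, own length)`` so that a
    circle's flank windows are not contaminated by a neighbour's coverage.
    Raises when placement repeatedly fails.
    """
    rng = np.random.default_rng(seed)
    size_model = size_model or bimodal_size_model()
    copy_model = copy_model or uniform_copy_model()
    sizes = size_model(rng, n)
    copies = copy_model(rng, sizes)
    chroms = index.chroms
    weights = np.array([index[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    circles: list[PlantedCircle] = []
    for size, copy in zip(sizes, copies):
        size = int(size)
        placed = False
        for _ in range(max_retries_per_circle):
            ci = rng.choice(len(chroms), p=weights)
            chrom = chroms[ci]
            clen = index[chrom]
            gap = max(min_gap, size)
            if clen < size + 2 * gap:
                continue
            start = int(rng.integers(gap, clen - size - gap + 1))
            end = start + size
            if any(
                start - gap < oe and os < end + gap for os, oe in occupied[chrom]
            ):
                continue
            occupied[chrom].append((start, end))
            circles.append(PlantedCircle(GenomicInterval(chrom, start, end), int(copy)))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place a {size} bp circle after "
                f"{max_retries_per_circle} retries; genome too crowded"
            )
    circles.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    return SimTruth(genome=genome, index=index, circles=circles, seed=seed)


# ---------------------------------------------------------------------------
# DNA read simulation
# ---------------------------------------------------------------------------


@dataclass
class SimReads:
    """Simulated alignment records (coordinate-sorted) plus their header."""

    header: pysam.AlignmentHeader
    records: list[pysam.AlignedSegment]

    def write_sam(self, path: str) -> None:
        with pysam.AlignmentFile(path, "w", header=self.header) as fh:
            for rec in self.records:
                fh.write(rec)

    def write_fastq(self, path: str) -> None:
        """Optional raw-read export for users who want to run a real aligner."""
        with open(path, "w") as fh:
            for rec in self.records:
                seq = rec.query_sequence or ""
                fh.write(f"@{rec.query_name}\n{seq}\n+\n{'I' * len(seq)}\n")

    def alignment_set(self) -> AlignmentSet:
        genome = GenomeIndex(
            [(sq["SN"], sq["LN"]) for sq in self.header.to_dict()["SQ"]]
        )
        return AlignmentSet(genome=genome, reads=[aligned_read_from_pysam(r) for r in self.records])


def _sam_header(index: GenomeIndex) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": l} for c, l in index.items()],
        }
    )


def _make_segment(
    header: pysam.AlignmentHeader,
    name: str,
    chrom: str,
    pos: int,
    cigar: str,
    seq: str,
    reverse: bool,
    sa: Optional[tuple[str, int, str]] = None,
    paired: bool = False,
    read1: bool = True,
    mate: Optional[tuple[str, int, bool]] = None,
    mapq: int = 60,
) -> pysam.AlignedSegment:
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.reference_id = header.get_tid(chrom)
    rec.reference_start = pos
    rec.mapping_quality = mapq
    rec.cigarstring = cigar
    rec.query_sequence = seq
    flag = 0
    if reverse:
        flag |= 0x10
    if paired:
        flag |= 0x1
        flag |= 0x40 if read1 else 0x80
        if mate is not None:
            mchrom, mpos, mrev = mate
            rec.next_reference_id = header.get_tid(mchrom)
            rec.next_reference_start = mpos
            if mrev:
                flag |= 0x20
    rec.flag = flag
    if sa is not None:
        schrom, spos, sstrand = sa
        rec.set_tag("SA", f"{schrom},{spos + 1},{sstrand},*,60,0;")
    return rec


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Uniform substitution errors at the given per-base rate."""
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in (b"A", b"C", b"G", b"T") if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


@dataclass
class _Placement:
    """Primary placement of one circle-coordinate read segment."""

    pos: int
    cigar: str
    seq: str
    sa: Optional[tuple[str, int, str]]


def _place_circular_segment(
    genome: dict[str, str],
    circle: GenomicInterval,
    u: int,
    v: int,
    strand: str,
    prefer: str = "auto",
) -> _Placement:
    """Map a read covering circle coordinates [u, v) to the genome.

    Non-wrapping segments align contiguously; a segment crossing the
    junction aligns its ``prefer``red (default: longer) portion as primary
    with the other portion soft-clipped, the clipped sequence being the
    reference sequence of the other side.
    """
    s, e = circle.start, circle.end
    L = circle.size
    seq = genome[circle.chrom]
    if v <= L:
        return _Placement(pos=s + u, cigar=f"{v - u}M", seq=seq[s + u : s + v], sa=None)
    len_tail = L - u  # [s+u, e)
    len_head = v - L  # [s, s+len_head)
    stored = seq[s + u : e] + seq[s : s + len_head]
    primary_tail = len_tail >= len_head if prefer == "auto" else (prefer == "tail")
    if primary_tail:
        return _Placement(
            pos=s + u,
            cigar=f"{len_tail}M{len_head}S",
            seq=stored,
            sa=(circle.chrom, s, strand),
        )
    return _Placement(
        pos=s,
        cigar=f"{len_tail}S{len_head}M",
        seq=stored,
        sa=(circle.chrom, s + u, strand),
    )


def simulate_dna_reads(
    truth: SimTruth,
    read_len: int = 100,
    insert_mean: int = 430,
    insert_sd: int = 30,
    internal_depth: float = 20.0,
    junction_read_min: int = 3,
    background_depth: float = 0.0,
    chimera_rate: float = 0.0,
    min_softclip: int = 50,
    subst_rate: float = 0.0,
    seed: Optional[int] = None,
) -> SimReads:
    """Emit coordinate-sorted alignments for a planted-circle truth set.

    Per circle: ``junction_read_min`` reads engineered to cross the junction
    with at least ``min_softclip`` clipped bases, plus circular fragments to
    ``internal_depth x copy_number`` coverage (paired when the circle can
    hold a full insert, single merged reads otherwise).  Background
    concordant pairs cover the linear genome at ``background_depth``;
    ``chimera_rate`` adds random-ligation artifact pairs; ``subst_rate``
    applies uniform substitution errors.
    """
    if read_len >= insert_mean:
        raise ValueError("read_len must be smaller than insert_mean")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    header = _sam_header(truth.index)
    records: list[pysam.AlignedSegment] = []
    truth.background_depth = background_depth

    for ci, planted in enumerate(truth.circles):
        circle = planted.interval
        L = circle.size
        rl_eff = min(read_len, L)
        emitted = {"junction": 0, "coverage": 0}

        # --- engineered junction-crossing reads (soft-clip/split evidence);
        # circles shorter than 2x the clip threshold cannot host a read with
        # both a >=min_softclip clip and an equally long anchor
        clip = min_softclip if rl_eff >= 2 * min_softclip else rl_eff // 2
        anchor = rl_eff - clip
        for j in range(junction_read_min):
            u, v = L - anchor, L + clip
            prefer = "tail" if j % 2 == 0 else "head"
            if prefer == "head":
                u, v = L - clip, L + anchor
            pl = _place_circular_segment(truth.genome, circle, u, v, "+", prefer=prefer)
            records.append(
                _make_segment(
                    header,
                    f"jx:{ci}:{j}",
                    circle.chrom,
                    pl.pos,
                    pl.cigar,
                    pl.seq,
                    reverse=False,
                    sa=pl.sa,
                )
            )
            emitted["junction"] += 1

        # --- circular fragments for internal coverage (and, for larger
        # circles, naturally occurring RF discordant pairs)
        depth = internal_depth * planted.copy_number
        if L < 2 * read_len + 50:
            n_single = math.ceil(depth * L / rl_eff)
            starts = rng.integers(0, L, size=n_single)
            for k, u in enumerate(starts):
                pl = _place_circular_segment(
                    truth.genome, circle, int(u), int(u) + rl_eff, "+"
                )
                records.append(
                    _make_segment(
                        header,
                        f"cov:{ci}:{k}",
                        circle.chrom,
                        pl.pos,
                        pl.cigar,
                        pl.seq,
                        reverse=False,
                        sa=pl.sa,
                    )
                )
                emitted["coverage"] += 1
        else:
            n_pairs = math.ceil(depth * L / (2 * read_len))
            starts = rng.integers(0, L, size=n_pairs)
            flens = np.clip(
                np.round(rng.normal(insert_mean, insert_sd, size=n_pairs)),
                2 * read_len,
                L,
            ).astype(int)
            for k, (u, flen) in enumerate(zip(starts, flens)):
                u = int(u)
                u2 = u + int(flen) - read_len
                if u2 >= L:
                    u2 -= L
                p1 = _place_circular_segment(truth.genome, circle, u, u + read_len, "+")
                p2 = _place_circular_segment(truth.genome, circle, u2, u2 + read_len, "-")
                name = f"cov:{ci}:{k}"
                records.append(
                    _make_segment(
                        header, name, circle.chrom, p1.pos, p1.cigar, p1.seq,
                        reverse=False, sa=p1.sa, paired=True, read1=True,
                        mate=(circle.chrom, p2.pos, True),
                    )
                )
                records.append(
                    _make_segment(
                        header, name, circle.chrom, p2.pos, p2.cigar, p2.seq,
                        reverse=True, sa=p2.sa, paired=True, read1=False,
                        mate=(circle.chrom, p1.pos, False),
                    )
                )
                emitted["coverage"] += 2
        planted.reads_emitted = emitted

    # --- linear background (concordant FR pairs)
    if background_depth > 0:
        total = truth.index.total_length
        n_bg = math.ceil(background_depth * total / (2 * read_len))
        chroms = truth.index.chroms
        weights = np.array([truth.index[c] for c in chroms], dtype=float)
        weights /= weights.sum()
        for k in range(n_bg):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            clen = truth.index[chrom]
            flen = int(np.clip(round(rng.normal(insert_mean, insert_sd)), 2 * read_len, clen))
            p = int(rng.integers(0, clen - flen + 1))
            name = f"bg:{k}"
            seq = truth.genome[chrom]
            records.append(
                _make_segment(
                    header, name, chrom, p, f"{read_len}M", seq[p : p + read_len],
                    reverse=False, paired=True, read1=True,
                    mate=(chrom, p + flen - read_len, True),
                )
            )
            records.append(
                _make_segment(
                    header, name, chrom, p + flen - read_len, f"{read_len}M",
                    seq[p + flen - read_len : p + flen],
                    reverse=True, paired=True, read1=False, mate=(chrom, p, False),
                )
            )

    # --- chimeric random-ligation artifacts
    if chimera_rate > 0:
        n_chi = round(chimera_rate * max(1, len(records) // 2))
        chroms = truth.index.chroms
        for k in range(n_chi):
            name = f"chi:{k}"
            locs = []
            for _ in range(2):
                chrom = chroms[rng.integers(0, len(chroms))]
                p = int(rng.integers(0, truth.index[chrom] - read_len + 1))
                locs.append((chrom, p, bool(rng.integers(0, 2))))
            (c1, p1, r1), (c2, p2, r2) = locs
            records.append(
                _make_segment(
                    header, name, c1, p1, f"{read_len}M",
                    truth.genome[c1][p1 : p1 + read_len],
                    reverse=r1, paired=True, read1=True, mate=(c2, p2, r2),
                )
            )
            records.append(
                _make_segment(
                    header, name, c2, p2, f"{read_len}M",
                    truth.genome[c2][p2 : p2 + read_len],
                    reverse=r2, paired=True, read1=False, mate=(c1, p1, r1),
                )
            )

    if subst_rate > 0:
        for rec in records:
            cig = rec.cigarstring
            rec.query_sequence = _mutate(rec.query_sequence, subst_rate, rng)
            rec.cigarstring = cig

    records.sort(key=lambda r: (r.reference_id, r.reference_start, r.query_name, r.flag))
    return SimReads(header=header, records=records)


# ---------------------------------------------------------------------------
# RNA junction reads
# ---------------------------------------------------------------------------


def simulate_rna_junction_reads(
    truth: SimTruth,
    subset: Sequence[int],
    read_len: int = 100,
    reads_per_circle: int = 2,
    start_jitter: int = 0,
    seed: Optional[int] = None,
) -> tuple[list, SimReads]:
    """Back-splice RNA reads across the junctions of selected circles.

    ``subset`` indexes into ``truth.circles``.  Each read's left (query-
    first) half aligns at the circle's 3' end and its right half at the 5'
    start, offset by ``start_jitter`` nt (a test knob for the start-deviation
    filter).  Returns the reads as
    :class:`~eccseq.transcription.SplitTranscriptRead` objects plus their SAM
    representation (primary + supplementary-locus records).
    """
    from .transcription import SplitTranscriptRead

    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    header = _sam_header(truth.index)
    reads: list[SplitTranscriptRead] = []
    records: list[pysam.AlignedSegment] = []
    for idx_pos, ci in enumerate(subset):
        circle = truth.circles[ci].interval
        s, e, L = circle.start, circle.end, circle.size
        for j in range(reads_per_circle):
            a = read_len // 2
            b = read_len - a
            a, b = min(a, max(1, L - 1)), min(b, max(1, L - 1))
            rs = s + start_jitter
            left = (e - b, e)
            right = (rs, rs + a)
            if right[1] > e or left[0] < s:
                continue
            name = f"rna:{ci}:{j}"
            reads.append(
                SplitTranscriptRead(
                    read_name=name,
                    chrom=circle.chrom,
                    left_part=left,
                    right_part=right,
                )
            )
            seq = truth.genome[circle.chrom]
            stored = seq[left[0] : left[1]] + seq[right[0] : right[1]]
            records.append(
                _make_segment(
                    header, name, circle.chrom, left[0], f"{b}M{a}S", stored,
                    reverse=False, sa=(circle.chrom, right[0], "+"),
                )
            )
    records.sort(key=lambda r: (r.reference_id, r.reference_start, r.query_name))
    return reads, SimReads(header=header, records=records)


def write_split_transcript_table(reads: Sequence, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_name\tchrom\tleft_start\tleft_end\tright_start\tright_end\tn_loci\n")
        for r in reads:
            fh.write(
                f"{r.read_name}\t{r.chrom}\t{r.left_part[0]}\t{r.left_part[1]}\t"
                f"{r.right_part[0]}\t{r.right_part[1]}\t{r.n_genomic_loci}\n"
            )


# ---------------------------------------------------------------------------
# Read-class / spike-in reads
# ---------------------------------------------------------------------------


def simulate_class_reads(
    class_fractions: dict[str, float],
    n_reads: int,
    seed: int = 0,
    read_len: int = 100,
    contig_length: int = 10_000,
) -> tuple[list[AlignedRead], dict[str, str]]:
    """Multinomial read sample over labelled contigs (one contig per class).

    Emulates the custom-genome mapping used for repeat classes and spike-in
    plasmids.  Returns the reads plus the contig->class map.
    """
    classes = sorted(class_fractions)
    probs = np.array([class_fractions[c] for c in classes], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("class fractions must sum to a positive value")
    probs /= probs.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, probs)
    reads: list[AlignedRead] = []
    class_map: dict[str, str] = {}
    for cls, n in zip(classes, counts):
        contig = f"{cls}_contig"
        class_map[contig] = cls
        for k in range(n):
            start = int(rng.integers(0, contig_length - read_len + 1))
            reads.append(
                AlignedRead(
                    read_name=f"{cls}:{k}",
                    chrom=contig,
                    start=start,
                    end=start + read_len,
                    strand="+",
                    cigar=[("M", read_len)],
                )
            )
    return reads, class_map
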