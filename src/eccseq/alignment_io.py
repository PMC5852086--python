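"""Reading and writing the standard formats the pipeline touches.

All internal coordinates are 0-based half-open.  SAM positions (1-based) are
converted on read; BED output needs no conversion.  The only containers that
cross module boundaries are :class:`AlignedRead`, :class:`GenomicInterval`
and :class:`GenomeIndex`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedRead",
    "GenomeIndex",
    "GenomicInterval",
    "AlignmentSet",
    "read_alignments",
    "aligned_read_from_pysam",
    "write_circle_table",
    "read_circle_table",
    "read_intervals",
    "write_bed",
    "CIRCLE_TABLE_COLUMNS",
]

# CIGAR operations that consume reference bases.
_REF_CONSUMING = {"M", "D", "N", "=", "X"}
# pysam integer op codes -> characters.
_CIGAR_OPS = "MIDNSHP=XB"


class GenomeIndex:
    """Ordered map of chromosome name -> length (bp)."""

    def __init__(self, lengths: dict[str, int] | Sequence[tuple[str, int]]):
        items = list(lengths.items()) if isinstance(lengths, dict) else list(lengths)
        names = [n for n, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome index")
        if any(l <= 0 for _, l in items):
            raise ValueError("chromosome lengths must be positive")
        self._lengths: dict[str, int] = dict(items)
        self._order: list[str] = names

    @property
    def chroms(self) -> list[str]:
        return list(self._order)

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __getitem__(self, chrom: str) -> int:
        return self._lengths[chrom]

    def __len__(self) -> int:
        return len(self._lengths)

    def __iter__(self) -> Iterator[str]:
        return iter(self._order)

    def items(self):
        return ((c, self._lengths[c]) for c in self._order)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeIndex) and list(self.items()) == list(other.items())

    def __repr__(self) -> str:
        return f"GenomeIndex({len(self)} chroms, {self.total_length} bp)"


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def size(self) -> int:
        return self.end - self.start

    def validate(self, genome: GenomeIndex) -> None:
        if self.chrom not in genome:
            raise ValueError(f"unknown chromosome {self.chrom!r}")
        if self.end > genome[self.chrom]:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {genome[self.chrom]}"
            )


@dataclass
class AlignedRead:
    """One read alignment — the unit of structural evidence.

    ``start``/``end`` are 0-based half-open reference coordinates of the
    aligned (clipped-excluded) span.  ``left_clip_len``/``right_clip_len``
    count leading/trailing soft *or* hard clipped bases; ``clipped_seq_*`` is
    available only for soft clips.
    """

    read_name: str
    chrom: str
    start: int
    end: int
    strand: str
    cigar: list[tuple[str, int]]
    mapq: int = 60
    is_read1: bool = True
    is_paired: bool = False
    mate_chrom: Optional[str] = None
    mate_start: Optional[int] = None
    mate_strand: Optional[str] = None
    left_clip_len: int = 0
    right_clip_len: int = 0
    clipped_seq_left: Optional[str] = None
    clipped_seq_right: Optional[str] = None
    supplementary_locus: Optional[tuple[str, int, str]] = None
    is_secondary: bool = False
    is_supplementary: bool = False
    is_duplicate: bool = False
    is_unmapped: bool = False

    def __post_init__(self) -> None:
        if self.is_unmapped:
            return
        ref_len = sum(n for op, n in self.cigar if op in _REF_CONSUMING)
        if self.end - self.start != ref_len:
            raise ValueError(
                f"read {self.read_name}: end-start={self.end - self.start} "
                f"does not match reference-consuming CIGAR length {ref_len}"
            )
        for seq, clip in (
            (self.clipped_seq_left, self.left_clip_len),
            (self.clipped_seq_right, self.right_clip_len),
        ):
            if seq is not None and len(seq) != clip:
                raise ValueError(
                    f"read {self.read_name}: clipped sequence length "
                    f"{len(seq)} != clip length {clip}"
                )

    @property
    def is_primary(self) -> bool:
        return not (self.is_secondary or self.is_supplementary or self.is_unmapped)

    def aligned_blocks(self) -> list[tuple[int, int]]:
        """Reference intervals covered by M/=/X operations (for depth)."""
        blocks: list[tuple[int, int]] = []
        pos = self.start
        for op, n in self.cigar:
            if op in ("M", "=", "X"):
                blocks.append((pos, pos + n))
                pos += n
            elif op in ("D", "N"):
                pos += n
        return blocks


def _parse_sa_tag(sa: str) -> Optional[tuple[str, int, str]]:
    """First locus of an SA tag -> (chrom, 0-based start, strand)."""
    first = sa.split(";")[0]
    if not first:
        return None
    parts = first.split(",")
    if len(parts) < 3:
        return None
    return parts[0], int(parts[1]) - 1, parts[2]


def aligned_read_from_pysam(rec: pysam.AlignedSegment) -> AlignedRead:
    """Convert a pysam record to an :class:`AlignedRead` (SAM 1-based to
    internal 0-based conversion is handled by pysam itself)."""
    if rec.is_unmapped:
        return AlignedRead(
            read_name=rec.query_name or "",
            chrom="*",
            start=0,
            end=0,
            strand="+",
            cigar=[],
            mapq=0,
            is_read1=not rec.is_read2,
            is_paired=rec.is_paired,
            is_unmapped=True,
        )
    cig = [(_CIGAR_OPS[op], n) for op, n in (rec.cigartuples or [])]
    seq = rec.query_sequence  # excludes hard-clipped bases
    left_op, left_n = cig[0] if cig else ("M", 0)
    right_op, right_n = cig[-1] if len(cig) > 1 else ("M", 0)
    left_clip = left_n if left_op in ("S", "H") else 0
    right_clip = right_n if right_op in ("S", "H") else 0
    seq_left = seq[:left_clip] if (seq and left_op == "S" and left_clip) else None
    seq_right = seq[-right_clip:] if (seq and right_op == "S" and right_clip) else None
    if seq is not None:
        expect = sum(n for op, n in cig if op in ("M", "I", "S", "=", "X"))
        if len(seq) != expect:
            raise ValueError(
                f"read {rec.query_name}: sequence length {len(seq)} does not "
                f"match CIGAR query length {expect}"
            )
    sup = None
    if rec.has_tag("SA"):
        sup = _parse_sa_tag(rec.get_tag("SA"))
    mate_chrom = mate_start = mate_strand = None
    if rec.is_paired and not rec.mate_is_unmapped:
        mate_chrom = rec.next_reference_name
        mate_start = rec.next_reference_start
        mate_strand = "-" if rec.mate_is_reverse else "+"
    return AlignedRead(
        read_name=rec.query_name or "",
        chrom=rec.reference_name,
        start=rec.reference_start,
        end=rec.reference_end,
        strand="-" if rec.is_reverse else "+",
        cigar=cig,
        mapq=rec.mapping_quality,
        is_read1=not rec.is_read2,
        is_paired=rec.is_paired,
        mate_chrom=mate_chrom,
        mate_start=mate_start,
        mate_strand=mate_strand,
        left_clip_len=left_clip,
        right_clip_len=right_clip,
        clipped_seq_left=seq_left,
        clipped_seq_right=seq_right,
        supplementary_locus=sup,
        is_secondary=rec.is_secondary,
        is_supplementary=rec.is_supplementary,
        is_duplicate=rec.is_duplicate,
    )


@dataclass
class AlignmentSet:
    """Parsed alignment file: genome index from the header plus all records."""

    genome: GenomeIndex
    reads: list[AlignedRead]

    def primary_reads(self, min_mapq: int = 0) -> list[AlignedRead]:
        return [
            r
            for r in self.reads
            if r.is_primary and not r.is_duplicate and r.mapq >= min_mapq
        ]


def read_alignments(source: str, require_sorted: bool = True) -> AlignmentSet:
    """Read a SAM-dialect file into an :class:`AlignmentSet`.

    Secondary/supplementary/duplicate records are kept and flagged, not
    dropped.  Raises on a missing header or (when ``require_sorted``) on
    coordinate-unsorted input.
    """
    with pysam.AlignmentFile(source, "r", check_sq=False) as fh:
        if not fh.header.get("SQ"):
            raise ValueError(f"{source}: SAM header with SQ lines is required")
        genome = GenomeIndex([(sq["SN"], sq["LN"]) for sq in fh.header["SQ"]])
        order = {c: i for i, c in enumerate(genome.chroms)}
        reads: list[AlignedRead] = []
        last = (-1, -1)
        for rec in fh:
            read = aligned_read_from_pysam(rec)
            if not read.is_unmapped:
                key = (order[read.chrom], read.start)
                if require_sorted and key < last:
                    raise ValueError(
                        f"{source}: input not coordinate-sorted at "
                        f"{read.chrom}:{read.start}"
                    )
                last = max(last, key)
            reads.append(read)
    return AlignmentSet(genome=genome, reads=reads)


# ---------------------------------------------------------------------------
# Circle-call tables
# ---------------------------------------------------------------------------

CIRCLE_TABLE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "size_bp",
    "confidence",
    "n_split",
    "n_softclip",
    "n_discordant",
    "n_reads",
    "mean_coverage",
    "coverage_fraction",
    "flank_coverage_sum",
    "gene_names",
]

_CONF_ORDER = {"hconf": 0, "conf": 1, "lowq": 2}


def _call_row(call) -> dict:
    iv = call.interval
    cov = call.coverage
    return {
        "chrom": iv.chrom,
        "start": iv.start,
        "end": iv.end,
        "size_bp": iv.size,
        "confidence": call.confidence,
        "n_split": call.evidence.get("split", 0),
        "n_softclip": call.evidence.get("softclip", 0),
        "n_discordant": call.evidence.get("discordant", 0),
        "n_reads": call.n_distinct_reads,
        "mean_coverage": round(cov.mean_cov, 2) if cov else 0.0,
        "coverage_fraction": round(cov.fraction_covered, 4) if cov else 0.0,
        "flank_coverage_sum": round(cov.flank_sum, 2) if cov else 0.0,
        "gene_names": ",".join(call.genes) if call.genes else ".",
    }


def write_circle_table(
    calls: Sequence,
    table_path: str,
    bed_path: Optional[str] = None,
    header_lines: Iterable[str] = (),
) -> pd.DataFrame:
    """Write circle calls as a TSV table plus a companion BED file.

    Ordering is deterministic: (chrom, start, end, confidence).
    """
    rows = [_call_row(c) for c in calls]
    df = pd.DataFrame(rows, columns=CIRCLE_TABLE_COLUMNS)
    df = df.sort_values(
        ["chrom", "start", "end", "confidence"],
        key=lambda s: s.map(_CONF_ORDER) if s.name == "confidence" else s,
        kind="stable",
    ).reset_index(drop=True)
    with open(table_path, "w") as fh:
        for line in header_lines:
            fh.write(line.rstrip("\n") + "\n")
        df.to_csv(fh, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for _, row in df.iterrows():
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\t"
                    f"{row.confidence}\t{row.n_reads}\n"
                )
    return df


def read_circle_table(table_path: str) -> list:
    """Re-read a circle table written by :func:`write_circle_table`."""
    from .circle_calling import CircleCall, CoverageStats

    df = pd.read_csv(table_path, sep="\t", comment="#")
    calls = []
    for _, row in df.iterrows():
        iv = GenomicInterval(str(row.chrom), int(row.start), int(row.end))
        cov = CoverageStats(
            mean_cov=float(row.mean_coverage),
            fraction_covered=float(row.coverage_fraction),
            flank_up_mean=float(row.flank_coverage_sum) / 2.0,
            flank_down_mean=float(row.flank_coverage_sum) / 2.0,
        )
        genes = [] if row.gene_names in (".", "", None) else str(row.gene_names).split(",")
        calls.append(
            CircleCall(
                interval=iv,
                confidence=str(row.confidence),
                evidence={
                    "split": int(row.n_split),
                    "softclip": int(row.n_softclip),
                    "discordant": int(row.n_discordant),
                },
                n_distinct_reads=int(row.n_reads),
                coverage=cov,
                genes=genes,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# BED / interval tables
# ---------------------------------------------------------------------------


class IntervalList(list):
    """List of :class:`GenomicInterval` with a count of skipped records."""

    n_skipped: int = 0


def read_intervals(source: str, genome: Optional[GenomeIndex] = None) -> IntervalList:
    """Read a BED (or any >=3-column table) into intervals.

    Records on chromosomes absent from ``genome`` are skipped with a counted
    warning; malformed coordinates raise.
    """
    out = IntervalList()
    with open(source) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{source}:{lineno}: fewer than 3 columns")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            start, end = int(start_s), int(end_s)
            if start >= end or start < 0:
                raise ValueError(
                    f"{source}:{lineno}: invalid interval {chrom}:{start}-{end}"
                )
            if genome is not None and chrom not in genome:
                out.n_skipped += 1
                continue
            name = parts[3] if len(parts) > 3 else None
            iv = GenomicInterval(chrom, start, end, name)
            if genome is not None:
                iv.validate(genome)
            out.append(iv)
    if out.n_skipped:
        logger.warning(
            "%s: skipped %d interval(s) on chromosomes absent from the genome index",
            source,
            out.n_skipped,
        )
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")
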