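"""Structural-read evidence for circle junctions.

Three read classes point at an eccDNA junction:

* **discordant** reverse-forward (RF) mate pairs — a sequencing fragment that
  crossed the circle junction maps its leftmost mate in reverse and its
  rightmost mate in forward orientation, giving *approximate* coordinates;
* **soft-clipped** reads — a read crossing the junction is clipped at exactly
  one circle boundary, fixing that boundary at base-pair resolution;
* **split** reads — a soft-clipped read whose clipped fragment realigns on
  the same chromosome and strand, fixing *both* boundaries exactly.

Evidence items are clustered by compatibility of their implied circle
intervals (transitive closure); clusters are the input to circle calling.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from .alignment_io import AlignedRead
from .config import DetectionConfig

__all__ = [
    "JunctionEvidence",
    "JunctionCluster",
    "classify_pair_orientation",
    "extract_discordant",
    "extract_softclip",
    "realign_clipped_fragment",
    "cluster_evidence",
    "collect_evidence",
    "pair_primary_mates",
]

KINDS = ("discordant", "softclip", "split")


@dataclass
class JunctionEvidence:
    """One structural-read variant with its implied circle boundaries.

    ``start_hint``/``end_hint`` are candidate circle start/end coordinates;
    a ``None`` boundary is unconstrained (a soft clip fixes only one side).
    """

    kind: str
    chrom: str
    start_hint: Optional[int]
    end_hint: Optional[int]
    start_exact: bool
    end_exact: bool
    read_name: str
    side: str  # {left_clip, right_clip, pair}

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown evidence kind {self.kind!r}")
        if self.kind == "split" and not (
            self.start_exact and self.end_exact
            and self.start_hint is not None and self.end_hint is not None
        ):
            raise ValueError("split evidence must have both coordinates exact")
        if self.kind == "softclip" and (self.start_exact == self.end_exact):
            raise ValueError("softclip evidence must have exactly one exact side")
        if self.kind == "discordant" and (self.start_exact or self.end_exact):
            raise ValueError("discordant evidence has no exact coordinates")
        if (
            self.start_hint is not None
            and self.end_hint is not None
            and self.start_hint >= self.end_hint
        ):
            raise ValueError("start_hint must be < end_hint")


@dataclass
class JunctionCluster:
    """A group of mutually compatible evidence items for one candidate circle."""

    chrom: str
    consensus_start: Optional[int]
    consensus_end: Optional[int]
    members: list[JunctionEvidence]

    @property
    def n_distinct_reads(self) -> int:
        return len({m.read_name for m in self.members})

    @property
    def kind_counts(self) -> dict[str, int]:
        # one count per distinct read and kind, so a read never inflates a
        # kind by contributing two clips
        seen = {(m.read_name, m.kind) for m in self.members}
        counts = Counter(kind for _, kind in seen)
        return {k: counts.get(k, 0) for k in KINDS}

    @property
    def size(self) -> Optional[int]:
        if self.consensus_start is None or self.consensus_end is None:
            return None
        return self.consensus_end - self.consensus_start


# ---------------------------------------------------------------------------
# Pair orientation / discordant evidence
# ---------------------------------------------------------------------------


def classify_pair_orientation(a: AlignedRead, b: AlignedRead) -> str:
    """Classify a primary mate pair as FR (concordant), RF (circle-junction
    discordant) or other.

    With L the leftmost-starting mate and R the other: FR when L is ``+`` and
    R is ``-``; RF when L is ``-`` and R is ``+``.
    """
    if a.is_unmapped or b.is_unmapped:
        raise ValueError(f"pair {a.read_name}: unmapped mate is unusable")
    if a.chrom != b.chrom:
        return "other"
    left, right = (a, b) if a.start <= b.start else (b, a)
    if left.strand == "+" and right.strand == "-":
        return "FR"
    if left.strand == "-" and right.strand == "+":
        return "RF"
    return "other"


def extract_discordant(
    pairs: Iterable[tuple[AlignedRead, AlignedRead]],
    cfg: DetectionConfig,
) -> tuple[list[JunctionEvidence], dict[str, int]]:
    """One piece of junction evidence per RF pair.

    The implied circle spans from the leftmost mate start to the rightmost
    mate end, both inexact.  Pairs implying a span above
    ``cfg.max_circle_size`` are dropped and counted.
    """
    evidence: list[JunctionEvidence] = []
    counters = {"rf_pairs": 0, "dropped_span": 0}
    for a, b in pairs:
        if classify_pair_orientation(a, b) != "RF":
            continue
        counters["rf_pairs"] += 1
        start = min(a.start, b.start)
        end = max(a.end, b.end)
        if end - start > cfg.max_circle_size:
            counters["dropped_span"] += 1
            continue
        evidence.append(
            JunctionEvidence(
                kind="discordant",
                chrom=a.chrom,
                start_hint=start,
                end_hint=end,
                start_exact=False,
                end_exact=False,
                read_name=a.read_name,
                side="pair",
            )
        )
    return evidence, counters


def pair_primary_mates(reads: Sequence[AlignedRead]) -> list[tuple[AlignedRead, AlignedRead]]:
    """Group primary paired records by read name into mate pairs."""
    by_name: dict[str, list[AlignedRead]] = defaultdict(list)
    for r in reads:
        if r.is_paired and r.is_primary:
            by_name[r.read_name].append(r)
    pairs = []
    for name, recs in by_name.items():
        if len(recs) == 2 and recs[0].is_read1 != recs[1].is_read1:
            pairs.append((recs[0], recs[1]))
    return pairs


# ---------------------------------------------------------------------------
# Soft-clip evidence
# ---------------------------------------------------------------------------


def extract_softclip(read: AlignedRead, cfg: DetectionConfig) -> list[JunctionEvidence]:
    """0-2 junction evidence items from a read's terminal clips.

    A left clip of at least ``cfg.min_softclip_bases`` marks the read start
    as a candidate circle START; a right clip marks the read end as a
    candidate circle END.  Hard clips count toward the length but carry no
    sequence, so they can seed soft-clip evidence but never realignment.
    """
    out: list[JunctionEvidence] = []
    if read.left_clip_len >= cfg.min_softclip_bases:
        out.append(
            JunctionEvidence(
                kind="softclip",
                chrom=read.chrom,
                start_hint=read.start,
                end_hint=None,
                start_exact=True,
                end_exact=False,
                read_name=read.read_name,
                side="left_clip",
            )
        )
    if read.right_clip_len >= cfg.min_softclip_bases:
        out.append(
            JunctionEvidence(
                kind="softclip",
                chrom=read.chrom,
                start_hint=None,
                end_hint=read.end,
                start_exact=False,
                end_exact=True,
                read_name=read.read_name,
                side="right_clip",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Clipped-fragment realignment (soft clip -> split)
# ---------------------------------------------------------------------------


def _chrom_seq(reference, chrom: str) -> str:
    """Chromosome sequence from a dict or a pyfaidx.Fasta-like object."""
    seq = reference[chrom]
    if not isinstance(seq, str):
        seq = str(seq)  # pyfaidx FastaRecord
    return seq.upper()


def _best_ungapped_loci(
    fragment: str, window: str, window_offset: int, k: int, min_identity: float
) -> tuple[list[int], float]:
    """Exact k-mer seeding plus ungapped extension over ``window``.

    Returns (candidate fragment-start positions in chromosome coordinates
    achieving the best identity >= min_identity, best identity).
    """
    flen = len(fragment)
    if flen < k or len(window) < flen:
        return [], 0.0
    seeds = sorted({0, flen // 2, flen - k})
    starts: set[int] = set()
    for off in seeds:
        kmer = fragment[off : off + k]
        pos = window.find(kmer)
        while pos != -1:
            cand = pos - off
            if 0 <= cand <= len(window) - flen:
                starts.add(cand)
            pos = window.find(kmer, pos + 1)
    best: list[int] = []
    best_id = 0.0
    for cand in sorted(starts):
        target = window[cand : cand + flen]
        matches = sum(1 for x, y in zip(fragment, target) if x == y)
        ident = matches / flen
        if ident < min_identity:
            continue
        if ident > best_id + 1e-12:
            best, best_id = [cand + window_offset], ident
        elif abs(ident - best_id) <= 1e-12:
            best.append(cand + window_offset)
    return best, best_id


def realign_clipped_fragment(
    ev: JunctionEvidence,
    clipped_seq: str,
    reference,
    cfg: DetectionConfig,
    read: Optional[AlignedRead] = None,
) -> Optional[JunctionEvidence]:
    """Upgrade soft-clip evidence to split evidence by realigning the clipped
    fragment on the same chromosome and strand.

    For a left-clip anchor at circle start ``s`` the clipped fragment aligned
    at ``[e-flen, e)`` with ``e > s`` implies circle ``[s, e)``; symmetric for
    right-clip anchors.  Ambiguous placements (tied best identity at distinct
    loci) are rejected.  If the read carries a consistent supplementary-
    alignment locus it is used directly and realignment is skipped.
    """
    if ev.kind != "softclip":
        raise ValueError("realignment applies to softclip evidence only")
    flen = len(clipped_seq)
    if flen < cfg.min_softclip_bases:
        return None
    clipped_seq = clipped_seq.upper()

    # supplementary-alignment shortcut
    if read is not None and read.supplementary_locus is not None:
        sup_chrom, sup_start, sup_strand = read.supplementary_locus
        if sup_chrom == ev.chrom and sup_strand == read.strand:
            split = _split_from_locus(ev, sup_start, flen, cfg)
            if split is not None:
                return split

    if reference is None:
        return None
    chrom_seq = _chrom_seq(reference, ev.chrom)
    clen = len(chrom_seq)
    if ev.side == "left_clip":
        s = ev.start_hint
        lo = max(0, s - flen + 1)
        hi = min(clen, s + cfg.max_circle_size)
    else:
        e = ev.end_hint
        lo = max(0, e - cfg.max_circle_size)
        hi = min(clen, e + flen - 1)
    if hi - lo < flen:
        return None
    loci, _ = _best_ungapped_loci(
        clipped_seq, chrom_seq[lo:hi], lo, cfg.realign_kmer, cfg.realign_min_identity
    )
    loci = [p for p in loci if _split_from_locus(ev, p, flen, cfg) is not None]
    if len(loci) != 1:
        return None  # no acceptable locus, or ambiguous tie
    return _split_from_locus(ev, loci[0], flen, cfg)


def _split_from_locus(
    ev: JunctionEvidence, frag_start: int, flen: int, cfg: DetectionConfig
) -> Optional[JunctionEvidence]:
    """Split evidence from a clipped-fragment locus, or None if the implied
    circle is invalid."""
    if ev.side == "left_clip":
        s, e = ev.start_hint, frag_start + flen
    else:
        s, e = frag_start, ev.end_hint
    if s is None or e is None or not (0 < e - s <= cfg.max_circle_size):
        return None
    return JunctionEvidence(
        kind="split",
        chrom=ev.chrom,
        start_hint=s,
        end_hint=e,
        start_exact=True,
        end_exact=True,
        read_name=ev.read_name,
        side=ev.side,
    )


# ---------------------------------------------------------------------------
# Evidence clustering
# ---------------------------------------------------------------------------


def _compatible(a: JunctionEvidence, b: JunctionEvidence, cfg: DetectionConfig) -> bool:
    """Whether two evidence items can describe the same circle."""
    if a.chrom != b.chrom:
        return False
    shared = False
    for va, vb, xa, xb in (
        (a.start_hint, b.start_hint, a.start_exact, b.start_exact),
        (a.end_hint, b.end_hint, a.end_exact, b.end_exact),
    ):
        if va is None or vb is None:
            continue
        shared = True
        tol = cfg.exact_tolerance_bp if (xa and xb) else cfg.cluster_tolerance_bp
        if abs(va - vb) > tol:
            return False
    if shared:
        return True
    # opposite-side soft clips share no boundary: compatible when the implied
    # interval is a valid circle
    starts = [v for v in (a.start_hint, b.start_hint) if v is not None]
    ends = [v for v in (a.end_hint, b.end_hint) if v is not None]
    if not starts or not ends:
        return False
    return 0 < max(ends) - min(starts) <= cfg.max_circle_size


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _modal(values: list[int]) -> int:
    counts = Counter(values)
    top = max(counts.values())
    return min(v for v, c in counts.items() if c == top)


def cluster_evidence(
    evidence: Sequence[JunctionEvidence], cfg: DetectionConfig
) -> list[JunctionCluster]:
    """Group evidence by transitive closure of pairwise compatibility.

    Exact coordinates must agree within ``cfg.exact_tolerance_bp``; inexact
    hints within ``cfg.cluster_tolerance_bp``.  Consensus coordinates come
    from the modal exact coordinate when available, else the extremal hints.
    The partition is independent of input order.
    """
    by_chrom: dict[str, list[JunctionEvidence]] = defaultdict(list)
    for ev in evidence:
        by_chrom[ev.chrom].append(ev)
    clusters: list[JunctionCluster] = []
    for chrom in sorted(by_chrom):
        items = sorted(
            by_chrom[chrom],
            key=lambda e: (
                e.start_hint if e.start_hint is not None else e.end_hint,
                e.end_hint if e.end_hint is not None else e.start_hint,
                e.read_name,
                e.side,
            ),
        )
        uf = _UnionFind(len(items))
        window = cfg.max_circle_size + cfg.cluster_tolerance_bp
        keys = [
            e.start_hint if e.start_hint is not None else e.end_hint for e in items
        ]
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                if keys[j] - keys[i] > window:
                    break
                if _compatible(items[i], items[j], cfg):
                    uf.union(i, j)
        groups: dict[int, list[JunctionEvidence]] = defaultdict(list)
        for i, ev in enumerate(items):
            groups[uf.find(i)].append(ev)
        for members in groups.values():
            exact_starts = [m.start_hint for m in members if m.start_exact]
            exact_ends = [m.end_hint for m in members if m.end_exact]
            start_hints = [m.start_hint for m in members if m.start_hint is not None]
            end_hints = [m.end_hint for m in members if m.end_hint is not None]
            start = (
                _modal(exact_starts)
                if exact_starts
                else (min(start_hints) if start_hints else None)
            )
            end = (
                _modal(exact_ends)
                if exact_ends
                else (max(end_hints) if end_hints else None)
            )
            if start is not None and end is not None and start >= end:
                end = None  # degenerate consensus; cluster cannot be called
            clusters.append(
                JunctionCluster(
                    chrom=chrom,
                    consensus_start=start,
                    consensus_end=end,
                    members=members,
                )
            )
    clusters.sort(
        key=lambda c: (
            c.chrom,
            c.consensus_start if c.consensus_start is not None else -1,
            c.consensus_end if c.consensus_end is not None else -1,
        )
    )
    return clusters


# ---------------------------------------------------------------------------
# Orchestrator
# ---------------------------------------------------------------------------


def collect_evidence(
    reads: Sequence[AlignedRead],
    cfg: DetectionConfig,
    reference=None,
) -> tuple[list[JunctionEvidence], dict[str, int]]:
    """Extract all three evidence classes from a read set.

    Soft-clip evidence whose clipped sequence realigns acceptably is
    *replaced* by split evidence (the same read never counts twice).
    Returns the evidence list plus run counters.
    """
    usable = [
        r
        for r in reads
        if r.is_primary
        and (cfg.use_duplicates or not r.is_duplicate)
        and r.mapq >= cfg.min_mapq
    ]
    counters: dict[str, int] = {"reads_in": len(reads), "reads_usable": len(usable)}

    pairs = pair_primary_mates(usable)
    same_chrom_pairs = [(a, b) for a, b in pairs if a.chrom == b.chrom]
    disc, disc_counters = extract_discordant(same_chrom_pairs, cfg)
    counters.update(disc_counters)

    evidence: list[JunctionEvidence] = list(disc)
    n_soft = n_split = 0
    for read in usable:
        for ev in extract_softclip(read, cfg):
            clipped = (
                read.clipped_seq_left if ev.side == "left_clip" else read.clipped_seq_right
            )
            split = None
            if clipped is not None:
                split = realign_clipped_fragment(ev, clipped, reference, cfg, read=read)
            if split is not None:
                evidence.append(split)
                n_split += 1
            else:
                evidence.append(ev)
                n_soft += 1
    counters["softclip_evidence"] = n_soft
    counters["split_evidence"] = n_split
    counters["discordant_evidence"] = len(disc)
    counters["evidence_total"] = len(evidence)
    return evidence, counters


def write_evidence_table(evidence: Sequence[JunctionEvidence], path: str) -> None:
    """Debug dump: one row per evidence item."""
    with open(path, "w") as fh:
        fh.write("kind\tchrom\tstart_hint\tend_hint\tstart_exact\tend_exact\tread_name\tside\n")
        for e in evidence:
            fh.write(
                f"{e.kind}\t{e.chrom}\t"
                f"{'.' if e.start_hint is None else e.start_hint}\t"
                f"{'.' if e.end_hint is None else e.end_hint}\t"
                f"{int(e.start_exact)}\t{int(e.end_exact)}\t{e.read_name}\t{e.side}\n"
            )
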