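"""Evidence extraction, clipped-fragment realignment, and clustering."""

import itertools

import numpy as np
import pytest

from eccseq.alignment_io import AlignedRead
from eccseq.config import DetectionConfig
from eccseq.sv_evidence import (
    JunctionEvidence,
    classify_pair_orientation,
    cluster_evidence,
    collect_evidence,
    extract_discordant,
    extract_softclip,
    realign_clipped_fragment,
)
from eccseq.synthetic_data import simulate_genome


def _read(name="r", chrom="chr1", start=100, cigar=None, strand="+", **kw):
    cigar = cigar or [("M", 100)]
    ref_len = sum(n for op, n in cigar if op in "MDN=X")
    return AlignedRead(name, chrom, start, start + ref_len, strand, cigar, **kw)


def _clip_read(name, start, left=0, right=0, mlen=100, chrom="chr1", seqs=(None, None)):
    cigar = []
    if left:
        cigar.append(("S", left))
    cigar.append(("M", mlen))
    if right:
        cigar.append(("S", right))
    return AlignedRead(
        name, chrom, start, start + mlen, "+", cigar,
        left_clip_len=left, right_clip_len=right,
        clipped_seq_left=seqs[0], clipped_seq_right=seqs[1],
    )


class TestPairOrientation:
    def test_forward_reverse_is_concordant(self):
        a = _read("p", start=100, strand="+")
        b = _read("p", start=400, strand="-")
        assert classify_pair_orientation(a, b) == "FR"

    def test_reverse_forward_is_discordant(self):
        a = _read("p", start=100, strand="-")
        b = _read("p", start=400, strand="+")
        assert classify_pair_orientation(a, b) == "RF"
        assert classify_pair_orientation(b, a) == "RF"  # argument order irrelevant

    def test_same_strand_and_cross_chromosome_are_other(self):
        assert classify_pair_orientation(_read(strand="+"), _read(start=400, strand="+")) == "other"
        assert classify_pair_orientation(_read(), _read(chrom="chr2", strand="-")) == "other"

    def test_unmapped_mate_is_an_error(self):
        bad = AlignedRead("r", "*", 0, 0, "+", [], is_unmapped=True)
        with pytest.raises(ValueError):
            classify_pair_orientation(_read(), bad)


class TestExtractDiscordant:
    def test_rf_pair_spans_junction(self, cfg):
        a = _read("p", start=1000, cigar=[("M", 100)], strand="-")
        b = _read("p", start=4900, cigar=[("M", 100)], strand="+")
        ev, counters = extract_discordant([(a, b)], cfg)
        (e,) = ev
        assert (e.start_hint, e.end_hint, e.kind) == (1000, 5000, "discordant")
        assert not e.start_exact and not e.end_exact
        assert counters["rf_pairs"] == 1

    def test_fr_pair_yields_nothing(self, cfg):
        a = _read("p", start=1000, strand="+")
        b = _read("p", start=4900, strand="-")
        ev, _ = extract_discordant([(a, b)], cfg)
        assert ev == []

    def test_oversized_span_dropped_with_counter(self, cfg):
        a = _read("p", start=0, strand="-")
        b = _read("p", start=1_200_000, strand="+")
        ev, counters = extract_discordant([(a, b)], cfg)
        assert ev == [] and counters["dropped_span"] == 1


class TestExtractSoftclip:
    def test_left_clip_at_threshold_marks_circle_start(self, cfg):
        (e,) = extract_softclip(_clip_read("r", 200, left=50, mlen=50), cfg)
        assert (e.start_hint, e.start_exact, e.end_hint, e.side) == (200, True, None, "left_clip")

    def test_one_base_below_threshold_is_ignored(self, cfg):
        assert extract_softclip(_clip_read("r", 200, left=49, mlen=51), cfg) == []

    def test_both_clips_give_two_evidences(self, cfg):
        read = _clip_read("r", 200, left=60, right=60, mlen=40)
        kinds = [(e.side, e.start_exact, e.end_exact) for e in extract_softclip(read, cfg)]
        assert kinds == [("left_clip", True, False), ("right_clip", False, True)]

    def test_right_clip_marks_circle_end(self, cfg):
        (e,) = extract_softclip(_clip_read("r", 200, right=55, mlen=45), cfg)
        assert (e.end_hint, e.end_exact) == (245, True)

    def test_hard_clip_seeds_evidence_without_sequence(self, cfg):
        read = AlignedRead(
            "r", "chr1", 200, 250, "+", [("H", 60), ("M", 50)], left_clip_len=60
        )
        (e,) = extract_softclip(read, cfg)
        assert e.kind == "softclip" and read.clipped_seq_left is None


def _brute_force_best_loci(fragment, chrom_seq, min_identity):
    """Independent oracle: score every possible placement."""
    flen = len(fragment)
    best, best_id = [], 0.0
    for pos in range(len(chrom_seq) - flen + 1):
        target = chrom_seq[pos : pos + flen]
        ident = sum(a == b for a, b in zip(fragment, target)) / flen
        if ident < min_identity:
            continue
        if ident > best_id + 1e-12:
            best, best_id = [pos], ident
        elif abs(ident - best_id) <= 1e-12:
            best.append(pos)
    return best, best_id


@pytest.fixture(scope="module")
def realign_genome():
    genome, _ = simulate_genome([60_000], seed=21)
    return genome


class TestRealignment:
    def _left_clip_evidence(self, s=10_000):
        return JunctionEvidence("softclip", "chr1", s, None, True, False, "r", "left_clip")

    def test_planted_junction_recovered_and_matches_brute_force(self, realign_genome, cfg):
        """A left-clip fragment taken from [14940, 15000) implies circle
        [10000, 15000); brute-force full-scan alignment agrees."""
        frag = realign_genome["chr1"][14_940:15_000]
        ev = self._left_clip_evidence()
        split = realign_clipped_fragment(ev, frag, realign_genome, cfg)
        assert split is not None and split.kind == "split"
        assert (split.start_hint, split.end_hint) == (10_000, 15_000)
        assert split.start_exact and split.end_exact
        loci, _ = _brute_force_best_loci(frag, realign_genome["chr1"], cfg.realign_min_identity)
        assert loci == [14_940]

    def test_reverse_strand_match_rejected(self, realign_genome, cfg):
        comp = str.maketrans("ACGT", "TGCA")
        frag = realign_genome["chr1"][14_940:15_000].translate(comp)[::-1]  # revcomp
        assert realign_clipped_fragment(self._left_clip_evidence(), frag, realign_genome, cfg) is None

    def test_other_chromosome_match_rejected(self, cfg):
        genome, _ = simulate_genome([30_000, 30_000], seed=22)
        frag = genome["chr2"][5_000:5_060]
        ev = self._left_clip_evidence(s=1_000)
        assert realign_clipped_fragment(ev, frag, genome, cfg) is None

    def test_ambiguous_tied_loci_rejected(self, cfg):
        unit, _ = simulate_genome([60], seed=23)
        frag = unit["chr1"]
        genome, _ = simulate_genome([40_000], seed=24)
        seq = genome["chr1"]
        # plant the identical 60-mer twice downstream of the anchor
        seq = seq[:20_000] + frag + seq[20_060:30_000] + frag + seq[30_060:]
        ev = self._left_clip_evidence(s=15_000)
        assert realign_clipped_fragment(ev, frag, {"chr1": seq}, cfg) is None

    def test_short_fragment_not_realigned(self, realign_genome, cfg):
        frag = realign_genome["chr1"][14_960:15_000]  # 40 < min_softclip_bases
        assert realign_clipped_fragment(self._left_clip_evidence(), frag, realign_genome, cfg) is None

    def test_right_clip_anchor_symmetric(self, realign_genome, cfg):
        """Right-clip anchored at circle end 15000 with fragment from the
        circle start fixes [10000, 15000)."""
        frag = realign_genome["chr1"][10_000:10_060]
        ev = JunctionEvidence("softclip", "chr1", None, 15_000, False, True, "r", "right_clip")
        split = realign_clipped_fragment(ev, frag, realign_genome, cfg)
        assert split is not None and (split.start_hint, split.end_hint) == (10_000, 15_000)

    def test_supplementary_locus_shortcut(self, cfg):
        read = AlignedRead(
            "r", "chr1", 10_000, 10_050, "+", [("S", 60), ("M", 50)],
            left_clip_len=60, clipped_seq_left="A" * 60,
            supplementary_locus=("chr1", 14_940, "+"),
        )
        ev = self._left_clip_evidence()
        split = realign_clipped_fragment(ev, "A" * 60, None, cfg, read=read)
        assert split is not None and (split.start_hint, split.end_hint) == (10_000, 15_000)


def _split(s, e, name, chrom="chr1"):
    return JunctionEvidence("split", chrom, s, e, True, True, name, "left_clip")


def _disc(s, e, name, chrom="chr1"):
    return JunctionEvidence("discordant", chrom, s, e, False, False, name, "pair")


def _brute_force_partition(evidence, cfg):
    """Transitive closure over pairwise compatibility by repeated merging."""
    from eccseq.sv_evidence import _compatible

    groups = [{i} for i in range(len(evidence))]
    changed = True
    while changed:
        changed = False
        for i, j in itertools.combinations(range(len(groups)), 2):
            if any(
                _compatible(evidence[a], evidence[b], cfg)
                for a in groups[i]
                for b in groups[j]
            ):
                groups[i] |= groups[j]
                del groups[j]
                changed = True
                break
    return {frozenset(g) for g in groups}


class TestClustering:
    def test_split_plus_discordant_form_one_cluster(self, cfg):
        clusters = cluster_evidence([_split(1000, 5000, "a"), _disc(950, 5050, "b")], cfg)
        (c,) = clusters
        assert (c.consensus_start, c.consensus_end) == (1000, 5000)
        assert c.n_distinct_reads == 2
        assert c.kind_counts == {"discordant": 1, "softclip": 0, "split": 1}

    def test_exact_coordinates_within_5bp_merge(self, cfg):
        clusters = cluster_evidence([_split(1000, 5000, "a"), _split(1001, 5001, "b")], cfg)
        assert len(clusters) == 1

    def test_exact_coordinates_1kb_apart_stay_separate(self, cfg):
        clusters = cluster_evidence([_split(1000, 5000, "a"), _split(2000, 5000, "b")], cfg)
        assert len(clusters) == 2

    def test_partition_matches_transitive_closure_oracle(self, cfg):
        rng = np.random.default_rng(42)
        for trial in range(30):
            n = int(rng.integers(2, 21))
            evidence = []
            for i in range(n):
                s = int(rng.integers(0, 50_000))
                e = s + int(rng.integers(100, 20_000))
                kind = rng.choice(["split", "discordant"])
                if kind == "split":
                    evidence.append(_split(s, e, f"r{i}"))
                else:
                    evidence.append(_disc(s, e, f"r{i}"))
            clusters = cluster_evidence(evidence, cfg)
            got = {
                frozenset(evidence.index(m) for m in c.members) for c in clusters
            }
            assert got == _brute_force_partition(evidence, cfg), f"trial {trial}"

    def test_order_invariance(self, cfg):
        rng = np.random.default_rng(9)
        evidence = [
            _split(int(s), int(s) + 500, f"r{i}")
            for i, s in enumerate(rng.integers(0, 10_000, size=15))
        ]
        base = cluster_evidence(evidence, cfg)
        key = lambda cs: sorted(
            tuple(sorted(m.read_name for m in c.members)) for c in cs
        )
        for _ in range(5):
            rng.shuffle(evidence)
            assert key(cluster_evidence(evidence, cfg)) == key(base)

    def test_no_read_double_counted(self, cfg):
        """The same read contributing a split and the residual soft clip on
        the other side counts once in n_distinct_reads."""
        soft = JunctionEvidence("softclip", "chr1", None, 5000, False, True, "a", "right_clip")
        clusters = cluster_evidence([_split(1000, 5000, "a"), soft], cfg)
        (c,) = clusters
        assert c.n_distinct_reads == 1


class TestCollectEvidence:
    def test_simulated_sample_evidence_inventory(self, clean_sample):
        cfg = clean_sample["cfg"]
        evidence, counters = collect_evidence(
            clean_sample["alignments"].reads, cfg, clean_sample["genome"]
        )
        assert counters["evidence_total"] == len(evidence)
        # every engineered junction read realigns: splits >= 3 per circle
        assert counters["split_evidence"] >= 3 * len(clean_sample["truth"].circles)

    def test_mapq_floor_filters_reads(self, cfg):
        low = _clip_read("r", 200, left=60, mlen=40)
        low.mapq = 0
        evidence, _ = collect_evidence([low], cfg)
        assert evidence == []

    def test_evidence_debug_dump(self, cfg, tmp_path):
        from eccseq.sv_evidence import write_evidence_table

        evidence = [_split(1000, 5000, "a"), _disc(950, 5050, "b")]
        path = tmp_path / "ev.tsv"
        write_evidence_table(evidence, str(path))
        lines = path.read_text().splitlines()
        assert len(lines) == 3 and lines[1].startswith("split\tchr1\t1000\t5000")
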