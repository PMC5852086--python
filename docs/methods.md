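# Methods

## Detection model and assumptions

`eccseq` detects eccDNA from coordinate-sorted alignments of paired-end
Circle-Seq reads against a linear reference. The model assumes each circle
derives from a single contiguous chromosomal interval `[s, e)` joined at one
junction; inter-chromosomal junctions, inversion-type (strand-flipping)
junctions and multi-fragment circles are out of scope, so a complex circle
will at best be reported as its dominant single-interval component.

Evidence extraction consumes primary, non-duplicate alignments with mapping
quality ≥ 1 (both floors configurable). Secondary alignments are excluded
from evidence and coverage; supplementary alignments contribute only through
the supplementary-alignment locus attached to their primary record. This
avoids counting one sequenced molecule twice.

Three evidence classes are extracted:

1. **Discordant (RF) pairs.** For mates on one chromosome, the pair is
   classified by the strand of the leftmost-starting mate: `+/-` is
   concordant (FR), `-/+` is a junction-spanning pair (RF). An RF pair
   yields an approximate circle `[leftmost start, rightmost end)`; pairs
   implying > 1 Mb are dropped (counted).
2. **Soft clips.** A terminal clip of ≥ 50 bases marks one circle boundary
   exactly (left clip → start, right clip → end). Hard clips count toward
   the length threshold but carry no sequence, so they can seed boundary
   evidence but never realignment.
3. **Splits.** The clipped sequence of a soft-clipped read is realigned on
   the same chromosome and strand within ±1 Mb of the anchor: exact k-mer
   seeding (k = 15, seeds at the fragment's start, middle and end) plus
   ungapped extension, accepting the best locus with identity ≥ 0.95.
   Only loci implying a valid circle (0 < e − s ≤ 1 Mb) are considered;
   ties at the best identity are rejected as ambiguous (conservatism over
   recall). A consistent supplementary-alignment locus, when present, is
   used directly and realignment is skipped. Accepted realignments *replace*
   the soft-clip evidence, so a read contributes one evidence item per clip.

Searching only ±1 Mb on the anchor chromosome is equivalent to genome-wide
remapping for any accepted call, because only same-chromosome loci within
the size ceiling can produce one.

## Clustering

Evidence items are grouped by transitive closure of pairwise compatibility.
Two items are compatible when every boundary both of them constrain agrees —
within 5 bp if both coordinates are exact, else within 500 bp (about one
sequencing insert, 430 ± 30 nt). A start-only and an end-only soft clip
share no boundary; they are compatible when the interval they jointly imply
is a valid circle. On noisy data this weak link can chain unrelated clips up
to 1 Mb apart; with the ≥ 2-distinct-reads call threshold and the coverage
ranking this has not produced spurious calls in practice, but it is the one
place where the grouping rule is genuinely permissive. Consensus
coordinates take the modal exact coordinate when any exact evidence exists,
else the extremal hints (minimum start, maximum end). The partition is
independent of input order (verified by property test against a brute-force
transitive-closure oracle).

## Calling, ranking, merging

A cluster becomes a call when it has ≥ 2 distinct supporting read names, a
consensus for both boundaries, and a span ≤ 1 Mb. Coverage is computed from
the aligned (reference-consuming M/=/X) blocks of primary non-duplicate
reads. For a call of length L, the two flanks are the L bases immediately
up- and downstream; a flank truncated by a chromosome end uses its available
bases, and a fully unavailable flank contributes the other flank's mean
(doubling it), which keeps the fold test defined at chromosome edges (the
`flank_truncated` field records this).

Ranking: `lowq` if the covered fraction (positions with depth ≥ 1; no
deeper threshold) is ≤ 0.95; otherwise `conf`; upgraded to `hconf` when the
mean internal coverage exceeds 2 × the *sum* of the two flank means. The
"sum of coverage" reading is the default because it matches the rule's
verbatim phrasing; `flank_mode: mean` switches to the average of the two
flanks (effectively a 2× vs 4× local-background bar) for users who prefer
that reading. Both the fraction and fold comparisons are strict
inequalities, so a call at exactly 95 % coverage is `lowq` and exactly
2-fold is `conf`. Ranking is monotone: more flank coverage never upgrades,
more internal covered fraction never downgrades.

Calls with reciprocal overlap ≥ 0.50 are collapsed by transitive closure.
The merged record keeps the member with the most distinct evidence reads
(ties: larger covered fraction, then leftmost) rather than the union
interval — the exact junction coordinates of the best-supported call are
the circle's identity, and a union would manufacture coordinates no read
supports. Constituents are retained in `merged_members`. Merging is
idempotent and order-independent. Below 0.50 nothing merges: overlapping
circles of clearly different sizes may be independent circularization
events from the same locus.

Gene annotation uses any positive overlap (not reciprocal), with names
sorted and deduplicated.

## Recurrence and variant-database intersection

Cross-sample recurrence groups calls from distinct samples at reciprocal
overlap ≥ 0.90, single-linkage first and then pairwise-verified: pure
single-linkage can chain intervals that never meet the threshold pairwise,
so failing groups are split greedily until every reported group satisfies
the pairwise bound exactly (re-checkable post hoc). Intersection with an
external variant database takes calls > 25 kb at reciprocal overlap ≥ 0.99
over full intervals (the breakpoint-pair interval is the circle's identity,
and full-interval reciprocal overlap is what the standard interval tools
implement; verified against `bedtools intersect -f 0.99 -r` in the tests).

The probability of cross-sample agreement by chance is estimated by a
seeded Monte Carlo null: per replicate, each sample receives its call count
of length-preserving intervals placed uniformly (chromosome chosen
proportional to length, intervals wholly inside), and a replicate is a hit
when any cross-sample pair reaches reciprocal overlap ≥ 0.95. The add-one
estimator (hits + 1)/(n + 1) bounds the probability in [1/(n+1), 1]. A
closed-form companion, 2L/G per pair, upper-bounds the per-replicate hit
probability for sanity checks. No attempt is made to reproduce any
analytically derived bound; the Monte Carlo machinery is the product.

## Transcription across junctions

RNA split reads in back-splice geometry (query-first half downstream,
second half upstream) evidence transcription across a circle junction. A
read supports a circle when its implied interval (right-half start to
left-half end) is contained in the circle and its start deviates ≤ 20 nt
from the circle start; the start-deviation rule is what excludes
trans-splicing products, which is why "100 % overlap" is read as
containment rather than both-end equality (both-end equality would make the
20-nt rule redundant). Only circles with at least one exact junction
coordinate (soft-clip or split evidence) are eligible; mitochondrial
alignments are excluded. Ranks: `hconf` — some read matches both
coordinates perfectly and its sequence is unique in the genome; `conf` —
perfect match but multi-mapping; `lowq` — one coordinate only.
Junction-sequence uniqueness (`n_genomic_loci`) is computed by realigning
each read half over every chromosome with the same seeded realigner and
taking the larger acceptable-locus count — the junction sequence itself is
not genomically contiguous, so half-wise counting is the operative notion
of multi-mapping here; the ranking only distinguishes unique from not.

Overlap significance: both interval sets (circles, transcript implied
intervals) are re-placed uniformly on the genome 1,000 times (lengths
preserved, chromosomes weighted by length); the empirical p-value is the
add-one fraction of replicates whose overlapping-pair count reaches the
observed count.

## Quantification

`copies_per_nucleus` anchors a target species' read fraction on a spike-in
plasmid of known copy number:

    copies = (f_target / f_spike) × (spike copies / nuclei)
             × (spike length / target length)

The length term converts a read (mass) ratio into a molecule ratio —
rolling-circle amplified reads scale with template mass, not copy number —
and can be disabled (`length_correction: false`) for the equal-length
case. The shipped spike inventory is the five-plasmid control mixture
(pSH63 6,998 bp × 100; pUC19_yEGFP3 3,397 bp × 100; YGPM3k20 26,305 bp ×
10,000; pBR322 4,361 bp × 20,000; pUG72 3,988 bp × 50,000). These estimates
are rough by construction: rolling-circle amplification is biased toward
small, abundant templates, and no attempt is made to model its kinetics.

The qPCR helper converts DNA mass to diploid genome count using
6.77 × 10⁻³ ng per diploid cell as the adopted default. Recomputing the
constant from first principles (2 × 3.14 × 10⁹ bp × 650 g·mol⁻¹ / N_A)
gives 6.78 × 10⁻³ ng; both are exposed and the difference (~0.15 %) is
immaterial at qPCR precision.

Saturation analysis decimates reads at 10 % intervals. Read groups (mates
stay together) are ranked by a seeded hash of the read name and each
fraction f takes the first round(f × n) groups — so subsamples are nested
(the 10 % set ⊂ 20 % set ⊂ …), pair integrity is preserved, counts are
exact, and the curve is smooth and reproducible. Fraction 1.0 is the full
read set by construction.

## The simulator

The generator emits post-alignment SAM records directly — the package's
scope begins at aligned reads, so no external aligner is needed (an
optional FASTQ emitter exists for users who want to run one). For each
planted circle it produces: (a) engineered junction-crossing reads
(≥ `junction_read_min`, default 3) whose shorter portion is soft-clipped
with the clipped sequence attached and a supplementary locus recorded;
(b) circular fragments to `internal_depth × copy_number` coverage — paired
2 × 100 nt with 430 ± 30 nt inserts when the circle can hold an insert,
single merged-style reads otherwise — which naturally yield concordant
internal pairs, RF discordant pairs for circles > ~2 read lengths, and
additional clipped reads where a fragment crosses the junction; (c) linear
background pairs at `background_depth`; (d) optional chimeric
random-ligation pairs, the realistic false-positive mode for circle
callers. Every read name carries a source tag (`jx:`, `cov:`, `bg:`,
`chi:`), and per-circle emission counts are recorded in the truth table.

Circle sizes follow a two-component log-normal mixture with modes at 0.1 kb
and 5 kb (σ = 0.15 / 0.25 in log10, equal weights), matching the
characteristic bimodal size distribution of somatic eccDNA; the optional
copy-number model draws copies ∝ (scale/size)^α with log-normal scatter
(α = 1 by default) as a phenomenological stand-in for rolling-circle
amplification bias. The generator's minimum circle size defaults to 100 bp:
with 100 nt reads, a junction-crossing read can carry both a ≥ 50-base clip
and a mappable anchor only when the circle is at least twice the clip
threshold, so smaller circles would be undetectable by construction rather
than by inference.

What the simulator does **not** model: sequencing errors beyond an optional
uniform substitution knob (off by default), base qualities, real repeat
families and mappability structure, chimera modes other than two-locus
ligation, inter-chromosomal or strand-flipping junctions, and aligner
idiosyncrasies (every junction read is clipped exactly at the junction).
Passing recovery tests therefore demonstrates that the detector inverts the
documented evidence geometry exactly and applies its thresholds correctly;
they do not measure sensitivity on real libraries, where mappability,
amplification bias and alignment noise dominate.

## Numerical choices and degenerate inputs

* Exact-coordinate cluster tolerance 5 bp; hint tolerance 500 bp (≈ insert
  size). Modal-coordinate ties break toward the smallest coordinate.
* Realignment: k = 15 seeds, identity ≥ 0.95, ungapped; ambiguity → reject.
* Coverage values are reported to 2 decimals; tables are ordered by
  (chrom, start, end, confidence) for byte-identical reruns.
* Empty alignment files yield an empty table and a clean exit; a cluster
  without both consensus boundaries is dropped and counted
  (`dropped_no_span`); malformed interval records raise with the line
  number, while records on unknown chromosomes are skipped and counted.
* All randomness flows through one seed; identical config + seed gives
  byte-identical FASTA/SAM/tables.
* Single-end and paired records are treated uniformly (merged
  "singleton-contig" reads simply have no mate).

## Problem sizes used by the test suite and acceptance script

The shipped checks run on 0.8–2.5 Mb genomes with 15–50 planted circles at
20–40× internal depth (~30 k alignment records clean, ~530 k with matched
background), 1,000-replicate Monte Carlo nulls, and 1,000-instance fuzz
comparisons against brute-force oracles. These sizes exercise every code
path — including the quadratic clustering and merging closures — while a
full run of suite plus acceptance script completes in about a minute on one
core.

## Known limitations

* Single-interval, single-junction circles only; no genotype or per-circle
  copy-number inference, no assignment to cell subpopulations.
* The permissive link between opposite-side soft clips (see Clustering) can
  over-merge on dense noisy data.
* Clustering, merging and recurrence grouping are quadratic within a
  chromosome window; adequate at desk scale, not tuned for hundreds of
  thousands of evidence items.
* Uniqueness ranking of junction transcripts is half-wise, not a full
  aligner mapping-quality model.
* The spike-in estimator inherits the amplification bias of the protocol;
  its outputs are order-of-magnitude estimates.
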