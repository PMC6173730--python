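# Methods

This note documents the models and procedures implemented in `synscaf`, the
parameters that matter, the numerical choices at the edges, and what the
simulator does and does not emulate.

## Coordinate conventions

All in-memory coordinates are 0-based half-open. GFF3, AGP and 12-column
tabular alignments are converted at the parse/write boundary; a
minus-strand tabular hit (subject start > end) is normalized to
start < end with the orientation kept as a strand flag, preserving the
(min, max) of the original subject interval.

## Anchor maps

An anchor point is a correspondence (contig, contig bp) ↔ (linkage group,
map position). The synteny map uses reference-genome bp (gene-model start
coordinates) as map positions; the genetic map uses cM. The two are never
compared directly — every consumer rank-normalizes per map.

*Best-hit selection.* One hit per gene model (first mRNA per gene in
annotation file order — annotation builds list the representative isoform
first): maximal bitscore, ties broken by longer alignment, then
lexicographically smaller subject id. Bitscore is the ranking column
because it is the only score in the tabular format that is comparable
across hits of different lengths.

*Spurious-run filter* (defaults `min_hits_for_filter = 3`,
`spurious_run_length = 1`). Hits on a contig are ordered by contig
coordinate; maximal runs of identical reference chromosome are computed
once; on contigs with ≥ 3 hits every hit in a run of length ≤ 1 is
removed. The filter is single-pass by design: removals do not merge the
flanking runs into new candidates, because cascading removals have no
natural stopping point and can hollow out genuinely mixed contigs.

*Anchor construction.* Contigs with k ≥ 2 surviving hits contribute k
anchors at the gene starts (contig position = the alignment endpoint on the
gene-start side, strand-aware). A single-hit contig contributes two
anchors — gene start and gene stop at the matching alignment endpoints — so
one gene is enough to orient it.

*Marker anchors* (defaults `min_identity = 95 %`, flank 200 bp, SNP offset
100). A marker is placed only when it has a unique best placement; a
runner-up within 10 bitscore units disqualifies it, guarding against
near-identical repeats. The SNP offset is projected through the alignment
(strand-aware); offsets falling outside the aligned flank interval drop the
marker with a warning rather than erroring, since partial flank alignments
are routine near contig ends.

## Chimera detection and splitting (`chunk = 4`)

Anchors from both maps are pooled per contig and ordered by position. Runs
of fewer than `chunk` anchors are transparent — skipped, not merged — so a
stray anchor cannot mask or fabricate a conflict. Every adjacent pair of
surviving runs with different linkage groups yields one breakpoint at the
floored midpoint between the last anchor of the left run and the first of
the right run. Only inter-group conflicts split contigs; large positional
jumps within one group do not, because translocation-scale rearrangements
within a chromosome are indistinguishable from map noise at this
resolution. Parts are named `<id>_part1..` in coordinate order; bases are
partitioned exactly and anchors shift by their part offset.

## Ordering and orientation

Within a linkage group each map's positions are converted to average ranks
rescaled to [0, 1] (a lone anchor maps to 0.5). A contig's position score
is the weighted mean of its anchors' normalized ranks, with weight =
map weight × anchor weight (default map weights genetic = synteny = 1).
Contigs sort ascending by score; ties go to the longer contig, then the
smaller id.

The score order is then refined deterministically: for each adjacent pair
the pairwise vote Σ w_a·w_b·sign(pos_b − pos_a) over same-map anchor pairs
is computed, and the pair is swapped when the vote is strictly negative;
passes repeat until stable (bounded by the number of contigs). The
refinement exists because mean ranks mix two quantile scales: a sparse
map's empirical quantiles can locally disagree with a dense map's, which
shifts a contig's mean enough to invert true neighbours even with perfect
anchors. The pairwise vote has no such artifact — whenever every anchor of
one contig precedes every anchor of the other in both maps, the vote is
unanimous — so on consistent data the refined order is exact, and ties are
left untouched.

Orientation is the sign of the weighted Pearson correlation between the
within-contig ranks of anchor contig positions and map positions, computed
per map and combined by total map weight (ranks of different maps are not
comparable, so a single pooled correlation would be meaningless). Zero
correlation or a single anchor defaults to "+".

Pseudomolecules are emitted with 100 N between placed contigs (the common
AGP scaffold-gap placeholder; configurable) and the unplaced pool as one
sequence with 1 kb separators. AGP 2.1 gap rows carry gap_type "scaffold",
linkage "yes", evidence "map". N50 is the largest L such that pieces
≥ L cover half the total; the placement rate is reported to two decimals.

## Haplotype variation

Small variants (both alleles ≤ 10 bp) and large between-alignment variants
(> 10 bp gap magnitude) are disjoint regimes by construction. Densities are
computed per 1-Mb bin and feature class as variants per kb of (merged)
feature bp in the bin; bins with zero feature bp are excluded from the
per-class median. The 1-kb-upstream class is derived strand-aware from loci
and clipped at chromosome edges.

Large variants come from the signed gaps R (reference) and Q (query)
between consecutive alignment blocks of the same (query, reference, strand)
pair in query order; for minus-strand pairs the reference gap is taken on
the strand-oriented axis. size = |Q − R|; Q > R is extra query sequence and
Q < R extra reference sequence; negative gaps are overlaps, giving the six
classes (insertion/deletion when both gaps are non-negative,
repeat expansion/contraction when exactly one side overlaps,
tandem expansion/contraction when both do). The > 10 bp retention filter is
applied to absolute gap values — the gap-size fields of the upstream
caller's output record magnitudes — and a configurable 10-kb size cap
excludes gaps between distant blocks that are breaks, not variants.
Swapping the two haplotypes' roles exactly swaps
insertion↔deletion and expansion↔contraction; this involution is enforced
by test.

## Synteny chains and Ks

Matches (deduplicated cross-genome gene pairs) are chained in rank space:
a chain is strictly increasing in both gene-rank axes with per-axis gaps
≤ D (default 20), scored as Σ match scores − λ·Σ(gap − 1) with λ = 1 per
skipped rank; match score is min(50, −log10 evalue). Chains shorter than
A = 5 pairs are discarded. The DP carries a length dimension capped at A,
so the best chain *subject to the length floor* is found exactly; chains
are extracted greedily by descending score, each match used at most once,
forward preferred over inverted on ties, and inverted chains are found by
negating one axis. The exactness claim is tested against exhaustive
enumeration on random instances.

Ks uses Nei–Gojobori (1986): per-codon synonymous site counts (per
position, the fraction of the three single-base changes that preserve the
amino acid; changes to stop codons count as nonsynonymous), pathway-averaged
synonymous differences for multi-substitution codons (all substitution
orderings averaged; steps through stop codons are traversed but count as
nonsynonymous), pS = Sd/S, and the Jukes–Cantor correction
Ks = −¾·ln(1 − 4pS/3). Pairs with mismatched lengths, lengths not divisible
by three, or internal stops are skipped with a reason; pS ≥ ¾ is flagged
saturated rather than extrapolated. Sequences are consumed pre-aligned and
equal-length; codon-aware alignment and ML substitution models are out of
scope — NG86 is a rank-preserving proxy adequate for separating recent
orthologs from ancient duplicates.

## Window enrichment

Chromosomes are tiled into ⌈L/size⌉ windows (default 0.5 Mb, last window
truncated). A gene belongs to the window containing its start. Every
(window, category) pair with k ≥ 1 members is tested with the one-sided
(enrichment) hypergeometric tail — the paper-style question is
over-representation; a two-sided switch exists — and Holm adjustment spans
all tested pairs as a single family.

## Simulator

Defaults: 4 chromosomes × 200 genes (1 kb genes, 2 kb intergenic,
~0.6 Mb chromosomes), 80 contigs cut at random intergenic midpoints, 30 %
inversion rate, 3 chimeric joins, 60 markers (cM = bp × 4 cM/Mb, the usual
plant recombination scale), 10 % missing anchors, 2 % spurious hits.
Spurious hits are injected with a *higher* bitscore than the true hit so
they win best-hit selection and must be caught by the run-length filter —
the harder, more realistic failure mode. Chimera partners each carry at
least `chunk` genes so injected mis-joins are detectable in principle;
joins below that support are invisible to any run-based detector.
All randomness flows from one integer seed through fixed per-stage
substreams; every artifact is byte-reproducible.

What the simulator does **not** emulate: repeats and paralogy (spurious
hits are uniform, not repeat-clustered), assembly base errors (the toolkit
never re-aligns, so composition is irrelevant and sequences are uniform
ACGT), marker genotyping error, rearrangements between target and
reference other than whole-contig inversions, and gene-order differences.
Passing recovery tests therefore demonstrates the correctness of the
anchoring/ordering machinery under controlled noise, not robustness to
biological divergence between real genomes.

Recovery scoring: per-chromosome Kendall tau of placed units against true
order, orientation accuracy over placed units, breakpoint precision/recall
with a ± one-intergenic (2 kb) tolerance, adjacent-true-pair order
accuracy, and placement rate. Degenerate conventions: fewer than two
placed units give tau 1.0; no true and no called breakpoints give
precision = recall = 1.0.

## Problem sizes used by the acceptance script

The published-statistics identities are O(1) arithmetic on the printed
inputs. Recovery runs use the default simulation (80 contigs, 800 genes,
~2.4 Mb genome) — small enough to complete in seconds while exercising
every pipeline stage — once noise-free and once with a 5 % spurious-hit
rate. Oracle suites in the test suite use 1,000 random N50 instances,
exhaustive hypergeometric tables to N = 25 plus 2,000 random tables to
N = 200, 120 random chain instances of ≤ 12 matches against exhaustive
search, and 60 random codon-sequence pairs against a brute-force NG86
oracle.

## Known limitations

* Ordering quality degrades gracefully with anchor noise but the pairwise
  refinement is local (adjacent swaps only); a contig teleported far from
  its true position by systematically wrong anchors will not be rescued.
* Chimeras joining segments of the same chromosome are not detected
  (conflict criterion is linkage-group disagreement only).
* Within-alignment (base-level) indels are out of scope for the large
  variant classifier; the consumed block format has no base-level detail.
* Gap sizes in emitted pseudomolecules are fixed placeholders, not
  estimates.
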