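# Methods

## Detection model

The caller targets the MMB-TI signature: a short insertion that is a
near-exact (usually inverted) copy of a template within ~100 bp, flanked by
microhomology. Because the insertion is short relative to the read length,
a read crossing the junction fails whole-read alignment under a strict
edit-distance budget but one of its halves still aligns cleanly; the other
half carries the insertion. The pipeline is therefore built entirely around
half-read anchoring rather than soft-clip parsing: it consumes raw FASTQ
and needs no prior alignment (a pre-extracted unmapped-read FASTQ is also
accepted).

Assumptions worth stating explicitly:

* the reference is locally correct around each event (the template search
  is intra-chromosomal and windowed, not genome-wide);
* events are separated by more than a read length, so each accepted cluster
  describes one junction;
* insertions are long enough (`min_len`, default 10 bp; 6 bp in the
  sensitivity regime) to make a half-read fail alignment when it straddles
  the junction.

## Alignment layer

Whole reads and half-reads are aligned with an exact-seed,
verify-by-edit-distance scheme: 20-mers sampled across the query at a 5-base
stride are looked up in a full-position index of the reference, and each
candidate placement is verified with banded edit distance (edlib), counting
mismatches and 1-bp indels as unit-cost edits, on both strands. A read is
*unmapped* when no placement has ≤ 4 edits.

Completeness: a placement of a read of length ≥ 125 with ≤ 4 edits contains
an exact run of at least ⌈121/5⌉ = 25 consecutive matching bases, and any
exact run of ≥ 24 bases contains a stride-5 20-mer, so the seed stage cannot
miss a qualifying whole-read placement. For 62-bp halves the same argument
holds up to 1 edit; halves carrying 2–4 errors can in principle be missed.
At the simulated error rate (0.1% substitutions) this affects a negligible
fraction of anchor reads and is invisible at the cluster level (clusters
need only 3 reads of ~30 available). An `exhaustive` mode that scans the
full reference with edlib instead of seeding exists and doubles as the
reference behaviour in the test-suite oracle; it is exact but ~1000× slower
and not used in production runs.

Ambiguity: when two placements (different positions or strands) tie at the
best edit distance the read is marked non-unique, and non-unique halves are
not allowed to anchor — an ambiguous anchor is worse than a lost read
because it can seed a spurious cluster.

## Clustering and consensus

Anchors are clustered by single linkage with a linkage distance of one read
length: two reads covering the same junction must anchor within a read
length of each other, and planted/real events are far sparser than that.
Accepted anchoring patterns are all-left, all-right and left-then-right;
right-then-left would imply inconsistent junction geometry and is rejected.

Consensus is built by stacking whole reads at offsets fully determined by
their anchor coordinates — no realignment or MSA — and taking the
per-column majority with lexicographic tie-breaking (ties are flagged).
This is exact for substitution-only errors; anchor-coordinate stacking
would blur around indel sequencing errors, which the read simulator does
not model and real Illumina data exhibits an order of magnitude less often
than substitutions. The L and R consensuses of a left-then-right cluster
are merged at their best local alignment (match +1, mismatch −2, gap −3)
when they overlap by ≥ 10 columns at ≥ 90% identity — i.e. tolerating about
one consensus error per 10 bp of overlap; otherwise the pair is reported
unmerged as a breakpoint pair.

## Breakpoint extraction and canonical placement

The merged consensus carries both a left reference start (from the L
anchors) and a right reference end (from the R anchors). Walking the
maximal matching prefix and suffix against the reference pins the
breakpoints; the walk steps through an isolated substitution only when
followed by ≥ 8 further matches, which tolerates rare consensus errors at
support-1 edge columns without ever walking across a junction. One-edge
contigs recover their free boundary by exact substring search of the
longest consensus suffix/prefix in the local window (≥ 12 bp required);
otherwise the call is reported one-sided.

An insertion inside junction microhomology admits several equivalent
placements (the insertion can be rotated into either flank). The truth
generator deliberately slides each planted site forward a few bases until
both junctions are rotation-free, so every planted event has a unique
placement and the benchmark can demand exact sequence recovery rather than
recovery up to rotation. Real data has no such guarantee; there the 10-bp
matching tolerance of the evaluator absorbs placement ambiguity.

## Template search and classification

The reverse complement of the insertion is aligned locally (same scoring as
the merge) against the reference between `left_bp − 100 − L` and
`right_bp + 100 + L`; the best hit with identity ≥ `min_identity`
(matches ÷ alignment columns, gaps counting against identity) and ≥
`min_len` insertion bases aligned is the inverted template. A
direct-orientation scan is kept for classification. Among co-optimal
alignments ties break by higher identity, then smaller |offset| from the
insertion, then leftmost position.

Classes are assigned by explicit rules operationalizing the event taxonomy:
IPI when the replaced span coincides with the inverted template interval;
DD when a direct-orientation template strictly beats the best inverted one;
DQP for net deletions whose flanks align as a quasi-palindrome (30-bp
flanks, ≥ 80% reverse-complement identity); CLSC when one inverted template
explains ≥ 90% of the insertion and the replaced span is shorter than the
template; CM when a single template explains < 90% but greedy left-to-right
multi-template segmentation (longest anchored local match per step, ≥ 10 bp
segments, either orientation) explains ≥ 90%; otherwise unresolved. Note
that replace-mode benchmark events sit exactly on the CLSC boundary
(replaced span equals template length) and are reported as
unresolved-with-template; recall scoring is position-based and unaffected.

## Junction microhomology

Microhomology is the longest common suffix of the donor's 3′ flank and the
sequence upstream of the annealing site on the acceptor, in copied
orientation (for an inverted template ending at `t1`, the acceptor context
is `revcomp(ref[t1:t1+k])`). Microhomeology allows exactly one interruption
— an aligned mismatch or a 1-bp gap on either strand — anywhere in the
walk, including at the 3′-most base; the maximum over interruption type and
placement is reported, and only if ≥ 1 base is gained. Reported values are
capped at 30 bp (configurable). Each resolved single-template call yields
two junctions (template entry and return to the reference).

## Synthetic data

The generator emulates the published sensitivity construction: a seeded
random reference (default GC 0.41, matching the human genome), insertions
of 20–50 bp (uniform per site — the original reports only "various sizes")
planted at regular intervals with ≥ 500 bp margins and ≥ 1 kb spacing, each
the reverse complement of the 80-bp-upstream template, in append and
replace modes; Illumina-like 125 bp paired-end reads with Gaussian insert
(500 ± 20) at 30× and i.i.d. substitution errors (default 0.1%, roughly an
Illumina platform average). Not modelled: indel sequencing errors, quality
profiles, coverage bias, PCR duplicates, repeats/microsatellites and N
runs beyond exclusion. Passing benchmarks therefore demonstrate the
correctness of the detection geometry and scoring, not robustness to
repeat-rich regions — on real genomes the DUST pre-filter stands in for the
manual microsatellite curation such analyses otherwise require, and
repeat-mediated ambiguous anchors are dropped by the uniqueness rule.

## Benchmark scale and defaults

The shipped benchmark runs on a 2 Mb reference with 50 planted events per
mode — large enough that the reference index, anchoring statistics and
cluster geometry behave as at genome scale, while a full append+replace run
completes in a few minutes on one CPU. Search defaults follow the
cancer-analysis regime (min_len 10 bp, identity 0.80, cluster ≥ 3, window
100 bp, sub-clonal < 30% of average coverage); the benchmark overrides
min_len to 6 to probe the caller's lower length limit. Determinism: every
random choice flows from explicit seeds; the search itself contains no
randomness, so fixed inputs give byte-identical outputs.

## Known limitations

* Genome-wide (trans-chromosomal) template search is out of scope; distant
  template switches surface as unresolved breakpoints.
* Identity conventions, merge-gate thresholds (10 bp / 90%), the 90%
  class-coverage rule and the quasi-palindrome test are this package's
  operationalizations of event classes otherwise assigned by expert
  curation.
* Half-read anchoring needs ~½ read length of clean flank on one side;
  events within that distance of a contig end are not callable.
* BAM/CRAM parsing is deliberately not implemented; export unmapped reads
  to FASTQ upstream instead.
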