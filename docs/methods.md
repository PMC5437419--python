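# Methods

This note documents the models, parameter choices and numerical conventions
behind `hor5s`, and what the synthetic benchmarks do and do not demonstrate
about real data.

## The repeat model

A 5S rDNA unit is modelled as a 120-nt genic region followed by an
intergenic spacer (IGS). The genic region carries the tripartite internal
RNA-polymerase-III promoter; box coordinates are configuration, not
inference, defaulting to the canonical layout Box-A [50, 64), IE [67, 72),
Box-C [80, 97) in 0-based genic coordinates. All coordinates in the package
are 0-based half-open on the forward strand of the stored sequence.

Spacers belong to three length classes — short [95, 116] bp, long
[321, 340] bp, ultralong [1153, 1209] bp (closed intervals; anything else is
`other`) — and carry a tetranucleotide MNP at a fixed spacer offset whose
two prominent states are TCCT ("T") and AGGA ("A"). The bundled reference
sequences are **synthetic**: frozen literals designed so that (i) each
monomer contains exactly one CCGG site and tandem junctions create none,
(ii) the MNP core sits at unit position 152–155 (spacer offset 32), and
(iii) each 10-nt motif query (core ± 3 nt) occurs in a unit exactly once at
≥ 9/10 identity on either strand. Real clone sequences live in public
archives and are deliberately not embedded; any user reference can be
supplied as FASTA + JSON config.

## Synthetic data generator

The generator is the package's stand-in for sequencing archives; its
defaults are the study conditions.

* **Long reads**: 10–30 kb, drawn from four architectural groups at the
  published read proportions (95:72:11:108). Group I is a single tandem
  block; II, two blocks separated by a 2–4-kb uniform-random linker; III, a
  forward and a reverse block, directly linked half the time, otherwise
  separated by 0.2–1.8 kb; IV, isolated copies or < 5-unit tandems embedded
  in 1.5–5-kb unique stretches. Blocks are homogeneous in template, with
  spacer classes drawn at 94 % / 5 % / 1 % (S/L/UL) and variants at
  83 % / 17 % (T/A) — the published unit-level shares. Deterministic group
  counts use largest-remainder apportionment; otherwise a seeded
  multinomial.
* **Error model**: per-base i.i.d. substitution/insertion/deletion noise.
  The published figure is only the ~13 % single-pass total; the split is the
  package's choice of 1 % / 8 % / 4 % (indel-dominated, long-read-like) and
  is configurable. `corrupt` emits an edit log whose replay reconstructs the
  noisy read byte-for-byte, and truth-table unit intervals are remapped
  through that log, so ground-truth coordinates are exact even on noisy
  reads. FASTQ qualities are constant per read (nominal Q11 for long reads);
  per-base quality structure is out of scope.
* **Short reads**: sampled uniformly (both strands) from background + a
  planted tandem compartment; the planted genome proportion is exact by
  construction and each read id carries its majority-overlap origin label.
  Background DNA is i.i.d. uniform A/C/G/T — it cannot reach the mapper's
  similarity floor except with negligible probability, but it also lacks the
  low-complexity and repetitive structure of real genomes, so mapping
  specificity against real backgrounds is *not* demonstrated by these tests.
* **Digestion**: cuts C^CGG at every CCGG; the methylation-sensitive enzyme
  skips sites whose internal CG is marked methylated in a mask indexed by CG
  positions. Fragment lengths always sum to the input length.

## Short-read mapping and the copy chain

The published analysis used a desktop mapper with mismatch/insertion/deletion
costs 2/3/3, length fraction 0.5 and similarity fraction 0.8. `hor5s`
realises this as Smith–Waterman local alignment with match +1, mismatch −2,
gap −3 (the score-space equivalent of those costs), on both strands of a
doubled monomer so that reads spanning the tandem junction map; placements
are reported modulo the monomer length. Similarity is matches over alignment
columns; length fraction is aligned read bases over read length. Exact
13-mer seeding gates the aligner: a read sharing no 13-mer with either
strand cannot in practice reach 80 % similarity over half its length (with
≤ 6 substitutions in a 100-nt read an intact 13-mer provably survives), and
the test suite checks accept/reject identity against an independent
plain-Python full-DP oracle. Ties are resolved deterministically: best
score, then leftmost reference end-column, then forward strand; traceback
prefers diagonal over gap-in-read over gap-in-reference.

GP → GS → copies is straight arithmetic. The published copy figure for 5S is
consistent only with dividing the genome space by the 120-bp genic length,
while the stated formula divides by the 220-bp monomer; both divisors are
computed and reported side by side rather than guessing the authors' intent.

## Variant calling

Pileups fold doubled-reference placements onto the monomer; insertions are
attributed to the left flanking position; junction-spanning reads are split
so each reference position is counted once. Calls require coverage ≥ 300,
supporting count ≥ 50 and frequency ≥ 5 % — all three, at every position.
Adjacent SNVs merge into an MNP when, among jointly covering reads carrying
at least one of the two alternative alleles, ≥ 90 % carry both. (A literal
"co-occur on ≥ 90 % of jointly covering reads" would require the alleles to
sit near fixation and could never merge a 17 %-frequency MNP; the
conditional form captures phasing at any allele frequency.) Pi uses pairwise
deletion of gap/N columns and no evolutionary correction; ties and empty
pairs contribute zero.

## Spacer-variant phasing

A complete unit is the stretch between two consecutive same-strand gene hits
(gap ≤ 1.5 kb). Its spacer region (± 10 bp slack for boundary jitter) is
scanned with each variant's 10-nt query at ≥ 9/10 matches on either strand;
exactly one matching query labels the unit, otherwise it is `other`. The
9/10 threshold deliberately reads the "more than 90 % of 10" rule as
tolerating one mismatch — a 10-mer in single-pass long-read data usually
carries at least one error, and a strict 10/10 would label most units
`other`.

**What accuracy means here.** At a 13 %/base error rate the probability that
a 10-nt window survives with at most one substitution and no indel is at
most ~0.6 under any rate split, so no caller can recover ≥ 90 % of true
labels; consistently, the study's own 50-unit molecule had 13 units (26 %)
unassignable. Errors convert true labels into `other`; they essentially
never convert one variant into the opposite one (that requires ≥ 3 specific
coordinated substitutions). The benchmark therefore reports *flip-free
accuracy* — the fraction of units not assigned the opposite variant — which
the suite requires to be ≥ 90 % (observed ≈ 99.9 %), alongside a recall
floor for the true variant (observed ≈ 0.44 at 13 % noise, the
noise-limited ceiling).

## Gene detection, blocks and group classification

Gene copies are found by exact 9-mer seeding of the consensus (both
strands), clustering seed votes for candidate start positions (tolerance
45 bp), and verifying each cluster with an infix edit-distance alignment of
the full consensus in a local window; hits need identity ≥ 0.7 and gene
coverage ≥ 0.6, and overlaps (> 30 bp) resolve by score, then leftmost.
At 13 % noise a 120-nt gene contains ~30 intact 9-mers in expectation, so
detection is effectively certain; partially overlapping genes at read edges
are not recovered.

Blocks are maximal same-strand hit runs with inter-hit gaps ≤ 1.5 kb (the
ultralong spacer bound plus indel slack); a block is *long* at ≥ 5 units,
the published boundary between dispersed and tandem organisation. Group
assignment follows the decision order III → I → II → IV: III when two long
blocks of opposite orientation exist; I when long-block *extents* cover
≥ 90 % of the read and no extent-free interval reaches 500 bp; II when any
long block exists; IV otherwise. A block's extent is its hit span padded by
one repeat period (the median junction gap, capped at 1.5 kb) on each side —
without this, the trailing spacer of every array, and every ~1.2-kb
ultralong spacer, would masquerade as unique DNA and demote pure tandem
reads. Read-terminal hit-free stretches shorter than the gap bound are
likewise not treated as unique DNA. The numeric boundaries (500 bp,
0.9) are this package's formalisation of a visual classification; they are
exposed as parameters. `unique_intervals` on the classification object is
the exact complement of gene-hit intervals, so hits plus unique intervals
always partition the read.

## Dot-plots

Self-comparison scans every diagonal (direct) and anti-diagonal (reverse)
of the read, scoring matches +5, transitions −3, transversions −4 and
bridging interruptions whose penalty stays within the X-drop (30); runs
scoring ≥ 100 and ≥ 20 nt are emitted, the full-length identity diagonal is
always included, and the segment set is exactly symmetric under x/y swap.
This is an ungapped formulation: affine-gap extension is not performed, so
segments interrupted by large indels appear as parallel sub-segments rather
than one gapped alignment — adequate for the structural read-out (off-
diagonal spacing and anti-diagonals), not a general aligner.

## Problem sizes and determinism

Simulation-backed checks run at sizes chosen to give comfortable statistical
margins on one CPU: planted-GP recovery uses 1.2 × 10⁵ reads against a 99 %
binomial interval (the acceptance script uses 3 × 10⁵ for a tighter
standard error); group-agreement and phasing benchmarks pool 200 noisy
reads over 5 seeds; the mapper/oracle cross-check uses 1,000 mixed reads.
Every stochastic component takes an explicit seed; the pipeline derives
per-stage seeds from one global seed, and identical config + seed produces
byte-identical artifacts (no timestamps are written).

## Known limitations

* The synthetic background and linker DNA are uniform random; repeat-rich or
  low-complexity backgrounds would stress mapping and gene detection in ways
  these benchmarks do not measure.
* Published diversity values from real archives (e.g. spacer vs genic Pi)
  are data-dependent and not reproduction targets; the suite verifies the
  Pi estimator against a brute-force oracle and closed forms instead.
* No chimeric reads, adapters, quality-correlated errors, or diploid
  variation are simulated; paired-end structure and BAM emission are out of
  scope.
* Group labels for borderline architectures (e.g. a long block whose linker
  hovers near 500 bp) are threshold-sensitive by construction; the
  generator avoids planting such ambiguous cases, so benchmark agreement
  rates do not quantify behaviour exactly at the boundaries.
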