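# Methods

## Scope and design

`inteinscan` reconstructs a phage intein survey as a desk-scale, fully
testable pipeline.  Real surveys of this kind hinge on profile-HMM searches
against curated databases, maximum-likelihood phylogenetics and live
annotation services; this package deliberately replaces each of those with a
transparent, dependency-light equivalent whose behaviour can be verified
against exact ground truth:

* profile HMMs → gap-free log-odds PSSMs over packaged seed alignments;
* ML trees with SH-aLRT support → neighbor joining on Poisson-corrected
  distances, compared by Robinson–Foulds bipartition counts;
* live InterPro/GO lookups → a static family → category table.

All coordinates are 0-based half-open internally; report writers convert to
1-based inclusive at the single output boundary.

## Block models

Each conserved block (splicing blocks A, B, F, G; HEN blocks C, D, E, H) is a
PSSM in bits built from a packaged seed alignment with the pseudocount
formula given in the README.  Key design points:

* The seed alignments are synthetic and consensus-anchored.  They encode the
  residue logic of the two splicing classes — a mixed nucleophile column at
  A1, both Trp and non-Trp at B12, Cys and non-Cys at F4, penultimate
  His/Gly/Lys variants at G6 — so one model set detects both classes.  They
  are labelled `synthetic_` in `data/` and make no residue-level claim about
  any real intein.
* Block G has length 8: columns 1–7 are intein residues (column 7 the
  terminal Asn), column 8 is the +1 extein nucleophile.  Detecting the block
  therefore pins both the intein's C terminus and the +1 residue at once,
  and a G window ending at the protein's last residue is impossible, which
  enforces the "no call without a +1 residue" rule structurally.
* Unknown residues ('X', ambiguity codes) score 0 — the background
  expectation — implemented as a 21st matrix column fixed at zero.
* Default threshold: 8 bits per block.  At uniform background this keeps the
  empirical false-hit rate on random 1,000-residue proteins below 0.05 hits
  per model (checked in the test suite), while a consensus block scores
  40–55 bits and tolerates roughly 15–20% substitution before dropping to
  the threshold.
* Columns with more than 50% gap characters are removed and key positions
  re-indexed; removing a key column is an error rather than a silent shift.

## Chaining and calling

Hits are chained A?–B–F–G by dynamic programming.  Gap constraints (end of
one block to start of the next) default to A→B 30–120, B→F 0–450 (room for
an embedded HEN), F→G 5–60 residues.  These are implementation defaults
bracketing known intein architectures, not literature measurements, and all
are configurable.  The maximum-total-score chain is extracted, its span's
hits removed, and the process repeats, so multiple inteins per protein
resolve to non-overlapping calls.  Ties break by higher score, then leftmost
start, then lexicographic block set — fully deterministic, and the whole
procedure is equivalence-tested against exhaustive enumeration for every
input with ≤ 12 hits.

Block A is optional in a chain because class 3 inteins diverge there; with A
absent the N terminus is placed 10 columns upstream of block B and the call
flagged "approximate N-terminus".  Calls whose terminal residue is not
Asn/Gln are demoted to warning status (excluded from default reports, never
silently dropped).  Classification: class 3 iff (B12, F4, G5) = (W, C, T) —
this wins even when A1 is nucleophilic — else class 1 iff A1 ∈ {C, S, T},
else unknown.

HEN detection scans only the region between block B end and block F start
and requires blocks C and E (the two that carry the actual LAGLIDADG motifs)
in order.  `mini_gap` (default 50 residues) separates HEN-less mini-inteins
from inteins whose B–F region is long but unrecognized.

## Insertion sites

The inteinless extein is aligned to each reference family with BLOSUM62,
gap open 11 / extend 1, and free end gaps; free end gaps make the mapped
column invariant to extra residues upstream of the host protein.  A family
is assignable when the alignment covers ≥ 50 columns at ≥ 25% identity
(terminal overhangs excluded from both counts); otherwise the error carries
the best identity found.  The insertion column is the reference position
aligned to the last N-extein residue; when that residue falls in an
insertion, the nearest upstream aligned column is used.  One coordinate
convention is used everywhere, including the generator: **ref_column = the
last N-extein residue; the +1 nucleophile is extein[ref_column + 1]**.  Site
identity requires the exact same column (sites one residue apart are
distinct); letters are assigned a, b, c… by ascending column within each
family, deterministically, and relabelling after new upstream sites logs a
warning.

## Transfer analysis

Percent identity is identical columns over aligned columns excluding
terminal overhangs.  This denominator choice is stated in every report
header because published intein identity figures are only comparable under a
declared convention.  The transfer threshold defaults to 35%: unrelated
inteins typically share ≤ 30% identity, and 35% cleanly separates
background-consistent pairs from the markedly elevated identities that
accompany recent transfer, while staying configurable.

Trees: distances are −ln(identity fraction) (Poisson-corrected p-distances,
capped at 5), neighbor joining via scikit-bio, negative branch lengths
clamped to zero with a warning.  Monophyly on an unrooted tree means "some
edge separates exactly the focal taxa".  A flagged pair counts as a transfer
candidate only with the joint signal: identity above threshold *and*
monophyletic in the intein tree but not in the extein tree.  High identity
alone (e.g. sister taxa) never suffices, which is what keeps the false-flag
rate low in the no-transfer controls.

## Synthetic data

The generator's defaults are the study conditions: two clusters of 62 and
145 genomes at intein rates 0.887 and 0.042 (an intein-rich versus a nearly
intein-free cluster), 8 genes per genome, divergence 0.1 substitutions/site,
30% class 3, half of inteins HEN-bearing, and a penultimate spectrum of
H 0.6 / G 0.2 / K 0.1 / S 0.1 (His-dominated with the Gly/Lys/Ser variants
seen in phage inteins).  Recovery experiments override genome counts, rates
and divergence explicitly (200 genomes, rate 1.0, divergence 0.15 in the
acceptance run).

Substitutions are uniform over the 19 alternative residues with no indels —
a Jukes–Cantor-like choice that keeps recovery statistics analysable
(binomial substitution counts; collinear alignments, hence exact site-column
recovery under pure divergence).  Real data add indels, compositional bias
and domain shuffling, so passing recovery tests bounds performance under
substitution noise only; they do not certify performance on real proteomes.
Key catalytic positions are never mutated: divergence measures how far the
rest of the element drifts while the diagnostic residues stay fixed, which
is also what the classifier assumes.  Genes are reverse-translated with one
preferred codon per residue (table 11) and embedded in uniform-random
intergenic spacers; every simulated protein keeps Met at position 0 so its
ORF starts with ATG.  Identical configurations produce byte-identical
output files.

HGT scenarios evolve an extein (240 aa) and an intein (160 aa) along a fixed
balanced 8-taxon tree (terminal branches 0.4, internal 0.2 substitutions/
site) and then copy the donor's intein onto the recipient at a small event
divergence (default 0.05).  Only the intein transfers — exteins never
recombine — mirroring the inference logic of intein/extein incongruence, not
full phage biology.  At these depths background intein identities sit well
below the 35% threshold while sister-taxon identities (~50%) remain
congruent in both trees, so the joint test isolates the planted event.

## Numerical choices and degenerate inputs

* Display percentages round half-up to one decimal; all comparisons use
  unrounded values.
* R² is the squared Pearson correlation; constant input returns NaN with a
  warning, never 0.
* Logo information is log2 20 − H with gaps excluded from the denominator
  (not a 21st symbol); all-gap columns report 0 bits with a flag.  The
  Miller–Madow small-sample correction is available behind a flag and off by
  default, since group sizes vary wildly between sets being compared.
* Empty FASTA files, duplicate ids, ragged alignments, asymmetric distance
  matrices and zero CDS counts are loud errors; ORFs without an in-frame
  stop are dropped by default (flag to include).

## Problem sizes

The shipped test and acceptance runs use: 200 genomes / 200 planted inteins
for recovery, 1,000 background proteins of length 500 for the false-positive
bound, 500 randomized hit sets for the chaining oracle, 50 random pairs for
the alignment oracle, 50 random additive matrices (4–8 taxa) for NJ, and
100 + 100 replicates for transfer sensitivity and false flags.  These sizes
give stable statistics (binomial standard errors of a few percent) while the
whole suite completes in well under a minute.

## Known limitations

* The PSSM scanner has no gap states; inteins whose blocks contain indels
  relative to the seeds lose score linearly and can fall below threshold.
* Boundary placement is exact only when block G is found at its true offset;
  there is no sub-column refinement.
* The class 3 N terminus is heuristic when block A is undetected.
* NJ+RF is a topology-level substitute for ML inference; branch support is
  not computed, and incongruence is binary (monophyly XOR), not
  support-weighted.
* Transfer directionality is not inferred — the incongruence signal is
  symmetric between donor and recipient.
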