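# Methods

## The genomes this package models

Ctenophore mitochondrial genomes are extreme outliers among animals: circular
molecules of ~10–11.6 kb carrying 11 protein genes (*cox1–3*, *cob*,
*nad1–6*, *nad4L*) and 2 rRNAs (*rns*, *rnl*), with all tRNAs and
*atp6*/*atp8* lost, every gene on the same strand, ~84% AT (T alone ~60% of
nucleotides), very little non-coding sequence, and gene orders so rearranged
between taxonomic orders that normalized breakpoint distances approach 1.
All coordinate arithmetic in the package is therefore circular: internal
coordinates are 0-based half-open, and a feature crossing the origin is
stored unwrapped (`end > genome length`, with `end − length ≤ start`), so
`end − start` is always the feature length. GenBank 1-based inclusive
locations, including `join(x..len,1..y)` origin spans, are converted exactly
at the I/O boundary, and round-trips are bit-exact.

## Annotation

ORFs are scanned in all three frames of the coding strand only (single-strand
coding; the minus strand is scanned only on request). A maximal ORF starts at
the first allowed start codon — ATA, ATG, ATT or TTA, the four observed in
these genomes — after the previous in-frame stop, and ends at a TAA/TAG stop.
Incomplete stops (a terminal T or TA completed to TAA by polyadenylation) are
accepted only where no in-frame complete stop precedes the next feature.

ORFs are labelled by global protein alignment (BLOSUM62, gap open 10, extend
1) against a labelled reference set, with the score normalized by the
reference's self-score so identity scores exactly 1; hits below a
configurable floor (default 0.3) are dropped. This floor is deliberately
permissive — it has no published anchor and mainly excludes noise ORFs.

Gene boundaries are then chosen lexicographically: (1) minimal total overlap
in bp with neighbouring annotated features, (2) among ties, maximal
similarity of the implied protein to the reference, (3) among remaining
ties, the longest ORF. The two criteria are applied in two passes: a first
pass refines every gene against its reference alone (maximal ORF spans are
systematically inflated at the 5′ end and would mislead the overlap
criterion), and a second pass re-selects each start with the refined spans of
all other genes as neighbours. rRNAs are placed by exact match against
reference rRNA sequences, with a local nucleotide alignment (match +1,
mismatch −1) as fallback — a deliberate simplification standing in for
covariance-model searches, adequate because rRNA location, not structure, is
needed downstream.

URFs (unidentified reading frames) are unassigned ORFs longer than 100 bp
(strict inequality) that contain at least one predicted transmembrane
segment. TM prediction is a Kyte–Doolittle sliding window: non-overlapping
19-residue windows with mean hydropathy > 1.6, scanned greedily left to
right. This is a classical heuristic chosen for determinism and
testability; it is coarser than HMM-based predictors, and the URF rule only
consumes the ≥ 1 threshold. tRNA-like candidates supplied by external
scanners are rejected exactly when they overlap an annotated protein/rRNA
feature *and* lack a canonical cloverleaf; everything else is kept, flagged
for review when it lies inside a feature.

## Genetic-code reassignment

For each codon used by a target species, the detector restricts codon-aware
alignments to columns where at least a fraction (default 0.7) of the
non-target species agree on one amino acid, and tallies that consensus per
target codon. A codon is flagged as reassigned when the modal consensus
differs from the expected table's meaning, rests on at least 5 columns, and
reaches modal frequency ≥ 0.5. The defaults were chosen to flag a TGA→Ser
reassignment robustly on simulated alignments of 8 species with 90%
column-level conservation; they are all configurable. The package ships both
the mold/protozoan/coelenterate table (TGA = Trp) and the TGA→Ser variant.

## Homopolymer frameshift repair

Within a small (≤ 500 bp) region, each homopolymer run (≥ 3 bases) is
re-estimated as the majority run length among reads that span it with both
8 bp flanks matching exactly. A differing majority produces one
insertion/deletion edit; a tie produces no edit (conservative: edits only
where reads confirm them), and an uncovered run is reported uncorrectable.

## Gene-order comparison

Because all genes share one strand, an adjacency is the directed ordered pair
(g, next(g)) on the circle; a full reversal therefore breaks every adjacency.
BD between two orders over the same label set (restrict first when sets
differ) is the count of adjacencies of one absent from the other — symmetric,
since both orders have the same number of adjacencies. BDn = BD / n_shared
(13 for the full ctenophore set); display rounding is two decimals half-up
(9/13 → 0.69, 12/13 → 0.92), with the stored value unrounded. Synteny blocks
are maximal runs of ≥ 2 genes consecutive and co-ordered in both circular
orders; the blocks cover exactly the n − BD conserved adjacencies (a fully
conserved pair yields one circular block of n genes covering n adjacencies).
Reporting is anchored at the lexicographically smallest label for
determinism; blocks may cross the anchor.

The packaged five-genome breakpoint table carries the published values
verbatim, including one internally inconsistent cell (the
*V. multiformis*–*P. bachei* pair prints BD 12 but BDn 0.77, where 12/13
rounds to 0.92); the package always reports bd/n_shared exactly and leaves
the published cell as data.

## Genome statistics

Non-coding length is the circular complement of the union of annotated
features, computed twice — URFs treated as coding ("without URFs" in NC) and
as non-coding ("with URFs") — along with counts of tracts > 20 bp (strict)
and the longest tract with its flanking genes; a gap spanning the origin
counts once. Codon usage tallies internal codons per protein gene, with
start codons, complete stops, and incomplete stops (T/TA) as separate
categories; percentages are over internal codons. The size~NC correlation is
the sample Pearson coefficient (scipy); recomputing it from the packaged
table's printed values gives 0.987, which displays as 0.99 — the source
prose prints 0.98, consistent with truncation rather than rounding; the
package reports full precision.

Perfect repeats are maximal exact repeated substrings of length ≥ 21 by
default ("longer than 20 bp", strict), found by seeding on unit-length
k-mers in the middle copy of a tripled sequence (so extension crosses the
origin in both directions) and extending each co-occurring pair maximally,
de-duplicating per circular offset; hits are grouped by unit string. A unit
is low-complexity when the Shannon entropy of its overlapping-dinucleotide
composition falls below 1.5 bits — a documented, switchable proxy for
"filter low complexity" options in repeat-web-servers, which reliably
catches the poly-T tracts these genomes accumulate.

## Contig elongation and circularization

Extension is by exact overlap: a read (either orientation) whose prefix
matches the contig suffix over ≥ 25 bp contributes its overhang, and the
appended extension is the column-wise majority consensus (a column where no
base reaches 50% stops the extension and is logged). With 100 bp reads a
productive round adds ≥ 75 bp to an end whenever a fully overhanging read
exists. Real pipelines use mapping software with mismatches; exact matching
with a mismatch knob (default 0) reproduces the same contract at desk scale
and is fully testable. Circularity is recognised when a contig suffix
equals its prefix over ≥ 25 bp (all such borders are found via the KMP
failure function; the longest is trimmed, with a warning when several
qualify). Coverage statistics place each read at every exact full-length
match on the doubled circle and report mean, population SD, min and max
per-base depth, counting unplaceable reads without failing.

## The synthetic generator

`generate_genome` emulates the observed structure: 13 canonical genes on one
strand, codon-structured CDS (start from the allowed set, no internal stop
under the chosen code, terminal TAA/TAG drawn 9:1), rRNAs as composition-
matched random sequence, URFs with a planted 21-residue hydrophobic stretch,
and short non-coding tracts each carrying a 5–12 bp poly-T run. Nucleotides
are drawn per-position from the target composition (defaults: AT 0.84 with
T 0.60) with codon-level rejection of stops, so realized composition is
approximate — within about ±1.5 percentage points at full genome size, as
asserted in tests. Default gene models put the genome at ~11.5 kb, inside
the observed 10.0–11.6 kb range; two NC tracts are wide enough to host a
planted perfect repeat (default request: 84 bp unit ~8.2 kb apart; the
ledger records the realized positions, and distinct flanking bases enforce
maximality). Everything is deterministic under the spec seed, and every
planted property lands in a JSON-serialisable truth ledger.

Rearranged orders are produced by single-gene transpositions (redrawn when a
draw would leave the circular order unchanged), each altering at most 3
adjacencies, so BD ≤ 3k after k moves; inversions are excluded because all
genes share one strand. Reads are error-free, uniformly placed on the
circle with Poisson-distributed counts, in random orientation; paired mode
emits mates from fragment ends. Simulated codon alignments conserve each
column with probability 0.9 across 8 species, and a planted reassignment
puts the new amino acid at ~25% of columns where the target writes the
reassigned codon.

What the generator does *not* emulate: sequencing error, chimeric reads,
nuclear contamination, realistic protein sequences (references in tests are
the planted proteins themselves, i.e. identity homology), or rRNA secondary
structure. Passing tests therefore demonstrate the correctness of the
algorithms under the stated statistical structure, not end-to-end accuracy
on diverged real data, where homology floors and boundary criteria carry
real uncertainty.

## Problem sizes and numerical choices

Simulation studies in the test suite and acceptance script run at desk
scale, chosen as a deliberate trade-off: boundary-recovery uses 200 genomes
with scaled-down gene models (40–72 aa proteins, short rRNAs and tracts);
elongation trials use ~2.5 kb circles at 20× with 100 bp reads; the
breakpoint oracle uses random circular permutations of up to 8 labels;
reassignment recovery uses 100 seeded alignments. Display conventions:
percentages to one decimal with a trailing ".0" dropped in prose-style
output, BDn to two decimals half-up. Degenerate inputs fail loudly:
N-containing sequences are accepted by I/O but rejected by ORF scanning and
translation; constant columns make the correlation an error rather than a
NaN; fewer than two shared labels make order comparison an error.
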