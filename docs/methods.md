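# Methods

## Coordinates and the junction convention

Genomic intervals are 0-based half-open; residue and codon indices are
1-based (so reports read like the familiar D171-style numbering).  An intron
position is the pair (codon index, phase), where phase ∈ {0,1,2} is the
number of nucleotides of the split codon contributed by the upstream exon.
A phase-0 junction falls between codons and is attached to the residue
immediately *following* it; phase-1/2 junctions are attached to the residue
whose codon they split.  With cumulative upstream exon length `c`, this is
`codon_index = c // 3 + 1`, `phase = c % 3`.  The convention is symmetric
between strands and is applied identically by the parser, the projector and
the simulator, which is what makes exact round-trip tests possible.

Splice dinucleotides are read on the coding strand: GT..AG is canonical,
GC..AG non-canonical, anything else (including N-containing dimers, which
warn rather than crash) is `other`.  Gene models whose spliced CDS lacks a
start, a terminal stop, or an intact frame are parsed but flagged partial
and excluded from junction analysis by default.  Transcript corroboration
of a splice prediction is user-supplied metadata (`GeneModel.corroborated`);
no corroboration procedure is implemented.

## Shared junctions

Intron positions are projected to the alignment column of their host
residue; the phase travels unchanged.  Junctions from distinct sequences are
grouped greedily left-to-right: the leftmost ungrouped junction anchors a
group, and junctions within `shift_tolerance` columns (equal phase when
`require_same_phase`) join it.  Defaults are `shift_tolerance=0` and
`require_same_phase=True` — the strict reading of junction conservation; at
tolerance 0 the greedy grouping is provably identical to exact
equality-class grouping (and is tested against that brute force).  At
tolerance > 0 greedy grouping is deterministic but not globally optimal;
looser settings are explicitly opt-in.  Support divides the supporter count
by the number of eligible (intron-bearing, non-partial) sequences.

## Local alignment and annotation

The local aligner is an explicit affine-gap Smith–Waterman over BLOSUM62
with the existence/extension convention: a gap of length *k* costs
`gap_open + k·gap_extend` (defaults 11/1).  Ties between optimal alignments
break deterministically: earlier query start, then earlier reference start,
then fewer gapped columns.  Identity is identical pairs over *all* alignment
columns.  `X` (unknown residue, e.g. from N-containing codons) scores 0
against everything.  Its optimum is verified against exhaustive enumeration
of every monotone set of aligned pairs on short sequences.

Transcript annotation scans six frames for ATG-initiated ORFs (5'-most ATG
per stop-bounded segment; nested starts behind a flag; 3'-running ORFs
flagged partial), aligns each ORF to a reference panel, and accepts on
score ≥ 100, identity ≥ 0.30, reference coverage ≥ 0.60 and ORF length
≥ 150 aa.  These are repository defaults standing in for search
"significance": no E-values are computed because there is no database size
in this setting — a deliberate, visible simplification.

## Region analytics

All region work is anchored to a named reference (for real data, human
PRPS1).  The packaged window defaults (FLAG 31–45, regulatory flexible loop
92–108, catalytic flexible loop 128–144, PP loop 170–174, R5P loop 213–228)
are editable approximations of the loop elements of the PRPS1 homodimer
structure; only the catalytic residue set D171/K194/R196/N200/T225 is fixed
by well-established enzymology.  Interface (bent/parallel dimer) and
allosteric set membership is analysis-specific and must be supplied by the
user; it is never hard-coded.

NHR detection counts residues a sequence holds in columns where the
reference is gapped inside a region window, merging runs separated by
≤ `gap_merge` (2) columns, reporting runs ≥ `min_insertion` (10) residues,
and marking runs with ≥ `flank_len` (5) aligned flanking column pairs as
anchored.

Difference concentration globally aligns a protein pair (end gaps free,
BLOSUM62, 11/1) and counts difference events: each mismatch column is one
event and each maximal indel run is one event, so a 25-residue NHR indel
weighs the same as one substitution — the point of "excluding the flexible
NHR residues" when asking where paralogs differ.  Masked region columns are
removed before counting; events map to first-sequence coordinates, indel
runs to the nearest preceding residue.  A caveat found during development
and kept visible: when a window is so diverged that local stretches stop
scoring positively, the end-gap-free aligner can absorb terminal differences
into free end gaps and under-count them; the measure is intended for
homolog pairs that remain alignable end to end.

Leader detection walks in-frame upstream of a declared canonical ATG,
collecting ATGs until the first in-frame stop; only AUG starts are
considered (non-AUG initiation is future work).

## Classification and duplication support

Feature vectors (loop-insertion lengths, residue-set conservation
fractions, intron presence) feed an ordered rule list: regulatory-loop
insertion ≥ 10 → PRS5-like; else CF-loop insertion ≥ 10 with catalytic
conservation ≤ 0.4 → PRPSAP-like; else catalytic ≥ 0.8 with either dimer
interface ≤ 0.5 → Class II; else catalytic ≥ 0.8 → Class I (retrocopy when
additionally intronless); else unclassified.  Prs5 precedes PRPSAP because
fungal Prs5 orthologs may carry *both* loop insertions.  The cutoffs are
repository choices (the biology is qualitative: ≥ 4/5 of the catalytic set
"intact", half an interface "poor"); every CLI report echoes them.  Missing
residue sets default to conservation 1.0, i.e. absence of evidence never
degrades a sequence into Class II.

Duplication support compares mean pairwise global identity of a child set
to a candidate parent clade versus an outgroup (`delta` = parent −
outgroup); bootstrap support resamples the pair-identity lists (not
sequences) 200 times with a mandatory seed, and junctions shared
child↔parent at tolerance 0 with equal phase are counted as independent
gene-structure evidence.

## The simulator: what it emulates, and what it does not

`synthetic_data` evolves a gene family along a clade tree with per-taxon
terminal branches.  Substitutions act per site with probability
`1 − exp(−d·rate)` on a branch of length `d` (default rate 1.0
substitutions/site per unit length; stock branch lengths 0.02–0.30 give
realistic 5–40% pairwise divergence); with probability `blosum_bias` (0.5)
the replacement is a BLOSUM62-positive neighbour, else uniform.  Residues
in any named residue set are protected from random substitution — a cartoon
of purifying selection at functional sites — and change only through
explicit `degrade` events, which force non-identical, non-positive-scoring
replacements at a chosen fraction of the set.  Insertions are codon-aligned
and confined to named region windows; retrocopies strip all introns;
leaders prepend an in-frame ATG extension in the transcript 5' UTR (the
gene model keeps the canonical CDS so that translating the model always
reproduces the truth protein); intron gain/loss counts are Poisson per
branch (default 0).  Introns are written as GT..AG (default length 84 nt),
ancestral introns default to four positions covering all three phases, and
the 5' UTR ends with an in-frame stop so leader detection has exact truth.

Because the only indels are scripted insertions, the true alignment is
known exactly (homology keys per residue), and substitutions never move
coordinates.  This is the point of the design — every downstream stage can
be tested against exact truth — and also its limit: real families
accumulate background indels, alignment error, splice-site drift and
non-AUG starts that these tests do not exercise.  Passing them shows the
machinery is correct, not that real alignments are this clean.

Two stock scenarios ship as configs: the Amorphea family (duplication to an
NHR-bearing, catalytically degraded paralog in the opisthokont ancestor; a
fungal regulatory-loop paralog; a holozoan retrocopy; a 29-aa leader) and a
jawed-vertebrate-style paralog pair (AP1/AP2 pattern: rapid N-terminal
divergence concentrated in residues 1–95, an NHR, full catalytic
degradation, 29- and 12-residue leaders).  The paralog-pair branch length
(0.02) and N-terminal block (27 of 30 marked positions forced) were chosen
to represent strongly diverged but still end-to-end alignable homologs —
the regime the difference-concentration measure is defined for.

## Problem sizes and determinism

The default test and acceptance runs use families of ~14 sequences of ~320
residues, 50 seeded replicates for round-trip and recovery checks, 500/200
random cases for the aligner and junction-grouping oracles, and 200
bootstrap replicates — sizes chosen so the full suite completes in well
under a minute while keeping binomial noise far from the asserted margins.
All randomness flows through `numpy.random.default_rng` seeded from the
config or CLI; identical configs produce byte-identical fixture files
(hash-checked manifests).

## Known limitations

* No alignment construction or refinement: the MSA is an input.
* No codon-level or dN/dS evolution model; no frameshifts; no background
  indel process.
* No E-value machinery in homology annotation; thresholds are score-based.
* Greedy junction grouping is exact only at tolerance 0.
* Difference concentration assumes end-to-end alignable pairs (see above).
* Non-nuclear genetic codes and trans-splicing are out of scope.
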