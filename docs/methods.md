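# Methods

## The procedure

`seedasm` implements iterative seeded local assembly. A target (seed)
sequence — nucleotide or protein — initiates a cycle of read retrieval,
assembly and filtering; the contigs that match the original seeds become
the queries of the next cycle. The procedure assumes (i) reads are stored
with unique names in an indexed store, (ii) the target locus is covered by
reads at some (possibly low) depth, and (iii) matching can be decided by
local alignment e-values. Nothing about the genome the reads came from is
assumed; off-target contigs arising from repeats are filtered each cycle by
the carry-forward rule, and are reported in the per-cycle statistics as the
gap between "all" and "matching" contig counts.

### Search

The aligner is seed-and-extend: exact k-mer matches (k = 11 for
nucleotide, k = 4 for translated searches) are grouped into diagonal
clusters; each cluster defines a band (cluster extent ± 48 diagonals) over
which a banded affine-gap Smith–Waterman with traceback (numba-compiled)
finds the best local alignment. Extension triggers on a single seed: a
two-hit rule would be marginally faster but can miss the optimum on short
instances, and the test suite holds the engine to exact agreement with a
full Smith–Waterman oracle on homologous pairs. Both strands are searched
for nucleotide queries; protein queries are aligned against all six
reading frames of the subject and hit coordinates are mapped back to the
forward nucleotide strand.

Raw scores convert to bitscores and e-values by the Karlin–Altschul
formulae `S' = (λS − ln K)/ln 2`, `E = m·n·2^(−S')`, with published gapped
parameters: λ = 1.28, K = 0.46 for the default +1/−2 scoring with gap
open 5 / extend 2, and λ = 0.267, K = 0.041 for BLOSUM62 with gap 11/1.
The database length `n` is the total stored bases, with no edge-effect
correction — cutoffs are user-tunable, so absolute calibration is
secondary. Scores do not reproduce NCBI BLAST exactly (no composition
statistics, no low-complexity masking); the e-value thresholds
(1e-10 initial, 1e-20 in later cycles) play the same role of ranking and
filtering.

### Selection and fragmentation

Ranked reads (a read's rank is its best bitscore over all queries, ties
broken by id) are limited by one of five policies; `increment` (default
step 10 reads/cycle) is the usual choice, and `population` advances whole
bitscore-tie groups at a time so the result is deterministic. Previous-cycle
reads that vanish from the ranking are skipped with a logged warning rather
than deadlocking the run. Fragmentation applies after selection, so ranking
reflects whole-read evidence: pieces of one length (default 600 nt), or of
two lengths (defaults 610 and 490 nt) pooled, tile each read without
overlap or gap; terminal remainders are kept because discarding them would
lose unique sequence exactly in the low-coverage regime fragmentation
targets.

### Assembly

The built-in assembler is greedy overlap–layout–consensus. Dovetail and
containment overlaps between current assemblies are proposed from shared
k-mers (vectorised integer-k-mer join; every third position sampled on the
query side), verified by edit-distance alignment of the implied junction
(edlib), and accepted when the overlap is at least `min_overlap` (default
40 nt) at identity at least `min_identity` (default 0.83; 0.93/0.97 are
the stricter documented settings for separating close paralogs). The
highest-scoring overlap (score = 2·matches − 4·mismatches − 5·gap columns)
is merged first; junction consensus is recomputed per merge by
depth-weighted majority, with ties broken in the fixed base order
A < C < G < T < N. Reads keep a canonical orientation from first
placement; contigs are reported in the orientation of their first-placed
read and named c1..cN in decreasing length. There is no scaffolding and no
paired-end constraint. Layout start coordinates are exact for error-free
reads and approximate to within alignment indels otherwise.

At the default permissive identity, reads from near-identical alleles
merge across alleles wherever a conserved tract is longer than the reads —
producing multi-allele consensus contigs and flank-joining chimeras. This
is a real property of overlap assembly at these settings, reproduced by
the nine-allele simulation below.

### Polishing

Polishing plays the racon role with an internal aligner: reads are locally
aligned to the contig, and each column with pileup depth ≥ `min_depth`
(default 2) is replaced by the weighted majority among {A, C, G, T,
deletion}; an insertion is applied where its supporting weight exceeds
half the flanking column's total weight. Weights are base qualities when
present, else 1. Columns below `min_depth` are never touched. Iteration 0
is the identity; iterations stop early at convergence, and the polished
contig id carries a `.polN` suffix. The pipeline caps iterations at a
configurable number (5 is a sensible ceiling; in simulation the first
iteration does essentially all the work).

### Stopping and outputs

A run stops at `max_cycles` (default 21), when the longest matching contig
changes by fewer than `minprogress` bases between consecutive cycles
(default 100; 0 disables; absolute difference, so shrinkage also counts),
when manual read counts run out, or when no contig (or no matching contig)
is produced. Each cycle writes a FASTA of matching contigs (plus a
separate polished FASTA when polishing), a layout TSV, and a row in
`report.tsv`; `log.txt` records every search/assembly/polish call with
parameters. Internal coordinates are 0-based half-open; tabular outputs
use 1-based inclusive BLAST convention. All randomness flows from the one
seed in the configuration, and identical configurations produce
byte-identical outputs.

## The simulators

The generator emulates the validation conditions end to end:

- **Locus**: a 7000-nt founder drawn i.i.d. (uniform base frequencies by
  default; an AT-rich plant-gene preset is provided), with a centred
  1800-nt conserved core. Nine alleles derive from the founder by
  independent substitution at 0.005/nt in the core and 0.02/nt in the
  flanks.
- **Reads**: 2×150 paired-end reads (insert Normal(400, 50), a
  conventional Illumina geometry; the insert distribution is our choice,
  not a reported value), 7–14 kb long single reads, or empirical/medium
  lengths (surrogate Uniform(300, 900) nt). Placement is uniform; ids
  encode source, start and strand for truth tracking; total bases track
  the requested coverage to within one read.
- **Errors**: four channels — per-base substitution, single-base deletion,
  single-base insertion, and a ±1 shift of homopolymer run length. The
  accurate preset is (0.005, 0.001, 0.001, 0.01), realized ≈ 0.007
  events/base; the noisy preset is (0.07, 0.01, 0.01, 0.80), realized
  ≈ 0.098 events/base and ≈ 90.7% mean alignment identity to source.

The run-shift channel needs an interpretation: applied per base, 0.80 is
irreconcilable with a ~10% total error rate. We apply it once per maximal
homopolymer run of length ≥ `min_run_len`. The threshold is a calibration:
at ≥ 2 the measured identity is 0.815, at ≥ 3 it is 0.887, and at ≥ 4 it
is 0.907 — only the last sits squarely at the intended ~90%, so
`min_run_len = 4` is the default (homopolymer miscalls in real nanopore
data are likewise concentrated in longer runs).

What the simulators do **not** model: quality-score variation along reads
(a constant default is emitted), GC bias, chimeric reads, adapters,
coverage waviness, and genome-scale repeat structure beyond what the
nine-allele locus provides. Passing tests therefore demonstrate the
machinery's correctness and its qualitative behaviour on homologous loci at
controlled error rates — not performance on real libraries.

## Evaluation procedures

- **Accuracy**: best local alignment of each contig to the reference;
  identity = matches / alignment columns. Mismatch and gap columns are
  split into the terminal 100 contig bases at each end of the alignment
  vs the middle, giving terminal and middle per-base mismatch rates (on
  low-coverage assemblies the terminal rate is the larger, reflecting
  thinner support at contig ends).
- **Trajectories**: per-cycle longest/mean/count for matching and all
  contigs, plus a deliberately simple classifier (monotone / stepwise /
  peaked / alternating by sign changes of consecutive differences).
- **Lengthening bins**: ratio of the maximum longest-matching contig over
  cycles to its cycle-1 value, binned in 0.4 increments from 1.0 with a
  final 3.0+ bin.
- **Locus calling**: reference hits sorted by start; a distinct hit is
  counted where a start exceeds the previous maximum end, and a gap over
  10 kb (default) opens a new locus. Book-ended hits (start = previous
  end + 1) count as distinct hits within one locus.
- **SNP anchors**: all-vs-all contig alignment at e-value 1e-8; within the
  interval where nonself coverage reaches `min_depth`, positions whose
  base differs from every aligned nonself base are contig-specific; pairs
  separated by a PCR-product-sized distance are reported together. A
  stricter "no nonself coverage at all" reading is available behind a
  flag, but only the default yields discriminating anchor SNPs. No
  default is claimed for `min_depth`; it is a required analysis choice.
- **Closed forms**: primer match probability `x^(m+n)`, coverage fold,
  1-based-inclusive region span sums, and a paired t helper (scipy).

## Problem sizes used by the test suite and acceptance script

Chosen to exercise each claim at desk scale: simulator calibrations use
≥ 1.2 Mb of reads from a 200 kb (long) or 100 kb (short) source; oracle
equivalence uses 1000 homologous pairs ≤ 560 nt; reconstruction uses 100
random sources of 0.8–8 kb tiled by 400-nt reads; the pipeline extension
check uses a 60-kb genome, a 2-kb seed and 20× error-free 600-nt reads for
5 cycles; the chimera and polishing phenomena use 20 independent seeds of
the nine-allele locus at 2.5× medium-read coverage and of a 7-kb locus
with one full-length noisy long read plus 30× accurate short reads,
respectively.

## Known limitations

- The greedy assembler's consensus is maintained incrementally per merge,
  not by global multiple alignment; very high error rates degrade it
  (polishing is the intended remedy).
- Layout coordinates are approximate under indels; depth is exact per
  column only up to the same approximation.
- e-values are not calibrated against NCBI BLAST; thresholds transfer in
  role, not in number.
- External assembler adapters are a contract (invocation + FASTA parsing);
  no external binary is required or tested.
- cap3's clipping options and quality trimming are not reproduced;
  de Bruijn and string-graph assembly are out of scope.
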