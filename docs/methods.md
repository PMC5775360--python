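# Methods

## The model system

`plastidkit` analyses sets of circular chloroplast genomes (plastomes) that
share the canonical quadripartite architecture: a large single-copy region
(LSC), a small single-copy region (SSC), and two inverted-repeat copies
(IRa, IRb), where the IRa sequence is the reverse complement of the IRb
sequence. Comparative questions the pipeline answers: where do the four
region boundaries sit and which genes straddle them; which perfect
microsatellites (SSRs) and large repeats does each genome carry; how
divergent are the genomes region by region; and which alignment intervals
are variable enough to serve as markers for species identification.

## Quadripartite detection and canonicalization

The IR extent is defined as the longest pair of disjoint maximal *exact*
inverted repeats on the circular sequence (extension stops at the first
mismatch; N never matches). This matches how published IR lengths are
conventionally reported. Search is seed-and-extend: exact k-mers of the
sequence are matched against the reverse complement (k = min(min_ir_len, 24)),
each seed extended maximally, candidates deduplicated, and the longest
disjoint pair kept. Ties are broken toward the pair with the most balanced
single-copy gaps, then the lowest start coordinate; a residual tie is an
error rather than an arbitrary pick.

Canonical frame: the genome is rotated so the longer single-copy region
(LSC) starts at position 0, giving region order LSC, IRa, SSC, IRb. The
strand is chosen so that the majority of LSC CDS bases lie on the forward
strand when annotations are supplied; without annotations, the strand with
the lexicographically smaller LSC sequence is used. Because the flipped
frame keeps the IR intervals fixed (revcomp of LSC and SSC in place), the
partition coordinates are identical in both frames and canonicalization is
idempotent. `min_ir_len` defaults to 1000 bp — far above chance matches in
a 150 kb genome and well below real plastome IRs (~25 kb); toy genomes in
tests use 300 bp for the same reason at smaller scale.

Junction analysis reports, for each of the four boundaries, every gene
whose span crosses it with the base-pair split on either side, the largest
overlapping partner gene (plastome ψ-ycf1/ndhF-style overlaps), and for
gene-free junctions an "intergenic" record naming the flanking genes and
the distances to them.

## SSR scanning

Perfect SSRs only, with MISA-style unit thresholds per motif period:
10, 5, 4, 3, 3, 3 for periods 1–6. For each period p, positions where
`s[i] == s[i+p]` are scanned for maximal runs; a run of r matches is a
repetitive tract of r+p bases. Tracts are reported at their minimal period
only (a divisor test on the motif), anchored at the leftmost base of the
run, counting complete motif copies (`units = floor((r+p)/p)`), so
`tract_length == period × units` by construction. Genomic context is CDS
if the tract overlaps a CDS exon by at least 1 bp, else intron if it lies
between exons of an annotated gene, else intergenic (IGS); tRNA/rRNA exon
bodies count as IGS, since the three-way CDS/intron/IGS classification has
no separate class for structural-RNA bodies. Cross-species loci are built
by projecting each genome's hits through its alignment row and merging
overlapping column intervals single-linkage; a locus is polymorphic when
at least two species descriptors (motif, units, or absence) differ.

## Large repeats

Four match types between segments of one genome: forward (F), reverse (R),
complement (C), palindromic/reverse-complement (P), at Hamming distance
≤ k (default min_len 30 bp, k ≤ 3, i.e. ≥ 90 % identity). A hit is a
*maximal pair*: extension on either flank would exceed the budget or leave
the sequence. The finder aligns the sequence against its transformed self
and, per diagonal, enumerates all maximal windows between mismatch
positions — an exact algorithm, not a heuristic. Candidate diagonals are
pre-filtered by shared exact q-mers (pigeonhole: a qualifying window
contains an exact run of ≥ ceil((min_len−k)/(k+1)) bases), which leaves
results unchanged. Sequences are treated as linear in the canonical frame;
origin-spanning repeats are out of scope. The genome's own IRa/IRb
duplication appears as one giant P hit (plus mirrored sub-hits); these are
excluded from summaries by default, as comparative repeat counts
conventionally are, and the exclusion is toggleable. Note that the number
of maximal pairs is *not* monotone in k — two maximal windows separated by
a single mismatch merge into one when the budget rises — but every hit at
budget k is contained in some hit at k+1, and that is the invariant tested.
Loci group hits by (type, length, region pair of the copies); the length
histogram uses bins 30–39, 40–49, 50–59, ≥ 60 bp.

## Divergence statistics

Site statistics use complete deletion: any column containing a gap or N is
excluded (ambiguity codes other than N are normalized to N upstream). A
column is variable with ≥ 2 observed bases and parsimony-informative with
≥ 2 bases each in ≥ 2 rows. Nucleotide diversity is Nei's π — the mean
pairwise p-distance over analyzed columns, computed from per-column base
counts as Σ_cols (pairs differing) / (C(n,2) · analyzed columns). Pairwise
distances use pairwise deletion: each pair is compared on the columns where
both rows are unambiguous, `p = n_diff / compared`. The complete/pairwise
split mirrors the defaults of the tools these statistics traditionally come
from (DnaSP and MEGA respectively). Region-wise tables project one
reference genome's partition through its alignment row; gap columns inside
a region belong to that region.

## Hotspot extraction

Windows slide over alignment columns (default 600-column windows, 200-column
step); window spans count gapped columns, statistics use the analyzed ones.
The selection threshold is T = mean(S) + k·sd(S) over all windows, with S
the per-window polymorphic-site count, k = 2, and the population standard
deviation (ddof = 0; switchable). Windows with S strictly greater than T
are selected; overlapping or exactly abutting windows merge into hotspot
regions — windows separated by an unselected step do not. Region statistics
(length, S, PI, π) are recomputed on the merged interval, not aggregated
from windows. Regions are named from the reference annotation: the gene
name when the interval lies inside one gene (suffixed a, b, … when one gene
yields several disjoint regions), otherwise the flanking and contained
genes joined with '-'. The threshold is applied to S, with the π profile
emitted alongside for plotting. Merged-window extents can overshoot the
core variable interval by up to a window length on each side; no trimming
is applied.

## Phylogeny stage

A deliberately small stage for topology checks, not inference: classical
neighbor joining on the p-distance matrix with deterministic tie-breaking
(ties in the Q criterion resolve by smallest contained leaf label; negative
branch lengths are kept as computed); Fitch parsimony scored column-wise on
bitmasks with gapped columns excluded, rooting the recursion at the first
leaf (score is rooting-invariant); Robinson–Foulds distance as the
symmetric difference of non-trivial bipartitions (delegated to dendropy
behind the module surface). Maximum-likelihood/Bayesian inference,
bootstrap, and model selection are out of scope.

## Synthetic data generator

The generator is the package's test bed: it builds plastomes whose every
analyzable feature is planted and recorded, so detectors can be checked
against exact truth without external data.

Ancestor construction: LSC, IRa, SSC drawn i.i.d. with 63 % AT (the typical
plastome composition); IRb is the reverse complement of IRa. Guard bases
make the planted structure exactly recoverable: the LSC starts and ends
with 'A' so the canonical-orientation rule cannot flip the genome, and the
bases flanking the IR pair are adjusted so exact extension stops precisely
at the planted boundaries. Planted SSRs get guards that break the
repetitive run at both ends; planted repeats (one of each type, with
chosen interior mismatches) get per-type flank guards so each pair is
maximal exactly at its planted budget.

Evolution: substitution-only Jukes–Cantor along a fixed 8-taxon tree, so
the true alignment is the identity mapping onto ancestor coordinates. Each
branch applies the exact JC transition probability
`p_change = 0.75·(1 − exp(−4·t_eff/3))` per site, with `t_eff` the branch
length times a per-site rate multiplier; composing branches therefore
reproduces the closed-form JC expected p-distance at the summed branch
lengths (the two-taxon test checks 0.0936 at total length 0.1). Rate
multipliers: 10× inside three planted 800 bp hotspot intervals (restricted
to LSC/SSC), 0.2× inside the IR (matching the empirically low IR
diversity), background 1×. Mutations in IRa are mirrored into IRb each
branch, keeping the IR identity invariant in every species — a concerted-
evolution model. After evolution, planted SSR tracts are rewritten per
species to configured unit counts (only shortenings, since substitution-only
evolution cannot change tract lengths), giving exact locus/polymorphism
truth.

Defaults are the study conditions: 20 kb genomes (LSC 11 kb, IR 2.5 kb,
SSC 4 kb), 8 taxa at 0.01 substitutions/site per branch, junction genes
mimicking the plastome convention (rps19 split 180/99 across LSC/IRa, ndhF
crossing IRa/SSC with a 25 bp overlap with a ycf1 fragment that reaches
17 bp into the SSC, ycf1 split 1000/406 across SSC/IRb), five planted SSRs
covering periods 1–5 with unit-count polymorphisms in two species, and one
planted repeat of each type. `small_config()` is a 5.6 kb miniature of the
same design used by fast end-to-end tests, and `toy_config()` gives bare
quadripartite genomes for partition tests.

What the generator does not emulate: indels (so no aligner is needed and
alignment truth is exact — an explicit design trade-off), rate
heterogeneity beyond the hotspot/IR multipliers, rearrangements, IR
expansion/contraction between species (boundaries shift only by chance
near-junction substitutions), and base-compositional structure beyond a
uniform AT fraction. Passing tests therefore demonstrate algorithmic
correctness on substitution-only data, not robustness to alignment error
or structural variation in real plastomes.

## Numerical and degenerate-input choices

Internal coordinates are 0-based half-open; reports are 1-based inclusive;
floats in reports print with 5 decimals (4 for p-distances, matching the
precision such tables are conventionally printed at). All randomness flows
from a single integer seed through `numpy.random.default_rng`; reruns are
byte-identical. Alignments need ≥ 2 rows; diversity is undefined (an error)
when every column carries a gap; distance is undefined for a pair with no
comparable column; hotspot selection needs ≥ 2 windows; NJ needs ≥ 3 taxa
(the pipeline skips the tree stage below that and says so in the run log).
An alignment shorter than one window yields a single truncated window with
a warning. The pipeline assumes alignment rows are in the canonical frame
produced by detection; a rotated input genome is canonicalized, which can
offset locus projection by the rotation amount relative to an alignment
built from the uncanonicalized sequence.

## Problem sizes used by the test suite

Oracle-equivalence tests run at the sizes where exhaustive enumeration is
honest: SSR oracle on 5 kb sequences, repeat oracle on 160 bp strings for
all four types and k = 0..3, diversity/distance oracles on 6 × 400
alignments, Fitch against brute-force internal labellings on 6 taxa,
partition recovery on 500 seeded ~2.5 kb toy plastomes, and hotspot
recovery on 100 seeded replicates at the full 20 kb / 8-taxon defaults.
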