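# Methods

This note documents the models and procedures implemented in `cobascan`,
the defaults they ship with, and what the synthetic benchmarks do and do
not demonstrate.

## Coordinate and identity conventions

All in-memory coordinates are 0-based half-open; SAM input (1-based) is
converted on ingestion and GFF3 output is written 1-based inclusive, so a
single convention governs every computation. Percent identity of an
alignment is `matches / (matches + mismatches + inserted + deleted
columns)` — the indel-inclusive denominator used by most read mappers; it
is the conservative choice and is applied everywhere a threshold appears.
SAM ingestion requires the `NM` tag (mismatches = NM − indel bases) and
keeps primary mapped records only; MD-tag parsing is deliberately not
attempted.

## Synthetic phage communities

`synthetic.simulate_genome` draws an i.i.d. nucleotide sequence at a target
G+C (default 0.47, length 40 kb — the scale of cultured cobavirus-type
podophages), duplicates the first `dtr_length` bases (default 170 bp,
within the 159–173 bp range typical of these phages) at the 3' end, draws
the first 30 bp of the repeat at G+C + 0.15 to emulate the conserved
GC-rich 5' region of the repeats, and plants a palindromic terminator
cassette with its hairpin midpoint at `terminator_offset × length`
(default 0.5, the boundary between the two genomic arms).

The cassette is `A6 | CC | stem(12 bp, G/C only) | CTTA | revcomp(stem) |
AC | T6`. Reading either strand 5'→3' gives hairpin-then-T-tract, i.e. the
terminator is bidirectional by construction. The two spacer dinucleotides
cannot base-pair across the hairpin; without them the A- and T-tracts pair
with each other and the detected stem start becomes indeterminate by up to
six bases.

The read simulator places uniform start positions on the linear genome,
reverse-complements about half the reads, and applies i.i.d. errors:
substitutions to one of the three alternative bases, single-base indels
with equal insertion/deletion probability. This is the simplest model
whose identity statistics are analytically checkable (truth identity mean
= 1 − subst_rate for indel-free reads); it does not emulate
platform-specific error profiles, quality-dependent miscalls, chimeras, or
GC coverage bias. Qualities are constant Q37 unless a linear 3'-decay tail
is requested (used to exercise the read cleaner). Communities assign reads
to members multinomially with the specified weight fractions; the truth
table records planted aligned bases and the expected per-Gb abundance.
One seeded NumPy generator per operation call makes every fixture
bit-reproducible.

`dinucleotide_shuffle` implements the Altschul–Erikson Eulerian-path
shuffle (exact dinucleotide counts preserved) and provides the negative
controls for the terminator scanner.

## Terminus detection and reorientation

`find_terminal_repeat` reports the longest end-anchored prefix/suffix pair
whose substitution fraction is ≤ 2% (default). Indels between the two
copies are disallowed: DTRs arise by replication of identical ends, and
indel tolerance inflates false repeats. Candidate repeat lengths come from
exact 16-mer seeds taken at four offsets in the prefix and located in the
3' half, so up to three seed-spanning mismatches are tolerated without an
O(n²) scan; each candidate is then verified by a full vectorized Hamming
count. Ties resolve to the longest qualifying repeat. The inverted-repeat
variant (prefix vs reverse-complemented suffix, a mis-assembly diagnostic)
reduces to a shift-free longest-qualifying-prefix scan. Detection is
invariant under reverse-complementing the genome.

`locate_dtr_by_reference` finds all placements of a known repeat in a
related genome by repeated semi-global alignment (edlib) with masking,
keeping hits at ≥ 70% identity covering ≥ 80% of the reference — the
identity range observed between DTRs of related podophages. With
`circular=True` the search wraps the origin, which matters when a
circularly permuted assembly happens to be cut inside the repeat.
`reorient_to_dtr` rotates the sequence so the repeat 5' end is position
zero and appends the leading repeat copy at the 3' end unless one is
already there; annotations are re-coordinated and features that would wrap
the new origin are dropped. `termini_from_alignments` standardizes
per-position alignment-start counts against a uniform null (mean N/L,
Poisson spread) and reports positions with z ≥ 6, merged within 5 bp —
physical termini produce start pileups because fragments cannot extend
past the genome end.

## Read recruitment

Cleaning trims each read end up to the first base with quality ≥ 20, then
drops reads with mean quality < 20 or length < 30. Library size is the
total base count *after* cleaning — the denominator consistent with what
was actually mapped.

The built-in aligner indexes every reference 15-mer, votes seeds into
(genome, diagonal) buckets on both strands, and verifies the strongest
candidates by banded semi-global alignment (edlib, free end-gaps in a
reference window padded by 16 bp). One primary alignment per read; ties
break to the lexicographically smallest genome id, then leftmost position,
then + strand. Multi-mapping rescue, paired-end logic and competitive host
mapping are out of scope; external mappers can be used instead via SAM
ingestion, which produces bit-identical `AlignmentRecord`s for the same
alignments.

Recruitment filters alignments at the identity cutoff, accumulates
per-position depth over the reference span of passing alignments, and
derives breadth (fraction of positions with depth ≥ 1), presence
(breadth ≥ 0.75, inclusive), per-Gb abundance (aligned bases / genome
length / library Gb, with aligned bases counted on the reference with
multiplicity), and a percent-of-library column as an alternative
normalization. Raising the identity cutoff can only shrink the passing
set, so breadth and abundance are monotone in the cutoff by construction;
the suite asserts it empirically across random samples.

## Protein families

Pairwise scores are Smith–Waterman local alignments under BLOSUM62 with
BLAST-convention gap costs (a gap of length g costs 11 + g); bit scores
and e-values use the standard gapped Karlin–Altschul constants λ = 0.267,
K = 0.041 with raw m×n search space (no length adjustment — only edges
near the cutoffs are affected and the cutoffs are configurable). Edges
must pass e-value ≤ 1e-5 *and* bitscore ≥ 50; isolated proteins survive as
singletons.

Markov clustering: self-loops at the node's maximum incident weight,
column-stochastic normalization, then alternating expansion (matrix
square) and inflation (elementwise power 2, renormalize, prune < 1e-12)
until the maximum elementwise change is < 1e-6 or 100 iterations (the
result then carries a non-converged flag). Clusters are the connected
structures of the converged flow matrix; they can never span disconnected
graph components, and the partition is invariant under protein relabeling.

## Terminator scanning

Candidates are hairpins with stem 4–20 bp, at most one mismatched rung,
loop 4–12 nt, and a T-tract of ≥ 3 within 8 bp downstream of the stem on
the scanned strand. The ΔG surrogate is a simplified nearest-neighbor
*stacking* model: each stack of two adjacent paired rungs contributes the
strength of its weaker rung — G:C 3.3, A:T 1.1, G:U wobble 0.0 kcal/mol —
minus 4.0 for loop initiation, 1.0 per loop base beyond four, and 3.0 per
mismatched rung (which also breaks stacking). Calls require |ΔG| ≥ 10.5
kcal/mol, the conventional magnitude cutoff for terminator screens. The
planted cassette scores 11 × 3.3 − 4.0 = 32.3 kcal/mol.

The stacking form, rather than a per-rung sum, is what makes the scanner
specific: in random DNA at G+C 0.47 a per-rung model with comparable
constants admits tens of qualifying hairpins per 40 kb strand (any rung
pairs with probability ≈ 0.38), whereas demanding contiguous G:C-rich
stacks brings the background to ~0.2 calls per genome on
dinucleotide-shuffled controls while leaving the planted cassette at three
times the threshold. All constants live in `TerminatorModel`. This is a
transparent surrogate sharing the decision rule of thermodynamic
predictors, not a Turner-rule folding engine; absolute ΔG values should
not be compared against RNAfold outputs. Opposite-strand calls whose
hairpins lie within 60 bp merge into one bidirectional call at the
midpoint of the two hairpin extents, keeping the stronger partner's
statistics.

## Genome distances and clustering

Contigs shorter than 34 kb (about 85% of a complete reference genome) are
treated as incomplete and dropped before distance analysis; the boundary
is inclusive (exactly 34,000 bp is retained). Fragment-ANI tiles each
genome into non-overlapping 1020 bp windows, places each window in the
other genome by seed-and-extend (13-mer seeds, both strands), keeps
fragments at ≥ 30% identity, and averages the two directions. It is a
point-estimate surrogate for BLAST-based intergenomic distances — adequate
at ANI scale (a 0.4% diverged pair measures 99.6% identity to within the
binomial noise), with no bootstrap replicates.

F-linkage clustering starts from singletons and repeatedly merges the
cluster pair with the highest link fraction (share of inter-cluster
distances ≤ the threshold) while that fraction is ≥ F. Ties resolve first
to the smallest maximum inter-cluster distance, then to the smallest
member id; the distance tie-break is what makes F = 1 coincide exactly
with complete linkage cut at the threshold (verified against the SciPy
oracle), while F → 0+ reproduces single linkage (threshold-graph
components). The default species threshold (distance 0.05) is a
configurable placeholder, not a universal constant.

## Problem sizes used by the test suite and acceptance script

Simulated benchmarks use the generator defaults (40 kb genomes, G+C 0.47,
170 bp DTRs) with: a two-member 7:3 community at 30× aggregate depth and
1% substitution error for abundance recovery; 20 (suite) / 10 (script)
single-genome samples at 4× depth for cutoff monotonicity; 100 (suite) /
50 (script) genomes for DTR and terminator recovery with an equal number
of dinucleotide-shuffled controls; 50–100 random 8-genome matrices for the
linkage oracles; and 3 × 5 protein families of 120 residues at 25%
divergence for Markov clustering. These sizes give the concentration the
assertions rely on (binomial standard errors well inside the stated
tolerances) while keeping a full run on one core in the low minutes.

## Known limitations

- Passing synthetic benchmarks demonstrates the statistics and algorithms,
  not robustness to real library artifacts (adapter chimeras, strand bias,
  uneven coverage) or to repeat-rich genomes, where seed voting can place
  reads at paralogous loci.
- The terminus z-score rule is this package's own operationalization of
  read-structure evidence; long-read polymerase artifacts are not modeled.
- The ΔG surrogate ranks hairpins consistently but is not calibrated
  against experimental terminator efficiencies.
- Fragment-ANI underestimates similarity between genomes with large
  rearrangements relative to whole-genome alignment, and reports 0 for
  pairs below the seeding horizon (~30–40% divergence).
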