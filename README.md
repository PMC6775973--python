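# cobascan

Analysis toolkit for small linear marine phage genomes of the T7-like
(podovirus) type: genome terminus detection and reorientation, identity-
filtered metagenomic read recruitment with presence/abundance statistics,
protein-family clustering, rho-independent terminator scanning, and
genome-similarity clustering. A first-class synthetic-data module generates
phage genomes and mixed communities with planted ground truth, so the entire
chain is testable without any downloads.

## Who it is for, and what it computes

Environmental virologists who isolate or assemble ~40 kb phage genomes and
want to answer, reproducibly:

- **Where do the genome ends sit?** Linear T7-like phages carry short direct
  terminal repeats (DTRs, order 150–250 bp) at both ends. `termini` finds
  them by end-anchored prefix/suffix comparison, anchors a known DTR in
  related genomes down to ~70% nucleotide identity, and rotates circularly
  permuted assemblies so the DTR 5' end defines position zero. Alignment-
  start pileups (z-score against a uniform-start null) serve as independent
  terminus evidence. Inverted-repeat scanning is available as a diagnostic
  for mis-assembled ends, but never drives reorientation.
- **Is the phage present in a metagenome, and how abundant?** `recruitment`
  cleans reads (end trim at Q20, mean quality ≥ 20, length ≥ 30), aligns
  them by seed-and-extend, and applies the standard presence rule: a phage
  is *present* when ≥ 75% of its genome is covered by reads of ≥ 90%
  identity (both thresholds inclusive). Relative abundance is

      aligned bases / genome size (bases) / library size (Gb)

  computed per identity cutoff (e.g. 90/95/100% for enrichment profiling).
- **Which proteins form families?** `protein_clustering` builds the
  all-vs-all Smith–Waterman graph (BLOSUM62, gap 11/1, Karlin–Altschul
  e-values), keeps edges with e-value ≤ 1e-5 *and* bitscore ≥ 50, and
  partitions it with Markov clustering at inflation 2.
- **Where is the bidirectional terminator?** Cobavirus-type genomes are
  organized in two transcriptional arms separated by a bidirectional
  rho-independent terminator. `features` scans both strands for hairpins
  followed by a T-tract, scores them with a simplified nearest-neighbor
  stacking model, keeps calls with |ΔG| ≥ 10.5 kcal/mol, and pairs
  opposite-strand calls at one locus.
- **Which genomes are one species?** `distance` filters incomplete contigs
  (< 34 kb), computes fragment-based ANI, and clusters the distance matrix
  with OPTSIL-style F-linkage (fraction F of inter-cluster links must fall
  below the threshold; default F = 0.5).

## Worked example

```python
from cobascan import synthetic as sy, termini, features, recruitment as rec, distance

g1 = sy.simulate_genome(sy.GenomeSpec(seed=1))   # 40 kb, GC 0.47, 170 bp DTR
g2 = sy.simulate_genome(sy.GenomeSpec(seed=2))

dtr = termini.find_terminal_repeat(g1)
calls = features.pair_bidirectional(features.find_terminators(g1))

comm = sy.CommunitySpec(members=[(g1, 0.7), (g2, 0.3)],
                        total_bases=30 * (len(g1) + len(g2)),
                        subst_rate=0.01, seed=5)
reads, truth = sy.simulate_community(comm)
reports = rec.profile_sample(reads, [g1, g2],
                             recruit_params=rec.RecruitParams(0.90, 0.75),
                             skip_cleaning=True)
```

prints (via the obvious f-strings):

```
DTR: 170 bp, 0 mismatches, intervals (0, 170) / (39830, 40000)
bidirectional terminator at 20000, stem 12 bp, dG = -32.3 kcal/mol
sim1: breadth 0.999, abundance 17421 per Gb, present=True
sim2: breadth 0.999, abundance 7578 per Gb, present=True
```

The planted truth table reports 17421.9 and 7578.1 bases/base/Gb for the
two genomes, so the recruited abundances recover the planted 7:3 community
to within 0.01%. A genome diverged by 0.4% substitutions gives a fragment
identity of 99.65% — the scale at which two isolates form one species
cluster.

Every stage is also exposed on the command line:

```sh
cobascan simulate --seed 1 -o sim/
cobascan termini sim/genome.fasta --reorient -o termini/
cobascan recruit --genomes sim/genome.fasta --reads sim/reads.fastq \
    --alt-identities 0.95,1.0 -o recruit/
cobascan cluster-proteins proteins.faa -o pc/
cobascan terminators sim/genome.fasta -o term/
cobascan genome-dist genomes.fasta -o dist/
cobascan cluster-genomes dist/distances.phylip --threshold 0.05 --f-link 0.5 -o cl/
```

Each run writes a `config.json` provenance snapshot and a `run.log` next to
its outputs.

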