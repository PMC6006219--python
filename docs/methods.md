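# Methods

## The data-generating model

`mhchap` targets transcript-level genotyping of a copy-number-variable
MHC class I region with two locus groups, *A* and *B*.  The synthetic
cohort generator (`mhchap.synthetic_data`) encodes the assumed structure
explicitly; everything downstream is tested against its ground truth.

**Allele pool.**  Sequences are 1098-nt coding transcripts (366 codons, a
24-codon signal peptide, no internal stops, terminal stop omitted).  Each
locus group is organised in lineages: lineage founders diverge from a
per-locus ancestor by half the configured inter-lineage divergence
(default 0.06 substitutions/site, so founder pairs sit near 0.06), and
alleles within a lineage diverge from their founder by half the
intra-lineage divergence (default 0.005).  Substitutions are uniform
(Jukes–Cantor-consistent, matching the distance model used in analysis);
substitutions creating stop codons are rejected.  Defaults of 12 *A* and
35 *B* lineages with 1–2 alleles each were chosen to reproduce the
catalogue density seen in real baboon-type data — about 21 *A* sequences
over ~32 haplotype slots and ~80 *B* sequences over ~80 slots — so the
frequency with which one allele recurs on several haplotypes (and inside
one animal's diplotype) is realistic rather than convenient.  One *A*
lineage is designated minor (the *A\*14*-like pattern: low diversity, low
transcription, present on many haplotypes); 60% of *B* lineages are
minor.  The mature-position 77–83 window can be planted per lineage with
`NLRIALR` (Bw4), `SLRNLRG` (Bw6), `NLRNLRG` (canonical Bw6) or left
non-motif; the window is excluded from mutation so the planted class is a
lineage property.  Bw4 defaults to frequency 0 — the system this emulates
shows none.  Two pseudogene transcripts are built by deleting one
nucleotide inside the exon-2 region of a *B* allele (frameshift plus
premature stop).

**Haplotypes and cohort.**  A haplotype carries 1–3 *A* genes (1–2
majors; absent entirely with probability 0.05), 3–7 *B* genes (at least
one major), pseudogenes with probability 0.10, and a linked STR
signature: 1–4 D6S2854 lengths (grid 180–260, step 2) and 0–2 D6S2859
lengths (140–180); STR lengths may collide across haplotypes (homoplasy).
The default cohort holds 10 haplotypes and 40 animals: 10 founders
drawing diplotypes uniformly, then two generations of 15 offspring.  Dams
are bred round-robin and sires drawn at random, the usage pattern of a
managed breeding colony (many dams, fewer, reused sires).  Per meiosis,
with probability 0.02 each, the transmitted haplotype is an A/B-block
swap or a within-B exchange of the parent's two haplotypes ("patchwork"
haplotypes; the STR signature travels with the *A* block).  The simulated
within-B event keeps ≥ 2 and drops ≥ 2 genes of a ≥ 4-gene block — the
content signature of a crossover between interior B loci; smaller blocks
exchange what they can.  15% of offspring list a second candidate sire.
Reads: 450 per animal, multinomial over carried transcripts with weight 1
(majors) or 0.05 (minors and pseudogenes — the data give no quantitative
anchor for "low transcription"; 0.05 is a modelling choice), independent
per-base substitution errors at 0.002, random orientation, full
transcript or a fixed 755-nt exon 2–3 window depending on platform.
Chimeric reads are not simulated (hook present, off).  All draws flow
from the mandatory seed; identical seeds give identical cohorts
byte-for-byte.

What the generator does *not* emulate: platform error profiles
(homopolymer indels, CCS pass-number effects), primer bias and allele
dropout, chimera formation, or population-level haplotype frequency
structure.  Passing tests therefore demonstrate the pipeline's logic
under the stated model, not robustness to those artefacts.

## Allele discovery

Orientation is normalized by the canonical form (lexicographic minimum of
a sequence and its reverse complement) — deterministic and symmetric.
"100% identity" against a database holding partial entries is interpreted
as exact containment of the shorter sequence in the longer; a read
matching several entries is counted 1/k to each, flagged ambiguous.  The
900–1200 bp size window is closed on both ends.  Clustering pools
residual reads across samples (each member keeps its sample), mirroring
the combined-pool workflow; the full-length rule keeps clusters of ≥ 3
identical reads, the exon 2–3 rule ≥ 10 reads with both orientations
present ("ten times" is read as ≥ 10 total with both directions seen, an
interpretation, since per-direction counts are not specified).  Accepted
candidates containing a known partial entry as an exact substring are
labelled extensions of the longest such entry.  Pseudogene status is
called from frame disturbance: length ≢ 0 mod 3, or a stop before the
(reference) CDS end.  Expression classes are per sample and locus: major
iff count ≥ τ × the locus maximum, τ = 0.10 by default (exposed; the
source data quantify "low transcription" only qualitatively).  Lineage
assignment of novels is nearest-neighbour by p-distance with a 0.02
membership threshold (exposed, reported as provisional); loci tied at
equal distance are left unassigned for review.  Quality scores are never
used: both rule sets are pure sequence-identity rules.

**Known limitation (by construction):** with per-base error ε and read
length L, only e^(−εL) of reads are error-free (≈ 11% at ε = 0.002,
L = 1098), and at per-allele depths of several hundred to a few thousand
reads the number of ≥ 3-read clusters sharing the *same* single-base
error — Σ C(0.24 n, 3)/(3L)² per allele — exceeds 1.  Identity clustering
plus a fixed read-support threshold therefore *will* emit error-collision
artifacts at high depth; the real workflow removes them by manual
validation, which is out of scope here and deliberately not replaced by a
heuristic filter (any distance-based shadow filter would also delete true
1-nt novel alleles).  `scripts/acceptance.py` reports the measured
false-novel rate instead of hiding it.

## Co-segregation phasing (STR and A–B haplotypes)

Observations are presence sets (no dosage: capillary STR patterns carry
none, and NGS read counts are expression-confounded, so they are not used
as copy-number evidence).  The model: every animal is the union of two
haplotypes; every non-founder received one haplotype of its dam and one
of a candidate sire, unchanged; the catalogue should be minimal
(parsimony — the same objective an analyst applies manually).

The solver (`mhchap._phasing`) works in four stages:

1. every animal owns two chromosome slots; transmission ties a child slot
   to one parental slot, merging slots into equivalence classes
   (union-find), each class one transmitted haplotype H with interval
   bounds lower ⊆ H ⊆ upper (upper = intersection of carriers'
   observations);
2. propagation to fixpoint: items absent from the partner slot's upper
   bound are forced into a slot's lower bound; transmissions and sire
   choices with a single consistent option are fixed; a homozygous class
   must equal the observation;
3. depth-first search over remaining transmission choices (deterministic
   ordering, node cap 20 000, up to 256 complete linkage states);
4. per complete state, classes are merged across families into a minimal
   catalogue (exact set-partition search per compatibility component up
   to 9 classes, greedy beyond), and left-over ambiguous items are placed
   by a small exact search that minimises catalogue size, then total
   content, then a lexicographic key.  Marker-cardinality bounds (≤ 4
   D6S2854, ≤ 2 D6S2859 per haplotype) act as validity constraints in the
   STR instantiation.

Animals whose observation cannot be explained are flagged, never forced;
an infeasible family raises a Mendelian-inconsistency error naming it; in
`allow_detach` mode the offending transmission is detached and surfaced
as a recombination suspect instead.  Ties among co-optimal catalogues are
broken canonically and counted (`n_optimal`), since the manual procedure
for choosing among equally parsimonious catalogues has no stated rule.
An independent checker (`check_solution`) verifies union and transmission
constraints of any proposed phasing from scratch; tests also compare
against a brute-force enumeration oracle on small instances.

**Identifiability.**  Exact catalogue recovery is impossible on some
cohorts: when an allele is shared between an animal's two haplotypes and
every other carrier pairs it with a partner that also carries it, the
parsimony optimum is not unique.  Two structural sources dominate at the
default conditions: haplotypes confined to a single founder, and the
minor-lineage *A* alleles present on many haplotypes.  On 20 default
cohorts the solver recovers the exact truth in ~15 and returns a
certified co-optimal alternative (consistent, same size) in the rest;
STR catalogues, whose length tokens rarely collide, are recovered
essentially completely (≥ 99%).

## Patchwork detection

Gene order within the B region is unknown from transcript data, so all
recombination calls are allele-content statements.  For a haplotype pair:
A/B recombinant iff one region is identical (non-empty) and the other
fully different; within-B recombinant iff ≥ `min_shared` B genes are
shared and ≥ `min_unique` are private on each side (defaults 2/2, chosen
so the canonical worked patterns — 3 shared/4 unique per side, and a pair
differing by one extra gene — classify as within-B and single-gene switch
respectively); single-gene switch (gene-conversion *candidate*) iff
exactly one allele differs overall.  Precedence: A/B > within-B >
single-gene switch.  Calls are symmetric and monotone in the thresholds.
At realistic allele-sharing density, unrelated haplotypes can satisfy the
within-B pattern by chance; calls are therefore candidates for
inspection, which is also why the zero-false-flag guarantee is only
stated for disjoint lineage pools.

## Motifs

Mature-protein numbering uses a configurable signal-peptide length
(default 24, the classical class I leader); the 77–83 window is
classified by exact string comparison only, and non-matching windows are
reported verbatim rather than fuzzily grouped.  Pseudogenes are skipped
(no stable frame).

## Distances and trees

Pairwise deletion removes positions where either sequence carries a gap
or IUPAC ambiguity, per sequence pair.  Jukes–Cantor:
d = −¾ ln(1 − 4/3 p), saturation (p ≥ ¾) is an error, not infinity.
Nei–Gojobori (unweighted pathway): synonymous site counts per codon
averaged over the pair (changes to stops count as nonsynonymous);
synonymous differences averaged with equal weight over minimal
substitution pathways, pathways through stop codons excluded (the
classical convention; if all pathways are blocked the average falls back
to all of them); dS = −¾ ln(1 − 4/3 pS).  Stop codons in the input are an
error — inputs are CDS without the terminal stop.  Neighbour joining uses
the standard Q criterion with ties broken on the lexicographically
smallest pair of node labels (a node is labelled by its smallest leaf),
making output deterministic; negative branch lengths are clamped to zero
with a warning; on additive matrices path lengths reproduce the input to
< 1e-9.  Maximum-likelihood tree search and bootstrap are deliberately
out of scope — lineage structure is served by distances, NJ and
single-linkage clustering at a threshold θ (components of the d ≤ θ
graph).

## Problem sizes

Stochastic checks in the test suite and `scripts/acceptance.py` use
20 replicate cohorts of the default configuration (10 haplotypes, 40
animals, 450 reads/animal) per quantity, 10 random additive matrices of
4–8 taxa for NJ, and 100–200 random CDS pairs of ≤ 30 codons for the
synonymous-distance oracle; the complete acceptance run finishes in
about half a minute.
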