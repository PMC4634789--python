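# Methods

## The evaluation model

`cladeval` scores read-level taxonomic classification against a known mock
community. The unit of evidence is a single read with a known source genome
and species; the unit of reporting is a genome (averaged unweighted) or the
pooled read set.

**Path rule.** An assignment to taxonomy node *a* for a read whose true
species is *s* is correct iff *a* lies on the path from *s* to the root
(through the superkingdom). Membership is tested on the *full* lineage,
including non-canonical ("no rank") nodes, so an assignment to an
intermediate clade such as a species group is correct. Assignments strictly
below *s* (strains of the truth organism) are projected up to *s* first and
count as correct. Truth organisms given as strains are likewise projected to
their species before scoring.

**Counts and metrics.** Per genome: TP = reads assigned on-path, FP =
assigned off-path, FN = unassigned (including reads the classifier dropped
from its output). Sensitivity = TP/(TP+FN), precision = TP/(TP+FP).
TP+FP+FN always equals the number of truth reads.

**Rank ladder and taxonomic distance.** The canonical ladder is species=0,
genus=1, family=2, order=3, class=4, phylum=5, superkingdom=6. Non-canonical
nodes are invisible to the ladder: every node projects to its nearest
canonical ancestor (a strain to its species; a node with no canonical
ancestor to a sentinel index 7, one above superkingdom). For a TP read,
taxonomic distance = max(0, ladder index of the assignment − best possible
rank index). Under clade exclusion at rank *r* the best possible rank index
is index(*r*)+1; without exclusion it is 0. The clamp at 0 matters in one
edge case: a classifier that emits the correct species taxid even though
species is excluded is on-path and scores distance 0, not −1. We also count
such reads as TP in strict mode (the path rule is applied literally), a
convention this harness fixes explicitly because it is ambiguous in parts of
the literature.

**Aggregation.** `per_genome_mean` averages sensitivity, precision and
distance unweighted over genomes, so species with larger genomes (hence more
reads) do not dominate. Per-genome precision is undefined when TP+FP = 0
(nothing assigned) and distance when TP = 0; undefined genomes are excluded
from the corresponding mean and their count is reported in the summary.
Averaging zeros instead would conflate "conservative" with "wrong". A genome
whose reads were all mis-assigned has sensitivity 0 by convention
(TP = FN = 0 cannot arise otherwise, since FN collects the unassigned).

**Pooled mode.** In vitro mock communities have no per-read source labels,
so all reads are scored jointly and an assignment on the truth path of *any*
community member is correct. Distance needs no per-member choice: it depends
only on the assignment's ladder index and the best possible rank, so the
"most generous member" tie-break is vacuous and the pooled distance is the
mean over TP reads.

**Overpredictions-as-correct.** With this mode on, an off-path assignment is
reclassified TP iff its canonical ancestor at the best possible rank exists
and equals the truth lineage's node at that rank (wrong species, right
genus, under species exclusion). This can only add TPs, so sensitivity and
precision are non-decreasing in the flag — a property the tests assert.
Rank-specific classifiers (which emit one fixed rank for all reads) should
be evaluated only in this mode; strict scoring penalizes them for rank
choices they cannot make.

**Rank distribution.** The proportion of reads assigned at each canonical
rank is reported against two denominators — assigned reads and all reads —
because published figures are ambiguous about which is meant; unassigned
reads are reported as a separate fraction of all reads.

## Clade exclusion

Exclusion at rank *r* for truth taxon *t* removes every reference genome
whose lineage contains *t*'s ancestor at *r*. Membership is by lineage
(taxid) rather than name matching, so strain-labeled genomes are caught. A
genome whose own lineage skips rank *r* entirely can never contain that
ancestor; it is kept and a warning is logged. Removed sets nest as *r* rises
(species ⊆ genus ⊆ … ⊆ class) — property-tested. Excludable ranks stop at
class; phylum/superkingdom exclusion would leave no meaningful reference.
Merged or deleted taxids are not remapped: an unknown taxid is a hard error.

## Read simulator

Error-free single-end reads at fixed length and per-genome coverage:
per genome, n = round(coverage · L / read_length) reads (round half away
from zero), start positions uniform with replacement on [0, L − read_length],
strands equiprobable, reverse-strand reads reverse-complemented, bases
copied exactly. Reads never wrap a circular origin — negligible at 1X and a
simpler contract. The error-free choice mirrors how mock-community read sets
for classifier evaluation are generated when no length-consistent error
model exists; real-error robustness is what in vitro data is for. Default
study conditions follow that practice: 1X coverage per organism, read
lengths of 100/250/500/1000 bp all supported. FASTA is the native output
(no qualities exist); a FASTQ writer emits constant Q40 for tools that
require it.

## Mock communities and synthetic worlds

Two community profiles are packaged: `MetaSimHC` (11 genomes, Bacteria +
Archaea, a proposed "high complexity" reference set) and `FW` (a freshwater
community: 13 genomes, 11 distinct species, with three *P. aeruginosa*
strains and three congeneric *Pseudomonas* species to stress close
relatives). Profiles carry organism names, internal taxids resolving in a
hand-built companion taxonomy with full canonical ladders, intended coverage
(1X each), and real NCBI species taxids as metadata where unambiguous. No
genome sequences are bundled — users supply their own FASTA for these
organisms — which keeps the package self-contained and small.

`make_synthetic_world` generates fully self-contained test worlds: a
taxonomy with complete ladders (congeneric species pairs on request),
i.i.d. uniform-ACGT genomes, and a 1X community profile; byte-identical
under a fixed seed. Synthetic genomes deliberately carry no composition
signal: the harness tests *evaluation logic*, not classifier biology, so a
passing suite certifies the scoring machinery, not any claim about how real
classifiers perform on real sequences.

## Classifier simulator

Per read, independently: unassigned with probability `p_unassigned`; correct
with `p_correct`, at a canonical rank drawn from `rank_profile` (the truth
lineage's node at that rank, walking up if the lineage skips it); otherwise
misassigned by mode — `sibling_species` (random congeneric species; falls
back to `random_other_clade` with a logged warning when the genus has one
species), `random_other_clade` (random species outside the truth genus), or
`lca_of_confusion_set` (LCA of truth and a random sibling, typically the
genus — an on-path conservative call). Per-read independence is sufficient
for metric testing; correlated classifier errors are out of scope. Under
strict scoring with off-clade misassignment the closed-form expectations are
sensitivity = p_c/(p_c+p_u) and precision = p_c/(p_c+p_m); the test suite
recovers both within 99% binomial confidence intervals over 20 fixed seeds
(at most 2 of the 40 interval checks may miss — the a-priori allowance that
keeps a 99% interval check non-flaky while still binding).

## Overprediction tables

Each assigned read is attributed to a species by canonical projection
(strains up to species; genus-or-higher calls attribute to nothing).
Relative abundance divides by species-attributed reads, not all reads — a
documented choice, flagged in the table metadata, since the alternative
denominator is defensible. A species survives cutoff *c* iff its abundance
is ≥ *c* ("at least" semantics; table headers elsewhere sometimes print
"> x%", and the boundary convention is recorded in the output metadata).
Correct means the species is a community member at species rank exactly.
Genome-size-corrected abundance would remove the bias toward large genomes
but is intentionally not implemented.

## Numerical and testing choices

Problem sizes in the test and acceptance suites — 200 randomized scenarios
of ≤500 reads for oracle equivalence, 10,000 reads × 20 seeds for parameter
recovery, 50 seeds for the coverage calibration — were chosen as the
smallest sizes at which the statistical checks are well-powered; everything
runs in seconds. The oracle is an independent, deliberately naive per-read
re-derivation of the scoring rules operating on raw parent dictionaries,
kept in the test tree and never imported by the implementation. All
randomness flows through seeded `numpy` generators; identical seeds give
byte-identical outputs everywhere, including the CLI.

## Known limitations

* No NCBI merged/deleted taxid remapping; inputs must use a consistent
  taxonomy snapshot.
* No sequencing-error models, paired-end reads, or non-uniform abundance
  distributions in the simulator.
* Parsers cover the generic TSV and Kraken dialects only; other formats are
  pre-converted by the user.
* The harness does not run classifiers or build their databases (Kraken
  hashes, BLAST indexes); it prepares inputs and scores outputs.
* Synthetic worlds cannot detect classifier-side biases (GC content, genome
  repetitiveness, database composition); conclusions about real tools
  require real genomes and, ideally, an in vitro control.
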