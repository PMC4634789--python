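# cladeval

**Clade-exclusion evaluation of shotgun-metagenomics taxonomic classifiers.**

Most reads in a real metagenome come from organisms whose genomes are in no
reference database, yet classifiers are routinely benchmarked on reads drawn
from the very genomes they were trained on — which makes their accuracy look
artificially high. *Clade exclusion* fixes this: before classification, every
reference genome belonging to the truth organism's clade at a chosen rank
(species, genus, family, order, or class) is removed, and the classifier is
scored on its ability to place reads correctly at the ranks that remain
achievable. `cladeval` is a library and CLI for running such evaluations
end-to-end against mock communities — simulated *in silico* or sequenced
*in vitro* — without ever running a classifier itself: it prepares the pruned
references and ground truth, and scores whatever read→taxid output a
classifier produces.

It is written for bioinformaticians who benchmark or develop taxonomic
classifiers, and for researchers who want to calibrate abundance-filtering
thresholds against a mock-community control.

## The scoring model

Each read carries a true species *s*. An assignment to node *a* of the
taxonomy is

* **TP** if *a* lies anywhere on the path from *s* to the superkingdom
  (strains below *s* project up to *s*),
* **FP** if assigned off that path,
* **FN** if the read is unassigned (reads a classifier silently drops count
  here too).

From per-genome counts,

```
sensitivity = TP / (TP + FN)        precision = TP / (TP + FP)
```

and for TP reads the **taxonomic distance** is the number of canonical-rank
steps (species=0 … superkingdom=6) the assignment sits above the *best
possible rank* — the rank just above the exclusion level (species when
nothing is excluded). Metrics are averaged **unweighted across genomes**, so
species with larger genomes (more reads) do not dominate; for in vitro data,
where reads cannot be attributed to a source genome, a **pooled** mode scores
all reads jointly and accepts a hit to any community member as correct.

An optional *overpredictions-as-correct* mode rescues assignments that are
too specific but right at the best possible rank (wrong species, correct
genus, under species exclusion) — the two conventions found in the
literature, both supported so methods can be compared under either.

## Worked example

```python
from cladeval import (ClassifierModel, EvalConfig, ExclusionSpec, evaluate,
                      make_synthetic_world, simulate_classifier, simulate_reads)

world = make_synthetic_world(n_species=6, n_congeneric_pairs=3,
                             genome_length_range=(20_000, 30_000), seed=7)
_, truth = simulate_reads(world, read_length=100, coverage=1.0, seed=8)
model = ClassifierModel(p_unassigned=0.1, p_correct=0.7,
                        misassignment_mode="sibling_species", seed=9)
assignments = simulate_classifier(truth, world.taxonomy, model)

spec = ExclusionSpec(world.community.members[0].taxid, "species")
for overpred in (False, True):
    r = evaluate(assignments, truth, world.taxonomy,
                 EvalConfig(exclusion=spec, overpredictions_correct=overpred))
    s = r.summary()
    print(f"overpredictions_correct={overpred}: "
          f"sensitivity={s['sensitivity']:.3f} precision={s['precision']:.3f} "
          f"taxonomic_distance={s['taxonomic_distance']:.3f}")
```

prints

```
overpredictions_correct=False: sensitivity=0.892 precision=0.788 taxonomic_distance=0.000
overpredictions_correct=True: sensitivity=0.913 precision=1.000 taxonomic_distance=0.000
```

The classifier was programmed to leave 10% of reads unassigned, place 70%
on the correct species, and put 20% on a congeneric sibling. Strict scoring
recovers sensitivity ≈ 0.7/(0.7+0.1) = 0.875 and precision ≈ 0.7/0.9 = 0.778;
because every mistake was congeneric, reclassifying overpredictions as
correct lifts precision to exactly 1.0. The `examples/` directory has one
short script per capability (communities, read simulation, exclusion,
closed-loop evaluation, overprediction tables).

## Command line

The same pipeline from a shell, each step writing standard formats plus a
`run_metadata.json` provenance record:

```bash
cladeval make-world --n-species 5 --seed 1 --outdir world/
cladeval simulate-reads --genomes world/genomes.fasta --mapping world/mapping.tsv \
         --read-length 250 --coverage 1.0 --seed 2 --outdir reads/
cladeval exclude --genomes world/genomes.fasta --mapping world/mapping.tsv \
         --taxonomy world/taxonomy.tsv --truth-taxid 30 --rank genus --outdir pruned/
cladeval simulate-classifier --truth reads/truth.tsv --taxonomy world/taxonomy.tsv \
         --p-correct 0.8 --seed 3 --out assignments.tsv
cladeval evaluate --assignments assignments.tsv --truth reads/truth.tsv \
         --taxonomy world/taxonomy.tsv --outdir eval/
cladeval species-report --assignments assignments.tsv --taxonomy world/taxonomy.tsv \
         --mapping world/mapping.tsv --outdir report/
```

Real classifier output is consumed either as a generic two-column TSV
(`read_id<TAB>taxid`, `0`/`U` = unassigned) or as Kraken's standard
five-column output (`--kraken`). Taxonomies load from NCBI taxdump
(`nodes.dmp`/`names.dmp`) or a simple 4-column TSV
(`taxid<TAB>parent<TAB>rank<TAB>name`).

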