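"""Predicted-species table with relative-abundance cutoffs.

A noisy classifier that sprays a small fraction of reads across the whole
taxonomy predicts many spurious species at very low abundance. Counting the
correct and incorrect species that survive increasing abundance cutoffs shows
how low-abundance filtering suppresses overprediction without (at moderate
cutoffs) losing true community members.
"""

from cladeval import (
    ClassifierModel,
    CommunityProfile,
    apply_cutoffs,
    make_synthetic_world,
    simulate_classifier,
    simulate_reads,
    species_table,
)

world = make_synthetic_world(n_species=12, n_congeneric_pairs=4,
                             genome_length_range=(10_000, 15_000), seed=11)
# restrict the "community" to 6 of the 12 species: the other 6 play the role
# of reference species that exist in the database but not in the sample
community = CommunityProfile("half", world.community.members[:6])

_, truth = simulate_reads(
    {m.genome_id: world.genomes[m.genome_id] for m in community.members},
    read_length=100, coverage=1.0, seed=12,
    genome_taxids={m.genome_id: m.taxid for m in community.members},
)
model = ClassifierModel(p_unassigned=0.05, p_correct=0.8,
                        misassignment_mode="random_other_clade", seed=13)
assignments = simulate_classifier(truth, world.taxonomy, model)

table = species_table(assignments, world.taxonomy, community)
print(f"{len(table)} species predicted from a {len(community)}-species community "
      f"({table.n_correct} correct, {table.n_incorrect} spurious)")
print(table.df.to_string(index=False))

counts = apply_cutoffs(table, [0.0, 0.0001, 0.001, 0.01])
print("\nspecies surviving each relative-abundance cutoff (>= cutoff):")
print(counts.to_string(index=False))
# The incorrect column shrinks as the cutoff rises: spurious species sit at
# low abundance, so a mild threshold removes most of them.
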