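"""Exclude a truth taxon's clade from a reference at increasing ranks.

Species-level exclusion of Pseudomonas aeruginosa removes its three strain
genomes from the FW reference; genus-level exclusion additionally removes
P. fluorescens and P. putida. Removed sets nest as the rank rises, and the
"best possible rank" a classifier can then be correct at rises with them.
"""

from cladeval import ExclusionSpec, builtin_community, exclude_clade

profile, taxonomy = builtin_community("FW")
reference = [(m.genome_id, m.taxid) for m in profile.members]
pao1 = next(m.taxid for m in profile.members
            if m.organism_name == "Pseudomonas aeruginosa PAO1")

for rank in (None, "species", "genus", "family"):
    spec = ExclusionSpec(truth_taxid=pao1, exclusion_rank=rank)
    kept, removed = exclude_clade(reference, taxonomy, spec)
    print(f"exclusion={str(rank):8s} best_possible_rank_index="
          f"{spec.best_possible_rank_index}  kept={len(kept):2d} removed={len(removed):2d}"
          f"  [{', '.join(g for g, _ in removed) or '-'}]")
# With species exclusion the best a classifier can do for P. aeruginosa reads
# is the genus Pseudomonas (rank index 1); taxonomic distance is measured
# from that rank.
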