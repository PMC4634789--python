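"""Inspect the two packaged mock communities and their toy taxonomies.

MetaSimHC spans Bacteria and Archaea with 11 diverse genomes; FW is a
freshwater community of 11 species over 13 genomes (Pseudomonas aeruginosa in
triplicate) with deliberately congeneric members.
"""

from cladeval import builtin_community

for name in ("MetaSimHC", "FW"):
    profile, taxonomy = builtin_community(name)
    print(f"\n{name}: {profile.n_genomes} genomes, "
          f"{profile.n_species(taxonomy)} distinct species, "
          f"taxonomy of {len(taxonomy)} nodes")
    for m in profile.members:
        lineage = " > ".join(
            n.name for n in taxonomy.lineage(m.taxid) if n.rank in ("superkingdom", "genus")
        )
        print(f"  {m.organism_name:45s} taxid={m.taxid:<4d} ({lineage})")

# Each genome is listed at 1X intended coverage; the three P. aeruginosa
# strains collapse to one species, which is why FW counts 11 species.
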