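"""Simulate error-free shotgun reads from a synthetic world.

Per genome the read count is round(coverage * length / read_length), so a
10-20 kb genome at 1X coverage and 250 bp reads yields 40-80 reads; every
read is an exact substring (or reverse complement) of its source genome.
"""

from cladeval import make_synthetic_world, reads_per_genome, simulate_reads

world = make_synthetic_world(n_species=11, n_congeneric_pairs=1,
                             genome_length_range=(10_000, 20_000), seed=42)
reads, truth = simulate_reads(world, read_length=250, coverage=1.0, seed=43)

print(f"{len(world.genomes)} genomes -> {len(reads)} reads of 250 bp at 1X")
for gid, seq in sorted(world.genomes.items())[:3]:
    n = (truth.df["genome_id"] == gid).sum()
    print(f"  {gid}: {len(seq)} bp -> {n} reads "
          f"(= round(1.0 * {len(seq)} / 250) = {reads_per_genome(1.0, len(seq), 250)})")

fwd = (truth.df["strand"] == "+").mean()
print(f"forward-strand fraction: {fwd:.3f} (both strands equiprobable)")
# The truth sidecar (read_id, genome_id, taxid, start, strand) is the ground
# truth every downstream evaluation is scored against.
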