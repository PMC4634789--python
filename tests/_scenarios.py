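"""Randomized read-scoring scenarios shared by the unit and acceptance suites."""

from __future__ import annotations

import numpy as np
import pandas as pd

from cladeval.assignment_io import AssignmentSet
from cladeval.read_sim import ReadTruthSet

from ._random_trees import random_taxonomy


def random_scenario(rng: np.random.Generator, max_reads: int = 500):
    """A random taxonomy plus reads with arbitrary assignments (any node of the
    tree, or unassigned). Returns (raw tree, Taxonomy, truth, assignments)."""
    raw, taxonomy, species, leaves = random_taxonomy(
        rng, n_species=int(rng.integers(3, 9))
    )
    n_reads = int(rng.integers(20, max_reads + 1))
    all_ids = list(raw)
    rows = []
    assignments: dict[str, int | None] = {}
    for i in range(n_reads):
        leaf_idx = int(rng.integers(len(leaves)))
        truth_taxid = int(leaves[leaf_idx])
        genome_id = f"g{leaf_idx}"
        read_id = f"{genome_id}_r{i}"
        rows.append((read_id, genome_id, truth_taxid, 0, "+"))
        u = rng.random()
        if u < 0.15:
            assignments[read_id] = None
        else:
            assignments[read_id] = int(all_ids[rng.integers(len(all_ids))])
    truth = ReadTruthSet(pd.DataFrame(
        rows, columns=["read_id", "genome_id", "taxid", "start", "strand"]
    ))
    return raw, taxonomy, truth, AssignmentSet(assignments, source_label="random")
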