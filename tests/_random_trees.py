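"""Seeded random taxonomies for property tests.

Trees are built layer by layer down the canonical ladder, with optional
"no rank" nodes spliced between layers and strain nodes below species —
the irregularities real NCBI trees have.
"""

from __future__ import annotations

import numpy as np

from cladeval.taxonomy import TaxNode, Taxonomy

LAYERS = ["superkingdom", "phylum", "class", "order", "family", "genus", "species"]


def random_taxonomy(
    rng: np.random.Generator,
    n_species: int = 8,
    p_no_rank: float = 0.2,
    p_strain: float = 0.3,
) -> tuple[dict[int, tuple[int, str]], Taxonomy, list[int], list[int]]:
    """Returns (raw taxid -> (parent, rank), Taxonomy, species taxids, leaf taxids).

    Leaf taxids are what truth organisms are drawn from: the species or, where
    present, a strain below it.
    """
    raw: dict[int, tuple[int, str]] = {1: (1, "no rank")}
    names: dict[int, str] = {1: "root"}
    next_id = 2

    def add(parent: int, rank: str, name: str) -> int:
        nonlocal next_id
        raw[next_id] = (parent, rank)
        names[next_id] = name
        next_id += 1
        return next_id - 1

    layer_nodes = [1]
    for depth, rank in enumerate(LAYERS):
        if rank == "species":
            n = n_species
        else:
            n = int(rng.integers(1, min(3 + depth, n_species) + 1))
        new_layer = []
        for i in range(n):
            parent = int(layer_nodes[rng.integers(len(layer_nodes))])
            if rng.random() < p_no_rank:
                parent = add(parent, "no rank", f"clade_{rank}_{i}")
            new_layer.append(add(parent, rank, f"{rank}_{i}"))
        layer_nodes = new_layer

    species = list(layer_nodes)
    leaves = []
    for sp in species:
        if rng.random() < p_strain:
            leaves.append(add(sp, "strain", f"{names[sp]}_strain"))
        else:
            leaves.append(sp)

    taxonomy = Taxonomy(
        TaxNode(t, raw[t][0], raw[t][1], names[t]) for t in raw
    )
    return raw, taxonomy, species, leaves
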