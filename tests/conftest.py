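import pytest

from cladeval.taxonomy import TaxNode, Taxonomy

# Toy tree: Proteobacteria down to two Pseudomonas species + E. coli, with a
# strain node below P. aeruginosa. Used across modules.
TOY_NODES = [
    (1, 1, "no rank", "root"),
    (2, 1, "superkingdom", "Bacteria"),
    (3, 2, "phylum", "Proteobacteria"),
    (4, 3, "class", "Gammaproteobacteria"),
    (5, 4, "order", "Pseudomonadales"),
    (6, 5, "family", "Pseudomonadaceae"),
    (7, 6, "genus", "Pseudomonas"),
    (8, 7, "species", "Pseudomonas aeruginosa"),
    (9, 7, "species", "Pseudomonas fluorescens"),
    (10, 4, "order", "Enterobacteriales"),
    (11, 10, "family", "Enterobacteriaceae"),
    (12, 11, "genus", "Escherichia"),
    (13, 12, "species", "Escherichia coli"),
    (14, 8, "strain", "Pseudomonas aeruginosa PAO1"),
]

P_AERUGINOSA, P_FLUORESCENS, E_COLI, PAO1 = 8, 9, 13, 14
PSEUDOMONAS, GAMMA = 7, 4


@pytest.fixture(scope="session")
def toy_taxonomy() -> Taxonomy:
    return Taxonomy(TaxNode(*row) for row in TOY_NODES)


@pytest.fixture(scope="session")
def toy_raw() -> dict[int, tuple[int, str]]:
    """The same tree as raw taxid -> (parent, rank) pairs, for oracles."""
    return {t: (p, r) for t, p, r, _ in TOY_NODES}
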