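"""Mock-community definitions and fully synthetic test worlds.

Two classic benchmark communities ship with the package as metadata-only
profiles with hand-built companion taxonomies:

* ``MetaSimHC`` — 11 diverse microbial genomes spanning several phyla of both
  Bacteria and Archaea, proposed as a "high complexity" reference set for
  classifier evaluation.
* ``FW`` — a freshwater community of 11 bacterial species (13 genomes: three
  Pseudomonas aeruginosa strains), deliberately containing congeneric species
  (three Pseudomonas) so that classifiers are stressed by close relatives.

No genome sequences are bundled; the profiles carry organism names, internal
taxids that resolve in the companion toy taxonomy, and real NCBI species
taxids as metadata where unambiguous. Users point the read simulator at their
own FASTA downloads, or use :func:`make_synthetic_world` for a fully
self-contained world of random genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .taxonomy import CANONICAL_RANKS, TaxNode, Taxonomy


@dataclass(frozen=True)
class CommunityMember:
    """One genome of a mock community."""

    genome_id: str
    organism_name: str
    taxid: int
    intended_coverage: float = 1.0
    genome_length: int | None = None
    #: real NCBI species-level taxid, metadata only (None when ambiguous)
    ncbi_species_taxid: int | None = None


@dataclass
class CommunityProfile:
    """The ground-truth composition of a mock community."""

    name: str
    members: list[CommunityMember]

    def __post_init__(self) -> None:
        ids = [m.genome_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ParameterError(f"duplicate genome_ids in community {self.name!r}")

    def __len__(self) -> int:
        return len(self.members)

    def member_taxids(self) -> list[int]:
        return [m.taxid for m in self.members]

    def species_taxids(self, taxonomy: Taxonomy) -> list[int]:
        """Distinct species-level taxids of the members (strains project up)."""
        seen: dict[int, None] = {}
        for m in self.members:
            sp = taxonomy.species_of(m.taxid)
            seen[sp.taxid if sp is not None else m.taxid] = None
        return list(seen)

    @property
    def n_genomes(self) -> int:
        return len(self.members)

    def n_species(self, taxonomy: Taxonomy) -> int:
        return len(self.species_taxids(taxonomy))


# --------------------------------------------------------------------------
# Built-in communities. Each row: (superkingdom, phylum, class, order, family,
# genus, species name, strain name, NCBI species taxid or None). Lineages follow
# the NCBI taxonomy of the era in which these communities were assembled.

_METASIMHC_ROWS = [
    ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rhizobiales", "Rhizobiaceae",
     "Agrobacterium", "Agrobacterium tumefaciens", "C58", 358),
    ("Bacteria", "Cyanobacteria", "Cyanophyceae", "Nostocales", "Nostocaceae",
     "Anabaena", "Anabaena variabilis", "ATCC 29413", None),
    ("Archaea", "Euryarchaeota", "Archaeoglobi", "Archaeoglobales", "Archaeoglobaceae",
     "Archaeoglobus", "Archaeoglobus fulgidus", "DSM 4304", 2234),
    ("Bacteria", "Proteobacteria", "Deltaproteobacteria", "Bdellovibrionales", "Bdellovibrionaceae",
     "Bdellovibrio", "Bdellovibrio bacteriovorus", "HD100", 959),
    ("Bacteria", "Proteobacteria", "Epsilonproteobacteria", "Campylobacterales", "Campylobacteraceae",
     "Campylobacter", "Campylobacter jejuni", "81-176", 197),
    ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae",
     "Clostridium", "Clostridium acetobutylicum", "ATCC 824", 1488),
    ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae",
     "Lactococcus", "Lactococcus lactis", "SK11", 1358),
    ("Bacteria", "Proteobacteria", "Betaproteobacteria", "Nitrosomonadales", "Nitrosomonadaceae",
     "Nitrosomonas", "Nitrosomonas europaea", "ATCC 19718", 915),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Pseudomonadaceae",
     "Pseudomonas", "Pseudomonas aeruginosa", "PAO1", 287),
    ("Bacteria", "Actinobacteria", "Actinobacteria", "Actinomycetales", "Streptomycetaceae",
     "Streptomyces", "Streptomyces coelicolor", "A3(2)", 1902),
    ("Archaea", "Crenarchaeota", "Thermoprotei", "Sulfolobales", "Sulfolobaceae",
     "Sulfolobus", "Sulfolobus tokodaii", "str. 7", 111955),
]

_FW_ROWS = [
    ("Bacteria", "Firmicutes", "Bacilli", "Bacillales", "Bacillaceae",
     "Bacillus", "Bacillus amyloliquefaciens", "FZB42", 1390),
    ("Bacteria", "Firmicutes", "Bacilli", "Bacillales", "Bacillaceae",
     "Bacillus", "Bacillus cereus", "ATCC 14579", 1396),
    ("Bacteria", "Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Burkholderiaceae",
     "Burkholderia", "Burkholderia cenocepacia", "J2315", 95486),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Enterobacteriales", "Enterobacteriaceae",
     "Escherichia", "Escherichia coli", "K-12", 562),
    ("Bacteria", "Actinobacteria", "Actinobacteria", "Actinomycetales", "Frankiaceae",
     "Frankia", "Frankia sp. CcI3", "CcI3", None),
    ("Bacteria", "Actinobacteria", "Actinobacteria", "Actinomycetales", "Micrococcaceae",
     "Micrococcus", "Micrococcus luteus", "NCTC 2665", 1270),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Pseudomonadaceae",
     "Pseudomonas", "Pseudomonas aeruginosa", "PAO1", 287),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Pseudomonadaceae",
     "Pseudomonas", "Pseudomonas aeruginosa", "UCBPP-PA14", 287),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Pseudomonadaceae",
     "Pseudomonas", "Pseudomonas aeruginosa", "PA7", 287),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Pseudomonadaceae",
     "Pseudomonas", "Pseudomonas fluorescens", "Pf-5", 294),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Pseudomonadaceae",
     "Pseudomonas", "Pseudomonas putida", "KT2440", 303),
    ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rhodobacterales", "Rhodobacteraceae",
     "Rhodobacter", "Rhodobacter capsulatus", "SB 1003", 1061),
    ("Bacteria", "Actinobacteria", "Actinobacteria", "Actinomycetales", "Streptomycetaceae",
     "Streptomyces", "Streptomyces coelicolor", "A3(2)", 1902),
]

_BUILTIN_ROWS = {"MetaSimHC": _METASIMHC_ROWS, "FW": _FW_ROWS}

_ROW_RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")


def _genome_id(species: str, strain: str) -> str:
    text = f"{species} {strain}"
    return "".join(c if c.isalnum() else "_" for c in text).strip("_")


def _build_community(name: str, rows) -> tuple[CommunityProfile, Taxonomy]:
    nodes: list[TaxNode] = [TaxNode(1, 1, "no rank", "root")]
    index: dict[tuple[str, str, int], int] = {}  # (rank, name, parent) -> taxid
    next_id = 2

    def intern(rank: str, node_name: str, parent: int) -> int:
        nonlocal next_id
        key = (rank, node_name, parent)
        if key not in index:
            index[key] = next_id
            nodes.append(TaxNode(next_id, parent, rank, node_name))
            next_id += 1
        return index[key]

    members: list[CommunityMember] = []
    for row in rows:
        *ladder, strain, ncbi = row
        parent = 1
        for rank, node_name in zip(_ROW_RANKS, ladder):
            parent = intern(rank, node_name, parent)
        species_name = ladder[-1]
        # avoid "Frankia sp. CcI3 CcI3": some species names already carry the strain
        full_name = species_name if species_name.endswith(strain) \
            else f"{species_name} {strain}"
        strain_taxid = intern("strain", full_name, parent)
        members.append(
            CommunityMember(
                genome_id=_genome_id(full_name, ""),
                organism_name=full_name,
                taxid=strain_taxid,
                intended_coverage=1.0,
                ncbi_species_taxid=ncbi,
            )
        )
    return CommunityProfile(name=name, members=members), Taxonomy(nodes)


def builtin_community(name: str) -> tuple[CommunityProfile, Taxonomy]:
    """A packaged mock-community profile and its companion toy taxonomy.

    ``name`` must be ``"MetaSimHC"`` or ``"FW"``. The profile lists each genome
    (strain-level) at an intended coverage of 1X; the taxonomy carries the full
    canonical ladder for every member.
    """
    try:
        rows = _BUILTIN_ROWS[name]
    except KeyError:
        raise ParameterError(
            f"unknown built-in community {name!r}; available: {sorted(_BUILTIN_ROWS)}"
        ) from None
    return _build_community(name, rows)


# --------------------------------------------------------------------------
# Synthetic worlds


@dataclass
class SyntheticWorld:
    """A self-contained test world: taxonomy + random genomes + community."""

    taxonomy: Taxonomy
    genomes: dict[str, str]
    community: CommunityProfile
    seed: int
    genome_taxids: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.genome_taxids = {m.genome_id: m.taxid for m in self.community.members}


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def make_synthetic_world(
    n_species: int = 11,
    n_congeneric_pairs: int = 1,
    genome_length_range: tuple[int, int] = (10_000, 20_000),
    seed: int = 0,
) -> SyntheticWorld:
    """Generate a random world: a taxonomy with full canonical ladders, one
    uniform-random genome per species, and a 1X community profile.

    ``n_congeneric_pairs`` of the species are placed into already-existing
    genera, so the world contains genera with >=2 species (the situation that
    makes species-level exclusion interesting). Genomes are i.i.d. uniform
    ACGT — they carry no composition signal on purpose; this harness tests
    evaluation logic, not classifier biology. Identical seed and parameters
    give byte-identical output.
    """
    if n_species < 1:
        raise ParameterError(f"n_species must be >= 1, got {n_species}")
    if not (0 <= n_congeneric_pairs <= n_species - 1):
        raise ParameterError(
            f"n_congeneric_pairs must be in [0, n_species-1], got {n_congeneric_pairs}"
        )
    lo, hi = genome_length_range
    if lo < 1000 or hi < lo:
        raise ParameterError(f"genome_length_range must satisfy 1000 <= lo <= hi, got {lo, hi}")

    n_genera = n_species - n_congeneric_pairs
    rng = np.random.default_rng(seed)

    nodes: list[TaxNode] = [TaxNode(1, 1, "no rank", "root"),
                            TaxNode(2, 1, "superkingdom", "Bacteria")]
    next_id = 3
    genus_taxids: list[int] = []
    ladder_above_genus = ("phylum", "class", "order", "family", "genus")
    for g in range(n_genera):
        parent = 2
        for rank in ladder_above_genus:
            nodes.append(TaxNode(next_id, parent, rank, f"{rank.capitalize()}_{g}"))
            parent = next_id
            next_id += 1
        genus_taxids.append(parent)

    members: list[CommunityMember] = []
    genomes: dict[str, str] = {}
    species_genus = [i if i < n_genera else i - n_genera for i in range(n_species)]
    per_genus_count: dict[int, int] = {}
    for s, g in enumerate(species_genus):
        k = per_genus_count.get(g, 0)
        per_genus_count[g] = k + 1
        name = f"Genus_{g} species_{k}"
        nodes.append(TaxNode(next_id, genus_taxids[g], "species", name))
        sp_taxid = next_id
        next_id += 1
        gid = _genome_id(name, "")
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(_BASES, size=length).tobytes().decode("ascii")
        genomes[gid] = seq
        members.append(
            CommunityMember(
                genome_id=gid,
                organism_name=name,
                taxid=sp_taxid,
                intended_coverage=1.0,
                genome_length=length,
            )
        )

    taxonomy = Taxonomy(nodes)
    community = CommunityProfile(name=f"synthetic_{seed}", members=members)
    return SyntheticWorld(taxonomy=taxonomy, genomes=genomes, community=community, seed=seed)


def write_world(world: SyntheticWorld, outdir: str | Path) -> dict[str, Path]:
    """Materialize a world on disk: genomes multi-FASTA, genome→taxid mapping
    TSV, taxonomy in the 4-column dialect, and the community table."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genomes": outdir / "genomes.fasta",
        "mapping": outdir / "mapping.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "community": outdir / "community.tsv",
    }
    records = [
        SeqRecord(Seq(seq), id=gid, description="") for gid, seq in world.genomes.items()
    ]
    SeqIO.write(records, paths["genomes"], "fasta")
    with open(paths["mapping"], "w") as fh:
        fh.write("genome_id\ttaxid\n")
        for m in world.community.members:
            fh.write(f"{m.genome_id}\t{m.taxid}\n")
    world.taxonomy.to_tsv(paths["taxonomy"])
    with open(paths["community"], "w") as fh:
        fh.write("genome_id\torganism\ttaxid\tintended_coverage\tgenome_length\n")
        for m in world.community.members:
            fh.write(
                f"{m.genome_id}\t{m.organism_name}\t{m.taxid}\t{m.intended_coverage}"
                f"\t{m.genome_length if m.genome_length is not None else 'NA'}\n"
            )
    return paths


def read_mapping_tsv(path: str | Path) -> dict[str, int]:
    """Read a genome→taxid mapping TSV (header optional)."""
    mapping: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParameterError(f"mapping line {lineno}: expected 2 columns")
            if lineno == 1 and parts[0] == "genome_id":
                continue
            mapping[parts[0]] = int(parts[1])
    return mapping
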