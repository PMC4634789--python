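"""Rooted taxonomy with named ranks: lineage, canonical-rank projection, path
membership, and lowest-common-ancestor queries.

The taxonomy is the frame against which every read assignment is judged: a read
is *correct* when its assigned node lies anywhere on the path from the true
species up to the superkingdom. Real NCBI trees interleave non-canonical
("no rank") nodes and strains below species with the seven canonical ranks, so
this module keeps two views of the tree: the full parent chain (used for path
membership) and the projection onto the canonical rank ladder (used for
taxonomic distance and rank tabulations).

Two on-disk dialects are supported: the classic NCBI taxdump pair
(``nodes.dmp``/``names.dmp``, pipe-delimited with trailing ``\\t|``) and a
human-writable 4-column TSV (taxid, parent taxid, rank, name).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

from .errors import FormatError, TaxonomyStructureError, UnknownTaxidError

#: Canonical rank ladder, most specific first. Indices are the currency of
#: taxonomic distance: species=0 ... superkingdom=6.
CANONICAL_RANKS: tuple[str, ...] = (
    "species",
    "genus",
    "family",
    "order",
    "class",
    "phylum",
    "superkingdom",
)

RANK_INDEX: dict[str, int] = {rank: i for i, rank in enumerate(CANONICAL_RANKS)}

#: Sentinel index for nodes (the root, typically) with no canonical ancestor:
#: one step above superkingdom on the ladder.
ROOT_RANK_INDEX: int = len(CANONICAL_RANKS)

#: Ranks at which clade exclusion is performed (class is the highest level used).
EXCLUDABLE_RANKS: tuple[str, ...] = ("species", "genus", "family", "order", "class")


@dataclass(frozen=True)
class TaxNode:
    """One node of the taxonomy.

    ``rank`` is free text; only labels present in :data:`CANONICAL_RANKS` are
    canonical. The root is the unique node whose parent is itself.
    """

    taxid: int
    parent_taxid: int
    rank: str
    name: str

    @property
    def is_root(self) -> bool:
        return self.taxid == self.parent_taxid


class Taxonomy:
    """Validated rooted tree of :class:`TaxNode`, keyed by taxid.

    Construction validates the structural invariants once (unique taxids,
    resolvable parents, exactly one root, no cycles); queries can then walk
    parent pointers without re-checking.
    """

    def __init__(self, nodes: Iterable[TaxNode]):
        table: dict[int, TaxNode] = {}
        for node in nodes:
            if node.taxid in table:
                raise TaxonomyStructureError(f"duplicate taxid {node.taxid}")
            if node.taxid <= 0:
                raise TaxonomyStructureError(f"taxid must be positive, got {node.taxid}")
            table[node.taxid] = node
        if not table:
            raise TaxonomyStructureError("taxonomy is empty")

        roots = [n.taxid for n in table.values() if n.is_root]
        if len(roots) != 1:
            raise TaxonomyStructureError(
                f"expected exactly one root (taxid == parent_taxid), found {len(roots)}: {roots}"
            )
        self._root_taxid = roots[0]

        for node in table.values():
            if node.parent_taxid not in table:
                raise TaxonomyStructureError(
                    f"node {node.taxid} ({node.name!r}) has missing parent {node.parent_taxid}"
                )

        # Cycle check: walk up from every node, reusing already-verified prefixes.
        verified: set[int] = {self._root_taxid}
        for node in table.values():
            path: list[int] = []
            seen: set[int] = set()
            cur = node.taxid
            while cur not in verified:
                if cur in seen:
                    raise TaxonomyStructureError(f"cycle detected through taxid {cur}")
                seen.add(cur)
                path.append(cur)
                cur = table[cur].parent_taxid
            verified.update(path)

        self._nodes = table
        self._lineage_cache: dict[int, tuple[TaxNode, ...]] = {}

    # -- basic access ------------------------------------------------------

    @property
    def root(self) -> TaxNode:
        return self._nodes[self._root_taxid]

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self._nodes

    def __iter__(self) -> Iterator[TaxNode]:
        return iter(self._nodes.values())

    def node(self, taxid: int) -> TaxNode:
        try:
            return self._nodes[taxid]
        except KeyError:
            raise UnknownTaxidError(f"unknown taxid {taxid}") from None

    def find_by_name(self, name: str) -> list[TaxNode]:
        """All nodes whose scientific name equals ``name`` (names need not be unique)."""
        return [n for n in self._nodes.values() if n.name == name]

    def nodes_at_rank(self, rank: str) -> list[TaxNode]:
        return [n for n in self._nodes.values() if n.rank == rank]

    # -- lineage & ladder queries -----------------------------------------

    def lineage(self, taxid: int) -> tuple[TaxNode, ...]:
        """Path of nodes from the root down to (and including) ``taxid``."""
        cached = self._lineage_cache.get(taxid)
        if cached is not None:
            return cached
        node = self.node(taxid)
        chain = [node]
        while not node.is_root:
            node = self._nodes[node.parent_taxid]
            chain.append(node)
        result = tuple(reversed(chain))
        self._lineage_cache[taxid] = result
        return result

    def lineage_taxids(self, taxid: int) -> tuple[int, ...]:
        return tuple(n.taxid for n in self.lineage(taxid))

    def nearest_canonical_ancestor(self, taxid: int) -> tuple[TaxNode, int]:
        """Deepest ancestor-or-self on the canonical ladder.

        A strain maps to its species (index 0); a node with no canonical
        ancestor at all maps to the root with :data:`ROOT_RANK_INDEX`.
        """
        for node in reversed(self.lineage(taxid)):
            idx = RANK_INDEX.get(node.rank)
            if idx is not None:
                return node, idx
        return self.root, ROOT_RANK_INDEX

    def canonical_ancestor_at_rank(self, taxid: int, rank_index: int) -> TaxNode | None:
        """The lineage node sitting exactly at canonical rank ``rank_index``, or
        ``None`` when the lineage skips that rank or never reaches down to it."""
        target = CANONICAL_RANKS[rank_index]
        for node in self.lineage(taxid):
            if node.rank == target:
                return node
        return None

    def species_of(self, taxid: int) -> TaxNode | None:
        """Project a node (e.g. a strain) onto the species rank; ``None`` if the
        node sits above species and has no species ancestor."""
        node, idx = self.nearest_canonical_ancestor(taxid)
        return node if idx == 0 else None

    def is_on_truth_path(self, assigned_taxid: int, truth_taxid: int) -> bool:
        """Correctness rule for a single assignment: true iff the assigned node
        lies on the path from the truth organism to the root (ancestor-or-self,
        counting non-canonical nodes), or is a strain *of* the truth organism
        (descendants project up to their species before the test)."""
        self.node(assigned_taxid)  # raise on unknown
        if assigned_taxid in set(self.lineage_taxids(truth_taxid)):
            return True
        # assigned strictly below truth: a strain/subnode of the truth organism
        return truth_taxid in set(self.lineage_taxids(assigned_taxid))

    def lca(self, taxid_a: int, taxid_b: int) -> TaxNode:
        """Lowest common ancestor: deepest shared node of the two lineages."""
        lin_a = self.lineage(taxid_a)
        lin_b = self.lineage(taxid_b)
        common = self.root
        for a, b in zip(lin_a, lin_b):
            if a.taxid != b.taxid:
                break
            common = a
        return common

    # -- serialization -----------------------------------------------------

    def to_tsv(self, path_or_handle: str | Path | TextIO) -> None:
        """Write the 4-column TSV dialect (taxid, parent, rank, name)."""
        def _write(handle: TextIO) -> None:
            for taxid in sorted(self._nodes):
                n = self._nodes[taxid]
                handle.write(f"{n.taxid}\t{n.parent_taxid}\t{n.rank}\t{n.name}\n")

        if isinstance(path_or_handle, (str, Path)):
            with open(path_or_handle, "w") as fh:
                _write(fh)
        else:
            _write(path_or_handle)


# -- loaders ---------------------------------------------------------------


def _as_lines(source: str | Path | TextIO | Iterable[str]) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            yield from fh
    elif isinstance(source, io.TextIOBase):
        yield from source
    else:
        yield from source


def taxonomy_from_tsv(source: str | Path | TextIO | Iterable[str]) -> Taxonomy:
    """Load the 4-column TSV dialect: taxid, parent taxid, rank, name.

    Blank lines and ``#`` comments are ignored.
    """
    nodes = []
    for lineno, raw in enumerate(_as_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(f"line {lineno}: expected 4 tab-separated columns, got {len(parts)}")
        try:
            taxid, parent = int(parts[0]), int(parts[1])
        except ValueError:
            raise FormatError(f"line {lineno}: taxid and parent must be integers") from None
        nodes.append(TaxNode(taxid=taxid, parent_taxid=parent, rank=parts[2], name=parts[3]))
    return Taxonomy(nodes)


def _parse_dmp_fields(line: str) -> list[str]:
    # taxdump rows are "<f>\t|\t<f>\t|\t...\t|" — strip the trailing delimiter
    line = line.rstrip("\n")
    if line.endswith("\t|"):
        line = line[:-2]
    return [f.strip("\t") for f in line.split("\t|\t")]


def taxonomy_from_taxdump(
    nodes_source: str | Path | TextIO | Iterable[str],
    names_source: str | Path | TextIO | Iterable[str],
) -> Taxonomy:
    """Load the NCBI taxdump dialect (``nodes.dmp`` + ``names.dmp``).

    Only the first three fields of ``nodes.dmp`` (taxid, parent, rank) and the
    "scientific name" class rows of ``names.dmp`` are used.
    """
    names: dict[int, str] = {}
    for lineno, raw in enumerate(_as_lines(names_source), start=1):
        if not raw.strip():
            continue
        fields = _parse_dmp_fields(raw)
        if len(fields) < 4:
            raise FormatError(f"names line {lineno}: expected >=4 pipe-delimited fields")
        if fields[3] == "scientific name":
            names[int(fields[0])] = fields[1]

    nodes = []
    for lineno, raw in enumerate(_as_lines(nodes_source), start=1):
        if not raw.strip():
            continue
        fields = _parse_dmp_fields(raw)
        if len(fields) < 3:
            raise FormatError(f"nodes line {lineno}: expected >=3 pipe-delimited fields")
        try:
            taxid, parent = int(fields[0]), int(fields[1])
        except ValueError:
            raise FormatError(f"nodes line {lineno}: taxid and parent must be integers") from None
        nodes.append(
            TaxNode(taxid=taxid, parent_taxid=parent, rank=fields[2], name=names.get(taxid, ""))
        )
    return Taxonomy(nodes)


def load_taxonomy(
    nodes_source: str | Path | TextIO | Iterable[str],
    names_source: str | Path | TextIO | Iterable[str] | None = None,
) -> Taxonomy:
    """Dispatch loader: with a ``names_source`` the taxdump dialect is assumed,
    without one the 4-column TSV dialect."""
    if names_source is None:
        return taxonomy_from_tsv(nodes_source)
    return taxonomy_from_taxdump(nodes_source, names_source)
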