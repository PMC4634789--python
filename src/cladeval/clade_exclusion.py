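"""Clade exclusion: prune a reference genome set at a chosen taxonomic rank.

Excluding the clade of a truth taxon at, say, the genus level removes every
reference genome whose lineage passes through the truth taxon's genus; a
classifier run against the pruned reference can then at best be correct at the
family level. The *best possible rank* recorded in the
:class:`ExclusionSpec` (one rank above the exclusion rank) is what taxonomic
distance and overprediction scoring are measured against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConsistencyError, ParameterError, SpecificationError
from .taxonomy import EXCLUDABLE_RANKS, RANK_INDEX, Taxonomy

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExclusionSpec:
    """Which clade to exclude: the truth taxon plus a rank in
    {species, genus, family, order, class}, or ``None`` for no exclusion."""

    truth_taxid: int
    exclusion_rank: str | None = None

    def __post_init__(self) -> None:
        if self.exclusion_rank is not None and self.exclusion_rank not in EXCLUDABLE_RANKS:
            raise ParameterError(
                f"exclusion_rank must be one of {EXCLUDABLE_RANKS} or None, "
                f"got {self.exclusion_rank!r}"
            )

    @property
    def best_possible_rank_index(self) -> int:
        """Ladder index of the lowest rank a correct call can still be made at:
        exclusion rank + 1, or 0 (species) when nothing is excluded."""
        if self.exclusion_rank is None:
            return 0
        return RANK_INDEX[self.exclusion_rank] + 1


#: no-exclusion spec usable when only the best-possible rank matters
NO_EXCLUSION = ExclusionSpec(truth_taxid=1, exclusion_rank=None)


def exclude_clade(
    reference: Sequence[tuple[str, int]],
    taxonomy: Taxonomy,
    spec: ExclusionSpec,
) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """Partition ``reference`` (genome_id, taxid) pairs into (kept, removed).

    A genome is removed iff its lineage contains the truth taxon's ancestor at
    the exclusion rank. Genomes whose own lineage skips that canonical rank
    can never contain the ancestor and are kept (logged as a warning).
    """
    if spec.exclusion_rank is None:
        for gid, taxid in reference:
            taxonomy.node(taxid)
        return list(reference), []

    rank_idx = RANK_INDEX[spec.exclusion_rank]
    ancestor = taxonomy.canonical_ancestor_at_rank(spec.truth_taxid, rank_idx)
    if ancestor is None:
        raise SpecificationError(
            f"truth taxon {spec.truth_taxid} has no ancestor at rank "
            f"{spec.exclusion_rank!r}; cannot exclude"
        )

    kept: list[tuple[str, int]] = []
    removed: list[tuple[str, int]] = []
    for gid, taxid in reference:
        lineage_ids = set(taxonomy.lineage_taxids(taxid))
        if ancestor.taxid in lineage_ids:
            removed.append((gid, taxid))
        else:
            if taxonomy.canonical_ancestor_at_rank(taxid, rank_idx) is None:
                logger.warning(
                    "genome %s (taxid %d) has no %s-rank ancestor; kept (cannot belong "
                    "to the excluded clade)", gid, taxid, spec.exclusion_rank,
                )
            kept.append((gid, taxid))
    return kept, removed


def exclusion_report(
    kept: Sequence[tuple[str, int]],
    removed: Sequence[tuple[str, int]],
    spec: ExclusionSpec,
) -> pd.DataFrame:
    """Tabular report: one row per genome with its kept/removed status."""
    rows = [
        (gid, taxid, "removed", f"in excluded clade at rank {spec.exclusion_rank}")
        for gid, taxid in removed
    ] + [(gid, taxid, "kept", "") for gid, taxid in kept]
    return pd.DataFrame(rows, columns=["genome_id", "taxid", "status", "reason"])


def prune_fasta(
    fasta_in: str | Path,
    mapping: Mapping[str, int],
    taxonomy: Taxonomy,
    spec: ExclusionSpec,
    fasta_out: str | Path,
) -> pd.DataFrame:
    """Write the kept genomes' FASTA records (input order preserved) and return
    the exclusion report. Every record id must appear in ``mapping``."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(fasta_in), "fasta"))
    for rec in records:
        if rec.id not in mapping:
            raise ConsistencyError(f"FASTA record {rec.id!r} missing from genome→taxid mapping")

    reference = [(rec.id, mapping[rec.id]) for rec in records]
    kept, removed = exclude_clade(reference, taxonomy, spec)
    kept_ids = {gid for gid, _ in kept}
    SeqIO.write((rec for rec in records if rec.id in kept_ids), str(fasta_out), "fasta")
    logger.info(
        "clade exclusion (%s @ %s): kept %d, removed %d genomes",
        spec.truth_taxid, spec.exclusion_rank, len(kept), len(removed),
    )
    return exclusion_report(kept, removed, spec)
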