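"""Predicted-species tables and abundance-cutoff filtering.

Popular classifiers can predict dozens to hundreds of species from a sample
that truly contains 11. This module tabulates, per predicted species, the
read count and relative abundance, flags each species as correct (a community
member) or incorrect, and counts how many of each survive a series of
relative-abundance cutoffs — demonstrating how low-abundance filtering
suppresses spurious species.

Conventions (documented because reasonable alternatives exist):

* a species "passes" cutoff ``c`` when its relative abundance is **>= c**
  (the "at least x%" reading);
* the abundance denominator is the number of species-attributed reads —
  reads assigned above species rank create no species row and do not enter
  the denominator;
* correctness is at species rank exactly: strain-level assignments project
  up to their species, genus-or-higher assignments contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .assignment_io import AssignmentSet
from .communities import CommunityProfile
from .errors import ParameterError
from .taxonomy import Taxonomy

DEFAULT_CUTOFFS = (0.0, 0.0001, 0.001, 0.01)


@dataclass
class SpeciesPredictionTable:
    """Per-species predictions: (species_taxid, name, read_count,
    relative_abundance, is_correct), plus provenance metadata."""

    df: pd.DataFrame
    community_name: str
    n_species_attributed_reads: int
    metadata: dict

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_correct(self) -> int:
        return int(self.df["is_correct"].sum()) if len(self.df) else 0

    @property
    def n_incorrect(self) -> int:
        return len(self.df) - self.n_correct

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def species_table(
    assignments: AssignmentSet,
    taxonomy: Taxonomy,
    community: CommunityProfile,
) -> SpeciesPredictionTable:
    """Attribute every assigned read to a species (projecting strains up;
    dropping genus-or-higher calls) and tabulate abundances and correctness."""
    counts: dict[int, int] = {}
    for taxid in assignments.assignments.values():
        if taxid is None:
            continue
        sp = taxonomy.species_of(taxid)
        if sp is None:
            continue  # assigned above species rank: no species attribution
        counts[sp.taxid] = counts.get(sp.taxid, 0) + 1

    total = sum(counts.values())
    truth_species = set(community.species_taxids(taxonomy))
    rows = [
        (
            sp_taxid,
            taxonomy.node(sp_taxid).name,
            n,
            n / total,
            sp_taxid in truth_species,
        )
        for sp_taxid, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    df = pd.DataFrame(
        rows,
        columns=["species_taxid", "species_name", "read_count", "relative_abundance",
                 "is_correct"],
    )
    return SpeciesPredictionTable(
        df=df,
        community_name=community.name,
        n_species_attributed_reads=total,
        metadata={
            "cutoff_semantics": "abundance >= cutoff",
            "abundance_denominator": "species-attributed reads",
        },
    )


def apply_cutoffs(
    table: SpeciesPredictionTable,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> pd.DataFrame:
    """Correct/incorrect species counts surviving each relative-abundance
    cutoff (``abundance >= cutoff``). Cutoffs are fractions in [0, 1)."""
    for c in cutoffs:
        if not (0 <= c < 1):
            raise ParameterError(f"cutoffs must be in [0, 1), got {c}")
    rows = []
    for c in cutoffs:
        surviving = table.df[table.df["relative_abundance"] >= c] if len(table.df) else table.df
        n_corr = int(surviving["is_correct"].sum()) if len(surviving) else 0
        rows.append((c, n_corr, len(surviving) - n_corr))
    return pd.DataFrame(rows, columns=["cutoff", "n_correct", "n_incorrect"])
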