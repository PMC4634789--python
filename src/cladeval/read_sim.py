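"""Error-free shotgun read simulation with a ground-truth sidecar.

Reads are sampled uniformly with replacement from each genome at a fixed read
length, both strands equiprobable, bases copied exactly (no error model), with
the per-genome read count fixed at ``round(coverage * genome_length /
read_length)`` — at 1X coverage and 100 bp reads, a 10 kb genome yields
exactly 100 reads. Reverse-strand reads are reverse-complemented. Reads never
wrap a (circular) origin. Every read is recorded in a :class:`ReadTruthSet`
mapping it back to its source genome, taxid, start and strand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .communities import SyntheticWorld
from .errors import ParameterError

TRUTH_COLUMNS = ("read_id", "genome_id", "taxid", "start", "strand")

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadTruthSet:
    """Ground truth of a simulated read set: one row per read
    (read_id, genome_id, taxid, start, strand)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(TRUTH_COLUMNS) - set(self.df.columns)
        if missing:
            raise ParameterError(f"truth table missing columns: {sorted(missing)}")
        if self.df["read_id"].duplicated().any():
            dup = self.df["read_id"][self.df["read_id"].duplicated()].iloc[0]
            raise ParameterError(f"duplicate read_id in truth set: {dup!r}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def read_ids(self) -> pd.Series:
        return self.df["read_id"]

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False, columns=list(TRUTH_COLUMNS))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReadTruthSet":
        return cls(pd.read_csv(path, sep="\t", dtype={"read_id": str, "genome_id": str}))


def reads_per_genome(coverage: float, genome_length: int, read_length: int) -> int:
    """round(coverage * L / read_length), half away from zero."""
    return int(math.floor(coverage * genome_length / read_length + 0.5))


def simulate_reads(
    genomes: Mapping[str, str] | SyntheticWorld,
    read_length: int,
    coverage: float = 1.0,
    seed: int = 0,
    genome_taxids: Mapping[str, int] | None = None,
) -> tuple[dict[str, str], ReadTruthSet]:
    """Simulate error-free reads from a genome set or a synthetic world.

    Returns the reads (read_id → sequence, insertion-ordered by genome) and
    the ground-truth sidecar. Deterministic per seed.
    """
    if isinstance(genomes, SyntheticWorld):
        genome_taxids = genomes.genome_taxids
        genomes = genomes.genomes
    if not genomes:
        raise ParameterError("empty genome set")
    if coverage <= 0:
        raise ParameterError(f"coverage must be > 0, got {coverage}")
    if read_length < 1:
        raise ParameterError(f"read_length must be >= 1, got {read_length}")
    genome_taxids = genome_taxids or {}

    for gid in genomes:
        if read_length > len(genomes[gid]):
            raise ParameterError(
                f"read_length {read_length} exceeds genome {gid!r} length {len(genomes[gid])}"
            )

    rng = np.random.default_rng(seed)
    reads: dict[str, str] = {}
    rows: list[tuple[str, str, int, int, str]] = []
    for gid in sorted(genomes):
        seq = genomes[gid]
        n = reads_per_genome(coverage, len(seq), read_length)
        starts = rng.integers(0, len(seq) - read_length + 1, size=n)
        strands = rng.integers(0, 2, size=n)  # 0 = forward, 1 = reverse
        taxid = genome_taxids.get(gid, 0)
        for i, (start, rev) in enumerate(zip(starts, strands)):
            read_id = f"{gid}_r{i:06d}"
            fragment = seq[start : start + read_length]
            reads[read_id] = reverse_complement(fragment) if rev else fragment
            rows.append((read_id, gid, taxid, int(start), "-" if rev else "+"))

    truth = ReadTruthSet(pd.DataFrame(rows, columns=list(TRUTH_COLUMNS)))
    return reads, truth


def write_reads_fasta(reads: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads.items():
            fh.write(f">{read_id}\n{seq}\n")


def write_reads_fastq(reads: Mapping[str, str], path: str | Path, quality: int = 40) -> None:
    """FASTQ with a constant quality (default Q40) — the simulation is
    error-free, so qualities are a formality for tools that demand FASTQ."""
    qchar = chr(quality + 33)
    with open(path, "w") as fh:
        for read_id, seq in reads.items():
            fh.write(f"@{read_id}\n{seq}\n+\n{qchar * len(seq)}\n")
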