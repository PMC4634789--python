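"""Normalized classifier output: one assignment (taxid or unassigned) per read.

Two input dialects are supported — a generic two-column TSV (read_id, taxid;
``0`` or ``U`` marks unassigned) and Kraken's standard five-column output.
Other classifiers' formats should be pre-converted to the generic TSV by the
user; normalization, not format coverage, is the stable contract here.

Reads present in the truth set but absent from a classifier's output are
treated as unassigned: many tools silently drop reads they cannot place, and
an unplaced read is a false negative either way.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import pandas as pd

from .errors import ConsistencyError, FormatError
from .read_sim import ReadTruthSet

logger = logging.getLogger(__name__)


@dataclass
class AssignmentSet:
    """A classifier's output: read_id → assigned taxid (``None`` = unassigned)."""

    assignments: dict[str, int | None]
    source_label: str = "unknown"

    def __len__(self) -> int:
        return len(self.assignments)

    def __getitem__(self, read_id: str) -> int | None:
        return self.assignments[read_id]

    @property
    def n_assigned(self) -> int:
        return sum(1 for t in self.assignments.values() if t is not None)


def _as_lines(source: str | Path | TextIO | Iterable[str]) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            yield from fh
    elif isinstance(source, io.TextIOBase):
        yield from source
    else:
        yield from source


def parse_generic_tsv(
    source: str | Path | TextIO | Iterable[str], source_label: str = "generic"
) -> AssignmentSet:
    """Parse the generic dialect: ``read_id<TAB>taxid`` with ``0`` or ``U`` for
    unassigned; an optional ``read_id\\ttaxid`` header line is skipped."""
    assignments: dict[str, int | None] = {}
    for lineno, raw in enumerate(_as_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"line {lineno}: expected 2 tab-separated columns")
        read_id, token = parts[0], parts[1]
        if lineno == 1 and read_id == "read_id":
            continue
        if read_id in assignments:
            raise FormatError(f"line {lineno}: duplicate read_id {read_id!r}")
        if token == "U":
            assignments[read_id] = None
        else:
            try:
                taxid = int(token)
            except ValueError:
                raise FormatError(
                    f"line {lineno}: taxid must be an integer or 'U', got {token!r}"
                ) from None
            assignments[read_id] = None if taxid == 0 else taxid
    return AssignmentSet(assignments, source_label=source_label)


def parse_kraken_output(
    source: str | Path | TextIO | Iterable[str], source_label: str = "kraken"
) -> AssignmentSet:
    """Parse Kraken's standard output: ``C|U \\t read_id \\t taxid \\t length \\t
    k-mer map``; columns beyond the third are ignored."""
    assignments: dict[str, int | None] = {}
    for lineno, raw in enumerate(_as_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"line {lineno}: expected >=3 tab-separated columns")
        flag, read_id, token = parts[0], parts[1], parts[2]
        if flag not in ("C", "U"):
            raise FormatError(f"line {lineno}: classification flag must be 'C' or 'U', got {flag!r}")
        if read_id in assignments:
            raise FormatError(f"line {lineno}: duplicate read_id {read_id!r}")
        if flag == "U":
            assignments[read_id] = None
        else:
            try:
                assignments[read_id] = int(token)
            except ValueError:
                raise FormatError(f"line {lineno}: taxid must be an integer, got {token!r}") from None
    return AssignmentSet(assignments, source_label=source_label)


def write_generic_tsv(aset: AssignmentSet, path_or_handle: str | Path | TextIO) -> None:
    """Write the generic dialect (``U`` for unassigned), no header."""
    def _write(handle: TextIO) -> None:
        for read_id, taxid in aset.assignments.items():
            handle.write(f"{read_id}\t{'U' if taxid is None else taxid}\n")

    if isinstance(path_or_handle, (str, Path)):
        with open(path_or_handle, "w") as fh:
            _write(fh)
    else:
        _write(path_or_handle)


def join_with_truth(assignments: AssignmentSet, truth: ReadTruthSet) -> pd.DataFrame:
    """One row per truth read: (read_id, genome_id, truth_taxid, assigned_taxid).

    Truth reads missing from the classifier output join as unassigned (the
    count is logged); classifier reads unknown to the truth set are an error.
    """
    truth_ids = set(truth.df["read_id"])
    extra = [r for r in assignments.assignments if r not in truth_ids]
    if extra:
        raise ConsistencyError(
            f"{len(extra)} assigned read(s) not present in the truth set "
            f"(first: {extra[0]!r})"
        )
    missing = len(truth_ids) - len(assignments.assignments)
    if missing:
        logger.info(
            "%d read(s) absent from classifier output %r; counted as unassigned",
            missing, assignments.source_label,
        )
    joined = truth.df[["read_id", "genome_id", "taxid"]].rename(
        columns={"taxid": "truth_taxid"}
    ).copy()
    # object dtype keeps None as-is (a float column would turn taxids into NaN)
    joined["assigned_taxid"] = pd.Series(
        [assignments.assignments.get(r) for r in joined["read_id"]],
        index=joined.index, dtype=object,
    )
    return joined
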