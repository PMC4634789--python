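"""Scoring core: per-read TP/FP/FN, sensitivity, precision, taxonomic distance.

The correctness rule is path-based: a read is a true positive when its
assigned node lies anywhere on the path from the true species up to the
superkingdom of the taxonomy; an assignment off that path is a false
positive; an unassigned read is a false negative. From the counts,

    sensitivity = TP / (TP + FN)        precision = TP / (TP + FP)

and, for true positives, the *taxonomic distance* is the number of canonical
ranks the assignment sits above the best possible rank (the rank just above
the clade-exclusion level, or species when nothing is excluded).

Two aggregation modes mirror how in silico and in vitro mock communities are
scored. With per-read ground truth (``per_genome_mean``) metrics are computed
per genome and averaged unweighted, so large genomes with more reads do not
dominate. Without it (``pooled``, the in vitro case) all reads are scored
jointly and an assignment on the truth path of *any* community member counts
as correct.

An optional *overpredictions-as-correct* mode rescues assignments that are
too specific but right at the best possible rank: under species exclusion, a
read placed on the wrong species of the correct genus is reclassified TP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd

from .assignment_io import AssignmentSet, join_with_truth
from .clade_exclusion import NO_EXCLUSION, ExclusionSpec
from .communities import CommunityProfile
from .errors import ParameterError, UsageError
from .read_sim import ReadTruthSet
from .taxonomy import CANONICAL_RANKS, ROOT_RANK_INDEX, Taxonomy

Outcome = Literal["TP", "FP", "FN"]


@dataclass(frozen=True)
class EvalConfig:
    """How reads are scored and aggregated."""

    exclusion: ExclusionSpec = NO_EXCLUSION
    overpredictions_correct: bool = False
    aggregation: Literal["per_genome_mean", "pooled"] = "per_genome_mean"
    pooled_community: CommunityProfile | None = None

    def __post_init__(self) -> None:
        if self.aggregation not in ("per_genome_mean", "pooled"):
            raise ParameterError(f"unknown aggregation {self.aggregation!r}")
        if (self.aggregation == "pooled") != (self.pooled_community is not None):
            raise ParameterError(
                "pooled_community must be given exactly when aggregation='pooled'"
            )


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN

    @property
    def sensitivity(self) -> float | None:
        d = self.TP + self.FN
        return self.TP / d if d else None

    @property
    def precision(self) -> float | None:
        d = self.TP + self.FP
        return self.TP / d if d else None


def _truth_species_taxid(taxonomy: Taxonomy, truth_taxid: int) -> int:
    """Project a truth organism (possibly a strain) to its species node; a
    truth taxon with no species-rank ancestor is used as-is."""
    sp = taxonomy.species_of(truth_taxid)
    return sp.taxid if sp is not None else truth_taxid


def classify_read(
    assigned_taxid: int | None,
    truth_taxid: int,
    taxonomy: Taxonomy,
    config: EvalConfig = EvalConfig(),
) -> Outcome:
    """Score one read as TP, FP, or FN (see module docstring for the rule)."""
    taxonomy.node(truth_taxid)
    if assigned_taxid is None:
        return "FN"
    truth_species = _truth_species_taxid(taxonomy, truth_taxid)
    if taxonomy.is_on_truth_path(assigned_taxid, truth_species):
        return "TP"
    if config.overpredictions_correct:
        b = config.exclusion.best_possible_rank_index
        if b <= len(CANONICAL_RANKS) - 1:
            assigned_at_b = taxonomy.canonical_ancestor_at_rank(assigned_taxid, b)
            truth_at_b = taxonomy.canonical_ancestor_at_rank(truth_species, b)
            if (
                assigned_at_b is not None
                and truth_at_b is not None
                and assigned_at_b.taxid == truth_at_b.taxid
            ):
                return "TP"
    return "FP"


def taxonomic_distance_of_read(
    assigned_taxid: int,
    truth_taxid: int,
    taxonomy: Taxonomy,
    config: EvalConfig = EvalConfig(),
) -> int:
    """Ranks above the best possible rank for a TP read (clamped at 0: a call
    at or below the best possible rank that is still on the path counts 0)."""
    if classify_read(assigned_taxid, truth_taxid, taxonomy, config) != "TP":
        raise UsageError("taxonomic distance is defined only for TP reads")
    _, idx = taxonomy.nearest_canonical_ancestor(assigned_taxid)
    return max(0, idx - config.exclusion.best_possible_rank_index)


@dataclass
class GenomeMetrics:
    counts: ConfusionCounts
    sensitivity: float
    precision: float | None
    taxonomic_distance: float | None


@dataclass
class RankDistribution:
    """Where assignments land on the canonical ladder.

    Fractions are reported against two denominators — assigned reads only and
    all reads — since conventions differ; ``unassigned_fraction`` is always
    over all reads. Assignments below species bin at species; assignments on
    non-canonical nodes bin at their nearest canonical ancestor; assignments
    with no canonical ancestor bin as ``above_superkingdom``.
    """

    counts: dict[str, int]
    n_assigned: int
    n_total: int

    @property
    def fractions_of_assigned(self) -> dict[str, float]:
        if self.n_assigned == 0:
            return {}
        return {r: c / self.n_assigned for r, c in self.counts.items()}

    @property
    def fractions_of_all(self) -> dict[str, float]:
        if self.n_total == 0:
            return {}
        return {r: c / self.n_total for r, c in self.counts.items()}

    @property
    def unassigned_fraction(self) -> float:
        return (self.n_total - self.n_assigned) / self.n_total if self.n_total else 0.0


@dataclass
class EvaluationResult:
    """Per-genome and aggregate scoring of one classifier run."""

    per_genome: dict[str, GenomeMetrics]
    pooled: GenomeMetrics | None
    aggregation: str
    rank_distribution: RankDistribution
    config: EvalConfig

    @property
    def aggregate_sensitivity(self) -> float:
        if self.pooled is not None:
            return self.pooled.sensitivity
        vals = [m.sensitivity for m in self.per_genome.values()]
        return sum(vals) / len(vals)

    @property
    def aggregate_precision(self) -> float | None:
        if self.pooled is not None:
            return self.pooled.precision
        vals = [m.precision for m in self.per_genome.values() if m.precision is not None]
        return sum(vals) / len(vals) if vals else None

    @property
    def aggregate_taxonomic_distance(self) -> float | None:
        if self.pooled is not None:
            return self.pooled.taxonomic_distance
        vals = [
            m.taxonomic_distance
            for m in self.per_genome.values()
            if m.taxonomic_distance is not None
        ]
        return sum(vals) / len(vals) if vals else None

    def per_genome_frame(self) -> pd.DataFrame:
        rows = [
            (
                gid, m.counts.TP, m.counts.FP, m.counts.FN,
                m.sensitivity, m.precision, m.taxonomic_distance,
            )
            for gid, m in sorted(self.per_genome.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["genome_id", "TP", "FP", "FN", "sensitivity", "precision",
                     "taxonomic_distance"],
        )

    def summary(self) -> dict:
        return {
            "aggregation": self.aggregation,
            "overpredictions_correct": self.config.overpredictions_correct,
            "exclusion_rank": self.config.exclusion.exclusion_rank,
            "best_possible_rank_index": self.config.exclusion.best_possible_rank_index,
            "sensitivity": self.aggregate_sensitivity,
            "precision": self.aggregate_precision,
            "taxonomic_distance": self.aggregate_taxonomic_distance,
            "n_genomes": len(self.per_genome),
            "n_genomes_precision_defined": sum(
                1 for m in self.per_genome.values() if m.precision is not None
            ),
            "n_genomes_distance_defined": sum(
                1 for m in self.per_genome.values() if m.taxonomic_distance is not None
            ),
            "unassigned_fraction": self.rank_distribution.unassigned_fraction,
        }

    def write_tsv(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "per_genome": outdir / "per_genome_metrics.tsv",
            "aggregate": outdir / "aggregate_metrics.tsv",
            "rank_distribution": outdir / "rank_distribution.tsv",
        }
        self.per_genome_frame().to_csv(paths["per_genome"], sep="\t", index=False)
        pd.DataFrame([self.summary()]).to_csv(paths["aggregate"], sep="\t", index=False)
        rd = self.rank_distribution
        rows = [
            (rank, rd.counts.get(rank, 0),
             rd.fractions_of_assigned.get(rank, 0.0), rd.fractions_of_all.get(rank, 0.0))
            for rank in list(CANONICAL_RANKS) + ["above_superkingdom"]
            if rank in rd.counts
        ]
        df = pd.DataFrame(
            rows, columns=["rank", "n_reads", "fraction_of_assigned", "fraction_of_all"]
        )
        df.loc[len(df)] = ["unassigned", rd.n_total - rd.n_assigned, float("nan"),
                           rd.unassigned_fraction]
        df.to_csv(paths["rank_distribution"], sep="\t", index=False)
        return paths


def rank_distribution(assignments: AssignmentSet, taxonomy: Taxonomy) -> RankDistribution:
    """Tabulate the canonical rank each assigned read lands at."""
    counts: dict[str, int] = {}
    n_assigned = 0
    for taxid in assignments.assignments.values():
        if taxid is None:
            continue
        n_assigned += 1
        _, idx = taxonomy.nearest_canonical_ancestor(taxid)
        label = CANONICAL_RANKS[idx] if idx < ROOT_RANK_INDEX else "above_superkingdom"
        counts[label] = counts.get(label, 0) + 1
    return RankDistribution(counts=counts, n_assigned=n_assigned, n_total=len(assignments))


def _classify_pooled(
    assigned_taxid: int | None,
    member_species: list[int],
    taxonomy: Taxonomy,
    config: EvalConfig,
) -> Outcome:
    """Pooled-mode rule: correct when on the truth path of any community member."""
    if assigned_taxid is None:
        return "FN"
    for sp in member_species:
        if taxonomy.is_on_truth_path(assigned_taxid, sp):
            return "TP"
    if config.overpredictions_correct:
        b = config.exclusion.best_possible_rank_index
        if b <= len(CANONICAL_RANKS) - 1:
            assigned_at_b = taxonomy.canonical_ancestor_at_rank(assigned_taxid, b)
            if assigned_at_b is not None:
                for sp in member_species:
                    truth_at_b = taxonomy.canonical_ancestor_at_rank(sp, b)
                    if truth_at_b is not None and truth_at_b.taxid == assigned_at_b.taxid:
                        return "TP"
    return "FP"


def evaluate(
    assignments: AssignmentSet,
    truth: ReadTruthSet,
    taxonomy: Taxonomy,
    config: EvalConfig = EvalConfig(),
) -> EvaluationResult:
    """Score a classifier run against the read truth.

    Per-genome mode: counts and metrics per genome, aggregate = unweighted
    mean over genomes where the metric is defined (precision needs at least
    one assigned read; distance at least one TP read; undefined genomes are
    excluded from the mean and counted in the summary).

    Pooled mode: one joint computation over all reads, correctness judged
    against every member of ``config.pooled_community``.
    """
    if len(truth) == 0:
        raise ParameterError("truth set contains zero reads")
    joined = join_with_truth(assignments, truth)
    rd = rank_distribution(assignments, taxonomy)
    b = config.exclusion.best_possible_rank_index

    def distance_of(assigned: int) -> int:
        _, idx = taxonomy.nearest_canonical_ancestor(assigned)
        return max(0, idx - b)

    if config.aggregation == "pooled":
        member_species = [
            _truth_species_taxid(taxonomy, t)
            for t in config.pooled_community.member_taxids()
        ]
        counts = ConfusionCounts()
        dist_sum = 0
        for assigned in joined["assigned_taxid"]:
            outcome = _classify_pooled(assigned, member_species, taxonomy, config)
            if outcome == "TP":
                counts.TP += 1
                dist_sum += distance_of(assigned)
            elif outcome == "FP":
                counts.FP += 1
            else:
                counts.FN += 1
        pooled = GenomeMetrics(
            counts=counts,
            sensitivity=counts.sensitivity or 0.0,
            precision=counts.precision,
            taxonomic_distance=dist_sum / counts.TP if counts.TP else None,
        )
        return EvaluationResult(
            per_genome={}, pooled=pooled, aggregation="pooled",
            rank_distribution=rd, config=config,
        )

    per_genome: dict[str, GenomeMetrics] = {}
    for gid, group in joined.groupby("genome_id", sort=True):
        counts = ConfusionCounts()
        dist_sum = 0
        for truth_taxid, assigned in zip(group["truth_taxid"], group["assigned_taxid"]):
            outcome = classify_read(assigned, int(truth_taxid), taxonomy, config)
            if outcome == "TP":
                counts.TP += 1
                dist_sum += distance_of(assigned)
            elif outcome == "FP":
                counts.FP += 1
            else:
                counts.FN += 1
        per_genome[str(gid)] = GenomeMetrics(
            counts=counts,
            sensitivity=counts.sensitivity,  # total > 0, so TP+FN may still be... see below
            precision=counts.precision,
            taxonomic_distance=dist_sum / counts.TP if counts.TP else None,
        )
        # TP+FN can only be 0 if every read was FP; sensitivity is then 0/NN —
        # treat as 0.0: the genome's reads were all mis-assigned.
        if per_genome[str(gid)].sensitivity is None:
            per_genome[str(gid)] = GenomeMetrics(
                counts=counts, sensitivity=0.0,
                precision=counts.precision,
                taxonomic_distance=dist_sum / counts.TP if counts.TP else None,
            )
    return EvaluationResult(
        per_genome=per_genome, pooled=None, aggregation="per_genome_mean",
        rank_distribution=rd, config=config,
    )
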