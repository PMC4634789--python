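"""Synthetic classifier output with programmable error behavior.

Real classifiers differ along a few axes this simulator exposes directly: how
many reads they leave unassigned, how often an assignment is correct, how
deep on the rank ladder correct calls are made (conservative tools emit
family/order-level calls; aggressive tools commit to species), and what shape
their mistakes take. Driving the evaluation stack with known parameters makes
the whole pipeline testable closed-loop: programmed sensitivity and precision
must be recovered by the metrics.

Misassignment modes:

* ``sibling_species`` — a random congeneric species != the truth species
  (wrong species, right genus: the canonical *overprediction*);
* ``random_other_clade`` — a random species outside the truth genus;
* ``lca_of_confusion_set`` — the LCA of the truth species and a random
  sibling (typically the genus node, i.e. an on-path conservative call).

Per-read draws are independent; deterministic per model seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np

from .assignment_io import AssignmentSet
from .errors import ParameterError
from .read_sim import ReadTruthSet
from .taxonomy import CANONICAL_RANKS, RANK_INDEX, Taxonomy

logger = logging.getLogger(__name__)

MisassignmentMode = Literal["sibling_species", "random_other_clade", "lca_of_confusion_set"]


@dataclass(frozen=True)
class ClassifierModel:
    """Behavioral knobs of the simulated classifier.

    ``p_unassigned + p_correct <= 1``; the residual mass is the per-read
    misassignment probability. ``rank_profile`` gives the distribution of
    canonical ranks at which *correct* assignments are emitted (on the truth
    lineage); it must sum to 1.
    """

    p_unassigned: float
    p_correct: float
    rank_profile: Mapping[str, float] = field(
        default_factory=lambda: {"species": 1.0}
    )
    misassignment_mode: MisassignmentMode = "sibling_species"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_unassigned <= 1 and 0 <= self.p_correct <= 1):
            raise ParameterError("p_unassigned and p_correct must be in [0, 1]")
        if self.p_unassigned + self.p_correct > 1 + 1e-12:
            raise ParameterError("p_unassigned + p_correct must be <= 1")
        for rank in self.rank_profile:
            if rank not in RANK_INDEX:
                raise ParameterError(f"rank_profile key {rank!r} is not a canonical rank")
        total = sum(self.rank_profile.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"rank_profile must sum to 1, got {total}")
        if self.misassignment_mode not in (
            "sibling_species", "random_other_clade", "lca_of_confusion_set",
        ):
            raise ParameterError(f"unknown misassignment_mode {self.misassignment_mode!r}")

    @property
    def p_misassigned(self) -> float:
        return max(0.0, 1.0 - self.p_unassigned - self.p_correct)


def _species_index(taxonomy: Taxonomy) -> tuple[list[int], dict[int, int]]:
    """All species taxids plus species → genus taxid (0 when no genus)."""
    species = sorted(n.taxid for n in taxonomy.nodes_at_rank("species"))
    genus_of: dict[int, int] = {}
    for sp in species:
        g = taxonomy.canonical_ancestor_at_rank(sp, RANK_INDEX["genus"])
        genus_of[sp] = g.taxid if g is not None else 0
    return species, genus_of


def simulate_classifier(
    truth: ReadTruthSet,
    taxonomy: Taxonomy,
    model: ClassifierModel,
) -> AssignmentSet:
    """Emit one assignment per truth read according to ``model``."""
    species, genus_of = _species_index(taxonomy)
    by_genus: dict[int, list[int]] = {}
    for sp, g in genus_of.items():
        by_genus.setdefault(g, []).append(sp)

    rank_labels = list(model.rank_profile)
    rank_probs = np.array([model.rank_profile[r] for r in rank_labels], dtype=float)
    rank_probs /= rank_probs.sum()

    # misassignment candidate pools, precomputed per truth species
    siblings_of: dict[int, list[int]] = {}
    others_of: dict[int, list[int]] = {}
    for sp in species:
        g = genus_of[sp]
        sibs = [s for s in by_genus.get(g, []) if s != sp]
        siblings_of[sp] = sibs
        if g == 0:
            others_of[sp] = [s for s in species if s != sp]
        else:
            others_of[sp] = [s for s in species if genus_of[s] != g]

    rng = np.random.default_rng(model.seed)
    assignments: dict[str, int | None] = {}
    fallback_logged = False

    for read_id, truth_taxid in zip(truth.df["read_id"], truth.df["taxid"]):
        truth_taxid = int(truth_taxid)
        sp_node = taxonomy.species_of(truth_taxid)
        truth_species = sp_node.taxid if sp_node is not None else truth_taxid
        u = rng.random()
        if u < model.p_unassigned:
            assignments[read_id] = None
            continue
        if u < model.p_unassigned + model.p_correct:
            # correct call at a rank drawn from the profile, on the truth lineage;
            # if that exact rank is missing from the lineage, walk up to the next
            # canonical ancestor that exists
            rank = rank_labels[rng.choice(len(rank_labels), p=rank_probs)]
            idx = RANK_INDEX[rank]
            node = None
            while node is None and idx <= RANK_INDEX["superkingdom"]:
                node = taxonomy.canonical_ancestor_at_rank(truth_species, idx)
                idx += 1
            assignments[read_id] = node.taxid if node is not None else taxonomy.root.taxid
            continue

        siblings = siblings_of.get(truth_species, [])
        others = others_of.get(truth_species, [s for s in species if s != truth_species])
        mode = model.misassignment_mode
        if mode in ("sibling_species", "lca_of_confusion_set") and not siblings:
            if not fallback_logged:
                logger.warning(
                    "truth species %d has no congeneric sibling; falling back to "
                    "random_other_clade", truth_species,
                )
                fallback_logged = True
            mode = "random_other_clade"
        if mode == "sibling_species":
            assignments[read_id] = int(siblings[rng.integers(len(siblings))])
        elif mode == "lca_of_confusion_set":
            sib = int(siblings[rng.integers(len(siblings))])
            assignments[read_id] = taxonomy.lca(truth_species, sib).taxid
        else:  # random_other_clade
            if not others:
                raise ParameterError(
                    "cannot misassign: taxonomy has no species outside the truth genus"
                )
            assignments[read_id] = int(others[rng.integers(len(others))])

    return AssignmentSet(assignments, source_label=f"simulated({model.misassignment_mode})")
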