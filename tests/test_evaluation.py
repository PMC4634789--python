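import math

import numpy as np
import pandas as pd
import pytest

from cladeval.assignment_io import AssignmentSet
from cladeval.clade_exclusion import ExclusionSpec
from cladeval.communities import CommunityMember, CommunityProfile
from cladeval.errors import ParameterError, UsageError
from cladeval.evaluation import (
    ConfusionCounts,
    EvalConfig,
    classify_read,
    evaluate,
    rank_distribution,
    taxonomic_distance_of_read,
)
from cladeval.read_sim import ReadTruthSet

from ._oracle import score_reads
from ._scenarios import random_scenario
from .conftest import (
    E_COLI,
    GAMMA,
    P_AERUGINOSA,
    P_FLUORESCENS,
    PAO1,
    PSEUDOMONAS,
)

FAMILY, ORDER = 6, 5  # Pseudomonadaceae, Pseudomonadales in the toy tree


def _truth_frame(rows):
    return ReadTruthSet(pd.DataFrame(
        rows, columns=["read_id", "genome_id", "taxid", "start", "strand"]
    ))


class TestClassifyRead:
    def test_unassigned_is_fn(self, toy_taxonomy):
        assert classify_read(None, P_AERUGINOSA, toy_taxonomy) == "FN"

    def test_on_path_ancestors_are_tp_strict(self, toy_taxonomy):
        for node in (P_AERUGINOSA, PSEUDOMONAS, FAMILY, ORDER, GAMMA, 2):
            assert classify_read(node, P_AERUGINOSA, toy_taxonomy) == "TP"

    def test_strain_truth_projects_to_species(self, toy_taxonomy):
        assert classify_read(P_AERUGINOSA, PAO1, toy_taxonomy) == "TP"
        assert classify_read(PAO1, PAO1, toy_taxonomy) == "TP"

    def test_sibling_species_strict_is_fp(self, toy_taxonomy):
        assert classify_read(P_FLUORESCENS, P_AERUGINOSA, toy_taxonomy) == "FP"

    def test_sibling_species_rescued_under_species_exclusion(self, toy_taxonomy):
        config = EvalConfig(exclusion=ExclusionSpec(P_AERUGINOSA, "species"),
                            overpredictions_correct=True)
        # both project to Pseudomonas at the genus (best possible) rank
        assert classify_read(P_FLUORESCENS, P_AERUGINOSA, toy_taxonomy, config) == "TP"

    def test_wrong_genus_not_rescued(self, toy_taxonomy):
        config = EvalConfig(exclusion=ExclusionSpec(P_AERUGINOSA, "species"),
                            overpredictions_correct=True)
        assert classify_read(E_COLI, P_AERUGINOSA, toy_taxonomy, config) == "FP"

    def test_overprediction_flag_without_exclusion_requires_exact_species(self, toy_taxonomy):
        config = EvalConfig(overpredictions_correct=True)
        assert classify_read(P_FLUORESCENS, P_AERUGINOSA, toy_taxonomy, config) == "FP"


class TestTaxonomicDistance:
    def test_species_assignment_no_exclusion(self, toy_taxonomy):
        assert taxonomic_distance_of_read(P_AERUGINOSA, P_AERUGINOSA, toy_taxonomy) == 0

    def test_genus_assignment_no_exclusion(self, toy_taxonomy):
        assert taxonomic_distance_of_read(PSEUDOMONAS, P_AERUGINOSA, toy_taxonomy) == 1

    def test_family_under_species_exclusion(self, toy_taxonomy):
        config = EvalConfig(exclusion=ExclusionSpec(P_AERUGINOSA, "species"))
        assert taxonomic_distance_of_read(FAMILY, P_AERUGINOSA, toy_taxonomy, config) == 1

    def test_clamped_at_zero_below_best_rank(self, toy_taxonomy):
        # correct species emitted even though species is excluded: distance 0
        config = EvalConfig(exclusion=ExclusionSpec(P_AERUGINOSA, "species"))
        assert taxonomic_distance_of_read(P_AERUGINOSA, P_AERUGINOSA,
                                          toy_taxonomy, config) == 0

    def test_usage_error_on_non_tp(self, toy_taxonomy):
        with pytest.raises(UsageError):
            taxonomic_distance_of_read(P_FLUORESCENS, P_AERUGINOSA, toy_taxonomy)

    def test_best_rank_rises_and_distance_never_increases(self, toy_taxonomy):
        prev_best = -1
        prev_dist = math.inf
        for rank in ("species", "genus", "family", "order", "class"):
            config = EvalConfig(exclusion=ExclusionSpec(P_AERUGINOSA, rank))
            best = config.exclusion.best_possible_rank_index
            assert best > prev_best
            d = taxonomic_distance_of_read(GAMMA, P_AERUGINOSA, toy_taxonomy, config)
            assert d <= prev_dist
            prev_best, prev_dist = best, d


class TestFormulas:
    @pytest.mark.parametrize("tp,fp,fn", [
        (tp, fp, fn) for tp in range(4) for fp in range(4) for fn in range(4)
    ])
    def test_sensitivity_and_precision_on_count_grid(self, tp, fp, fn):
        c = ConfusionCounts(TP=tp, FP=fp, FN=fn)
        assert c.sensitivity == (tp / (tp + fn) if tp + fn else None)
        assert c.precision == (tp / (tp + fp) if tp + fp else None)
        assert c.total == tp + fp + fn


class TestEvaluate:
    def test_perfect_classifier(self, toy_taxonomy):
        truth = _truth_frame([(f"r{i}", "pa", P_AERUGINOSA, 0, "+") for i in range(5)]
                             + [(f"s{i}", "ec", E_COLI, 0, "+") for i in range(5)])
        aset = AssignmentSet({f"r{i}": P_AERUGINOSA for i in range(5)}
                             | {f"s{i}": E_COLI for i in range(5)})
        result = evaluate(aset, truth, toy_taxonomy)
        assert result.aggregate_sensitivity == 1.0
        assert result.aggregate_precision == 1.0
        assert result.aggregate_taxonomic_distance == 0.0

    def test_three_tp_one_fn(self, toy_taxonomy):
        truth = _truth_frame([(f"r{i}", "pa", P_AERUGINOSA, 0, "+") for i in range(4)])
        aset = AssignmentSet({"r0": P_AERUGINOSA, "r1": P_AERUGINOSA,
                              "r2": PSEUDOMONAS, "r3": None})
        result = evaluate(aset, truth, toy_taxonomy)
        m = result.per_genome["pa"]
        assert (m.counts.TP, m.counts.FP, m.counts.FN) == (3, 0, 1)
        assert m.sensitivity == 0.75
        assert m.precision == 1.0

    def test_counts_partition_reads(self, toy_taxonomy):
        truth = _truth_frame([(f"r{i}", "pa", P_AERUGINOSA, 0, "+") for i in range(6)])
        aset = AssignmentSet({"r0": P_AERUGINOSA, "r1": E_COLI, "r2": None,
                              "r3": P_FLUORESCENS, "r4": GAMMA})  # r5 missing
        result = evaluate(aset, truth, toy_taxonomy)
        assert result.per_genome["pa"].counts.total == 6

    def test_precision_undefined_when_nothing_assigned(self, toy_taxonomy):
        truth = _truth_frame([("r0", "pa", P_AERUGINOSA, 0, "+"),
                              ("s0", "ec", E_COLI, 0, "+")])
        aset = AssignmentSet({"r0": None, "s0": E_COLI})
        result = evaluate(aset, truth, toy_taxonomy)
        assert result.per_genome["pa"].precision is None
        assert result.per_genome["pa"].taxonomic_distance is None
        # undefined genomes excluded from the aggregate mean, reported in summary
        assert result.aggregate_precision == 1.0
        assert result.summary()["n_genomes_precision_defined"] == 1

    def test_zero_truth_reads_rejected(self, toy_taxonomy):
        empty = ReadTruthSet(pd.DataFrame(
            [], columns=["read_id", "genome_id", "taxid", "start", "strand"]
        ))
        with pytest.raises(ParameterError):
            evaluate(AssignmentSet({}), empty, toy_taxonomy)

    def test_matches_brute_force_oracle_on_random_scenarios(self):
        rng = np.random.default_rng(2024)
        for trial in range(40):
            raw, taxonomy, truth, aset = random_scenario(rng, max_reads=200)
            overpred = bool(rng.integers(2))
            rank = [None, "species", "genus", "family"][rng.integers(4)]
            leaf0 = int(truth.df["taxid"].iloc[0])
            spec = (ExclusionSpec(leaf0, rank) if rank else ExclusionSpec(1, None))
            config = EvalConfig(exclusion=spec, overpredictions_correct=overpred)
            result = evaluate(aset, truth, taxonomy, config)
            reads = [
                (row.genome_id, int(row.taxid), aset.assignments[row.read_id])
                for row in truth.df.itertuples()
            ]
            expected = score_reads(raw, reads, spec.best_possible_rank_index, overpred)
            assert set(result.per_genome) == set(expected)
            for gid, exp in expected.items():
                got = result.per_genome[gid]
                assert (got.counts.TP, got.counts.FP, got.counts.FN) == \
                    (exp["TP"], exp["FP"], exp["FN"])
                assert got.sensitivity == pytest.approx(exp["sensitivity"])
                if exp["precision"] is None:
                    assert got.precision is None
                else:
                    assert got.precision == pytest.approx(exp["precision"])
                if exp["distance"] is None:
                    assert got.taxonomic_distance is None
                else:
                    assert got.taxonomic_distance == pytest.approx(exp["distance"])

    def test_overprediction_mode_never_decreases_metrics(self):
        rng = np.random.default_rng(99)
        for trial in range(20):
            raw, taxonomy, truth, aset = random_scenario(rng, max_reads=150)
            leaf0 = int(truth.df["taxid"].iloc[0])
            spec = ExclusionSpec(leaf0, "species")
            strict = evaluate(aset, truth, taxonomy,
                              EvalConfig(exclusion=spec))
            loose = evaluate(aset, truth, taxonomy,
                             EvalConfig(exclusion=spec, overpredictions_correct=True))
            for gid in strict.per_genome:
                assert loose.per_genome[gid].counts.TP >= strict.per_genome[gid].counts.TP
            assert loose.aggregate_sensitivity >= strict.aggregate_sensitivity - 1e-12
            sp, lp = strict.aggregate_precision, loose.aggregate_precision
            if sp is not None and lp is not None:
                assert lp >= sp - 1e-12


class TestPooledMode:
    @pytest.fixture()
    def community(self):
        return CommunityProfile("toy", [
            CommunityMember("pa", "P. aeruginosa", P_AERUGINOSA),
            CommunityMember("ec", "E. coli", E_COLI),
        ])

    def test_hit_to_any_member_is_correct(self, toy_taxonomy, community):
        # reads truly from P. aeruginosa but assigned to E. coli: pooled mode
        # cannot attribute reads, so a hit to any community taxon counts
        truth = _truth_frame([(f"r{i}", "pa", P_AERUGINOSA, 0, "+") for i in range(4)])
        aset = AssignmentSet({"r0": E_COLI, "r1": P_AERUGINOSA,
                              "r2": None, "r3": P_FLUORESCENS})
        config = EvalConfig(aggregation="pooled", pooled_community=community)
        result = evaluate(aset, truth, toy_taxonomy, config)
        assert (result.pooled.counts.TP, result.pooled.counts.FP,
                result.pooled.counts.FN) == (2, 1, 1)
        assert result.pooled.sensitivity == pytest.approx(2 / 3)
        assert result.pooled.precision == pytest.approx(2 / 3)

    def test_pooled_requires_community(self):
        with pytest.raises(ParameterError):
            EvalConfig(aggregation="pooled")
        with pytest.raises(ParameterError):
            EvalConfig(pooled_community=CommunityProfile("x", []))

    def test_pooled_distance_is_over_tp_reads(self, toy_taxonomy, community):
        truth = _truth_frame([("r0", "pa", P_AERUGINOSA, 0, "+"),
                              ("r1", "pa", P_AERUGINOSA, 0, "+")])
        aset = AssignmentSet({"r0": PSEUDOMONAS, "r1": P_AERUGINOSA})
        config = EvalConfig(aggregation="pooled", pooled_community=community)
        result = evaluate(aset, truth, toy_taxonomy, config)
        assert result.pooled.taxonomic_distance == pytest.approx(0.5)


class TestRankDistribution:
    def test_all_species(self, toy_taxonomy):
        aset = AssignmentSet({"r0": P_AERUGINOSA, "r1": E_COLI})
        rd = rank_distribution(aset, toy_taxonomy)
        assert rd.fractions_of_assigned == {"species": 1.0}
        assert rd.unassigned_fraction == 0.0

    def test_half_species_half_genus(self, toy_taxonomy):
        aset = AssignmentSet({"r0": P_AERUGINOSA, "r1": PSEUDOMONAS})
        rd = rank_distribution(aset, toy_taxonomy)
        assert rd.fractions_of_assigned == {"species": 0.5, "genus": 0.5}

    def test_all_unassigned(self, toy_taxonomy):
        aset = AssignmentSet({"r0": None, "r1": None})
        rd = rank_distribution(aset, toy_taxonomy)
        assert rd.fractions_of_assigned == {}
        assert rd.unassigned_fraction == 1.0

    def test_strain_bins_at_species_and_fractions_sum_to_one(self, toy_taxonomy):
        aset = AssignmentSet({"r0": PAO1, "r1": GAMMA, "r2": None, "r3": 1})
        rd = rank_distribution(aset, toy_taxonomy)
        assert rd.counts == {"species": 1, "class": 1, "above_superkingdom": 1}
        assert sum(rd.fractions_of_assigned.values()) == pytest.approx(1.0)
        assert sum(rd.fractions_of_all.values()) + rd.unassigned_fraction == \
            pytest.approx(1.0)
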