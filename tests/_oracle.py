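"""Independent brute-force re-derivation of the scoring rules.

Deliberately written against raw ``taxid -> (parent, rank)`` dictionaries,
never against the package's Taxonomy/evaluation code, so the two routes can
disagree. Everything is the most literal possible transcription of the
scoring definitions: path membership by explicit root-walk, distance by
counting ladder steps, metrics from re-accumulated counts.
"""

from __future__ import annotations

LADDER = ["species", "genus", "family", "order", "class", "phylum", "superkingdom"]


def walk_to_root(tree: dict[int, tuple[int, str]], taxid: int) -> list[int]:
    path = [taxid]
    while tree[taxid][0] != taxid:
        taxid = tree[taxid][0]
        path.append(taxid)
    return path


def ladder_index(tree: dict[int, tuple[int, str]], taxid: int) -> int:
    """Ladder index of the deepest canonical ancestor-or-self; 7 when none."""
    for node in walk_to_root(tree, taxid):
        rank = tree[node][1]
        if rank in LADDER:
            return LADDER.index(rank)
    return len(LADDER)


def species_of(tree: dict[int, tuple[int, str]], taxid: int) -> int:
    for node in walk_to_root(tree, taxid):
        if tree[node][1] == "species":
            return node
    return taxid


def on_path(tree: dict[int, tuple[int, str]], assigned: int, truth: int) -> bool:
    truth_sp = species_of(tree, truth)
    return assigned in walk_to_root(tree, truth_sp) or truth_sp in walk_to_root(tree, assigned)


def ancestor_at(tree: dict[int, tuple[int, str]], taxid: int, rank: str) -> int | None:
    for node in walk_to_root(tree, taxid):
        if tree[node][1] == rank:
            return node
    return None


def classify(
    tree: dict[int, tuple[int, str]],
    assigned: int | None,
    truth: int,
    best_rank_index: int = 0,
    overpredictions_correct: bool = False,
) -> str:
    if assigned is None:
        return "FN"
    if on_path(tree, assigned, truth):
        return "TP"
    if overpredictions_correct and best_rank_index < len(LADDER):
        rank = LADDER[best_rank_index]
        a = ancestor_at(tree, assigned, rank)
        t = ancestor_at(tree, species_of(tree, truth), rank)
        if a is not None and t is not None and a == t:
            return "TP"
    return "FP"


def distance(tree: dict[int, tuple[int, str]], assigned: int, best_rank_index: int) -> int:
    d = ladder_index(tree, assigned) - best_rank_index
    return d if d > 0 else 0


def score_reads(
    tree: dict[int, tuple[int, str]],
    reads: list[tuple[str, int, int | None]],  # (genome_id, truth_taxid, assigned)
    best_rank_index: int = 0,
    overpredictions_correct: bool = False,
) -> dict[str, dict[str, float | None]]:
    """Per-genome TP/FP/FN, sensitivity, precision, distance — re-derived."""
    per: dict[str, dict[str, float]] = {}
    dists: dict[str, list[int]] = {}
    for gid, truth, assigned in reads:
        g = per.setdefault(gid, {"TP": 0, "FP": 0, "FN": 0})
        out = classify(tree, assigned, truth, best_rank_index, overpredictions_correct)
        g[out] += 1
        if out == "TP":
            dists.setdefault(gid, []).append(distance(tree, assigned, best_rank_index))
    result = {}
    for gid, g in per.items():
        tp, fp, fn = g["TP"], g["FP"], g["FN"]
        result[gid] = {
            "TP": tp, "FP": fp, "FN": fn,
            "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
            "precision": tp / (tp + fp) if tp + fp else None,
            "distance": sum(dists[gid]) / len(dists[gid]) if gid in dists else None,
        }
    return result
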