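"""Summaries and evaluation of per-read taxonomic profiles.

Profiles are summarised into frequency tables (optionally snapped to a
canonical rank, CSV-exportable), evaluated against a truth table with
confusion-matrix metrics, and exported as a rooted hierarchical JSON
document for visualization.

Evaluation follows the snap-to-rank convention: predictions more
specific than the rank under evaluation are mapped onto it, predictions
less specific count as no assignment, and reads whose expected
identification is less specific than the rank are ignored. Shuffled
reads are a negative control: assigning them anything is a false
positive, leaving them at the root a true negative.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .profiler import ReadProfile
from .taxonomy import ROOT_ID, TaxonomyTree

__all__ = [
    "FrequencyTable",
    "EvaluationResult",
    "frequency_table",
    "evaluate",
    "export_tree_json",
]


@dataclass(frozen=True)
class FrequencyTable:
    """Taxon frequency rows sorted by descending count, then id."""

    rows: tuple[tuple[int, str, str, int], ...]  # (id, name, rank, count)
    rank_filter: str | None = None
    min_count: int = 1
    total_reads: int = 0

    def to_csv(self, sink) -> None:
        """Write as CSV with header taxon_id,taxon_name,taxon_rank,count."""
        own = not hasattr(sink, "write")
        handle = open(sink, "wt", encoding="utf-8", newline="") if own else sink
        try:
            writer = csv.writer(handle, lineterminator="\n")
            writer.writerow(["taxon_id", "taxon_name", "taxon_rank", "count"])
            writer.writerows(self.rows)
        finally:
            if own:
                handle.close()


def frequency_table(
    profiles: Iterable[ReadProfile],
    tree: TaxonomyTree,
    rank: str | None = None,
    min_count: int = 1,
) -> FrequencyTable:
    """Aggregate read profiles into a taxon frequency table.

    When ``rank`` is given every profile is first snapped onto it;
    profiles that snap to the root appear as an "unassigned" root row.
    Rows below ``min_count`` are dropped.
    """
    counts: dict[int, int] = {}
    total = 0
    for profile in profiles:
        total += 1
        taxon_id = profile.taxon_id
        if rank is not None:
            taxon_id = tree.snap_to_rank(taxon_id, rank)
        counts[taxon_id] = counts.get(taxon_id, 0) + 1
    rows = []
    for taxon_id, count in counts.items():
        if count < min_count:
            continue
        if taxon_id == ROOT_ID:
            rows.append((ROOT_ID, "unassigned", tree[ROOT_ID].rank, count))
        else:
            taxon = tree[taxon_id]
            rows.append((taxon.id, taxon.name, taxon.rank, count))
    rows.sort(key=lambda row: (-row[3], row[0]))
    return FrequencyTable(tuple(rows), rank, min_count, total)


@dataclass(frozen=True)
class EvaluationResult:
    """Confusion-matrix counts and derived metrics at one rank.

    Metrics with an empty denominator are reported as 0.0 and listed in
    ``undefined`` rather than raising, since small data sets routinely
    produce empty classes.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    sensitivity: float
    specificity: float
    npv: float
    mcc: float
    ignored: int = 0
    undefined: frozenset[str] = frozenset()


def _safe_ratio(num: float, den: float, name: str, undefined: set[str]) -> float:
    if den == 0:
        undefined.add(name)
        return 0.0
    return num / den


def evaluate(
    profiles: Iterable[ReadProfile],
    truth: Mapping[str, int],
    tree: TaxonomyTree,
    rank: str,
    shuffled: Iterable[str] = (),
) -> EvaluationResult:
    """Score profiles against the truth at a canonical rank.

    True positives: non-shuffled reads assigned the expected taxon.
    False positives: non-shuffled reads assigned a different taxon, or
    shuffled reads assigned anything. True negatives: shuffled reads
    left unassigned. False negatives: non-shuffled reads left
    unassigned. Reads whose expected taxon is less specific than
    ``rank`` are ignored.
    """
    shuffled_ids = set(shuffled)
    tp = fp = fn = tn = ignored = 0
    for profile in profiles:
        predicted = tree.snap_to_rank(profile.taxon_id, rank)
        assigned = predicted != ROOT_ID
        if profile.read_id in shuffled_ids:
            if assigned:
                fp += 1
            else:
                tn += 1
            continue
        if profile.read_id not in truth:
            raise ValueError(f"read {profile.read_id!r} missing from truth table")
        expected = tree.snap_to_rank(truth[profile.read_id], rank)
        if expected == ROOT_ID:
            ignored += 1
            continue
        if not assigned:
            fn += 1
        elif predicted == expected:
            tp += 1
        else:
            fp += 1

    undefined: set[str] = set()
    precision = _safe_ratio(tp, tp + fp, "precision", undefined)
    sensitivity = _safe_ratio(tp, tp + fn, "sensitivity", undefined)
    specificity = _safe_ratio(tn, tn + fp, "specificity", undefined)
    npv = _safe_ratio(tn, tn + fn, "npv", undefined)
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _safe_ratio(tp * tn - fp * fn, mcc_den, "mcc", undefined)
    return EvaluationResult(
        tp, fp, fn, tn, precision, sensitivity, specificity, npv, mcc,
        ignored, frozenset(undefined),
    )


def export_tree_json(table: FrequencyTable, tree: TaxonomyTree) -> dict:
    """Render a frequency table as a rooted hierarchical document.

    Each node carries its own read count (``self_count``) and the
    subtree total (``subtree_count`` = self + children), suitable for
    sunburst/treeview rendering. Taxa absent from the table appear only
    as connecting nodes with ``self_count`` 0.
    """
    self_counts = {row[0]: row[3] for row in table.rows}
    children_map: dict[int, list[int]] = {ROOT_ID: []}
    needed: set[int] = {ROOT_ID}
    for taxon_id in self_counts:
        for node in tree.lineage(taxon_id):
            needed.add(node)
    for node in needed:
        lineage = tree.lineage(node)
        if len(lineage) > 1:
            children_map.setdefault(lineage[-2], []).append(node)
        children_map.setdefault(node, children_map.get(node, []))
    for ids in children_map.values():
        ids.sort()
    # deduplicate child lists (a node may be reached via several leaves)
    children_map = {k: sorted(set(v)) for k, v in children_map.items()}

    def build(node: int) -> dict:
        taxon = tree[node]
        kids = [build(child) for child in children_map.get(node, [])]
        self_count = self_counts.get(node, 0)
        name = "unassigned" if node == ROOT_ID and ROOT_ID in self_counts else taxon.name
        return {
            "id": node,
            "name": name if node != ROOT_ID else taxon.name or "root",
            "rank": taxon.rank,
            "self_count": self_count,
            "subtree_count": self_count + sum(k["subtree_count"] for k in kids),
            "children": kids,
        }

    return build(ROOT_ID)


def write_tree_json(table: FrequencyTable, tree: TaxonomyTree, sink) -> None:
    document = export_tree_json(table, tree)
    if hasattr(sink, "write"):
        json.dump(document, sink, indent=1)
    else:
        with open(sink, "wt", encoding="utf-8") as handle:
            json.dump(document, handle, indent=1)
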