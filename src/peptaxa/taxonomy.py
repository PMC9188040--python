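"""Taxonomic tree handling and per-read consensus heuristics.

The taxonomy is an NCBI-style rooted tree: integer identifiers, named
ranks, parent links, and a validity flag per node. On top of it live the
four consensus heuristics used to collapse a multiset of per-peptide
identifications into a single taxon for a read:

* **LCA** — the deepest taxon that is an ancestor of every input taxon.
* **LCA*** — the LCA computed after discarding every input taxon that is
  a strict ancestor of another input taxon; equivalently, the most
  specific taxon that contradicts no input (every input is an ancestor
  or a descendant of it).
* **MRTL** (maximum root-to-leaf) — the input taxon whose lineage covers
  the largest count-weighted number of inputs; always a member of the
  input.
* **hybrid_f** — a greedy root-to-leaf descent that keeps descending
  past a split only while the heaviest child subtree holds a fraction
  >= ``f`` of the remaining identification mass. ``f = 1`` reproduces
  LCA*; ``f = 0`` is close to MRTL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "CANONICAL_RANKS",
    "Taxon",
    "TaxonomyTree",
    "TaxonomyError",
    "load_taxonomy",
    "aggregate_lca",
    "aggregate_lca_star",
    "aggregate_mrtl",
    "aggregate_hybrid",
]

ROOT_ID = 1

#: Canonical rank order, root-most to leaf-most (the NCBI list as used
#: by protein-database taxonomies). "no rank" is allowed on any node but
#: is not a snap target.
CANONICAL_RANKS: tuple[str, ...] = (
    "superkingdom",
    "kingdom",
    "subkingdom",
    "superphylum",
    "phylum",
    "subphylum",
    "superclass",
    "class",
    "subclass",
    "infraclass",
    "superorder",
    "order",
    "suborder",
    "infraorder",
    "parvorder",
    "superfamily",
    "family",
    "subfamily",
    "tribe",
    "subtribe",
    "genus",
    "subgenus",
    "species group",
    "species subgroup",
    "species",
    "subspecies",
    "varietas",
    "forma",
)


class TaxonomyError(ValueError):
    """Structural or lookup problem in a taxonomy."""


@dataclass(frozen=True)
class Taxon:
    id: int
    name: str
    rank: str
    parent_id: int
    valid: bool = True


class TaxonomyTree:
    """A validated rooted taxonomy with lineage and consensus queries.

    Parameters
    ----------
    taxa:
        Taxon records. Must contain the root (id 1, its own parent) and
        form a single tree: every parent resolves and every parent chain
        terminates at the root.
    rank_order:
        Ordered canonical ranks, root-most first.
    """

    def __init__(
        self,
        taxa: Iterable[Taxon],
        rank_order: tuple[str, ...] = CANONICAL_RANKS,
    ) -> None:
        self.taxa: dict[int, Taxon] = {}
        self.rank_order = tuple(rank_order)
        for taxon in taxa:
            if taxon.id in self.taxa:
                raise TaxonomyError(f"duplicate taxon id {taxon.id}")
            self.taxa[taxon.id] = taxon
        self._validate()
        self._lineages: dict[int, tuple[int, ...]] = {}
        self._children: dict[int, list[int]] = {tid: [] for tid in self.taxa}
        for taxon in self.taxa.values():
            if taxon.id != ROOT_ID:
                self._children[taxon.parent_id].append(taxon.id)
        for ids in self._children.values():
            ids.sort()

    def _validate(self) -> None:
        root = self.taxa.get(ROOT_ID)
        if root is None or root.parent_id != ROOT_ID:
            raise TaxonomyError("taxonomy must contain root taxon 1 with parent 1")
        for taxon in self.taxa.values():
            if taxon.id != ROOT_ID and taxon.parent_id not in self.taxa:
                raise TaxonomyError(
                    f"taxon {taxon.id} has unknown parent {taxon.parent_id}"
                )
        # parent chains must reach the root (no cycles)
        for taxon in self.taxa.values():
            seen = set()
            node = taxon.id
            while node != ROOT_ID:
                if node in seen:
                    raise TaxonomyError(f"cycle through taxon {node}")
                seen.add(node)
                node = self.taxa[node].parent_id

    # -- basic queries ---------------------------------------------------

    def __contains__(self, taxon_id: int) -> bool:
        return taxon_id in self.taxa

    def __len__(self) -> int:
        return len(self.taxa)

    def __getitem__(self, taxon_id: int) -> Taxon:
        try:
            return self.taxa[taxon_id]
        except KeyError:
            raise TaxonomyError(f"unknown taxon id {taxon_id}") from None

    def children(self, taxon_id: int) -> tuple[int, ...]:
        self[taxon_id]
        return tuple(self._children[taxon_id])

    def lineage(self, taxon_id: int) -> tuple[int, ...]:
        """Root-first path of taxon ids from the root down to ``taxon_id``."""
        cached = self._lineages.get(taxon_id)
        if cached is not None:
            return cached
        self[taxon_id]
        path = []
        node = taxon_id
        while node != ROOT_ID:
            path.append(node)
            node = self.taxa[node].parent_id
        path.append(ROOT_ID)
        result = tuple(reversed(path))
        self._lineages[taxon_id] = result
        return result

    def depth(self, taxon_id: int) -> int:
        return len(self.lineage(taxon_id)) - 1

    def is_ancestor(self, a: int, b: int) -> bool:
        """True iff ``a`` lies on the lineage of ``b`` (every taxon is its
        own ancestor)."""
        self[a]
        return a in self.lineage(b)

    def valid_ancestor(self, taxon_id: int) -> int:
        """Nearest ancestor-or-self flagged valid (the root is always
        accepted as a fallback)."""
        for node in reversed(self.lineage(taxon_id)):
            if self.taxa[node].valid or node == ROOT_ID:
                return node
        return ROOT_ID

    def snap_to_rank(self, taxon_id: int, rank: str) -> int:
        """Map a taxon onto a canonical rank.

        Returns the lineage ancestor carrying ``rank`` when one exists;
        otherwise the root (1), meaning the identification is less
        specific than the rank under consideration and counts as no
        assignment. Idempotent for every taxon/rank pair.
        """
        if rank not in self.rank_order:
            raise TaxonomyError(f"unknown rank {rank!r}")
        for node in reversed(self.lineage(taxon_id)):
            if self.taxa[node].rank == rank:
                return node
        return ROOT_ID


def load_taxonomy(source) -> TaxonomyTree:
    """Read a taxonomy from a tab-separated node table.

    One row per taxon with five fields: id, name, rank, parent id and a
    true/false validity flag; no header. ``source`` may be a path or an
    open text stream.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source, "rt", encoding="utf-8") as handle:
            lines = handle.read().splitlines()
    taxa = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\r\n").split("\t")
        if len(fields) != 5:
            raise TaxonomyError(
                f"line {lineno}: expected 5 tab-separated fields, got {len(fields)}"
            )
        raw_id, name, rank, raw_parent, raw_valid = fields
        try:
            taxon_id = int(raw_id)
            parent_id = int(raw_parent)
        except ValueError:
            raise TaxonomyError(f"line {lineno}: non-integer taxon/parent id") from None
        if raw_valid not in ("true", "false"):
            raise TaxonomyError(f"line {lineno}: validity flag must be true/false")
        taxa.append(Taxon(taxon_id, name, rank, parent_id, raw_valid == "true"))
    return TaxonomyTree(taxa)


def save_taxonomy(tree: TaxonomyTree, sink) -> None:
    """Write the 5-column tab-separated node table (sorted by id, LF)."""
    rows = [
        "\t".join(
            (
                str(t.id),
                t.name,
                t.rank,
                str(t.parent_id),
                "true" if t.valid else "false",
            )
        )
        for t in sorted(tree.taxa.values(), key=lambda t: t.id)
    ]
    text = "\n".join(rows) + "\n"
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with open(sink, "wt", encoding="utf-8", newline="\n") as handle:
            handle.write(text)


# -- consensus heuristics ------------------------------------------------


def _check_multiset(tree: TaxonomyTree, taxa: Mapping[int, int]) -> dict[int, int]:
    if not taxa:
        raise ValueError("consensus of an empty taxon multiset is undefined")
    clean: dict[int, int] = {}
    for tid, count in taxa.items():
        tree[tid]
        if count <= 0:
            raise ValueError(f"non-positive count {count} for taxon {tid}")
        clean[tid] = count
    return clean


def aggregate_lca(tree: TaxonomyTree, taxa: Mapping[int, int]) -> int:
    """Deepest taxon that is an ancestor of every taxon in the multiset."""
    counts = _check_multiset(tree, taxa)
    lineages = [tree.lineage(tid) for tid in counts]
    prefix_len = min(len(l) for l in lineages)
    result = ROOT_ID
    for i in range(prefix_len):
        node = lineages[0][i]
        if all(l[i] == node for l in lineages):
            result = node
        else:
            break
    return result


def _drop_strict_ancestors(tree: TaxonomyTree, counts: dict[int, int]) -> dict[int, int]:
    kept = {}
    for tid, count in counts.items():
        strict_ancestor = any(
            tid != other and tree.is_ancestor(tid, other) for other in counts
        )
        if not strict_ancestor:
            kept[tid] = count
    return kept


def aggregate_lca_star(tree: TaxonomyTree, taxa: Mapping[int, int]) -> int:
    """Most specific taxon contradicting no input taxon.

    Computed as the LCA of the inputs after discarding every input that
    is a strict ancestor of another input; every input is then an
    ancestor or a descendant of the result.
    """
    counts = _check_multiset(tree, taxa)
    return aggregate_lca(tree, _drop_strict_ancestors(tree, counts))


def aggregate_mrtl(tree: TaxonomyTree, taxa: Mapping[int, int]) -> int:
    """Input taxon whose lineage holds the most (count-weighted) inputs.

    The result is always a member of the input multiset. Ties break on
    the smallest taxon id for reproducibility.
    """
    counts = _check_multiset(tree, taxa)
    best_id, best_score = None, -1
    for candidate in sorted(counts):
        lineage = set(tree.lineage(candidate))
        score = sum(count for tid, count in counts.items() if tid in lineage)
        if score > best_score:
            best_id, best_score = candidate, score
    assert best_id is not None
    return best_id


def aggregate_hybrid(tree: TaxonomyTree, taxa: Mapping[int, int], f: float) -> int:
    """Greedy root-to-leaf descent interpolating LCA* (f=1) toward MRTL.

    Strict ancestors of other inputs are discarded first (the LCA*
    preprocessing), leaving an antichain of identifications whose counts
    form the descent mass. From the root, while a single child subtree
    holds all remaining mass the descent follows it; at a genuine split
    it continues into the heaviest child (smallest id on ties) only when
    that child's share of the current node's mass is >= ``f``.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"hybrid fraction f must be in [0, 1], got {f}")
    counts = _check_multiset(tree, taxa)
    counts = _drop_strict_ancestors(tree, counts)

    # mass[node] = count of remaining identifications in node's subtree
    mass: dict[int, int] = {}
    for tid, count in counts.items():
        for node in tree.lineage(tid):
            mass[node] = mass.get(node, 0) + count

    node = ROOT_ID
    while True:
        here = mass[node]
        candidates = [c for c in tree.children(node) if mass.get(c, 0) > 0]
        if not candidates:
            return node
        child = max(candidates, key=lambda c: (mass[c], -c))
        if mass[child] == here:
            node = child  # single subtree holds everything: LCA* descent
        elif mass[child] / here >= f:
            node = child
        else:
            return node
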