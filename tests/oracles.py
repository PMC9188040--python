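"""Brute-force reference implementations used only by the tests.

Each oracle recomputes a result by exhaustive scanning or fixed-point
iteration, independently of the algorithms in the package, so that the
two routes can be compared on small inputs.
"""

from __future__ import annotations

import random

from peptaxa.taxonomy import Taxon, TaxonomyTree


def random_tree(rng: random.Random, n_nodes: int) -> TaxonomyTree:
    """A random rooted tree with ids 1..n (1 = root), arbitrary ranks."""
    ranks = ["no rank", "superkingdom", "phylum", "class", "order",
             "family", "genus", "species"]
    taxa = [Taxon(1, "root", "no rank", 1)]
    for node in range(2, n_nodes + 1):
        parent = rng.randint(1, node - 1)
        taxa.append(Taxon(node, f"n{node}", rng.choice(ranks), parent))
    return TaxonomyTree(taxa)


def _comparable(tree: TaxonomyTree, a: int, b: int) -> bool:
    return tree.is_ancestor(a, b) or tree.is_ancestor(b, a)


def lca_oracle(tree: TaxonomyTree, taxa: dict[int, int]) -> int:
    """Deepest node that is an ancestor of every input, by full scan."""
    best, best_depth = 1, -1
    for node in tree.taxa:
        if all(tree.is_ancestor(node, t) for t in taxa):
            depth = tree.depth(node)
            if depth > best_depth or (depth == best_depth and node < best):
                best, best_depth = node, depth
    return best


def lca_star_oracle(tree: TaxonomyTree, taxa: dict[int, int]) -> int:
    """Deepest node consistent (ancestor-or-descendant) with every input.

    Restricting candidates to ancestors of at least one input makes the
    deepest consistent node unique: the most specific taxon that
    contradicts no input.
    """
    best, best_depth = 1, -1
    for node in tree.taxa:
        if not any(tree.is_ancestor(node, t) for t in taxa):
            continue
        if all(_comparable(tree, node, t) for t in taxa):
            depth = tree.depth(node)
            if depth > best_depth or (depth == best_depth and node < best):
                best, best_depth = node, depth
    return best


def mrtl_oracle(tree: TaxonomyTree, taxa: dict[int, int]) -> int:
    """Enumerate the members; count-weighted lineage score; id tie-break."""
    def score(candidate: int) -> int:
        lineage = tree.lineage(candidate)
        return sum(c for t, c in taxa.items() if t in lineage)

    return min(taxa, key=lambda t: (-score(t), t))


def hybrid_oracle(tree: TaxonomyTree, taxa: dict[int, int], f: float) -> int:
    """Recursive descent recomputing subtree masses from scratch."""
    remaining = {
        t: c
        for t, c in taxa.items()
        if not any(t != o and tree.is_ancestor(t, o) for o in taxa)
    }

    def subtree_mass(node: int) -> int:
        return sum(c for t, c in remaining.items() if tree.is_ancestor(node, t))

    def descend(node: int) -> int:
        here = subtree_mass(node)
        weighted = [(subtree_mass(c), c) for c in tree.children(node)]
        weighted = [(m, c) for m, c in weighted if m > 0]
        if not weighted:
            return node
        mass, child = max(weighted, key=lambda mc: (mc[0], -mc[1]))
        if mass == here or mass / here >= f:
            return descend(child)
        return node

    return descend(1)


def seed_extend_oracle(values: list, s: int, g: int) -> list[int]:
    """Retained item indices for one adjacency segment, by fixed point.

    ``values`` holds a taxon id or None per item. Seeds are windows of
    >= s equal identified values; then any identified item separated
    from a retained item only by <= g unidentified items joins, until
    nothing changes.
    """
    n = len(values)
    retained: set[int] = set()
    for i in range(n - s + 1):
        window = values[i : i + s]
        if window[0] is not None and all(v == window[0] for v in window):
            retained.update(range(i, i + s))
    changed = True
    while changed:
        changed = False
        for j in range(n):
            if values[j] is None or j in retained:
                continue
            for r in retained:
                lo, hi = (j, r) if j < r else (r, j)
                between = values[lo + 1 : hi]
                if all(v is None for v in between) and len(between) <= g:
                    retained.add(j)
                    changed = True
                    break
    return sorted(i for i in retained if values[i] is not None)
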