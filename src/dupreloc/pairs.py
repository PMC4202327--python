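"""Discovery of candidate duplicate pairs from gene-family tree sets.

Candidate pairs are the two-member monophyletic groups (cherries) of the
strict-majority (>50%) consensus of a bootstrap tree set.  Pairs already
attributed to the alpha whole-genome duplication or to tandem duplication
are labelled from the supplied rosters; the remainder are "other"
duplicates.  A pairwise dS cutoff (default 1.0, inclusive — roughly the
mean age of the alpha-WGD duplicates) removes older pairs so that only
lineage-specific duplications remain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy

logger = logging.getLogger(__name__)

DS_CUTOFF_DEFAULT = 1.0


@dataclass
class DuplicatePair:
    gene1: str
    gene2: str
    duplication_type: str = "unlabeled"  # alpha-WGD | tandem | other
    ds: float | None = None

    def __post_init__(self) -> None:
        if self.gene1 == self.gene2:
            raise ValueError(f"a pair needs two distinct genes, got {self.gene1!r} twice")
        if self.ds is not None and not self.ds >= 0:
            raise ValueError(f"dS must be >= 0, got {self.ds}")

    @property
    def key(self) -> frozenset[str]:
        return frozenset((self.gene1, self.gene2))


def _tree_clades(tree: dendropy.Tree, taxa: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial clades (monophyletic leaf sets) of a rooted tree."""
    n = len(taxa)
    clades: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        clade = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if 2 <= len(clade) <= n - 1:
            clades.add(clade)
    return clades


def majority_consensus(trees: list[dendropy.Tree],
                       threshold: float = 0.5) -> dendropy.Tree:
    """Strict-majority-rule consensus of a tree set.

    Trees are read as rooted (gene-family trees come rooted as written);
    the consensus keeps exactly the non-trivial clades present in strictly
    more than ``threshold`` of the input trees (such clades are pairwise
    compatible for threshold >= 0.5), each annotated with its support
    fraction.  All trees must share one leaf set.
    """
    if not trees:
        raise ValueError("need at least one tree")
    if not 0.5 <= threshold < 1.0:
        raise ValueError("threshold must lie in [0.5, 1)")
    leafsets = [frozenset(l.taxon.label for l in t.leaf_node_iter()) for t in trees]
    taxa = leafsets[0]
    for i, ls in enumerate(leafsets[1:], start=2):
        if ls != taxa:
            raise ValueError(
                f"tree {i} leaf set differs from tree 1: "
                f"{sorted(ls ^ taxa)} not shared")
    counts: dict[frozenset[str], int] = {}
    for tree in trees:
        for split in _tree_clades(tree, taxa):
            counts[split] = counts.get(split, 0) + 1
    n = len(trees)
    retained = {s: c / n for s, c in counts.items() if c / n > threshold}

    # assemble the (laminar) retained splits into a rooted representation
    ns = dendropy.TaxonNamespace(sorted(taxa))
    tree = dendropy.Tree(taxon_namespace=ns)
    by_size = sorted(retained, key=len, reverse=True)
    nodes: dict[frozenset[str], dendropy.Node] = {}

    def parent_of(split):
        best = None
        for other in by_size:
            if other is not split and len(other) > len(split) and split <= other:
                if best is None or len(other) < len(best):
                    best = other
        return nodes[best] if best is not None else tree.seed_node
    for split in by_size:
        node = dendropy.Node()
        node.label = f"{retained[split]:g}"
        node.support = retained[split]
        nodes[split] = node
    for split in by_size:
        parent_of(split).add_child(nodes[split])
    for label in sorted(taxa):
        best = None
        for split in by_size:
            if label in split and (best is None or len(split) < len(best)):
                best = split
        leaf = dendropy.Node(taxon=ns.get_taxon(label))
        (nodes[best] if best is not None else tree.seed_node).add_child(leaf)
    tree.is_rooted = False
    return tree


def extract_two_member_clades(tree: dendropy.Tree) -> list[tuple[str, str]]:
    """All cherries (internal nodes with exactly two leaf children), as
    unordered pairs in deterministic lexicographic order."""
    pairs = []
    for node in tree.preorder_internal_node_iter():
        children = node.child_nodes()
        if len(children) == 2 and all(c.is_leaf() for c in children):
            labels = sorted(c.taxon.label for c in children)
            pairs.append(tuple(labels))
    return sorted(pairs)


def filter_by_age(pairs: list[DuplicatePair],
                  cutoff: float = DS_CUTOFF_DEFAULT) -> list[DuplicatePair]:
    """Keep pairs with dS <= cutoff (inclusive); drops are logged."""
    kept = []
    for pair in pairs:
        if pair.ds is None:
            raise ValueError(f"pair {pair.gene1}/{pair.gene2} has no dS estimate")
        if pair.ds <= cutoff:
            kept.append(pair)
        else:
            logger.info("dropping %s/%s: dS=%.3f exceeds cutoff %.3f",
                        pair.gene1, pair.gene2, pair.ds, cutoff)
    return kept


def label_duplication_type(pairs: list[DuplicatePair],
                           wgd_roster: set[frozenset[str]],
                           tandem_roster: set[frozenset[str]]) -> list[DuplicatePair]:
    """Assign alpha-WGD / tandem / other by roster membership (order-free).

    A pair present in both rosters has ambiguous provenance and is an error.
    """
    out = []
    for pair in pairs:
        in_wgd = pair.key in wgd_roster
        in_tandem = pair.key in tandem_roster
        if in_wgd and in_tandem:
            raise ValueError(
                f"pair {pair.gene1}/{pair.gene2} appears in both the WGD and"
                " tandem rosters")
        dtype = "alpha-WGD" if in_wgd else ("tandem" if in_tandem else "other")
        out.append(DuplicatePair(pair.gene1, pair.gene2, dtype, pair.ds))
    return out
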