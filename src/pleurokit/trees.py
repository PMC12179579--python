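"""Rooted-tree substrate: newick I/O, pruning, support collapsing, bipartitions.

Trees are :class:`dendropy.Tree` objects used *rooted*; every function here
treats tip labels as opaque unique strings.  Bipartitions (splits) are the
unit of all downstream concordance accounting, so their canonical form lives
here too.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import dendropy

__all__ = [
    "Bipartition",
    "parse_newick",
    "parse_newick_list",
    "write_newick",
    "tip_labels",
    "prune_to_taxa",
    "collapse_low_support",
    "bipartitions",
    "reroot_at_outgroup",
    "internal_node_count",
    "is_fully_resolved",
    "canonical_topology_newick",
]


class NewickError(ValueError):
    """Raised for malformed or invalid newick input."""


@dataclass(frozen=True)
class Bipartition:
    """A two-way split of a taxon set, stored in canonical orientation.

    ``side_a`` is the side whose sorted label tuple is lexicographically
    smallest, so equality and hashing are orientation-free.
    """

    side_a: frozenset
    side_b: frozenset

    def __post_init__(self):
        if self.side_a & self.side_b:
            raise ValueError("bipartition sides overlap: %r" % sorted(self.side_a & self.side_b))
        if not self.side_a or not self.side_b:
            raise ValueError("bipartition sides must be non-empty")
        a, b = sorted(self.side_a), sorted(self.side_b)
        if b < a:
            object.__setattr__(self, "side_a", frozenset(b))
            object.__setattr__(self, "side_b", frozenset(a))
        else:
            object.__setattr__(self, "side_a", frozenset(a))
            object.__setattr__(self, "side_b", frozenset(b))

    @property
    def universe(self) -> frozenset:
        return self.side_a | self.side_b

    def restrict(self, taxa: Iterable) -> Optional["Bipartition"]:
        """Restriction to ``taxa``; ``None`` when a side empties out (trivial)."""
        taxa = frozenset(taxa)
        a = self.side_a & taxa
        b = self.side_b & taxa
        if not a or not b:
            return None
        return Bipartition(a, b)

    def conflicts_with(self, other: "Bipartition") -> bool:
        """Two splits on the same taxon set are incompatible iff all four
        pairwise side-intersections are non-empty."""
        return (
            bool(self.side_a & other.side_a)
            and bool(self.side_a & other.side_b)
            and bool(self.side_b & other.side_a)
            and bool(self.side_b & other.side_b)
        )

    def sort_key(self):
        return (tuple(sorted(self.side_a)), tuple(sorted(self.side_b)))

    def __str__(self):
        return "{%s | %s}" % (",".join(sorted(self.side_a)), ",".join(sorted(self.side_b)))


def _check_unique_tips(tree: dendropy.Tree) -> None:
    seen = set()
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon is not None else None
        if label is None or label == "":
            raise NewickError("unlabeled tip in tree")
        if label in seen:
            raise NewickError("duplicate tip label: %r" % label)
        seen.add(label)


def parse_newick(text: str, internal_labels: str = "support") -> dendropy.Tree:
    """Parse one newick tree.

    internal_labels:
        "support" -- internal node labels are support values (RAxML
        convention); stored as float on ``node.support`` where parseable.
        "name" -- internal labels are clade names, kept verbatim on
        ``node.label``.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError("malformed newick: %s" % exc) from exc
    _check_unique_tips(tree)
    tree.is_rooted = True
    if internal_labels == "support":
        for nd in tree.preorder_internal_node_iter():
            if nd.label is not None and nd.label != "":
                try:
                    nd.support = float(nd.label)
                except ValueError:
                    nd.support = None
            else:
                nd.support = None
    elif internal_labels != "name":
        raise ValueError("internal_labels must be 'support' or 'name'")
    return tree


def parse_newick_list(text: str, internal_labels: str = "support") -> list:
    """Parse a multi-tree newick string / file content (one tree per line)."""
    trees = []
    for line in text.strip().splitlines():
        line = line.strip()
        if line:
            trees.append(parse_newick(line, internal_labels=internal_labels))
    return trees


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True).strip()


def tip_labels(tree: dendropy.Tree) -> frozenset:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


def prune_to_taxa(tree: dendropy.Tree, keep: Iterable) -> dendropy.Tree:
    """Prune to ``keep`` (intersection with the tree's tips), suppressing
    unary nodes with branch lengths summed along the way."""
    keep = set(keep)
    present = tip_labels(tree)
    retained = keep & present
    if not retained:
        raise ValueError("no taxa to keep: empty intersection with tree tips")
    pruned = tree.extract_tree_with_taxa_labels(
        labels=retained, suppress_unifurcations=True
    )
    # detach from the source tree's taxon namespace so later relabeling of
    # the pruned tree can never touch the original
    pruned.migrate_taxon_namespace(dendropy.TaxonNamespace(), unify_taxa_by_label=True)
    pruned.is_rooted = True
    # extract_tree copies node attributes; make sure the root has no leftover
    # unifurcation (dendropy suppresses these already, assert the invariant).
    for nd in pruned.preorder_internal_node_iter():
        if len(nd.child_nodes()) == 1:  # pragma: no cover - dendropy contract
            raise AssertionError("unary node survived pruning")
    return pruned


def collapse_low_support(tree: dendropy.Tree, threshold: float) -> dendropy.Tree:
    """Contract every internal (non-root) edge whose support < threshold.

    Comparison is strict, matching the convention of collapsing branches
    below a bootstrap cutoff into polytomies.
    """
    tree = tree.clone(depth=1)
    missing = []
    to_collapse = []
    for nd in tree.preorder_internal_node_iter(exclude_seed_node=True):
        support = getattr(nd, "support", None)
        if support is None:
            missing.append(nd)
        elif support < threshold:
            to_collapse.append(nd)
    if missing and threshold > 0:
        raise ValueError(
            "missing support on %d internal node(s); cannot apply threshold" % len(missing)
        )
    for nd in to_collapse:
        nd.edge.collapse()
    return tree


def bipartitions(tree: dendropy.Tree, restrict_to: Optional[Iterable] = None) -> set:
    """All non-trivial splits induced by internal non-root nodes.

    With ``restrict_to``, each split is restricted to that taxon set and
    splits that lose a whole side are dropped.
    """
    universe = tip_labels(tree)
    out = set()
    for nd in tree.preorder_internal_node_iter(exclude_seed_node=True):
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        above = universe - below
        if not above:
            continue
        bp = Bipartition(below, above)
        if restrict_to is not None:
            bp = bp.restrict(restrict_to)
            if bp is None:
                continue
        out.add(bp)
    return out


def reroot_at_outgroup(tree: dendropy.Tree, outgroup: Iterable) -> dendropy.Tree:
    """Reroot so the given taxa form (one side of) the basal split."""
    tree = tree.clone(depth=1)
    outgroup = set(outgroup)
    taxa = [leaf.taxon for leaf in tree.leaf_node_iter() if leaf.taxon.label in outgroup]
    if not taxa:
        raise ValueError("outgroup taxa not present in tree")
    if len(taxa) == 1:
        node = tree.find_node_with_taxon_label(taxa[0].label)
    else:
        node = tree.mrca(taxa=taxa)
    tree.to_outgroup_position(node, update_bipartitions=False, suppress_unifurcations=True)
    tree.is_rooted = True
    return tree


def internal_node_count(tree: dendropy.Tree) -> int:
    """Number of internal nodes, root included."""
    return sum(1 for _ in tree.preorder_internal_node_iter())


def is_fully_resolved(tree: dendropy.Tree) -> bool:
    """Rooted binary: every internal node has exactly two children."""
    return all(len(nd.child_nodes()) == 2 for nd in tree.preorder_internal_node_iter())


def _canonical(node) -> tuple:
    children = node.child_nodes()
    if not children:
        return (node.taxon.label,)
    subs = sorted((_canonical(c) for c in children), key=_canon_key)
    return tuple(subs)


def _canon_key(t):
    if isinstance(t, tuple) and len(t) == 1 and isinstance(t[0], str):
        return (0, t[0])
    return (1, tuple(_canon_key(x) for x in t))


def _render(t) -> str:
    if len(t) == 1 and isinstance(t[0], str):
        return t[0]
    return "(" + ",".join(_render(c) for c in t) + ")"


def canonical_topology_newick(tree: dendropy.Tree) -> str:
    """Branch-length-free newick in a rotation-invariant canonical order.

    Identical rooted topologies map to identical strings; used as the
    dictionary key for scenario ranking.
    """
    return _render(_canonical(tree.seed_node)) + ";"
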