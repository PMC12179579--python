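"""Per-node gene-tree concordance against a reference species tree.

For every internal (non-root) node of the species tree with defining split
B, each gene tree is classified as

* uninformative -- B restricted to the gene tree's tips loses a whole side,
  or the gene tree neither contains nor contradicts the restricted split
  (e.g. because the relevant branches are collapsed into a polytomy);
* concordant -- the restricted split is among the gene tree's own splits;
* conflicting -- some gene-tree split is incompatible with the restricted
  split (all four pairwise side-intersections non-empty).

This mirrors the accounting used to annotate species trees with
concordant/conflicting gene-tree counts and pie charts, and feeds both the
taxon-removal jackknife and the alternative-topology scenario scoring.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy

from .trees import Bipartition, bipartitions, prune_to_taxa, tip_labels

__all__ = [
    "NodeConcordance",
    "JackknifeNode",
    "JackknifeReport",
    "species_node_splits",
    "node_concordance",
    "pie_fractions",
    "taxon_jackknife",
]


@dataclass
class NodeConcordance:
    node_id: str
    split: Bipartition
    concordant: int = 0
    conflicting: int = 0
    uninformative: int = 0
    top_alternative: Optional[Bipartition] = None
    top_alternative_count: int = 0

    @property
    def n_genes(self) -> int:
        return self.concordant + self.conflicting + self.uninformative


def species_node_splits(species_tree: dendropy.Tree) -> List[Tuple[str, Bipartition]]:
    """(node_id, defining split) for every internal non-root node, preorder.

    Node ids are "N1", "N2", ... in preorder so they are stable for a given
    species tree.
    """
    universe = tip_labels(species_tree)
    out = []
    i = 0
    for nd in species_tree.preorder_internal_node_iter(exclude_seed_node=True):
        i += 1
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        above = universe - below
        if not above:
            continue
        out.append(("N%d" % i, Bipartition(below, above)))
    return out


def _gene_summaries(gene_trees: Sequence[dendropy.Tree], species_taxa: frozenset):
    """Precompute (tip set, split set) per gene tree, validating labels."""
    summaries = []
    for gt in gene_trees:
        tips = tip_labels(gt)
        extra = tips - species_taxa
        if extra:
            raise ValueError("gene-tree tip not in species tree: %r" % sorted(extra)[0])
        summaries.append((tips, bipartitions(gt)))
    return summaries


def _classify(split: Bipartition, gene_tips: frozenset, gene_splits: set):
    """Return ('u', None) / ('c', None) / ('x', incompatible splits)."""
    restricted = split.restrict(gene_tips)
    if restricted is None:
        return "u", None
    if restricted in gene_splits:
        return "c", None
    incompatible = [s for s in gene_splits if restricted.conflicts_with(s)]
    if incompatible:
        return "x", incompatible
    return "u", None


def node_concordance(
    species_tree: dendropy.Tree,
    gene_trees: Sequence[dendropy.Tree],
    _gene_summaries_cache=None,
) -> Dict[str, NodeConcordance]:
    """Concordance triple + modal alternative split, per species-tree node."""
    species_taxa = tip_labels(species_tree)
    summaries = (
        _gene_summaries(gene_trees, species_taxa)
        if _gene_summaries_cache is None
        else _gene_summaries_cache
    )
    result: Dict[str, NodeConcordance] = {}
    for node_id, split in species_node_splits(species_tree):
        nc = NodeConcordance(node_id=node_id, split=split)
        alt_counter: Counter = Counter()
        for gene_tips, gene_splits in summaries:
            kind, incompatible = _classify(split, gene_tips, gene_splits)
            if kind == "c":
                nc.concordant += 1
            elif kind == "x":
                nc.conflicting += 1
                # each conflicting gene tree votes once for every split it
                # holds against this node; the modal one is the reported
                # dominant alternative and its count stays <= conflicting
                for s in set(incompatible):
                    alt_counter[s] += 1
            else:
                nc.uninformative += 1
        if alt_counter:
            best = max(alt_counter.items(), key=lambda kv: (kv[1],), default=None)
            top_count = best[1]
            candidates = sorted(
                (s for s, c in alt_counter.items() if c == top_count),
                key=lambda s: s.sort_key(),
            )
            nc.top_alternative = candidates[0]
            nc.top_alternative_count = top_count
        result[node_id] = nc
    return result


def pie_fractions(nc: NodeConcordance) -> Tuple[float, float, float, float]:
    """(concordant, top-conflict, other-conflict, uninformative) fractions."""
    total = nc.n_genes
    if total == 0:
        raise ValueError("no gene trees: fractions undefined")
    top = nc.top_alternative_count
    return (
        nc.concordant / total,
        top / total,
        (nc.conflicting - top) / total,
        nc.uninformative / total,
    )


@dataclass
class JackknifeNode:
    node_id: str
    before: NodeConcordance
    after: Optional[NodeConcordance]

    @property
    def delta_concordant(self) -> Optional[int]:
        if self.after is None:
            return None
        return self.after.concordant - self.before.concordant


@dataclass
class JackknifeReport:
    removed_taxa: frozenset
    nodes: Dict[str, JackknifeNode] = field(default_factory=dict)
    dropped_nodes: List[str] = field(default_factory=list)


def taxon_jackknife(
    species_tree: dendropy.Tree,
    gene_trees: Sequence[dendropy.Tree],
    removals: Sequence,
) -> List[JackknifeReport]:
    """Recompute per-node concordance after deleting taxon sets everywhere.

    For each removal set, the taxa are pruned from the species tree and from
    every gene tree (gene trees losing all tips are discarded for the
    recount), and node_concordance is re-run.  Nodes are matched by the
    restriction of their defining split; a node whose split becomes trivial
    after removal is listed under ``dropped_nodes``.
    """
    all_tips = tip_labels(species_tree)
    before = node_concordance(species_tree, gene_trees)
    reports = []
    for removal in removals:
        removal = frozenset(removal)
        if not removal <= all_tips:
            raise ValueError("removal set contains non-species-tree taxa: %r"
                             % sorted(removal - all_tips))
        if removal == all_tips:
            raise ValueError("cannot remove every taxon")
        report = JackknifeReport(removed_taxa=removal)
        if not removal:
            for node_id, nc in before.items():
                report.nodes[node_id] = JackknifeNode(node_id, nc, nc)
            reports.append(report)
            continue
        keep = all_tips - removal
        sp_pruned = prune_to_taxa(species_tree, keep)
        genes_pruned = []
        for gt in gene_trees:
            kept = tip_labels(gt) - removal
            if len(kept) >= 2:
                genes_pruned.append(prune_to_taxa(gt, kept))
        after = node_concordance(sp_pruned, genes_pruned)
        # match original nodes to pruned nodes via restricted splits
        after_by_split = {nc.split: nc for nc in after.values()}
        for node_id, nc in before.items():
            restricted = nc.split.restrict(keep)
            if restricted is None or restricted not in after_by_split:
                report.dropped_nodes.append(node_id)
                continue
            report.nodes[node_id] = JackknifeNode(node_id, nc, after_by_split[restricted])
        reports.append(report)
    return reports
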