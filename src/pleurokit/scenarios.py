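"""Alternative-topology scenario testing at the clade level.

The test reduces the problem of comparing species-tree hypotheses on the
full taxon set to clade-level representatives: pick one representative per
predefined clade (plus a fixed set of always-kept taxa), prune every gene
tree to those tips, relabel representatives by their clade names, collect
the fully resolved topologies observed among the pruned gene trees as
candidates, and score every candidate by the mean number of concordant gene
trees per internal node, excluding the root.  Candidates are ranked by that
support score, aggregated over repeated random representative draws.

The full rooted binary topology space on k tips has (2k-3)!! members, which
is why candidate enumeration from observed gene-tree topologies (rather
than exhaustive scoring) is the point of the procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np

from .concordance import node_concordance
from .trees import (
    canonical_topology_newick,
    internal_node_count,
    is_fully_resolved,
    parse_newick,
    prune_to_taxa,
    reroot_at_outgroup,
    tip_labels,
)

__all__ = [
    "CladeMap",
    "ScenarioConfig",
    "RankedScenario",
    "ScenarioRanking",
    "count_rooted_topologies",
    "enumerate_rooted_topologies",
    "draw_representatives",
    "prune_and_relabel",
    "enumerate_candidates",
    "score_topology",
    "rank_scenarios",
]

#: refuse exhaustive enumeration beyond this (15!! = 2,027,025 already)
_ENUMERATION_LIMIT = 9


@dataclass(frozen=True)
class CladeMap:
    """Named, pairwise-disjoint clades plus taxa fixed in every test."""

    clades: Dict[str, frozenset]
    fixed_taxa: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(
            self, "clades", {k: frozenset(v) for k, v in self.clades.items()}
        )
        object.__setattr__(self, "fixed_taxa", frozenset(self.fixed_taxa))
        names = sorted(self.clades)
        for i, a in enumerate(names):
            if not self.clades[a]:
                raise ValueError("empty clade: %r" % a)
            if self.clades[a] & self.fixed_taxa:
                raise ValueError("clade %r overlaps fixed taxa" % a)
            for b in names[i + 1:]:
                if self.clades[a] & self.clades[b]:
                    raise ValueError("clades %r and %r overlap" % (a, b))

    @property
    def k(self) -> int:
        """Tip count after reduction: one per clade plus the fixed taxa."""
        return len(self.clades) + len(self.fixed_taxa)


@dataclass(frozen=True)
class ScenarioConfig:
    """Clade map plus draw/seed settings.

    ``outgroup`` (a clade name or fixed taxon) mirrors the practice of
    rooting every gene tree with a designated outgroup clade before
    candidate enumeration: pruned gene trees are rerooted so the outgroup
    is basal, which makes candidate rootings well-defined (without it,
    rootings of the same unrooted topology are near-ties under split-based
    scoring).
    """

    clade_map: CladeMap
    n_draws: int = 10
    seed: int = 0
    candidate_mode: str = "observed"  # or "consensus"
    outgroup: Optional[str] = None

    def __post_init__(self):
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.candidate_mode not in ("observed", "consensus"):
            raise ValueError("candidate_mode must be 'observed' or 'consensus'")
        if self.outgroup is not None and self.outgroup not in (
            set(self.clade_map.clades) | set(self.clade_map.fixed_taxa)
        ):
            raise ValueError("outgroup %r is not a clade name or fixed taxon" % self.outgroup)

    @property
    def k(self) -> int:
        return self.clade_map.k

    @property
    def required_nodes(self) -> int:
        """Internal node count of a fully resolved rooted tree on k tips."""
        return self.k - 1


def count_rooted_topologies(k: int) -> int:
    """(2k-3)!! rooted binary topologies on k labeled tips, exact."""
    if k < 2:
        raise ValueError("need at least 2 tips")
    n = 1
    for m in range(3, 2 * k - 2, 2):
        n *= m
    return n


def enumerate_rooted_topologies(labels: Sequence[str]) -> List[str]:
    """All rooted binary topologies on ``labels`` by recursive tip insertion.

    Returns canonical newick strings; intended as the small-k oracle for
    :func:`count_rooted_topologies` (guarded beyond k = %d).
    """ % _ENUMERATION_LIMIT
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 tips")
    if len(labels) > _ENUMERATION_LIMIT:
        raise ValueError(
            "refusing exhaustive enumeration for k > %d; use candidate "
            "enumeration from observed gene trees instead" % _ENUMERATION_LIMIT
        )

    def insert_all(structure, label):
        # returns list of structures with `label` attached on every edge,
        # including above the current root
        results = [((label,), structure) if False else ((structure, (label,)))]
        if len(structure) != 1:
            left, right = structure
            results.extend((new_left, right) for new_left in insert_all(left, label))
            results.extend((left, new_right) for new_right in insert_all(right, label))
        return results

    structures = [((labels[0],), (labels[1],))]
    for label in labels[2:]:
        structures = [s for st in structures for s in insert_all(st, label)]

    def canon(t):
        if len(t) == 1:
            return t
        a, b = canon(t[0]), canon(t[1])
        return (a, b) if _tkey(a) <= _tkey(b) else (b, a)

    def render(t):
        if len(t) == 1:
            return t[0]
        return "(" + ",".join(render(c) for c in t) + ")"

    return sorted({render(canon(s)) + ";" for s in structures})


def _tkey(t):
    if len(t) == 1 and isinstance(t[0], str):
        return (0, t[0])
    return (1, tuple(_tkey(x) for x in t))


def draw_representatives(
    clade_map: CladeMap, n_draws: int, seed: int
) -> List[Dict[str, str]]:
    """n_draws mappings clade_name -> chosen representative, reproducible.

    Clades are visited in sorted-name order with a single seeded generator,
    so identical (clade_map, n_draws, seed) yields identical draws.
    """
    rng = np.random.default_rng(seed)
    names = sorted(clade_map.clades)
    draws = []
    for _ in range(n_draws):
        pick = {}
        for name in names:
            members = sorted(clade_map.clades[name])
            pick[name] = members[rng.integers(len(members))]
        draws.append(pick)
    return draws


def prune_and_relabel(
    tree: dendropy.Tree, representatives: Dict[str, str], fixed_taxa: frozenset
) -> Optional[dendropy.Tree]:
    """Prune to the draw's tips and rename each representative to its clade.

    Returns ``None`` when fewer than two of the draw's tips occur in the
    tree (nothing left to compare).
    """
    rep_to_clade = {rep: clade for clade, rep in representatives.items()}
    wanted = set(rep_to_clade) | set(fixed_taxa)
    present = wanted & tip_labels(tree)
    if len(present) < 2:
        return None
    pruned = prune_to_taxa(tree, present)
    for leaf in pruned.leaf_node_iter():
        if leaf.taxon.label in rep_to_clade:
            leaf.taxon.label = rep_to_clade[leaf.taxon.label]
    return pruned


def enumerate_candidates(
    pruned_gene_trees: Sequence[dendropy.Tree],
    required_nodes: int,
    mode: str = "observed",
) -> Dict[str, dendropy.Tree]:
    """Distinct fully resolved clade-level topologies, keyed by canonical newick.

    mode "observed": topologies present among the pruned gene trees.
    mode "consensus": the majority-rule consensus of the pruned gene trees
    (kept only if fully resolved with the required node count).
    """
    candidates: Dict[str, dendropy.Tree] = {}
    if mode == "consensus":
        full = [t for t in pruned_gene_trees if t is not None]
        if full:
            tns = dendropy.TaxonNamespace()
            tl = dendropy.TreeList(taxon_namespace=tns)
            for t in full:
                tl.append(dendropy.Tree.get(data=t.as_string(schema="newick"),
                                            schema="newick",
                                            taxon_namespace=tns,
                                            preserve_underscores=True))
            cons = tl.consensus(min_freq=0.5)
            cons.is_rooted = True
            if is_fully_resolved(cons) and internal_node_count(cons) == required_nodes:
                candidates[canonical_topology_newick(cons)] = cons
        if not candidates:
            warnings.warn("no fully resolved consensus candidate")
        return candidates
    for t in pruned_gene_trees:
        if t is None:
            continue
        if not is_fully_resolved(t):
            continue
        if internal_node_count(t) != required_nodes:
            continue
        key = canonical_topology_newick(t)
        if key not in candidates:
            candidates[key] = parse_newick(key, internal_labels="name")
    if not candidates:
        warnings.warn("no fully resolved pruned gene tree: empty candidate set")
    return candidates


def score_topology(
    candidate: dendropy.Tree,
    pruned_gene_trees: Sequence[dendropy.Tree],
    _gene_summaries=None,
) -> Tuple[float, Dict[str, int]]:
    """Support score = mean concordant gene-tree count per internal node,
    excluding the root; also returns the per-node concordant counts.

    ``_gene_summaries`` lets callers scoring many candidates against the
    same gene trees reuse precomputed (tip set, split set) pairs.
    """
    genes = [t for t in pruned_gene_trees if t is not None]
    cand_tips = tip_labels(candidate)
    if _gene_summaries is None:
        for g in genes:
            if not tip_labels(g) <= cand_tips:
                raise ValueError("gene-tree tips not a subset of candidate tips")
    nc = node_concordance(candidate, genes, _gene_summaries_cache=_gene_summaries)
    per_node = {node_id: c.concordant for node_id, c in nc.items()}
    if not per_node:
        return 0.0, {}
    score = float(np.mean(list(per_node.values())))
    return score, per_node


@dataclass
class RankedScenario:
    topology: str  # canonical newick over clade names + fixed taxa
    mean_score: float
    per_draw_scores: List[float]
    per_node_support: Dict[str, float]  # mean concordant count per node


@dataclass
class ScenarioRanking:
    config: ScenarioConfig
    scenarios: List[RankedScenario] = field(default_factory=list)


def rank_scenarios(
    config: ScenarioConfig,
    gene_trees: Sequence[dendropy.Tree],
    top_n: Optional[int] = None,
) -> ScenarioRanking:
    """Full prune -> relabel -> enumerate -> score pipeline over all draws.

    Every candidate observed in any draw is scored against every draw's
    pruned gene trees so the aggregated (mean) scores are comparable;
    ties are broken by canonical newick.
    """
    from .concordance import _gene_summaries as _summarize

    draws = draw_representatives(config.clade_map, config.n_draws, config.seed)
    clade_universe = frozenset(config.clade_map.clades) | config.clade_map.fixed_taxa
    per_draw_genes: List[List[dendropy.Tree]] = []
    per_draw_summaries = []
    candidates: Dict[str, dendropy.Tree] = {}
    for reps in draws:
        pruned = [
            prune_and_relabel(gt, reps, config.clade_map.fixed_taxa)
            for gt in gene_trees
        ]
        pruned = [t for t in pruned if t is not None]
        if config.outgroup is not None:
            pruned = [
                reroot_at_outgroup(t, {config.outgroup})
                if config.outgroup in tip_labels(t) else t
                for t in pruned
            ]
        per_draw_genes.append(pruned)
        per_draw_summaries.append(_summarize(pruned, clade_universe))
        for key, tree in enumerate_candidates(
            pruned, config.required_nodes, mode=config.candidate_mode
        ).items():
            candidates.setdefault(key, tree)

    scenarios = []
    for key in sorted(candidates):
        cand = candidates[key]
        draw_scores = []
        node_accum: Dict[str, List[int]] = {}
        for pruned, summaries in zip(per_draw_genes, per_draw_summaries):
            score, per_node = score_topology(cand, pruned, _gene_summaries=summaries)
            draw_scores.append(score)
            for node_id, c in per_node.items():
                node_accum.setdefault(node_id, []).append(c)
        scenarios.append(
            RankedScenario(
                topology=key,
                mean_score=float(np.mean(draw_scores)) if draw_scores else 0.0,
                per_draw_scores=draw_scores,
                per_node_support={k: float(np.mean(v)) for k, v in node_accum.items()},
            )
        )
    scenarios.sort(key=lambda s: (-s.mean_score, s.topology))
    if top_n is not None:
        scenarios = scenarios[:top_n]
    return ScenarioRanking(config=config, scenarios=scenarios)
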