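"""Synthetic inputs with the statistical structure the analyses assume.

Generators (all deterministic under their seed):

* multispecies-coalescent (MSC) gene trees on a species tree with branch
  lengths in coalescent units (within a branch, j lineages coalesce at
  rate j(j-1)/2 per unit time), the regime that produces incomplete
  lineage sorting;
* topological hybrid-signal injection (a clade re-attached elsewhere in a
  gamma fraction of gene trees, mimicking the two-dominant-topology
  signature of a hybridogenous lineage);
* Brownian-motion traits with a tunable Pagel's lambda;
* flow-cytometry peak series under the partial-endoreplication model with
  multiplicative lognormal noise;
* a synthetic landscape (smooth DEM, region mosaic, ecoregions,
  environmental layers optionally correlated with elevation);
* a make_fixture_suite bundle writing a complete miniature study to disk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
from scipy.ndimage import gaussian_filter

from . import fcm as _fcm
from .comparative import phylo_covariance
from .spatial import Raster, TaxonRange, write_ascii_grid
from .trees import parse_newick, tip_labels, write_newick

__all__ = [
    "MscModel",
    "HybridSignal",
    "simulate_gene_trees_msc",
    "inject_hybrid_signal",
    "simulate_bm_traits",
    "simulate_fcm_run",
    "Landscape",
    "simulate_landscape",
    "make_fixture_suite",
]


@dataclass(frozen=True)
class MscModel:
    """Species tree (newick or dendropy.Tree; branch lengths in coalescent
    units of 2N generations), number of gene trees, RNG seed."""

    species_tree: object
    n_genes: int
    seed: int = 0

    def tree(self) -> dendropy.Tree:
        if isinstance(self.species_tree, dendropy.Tree):
            return self.species_tree
        return parse_newick(str(self.species_tree))


class _Lineage:
    __slots__ = ("label", "children", "length")

    def __init__(self, label=None, children=(), length=0.0):
        self.label = label
        self.children = list(children)
        self.length = length

    def newick(self):
        if not self.children:
            return "%s:%.6g" % (self.label, self.length)
        return "(%s):%.6g" % (",".join(c.newick() for c in self.children), self.length)


def _coalesce(lineages: List[_Lineage], duration: float, rng) -> List[_Lineage]:
    """Standard coalescent within one species-tree branch.

    ``duration`` may be inf (the root stem), in which case coalescence
    continues until one lineage remains.
    """
    t = 0.0
    lineages = list(lineages)
    while len(lineages) > 1:
        j = len(lineages)
        rate = j * (j - 1) / 2.0
        wait = rng.exponential(1.0 / rate)
        if t + wait > duration:
            break
        t += wait
        for lin in lineages:
            lin.length += wait
        i, k = rng.choice(j, size=2, replace=False)
        a, b = lineages[i], lineages[k]
        parent = _Lineage(children=[a, b])
        lineages = [lin for m, lin in enumerate(lineages) if m not in (i, k)]
        lineages.append(parent)
    if np.isfinite(duration):
        remaining = duration - t
        for lin in lineages:
            lin.length += remaining
    return lineages


def simulate_gene_trees_msc(model: MscModel) -> List[dendropy.Tree]:
    """Sample gene trees under the MSC, one lineage per species.

    Branch lengths of the returned gene trees are in coalescent units.
    """
    sp = model.tree()
    rng = np.random.default_rng(model.seed)
    # per-species-node edge durations; the root gets an infinite stem
    genes = []
    for _ in range(model.n_genes):
        carry: Dict[int, List[_Lineage]] = {}
        for nd in sp.postorder_node_iter():
            if nd.is_leaf():
                incoming = [_Lineage(label=nd.taxon.label)]
            else:
                incoming = []
                for child in nd.child_nodes():
                    incoming.extend(carry.pop(id(child)))
            if nd is sp.seed_node:
                duration = np.inf
            else:
                duration = float(nd.edge.length) if nd.edge.length is not None else 0.0
            carry[id(nd)] = _coalesce(incoming, duration, rng)
        (root,) = carry[id(sp.seed_node)]
        newick = root.newick()
        # strip the root's stem length for a clean rooted tree
        newick = newick[: newick.rfind(":")] + ";"
        genes.append(parse_newick(newick))
    return genes


@dataclass(frozen=True)
class HybridSignal:
    """Move ``target_clade`` to sister position of ``attachment`` in a
    gamma fraction of gene trees (seeded Bernoulli per tree)."""

    target_clade: frozenset
    attachment: frozenset
    gamma: float

    def __post_init__(self):
        object.__setattr__(self, "target_clade", frozenset(self.target_clade))
        object.__setattr__(self, "attachment", frozenset(self.attachment))
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must be in [0, 1]")
        if self.target_clade & self.attachment:
            raise ValueError("target clade overlaps attachment clade")


def _mrca_if_monophyletic(tree: dendropy.Tree, labels: frozenset):
    taxa = [lf.taxon for lf in tree.leaf_node_iter() if lf.taxon.label in labels]
    if len(taxa) != len(labels):
        return None
    node = tree.mrca(taxa=taxa) if len(taxa) > 1 else tree.find_node_with_taxon_label(taxa[0].label)
    leafset = frozenset(lf.taxon.label for lf in node.leaf_iter())
    return node if leafset == labels else None


def inject_hybrid_signal(
    gene_trees: Sequence[dendropy.Tree], hs: HybridSignal, seed: int = 0
) -> List[dendropy.Tree]:
    """Return gene trees with the hybrid signal injected (inputs untouched).

    Trees in which the target clade is not monophyletic are passed through
    unchanged with a warning.
    """
    rng = np.random.default_rng(seed)
    out = []
    skipped = 0
    for gt in gene_trees:
        move = rng.random() < hs.gamma
        if not move:
            out.append(gt)
            continue
        tree = gt.clone(depth=1)
        src = _mrca_if_monophyletic(tree, hs.target_clade)
        if src is None:
            skipped += 1
            out.append(gt)
            continue
        src_len = float(src.edge.length or 0.0)
        parent = src.parent_node
        parent.remove_child(src)
        tree.suppress_unifurcations()
        dst = _mrca_if_monophyletic(tree, hs.attachment)
        if dst is None:
            skipped += 1
            out.append(gt)
            continue
        dst_parent = dst.parent_node
        dst_len = float(dst.edge.length or 0.0)
        joint = dendropy.Node()
        if dst_parent is None:
            # attaching at the root: new root above old root
            tree.seed_node = joint
        else:
            dst_parent.remove_child(dst)
            dst_parent.add_child(joint)
        joint.edge.length = dst_len / 2.0
        dst.edge.length = dst_len / 2.0 if dst_parent is not None else dst_len
        joint.add_child(dst)
        joint.add_child(src)
        src.edge.length = src_len
        tree.is_rooted = True
        out.append(tree)
    if skipped:
        warnings.warn("target clade not monophyletic in %d gene tree(s); skipped" % skipped)
    return out


def simulate_bm_traits(
    tree: dendropy.Tree,
    sigma2: float = 1.0,
    lam: float = 1.0,
    root_state: float = 0.0,
    seed: int = 0,
) -> Dict[str, float]:
    """Multivariate-normal tip traits with lambda-transformed BM covariance."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    cov = phylo_covariance(tree)
    c = sigma2 * cov.lambda_transform(lam)
    rng = np.random.default_rng(seed)
    if sigma2 == 0:
        values = np.full(len(cov.taxa), root_state)
    else:
        jitter = 1e-12 * max(np.max(np.diag(c)), 1.0)
        l_chol = np.linalg.cholesky(c + jitter * np.eye(len(cov.taxa)))
        values = root_state + l_chol @ rng.standard_normal(len(cov.taxa))
    return dict(zip(cov.taxa, values.tolist()))


@dataclass(frozen=True)
class StandardSpec:
    """Internal FCM standard: its PI peak position, 2C size, and GC."""

    peak_pi: float = 400.0
    gs_2c_mbp: float = 8840.0
    gc_pct: float = 41.8


def simulate_fcm_run(
    accession: str,
    gs_2c_mbp: float,
    p: float,
    gc_pct: float,
    standard: StandardSpec = StandardSpec(),
    n_peaks: int = 5,
    cv: float = 0.0,
    seed: int = 0,
    binding_length: int = _fcm.DEFAULT_BINDING_LENGTH,
) -> _fcm.FcmRun:
    """Noisy FCM peak table under the partial-endoreplication model.

    PI peaks sit at F_0 (1 + (2^r - 1) P); DAPI peaks are scaled so the
    implied GC under the binding-length model equals ``gc_pct``.
    Multiplicative lognormal noise with coefficient of variation ``cv`` is
    applied per peak (cv = 0 reproduces the model exactly, so the
    fcm-traits derivation round-trips).
    """
    if not (0.0 < p <= 1.0):
        raise ValueError("P must be in (0, 1]")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    f0 = gs_2c_mbp / standard.gs_2c_mbp * standard.peak_pi
    r = np.arange(n_peaks)
    pi_peaks = f0 * (1.0 + (2.0 ** r - 1.0) * p)
    at_standard = 100.0 - standard.gc_pct
    df_standard = 1.0  # standard dye factor normalized to 1
    df_sample = df_standard * ((100.0 - gc_pct) / at_standard) ** binding_length
    dapi_peaks = df_sample * pi_peaks
    if cv > 0:
        sigma = np.sqrt(np.log(1.0 + cv ** 2))
        noise = lambda size: np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size))
        pi_peaks = pi_peaks * noise(n_peaks)
        dapi_peaks = dapi_peaks * noise(n_peaks)
        pi_peaks.sort()
        dapi_peaks.sort()
    return _fcm.FcmRun(
        accession=accession,
        sample_peaks_pi=tuple(pi_peaks),
        sample_peaks_dapi=tuple(dapi_peaks),
        standard_peak_pi=standard.peak_pi,
        standard_peak_dapi=standard.peak_pi * df_standard,
        standard_2c_mbp=standard.gs_2c_mbp,
        standard_gc_pct=standard.gc_pct,
    )


@dataclass
class Landscape:
    dem: Raster
    regions: Raster
    ecoregions: Raster
    env: List[Raster] = field(default_factory=list)


def _smooth_field(shape, rng, roughness: float) -> np.ndarray:
    """Standardized Gaussian-filtered white noise; larger roughness =
    shorter correlation length."""
    sigma = max(min(shape) / (4.0 * max(roughness, 1e-6)), 1.0)
    z = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    z -= z.mean()
    sd = z.std()
    return z / sd if sd > 0 else z


def simulate_landscape(
    west: float = -80.0,
    south: float = -20.0,
    nrows: int = 200,
    ncols: int = 200,
    cellsize: float = 1.0 / 120.0,
    n_regions: int = 8,
    n_ecoregions: int = 4,
    elevation_range: Tuple[float, float] = (0.0, 4000.0),
    roughness: float = 2.0,
    n_env_layers: int = 2,
    env_dem_correlation: float = 0.0,
    seed: int = 0,
) -> Landscape:
    """Seeded DEM + nearest-center region mosaic + environmental layers."""
    rng = np.random.default_rng(seed)
    shape = (nrows, ncols)
    z = _smooth_field(shape, rng, roughness)
    lo, hi = elevation_range
    zmin, zmax = z.min(), z.max()
    dem_data = lo + (z - zmin) / (zmax - zmin) * (hi - lo)
    geo = dict(west=west, south=south, cellsize=cellsize)

    def mosaic(k):
        centers = np.column_stack([rng.uniform(0, nrows, k), rng.uniform(0, ncols, k)])
        rr, cc = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
        d2 = (rr[..., None] - centers[:, 0]) ** 2 + (cc[..., None] - centers[:, 1]) ** 2
        return np.argmin(d2, axis=-1).astype(float) + 1.0

    regions = mosaic(n_regions)
    ecoregions = mosaic(n_ecoregions)
    env_layers = []
    zstd = (z - z.mean()) / z.std() if z.std() > 0 else z
    rho = env_dem_correlation
    for _ in range(n_env_layers):
        noise = _smooth_field(shape, rng, roughness)
        layer = rho * zstd + np.sqrt(max(1.0 - rho ** 2, 0.0)) * noise
        env_layers.append(Raster(layer, **geo))
    return Landscape(
        dem=Raster(dem_data, **geo),
        regions=Raster(regions, **geo),
        ecoregions=Raster(ecoregions, **geo),
        env=env_layers,
    )


def _random_species_tree(labels: Sequence[str], rng, internal_branch: float) -> str:
    """Random rooted binary topology with the given internal branch length
    (coalescent units) and unit tip branches, as newick."""
    nodes = ["%s:1.0" % lb for lb in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append("(%s,%s):%.4f" % (a, b, internal_branch))
    root = nodes[0]
    return root[: root.rfind(":")] + ";"


def make_fixture_suite(seed: int, out_dir) -> Dict[str, str]:
    """Write a complete miniature study to ``out_dir``; returns file paths.

    Contents: a 13-clade species tree (two accessions per clade), 200 MSC
    gene trees with one clade carrying an injected hybrid signal, the
    derived FCM peak/trait tables, a synthetic landscape and taxon range
    table -- everything the analysis modules consume, end to end.
    """
    import os

    rng = np.random.default_rng(seed)
    os.makedirs(out_dir, exist_ok=True)
    clade_names = ["C%02d" % i for i in range(1, 14)]
    accessions = {c: ["%s_a" % c, "%s_b" % c] for c in clade_names}
    # species tree over accessions: each clade is a cherry on a random backbone
    cherries = ["(%s:0.5,%s:0.5):3.0" % (a, b) for a, b in
                (accessions[c] for c in clade_names)]
    nodes = list(cherries)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append("(%s,%s):3.0" % (a, b))
    species_newick = nodes[0][: nodes[0].rfind(":")] + ";"
    species = parse_newick(species_newick)
    genes = simulate_gene_trees_msc(MscModel(species, n_genes=200, seed=int(rng.integers(2 ** 31))))
    hs = HybridSignal(
        target_clade=frozenset(accessions[clade_names[0]]),
        attachment=frozenset(accessions[clade_names[1]]),
        gamma=0.3,
    )
    genes = inject_hybrid_signal(genes, hs, seed=int(rng.integers(2 ** 31)))

    paths = {}
    paths["species_tree"] = os.path.join(out_dir, "species.nwk")
    with open(paths["species_tree"], "w") as fh:
        fh.write(write_newick(species) + "\n")
    paths["gene_trees"] = os.path.join(out_dir, "gene_trees.nwk")
    with open(paths["gene_trees"], "w") as fh:
        for gt in genes:
            fh.write(write_newick(gt) + "\n")

    # FCM: one run per clade representative accession
    taxa = sorted(t for acc in accessions.values() for t in acc)
    runs = []
    for t in taxa:
        gs = float(rng.uniform(600.0, 7000.0))
        p = 1.0 if rng.random() < 0.8 else float(rng.uniform(0.25, 0.9))
        gc = float(rng.uniform(25.0, 45.0))
        runs.append(simulate_fcm_run(t, gs, p, gc, cv=0.01,
                                     seed=int(rng.integers(2 ** 31))))
    import pandas as pd

    paths["fcm_peaks"] = os.path.join(out_dir, "fcm_peaks.tsv")
    pd.DataFrame([{
        "accession": r.accession,
        "pi_peaks": ",".join("%.6g" % x for x in r.sample_peaks_pi),
        "dapi_peaks": ",".join("%.6g" % x for x in r.sample_peaks_dapi),
        "standard_pi": r.standard_peak_pi,
        "standard_dapi": r.standard_peak_dapi,
        "standard_2c_mbp": r.standard_2c_mbp,
        "standard_gc_pct": r.standard_gc_pct,
    } for r in runs]).to_csv(paths["fcm_peaks"], sep="\t", index=False)

    records = [_fcm.derive_traits(r) for r in runs]
    paths["traits"] = os.path.join(out_dir, "traits.tsv")
    _fcm.write_trait_table(records, paths["traits"])

    land = simulate_landscape(nrows=120, ncols=120, n_regions=6,
                              seed=int(rng.integers(2 ** 31)))
    for name, raster in (("dem", land.dem), ("regions", land.regions),
                         ("ecoregions", land.ecoregions)):
        paths[name] = os.path.join(out_dir, "%s.asc" % name)
        write_ascii_grid(raster, paths[name])
    for i, layer in enumerate(land.env, start=1):
        paths["env_%d" % i] = os.path.join(out_dir, "env_%d.asc" % i)
        write_ascii_grid(layer, paths["env_%d" % i])

    ranges = []
    for t in taxa:
        k = int(rng.integers(1, 4))
        regions = rng.choice(np.arange(1, 7), size=k, replace=False)
        lo = float(rng.uniform(0, 1500))
        hi = lo + float(rng.uniform(500, 2500))
        ranges.append({"taxon": t, "regions": ",".join(str(int(r)) for r in regions),
                       "elev_min": lo, "elev_max": hi})
    paths["ranges"] = os.path.join(out_dir, "ranges.tsv")
    pd.DataFrame(ranges).to_csv(paths["ranges"], sep="\t", index=False)

    paths["clade_map"] = os.path.join(out_dir, "clades.tsv")
    pd.DataFrame([{"clade": c, "members": ",".join(accessions[c])}
                  for c in clade_names]).to_csv(paths["clade_map"], sep="\t", index=False)
    return paths
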