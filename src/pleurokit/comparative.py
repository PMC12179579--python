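"""Phylogenetic comparative statistics under Brownian motion.

Implements the statistics used to analyse flow-cytometric genome traits on
a dated species tree: Pagel's lambda (ML, with a likelihood-ratio CI),
phylogenetic generalized least squares (PGLS) with fixed or ML lambda,
PGLS with predictor uncertainty (replicated draws within per-taxon
percentile bounds), simulation-based phylogenetic ANOVA, Felsenstein's
independent contrasts, ML ancestral states, and branch-wise detection of
significant trait changes.

All covariance algebra is dense (the trees involved have at most a few
hundred tips): C[i, j] is the shared root-to-MRCA path length, and the
lambda transform multiplies off-diagonal entries by lambda in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = [
    "PhyloCovariance",
    "PglsResult",
    "LambdaResult",
    "UncertaintyResult",
    "phylo_covariance",
    "pagel_lambda_ml",
    "pgls",
    "pgls_with_uncertainty",
    "phylo_anova",
    "pic",
    "pic_correlation",
    "ancestral_states_bm",
    "significant_changes",
]


@dataclass
class PhyloCovariance:
    taxa: List[str]
    matrix: np.ndarray  # BM covariance: shared path lengths from the root

    def lambda_transform(self, lam: float) -> np.ndarray:
        if not (0.0 <= lam <= 1.0):
            raise ValueError("lambda must be in [0, 1]")
        c = self.matrix * lam
        np.fill_diagonal(c, np.diag(self.matrix))
        return c

    def order(self, taxa: Sequence[str]) -> "PhyloCovariance":
        idx = [self.taxa.index(t) for t in taxa]
        return PhyloCovariance(list(taxa), self.matrix[np.ix_(idx, idx)])


def phylo_covariance(tree: dendropy.Tree) -> PhyloCovariance:
    """Dense BM covariance from branch lengths (missing lengths are errors)."""
    leaves = []
    depth: Dict[int, float] = {id(tree.seed_node): 0.0}
    for nd in tree.preorder_node_iter():
        if nd is not tree.seed_node:
            if nd.edge.length is None:
                raise ValueError("missing branch length on an edge")
            depth[id(nd)] = depth[id(nd.parent_node)] + float(nd.edge.length)
        if nd.is_leaf():
            leaves.append(nd)
    taxa = [lf.taxon.label for lf in leaves]
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    c = np.zeros((n, n))
    for lf in leaves:
        c[index[lf.taxon.label], index[lf.taxon.label]] = depth[id(lf)]
    # off-diagonals: for each internal node, leaf pairs split across its
    # child subtrees share exactly that node's depth
    for nd in tree.preorder_internal_node_iter():
        groups = [
            [index[lf.taxon.label] for lf in child.leaf_iter()]
            for child in nd.child_nodes()
        ]
        d = depth[id(nd)]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        c[a, b] = c[b, a] = d
    return PhyloCovariance(taxa, c)


def _gls_loglik(y: np.ndarray, x: np.ndarray, v: np.ndarray) -> Tuple[float, np.ndarray, float]:
    """Profile ML log-likelihood of a GLS model with V known up to sigma^2.

    Returns (loglik, beta_hat, sigma2_ml).
    """
    n = len(y)
    l_chol = np.linalg.cholesky(v)
    zx = np.linalg.solve(l_chol, x)
    zy = np.linalg.solve(l_chol, y)
    beta, *_ = np.linalg.lstsq(zx, zy, rcond=None)
    resid = zy - zx @ beta
    sigma2 = float(resid @ resid) / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(l_chol))))
    ll = -0.5 * (n * math.log(2.0 * math.pi * sigma2) + logdet + n)
    return ll, beta, sigma2


@dataclass
class LambdaResult:
    lambda_hat: float
    ci_low: float
    ci_high: Optional[float]  # None = upper bound not excluded at the boundary
    loglik: float


def _profile_lambda(y, x, cov: PhyloCovariance) -> Tuple[float, float]:
    """(lambda_hat, loglik at hat) by grid pre-scan + bounded refinement."""

    def nll(lam):
        return -_gls_loglik(y, x, cov.lambda_transform(lam))[0]

    grid = np.linspace(0.0, 1.0, 21)
    values = [nll(g) for g in grid]
    i = int(np.argmin(values))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if lo == hi:
        best_lam = lo
    else:
        res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-6})
        best_lam = float(res.x)
    # boundary polish: the interior optimizer cannot land exactly on 0 or 1
    best_val = nll(best_lam)
    for edge in (0.0, 1.0):
        if nll(edge) <= best_val + 1e-9:
            edge_val = nll(edge)
            if edge_val < best_val + 1e-9:
                best_lam, best_val = edge, edge_val
    return best_lam, -best_val


def pagel_lambda_ml(tree: dendropy.Tree, trait: Dict[str, float]) -> LambdaResult:
    """ML estimate of Pagel's lambda with a chi2(1) likelihood-ratio CI.

    The upper CI bound is reported as ``None`` (printed "NA") when the
    estimate sits at the boundary lambda = 1 and no lambda < 1 can be
    excluded above it.
    """
    cov = phylo_covariance(tree)
    taxa = [t for t in cov.taxa if t in trait]
    if len(taxa) < 4:
        raise ValueError("need at least 4 taxa with trait values")
    cov = cov.order(taxa)
    y = np.array([float(trait[t]) for t in taxa])
    if np.allclose(y, y[0]):
        raise ValueError("zero-variance trait: lambda undefined")
    x = np.ones((len(y), 1))
    lam_hat, ll_hat = _profile_lambda(y, x, cov)
    cutoff = ll_hat - 0.5 * stats.chi2.ppf(0.95, df=1)

    def ll(lam):
        return _gls_loglik(y, x, cov.lambda_transform(lam))[0]

    ci_low = 0.0
    if ll(0.0) < cutoff:
        lo, hi = 0.0, lam_hat
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if ll(mid) < cutoff:
                lo = mid
            else:
                hi = mid
        ci_low = hi
    ci_high: Optional[float] = 1.0
    if ll(1.0) >= cutoff:
        ci_high = None  # boundary not excluded: reported as NA
    else:
        lo, hi = lam_hat, 1.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if ll(mid) < cutoff:
                hi = mid
            else:
                lo = mid
        ci_high = lo
    return LambdaResult(lambda_hat=lam_hat, ci_low=ci_low, ci_high=ci_high,
                        loglik=ll_hat)


@dataclass
class PglsResult:
    slope: float
    intercept: float
    p_value: float
    explained_variance_pct: float
    lam: float
    n: int
    slope_se: float


def pgls(
    tree: dendropy.Tree,
    response: Dict[str, float],
    predictor: Dict[str, float],
    lam: object = 1.0,
    _cov: Optional[PhyloCovariance] = None,
) -> PglsResult:
    """Phylogenetic GLS regression of response on predictor.

    ``lam`` is a fixed value in [0, 1] or "ML".  Explained variance is the
    GLS (whitened-space) R^2, in percent.  With lam = 0 the fit reduces
    exactly to ordinary least squares.
    """
    cov = _cov if _cov is not None else phylo_covariance(tree)
    taxa = [t for t in cov.taxa if t in response and t in predictor]
    if len(taxa) < 3:
        raise ValueError("need at least 3 complete cases")
    cov = cov.order(taxa)
    y = np.array([float(response[t]) for t in taxa])
    xv = np.array([float(predictor[t]) for t in taxa])
    if np.allclose(xv, xv[0]):
        raise ValueError("singular design: constant predictor")
    x = np.column_stack([np.ones_like(xv), xv])
    if lam == "ML":
        lam_val, _ = _profile_lambda(y, x, cov)
    else:
        lam_val = float(lam)
    v = cov.lambda_transform(lam_val)
    l_chol = np.linalg.cholesky(v)
    zx = np.linalg.solve(l_chol, x)
    zy = np.linalg.solve(l_chol, y)
    xtx_inv = np.linalg.inv(zx.T @ zx)
    beta = xtx_inv @ zx.T @ zy
    resid = zy - zx @ beta
    n, p = len(y), 2
    rss = float(resid @ resid)
    sigma2 = rss / (n - p)
    se = math.sqrt(sigma2 * xtx_inv[1, 1])
    tstat = beta[1] / se
    p_value = 2.0 * stats.t.sf(abs(tstat), df=n - p)
    # null (intercept-only) GLS fit for the whitened-space R^2
    z1 = np.linalg.solve(l_chol, np.ones_like(y))
    mu = float(z1 @ zy) / float(z1 @ z1)
    rss0 = float((zy - mu * z1) @ (zy - mu * z1))
    r2 = 1.0 - rss / rss0 if rss0 > 0 else 0.0
    return PglsResult(
        slope=float(beta[1]), intercept=float(beta[0]),
        p_value=float(max(p_value, np.finfo(float).tiny)),
        explained_variance_pct=100.0 * max(min(r2, 1.0), 0.0),
        lam=lam_val, n=n, slope_se=se,
    )


@dataclass
class UncertaintyResult:
    p_values: np.ndarray
    p_median: float
    p_min: float
    p_max: float
    seed: int

    def summary(self) -> str:
        """The "p (p_min-p_max)" form used to tabulate replicate PGLS runs."""
        return "%.3f (%.3f-%.3f)" % (self.p_median, self.p_min, self.p_max)


def pgls_with_uncertainty(
    tree: dendropy.Tree,
    response: Dict[str, float],
    predictor_bounds: Dict[str, Tuple[float, float]],
    n_intra: int = 1000,
    seed: int = 0,
    lam: object = 1.0,
) -> UncertaintyResult:
    """PGLS replicated with the predictor drawn uniformly within per-taxon
    bounds (e.g. the 47.5-52.5 or 45-55 percentile interval of the
    environmental layer over the taxon's range)."""
    for t, (lo, hi) in predictor_bounds.items():
        if lo > hi:
            raise ValueError("taxon %r: lower bound exceeds upper" % t)
    cov = phylo_covariance(tree)
    taxa = sorted(t for t in predictor_bounds if t in response)
    rng = np.random.default_rng(seed)
    p_values = np.empty(n_intra)
    for i in range(n_intra):
        draw = {t: rng.uniform(predictor_bounds[t][0], predictor_bounds[t][1])
                for t in taxa}
        p_values[i] = pgls(tree, response, draw, lam=lam, _cov=cov).p_value
    return UncertaintyResult(
        p_values=p_values,
        p_median=float(np.median(p_values)),
        p_min=float(p_values.min()),
        p_max=float(p_values.max()),
        seed=seed,
    )


def phylo_anova(
    tree: dendropy.Tree,
    trait: Dict[str, float],
    groups: Dict[str, object],
    n_sim: int = 1000,
    seed: int = 0,
) -> Tuple[float, float, float]:
    """(F, p_standard, p_phylo): classical one-way ANOVA F plus a
    phylogenetic p-value from BM simulation of the trait.

    The null traits are simulated under BM on the tree with sigma^2
    estimated from the data (ML); p_phylo is the +1-smoothed fraction of
    simulated F statistics >= the observed one.
    """
    cov = phylo_covariance(tree)
    taxa = [t for t in cov.taxa if t in trait and t in groups]
    cov = cov.order(taxa)
    y = np.array([float(trait[t]) for t in taxa])
    labels = np.array([groups[t] for t in taxa], dtype=object)
    uniq = sorted(set(labels.tolist()), key=str)
    if len(uniq) < 2 or any((labels == g).sum() < 2 for g in uniq):
        raise ValueError("need >= 2 groups with >= 2 members each")
    masks = [labels == g for g in uniq]

    def f_stat(values: np.ndarray) -> np.ndarray:
        """Vectorized one-way ANOVA F over columns of ``values``."""
        values = np.atleast_2d(values.T).T  # (n, m)
        grand = values.mean(axis=0)
        ssb = np.zeros(values.shape[1])
        ssw = np.zeros(values.shape[1])
        for m in masks:
            sub = values[m]
            gm = sub.mean(axis=0)
            ssb += m.sum() * (gm - grand) ** 2
            ssw += ((sub - gm) ** 2).sum(axis=0)
        dfb = len(masks) - 1
        dfw = values.shape[0] - len(masks)
        return (ssb / dfb) / (ssw / dfw)

    f_obs = float(f_stat(y)[0])
    dfb, dfw = len(uniq) - 1, len(y) - len(uniq)
    p_standard = float(stats.f.sf(f_obs, dfb, dfw))
    # BM null: sigma^2 by ML around the phylogenetic mean
    ll, beta, sigma2 = _gls_loglik(y, np.ones((len(y), 1)), cov.matrix)
    l_chol = np.linalg.cholesky(cov.matrix)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((len(y), n_sim))
    sims = beta[0] + math.sqrt(sigma2) * (l_chol @ z)
    f_sim = f_stat(sims)
    p_phylo = (1.0 + float(np.sum(f_sim >= f_obs))) / (n_sim + 1.0)
    return f_obs, p_standard, p_phylo


def _resolve_polytomies(tree: dendropy.Tree) -> dendropy.Tree:
    tree = tree.clone(depth=1)
    tree.resolve_polytomies(limit=2, update_bipartitions=False)
    for nd in tree.preorder_node_iter():
        if nd is not tree.seed_node and nd.edge.length is None:
            nd.edge.length = 0.0
    return tree


def pic(tree: dendropy.Tree, trait: Dict[str, float]) -> np.ndarray:
    """Standardized phylogenetic independent contrasts (n_tips - 1 values).

    Polytomies are resolved arbitrarily with zero-length edges; missing
    branch lengths elsewhere are an error.
    """
    tree = _resolve_polytomies(tree)
    values: Dict[int, float] = {}
    lengths: Dict[int, float] = {}
    contrasts: List[float] = []
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            label = nd.taxon.label
            if label not in trait:
                raise ValueError("no trait value for tip %r" % label)
            values[id(nd)] = float(trait[label])
            if nd.edge.length is None:
                raise ValueError("missing branch length")
            lengths[id(nd)] = float(nd.edge.length)
            continue
        children = nd.child_nodes()
        if len(children) != 2:  # pragma: no cover - resolved above
            raise AssertionError("unresolved node after polytomy resolution")
        a, b = children
        va, vb = values[id(a)], values[id(b)]
        ta, tb = lengths[id(a)], lengths[id(b)]
        ta = max(ta, 1e-12)
        tb = max(tb, 1e-12)
        contrasts.append((va - vb) / math.sqrt(ta + tb))
        values[id(nd)] = (va / ta + vb / tb) / (1.0 / ta + 1.0 / tb)
        extra = ta * tb / (ta + tb)
        edge = float(nd.edge.length) if nd is not tree.seed_node and nd.edge.length is not None else 0.0
        lengths[id(nd)] = edge + extra
    return np.array(contrasts)


def pic_correlation(
    tree: dendropy.Tree, trait_x: Dict[str, float], trait_y: Dict[str, float]
) -> Tuple[float, float]:
    """Contrast correlation through the origin and its two-sided p-value."""
    u = pic(tree, trait_x)
    v = pic(tree, trait_y)
    denom = math.sqrt(float(u @ u) * float(v @ v))
    if denom == 0:
        return 0.0, 1.0
    r = float(u @ v) / denom
    df = len(u) - 1
    if df < 1:
        return r, 1.0
    r_clamped = max(min(r, 1.0 - 1e-15), -1.0 + 1e-15)
    tstat = r_clamped * math.sqrt(df / (1.0 - r_clamped ** 2))
    p = 2.0 * stats.t.sf(abs(tstat), df=df)
    return r, float(p)


@dataclass
class AncestralStates:
    """ML (= GLS) ancestral estimates under BM, with estimation variances."""

    node_states: Dict[int, float]  # keyed by id(node) of the input tree clone
    node_variances: Dict[int, float]
    sigma2: float
    tree: dendropy.Tree  # the (cloned, polytomy-resolved) tree the keys refer to

    @property
    def root_state(self) -> float:
        return self.node_states[id(self.tree.seed_node)]


def ancestral_states_bm(tree: dendropy.Tree, trait: Dict[str, float]) -> AncestralStates:
    """Joint ML ancestral states: minimize sum (delta_x)^2 / t over edges.

    This is the GLS solution; the root estimate equals the phylogenetic
    mean.  Estimation variances are sigma^2-scaled diagonals of the inverse
    precision of the internal states given the tips.
    """
    tree = _resolve_polytomies(tree)
    internal = [nd for nd in tree.preorder_internal_node_iter()]
    idx = {id(nd): i for i, nd in enumerate(internal)}
    n = len(internal)
    a = np.zeros((n, n))
    b = np.zeros(n)
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        t = max(float(nd.edge.length), 1e-12)
        parent = nd.parent_node
        i = idx[id(parent)]
        w = 1.0 / t
        a[i, i] += w
        if nd.is_leaf():
            b[i] += w * float(trait[nd.taxon.label])
        else:
            j = idx[id(nd)]
            a[j, j] += w
            a[i, j] -= w
            a[j, i] -= w
    a_inv = np.linalg.inv(a)
    states_int = a_inv @ b
    node_states: Dict[int, float] = {}
    node_vars: Dict[int, float] = {}
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            node_states[id(nd)] = float(trait[nd.taxon.label])
            node_vars[id(nd)] = 0.0
        else:
            i = idx[id(nd)]
            node_states[id(nd)] = float(states_int[i])
            node_vars[id(nd)] = float(a_inv[i, i])
    # sigma^2 by REML-style normalization of the BM quadratic form at the fit
    cov = phylo_covariance(tree)
    y = np.array([float(trait[t]) for t in cov.taxa])
    l_chol = np.linalg.cholesky(cov.matrix)
    z1 = np.linalg.solve(l_chol, np.ones_like(y))
    zy = np.linalg.solve(l_chol, y)
    mu = float(z1 @ zy) / float(z1 @ z1)
    resid = zy - mu * z1
    sigma2 = float(resid @ resid) / max(len(y) - 1, 1)
    for k in node_vars:
        node_vars[k] *= sigma2
    return AncestralStates(node_states=node_states, node_variances=node_vars,
                           sigma2=sigma2, tree=tree)


def significant_changes(
    tree: dendropy.Tree, trait: Dict[str, float], alpha: float = 0.05
) -> List[Tuple[frozenset, float, float]]:
    """Branches whose reconstructed trait change exceeds BM expectation.

    A branch parent->child is flagged when |x_child - x_parent| exceeds the
    (1 - alpha) quantile of |N(0, v)| with v = sigma^2 * t plus the
    estimation variances of both endpoint states.  Returns
    (clade_below_branch, change, z_score) triples for flagged branches.
    """
    anc = ancestral_states_bm(tree, trait)
    tree = anc.tree
    # degenerate input: an (effectively) constant trait has no changes to
    # flag, and its sigma^2 is pure floating-point noise
    y = np.array([float(v) for v in trait.values()])
    scale = max(float(np.mean(y * y)), 1.0)
    if anc.sigma2 <= 1e-14 * scale:
        return []
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    flagged = []
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        t = max(float(nd.edge.length), 1e-12)
        change = anc.node_states[id(nd)] - anc.node_states[id(nd.parent_node)]
        v = anc.sigma2 * t + anc.node_variances[id(nd)] + anc.node_variances[id(nd.parent_node)]
        if v <= 0:
            continue
        z = change / math.sqrt(v)
        if abs(z) > z_crit:
            clade = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            flagged.append((clade, float(change), float(z)))
    return flagged
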