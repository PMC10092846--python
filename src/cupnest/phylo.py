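"""Tree-based comparative machinery.

Continuous traits are modelled as Brownian motion (BM) on a rooted tree
with branch lengths: the trait vector across tips is multivariate normal
with covariance sigma^2 * C, where C[i, j] is the root-to-MRCA path length
shared by tips i and j.  On top of this base model the module provides

* maximum-likelihood estimation of Pagel's lambda, the multiplier on the
  off-diagonal entries of C that measures phylogenetic signal (0 = star
  phylogeny, 1 = pure BM);
* ML ancestral state reconstruction with per-node 95% confidence
  intervals (re-rooting GLS method);
* the evolutionary (phylogenetically corrected) correlation between two
  traits from the GLS cross-covariance of contrasts;
* aggregation of any per-tree estimator over a sample of topologies.

Trees are `dendropy.Tree` objects; traits are mappings (or pandas Series)
from tip label to value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import dendropy
import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .errors import TraitError, TreeError

__all__ = [
    "read_trees",
    "tip_labels",
    "prune_to",
    "bm_covariance",
    "LambdaFit",
    "fit_lambda",
    "AncestralReconstruction",
    "ancestral_states",
    "EvolutionaryCorrelation",
    "phylo_correlation",
    "TreeSummary",
    "over_trees",
]


# ---------------------------------------------------------------------------
# tree I/O and bookkeeping

def read_trees(path, schema: str | None = None, normalize_names: bool = True) -> list[dendropy.Tree]:
    """Read one or more rooted trees from a Newick or Nexus file.

    ``schema`` is guessed from the extension when not given.  With
    ``normalize_names`` underscores in tip labels are replaced by spaces'
    inverse convention: spaces become underscores, so labels match the
    underscore-separated species identifiers used in data tables.
    """
    if schema is None:
        s = str(path).lower()
        schema = "nexus" if s.endswith((".nex", ".nexus", ".trees")) else "newick"
    trees = dendropy.TreeList.get(path=str(path), schema=schema)
    out = []
    for t in trees:
        t.is_rooted = True
        if normalize_names:
            for leaf in t.leaf_node_iter():
                if leaf.taxon is not None:
                    leaf.taxon.label = leaf.taxon.label.replace(" ", "_")
        out.append(t)
    return out


def tip_labels(tree: dendropy.Tree) -> list[str]:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise TreeError("duplicate tip names in tree")
    return labels


def prune_to(tree: dendropy.Tree, taxa: Sequence[str]) -> dendropy.Tree:
    """Return a clone of ``tree`` pruned to the given tip labels."""
    keep = set(taxa)
    missing = keep - set(tip_labels(tree))
    if missing:
        raise TreeError(f"taxa absent from tree: {sorted(missing)}")
    clone = tree.clone(depth=1)
    clone.retain_taxa_with_labels(sorted(keep))
    return clone


# ---------------------------------------------------------------------------
# BM covariance

def bm_covariance(
    tree: dendropy.Tree, order: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance matrix of the tips.

    Entry (i, j) is the path length from the root to the most recent common
    ancestor of tips i and j; the diagonal holds root-to-tip depths.  The
    matrix is symmetric positive semidefinite by construction.  ``order``
    fixes the row order; default is the tree's leaf iteration order.
    """
    labels = tip_labels(tree)
    if order is not None:
        unknown = set(order) - set(labels)
        if unknown:
            raise TreeError(f"requested taxa not in tree: {sorted(unknown)}")
        labels = list(order)
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))

    # depth of every node, then assign depth(node) to cross-subtree tip pairs
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    tips_below: dict[dendropy.Node, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = idx.get(node.taxon.label)
            tips_below[node] = [i] if i is not None else []
            if i is not None:
                C[i, i] = node.root_distance
            continue
        children = node.child_nodes()
        groups = [tips_below[c] for c in children]
        depth = node.root_distance
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                ia = np.asarray(groups[a], dtype=int)
                ib = np.asarray(groups[b], dtype=int)
                if ia.size and ib.size:
                    C[np.ix_(ia, ib)] = depth
                    C[np.ix_(ib, ia)] = depth
        tips_below[node] = [i for g in groups for i in g]
    return C, labels


def _trait_vector(trait: Mapping[str, float], labels: Sequence[str]) -> np.ndarray:
    missing = [lab for lab in labels if lab not in trait or trait[lab] is None]
    if missing:
        raise TraitError(f"trait missing for tips: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    y = np.asarray([float(trait[lab]) for lab in labels])
    if not np.all(np.isfinite(y)):
        raise TraitError("non-finite trait values")
    return y


def _gls_mean_and_rss(C: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """GLS phylogenetic mean, residual quadratic form and log|C|."""
    cf = cho_factor(C, lower=True)
    one = np.ones(len(y))
    Ci1 = cho_solve(cf, one)
    Ciy = cho_solve(cf, y)
    a = float(one @ Ciy) / float(one @ Ci1)
    r = y - a
    q = float(r @ cho_solve(cf, r))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return a, q, logdet


def _bm_loglik(C: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Profile ML log-likelihood under BM with covariance sigma^2*C.

    Returns (loglik, sigma2_hat, root_state_hat); sigma^2 and the root
    state are profiled out in closed form (ML divisor n).
    """
    n = len(y)
    a, q, logdet = _gls_mean_and_rss(C, y)
    s2 = q / n
    if s2 <= 0:
        # trait constant across tips: likelihood unbounded; report by convention
        return math.inf, 0.0, a
    ll = -0.5 * (n * math.log(2.0 * math.pi * s2) + logdet + n)
    return ll, s2, a


# ---------------------------------------------------------------------------
# Pagel's lambda

@dataclass
class LambdaFit:
    """ML fit of Pagel's lambda for one trait on one tree."""

    lambda_hat: float
    sigma2_hat: float
    root_state_hat: float
    log_likelihood: float
    flat_likelihood: bool
    ci95: tuple[float, float]


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def fit_lambda(tree: dendropy.Tree, trait: Mapping[str, float]) -> LambdaFit:
    """Maximise the Pagel's-lambda likelihood over lambda in [0, 1].

    Lambda multiplies the off-diagonal covariance entries; sigma^2 and the
    root state are profiled out at every lambda.  On a star tree the
    likelihood is constant in lambda; the fit is flagged ``flat_likelihood``
    and lambda = 0 is returned by convention.  The 95% interval is the
    profile-likelihood interval (chi-square 1 df cutoff).
    """
    C, labels = bm_covariance(tree)
    if len(labels) < 3:
        raise TreeError("lambda estimation needs at least 3 tips")
    y = _trait_vector(trait, labels)

    off = C.copy()
    np.fill_diagonal(off, 0.0)
    if np.max(np.abs(off)) < 1e-12 * max(1.0, np.max(np.diag(C))):
        ll, s2, a = _bm_loglik(C, y)
        return LambdaFit(0.0, s2, a, ll, True, (0.0, 1.0))

    def nll(lam: float) -> float:
        ll, _, _ = _bm_loglik(_lambda_cov(C, lam), y)
        return -ll

    res = optimize.minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": 1e-8})
    lam_hat = float(res.x)
    # guard the boundary: the bounded search can stall short of an endpoint
    cands = [(nll(0.0), 0.0), (nll(1.0), 1.0), (res.fun, lam_hat)]
    best_nll, lam_hat = min(cands, key=lambda t: t[0])
    ll, s2, a = _bm_loglik(_lambda_cov(C, lam_hat), y)

    cutoff = -ll + 0.5 * stats.chi2.ppf(0.95, df=1)

    def above(lam: float) -> float:
        return nll(lam) - cutoff

    lo, hi = 0.0, 1.0
    if above(0.0) > 0:
        lo = optimize.brentq(above, 0.0, lam_hat, xtol=1e-6)
    if above(1.0) > 0:
        hi = optimize.brentq(above, lam_hat, 1.0, xtol=1e-6)
    return LambdaFit(lam_hat, s2, a, ll, False, (float(lo), float(hi)))


# ---------------------------------------------------------------------------
# ancestral states

@dataclass
class AncestralReconstruction:
    """ML ancestral states under BM with 95% confidence intervals."""

    node_states: dict[str, float]
    node_ci95: dict[str, tuple[float, float]]
    root_state: float
    root_ci95: tuple[float, float]
    sigma2_hat: float
    #: tip sets identifying each internal node, keyed like node_states
    node_tips: dict[str, frozenset[str]]


def _all_distances(tree: dendropy.Tree) -> tuple[dict, list, list]:
    """Path-length distances between all pairs of nodes (undirected)."""
    nodes = list(tree.preorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    adj: list[list[tuple[int, float]]] = [[] for _ in nodes]
    for node in nodes:
        for child in node.child_nodes():
            bl = child.edge.length if child.edge.length is not None else 0.0
            i, j = index[id(node)], index[id(child)]
            adj[i].append((j, bl))
            adj[j].append((i, bl))
    m = len(nodes)
    D = np.zeros((m, m))
    for s in range(m):
        dist = np.full(m, -1.0)
        dist[s] = 0.0
        stack = [s]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + w
                    stack.append(v)
        D[s] = dist
    return index, nodes, D


def ancestral_states(tree: dendropy.Tree, trait: Mapping[str, float]) -> AncestralReconstruction:
    """ML ancestral states at every internal node under BM.

    Each node's state is the GLS phylogenetic mean of the tips computed
    with the tree re-rooted at that node (covariance built from unrooted
    path distances), which equals the ML / empirical-BLUP estimate.  The
    estimation variance is sigma2_hat / (1' C_k^-1 1) and the 95% CI is
    estimate +/- 1.96 sd.
    """
    labels = tip_labels(tree)
    y_map = {lab: trait[lab] for lab in labels if lab in trait}
    y = _trait_vector(trait, labels)
    C, _ = bm_covariance(tree, order=labels)
    n = len(labels)
    _, q, _ = _gls_mean_and_rss(C, y)
    # rate from the mean squared phylogenetic contrast (divisor n-1),
    # the convention behind the usual ancestral-state CIs
    s2 = q / (n - 1)

    index, nodes, D = _all_distances(tree)
    tip_idx = np.array([index[id(leaf)] for leaf in tree.leaf_node_iter()])
    lab_order = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    yv = np.asarray([float(y_map[lab]) for lab in lab_order])
    Dtt = D[np.ix_(tip_idx, tip_idx)]

    states: dict[str, float] = {}
    cis: dict[str, tuple[float, float]] = {}
    node_tips: dict[str, frozenset[str]] = {}
    root_state = math.nan
    root_ci = (math.nan, math.nan)
    internal_counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        internal_counter += 1
        name = node.label if node.label else f"n{internal_counter}"
        dk = D[index[id(node)], tip_idx]
        Ck = (dk[:, None] + dk[None, :] - Dtt) / 2.0
        try:
            cf = cho_factor(Ck, lower=True)
        except np.linalg.LinAlgError as exc:
            raise TreeError(f"singular tip covariance at node {name!r} "
                            f"(zero-length pendant branches?)") from exc
        one = np.ones(len(yv))
        Ci1 = cho_solve(cf, one)
        denom = float(one @ Ci1)
        est = float(yv @ Ci1) / denom
        var = s2 / denom
        half = 1.96 * math.sqrt(max(var, 0.0))
        states[name] = est
        cis[name] = (est - half, est + half)
        node_tips[name] = frozenset(
            leaf.taxon.label for leaf in node.leaf_iter()
        )
        if node is tree.seed_node:
            root_state = est
            root_ci = (est - half, est + half)
    return AncestralReconstruction(states, cis, root_state, root_ci, s2, node_tips)


# ---------------------------------------------------------------------------
# evolutionary correlation

@dataclass
class EvolutionaryCorrelation:
    """Phylogenetically corrected Pearson-type correlation of two traits."""

    r: float
    p_value: float
    n_species: int
    covariance: np.ndarray


def phylo_correlation(
    tree: dendropy.Tree, trait_x: Mapping[str, float], trait_y: Mapping[str, float]
) -> EvolutionaryCorrelation:
    """Evolutionary correlation from the GLS cross-covariance.

    R = (X - 1 a)' C^-1 (X - 1 a) / (n - 1) with a the GLS phylogenetic
    means; r = R_xy / sqrt(R_xx R_yy).  The p-value is a t test with
    n - 2 df applied to the corrected r.
    """
    C, labels = bm_covariance(tree)
    n = len(labels)
    X = np.column_stack([_trait_vector(trait_x, labels), _trait_vector(trait_y, labels)])
    if np.var(X[:, 0]) == 0 or np.var(X[:, 1]) == 0:
        raise TraitError("zero evolutionary variance; correlation undefined")
    cf = cho_factor(C, lower=True)
    one = np.ones(n)
    Ci1 = cho_solve(cf, one)
    denom = float(one @ Ci1)
    a = (X.T @ Ci1) / denom
    Xc = X - a[None, :]
    R = (Xc.T @ cho_solve(cf, Xc)) / (n - 1)
    if R[0, 0] <= 0 or R[1, 1] <= 0:
        raise TraitError("zero evolutionary variance; correlation undefined")
    r = float(R[0, 1] / math.sqrt(R[0, 0] * R[1, 1]))
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return EvolutionaryCorrelation(r=r, p_value=p, n_species=n, covariance=R)


# ---------------------------------------------------------------------------
# multi-tree aggregation

@dataclass
class TreeSummary:
    """Per-tree estimates and their spread over a tree sample."""

    values: list
    mean: Optional[float]
    min: Optional[float]
    max: Optional[float]


def over_trees(
    trees: Sequence[dendropy.Tree],
    op: Callable[[dendropy.Tree], object],
    prune_to_common: bool = True,
) -> TreeSummary:
    """Apply a per-tree estimator across a sample of topologies.

    Trees are pruned to their common tip set first (so estimates are
    comparable), then ``op`` runs on each; numeric results are summarised
    by mean/min/max.  Deterministic given tree order.
    """
    if len(trees) == 0:
        raise TreeError("empty tree collection")
    work = list(trees)
    if prune_to_common and len(work) > 1:
        common = set(tip_labels(work[0]))
        for t in work[1:]:
            common &= set(tip_labels(t))
        if not common:
            raise TreeError("trees share no tips")
        work = [prune_to(t, sorted(common)) if set(tip_labels(t)) != common else t
                for t in work]
    values = [op(t) for t in work]
    if all(isinstance(v, (int, float)) and not isinstance(v, bool) for v in values):
        arr = np.asarray(values, dtype=float)
        return TreeSummary(values, float(arr.mean()), float(arr.min()), float(arr.max()))
    return TreeSummary(values, None, None, None)
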