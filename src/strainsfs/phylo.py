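"""Pagel's lambda phylogenetic signal for continuous DFE summaries.

Maximum likelihood over (lambda, sigma^2, root state) of a multivariate
normal whose covariance is the Brownian-motion phylogenetic covariance
with off-diagonals scaled by lambda.  The upper bound on lambda is set
by positive-definiteness of the transformed covariance rather than 1.0,
so estimates slightly above 1 are attainable.  The test against
lambda = 0 uses a plain chi-square(1) p-value (no boundary mixture).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

__all__ = [
    "PhyloSignalResult",
    "pagels_lambda",
    "leave_out_rerun",
    "phylo_covariance",
]


@dataclass
class PhyloSignalResult:
    lambda_hat: float
    loglik_at_hat: float
    loglik_at_zero: float
    p_value: float
    sigma2_hat: float
    root_state_hat: float
    lambda_max: float


def _as_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=str(tree), schema="newick")


def phylo_covariance(tree) -> tuple[list[str], np.ndarray]:
    """Tip labels and BM covariance matrix (shared root-to-MRCA paths).

    Zero-length terminal branches are perturbed by 1e-8 with a warning
    so the matrix stays positive-definite.
    """
    t = _as_tree(tree)
    for edge in t.preorder_edge_iter():
        if edge.length is None and edge.head_node is not t.seed_node:
            raise ValueError("tree must have branch lengths on all edges")
    leaves = t.leaf_nodes()
    labels = [lf.taxon.label for lf in leaves]
    idx = {id(lf): i for i, lf in enumerate(leaves)}
    m = len(leaves)
    C = np.zeros((m, m))

    # Depth-first: each node carries its root distance; tips descending
    # through different children of a node share that node's depth.
    def depth(node):
        d = 0.0
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        return d

    tip_sets = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            tip_sets[id(node)] = [idx[id(node)]]
            continue
        children = node.child_nodes()
        sets = [tip_sets[id(c)] for c in children]
        d = depth(node)
        for a in range(len(sets)):
            for b in range(a + 1, len(sets)):
                for i in sets[a]:
                    for j in sets[b]:
                        C[i, j] = C[j, i] = d
        tip_sets[id(node)] = [i for s in sets for i in s]

    for i, lf in enumerate(leaves):
        C[i, i] = depth(lf)
    term_zero = [i for i in range(m)
                 if (leaves[i].edge.length or 0.0) == 0.0]
    if term_zero:
        warnings.warn("zero-length terminal branches perturbed by 1e-8",
                      stacklevel=2)
        for i in term_zero:
            C[i, i] += 1e-8
    return labels, C


def _lambda_ll(lam: float, y: np.ndarray, C: np.ndarray):
    """Profile log-likelihood of lambda with (mu, sigma2) maximized out."""
    m = y.size
    V = lam * C + (1.0 - lam) * np.diag(np.diag(C))
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf, np.nan, np.nan
    one = np.ones(m)
    from scipy.linalg import solve_triangular
    a = solve_triangular(L, y, lower=True)
    b = solve_triangular(L, one, lower=True)
    mu = float(b @ a / (b @ b))
    r = a - mu * b
    sigma2 = float(r @ r) / m
    if sigma2 <= 0:
        return -np.inf, mu, sigma2
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    ll = -0.5 * (m * np.log(2.0 * np.pi * sigma2) + logdet + m)
    return ll, mu, sigma2


def _lambda_upper_bound(C: np.ndarray, hi: float = 3.0) -> float:
    """Largest lambda keeping the transformed covariance positive-definite."""
    def ok(lam):
        V = lam * C + (1.0 - lam) * np.diag(np.diag(C))
        try:
            np.linalg.cholesky(V)
            return True
        except np.linalg.LinAlgError:
            return False

    if ok(hi):
        return hi
    lo, up = 1.0, hi
    for _ in range(60):
        mid = 0.5 * (lo + up)
        if ok(mid):
            lo = mid
        else:
            up = mid
    return lo * 0.999999


def pagels_lambda(tree, traits) -> PhyloSignalResult:
    """ML estimate of Pagel's lambda with an LRT against lambda = 0.

    ``traits`` maps tip labels to values (dict or pandas Series).
    """
    labels, C = phylo_covariance(tree)
    if len(labels) < 4:
        raise ValueError("need at least four tips with trait values")
    missing = [l for l in labels if l not in traits]
    if missing:
        raise ValueError(f"traits missing for tips: {missing[:5]}")
    y = np.array([float(traits[l]) for l in labels])
    if np.var(y) == 0:
        raise ValueError("trait variance is zero")
    off = C - np.diag(np.diag(C))
    if np.max(np.abs(off)) == 0:
        raise ValueError("star tree: lambda is unidentifiable")

    lam_max = _lambda_upper_bound(C)
    res = minimize_scalar(lambda l: -_lambda_ll(l, y, C)[0],
                          bounds=(0.0, lam_max), method="bounded",
                          options={"xatol": 1e-8})
    ll_hat, mu_hat, s2_hat = _lambda_ll(res.x, y, C)
    ll_zero, _, _ = _lambda_ll(0.0, y, C)
    lam_hat = float(res.x)
    if ll_zero >= ll_hat:          # boundary optimum at 0
        lam_hat = 0.0
        ll_hat, mu_hat, s2_hat = _lambda_ll(0.0, y, C)
    stat = max(0.0, 2.0 * (ll_hat - ll_zero))
    p = float(chi2.sf(stat, df=1))
    return PhyloSignalResult(
        lambda_hat=lam_hat, loglik_at_hat=float(ll_hat),
        loglik_at_zero=float(ll_zero), p_value=p,
        sigma2_hat=float(s2_hat), root_state_hat=float(mu_hat),
        lambda_max=float(lam_max),
    )


def leave_out_rerun(tree, traits, drop) -> PhyloSignalResult:
    """Re-estimate lambda after pruning ``drop`` tips from the tree.

    Pruning collapses unifurcations, summing branch lengths, so
    root-to-tip path lengths of the remaining tips are preserved.
    """
    t = _as_tree(tree)
    drop = set(drop)
    keep = [tx for tx in t.taxon_namespace if tx.label not in drop]
    if len(keep) < 4:
        raise ValueError("fewer than four tips would remain after dropping")
    pruned = t.extract_tree_with_taxa(taxa=keep,
                                      suppress_unifurcations=True)
    kept_traits = {l: traits[l] for l in (tx.label for tx in keep)}
    return pagels_lambda(pruned, kept_traits)
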