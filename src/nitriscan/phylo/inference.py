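"""Tree inference: neighbor joining, NNI hill-climbing, BIC model choice,
and nonparametric bootstrap supports.

The maximum-likelihood search strategy is a neighbor-joining start followed
by nearest-neighbor-interchange passes that accept strict likelihood
improvements — adequate at the scale of single-gene protein trees (tens of
leaves) and fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .distances import (ml_distance_from_counts, pair_count_matrix,
                        poisson_distance_from_p)
from .likelihood import log_likelihood
from .models import SubstitutionModel
from .msa import Msa
from .trees import Node, Tree

# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(d: np.ndarray, labels: list[str]) -> Tree:
    """Saitou-Nei neighbor joining.

    Negative branch-length estimates are clamped to zero with the deficit
    moved to the sister branch.  Ties in the Q criterion are broken by the
    lexicographically smallest (min-leaf-label) pair, so the result is
    deterministic and equivariant under label permutation.
    """
    d = np.asarray(d, float)
    n = d.shape[0]
    if d.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix and labels are inconsistent")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes: list[Node] = [Node(label) for label in labels]
    keys: list[str] = list(labels)  # min leaf label below each active node
    d = d.copy()
    active = list(range(n))

    def join(i: int, j: int, li: float, lj: float) -> int:
        """Join active rows i, j into a new internal node; returns its row."""
        ni, nj = nodes[i], nodes[j]
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        ni.length, nj.length = max(li, 0.0), max(lj, 0.0)
        parent = Node("")
        parent.add(ni)
        parent.add(nj)
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        return len(nodes) - 1

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] <= qmin + 1e-12 * max(1.0, abs(qmin)):
                    key = tuple(sorted((keys[active[a]], keys[active[b]])))
                    if best is None or key < best[0]:
                        best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        new_row = join(i, j, li, lj)
        # distances from the new node to the remaining taxa
        d = np.pad(d, ((0, 1), (0, 1)))
        for c in range(m):
            if c in (a, b):
                continue
            k = active[c]
            d[new_row, k] = d[k, new_row] = 0.5 * (sub[a, c] + sub[b, c] - dij)
        active = [k for k in active if k not in (i, j)] + [new_row]

    if len(active) == 3:
        i, j, k = active
        root = Node("")
        la = 0.5 * (d[i, j] + d[i, k] - d[j, k])
        lb = 0.5 * (d[i, j] + d[j, k] - d[i, k])
        lc = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        for idx, length in ((i, la), (j, lb), (k, lc)):
            nodes[idx].length = max(length, 0.0)
            root.add(nodes[idx])
        return Tree(root)
    # two taxa: single edge, split at the midpoint
    i, j = active
    root = Node("")
    nodes[i].length = nodes[j].length = d[i, j] / 2.0
    root.add(nodes[i])
    root.add(nodes[j])
    return Tree(root)


# ---------------------------------------------------------------------------
# Branch-length optimization and NNI search

_BL_BOUNDS = (1e-9, 20.0)


def _optimize_branch(tree: Tree, node: Node, msa: Msa, model: SubstitutionModel,
                     tol: float = 1e-6) -> float:
    def nll(t: float) -> float:
        node.length = t
        return -log_likelihood(msa, tree, model)

    res = minimize_scalar(nll, bounds=_BL_BOUNDS, method="bounded",
                          options={"xatol": tol})
    node.length = float(res.x)
    return -float(res.fun)


def optimize_branch_lengths(tree: Tree, msa: Msa, model: SubstitutionModel,
                            rounds: int = 2, tol: float = 1e-6) -> float:
    """Round-robin 1-D optimization of every branch; returns final lnL."""
    lnl = log_likelihood(msa, tree, model)
    for _ in range(rounds):
        for node in tree.postorder():
            if node is tree.root:
                continue
            lnl = _optimize_branch(tree, node, msa, model, tol)
    return lnl


def _internal_edges(tree: Tree) -> list[Node]:
    """Internal nodes whose parent edge is an internal edge of the unrooted tree."""
    return [n for n in tree.postorder()
            if not n.is_leaf and n is not tree.root and n.parent is not None]


def _nni_candidates(tree: Tree):
    """Yield (candidate_tree, central_node) for both swaps at each internal edge.

    Trees are deep copies; the central node is the copy's counterpart of the
    edge's child node.
    """
    base_edges = _internal_edges(tree)
    for edge_idx in range(len(base_edges)):
        for variant in range(2):
            cand = tree.copy()
            edges = _internal_edges(cand)
            c = edges[edge_idx]
            p = c.parent
            # subtrees on the far side of the edge: p's other children,
            # plus (if p is not the root) the parent-side subtree which we
            # cannot detach — swapping with both of p's other neighbours is
            # covered because the two distinct NNI topologies arise from
            # swapping one fixed child of c with either far-side subtree.
            far = [x for x in p.children if x is not c]
            if not far:
                continue
            a = c.children[0]
            if len(far) >= 2:
                b = far[variant % len(far)]
            else:
                # p binary and not root: second alternative swaps c's other child
                a = c.children[variant % len(c.children)]
                b = far[0]
            # swap subtrees a (under c) and b (under p)
            c.children[c.children.index(a)] = b
            p.children[p.children.index(b)] = a
            a.parent, b.parent = p, c
            yield cand, c


def nni_search(msa: Msa, tree: Tree, model: SubstitutionModel,
               tol: float = 1e-6, max_passes: int = 20) -> Tree:
    """Nearest-neighbor-interchange hill climbing.

    Repeats full NNI passes, accepting strict likelihood improvements, until
    a pass yields none.  For each candidate only the central edge length is
    re-optimized when scoring; after an accepted move the edges around the
    central edge are re-optimized as well.
    """
    tree = tree.copy()
    current = optimize_branch_lengths(tree, msa, model, rounds=1, tol=tol)
    for _ in range(max_passes):
        improved = False
        for cand, central in _nni_candidates(tree):
            lnl = _optimize_branch(cand, central, msa, model, tol)
            if lnl > current + 1e-9:
                # refine the neighborhood of the accepted swap
                for node in [central] + central.children + [
                        x for x in central.parent.children if x is not central]:
                    lnl = _optimize_branch(cand, node, msa, model, tol)
                tree, current = cand, lnl
                improved = True
                break
        if not improved:
            break
    return tree


# ---------------------------------------------------------------------------
# BIC model selection


@dataclass
class ModelFit:
    model: SubstitutionModel
    log_l: float
    k: int
    bic: float


def _fit_model(msa: Msa, tree: Tree, model: SubstitutionModel,
               rounds: int = 2) -> tuple[SubstitutionModel, Tree, float]:
    """Optimize branch lengths plus alpha (+G) and p_inv (+I) by coordinate descent."""
    tree = tree.copy()
    fit = model
    lnl = optimize_branch_lengths(tree, msa, fit, rounds=1)
    for _ in range(rounds):
        if model.alpha is not None:
            def nll_a(a: float) -> float:
                return -log_likelihood(msa, tree, fit.with_params(alpha=a))
            res = minimize_scalar(nll_a, bounds=(0.05, 50.0), method="bounded",
                                  options={"xatol": 1e-3})
            fit = fit.with_params(alpha=float(res.x))
        if model.p_inv > 0:
            def nll_i(p: float) -> float:
                return -log_likelihood(msa, tree, fit.with_params(p_inv=p))
            res = minimize_scalar(nll_i, bounds=(1e-6, 0.9), method="bounded",
                                  options={"xatol": 1e-3})
            fit = fit.with_params(p_inv=float(res.x))
        lnl = optimize_branch_lengths(tree, msa, fit, rounds=1)
    return fit, tree, lnl


def bic_select(msa: Msa, tree: Tree,
               candidates: list[SubstitutionModel]) -> tuple[SubstitutionModel, pd.DataFrame]:
    """Fit each candidate on the fixed topology and rank by BIC.

    BIC = k ln(n_sites) - 2 lnL with k = branch count plus one per fitted
    rate parameter (alpha, p_inv).  A candidate declares +G via a non-None
    alpha and +I via p_inv > 0 (both are then optimized).  Lowest BIC wins.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    n_branches = sum(1 for n in tree.postorder() if n is not tree.root)
    rows = []
    fits: list[ModelFit] = []
    for cand in candidates:
        fit, _, lnl = _fit_model(msa, tree, cand)
        k = n_branches + (1 if cand.alpha is not None else 0) + (1 if cand.p_inv > 0 else 0)
        bic = k * np.log(msa.n_sites) - 2.0 * lnl
        fits.append(ModelFit(fit, lnl, k, bic))
        rows.append({"model": fit.describe(), "lnL": lnl, "k": k, "BIC": bic})
    table = pd.DataFrame(rows).sort_values("BIC", ignore_index=True)
    best = min(fits, key=lambda f: f.bic)
    return best.model, table


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_support(msa: Msa, model: SubstitutionModel, n_reps: int = 1000,
                      seed: int = 0, use_nni: bool = False) -> Tree:
    """Point-estimate tree with column-resampling bootstrap supports.

    The point tree is NJ on ML distances (optionally NNI-refined); each
    replicate resamples alignment columns with replacement and rebuilds by NJ
    (plus NNI when ``use_nni``).  A bipartition's support is the percentage
    of replicates containing it.  Fully seeded and reproducible.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    enc = msa.encoded()
    n = msa.n_taxa

    def tree_from_columns(idx: np.ndarray | None) -> Tree:
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if idx is None:
                    counts = pair_count_matrix(enc[i], enc[j])
                else:
                    counts = pair_count_matrix(enc[i][idx], enc[j][idx])
                dij = ml_distance_from_counts(counts, model)
                if dij is None:
                    dij = poisson_distance_from_p(0.95)  # saturate absent overlap
                d[i, j] = d[j, i] = dij
        return nj_tree(d, msa.labels)

    point = tree_from_columns(None)
    if use_nni:
        point = nni_search(msa, point, model)
    target = point.bipartitions()
    tally = {bp: 0 for bp in target}
    for _ in range(n_reps):
        idx = rng.integers(0, msa.n_sites, size=msa.n_sites)
        rep = tree_from_columns(idx)
        if use_nni:
            rep = nni_search(msa.take_columns(idx), rep, model)
        for bp in rep.bipartitions() & tally.keys():
            tally[bp] += 1
    leafsets = point.clade_leafsets()
    all_leaves = frozenset(msa.labels)
    anchor = min(all_leaves)
    for node in point.postorder():
        if node.is_leaf or node is point.root:
            continue
        s = leafsets[id(node)]
        side = s if anchor not in s else all_leaves - s
        if side in tally:
            node.support = 100.0 * tally[side] / n_reps
    return point
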