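"""Felsenstein pruning log-likelihood for protein alignments.

Gaps and unrecognized residues are treated as missing data (all-ones partial
vectors).  Site patterns are compressed before the pruning pass; the per-site
likelihood is a mixture over the model's discrete-gamma categories plus, with
+I, the zero-rate invariant class.  For time-reversible models the result is
invariant under the choice of root (pulley principle).
"""

from __future__ import annotations

import numpy as np

from .models import N_STATES, SubstitutionModel
from .msa import Msa
from .trees import Tree


def _compress(encoded: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    patterns, counts = np.unique(encoded, axis=1, return_counts=True)
    return patterns, counts


def _invariant_site_likelihood(patterns: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Likelihood of each pattern under the zero-rate (invariant) class."""
    n_pat = patterns.shape[1]
    out = np.zeros(n_pat)
    for p in range(n_pat):
        col = patterns[:, p]
        observed = col[col >= 0]
        if observed.size == 0:
            out[p] = 1.0
        elif np.all(observed == observed[0]):
            out[p] = pi[observed[0]]
    return out


def log_likelihood(msa: Msa, tree: Tree, model: SubstitutionModel) -> float:
    """Pruning log-likelihood of an alignment on a tree.

    Raises ValueError when tree leaves and alignment labels differ or a
    branch length is not finite.
    """
    labels = set(msa.labels)
    leaf_names = tree.leaf_names()
    if set(leaf_names) != labels or len(leaf_names) != len(labels):
        raise ValueError("tree leaves do not match alignment labels")
    encoded = msa.encoded()
    patterns, counts = _compress(encoded)
    row_of = {label: i for i, label in enumerate(msa.labels)}
    pi = model.frequencies
    rates, weights = model.rate_classes()
    n_pat = patterns.shape[1]

    site_lik = np.zeros(n_pat)
    eye = np.eye(N_STATES)
    for rate, weight in zip(rates, weights):
        partials: dict[int, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_leaf:
                codes = patterns[row_of[node.name]]
                part = np.ones((n_pat, N_STATES))
                obs = codes >= 0
                part[obs] = eye[codes[obs]]
            else:
                part = np.ones((n_pat, N_STATES))
                for child in node.children:
                    if not np.isfinite(child.length):
                        raise ValueError(f"non-finite branch length on {child.name!r}")
                    p = model.transition_matrix(child.length * rate)
                    part *= partials.pop(id(child)) @ p.T
            partials[id(node)] = part
        root_part = partials[id(tree.root)]
        site_lik += weight * (root_part @ pi)
    if model.p_inv > 0:
        site_lik += model.p_inv * _invariant_site_likelihood(patterns, pi)
    with np.errstate(divide="ignore"):
        logs = np.log(site_lik)
    if np.any(np.isneginf(logs)):
        return float("-inf")
    return float(np.dot(counts, logs))
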