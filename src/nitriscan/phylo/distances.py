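"""Pairwise maximum-likelihood distances between aligned proteins."""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .models import N_STATES, SubstitutionModel
from .msa import Msa

_MAX_DISTANCE = 50.0


def pair_count_matrix(a_codes: np.ndarray, b_codes: np.ndarray) -> np.ndarray:
    """20x20 residue-pair counts over columns where both states are observed."""
    valid = (a_codes >= 0) & (b_codes >= 0)
    idx = a_codes[valid].astype(np.int64) * N_STATES + b_codes[valid]
    return np.bincount(idx, minlength=N_STATES * N_STATES).reshape(N_STATES, N_STATES).astype(float)


def _mixture_p(t: float, model: SubstitutionModel) -> tuple[np.ndarray, np.ndarray]:
    """(P_mix(t), dP_mix/dt) over the model's rate classes (+I included)."""
    lam, right, left = model._eigen()
    rates, weights = model.rate_classes()
    p_mix = np.zeros((N_STATES, N_STATES))
    dp_mix = np.zeros((N_STATES, N_STATES))
    for rate, weight in zip(rates, weights):
        e = np.exp(lam * t * rate)
        p_mix += weight * ((right * e[None, :]) @ left)
        dp_mix += weight * rate * ((right * (lam * e)[None, :]) @ left)
    if model.p_inv > 0:
        p_mix += model.p_inv * np.eye(N_STATES)
    return p_mix, dp_mix


def _neg_log_likelihood(t: float, counts: np.ndarray, model: SubstitutionModel) -> float:
    p_mix, _ = _mixture_p(t, model)
    joint = model.frequencies[:, None] * p_mix
    mask = counts > 0
    if np.any(joint[mask] <= 0):
        return float("inf")
    return -float(np.sum(counts[mask] * np.log(joint[mask])))


def _dneg_log_likelihood(t: float, counts: np.ndarray, model: SubstitutionModel) -> float:
    p_mix, dp_mix = _mixture_p(t, model)
    mask = counts > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mask, dp_mix / np.where(p_mix > 0, p_mix, 1.0), 0.0)
    return -float(np.sum(counts * ratio))


def poisson_distance_from_p(p_mismatch: float) -> float:
    """Closed-form ML distance under the Poisson (uniform-frequency) model.

    d = -(19/20) ln(1 - 20 p / 19); saturated pairs are capped at a large
    finite distance.
    """
    arg = 1.0 - p_mismatch * N_STATES / (N_STATES - 1)
    if arg <= 0:
        return _MAX_DISTANCE
    return min(-(N_STATES - 1) / N_STATES * math.log(arg), _MAX_DISTANCE)


def _is_plain_poisson(model: SubstitutionModel) -> bool:
    return (model.matrix == "Poisson" and model.alpha is None
            and model.p_inv == 0.0 and model.freqs is None)


def ml_distance(a: str, b: str, model: SubstitutionModel) -> float | None:
    """Distance (substitutions/site) maximizing the two-sequence likelihood.

    Returns None when the pair shares no ungapped columns.  For the plain
    Poisson model the closed form is used; otherwise a bounded 1-D
    optimization of the mixture likelihood.
    """
    msa = Msa(["a", "b"], [a, b])
    enc = msa.encoded()
    counts = pair_count_matrix(enc[0], enc[1])
    return ml_distance_from_counts(counts, model)


def ml_distance_from_counts(counts: np.ndarray, model: SubstitutionModel) -> float | None:
    total = counts.sum()
    if total == 0:
        return None
    mismatch = total - np.trace(counts)
    if mismatch == 0:
        return 0.0
    if _is_plain_poisson(model):
        return poisson_distance_from_p(mismatch / total)
    # the negative log-likelihood is unimodal in t: root-find its gradient
    # for machine-precision optima, falling back to bounded search if the
    # gradient does not change sign on the interval
    lo, hi = 1e-9, _MAX_DISTANCE
    g_lo = _dneg_log_likelihood(lo, counts, model)
    g_hi = _dneg_log_likelihood(hi, counts, model)
    if g_lo >= 0:
        return lo
    if g_hi <= 0:
        return hi
    if np.isfinite(g_lo) and np.isfinite(g_hi):
        return float(brentq(_dneg_log_likelihood, lo, hi, args=(counts, model),
                            xtol=1e-12))
    res = minimize_scalar(_neg_log_likelihood, bounds=(lo, hi),
                          args=(counts, model), method="bounded",
                          options={"xatol": 1e-12, "maxiter": 2000})
    return float(res.x)


def distance_matrix(msa: Msa, model: SubstitutionModel) -> np.ndarray:
    """Symmetric pairwise ML distance matrix; raises if a pair is undefined."""
    enc = msa.encoded()
    n = msa.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            counts = pair_count_matrix(enc[i], enc[j])
            dij = ml_distance_from_counts(counts, model)
            if dij is None:
                raise ValueError(
                    f"no shared ungapped columns between {msa.labels[i]} and {msa.labels[j]}")
            d[i, j] = d[j, i] = dij
    return d
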