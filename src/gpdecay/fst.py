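"""Beta-Binomial maximum-likelihood estimation of F_ST.

The training subsample is treated as the ancestral population: its observed
allele frequencies pi_k are plugged into a Balding-Nichols model in which
the target population's allele frequency at marker k is

    p_k ~ Beta(alpha_k, beta_k),
    alpha_k = pi_k (1 - F) / F,     beta_k = (1 - pi_k)(1 - F) / F,

so that E[p_k] = pi_k and Var[p_k] = F pi_k (1 - pi_k).  Integrating p_k
out, the target allele count c_k out of n_k sampled chromosomes is
Beta-Binomial, and the log-likelihood (up to the binomial coefficient,
which does not depend on F) is

    l(F) = sum_k [ ln B(c_k + alpha_k, n_k - c_k + beta_k) - ln B(alpha_k, beta_k) ].

F_ST is estimated by maximizing l over a bounded interval with Brent's
method.  Markers monomorphic in the training subsample are excluded (their
alpha or beta would be zero).  Marker independence is assumed; linked
markers make the likelihood a composite likelihood, which leaves the point
estimate consistent but is not corrected for here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import betaln

from .exceptions import ValidationError
from .genotype_io import GenotypeMatrix

DEFAULT_BOUNDS = (1e-6, 0.99)


@dataclass
class FstEstimate:
    value: float
    loglik: float
    n_markers_used: int
    converged: bool

    def __post_init__(self):
        if self.n_markers_used < 1:
            raise ValidationError("F_ST estimate must use at least one marker")


def allele_frequencies(g: GenotypeMatrix, idx) -> np.ndarray:
    """Per-marker allele frequency in the subsample ``idx`` (complete data)."""
    idx = np.asarray(idx, dtype=int)
    if idx.size == 0:
        raise ValidationError("index set must be non-empty")
    sub = g.counts[idx]
    if np.isnan(sub).any():
        raise ValidationError("allele_frequencies requires complete data")
    return sub.sum(axis=0) / (2.0 * idx.size)


def beta_binomial_loglik(
    f: float,
    anc_freq: np.ndarray,
    target_counts: np.ndarray,
    n_chrom: np.ndarray,
) -> float:
    """Beta-Binomial log-likelihood of target allele counts at divergence f.

    The binomial coefficient ln C(n_k, c_k) is omitted: it is constant in f
    and cancels in the maximization.
    """
    if not (0.0 < f < 1.0):
        raise ValidationError("f must lie strictly in (0, 1)")
    pi = np.asarray(anc_freq, dtype=float)
    c = np.asarray(target_counts, dtype=float)
    n = np.broadcast_to(np.asarray(n_chrom, dtype=float), pi.shape)
    if ((pi <= 0.0) | (pi >= 1.0)).any():
        raise ValidationError("ancestral frequencies must be strictly in (0, 1)")
    if ((c < 0) | (c > n)).any():
        raise ValidationError("target counts must satisfy 0 <= c <= n_chrom")
    lam = (1.0 - f) / f
    alpha = pi * lam
    beta = (1.0 - pi) * lam
    return float(np.sum(betaln(c + alpha, n - c + beta) - betaln(alpha, beta)))


def fst_mle(
    anc_freq: np.ndarray,
    target_counts: np.ndarray,
    n_chrom,
    bounds=DEFAULT_BOUNDS,
    xatol: float = 1e-6,
) -> FstEstimate:
    """Maximize the Beta-Binomial likelihood over ``bounds`` (Brent, bounded).

    Markers with ancestral frequency outside (0, 1) are excluded; at least 10
    usable markers are required for a stable estimate.
    """
    pi = np.asarray(anc_freq, dtype=float)
    c = np.asarray(target_counts, dtype=float)
    n = np.broadcast_to(np.asarray(n_chrom, dtype=float), pi.shape)
    usable = (pi > 0.0) & (pi < 1.0)
    if usable.sum() < 10:
        raise ValidationError(
            f"only {int(usable.sum())} polymorphic-in-training markers; "
            "need >= 10 for a stable F_ST estimate"
        )
    pi, c, n = pi[usable], c[usable], n[usable]
    res = minimize_scalar(
        lambda f: -beta_binomial_loglik(f, pi, c, n),
        bounds=bounds,
        method="bounded",
        options={"xatol": xatol},
    )
    return FstEstimate(
        value=float(res.x),
        loglik=float(-res.fun),
        n_markers_used=int(pi.size),
        converged=bool(res.success),
    )


def fst_beta_binomial(
    g: GenotypeMatrix,
    train_idx,
    target_idx,
    bounds=DEFAULT_BOUNDS,
) -> FstEstimate:
    """F_ST between a training (ancestral) and a target subsample.

    Ancestral allele frequencies come from ``train_idx``; the likelihood is
    over the pooled allele counts of ``target_idx`` (2 chromosomes per
    individual per marker).
    """
    train_idx = np.asarray(train_idx, dtype=int)
    target_idx = np.asarray(target_idx, dtype=int)
    if train_idx.size == 0 or target_idx.size == 0:
        raise ValidationError("index sets must be non-empty")
    if np.intersect1d(train_idx, target_idx).size:
        raise ValidationError("training and target index sets overlap")
    pi = allele_frequencies(g, train_idx)
    target = g.counts[target_idx]
    if np.isnan(target).any():
        raise ValidationError("fst_beta_binomial requires complete data")
    c = target.sum(axis=0)
    n = np.full(pi.shape, 2.0 * target_idx.size)
    return fst_mle(pi, c, n, bounds=bounds)
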