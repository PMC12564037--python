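"""Admixture-model inference: EM point estimation and a Gibbs sampler.

The model: individual i draws each of its two allele copies at locus l
from cluster k with probability q_ik, and the copy is the counted allele
with probability p_kl, so the dosage likelihood is

    l(Q, P) = sum_il [ g_il log(sum_k q_ik p_kl)
                       + (2 - g_il) log(sum_k q_ik (1 - p_kl)) ].

``em_fit`` runs the standard multiplicative EM updates (monotone in the
log-likelihood); ``gibbs_fit`` is a data-augmentation sampler that draws
latent copy origins Z, then P | Z from conjugate Betas and Q | Z from a
Dirichlet with concentration ``alpha`` (fixed, default 1.0), reporting
posterior means over the post-burn-in chain.  Cluster labels are arbitrary
in both; :func:`match_clusters` aligns an estimate to a reference by greedy
correlation matching before any comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cohort import MISSING, DosageMatrix

log = logging.getLogger(__name__)

_EPS = 1e-300


class AdmixtureError(ValueError):
    pass


@dataclass
class AdmixtureResult:
    Q: np.ndarray  # (n, K) ancestry proportions
    P: np.ndarray  # (K, L) cluster allele frequencies
    loglik_trace: np.ndarray
    method: str  # "em" | "gibbs"
    seed: int
    iterations: int
    burn_in: int = 0
    divergence: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.abs(self.Q.sum(axis=1) - 1.0).max() > 1e-6:
            raise AdmixtureError("rows of Q must sum to 1")
        if ((self.P < 0) | (self.P > 1)).any():
            raise AdmixtureError("P entries must lie in [0, 1]")


def _as_masked(G) -> tuple[np.ndarray, np.ndarray]:
    vals = G.values if isinstance(G, DosageMatrix) else np.asarray(G)
    mask = vals != MISSING
    g = np.where(mask, vals, 0).astype(float)
    return g, mask


def admixture_loglik(G, Q: np.ndarray, P: np.ndarray) -> float:
    """Binomial mixture log-likelihood; MISSING entries are skipped.

    A mixture probability of exactly zero against a nonzero count yields
    -inf (logged), not an exception.
    """
    g, mask = _as_masked(G)
    Q = np.asarray(Q, float)
    P = np.asarray(P, float)
    if Q.shape[1] != P.shape[0] or g.shape != (Q.shape[0], P.shape[1]):
        raise AdmixtureError("inconsistent shapes for G, Q, P")
    mu = Q @ P
    nu = Q @ (1.0 - P)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = g * np.log(mu) + (2.0 - g) * np.log(nu)
        term = np.where(mask, term, 0.0)
        # 0 * log 0 is a structural zero, not -inf
        term = np.where(mask & (g == 0) & (mu == 0), (2.0) * np.log(nu), term)
        term = np.where(mask & (g == 2) & (nu == 0), g * np.log(mu), term)
    ll = term.sum()
    if not np.isfinite(ll):
        log.warning("log-likelihood is -inf: a mixture probability hit zero")
        return float("-inf")
    return float(ll)


def _init_qp(
    n: int, L: int, K: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    Q = rng.dirichlet(np.ones(K), size=n)
    P = rng.uniform(0.05, 0.95, size=(K, L))
    return Q, P


def em_fit(
    G,
    K: int,
    seed: int,
    tol: float = 1e-6,
    max_iter: int = 2000,
    n_init: int = 1,
    supervised_labels=None,
) -> AdmixtureResult:
    """Maximum-likelihood Q, P by EM.

    ``supervised_labels`` (optional, length n, entries in 0..K-1 or -1 for
    unlabeled) pins the labeled rows of Q to one-hot vectors, anchoring
    cluster identities to known reference panels.
    """
    g, mask = _as_masked(G)
    n, L = g.shape
    if K < 1 or n < K:
        raise AdmixtureError("need K >= 1 and at least K samples")
    sup = None
    if supervised_labels is not None:
        sup = np.asarray(supervised_labels, int)
        if sup.shape != (n,):
            raise AdmixtureError("supervised label vector length mismatch")
    rng = np.random.default_rng(seed)
    best: AdmixtureResult | None = None
    for _ in range(max(1, n_init)):
        Q, P = _init_qp(n, L, K, rng)
        if sup is not None:
            labeled = sup >= 0
            Q[labeled] = np.eye(K)[sup[labeled]]
        trace = []
        for _it in range(max_iter):
            # E-step responsibilities for variant (a) and reference (b) copies
            wa = Q[:, :, None] * P[None, :, :]  # (n, K, L)
            wb = Q[:, :, None] * (1.0 - P[None, :, :])
            sa = wa.sum(axis=1, keepdims=True)
            sb = wb.sum(axis=1, keepdims=True)
            a = wa / np.maximum(sa, _EPS)
            b = wb / np.maximum(sb, _EPS)
            gm = (g * mask)[:, None, :]
            hm = ((2.0 - g) * mask)[:, None, :]
            va = gm * a  # expected variant copies from cluster k
            vb = hm * b  # expected reference copies from cluster k
            # M-step
            copies = 2.0 * mask.sum(axis=1)  # per-individual called copies
            Qn = (va.sum(axis=2) + vb.sum(axis=2)) / np.maximum(
                copies[:, None], _EPS
            )
            num_p = va.sum(axis=0)  # (K, L)
            den_p = num_p + vb.sum(axis=0)
            empty = den_p.sum(axis=1) < 1e-9
            Pn = num_p / np.maximum(den_p, _EPS)
            if empty.any():
                for k in np.flatnonzero(empty):
                    i = rng.integers(n)
                    Pn[k] = np.clip(g[i] / 2.0, 0.05, 0.95)
                    log.warning("cluster %d empty; reseeded from sample %d", k, i)
            Q, P = Qn, np.clip(Pn, 1e-9, 1.0 - 1e-9)
            if sup is not None:
                Q[labeled] = np.eye(K)[sup[labeled]]
            Q = Q / Q.sum(axis=1, keepdims=True)
            trace.append(admixture_loglik(np.where(mask, g, MISSING), Q, P))
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
                break
        cand = AdmixtureResult(
            Q=Q,
            P=P,
            loglik_trace=np.asarray(trace),
            method="em",
            seed=seed,
            iterations=len(trace),
            divergence=cluster_divergence(P),
        )
        if best is None or cand.loglik_trace[-1] > best.loglik_trace[-1]:
            best = cand
    assert best is not None
    return best


def gibbs_fit(
    G,
    K: int,
    burn_in: int = 10_000,
    iterations: int = 50_000,
    seed: int = 0,
    alpha: float = 1.0,
    thin: int = 1,
) -> AdmixtureResult:
    """Posterior-mean Q, P from a collapsed-origins Gibbs sampler.

    ``iterations`` counts total sweeps; samples after ``burn_in`` (every
    ``thin``-th) contribute to the posterior means and the stored
    log-likelihood trace.
    """
    if burn_in >= iterations:
        raise AdmixtureError("burn_in must be smaller than iterations")
    g, mask = _as_masked(G)
    n, L = g.shape
    if K < 1 or n < K:
        raise AdmixtureError("need K >= 1 and at least K samples")
    rng = np.random.default_rng(seed)
    Q, P = _init_qp(n, L, K, rng)
    g_int = g.astype(np.int64)
    h_int = np.where(mask, 2 - g_int, 0)
    g_int = np.where(mask, g_int, 0)
    q_sum = np.zeros_like(Q)
    p_sum = np.zeros_like(P)
    trace = []
    kept = 0
    for it in range(iterations):
        wa = Q[:, :, None] * P[None, :, :]
        wb = Q[:, :, None] * (1.0 - P[None, :, :])
        pa = wa / np.maximum(wa.sum(axis=1, keepdims=True), _EPS)
        pb = wb / np.maximum(wb.sum(axis=1, keepdims=True), _EPS)
        # latent origins of variant / reference copies, multinomial per (i, l)
        za = rng.multinomial(g_int, pa.swapaxes(1, 2))  # (n, L, K)
        zb = rng.multinomial(h_int, pb.swapaxes(1, 2))
        var_k = za.sum(axis=0).T  # (K, L) variant copies per cluster/locus
        ref_k = zb.sum(axis=0).T
        P = rng.beta(1.0 + var_k, 1.0 + ref_k)
        counts_ik = za.sum(axis=1) + zb.sum(axis=1)  # (n, K)
        Q = rng.gamma(alpha + counts_ik)
        Q = Q / Q.sum(axis=1, keepdims=True)
        if it >= burn_in and (it - burn_in) % thin == 0:
            q_sum += Q
            p_sum += P
            kept += 1
            trace.append(admixture_loglik(np.where(mask, g, MISSING), Q, P))
    Qm = q_sum / kept
    Pm = p_sum / kept
    return AdmixtureResult(
        Q=Qm / Qm.sum(axis=1, keepdims=True),
        P=Pm,
        loglik_trace=np.asarray(trace),
        method="gibbs",
        seed=seed,
        iterations=iterations,
        burn_in=burn_in,
        divergence=cluster_divergence(Pm),
    )


def cluster_divergence(P: np.ndarray) -> np.ndarray:
    """Mean expected heterozygosity per cluster: (1/L) sum_l 2 p (1 - p)."""
    P = np.asarray(P, float)
    if P.ndim != 2:
        raise AdmixtureError("P must be K x L")
    return (2.0 * P * (1.0 - P)).mean(axis=1)


def match_clusters(Q_est: np.ndarray, Q_ref: np.ndarray) -> np.ndarray:
    """Greedy column permutation aligning Q_est to Q_ref by correlation.

    Returns ``perm`` such that ``Q_est[:, perm]`` corresponds column-wise
    to ``Q_ref``.
    """
    Q_est = np.asarray(Q_est, float)
    Q_ref = np.asarray(Q_ref, float)
    K = Q_ref.shape[1]
    corr = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            a, b = Q_ref[:, i], Q_est[:, j]
            sa, sb = a.std(), b.std()
            corr[i, j] = (
                0.0 if sa == 0 or sb == 0 else np.corrcoef(a, b)[0, 1]
            )
    perm = np.full(K, -1)
    used: set[int] = set()
    for i, j in sorted(
        ((i, j) for i in range(K) for j in range(K)),
        key=lambda ij: -corr[ij[0], ij[1]],
    ):
        if perm[i] == -1 and j not in used:
            perm[i] = j
            used.add(j)
    return perm
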