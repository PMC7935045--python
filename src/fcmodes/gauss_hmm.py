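"""Gaussian-observation hidden Markov model for concatenated BOLD features.

The model: a latent first-order Markov chain s_t over K states with
transition matrix Theta (rows Theta[l, :] = P(s_t = k | s_{t-1} = l)) and,
per state, a multivariate Gaussian emission N(mu_k, Sigma_k). Chains restart
at every subject-session boundary: no transition is counted across blocks,
and each block contributes an initial-state observation.

Two inference flavors are provided:

* ``method="vb"`` (default): variational Bayes with conjugate priors —
  Gaussian-Wishart on (mu_k, Lambda_k) and Dirichlet on the rows of Theta
  and on pi. The reported objective is the variational free energy (ELBO)
  computed as the sum over blocks of the log-normalizer of the forward pass
  under the expected-log parameters, minus the KL divergences of the
  parameter posteriors from their priors. This bound is nondecreasing
  across iterations.
* ``method="em"``: maximum-likelihood Baum-Welch; the objective is the exact
  log-likelihood, also nondecreasing. Used as an internal cross-check.

Message passing uses per-timestep rescaling with a per-row log shift of the
emission scores, which is numerically equivalent to log-domain propagation
and safe for emission likelihoods with dynamic range far beyond float
overflow.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import digamma, gammaln, multigammaln
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class HMMModel:
    """Point-estimate HMM parameters (posterior means under VB)."""

    means: np.ndarray        # (K, d)
    covars: np.ndarray       # (K, d, d)
    transmat: np.ndarray     # (K, K), rows sum to 1
    startprob: np.ndarray    # (K,)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.covars = np.asarray(self.covars, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.startprob = np.asarray(self.startprob, dtype=float)
        K = self.n_states
        if self.transmat.shape != (K, K):
            raise ValueError("transition matrix shape mismatch")
        if not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition matrix rows must sum to 1")
        if not np.isclose(self.startprob.sum(), 1.0, atol=1e-10):
            raise ValueError("initial distribution must sum to 1")
        for k in range(K):
            if not np.allclose(self.covars[k], self.covars[k].T, atol=1e-10):
                raise ValueError(f"covariance of state {k} not symmetric")
            np.linalg.cholesky(self.covars[k])  # raises if not SPD

    @property
    def n_states(self) -> int:
        return self.means.shape[0]

    @property
    def n_features(self) -> int:
        return self.means.shape[1]


@dataclass
class StateTimeCourse:
    """Posterior state probabilities P(s_t = k), rows indexed by ``blocks``."""

    probs: np.ndarray          # (T_total, K)
    blocks: pd.DataFrame       # columns: subject, session, start, stop

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("posterior rows must sum to 1")
        if self.probs.min() < -1e-12 or self.probs.max() > 1 + 1e-12:
            raise ValueError("posterior entries must lie in [0, 1]")

    @property
    def n_states(self) -> int:
        return self.probs.shape[1]


@dataclass
class FitResult:
    model: HMMModel
    state_time_course: StateTimeCourse
    objective_trace: np.ndarray
    converged: bool
    method: str
    seed: int
    restart_objectives: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# message passing
# ---------------------------------------------------------------------------

def _forward_backward(log_b: np.ndarray, A: np.ndarray, pi: np.ndarray):
    """Scaled forward-backward for one chain.

    Returns (gamma, xi_sum, loglik) where gamma[t, k] are smoothed
    marginals, xi_sum is the K x K matrix of summed pairwise marginals and
    loglik the log-normalizer of the chain under (pi, A, exp(log_b)).
    """
    T, K = log_b.shape
    shift = log_b.max(axis=1)
    b = np.exp(log_b - shift[:, None])

    alpha = np.empty((T, K))
    c = np.empty(T)
    a = pi * b[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * b[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]

    beta = np.empty((T, K))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (b[t + 1] * beta[t + 1])) / c[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)

    xi_sum = np.zeros((K, K))
    for t in range(T - 1):
        xi = alpha[t][:, None] * A * (b[t + 1] * beta[t + 1])[None, :] / c[t + 1]
        xi_sum += xi
    loglik = float(np.log(c).sum() + shift.sum())
    return gamma, xi_sum, loglik


def _block_ranges(blocks: pd.DataFrame) -> list[tuple[int, int]]:
    return [(int(r.start), int(r.stop)) for r in blocks.itertuples()]


def _gauss_logpdf(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = X.shape[1]
    L = np.linalg.cholesky(cov)
    sol = np.linalg.solve(L, (X - mean).T)
    maha = np.einsum("ij,ij->j", sol, sol)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return -0.5 * (d * _LOG2PI + logdet + maha)


# ---------------------------------------------------------------------------
# KL divergences for the VB objective
# ---------------------------------------------------------------------------

def _kl_dirichlet(a: np.ndarray, b: np.ndarray) -> float:
    a0, b0 = a.sum(), b.sum()
    return float(
        gammaln(a0) - gammaln(b0)
        - np.sum(gammaln(a) - gammaln(b))
        + np.sum((a - b) * (digamma(a) - digamma(a0)))
    )


def _log_wishart_B(W: np.ndarray, nu: float) -> float:
    d = W.shape[0]
    _, logdetW = np.linalg.slogdet(W)
    return float(-(nu / 2.0) * logdetW - (nu * d / 2.0) * np.log(2.0) - multigammaln(nu / 2.0, d))


def _e_logdet_lambda(W: np.ndarray, nu: float) -> float:
    d = W.shape[0]
    _, logdetW = np.linalg.slogdet(W)
    return float(np.sum(digamma((nu - np.arange(d)) / 2.0)) + d * np.log(2.0) + logdetW)


def _kl_normal_wishart(m1, b1, W1, n1, m0, b0, W0, n0) -> float:
    """KL( NW(m1,b1,W1,n1) || NW(m0,b0,W0,n0) ), precision-Wishart form."""
    d = len(m1)
    elogdet = _e_logdet_lambda(W1, n1)
    # entropy of q(Lambda)
    h_wish = -_log_wishart_B(W1, n1) - (n1 - d - 1) / 2.0 * elogdet + n1 * d / 2.0
    e_log_q_mu = 0.5 * (d * np.log(b1 / (2 * np.pi)) + elogdet - d)
    e_log_q = e_log_q_mu - h_wish
    dm = np.asarray(m1) - np.asarray(m0)
    quad = float(n1 * dm @ W1 @ dm)
    e_log_p_mu = 0.5 * (
        d * np.log(b0 / (2 * np.pi)) + elogdet - b0 * (d / b1 + quad)
    )
    tr = float(np.trace(np.linalg.solve(W0, W1)))  # tr(W0^{-1} W1); E[Lambda] = n1 W1
    e_log_p_lam = _log_wishart_B(W0, n0) + (n0 - d - 1) / 2.0 * elogdet - 0.5 * n1 * tr
    return float(e_log_q - e_log_p_mu - e_log_p_lam)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_hmm(
    X: np.ndarray,
    blocks: pd.DataFrame,
    n_states: int = 12,
    *,
    method: str = "vb",
    max_iter: int = 500,
    tol: float = 1e-5,
    n_restarts: int = 5,
    seed: int = 0,
    prior_strength: float = 1.0,
) -> FitResult:
    """Fit a K-state Gaussian HMM to block-structured rows.

    ``blocks`` maps rows to subject-sessions (columns start/stop); chains
    restart at each block. The best of ``n_restarts`` k-means-initialized
    runs (by final objective) is returned.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n, d = X.shape
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if n <= n_states:
        raise ValueError("need more rows than states")
    if method not in ("vb", "em"):
        raise ValueError(f"unknown method {method!r}")
    ranges = _block_ranges(blocks)
    if not ranges or ranges[-1][1] != n or any(b - a < 2 for a, b in ranges):
        raise ValueError("block index does not tile the rows (or has a 1-frame block)")

    ss = np.random.SeedSequence([seed, n_states, 0x5CA1])
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(max(n_restarts, 1))]

    best = None
    restart_objs = []
    for rs in child_seeds:
        result = _fit_once(X, ranges, n_states, method, max_iter, tol, rs, prior_strength)
        restart_objs.append(result[2][-1])
        if best is None or result[2][-1] > best[2][-1]:
            best = result
    gamma, model, trace, converged = best[0], best[1], best[2], best[3]
    stc = StateTimeCourse(probs=gamma, blocks=blocks.reset_index(drop=True))
    return FitResult(
        model=model,
        state_time_course=stc,
        objective_trace=np.asarray(trace),
        converged=converged,
        method=method,
        seed=seed,
        restart_objectives=restart_objs,
    )


def _init_responsibilities(X: np.ndarray, K: int, seed: int) -> np.ndarray:
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    sub = rng.choice(n, size=min(n, 5000), replace=False)
    km = KMeans(n_clusters=K, n_init=1, random_state=seed).fit(X[sub])
    labels = km.predict(X)
    gamma = np.full((n, K), 1e-3)
    gamma[np.arange(n), labels] = 1.0
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma


def _fit_once(X, ranges, K, method, max_iter, tol, seed, prior_strength):
    n, d = X.shape
    if K == 1:
        gamma = np.ones((n, 1))
        mu = X.mean(axis=0)[None, :]
        cov = np.cov(X.T, ddof=0).reshape(d, d) + 1e-9 * np.eye(d)
        model = HMMModel(mu, cov[None], np.ones((1, 1)), np.ones(1))
        ll = float(_gauss_logpdf(X, mu[0], cov).sum())
        return gamma, model, [ll], True

    gamma = _init_responsibilities(X, K, seed)
    # fake pairwise stats from the hard init for the first M-step
    xi_sum = np.zeros((K, K))
    start_counts = np.zeros(K)
    for a, b in ranges:
        g = gamma[a:b]
        xi_sum += g[:-1].T @ g[1:]
        start_counts += g[0]

    if method == "vb":
        return _fit_vb(X, ranges, K, gamma, xi_sum, start_counts, max_iter, tol, prior_strength)
    return _fit_em(X, ranges, K, gamma, xi_sum, start_counts, max_iter, tol)


def _suff_stats(X, gamma):
    Nk = gamma.sum(axis=0) + 1e-300
    xbar = (gamma.T @ X) / Nk[:, None]
    K, d = xbar.shape
    S = np.empty((K, d, d))
    for k in range(K):
        dev = X - xbar[k]
        S[k] = (gamma[:, k][:, None] * dev).T @ dev / Nk[k]
    return Nk, xbar, S


def _fit_vb(X, ranges, K, gamma, xi_sum, start_counts, max_iter, tol, prior_strength):
    n, d = X.shape
    # priors
    m0 = X.mean(axis=0)
    beta0 = float(prior_strength)
    nu0 = d + float(prior_strength)
    data_var = X.var(axis=0) + 1e-12
    W0 = np.diag(1.0 / data_var) / nu0
    W0_inv = np.diag(data_var) * nu0
    alpha0 = float(prior_strength)

    trace = []
    converged = False
    # q parameters, updated from responsibilities each M-step
    for it in range(max_iter):
        # ---- M-step (VBM): parameter posteriors from current stats ----
        Nk, xbar, S = _suff_stats(X, gamma)
        beta_k = beta0 + Nk
        m_k = (beta0 * m0 + Nk[:, None] * xbar) / beta_k[:, None]
        nu_k = nu0 + Nk
        W_k = np.empty((K, d, d))
        for k in range(K):
            dm = xbar[k] - m0
            W_inv = W0_inv + Nk[k] * S[k] + (beta0 * Nk[k] / beta_k[k]) * np.outer(dm, dm)
            W_inv = 0.5 * (W_inv + W_inv.T)
            W_k[k] = np.linalg.inv(W_inv)
            W_k[k] = 0.5 * (W_k[k] + W_k[k].T)
        alpha_A = alpha0 + xi_sum
        alpha_pi = alpha0 + start_counts

        empty = np.flatnonzero(Nk < 1.0)
        if empty.size:
            logger.info("states %s have < 1 frame of occupancy", empty.tolist())

        # ---- E-step (VBE): expected-log parameters, messages, bound ----
        elog_A = digamma(alpha_A) - digamma(alpha_A.sum(axis=1, keepdims=True))
        elog_pi = digamma(alpha_pi) - digamma(alpha_pi.sum())
        A_t = np.exp(elog_A)
        pi_t = np.exp(elog_pi)

        log_b = np.empty((n, K))
        for k in range(K):
            elogdet = _e_logdet_lambda(W_k[k], nu_k[k])
            dev = X - m_k[k]
            maha = nu_k[k] * np.einsum("ij,jl,il->i", dev, W_k[k], dev)
            log_b[:, k] = 0.5 * (elogdet - d * _LOG2PI - d / beta_k[k] - maha)

        gamma = np.empty((n, K))
        xi_sum = np.zeros((K, K))
        start_counts = np.zeros(K)
        log_z = 0.0
        for a, b in ranges:
            g, xs, ll = _forward_backward(log_b[a:b], A_t, pi_t)
            gamma[a:b] = g
            xi_sum += xs
            start_counts += g[0]
            log_z += ll

        kl = _kl_dirichlet(alpha_pi, np.full(K, alpha0))
        for l in range(K):
            kl += _kl_dirichlet(alpha_A[l], np.full(K, alpha0))
        for k in range(K):
            kl += _kl_normal_wishart(m_k[k], beta_k[k], W_k[k], nu_k[k], m0, beta0, W0, nu0)
        elbo = log_z - kl
        trace.append(elbo)
        if it > 0 and abs(trace[-1] - trace[-2]) < tol * abs(trace[-2]):
            converged = True
            break
    if not converged:
        warnings.warn("VB HMM did not converge within max_iter", RuntimeWarning)

    # point estimates: posterior means
    covs = np.empty((K, d, d))
    for k in range(K):
        covs[k] = np.linalg.inv(nu_k[k] * W_k[k])
        covs[k] = 0.5 * (covs[k] + covs[k].T)
    transmat = alpha_A / alpha_A.sum(axis=1, keepdims=True)
    startprob = alpha_pi / alpha_pi.sum()
    model = HMMModel(m_k, covs, transmat, startprob)
    return gamma, model, trace, converged


def _fit_em(X, ranges, K, gamma, xi_sum, start_counts, max_iter, tol):
    n, d = X.shape
    trace = []
    converged = False
    model_params = None
    for it in range(max_iter):
        # M-step
        Nk, mu, S = _suff_stats(X, gamma)
        covs = np.empty((K, d, d))
        for k in range(K):
            cov = S[k]
            jitter = 1e-6 * np.trace(cov) / d + 1e-12
            covs[k] = 0.5 * (cov + cov.T) + jitter * np.eye(d)
        A = xi_sum + 1e-12
        A /= A.sum(axis=1, keepdims=True)
        pi = start_counts + 1e-12
        pi /= pi.sum()
        model_params = (mu, covs, A, pi)

        # E-step
        log_b = np.empty((n, K))
        for k in range(K):
            log_b[:, k] = _gauss_logpdf(X, mu[k], covs[k])
        gamma = np.empty((n, K))
        xi_sum = np.zeros((K, K))
        start_counts = np.zeros(K)
        ll = 0.0
        for a, b in ranges:
            g, xs, l = _forward_backward(log_b[a:b], A, pi)
            gamma[a:b] = g
            xi_sum += xs
            start_counts += g[0]
            ll += l
        trace.append(ll)
        if it > 0 and abs(trace[-1] - trace[-2]) < tol * abs(trace[-2]):
            converged = True
            break
    if not converged:
        warnings.warn("EM HMM did not converge within max_iter", RuntimeWarning)
    mu, covs, A, pi = model_params
    model = HMMModel(mu, covs, A, pi)
    return gamma, model, trace, converged


def posterior_decode(model: HMMModel, X: np.ndarray, blocks: pd.DataFrame) -> StateTimeCourse:
    """Forward-backward smoothed marginals per block under fixed parameters."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1] if X.ndim == 2 else '?'} does not match "
            f"model dimension {model.n_features}"
        )
    K = model.n_states
    log_b = np.empty((X.shape[0], K))
    for k in range(K):
        log_b[:, k] = _gauss_logpdf(X, model.means[k], model.covars[k])
    gamma = np.empty((X.shape[0], K))
    for a, b in _block_ranges(blocks):
        g, _, _ = _forward_backward(log_b[a:b], model.transmat, model.startprob)
        gamma[a:b] = g
    return StateTimeCourse(probs=gamma, blocks=blocks.reset_index(drop=True))


# ---------------------------------------------------------------------------
# evaluation helpers (label alignment against a generating model)
# ---------------------------------------------------------------------------

def align_states(true_path: np.ndarray, est_path: np.ndarray, n_states: int):
    """Best state permutation (est -> true) by maximum agreement.

    Returns (perm, accuracy) where perm[j] is the true label assigned to
    estimated label j and accuracy the fraction of frames agreeing after
    relabeling.
    """
    true_path = np.asarray(true_path)
    est_path = np.asarray(est_path)
    agree = np.zeros((n_states, n_states))
    for j in range(n_states):
        mask = est_path == j
        if mask.any():
            agree[j] = np.bincount(true_path[mask], minlength=n_states)
    row, col = linear_sum_assignment(-agree)
    perm = np.empty(n_states, dtype=int)
    perm[row] = col
    accuracy = float(agree[row, col].sum() / len(true_path))
    return perm, accuracy


def permute_columns(M: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Relabel state columns: column j of the estimate becomes column perm[j]."""
    out = np.empty_like(np.asarray(M, dtype=float))
    for j, pj in enumerate(perm):
        out[:, pj] = M[:, j]
    return out


def permute_transmat(transmat: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Relabel both axes of a transition matrix with ``perm`` (est -> true)."""
    K = len(perm)
    P = np.zeros((K, K))
    P[np.arange(K), perm] = 1.0
    return P.T @ np.asarray(transmat, dtype=float) @ P
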