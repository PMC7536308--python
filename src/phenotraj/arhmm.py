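"""Autoregressive (order-1) Gaussian hidden Markov model.

The hidden state z_t follows a Markov chain (initial distribution pi,
transition matrix A).  The first observation in a sequence is Gaussian
around a per-state mean, x_1 | z_1=k ~ N(mu_k, diag(var0_k)); subsequent
observations regress on their predecessor,

    x_t | z_t=k, x_{t-1} ~ N(c_k + Phi_k x_{t-1}, diag(var_k)),

with per-state intercept c_k, AR coefficient matrix Phi_k and diagonal
noise.  Inference on a chain uses the scaled forward-backward recursion
(exact), parameters are fitted by EM with closed-form M-steps
(responsibility-weighted least squares for the AR coefficients), and the
most probable state path is recovered by Viterbi decoding.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

logger = logging.getLogger("phenotraj")

_VAR_FLOOR = 1e-8


@dataclass
class ARHMMParams:
    """Parameters of a K-state, d-dimensional AR(1) Gaussian HMM."""

    pi: np.ndarray          # (K,)
    A: np.ndarray           # (K, K) row-stochastic
    mu: np.ndarray          # (K, d) first-step emission means
    var0: np.ndarray        # (K, d) first-step emission variances
    c: np.ndarray           # (K, d) AR intercepts
    Phi: np.ndarray         # (K, d, d) AR coefficient matrices
    var: np.ndarray         # (K, d) AR noise variances

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        self.var0 = np.atleast_2d(np.asarray(self.var0, dtype=float))
        self.c = np.atleast_2d(np.asarray(self.c, dtype=float))
        self.Phi = np.asarray(self.Phi, dtype=float)
        if self.Phi.ndim == 2:
            self.Phi = self.Phi[:, None, None] if self.Phi.shape[1] == 1 else self.Phi
        self.var = np.atleast_2d(np.asarray(self.var, dtype=float))
        self.validate()

    @property
    def K(self) -> int:
        return len(self.pi)

    @property
    def dim(self) -> int:
        return self.mu.shape[1]

    def validate(self) -> None:
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError(f"pi must sum to 1 (got {self.pi.sum()})")
        if np.any(self.pi < -1e-12):
            raise ValueError("pi must be non-negative")
        rows = self.A.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-9):
            raise ValueError(f"every row of A must sum to 1 (row sums {rows})")
        if np.any(self.A < -1e-12):
            raise ValueError("A must be non-negative")
        if np.any(self.var0 <= 0) or np.any(self.var <= 0):
            raise ValueError("variances must be strictly positive")
        K, d = self.mu.shape
        if self.A.shape != (K, K) or self.Phi.shape != (K, d, d):
            raise ValueError("parameter shapes disagree")

    def to_json(self) -> str:
        return json.dumps(
            {
                "pi": self.pi.tolist(), "A": self.A.tolist(), "mu": self.mu.tolist(),
                "var0": self.var0.tolist(), "c": self.c.tolist(),
                "Phi": self.Phi.tolist(), "var": self.var.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ARHMMParams":
        d = json.loads(text)
        return cls(
            pi=np.array(d["pi"]), A=np.array(d["A"]), mu=np.array(d["mu"]),
            var0=np.array(d["var0"]), c=np.array(d["c"]),
            Phi=np.array(d["Phi"]), var=np.array(d["var"]),
        )

    def permuted(self, order: np.ndarray) -> "ARHMMParams":
        """Relabel states by ``order`` (new state i = old state order[i])."""
        return ARHMMParams(
            pi=self.pi[order], A=self.A[np.ix_(order, order)], mu=self.mu[order],
            var0=self.var0[order], c=self.c[order], Phi=self.Phi[order], var=self.var[order],
        )


@dataclass
class StateSequenceData:
    """A collection of observation sequences, with true states when simulated."""

    sequences: list[np.ndarray]
    states: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.sequences = [np.atleast_2d(np.asarray(s, dtype=float)) for s in self.sequences]
        dims = {s.shape[1] for s in self.sequences}
        if len(dims) > 1:
            raise ValueError("sequences have inconsistent dimensionality")
        if any(len(s) < 1 for s in self.sequences):
            raise ValueError("sequences must be non-empty")
        if self.states is not None:
            self.states = [np.asarray(z, dtype=int) for z in self.states]

    @property
    def n_obs(self) -> int:
        return sum(len(s) for s in self.sequences)

    @property
    def dim(self) -> int:
        return self.sequences[0].shape[1]


def simulate(params: ARHMMParams, n_sequences: int, length: int, seed: int = 0) -> StateSequenceData:
    """Draw sequences forward from the model; true state paths are returned."""
    params.validate()
    rng = np.random.default_rng(seed)
    K, d = params.K, params.dim
    seqs, states = [], []
    for _ in range(n_sequences):
        z = np.empty(length, dtype=int)
        x = np.empty((length, d))
        z[0] = rng.choice(K, p=params.pi)
        x[0] = params.mu[z[0]] + rng.standard_normal(d) * np.sqrt(params.var0[z[0]])
        for t in range(1, length):
            z[t] = rng.choice(K, p=params.A[z[t - 1]])
            mean = params.c[z[t]] + params.Phi[z[t]] @ x[t - 1]
            x[t] = mean + rng.standard_normal(d) * np.sqrt(params.var[z[t]])
        seqs.append(x)
        states.append(z)
    return StateSequenceData(seqs, states)


def _log_emission(params: ARHMMParams, x: np.ndarray) -> np.ndarray:
    """log p(x_t | z_t = k, x_{t-1}) as a (T, K) matrix."""
    T, d = x.shape
    K = params.K
    logb = np.empty((T, K))
    # first step: static Gaussian
    diff0 = x[0] - params.mu                      # (K, d)
    logb[0] = -0.5 * (np.sum(diff0**2 / params.var0, axis=1)
                      + np.sum(np.log(2 * np.pi * params.var0), axis=1))
    if T > 1:
        # mean[t, k] = c_k + Phi_k x_{t-1}
        means = np.einsum("kij,tj->tki", params.Phi, x[:-1]) + params.c  # (T-1, K, d)
        diff = x[1:, None, :] - means
        logb[1:] = -0.5 * (np.sum(diff**2 / params.var, axis=2)
                           + np.sum(np.log(2 * np.pi * params.var), axis=1))
    return logb


def _forward_backward(params: ARHMMParams, x: np.ndarray):
    """Scaled forward-backward.  Returns (loglik, gamma (T,K), xi_sum (K,K))."""
    logb = _log_emission(params, x)
    T, K = logb.shape
    b = np.exp(logb - logb.max(axis=1, keepdims=True))
    alpha = np.empty((T, K))
    scale = np.empty(T)
    a = params.pi * b[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ params.A) * b[t]
        scale[t] = a.sum()
        alpha[t] = a / scale[t]
    loglik = float(np.sum(np.log(scale)) + np.sum(logb.max(axis=1)))
    beta = np.empty((T, K))
    beta[-1] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        beta[t] = (params.A @ (b[t + 1] * beta[t + 1])) / scale[t + 1]
        xi = params.A * np.outer(alpha[t], b[t + 1] * beta[t + 1]) / scale[t + 1]
        xi_sum += xi
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return loglik, gamma, xi_sum


def loglikelihood(params: ARHMMParams, data: StateSequenceData) -> float:
    """Exact log p(data | params), summed over independent sequences."""
    params.validate()
    total = 0.0
    for x in data.sequences:
        logb = _log_emission(params, x)
        T, K = logb.shape
        b = np.exp(logb - logb.max(axis=1, keepdims=True))
        a = params.pi * b[0]
        log_total = np.log(a.sum()) + logb[0].max()
        a = a / a.sum()
        for t in range(1, T):
            a = (a @ params.A) * b[t]
            log_total += np.log(a.sum()) + logb[t].max()
            a = a / a.sum()
        total += float(log_total)
    return total


def _kmeans_init(data: StateSequenceData, K: int, seed: int) -> ARHMMParams:
    X = np.vstack(data.sequences)
    d = X.shape[1]
    km = KMeans(n_clusters=min(K, len(np.unique(X, axis=0))), n_init=5, random_state=seed)
    km.fit(X)
    centers = km.cluster_centers_
    if centers.shape[0] < K:  # fewer distinct points than states
        extra = centers[np.zeros(K - centers.shape[0], dtype=int)] + 1e-3
        centers = np.vstack([centers, extra])
    var = np.maximum(X.var(axis=0), 1e-3)
    return ARHMMParams(
        pi=np.full(K, 1.0 / K),
        A=0.8 * np.eye(K) + 0.2 / K,
        mu=centers.copy(),
        var0=np.tile(var, (K, 1)),
        c=centers.copy(),
        Phi=np.zeros((K, d, d)),
        var=np.tile(var, (K, 1)),
    )


def _m_step(params: ARHMMParams, data: StateSequenceData, stats) -> ARHMMParams:
    gammas, xi_total = stats
    K, d = params.K, params.dim
    gamma1 = np.sum([g[0] for g in gammas], axis=0)
    pi = gamma1 / gamma1.sum()
    A = xi_total / np.maximum(xi_total.sum(axis=1, keepdims=True), 1e-300)
    # first-step emission
    x1 = np.stack([x[0] for x in data.sequences])            # (S, d)
    g1 = np.stack([g[0] for g in gammas])                    # (S, K)
    w1 = np.maximum(g1.sum(axis=0), 1e-12)
    mu = (g1.T @ x1) / w1[:, None]
    var0 = (g1.T @ (x1**2)) / w1[:, None] - mu**2
    var0 = np.maximum(var0, _VAR_FLOOR)
    # AR step: weighted least squares of x_t on (1, x_{t-1}) per state
    prev = np.vstack([x[:-1] for x in data.sequences if len(x) > 1])
    curr = np.vstack([x[1:] for x in data.sequences if len(x) > 1])
    gs = np.vstack([g[1:] for g, x in zip(gammas, data.sequences) if len(x) > 1])  # (N, K)
    Z = np.column_stack([np.ones(len(prev)), prev])          # (N, d+1)
    c = params.c.copy()
    Phi = params.Phi.copy()
    var = params.var.copy()
    for k in range(K):
        w = gs[:, k]
        sw = w.sum()
        if sw < 1e-10:
            continue
        Zw = Z * w[:, None]
        G = Z.T @ Zw + 1e-10 * np.eye(d + 1)
        beta = np.linalg.solve(G, Zw.T @ curr)               # (d+1, d)
        c[k] = beta[0]
        Phi[k] = beta[1:].T
        resid = curr - Z @ beta
        var[k] = np.maximum((w[:, None] * resid**2).sum(axis=0) / sw, _VAR_FLOOR)
    return ARHMMParams(pi=pi, A=A, mu=mu, var0=var0, c=c, Phi=Phi, var=var)


def em_fit(
    data: StateSequenceData,
    K: int,
    max_iter: int = 200,
    tol: float = 1e-6,
    n_restarts: int = 5,
    seed: int = 0,
) -> tuple[ARHMMParams, list[float]]:
    """Fit by EM; best of ``n_restarts`` k-means-seeded runs is returned.

    The E-step runs the exact scaled forward-backward recursion per
    sequence; the M-step is closed form (responsibility-weighted least
    squares for c_k and Phi_k, weighted moments for the rest).  The
    returned log-likelihood trace is non-decreasing; restarts that starve
    a state of responsibility mass are discarded with a warning.  States
    are relabelled by ascending first component of the first-step emission
    mean so that fits are comparable across runs.
    """
    if data.n_obs < K * (data.dim + 2):
        raise ValueError("too few observations for the requested state count")
    best: tuple[ARHMMParams, list[float]] | None = None
    for r in range(n_restarts):
        params = _kmeans_init(data, K, seed + 1000 * r)
        trace: list[float] = []
        starved = False
        for _ in range(max_iter):
            gammas = []
            xi_total = np.zeros((K, K))
            ll = 0.0
            for x in data.sequences:
                l, g, xs = _forward_backward(params, x)
                ll += l
                gammas.append(g)
                xi_total += xs
            trace.append(ll)
            mass = np.sum([g.sum(axis=0) for g in gammas], axis=0)
            if np.any(mass < 1e-6):
                logger.warning("em_fit: restart %d starved state(s) %s; discarded",
                               r, np.flatnonzero(mass < 1e-6).tolist())
                starved = True
                break
            params = _m_step(params, data, (gammas, xi_total))
            if len(trace) > 1 and trace[-1] - trace[-2] < tol:
                break
        if starved or not trace:
            continue
        if best is None or trace[-1] > best[1][-1]:
            best = (params, trace)
    if best is None:
        raise RuntimeError("every EM restart was discarded")
    params, trace = best
    order = np.argsort(params.mu[:, 0], kind="stable")
    return params.permuted(order), trace


def decode(params: ARHMMParams, sequence: np.ndarray) -> np.ndarray:
    """Viterbi most-probable state path; ties go to the lower state index."""
    params.validate()
    x = np.atleast_2d(np.asarray(sequence, dtype=float))
    logb = _log_emission(params, x)
    T, K = logb.shape
    with np.errstate(divide="ignore"):
        logpi = np.log(params.pi)
        logA = np.log(params.A)
    delta = logpi + logb[0]
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + logA
        back[t] = np.argmax(scores, axis=0)      # first max -> lower index
        delta = scores[back[t], np.arange(K)] + logb[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def expected_state_statistics(params: ARHMMParams, data: StateSequenceData) -> np.ndarray:
    """Responsibility-weighted mean of every observed feature per state.

    Returns a (K, d) matrix: row k is the expected feature vector of
    observations attributed to hidden state k.  Because responsibilities
    sum to one per observation, each row is a convex combination of the
    observed vectors.
    """
    params.validate()
    K, d = params.K, params.dim
    num = np.zeros((K, d))
    den = np.zeros(K)
    for x in data.sequences:
        _, gamma, _ = _forward_backward(params, x)
        num += gamma.T @ x
        den += gamma.sum(axis=0)
    return num / np.maximum(den, 1e-300)[:, None]
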