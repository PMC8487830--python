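"""Low-coherence measurement-matrix / sensing-dictionary construction (ICSCA).

Compressed sensing recovers a K-sparse N-dimensional signal from M < N
linear measurements y = Phi x provided the columns of the measurement
matrix are close to mutually orthogonal. This module learns a pair
(Phi, Psi) — measurement matrix and sensing dictionary, both M x N with
paired columns — whose Gram matrix G = Psi^T Phi has small off-diagonal
coherence, by alternating:

* Problem 1 — gradient descent on C(Phi) = ||Phi^T Phi - H||_F^2, where H
  is an ideal Gram with unit diagonal and off-diagonals +-t_E (the
  Welch/ETF bound) carrying the current Gram's signs;
* Problem 2 — shrink the off-diagonals of G = Psi^T Phi with an arctan
  tighten operator into [-gamma, gamma], then refactor the shrunk Gram by
  a rank-M truncated SVD into a new (Phi, Psi) pair.

After each refactorization the columns are normalized so that
||phi_i|| = 1 and <eps_i, phi_i> = 1. Progress is tracked by the t-mean
coherence mu_t (mean absolute off-diagonal Gram entry of magnitude >= t)
and by OMP reconstruction error on sparse probes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np


@dataclass(frozen=True)
class SensingPair:
    """Measurement matrix Phi (M x N) with its paired sensing dictionary Psi.

    Invariants after normalization: ||phi_i||_2 = 1 and <eps_i, phi_i> = 1
    for every column i.
    """

    phi: np.ndarray
    psi: np.ndarray

    @property
    def m(self) -> int:
        return self.phi.shape[0]

    @property
    def n(self) -> int:
        return self.phi.shape[1]

    @property
    def gram(self) -> np.ndarray:
        return self.psi.T @ self.phi


@dataclass(frozen=True)
class ICSCAConfig:
    """Hyperparameters of the alternating construction.

    beta : Problem-1 gradient step size
    gamma : range of the tighten operator, off-diagonals map into [-gamma, gamma]
    t : coherence threshold defining mu_t
    tol : stop when |mu_t change| between outer rounds falls below this
    omp_sparsity : K used for the reconstruction-error trace (None -> M // 4)
    """

    beta: float = 0.001
    gamma: float = 0.4
    t: float = 0.0
    max_outer: int = 50
    max_inner: int = 1000
    tol: float = 1e-6
    seed: int = 0
    omp_sparsity: int | None = None

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must lie in (0, 1)")
        if not 0.0 <= self.t < 1.0:
            raise ValueError("t must lie in [0, 1)")


@dataclass
class ICSCAReport:
    """Per-outer-round traces of the construction."""

    mu_t: list[float] = field(default_factory=list)
    omp_error: list[float] = field(default_factory=list)
    phi_cost: list[float] = field(default_factory=list)
    mu_init: float = float("nan")
    converged: bool = False


@dataclass(frozen=True)
class SparseCode:
    """OMP output: coefficient vector, its support, and the residual norm."""

    coefficients: np.ndarray
    support: np.ndarray
    residual_norm: float


def t_mean_coherence(G: np.ndarray, t: float = 0.0) -> float:
    """Mean |G(i,j)| over off-diagonal entries with |G(i,j)| >= t.

    Returns 0.0 when no off-diagonal entry qualifies.
    """
    G = np.asarray(G)
    if G.shape[0] != G.shape[1]:
        raise ValueError("G must be square")
    off = np.abs(G[~np.eye(G.shape[0], dtype=bool)])
    sel = off[off >= t]
    return float(sel.mean()) if sel.size else 0.0


def etf_bound(m: int, n: int) -> float:
    """Welch/ETF lower bound sqrt((n - m) / (m (n - 1))) on frame coherence."""
    if not 1 <= m < n:
        raise ValueError("require 1 <= m < n")
    return math.sqrt((n - m) / (m * (n - 1)))


def target_gram(G: np.ndarray, t_E: float) -> np.ndarray:
    """Ideal Gram: unit diagonal, off-diagonals t_E * sign(G); sign(0) -> +1."""
    G = np.asarray(G, dtype=float)
    if G.shape[0] != G.shape[1]:
        raise ValueError("G must be square")
    signs = np.where(G >= 0.0, 1.0, -1.0)
    H = t_E * signs
    np.fill_diagonal(H, 1.0)
    return H


def optimize_phi(
    phi0: np.ndarray,
    H_target: np.ndarray,
    beta: float = 0.001,
    max_iter: int = 1000,
    tol: float = 1e-10,
) -> tuple[np.ndarray, list[float]]:
    """Gradient descent on C(Phi) = ||Phi^T Phi - H||_F^2.

    Iterates Phi <- Phi - beta * 4 Phi (Phi^T Phi - H) until the cost
    change drops below tol or max_iter is reached. Returns the final
    iterate and the cost trace.
    """
    phi = np.array(phi0, dtype=float)
    diff = phi.T @ phi - H_target
    cost = float(np.sum(diff**2))
    trace = [cost]
    for _ in range(max_iter):
        phi = phi - beta * 4.0 * (phi @ diff)
        diff = phi.T @ phi - H_target
        new_cost = float(np.sum(diff**2))
        if not np.isfinite(new_cost) or new_cost > 1e12:
            raise FloatingPointError(
                "Problem-1 iteration diverged; use a smaller beta"
            )
        trace.append(new_cost)
        if abs(cost - new_cost) < tol:
            break
        cost = new_cost
    return phi, trace


def tighten(G: np.ndarray, gamma: float = 0.4) -> np.ndarray:
    """Shrink off-diagonals by (4 gamma / pi) * arctan; diagonal untouched.

    Maps [-1, 1] into [-gamma, gamma], strictly increasing, sign-preserving.
    """
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must lie in (0, 1)")
    G = np.asarray(G, dtype=float)
    out = (4.0 * gamma / np.pi) * np.arctan(G)
    np.fill_diagonal(out, np.diag(G))
    return out


def solve_psi_phi(G_shrunk: np.ndarray, m: int) -> SensingPair:
    """Refactor a shrunk Gram into a normalized (Phi, Psi) pair by SVD.

    G = U S W^T is truncated to its m largest singular values and split
    symmetrically: Psi = S_m^{1/2} U_m^T, Phi = S_m^{1/2} W_m^T (both m x N),
    so Psi^T Phi reproduces the rank-m truncation. Columns are then
    rescaled so ||phi_i|| = 1 and <eps_i, phi_i> = 1.
    """
    G = np.asarray(G_shrunk, dtype=float)
    n = G.shape[0]
    if G.shape[0] != G.shape[1]:
        raise ValueError("G_shrunk must be square")
    if not 1 <= m < n:
        raise ValueError("require 1 <= m < n")
    U, s, Wt = np.linalg.svd(G)
    root = np.sqrt(s[:m])
    psi = root[:, None] * U[:, :m].T
    phi = root[:, None] * Wt[:m, :]
    norms = np.linalg.norm(phi, axis=0)
    if np.any(norms == 0.0):
        raise ValueError("degenerate zero column in Phi")
    phi = phi / norms
    dots = np.einsum("ij,ij->j", psi, phi)
    if np.any(np.abs(dots) < 1e-14):
        raise ValueError("degenerate atom pair: <eps_i, phi_i> = 0")
    psi = psi / dots
    return SensingPair(phi=phi, psi=psi)


def gaussian_measurement_matrix(m: int, n: int, seed: int = 0) -> np.ndarray:
    """Seeded i.i.d. Gaussian M x N matrix with unit-norm columns."""
    rng = np.random.default_rng(seed)
    phi = rng.standard_normal((m, n))
    return phi / np.linalg.norm(phi, axis=0)


def compress(phi: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Linear measurement y = Phi x (x may be a vector or a stack of rows)."""
    phi = np.asarray(phi)
    x = np.asarray(x)
    if x.ndim == 1:
        if x.size != phi.shape[1]:
            raise ValueError("x length must equal Phi's column count")
        return phi @ x
    if x.shape[1] != phi.shape[1]:
        raise ValueError("x rows must have length equal to Phi's column count")
    return x @ phi.T


def omp(A: np.ndarray, y: np.ndarray, K: int, tol: float = 1e-12) -> SparseCode:
    """Orthogonal matching pursuit: greedy sparse coding of y in A's columns.

    Selects the column most correlated with the residual, re-solves least
    squares on the accumulated support, and stops after K atoms or when the
    residual norm falls below tol.
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = A.shape
    if K > m:
        raise ValueError("K must not exceed the number of measurements")
    support: list[int] = []
    coef = np.zeros(n)
    residual = y.copy()
    for _ in range(K):
        rnorm = float(np.linalg.norm(residual))
        if rnorm < tol:
            break
        corr = np.abs(A.T @ residual)
        corr[support] = -1.0
        j = int(np.argmax(corr))
        support.append(j)
        sol, *_ = np.linalg.lstsq(A[:, support], y, rcond=None)
        residual = y - A[:, support] @ sol
    if support:
        coef[support] = sol
    return SparseCode(
        coefficients=coef,
        support=np.array(sorted(support), dtype=int),
        residual_norm=float(np.linalg.norm(residual)),
    )


def _omp_probe_error(phi: np.ndarray, K: int, rng: np.random.Generator, n_probe: int = 20) -> float:
    """Mean relative OMP reconstruction error on random K-sparse probes."""
    m, n = phi.shape
    err = 0.0
    for _ in range(n_probe):
        support = rng.choice(n, size=K, replace=False)
        x = np.zeros(n)
        x[support] = rng.standard_normal(K)
        code = omp(phi, phi @ x, K)
        err += float(np.linalg.norm(code.coefficients - x) / np.linalg.norm(x))
    return err / n_probe


def icsca_learn(
    n: int, m: int, config: ICSCAConfig | None = None
) -> tuple[SensingPair, ICSCAReport]:
    """Learn a low-coherence (Phi, Psi) pair by the alternating scheme.

    Each outer round rebuilds the ideal Gram H from the current signs, runs
    a full Problem-1 gradient solve, then a Problem-2 tighten + SVD
    refactorization. Terminates when mu_t changes by less than config.tol
    between rounds or max_outer is reached.
    """
    if config is None:
        config = ICSCAConfig()
    if not 1 <= m < n:
        raise ValueError("require 1 <= m < n")
    rng = np.random.default_rng(config.seed)
    t_E = etf_bound(m, n)
    K = config.omp_sparsity if config.omp_sparsity is not None else max(1, m // 4)

    phi = rng.standard_normal((m, n))
    phi /= np.linalg.norm(phi, axis=0)
    psi = rng.standard_normal((m, n))
    psi /= np.linalg.norm(psi, axis=0)
    # enforce the pair contract <eps_i, phi_i> = 1 on the initialization so
    # mu_t is compared between valid sensing pairs throughout
    dots = np.einsum("ij,ij->j", psi, phi)
    dots = np.where(np.abs(dots) < 1e-12, 1e-12, dots)
    psi = psi / dots
    pair = SensingPair(phi=phi, psi=psi)

    report = ICSCAReport()
    mu_prev = t_mean_coherence(pair.gram, config.t)
    report.mu_init = mu_prev
    for _ in range(config.max_outer):
        H = target_gram(pair.phi.T @ pair.phi, t_E)
        phi_opt, trace = optimize_phi(
            pair.phi, H, beta=config.beta, max_iter=config.max_inner
        )
        report.phi_cost.append(trace[-1])
        G = pair.psi.T @ phi_opt
        pair = solve_psi_phi(tighten(G, config.gamma), m)
        mu = t_mean_coherence(pair.gram, config.t)
        report.mu_t.append(mu)
        report.omp_error.append(_omp_probe_error(pair.phi, K, rng))
        if abs(mu - mu_prev) < config.tol:
            report.converged = True
            break
        mu_prev = mu
    return pair, report


def rip_constant_bruteforce(phi: np.ndarray, k: int, max_supports: int = 20000) -> float:
    """Exhaustive restricted-isometry constant of order k.

    delta_k = max over all k-column supports of max(1 - s_min^2, s_max^2 - 1)
    for the unit-column-normalized submatrix. Only feasible for small N;
    guarded by a cap on the number of supports.
    """
    phi = np.asarray(phi, dtype=float)
    phi = phi / np.linalg.norm(phi, axis=0)
    n = phi.shape[1]
    n_supports = math.comb(n, k)
    if n_supports > max_supports:
        raise ValueError(
            f"C({n},{k}) = {n_supports} supports exceeds the cap {max_supports}"
        )
    delta = 0.0
    for support in combinations(range(n), k):
        s = np.linalg.svd(phi[:, support], compute_uv=False)
        delta = max(delta, max(1.0 - s[-1] ** 2, s[0] ** 2 - 1.0))
    return float(delta)
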