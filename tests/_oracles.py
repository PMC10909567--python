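"""Independent brute-force and closed-form oracles used by the test suite.

Every routine here deliberately avoids the code paths it checks: eigenvalues
via power iteration where the implementation uses dense solvers, Kreiss
bounds via an eigendecomposition dense grid where the implementation uses
linear solves plus scalar optimization, maximal amplification via explicit
matrix powers where the implementation iterates column-sum vectors.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize, minimize_scalar


def random_primitive(rng: np.random.Generator, n: int,
                     target_radius: float | None = None) -> np.ndarray:
    """Strictly positive (hence primitive) random matrix."""
    M = rng.uniform(0.01, 1.0, size=(n, n))
    if target_radius is not None:
        M *= target_radius / np.max(np.abs(np.linalg.eigvals(M)))
    return M


def power_iteration_lambda(K: np.ndarray, tol: float = 1e-14,
                           max_iter: int = 100_000) -> float:
    v = np.ones(K.shape[0]) / K.shape[0]
    lam = 0.0
    for _ in range(max_iter):
        w = K @ v
        new = np.linalg.norm(w)
        v = w / new
        if abs(new - lam) <= tol * new:
            break
        lam = new
    return float(new)


def damping_ratio_eig(K: np.ndarray) -> float:
    mods = np.sort(np.abs(np.linalg.eigvals(K)))[::-1]
    return float(mods[0] / mods[1])


def maxamp_brute(K: np.ndarray, t_max: int = 10_000) -> float:
    """Max over t of the maximum column sum of (K/lambda)^t, by matrix powers."""
    lam = np.max(np.abs(np.linalg.eigvals(K)))
    A = K / lam
    M = np.eye(K.shape[0])
    best = 0.0
    for _ in range(t_max):
        M = M @ A
        best = max(best, float(M.sum(axis=0).max()))
    return best


def kreiss_grid_oracle(K: np.ndarray, n_points: int = 100_000,
                       u_lo: float = -6.0, u_hi: float = 3.0,
                       chunk: int = 20_000):
    """Kreiss bounds from a dense log-spaced r-grid plus local refinement.

    Resolvent column sums are evaluated through the eigendecomposition of
    the lambda-normalized matrix: colsum_j(r) = sum_k C[k, j] / (r - mu_k).
    """
    lam = np.max(np.abs(np.linalg.eigvals(K)))
    A = K / lam
    mu, W = np.linalg.eig(A)
    C = (np.ones(A.shape[0]) @ W)[:, None] * np.linalg.inv(W)
    us = np.linspace(u_lo, u_hi, n_points)
    rs = 1.0 + 10.0 ** us
    best_up = -np.inf
    best_lo = np.inf
    arg_up = arg_lo = 0.0
    for start in range(0, n_points, chunk):
        r = rs[start:start + chunk]
        G = 1.0 / (r[:, None] - mu[None, :])
        vals = (G @ C).real
        fup = (r - 1.0) * vals.max(axis=1)
        flo = (r - 1.0) * vals.min(axis=1)
        i = int(np.argmax(fup))
        if fup[i] > best_up:
            best_up, arg_up = float(fup[i]), float(r[i])
        i = int(np.argmin(flo))
        if flo[i] < best_lo:
            best_lo, arg_lo = float(flo[i]), float(r[i])

    def colsums(r):
        return ((1.0 / (r - mu)) @ C).real

    def refine(r0, maximize):
        lo_u = np.log10(max(r0 - 1, 1e-12)) - 2e-4
        hi_u = np.log10(r0 - 1) + 2e-4

        def value(u):
            r = 1.0 + 10.0 ** u
            cs = colsums(r)
            return (r - 1.0) * (cs.max() if maximize else cs.min())

        res = minimize_scalar(lambda u: -value(u) if maximize else value(u),
                              bounds=(lo_u, hi_u), method="bounded",
                              options={"xatol": 1e-12})
        return -res.fun if maximize else res.fun

    best_up = max(best_up, refine(arg_up, True), 1.0)
    best_lo = max(min(best_lo, refine(arg_lo, False), 1.0), 0.0)
    return best_up, best_lo


def rma_perpendicular_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Ranged major-axis slope by direct perpendicular-distance minimization.

    Scales both variables to [0, 1], fits the line minimizing summed squared
    perpendicular distances (parametrized by angle and offset), and
    back-transforms the slope.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rx, ry = np.ptp(x), np.ptp(y)
    xs = (x - x.min()) / rx
    ys = (y - y.min()) / ry

    def cost(p):
        theta, c = p
        return np.sum((xs * np.sin(theta) - ys * np.cos(theta) + c) ** 2)

    best = None
    for theta0 in np.linspace(-1.4, 1.4, 15):
        res = minimize(cost, x0=[theta0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14,
                                "maxiter": 5000})
        if best is None or res.fun < best.fun:
            best = res
    slope_scaled = np.tan(best.x[0])
    return float(slope_scaled * ry / rx)


def simulate_lifetime_offspring(P: np.ndarray, c0: np.ndarray,
                                fvec: np.ndarray, n_sim: int,
                                rng: np.random.Generator,
                                t_cap: int = 5000) -> float:
    """Monte-Carlo net reproductive rate for a rank-one reproduction kernel.

    Individuals are born into states drawn from c0, move or die according to
    the columns of P (column sums are the survival probabilities), and
    accrue the expected per-step offspring fvec[state]; returns the mean
    lifetime total, an unbiased estimate of R0 when F = outer(c0, fvec).
    """
    m = P.shape[0]
    col_surv = P.sum(axis=0)
    if np.any(col_surv > 1 + 1e-12):
        raise ValueError("oracle needs sub-stochastic P columns")
    cond = P / np.maximum(col_surv, 1e-300)
    cum = np.cumsum(cond, axis=0)
    state = rng.choice(m, size=n_sim, p=c0 / c0.sum())
    alive = np.ones(n_sim, dtype=bool)
    total = np.zeros(n_sim)
    for _ in range(t_cap):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        s = state[idx]
        total[idx] += fvec[s]
        u = rng.random(idx.size)
        dead = u > col_surv[s]
        alive[idx[dead]] = False
        move = ~dead
        if move.any():
            r = rng.random(move.sum())
            cols = cum[:, s[move]]
            new_states = (r[None, :] > cols).sum(axis=0)
            state[idx[move]] = new_states
    return float(total.mean())
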