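"""Independent reference implementations used only to verify the solvers.

Each oracle takes a different algorithmic route than the implementation it
checks: generic smooth minimization (L-BFGS-B on a positive/negative split
with an epsilon-smoothed group norm) for the penalized objectives, an
exact eigendecomposition + scalar root-finding block descent for the group
Lasso, SLSQP on the epigraph formulation for the small max-norm
semidefinite projection, and exhaustive BFS path counting for betweenness.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import brentq, minimize

_EPS = 1e-18  # group-norm smoothing; sqrt(eps) = 1e-9 objective error


def _smooth_norm(v: np.ndarray) -> float:
    return float(np.sqrt(v @ v + _EPS))


def minimize_split(objective_parts, p: int, starts: list[np.ndarray]) -> tuple[np.ndarray, float]:
    """Minimize smooth(beta) + l1-type terms via the beta = u - v split.

    ``objective_parts`` is (smooth_fn, l1_weights, group_terms) where
    group_terms is a list of (weight, index_array). The split makes the l1
    term linear over u, v >= 0; group norms are epsilon-smoothed.
    """
    smooth_fn, l1_w, group_terms = objective_parts

    def f(z):
        u, v = z[:p], z[p:]
        b = u - v
        val = smooth_fn(b) + float(l1_w @ (u + v))
        for w, idx in group_terms:
            val += w * _smooth_norm(b[idx])
        return val

    best = None
    for s in starts:
        z0 = np.concatenate([np.maximum(s, 0), np.maximum(-s, 0)])
        res = minimize(
            f, z0, method="L-BFGS-B", bounds=[(0, None)] * (2 * p),
            options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-12},
        )
        if best is None or res.fun < best[1]:
            best = (res.x[:p] - res.x[p:], float(res.fun))
    return best


def group_lasso_bcd(
    y: np.ndarray,
    X_groups: list[np.ndarray],
    lam: float,
    tol: float = 1e-12,
    max_iter: int = 50000,
) -> np.ndarray:
    """Classical group Lasso (penalty lam * sum sqrt(p_g) ||b_g||) by exact
    block updates: eigendecomposition plus scalar root finding per block."""
    p_g = [X.shape[1] for X in X_groups]
    betas = [np.zeros(p) for p in p_g]
    eigs = [np.linalg.eigh(X.T @ X) for X in X_groups]
    for _ in range(max_iter):
        max_change = 0.0
        for g, X in enumerate(X_groups):
            kappa = lam * np.sqrt(p_g[g])
            r = y - sum(Xo @ b for o, (Xo, b) in enumerate(zip(X_groups, betas)) if o != g)
            c = X.T @ r
            if np.linalg.norm(c) <= kappa:
                b_new = np.zeros(p_g[g])
            else:
                lam_e, Q = eigs[g]
                d = Q.T @ c

                def phi(t):
                    return float(np.sum((d / (lam_e * t + kappa)) ** 2)) - 1.0

                hi = np.linalg.norm(c) / max(lam_e.min(), 1e-12)
                t = brentq(phi, 1e-14, max(hi, 1.0) * 10, xtol=1e-15, rtol=1e-15)
                b_new = Q @ (d * t / (lam_e * t + kappa))
            change = float(np.max(np.abs(b_new - betas[g]))) if p_g[g] else 0.0
            betas[g] = b_new
            max_change = max(max_change, change)
        if max_change < tol:
            break
    return np.concatenate(betas)


def sdp_maxnorm_project(S: np.ndarray) -> tuple[np.ndarray, float]:
    """Small-scale solve of min ||Sigma - S||_max over PSD Sigma via SLSQP
    on the epigraph formulation (variables: upper triangle of Sigma and t)."""
    p = S.shape[0]
    iu = np.triu_indices(p)

    def to_mat(x):
        M = np.zeros((p, p))
        M[iu] = x[:-1]
        return M + np.triu(M, 1).T

    def obj(x):
        return x[-1]

    cons = [
        {"type": "ineq", "fun": lambda x: np.linalg.eigvalsh(to_mat(x)).min()},
    ]

    def make_abs_cons(i, j, sign):
        def fun(x):
            M = to_mat(x)
            return x[-1] - sign * (M[i, j] - S[i, j])

        return {"type": "ineq", "fun": fun}

    for i, j in zip(*iu):
        cons.append(make_abs_cons(i, j, 1.0))
        cons.append(make_abs_cons(i, j, -1.0))

    # start from the eigenvalue-clipped projection
    w, V = np.linalg.eigh((S + S.T) / 2)
    clip = (V * np.maximum(w, 0)) @ V.T
    x0 = np.concatenate([clip[iu], [np.abs(clip - S).max()]])
    res = minimize(obj, x0, method="SLSQP", constraints=cons,
                   options={"maxiter": 2000, "ftol": 1e-12})
    M = to_mat(res.x)
    return M, float(np.abs(M - S).max())


def brute_force_betweenness(nodes: list, edges: set) -> dict:
    """Normalized betweenness by explicit enumeration of all shortest paths."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    def all_shortest_paths(s, t):
        # BFS layering, then DFS over predecessor links
        from collections import deque

        dist = {s: 0}
        preds = {s: []}
        q = deque([s])
        while q:
            u = q.popleft()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    preds[v] = [u]
                    q.append(v)
                elif dist[v] == dist[u] + 1:
                    preds[v].append(u)
        if t not in dist:
            return []
        paths = []

        def back(v, acc):
            if v == s:
                paths.append([s] + acc[::-1] + [])
                return
            for u in preds[v]:
                back(u, acc + [v])

        back(t, [])
        return [pth for pth in paths]

    bc = {n: 0.0 for n in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_shortest_paths(s, t)
        if not paths:
            continue
        for n in nodes:
            if n in (s, t):
                continue
            through = sum(1 for pth in paths if n in pth)
            bc[n] += through / len(paths)
    N = len(nodes)
    norm = (N - 1) * (N - 2) / 2 if N > 2 else 1.0
    return {n: v / norm for n, v in bc.items()}


def brute_force_transitivity(nodes: list, edges: set) -> float:
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    triangles = 0
    triples = 0
    for n in nodes:
        k = len(adj[n])
        triples += k * (k - 1) // 2
        for a, b in itertools.combinations(adj[n], 2):
            if b in adj[a]:
                triangles += 1
    # each triangle counted once per vertex = 3 times total
    return triangles / triples if triples else 0.0
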