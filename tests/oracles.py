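"""Independent brute-force oracles used to verify the fast implementations.

These deliberately share no code with the package: the painting oracle
enumerates every donor path of the copying HMM, the fit oracle solves the
normal equations explicitly, and the NNLS oracle is a refining grid
search over the feasible set.
"""

from __future__ import annotations

import itertools

import numpy as np


def site_weights(gpos: np.ndarray) -> np.ndarray:
    L = len(gpos)
    if L == 1:
        return np.ones(1)
    d = np.diff(gpos)
    w = np.zeros(L)
    w[:-1] += d / 2
    w[1:] += d / 2
    return w


def enumerate_painting(hap, donors, gpos, M, n_rate):
    """Exhaustive-path posteriors of the copying HMM.

    Returns (genome fractions (D,), expected chunk counts (D,)) by summing
    over all D^L donor paths: initial probability 1/D, stay probability
    exp(-n*g) plus uniform jump, emission 1-M / M.  Chunk count of donor d
    along a path = [path starts in d] + #transitions into d from a
    different donor.
    """
    donors = np.asarray(donors)
    hap = np.asarray(hap)
    D, L = donors.shape
    rho = np.exp(-n_rate * np.diff(np.asarray(gpos, dtype=float)))
    w = site_weights(np.asarray(gpos, dtype=float))
    w = w / w.sum()

    frac = np.zeros(D)
    chunks = np.zeros(D)
    total = 0.0
    for path in itertools.product(range(D), repeat=L):
        p = (1.0 / D) * ((1 - M) if donors[path[0], 0] == hap[0] else M)
        for l in range(1, L):
            r = rho[l - 1]
            trans = r + (1 - r) / D if path[l] == path[l - 1] else (1 - r) / D
            emit = (1 - M) if donors[path[l], l] == hap[l] else M
            p *= trans * emit
        total += p
        occ = np.zeros(D)
        ent = np.zeros(D)
        ent[path[0]] += 1
        for l in range(L):
            occ[path[l]] += w[l]
        for l in range(1, L):
            if path[l] != path[l - 1]:
                ent[path[l]] += 1
        frac += p * occ
        chunks += p * ent
    return frac / total, chunks / total


def normal_equations_fit(A, C):
    """X = (A^T A)^{-1} A^T C via explicit inversion."""
    A = np.asarray(A, dtype=float)
    C = np.asarray(C, dtype=float)
    return np.linalg.inv(A.T @ A) @ A.T @ C


def grid_nnls(A, c, lo=0.0, hi=4.0, levels=5, n=81):
    """Refining dense-grid minimizer of ||A x - c||^2 over x >= 0 (K=2)."""
    A = np.asarray(A, dtype=float)
    c = np.asarray(c, dtype=float)
    best = None
    lo1, hi1, lo2, hi2 = lo, hi, lo, hi
    for _ in range(levels):
        xs = np.linspace(lo1, hi1, n)
        ys = np.linspace(lo2, hi2, n)
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel()])
        obj = ((A @ pts - c[:, None]) ** 2).sum(axis=0)
        k = int(np.argmin(obj))
        best = (pts[0, k], pts[1, k], obj[k])
        sx = (hi1 - lo1) / (n - 1)
        sy = (hi2 - lo2) / (n - 1)
        lo1, hi1 = max(lo, best[0] - 2 * sx), best[0] + 2 * sx
        lo2, hi2 = max(lo, best[1] - 2 * sy), best[1] + 2 * sy
    return np.array([best[0], best[1]]), best[2]


def brute_force_max_r2_within_window(genotypes, positions, window_bp):
    """Exhaustive max r^2 over all site pairs within the window."""
    g = np.asarray(genotypes, dtype=float)
    best = 0.0
    L = g.shape[1]
    for i in range(L):
        for j in range(i + 1, L):
            if positions[j] - positions[i] > window_bp:
                break
            xi = g[:, i] - g[:, i].mean()
            xj = g[:, j] - g[:, j].mean()
            denom = (xi @ xi) * (xj @ xj)
            if denom <= 0:
                continue
            r2 = (xi @ xj) ** 2 / denom
            best = max(best, r2)
    return best
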