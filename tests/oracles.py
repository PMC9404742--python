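"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the code paths they check: relationships come from
Wright's path-counting over the parent DAG (not the tabular recursion),
REML log-likelihoods from dense phenotypic covariance matrices (not the
mixed-model equations), and balanced-design variance components from
one-way ANOVA mean squares.
"""

from __future__ import annotations

import numpy as np


def _paths_up(ped, i):
    """All upward node-paths from animal i to each of its ancestors."""
    out = [(i, (i,))]
    for p in (ped.sire[i], ped.dam[i]):
        if p >= 0:
            for anc, path in _paths_up(ped, int(p)):
                out.append((anc, (i,) + path))
    return out


def nrm_path_counting(ped) -> np.ndarray:
    """Numerator relationships by Wright's coefficients.

    a_ij = sum over common ancestors ca and pairs of node-disjoint upward
    paths (sharing only ca) of (1/2)^(edges) * (1 + F_ca); the diagonal is
    1 + F_i with F_i = a(sire, dam)/2.  Exponential in pedigree depth —
    only for small pedigrees.
    """
    n = len(ped)
    A = np.zeros((n, n))
    F = np.zeros(n)
    paths = [_paths_up(ped, i) for i in range(n)]
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        F[i] = 0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + F[i]
        for j in range(i):
            tot = 0.0
            for ca1, p1 in paths[i]:
                for ca2, p2 in paths[j]:
                    if ca1 == ca2 and set(p1) & set(p2) == {ca1}:
                        tot += 0.5 ** (len(p1) + len(p2) - 2) * (1.0 + F[ca1])
            A[i, j] = A[j, i] = tot
    return A


def random_pedigree(rng, n_max=12):
    """A random small pedigree (possibly with unknown single parents)."""
    from methaherd.pedigree import Pedigree

    n = int(rng.integers(3, n_max + 1))
    ids = [f"P{i}" for i in range(n)]
    parents = {}
    for i, a in enumerate(ids):
        if i < 2 or rng.random() < 0.3:
            parents[a] = (None, None)
            continue
        s = ids[int(rng.integers(0, i))] if rng.random() < 0.9 else None
        d = ids[int(rng.integers(0, i))] if rng.random() < 0.9 else None
        if s is not None and s == d:
            d = None
        parents[a] = (s, d)
    return Pedigree.from_parent_map(parents)


def dense_reml_logL(X, Z, W, A, Y, Ga, Gpe, R0):
    """REML log-likelihood from the dense phenotypic covariance matrix.

    Handles k traits stacked trait-major: V has (s,t) record-blocks
    Ga[s,t] ZAZ' + Gpe[s,t] WW' + R0[s,t] I.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    n, k = Y.shape
    Ga, Gpe, R0 = (np.atleast_2d(np.asarray(m, float)) for m in (Ga, Gpe, R0))
    ZAZ = Z @ A @ Z.T
    WW = W @ W.T
    V = np.kron(Ga, ZAZ) + np.kron(Gpe, WW) + np.kron(R0, np.eye(n))
    Xs = np.kron(np.eye(k), X)
    y = Y.T.reshape(-1)
    Vi = np.linalg.inv(V)
    XVX = Xs.T @ Vi @ Xs
    P = Vi - Vi @ Xs @ np.linalg.inv(XVX) @ Xs.T @ Vi
    p = X.shape[1]
    return -0.5 * (
        k * (n - p) * np.log(2 * np.pi)
        + np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XVX)[1]
        + y @ P @ y
    )


def anova_oneway(y, group_sizes):
    """Between/within variance components of a balanced one-way layout.

    ``y`` ordered by group; all groups of equal size m.  Returns
    (sigma2_between, sigma2_within) from expected mean squares.
    """
    y = np.asarray(y, dtype=float)
    m = group_sizes
    groups = y.reshape(-1, m)
    g = groups.shape[0]
    gm = groups.mean(axis=1)
    grand = y.mean()
    msb = m * ((gm - grand) ** 2).sum() / (g - 1)
    msw = ((groups - gm[:, None]) ** 2).sum() / (g * (m - 1))
    return (msb - msw) / m, msw
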