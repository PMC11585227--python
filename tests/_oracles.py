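"""Independent brute-force oracles used to verify the implementation.

Everything here is written directly from the defining formulas with plain
O(N^2) loops and numpy's generic pseudoinverse — deliberately sharing no
code with the package's optimized paths.
"""

import numpy as np


def counting(u):
    """Normalized counting function c(u) = 0, 1/2, 1 for u < 0, = 0, > 0."""
    return 0.0 if u < 0 else (0.5 if u == 0 else 1.0)


def oracle_midranks(data):
    """Mid-ranks R = 1/2 + sum of c over all observed pairs (O(N^2) loops)."""
    pooled = []
    for v, m in zip(data.values, data.observed):
        for k in range(v.shape[0]):
            for j in range(v.shape[1]):
                if m[k, j]:
                    pooled.append(v[k, j])
    out = []
    for v, m in zip(data.values, data.observed):
        r = np.zeros_like(v)
        for k in range(v.shape[0]):
            for j in range(v.shape[1]):
                if m[k, j]:
                    r[k, j] = 0.5 + sum(counting(v[k, j] - x) for x in pooled)
        out.append(r)
    return out, len(pooled)


def oracle_effects(data):
    """p_ij = integral of H-hat w.r.t. F-hat_ij by direct summation."""
    pooled = [
        v[k, j]
        for v, m in zip(data.values, data.observed)
        for k in range(v.shape[0])
        for j in range(v.shape[1])
        if m[k, j]
    ]
    N = len(pooled)

    def H(x):
        return sum(counting(x - y) for y in pooled) / N

    p = []
    for v, m in zip(data.values, data.observed):
        for j in range(v.shape[1]):
            obs = [v[k, j] for k in range(v.shape[0]) if m[k, j]]
            p.append(sum(H(x) for x in obs) / len(obs))
    return np.array(p)


def oracle_covariance(data):
    """Term-by-term evaluation of the V-hat entries from oracle mid-ranks."""
    R, N = oracle_midranks(data)
    a, d = len(data.values), data.values[0].shape[1]
    n = [v.shape[0] for v in data.values]
    n_tot = sum(n)
    V = np.zeros((a * d, a * d))
    for i in range(a):
        m = data.observed[i]
        lam = [sum(m[k, j] for k in range(n[i])) for j in range(d)]
        rbar = [
            sum(R[i][k, j] for k in range(n[i]) if m[k, j]) / lam[j] for j in range(d)
        ]
        for j in range(d):
            for j2 in range(d):
                if j == j2:
                    num = sum(
                        (R[i][k, j] - rbar[j]) ** 2 for k in range(n[i]) if m[k, j]
                    )
                    den = N**2 * lam[j] * (lam[j] - 1)
                else:
                    delta = sum(m[k, j] and m[k, j2] for k in range(n[i]))
                    num = sum(
                        (R[i][k, j] - rbar[j]) * (R[i][k, j2] - rbar[j2])
                        for k in range(n[i])
                        if m[k, j] and m[k, j2]
                    )
                    den = N**2 * ((lam[j] - 1) * (lam[j2] - 1) + delta - 1)
                if den <= 0:
                    v = 0.0
                else:
                    v = n[i] * num / den
                V[i * d + j, i * d + j2] = (n_tot / n[i]) * v
    return V


def oracle_wts(p, V, C, n):
    Cp = C @ p
    return float(n * Cp @ np.linalg.pinv(C @ V @ C.T) @ Cp)


def oracle_ats(p, V, C, n):
    T = C.T @ np.linalg.pinv(C @ C.T) @ C
    return float(n * p @ T @ p / np.trace(T @ V))


def oracle_mats(p, V, C, n):
    D = np.diag(np.diag(V))
    Cp = C @ p
    return float(n * Cp @ np.linalg.pinv(C @ D @ C.T) @ Cp)


def oracle_bootstrap_stats(data, C, weights_per_group):
    """One bootstrap replicate's (WTS*, ATS*, MATS*) by direct formula loops."""
    R, N = oracle_midranks(data)
    a, d = len(data.values), data.values[0].shape[1]
    n = [v.shape[0] for v in data.values]
    n_tot = sum(n)
    p_star, V = [], np.zeros((a * d, a * d))
    for i in range(a):
        m = data.observed[i]
        lam = [sum(m[k, j] for k in range(n[i])) for j in range(d)]
        rbar = [
            sum(R[i][k, j] for k in range(n[i]) if m[k, j]) / lam[j] for j in range(d)
        ]
        W = weights_per_group[i]
        Zs = np.zeros((n[i], d))
        for k in range(n[i]):
            for j in range(d):
                if m[k, j]:
                    Zs[k, j] = W[k] * (R[i][k, j] - rbar[j])
        zbar = [
            sum(Zs[k, j] for k in range(n[i]) if m[k, j]) / lam[j] for j in range(d)
        ]
        for j in range(d):
            p_star.append(
                sum(Zs[k, j] for k in range(n[i]) if m[k, j]) / (lam[j] * N)
            )
        for j in range(d):
            for j2 in range(d):
                if j == j2:
                    num = sum(
                        (Zs[k, j] - zbar[j]) ** 2 for k in range(n[i]) if m[k, j]
                    )
                    den = N**2 * lam[j] * (lam[j] - 1)
                else:
                    delta = sum(m[k, j] and m[k, j2] for k in range(n[i]))
                    num = sum(
                        (Zs[k, j] - zbar[j]) * (Zs[k, j2] - zbar[j2])
                        for k in range(n[i])
                        if m[k, j] and m[k, j2]
                    )
                    den = N**2 * ((lam[j] - 1) * (lam[j2] - 1) + delta - 1)
                V[i * d + j, i * d + j2] = (
                    0.0 if den <= 0 else (n_tot / n[i]) * n[i] * num / den
                )
    p_star = np.array(p_star)
    return (
        oracle_wts(p_star, V, C, n_tot),
        oracle_ats(p_star, V, C, n_tot),
        oracle_mats(p_star, V, C, n_tot),
    )
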