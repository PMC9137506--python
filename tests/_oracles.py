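"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (explicit loops, textbook
formulas) and shares no code path with the package implementation.
"""

from collections import deque
from itertools import combinations

import numpy as np


def ols_contrast_t(y, X, C):
    """Textbook OLS contrast t via an explicit normal-equations solve,
    with the same implicit-intercept df convention (n - 1 - rank)."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n = len(y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    XtX = Xc.T @ Xc
    rank = np.linalg.matrix_rank(XtX)
    G = np.linalg.inv(XtX)  # callers supply full-rank designs
    beta = G @ Xc.T @ yc
    resid = yc - Xc @ beta
    df = n - 1 - rank
    sigma2 = float(resid @ resid) / df
    return float(C @ beta) / np.sqrt(sigma2 * float(C @ G @ C))


def dense_gaussian_smooth(volume, sd_mm, voxel_size_mm, truncate=4.0):
    """Direct dense convolution with an explicitly sampled, per-axis
    normalised Gaussian kernel, zero-padded and renormalised over the
    in-grid support."""
    vol = np.asarray(volume, float)
    kernels = []
    for v in voxel_size_mm:
        sigma = sd_mm / v
        radius = int(truncate * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k = np.exp(-0.5 * (x / sigma) ** 2)
        kernels.append(k / k.sum())
    out = np.zeros_like(vol)
    norm = np.zeros_like(vol)
    shape = vol.shape
    for idx in np.ndindex(shape):
        acc = 0.0
        nrm = 0.0
        kx, ky, kz = kernels
        rx, ry, rz = (len(k) // 2 for k in kernels)
        for dx in range(-rx, rx + 1):
            i = idx[0] + dx
            if not 0 <= i < shape[0]:
                continue
            for dy in range(-ry, ry + 1):
                j = idx[1] + dy
                if not 0 <= j < shape[1]:
                    continue
                for dz in range(-rz, rz + 1):
                    k = idx[2] + dz
                    if not 0 <= k < shape[2]:
                        continue
                    w = kx[rx + dx] * ky[ry + dy] * kz[rz + dz]
                    acc += w * vol[i, j, k]
                    nrm += w
        out[idx] = acc
        norm[idx] = nrm
    return out / norm


def flood_fill_clusters(binary, connectivity):
    """Connected components by explicit BFS.  Returns a list of voxel
    coordinate lists, one per component."""
    binary = np.asarray(binary, bool)
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    visited = np.zeros_like(binary)
    comps = []
    for start in np.argwhere(binary):
        start = tuple(start)
        if visited[start]:
            continue
        comp = []
        queue = deque([start])
        visited[start] = True
        while queue:
            cur = queue.popleft()
            comp.append(cur)
            for off in offsets:
                nxt = tuple(c + o for c, o in zip(cur, off))
                if any(not 0 <= nxt[a] < binary.shape[a] for a in range(3)):
                    continue
                if binary[nxt] and not visited[nxt]:
                    visited[nxt] = True
                    queue.append(nxt)
        comps.append(comp)
    return comps


def mann_whitney_u_enumerate(g1, g2):
    """Exact U and two-sided p by enumerating every group-1 labelling of
    the pooled sample (no ties assumed)."""
    pooled = np.concatenate([g1, g2])
    n1 = len(g1)
    u_obs = sum(1 for a in g1 for b in g2 if a < b)
    idx = range(len(pooled))
    null_us = []
    for comb in combinations(idx, n1):
        a = pooled[list(comb)]
        b = np.delete(pooled, list(comb))
        null_us.append(sum(1 for x in a for y in b if x < y))
    null_us = np.asarray(null_us)
    mu = len(g1) * len(g2) / 2
    p = np.mean(np.abs(null_us - mu) >= abs(u_obs - mu) - 1e-12)
    return u_obs, float(p)


def median_by_sorting(values):
    """Order-statistic median: midpoint of the two central values for
    even counts."""
    v = sorted(values)
    n = len(v)
    if n % 2:
        return v[n // 2]
    return 0.5 * (v[n // 2 - 1] + v[n // 2])
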