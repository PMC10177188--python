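"""Independent brute-force reference implementations used only by the tests.

Each function recomputes a pipeline quantity by direct enumeration or a
closed form, deliberately avoiding the vectorised/library code paths it
checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def closed_form_mu_est(mu: float, depth_below: float) -> float:
    """Finite-depth value of the depth-resolved estimator on an exact
    exponential: mu / (1 - exp(-2 mu L)) with L the remaining depth."""
    return mu / (1.0 - np.exp(-2.0 * mu * depth_below))


def triple_loop_boxcar(arr: np.ndarray) -> np.ndarray:
    """3x3x3 mean with edge-inclusive reflective padding, by explicit loops."""
    pad = np.pad(arr, 1, mode="symmetric")
    out = np.empty_like(arr, dtype=float)
    nz, nx, ny = arr.shape
    for i in range(nz):
        for j in range(nx):
            for k in range(ny):
                acc = 0.0
                for di in range(3):
                    for dj in range(3):
                        for dk in range(3):
                            acc += pad[i + di, j + dj, k + dk]
                out[i, j, k] = acc / 27.0
    return out


def concordance_auc(pos, neg, direction: str = "lower") -> float:
    """AUC as explicit pairwise concordance with ties counted 1/2."""
    total = 0.0
    for p in pos:
        for q in neg:
            if p == q:
                total += 0.5
            elif (p < q) == (direction == "lower"):
                total += 1.0
    return total / (len(pos) * len(neg))


def mann_whitney_enumeration_p(x, y) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all group assignments."""
    x = list(x)
    y = list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(sample_a, sample_b):
        u = 0.0
        for a in sample_a:
            for b in sample_b:
                u += 1.0 if a > b else (0.5 if a == b else 0.0)
        return u

    mean_u = n1 * len(y) / 2.0
    obs = abs(u_stat(x, y) - mean_u)
    count = 0
    total = 0
    idx = range(len(pooled))
    for chosen in combinations(idx, n1):
        chosen_set = set(chosen)
        a = [pooled[i] for i in chosen]
        b = [pooled[i] for i in idx if i not in chosen_set]
        if abs(u_stat(a, b) - mean_u) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


def percentile_scan(values, q: float) -> float:
    """Linear-interpolation percentile computed from first principles."""
    vals = sorted(values)
    pos = (len(vals) - 1) * q / 100.0
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return vals[lo] * (1 - frac) + vals[hi] * frac


def youden_scan(pos, neg, direction: str = "lower"):
    """Exhaustive Youden search over all midpoints; returns best se + sp."""
    vals = sorted(set(list(pos) + list(neg)))
    cands = [vals[0] - 1.0] + [
        (a + b) / 2.0 for a, b in zip(vals[:-1], vals[1:])
    ] + [vals[-1] + 1.0]
    best = -1.0
    for pth in cands:
        if direction == "lower":
            se = np.mean([p < pth for p in pos])
            sp = np.mean([q >= pth for q in neg])
        else:
            se = np.mean([p > pth for p in pos])
            sp = np.mean([q <= pth for q in neg])
        best = max(best, se + sp)
    return best
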