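"""Independent brute-force reference implementations.

Everything here is written as literal double loops straight from the
defining formulas, deliberately sharing no code with the package, so the
vectorized implementations can be checked against them.
"""

import math


def sen_slope_brute(x, t):
    slopes = []
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            slopes.append((x[j] - x[i]) / (t[j] - t[i]))
    slopes.sort()
    m = len(slopes)
    if m % 2:
        return slopes[m // 2]
    return (slopes[m // 2 - 1] + slopes[m // 2]) / 2


def mk_s_brute(x):
    s = 0
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            d = x[j] - x[i]
            s += (1 if d > 0 else 0) - (1 if d < 0 else 0)
    return s


def mk_z_brute(x):
    n = len(x)
    s = mk_s_brute(x)
    # tie groups by value
    ties = {}
    for v in x:
        ties[v] = ties.get(v, 0) + 1
    var = n * (n - 1) * (2 * n + 5)
    for c in ties.values():
        if c > 1:
            var -= c * (c - 1) * (2 * c + 5)
    var /= 18.0
    if s > 0:
        return (s - 1) / math.sqrt(var)
    if s < 0:
        return (s + 1) / math.sqrt(var)
    return 0.0


def gi_star_brute(x, ids, neighbors):
    """Getis-Ord Gi* with self-inclusion and binary weights."""
    t = len(x)
    xbar = sum(x) / t
    s = math.sqrt(sum((v - xbar) ** 2 for v in x) / t)
    out = []
    for i, rid in enumerate(ids):
        nbr_idx = [ids.index(j) for j in neighbors[rid]] + [i]
        wsum = len(nbr_idx)
        wx = sum(x[j] for j in nbr_idx)
        num = wx - xbar * wsum
        inner = (t * wsum - wsum ** 2) / (t - 1)  # w_ij in {0,1}: sum w^2 = sum w
        denom = s * math.sqrt(inner) if inner > 0 else 0.0
        out.append(num / denom if denom > 0 else 0.0)
    return out


def _z(v):
    n = len(v)
    m = sum(v) / n
    sd = math.sqrt(sum((u - m) ** 2 for u in v) / n)
    return [(u - m) / sd for u in v]


def global_moran_brute(y, x, ids, neighbors, weights):
    zy, zx = _z(y), _z(x)
    num = s0 = 0.0
    for i, rid in enumerate(ids):
        for j_id, w in zip(neighbors[rid], weights[rid]):
            j = ids.index(j_id)
            num += w * zy[i] * zx[j]
            s0 += w
    return num / s0


def local_moran_brute(y, x, ids, neighbors, weights):
    zy, zx = _z(y), _z(x)
    out = []
    for i, rid in enumerate(ids):
        lag = 0.0
        for j_id, w in zip(neighbors[rid], weights[rid]):
            lag += w * zx[ids.index(j_id)]
        out.append(zy[i] * lag)
    return out
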