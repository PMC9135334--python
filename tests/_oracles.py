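"""Independent scalar reference implementations used to check the package.

Everything here is deliberately written as plain Python double loops over
scalars, sharing no code path with the vectorized implementations under
test.
"""

from __future__ import annotations

import math
from fractions import Fraction


def oracle_pseudo_cb(n_xyz, ca_xyz, c_xyz):
    """Ideal CB from the backbone frame, scalar arithmetic."""
    b = [ca_xyz[k] - n_xyz[k] for k in range(3)]
    c = [c_xyz[k] - ca_xyz[k] for k in range(3)]
    a = [
        b[1] * c[2] - b[2] * c[1],
        b[2] * c[0] - b[0] * c[2],
        b[0] * c[1] - b[1] * c[0],
    ]
    return [
        ca_xyz[k] - 0.58273431 * a[k] + 0.56802827 * b[k] - 0.54067466 * c[k]
        for k in range(3)
    ]


def brute_force_ppse(structure, pae, radius, angle, use_pae):
    """O(n^2) neighbor count per residue; returns a list of ints."""
    n = len(structure)
    ca = structure.ca_xyz
    dirs = []
    for i in range(n):
        cb = structure.cb_xyz[i]
        if any(math.isnan(v) for v in cb):
            cb = oracle_pseudo_cb(structure.n_xyz[i], ca[i], structure.c_xyz[i])
        v = [cb[k] - ca[i][k] for k in range(3)]
        norm = math.sqrt(sum(x * x for x in v)) or 1.0
        dirs.append([x / norm for x in v])
    cos_thresh = math.cos(math.radians(angle))
    counts = []
    for i in range(n):
        c = 0
        for j in range(n):
            if j == i:
                continue
            diff = [ca[j][k] - ca[i][k] for k in range(3)]
            d = math.sqrt(sum(x * x for x in diff))
            eff = d
            if use_pae:
                eff = d + max(pae.values[i][j], pae.values[j][i])
            if eff > radius:
                continue
            if angle < 180.0:
                cosang = sum(dirs[i][k] * diff[k] for k in range(3)) / d
                if cosang < cos_thresh:
                    continue
            c += 1
        counts.append(c)
    return counts


def exact_fisher_two_sided(a, b, c, d):
    """Two-sided Fisher p by exact rational enumeration over the support."""
    r1, r2, c1 = a + b, c + d, a + c
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    weights = {x: math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)}
    w_obs = weights[a]
    included = sum(
        w for w in weights.values() if w * 10**7 <= w_obs * (10**7 + 1)
    )
    return float(Fraction(included, math.comb(r1 + r2, c1)))


def closed_form_bh(pvals):
    """Benjamini-Hochberg by its textbook step-up definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj
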