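"""Neighbour-joining tree construction (Saitou & Nei).

At each step the pair (i, j) minimizing Q(i, j) = (n-2) d(i, j) - r_i -
r_j is joined (ties broken by the lexicographically lowest index pair),
with branch lengths from the standard three-point formulas. On additive
(tree-metric) distances the algorithm recovers the generating tree's
topology and branch lengths exactly. The unrooted result is serialized as
Newick with a trifurcating root.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _validate(d: np.ndarray) -> None:
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-9):
        raise ValueError("distance matrix must have a zero diagonal")


def _fmt(x: float) -> str:
    return format(float(x), ".12g")


def nj_tree(dist, labels=None) -> str:
    """Build an unrooted neighbour-joining tree; returns a Newick string.

    ``dist`` may be a pandas DataFrame (labels from its index) or an
    ndarray plus an explicit ``labels`` sequence. Requires n >= 3 taxa.
    Negative branch lengths arising from non-additive inputs are clamped
    to zero, as is conventional.
    """
    if isinstance(dist, pd.DataFrame):
        if labels is None:
            labels = list(dist.index)
        d = dist.to_numpy(dtype=float)
    else:
        d = np.asarray(dist, dtype=float)
        if labels is None:
            labels = [f"t{i + 1}" for i in range(d.shape[0])]
    _validate(d)
    n = d.shape[0]
    if n < 3:
        raise ValueError("need >= 3 taxa")
    if len(labels) != n:
        raise ValueError("labels do not match matrix size")

    nodes = [str(l) for l in labels]  # newick fragment per active node
    d = d.copy()
    active = list(range(n))

    def clamp(x: float) -> float:
        return max(x, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest index pair among ties
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if best is None or q[a, b] < q[best[0], best[1]] - 1e-12:
                    best = (a, b)
        a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        bi = clamp(0.5 * dij + (r[a] - r[b]) / (2 * (m - 2)))
        bj = clamp(dij - (0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))))
        new = f"({nodes[i]}:{_fmt(bi)},{nodes[j]}:{_fmt(bj)})"
        # distances from the new internal node to every remaining node
        new_idx = d.shape[0]
        newd = np.zeros((new_idx + 1, new_idx + 1))
        newd[:new_idx, :new_idx] = d
        for c in range(m):
            if c in (a, b):
                continue
            k = active[c]
            dk = 0.5 * (sub[a, c] + sub[b, c] - dij)
            newd[new_idx, k] = newd[k, new_idx] = dk
        d = newd
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [new_idx]

    # join the last three nodes at a single internal vertex
    i, j, k = active
    x = clamp(0.5 * (d[i, j] + d[i, k] - d[j, k]))
    y = clamp(0.5 * (d[i, j] + d[j, k] - d[i, k]))
    z = clamp(0.5 * (d[i, k] + d[j, k] - d[i, j]))
    return f"({nodes[i]}:{_fmt(x)},{nodes[j]}:{_fmt(y)},{nodes[k]}:{_fmt(z)});"
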