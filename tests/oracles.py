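"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package: Rips persistence by
full boundary-matrix reduction over GF(2) with Python sets, Higuchi
lengths by literal nested-loop evaluation of their definition, and TP_0
via scipy's minimum spanning tree.
"""

from itertools import combinations
from math import floor

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform


def brute_rips_bars(points, maxdim=2):
    """All positive-persistence bars (birth, death, dim) of the Rips
    filtration, by textbook boundary-matrix reduction.

    Enumerates every simplex up to dimension maxdim+1, sorts by
    (diameter, dimension, vertex tuple), reduces the full boundary matrix
    (columns as sets of row indices, pivot = max row), and reads bars off
    the pivot pairs.  Essential classes get death = inf.
    """
    pts = np.asarray(points, float)
    n = len(pts)
    dm = squareform(pdist(pts))
    simplices = []
    for d in range(0, maxdim + 2):
        for vs in combinations(range(n), d + 1):
            diam = max((dm[a, b] for a, b in combinations(vs, 2)), default=0.0)
            simplices.append((diam, d, vs))
    simplices.sort(key=lambda s: (s[0], s[1], s[2]))
    index = {s[2]: i for i, s in enumerate(simplices)}

    columns = []
    for diam, d, vs in simplices:
        if d == 0:
            columns.append(set())
        else:
            columns.append({index[f] for f in combinations(vs, d)})

    low_to_col = {}
    pairs = {}  # birth index -> death index
    for j, col in enumerate(columns):
        while col:
            low = max(col)
            if low in low_to_col:
                col ^= columns[low_to_col[low]]
            else:
                low_to_col[low] = j
                pairs[low] = j
                break
        columns[j] = col

    bars = []
    dead = set(pairs.values())
    for i, (diam, d, vs) in enumerate(simplices):
        if columns[i]:
            continue  # i is a death simplex, not a birth
        if i in pairs:
            j = pairs[i]
            birth, death = diam, simplices[j][0]
            if death > birth:
                bars.append((birth, death, d))
        elif i not in dead and d <= maxdim:
            bars.append((diam, np.inf, d))
    return sorted(bars, key=lambda b: (b[2], b[0], b[1]))


def mst_total_weight(points):
    """Total edge weight of the Euclidean minimum spanning tree.

    Zero-length edges (duplicate points) would be dropped by the sparse
    representation, so all off-diagonal weights are shifted by a constant
    that is subtracted from the total afterwards.
    """
    pts = np.asarray(points, float)
    n = len(pts)
    dm = squareform(pdist(pts))
    shift = 1.0 + dm.max()
    graph = dm + shift
    np.fill_diagonal(graph, 0.0)
    return float(minimum_spanning_tree(graph).sum() - (n - 1) * shift)


def higuchi_length_m_direct(x, m, k):
    """Literal evaluation of the offset-m lag-k Higuchi length."""
    x = list(map(float, x))
    T = len(x)
    n_inc = floor((T - m) / k)
    s = 0.0
    for i in range(1, n_inc + 1):
        s += abs(x[m + i * k - 1] - x[m + (i - 1) * k - 1])  # 1-based indexing
    return s * (T - 1) / (n_inc * k * k)


def higuchi_length_direct(x, k):
    return sum(higuchi_length_m_direct(x, m, k) for m in range(1, k + 1)) / k


def sierpinski_points(level=7):
    """Vertex set of the level-`level` Sierpinski triangle approximation."""
    tri = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
    pts = tri.copy()
    for _ in range(level):
        pts = np.concatenate([pts / 2 + v / 2 for v in tri])
    return np.unique(pts, axis=0)
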