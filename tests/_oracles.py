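"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a production quantity by a different route:
boundary-matrix reduction on an explicit cubical complex for persistence,
threshold sweeps with connected-component labelling for Betti numbers,
breadth-first search for distances, exhaustive search for Otsu and kNN,
and fine-grid quadrature for persistence-image masses.
"""

from __future__ import annotations

import collections

import numpy as np
from scipy import ndimage

_CROSS = ndimage.generate_binary_structure(2, 1)
_BOX = np.ones((3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# Betti numbers of the superlevel set (8-conn foreground / 4-conn background)


def betti_numbers(vals: np.ndarray, t: float) -> tuple[int, int]:
    S = vals >= t
    b0 = ndimage.label(S, structure=_BOX)[1]
    comp = np.pad(~S, 1, constant_values=True)
    b1 = ndimage.label(comp, structure=_CROSS)[1] - 1  # drop the outside
    return b0, b1


# ---------------------------------------------------------------------------
# boundary-matrix reduction on the subdivided cubical complex
#
# 8-connectivity of the superlevel set is realized by inserting one centre
# vertex per 2x2 pixel block with value equal to the block's second-largest
# corner (two diagonal corners become connected through the centre exactly
# when both are present), then triangulating each block into four
# corner-corner-centre triangles.  Cell value = min of its vertices
# (a cell enters when its last vertex does).


def _build_complex(vals: np.ndarray):
    h, w = vals.shape
    cells = []  # (value, dim, boundary cell ids)
    vid = {}
    for i in range(h):
        for j in range(w):
            vid[(i, j)] = len(cells)
            cells.append((float(vals[i, j]), 0, []))
    cid = {}
    for i in range(h - 1):
        for j in range(w - 1):
            block = [vals[i, j], vals[i, j + 1], vals[i + 1, j], vals[i + 1, j + 1]]
            second = float(np.sort(block)[-2])
            cid[(i, j)] = len(cells)
            cells.append((second, 0, []))

    def add_edge(a: int, b: int) -> int:
        value = min(cells[a][0], cells[b][0])
        cells.append((value, 1, [a, b]))
        return len(cells) - 1

    eid = {}  # side edges, keyed by sorted corner pair
    for i in range(h):
        for j in range(w):
            if j + 1 < w:
                eid[((i, j), (i, j + 1))] = add_edge(vid[(i, j)], vid[(i, j + 1)])
            if i + 1 < h:
                eid[((i, j), (i + 1, j))] = add_edge(vid[(i, j)], vid[(i + 1, j)])
    sid = {}  # spokes, keyed by (corner, block)
    for (bi, bj), c in cid.items():
        for corner in ((bi, bj), (bi, bj + 1), (bi + 1, bj), (bi + 1, bj + 1)):
            sid[(corner, (bi, bj))] = add_edge(vid[corner], c)

    for (bi, bj), _c in cid.items():
        corners = [(bi, bj), (bi, bj + 1), (bi + 1, bj + 1), (bi + 1, bj)]  # cyclic
        for k in range(4):
            p, q = corners[k], corners[(k + 1) % 4]
            e1 = eid[min(p, q), max(p, q)]
            e2 = sid[(p, (bi, bj))]
            e3 = sid[(q, (bi, bj))]
            value = min(cells[e1][0], cells[e2][0], cells[e3][0])
            cells.append((value, 2, [e1, e2, e3]))
    return cells


def euler_characteristic(vals: np.ndarray, t: float) -> int:
    """V - E + F of the superlevel complex at threshold t."""
    cells = _build_complex(vals)
    chi = 0
    for value, dim, _ in cells:
        if value >= t:
            chi += 1 if dim % 2 == 0 else -1
    return chi


def reduction_diagram(vals: np.ndarray):
    """Superlevel persistence via boundary-matrix reduction (Z/2 columns).

    Returns (finite_pairs, essential_pairs) where finite_pairs is a sorted
    list of (dim, birth, death) with birth > death and essential_pairs the
    unpaired creators (dim, birth).
    """
    cells = _build_complex(vals)
    order = sorted(range(len(cells)), key=lambda c: (-cells[c][0], cells[c][1], c))
    pos = {c: k for k, c in enumerate(order)}
    low_to_col: dict[int, int] = {}
    columns: dict[int, set[int]] = {}
    pairs = []
    creators = set()
    for k in (pos[c] for c in sorted(pos, key=lambda c: pos[c])):
        cell = order[k]
        col = {pos[b] for b in cells[cell][2]}
        while col:
            lo = max(col)
            if lo not in low_to_col:
                break
            col ^= columns[low_to_col[lo]]
        if col:
            lo = max(col)
            low_to_col[lo] = k
            columns[k] = col
            creators.discard(lo)
            birth_cell, death_cell = order[lo], cell
            dim = cells[birth_cell][1]
            birth, death = cells[birth_cell][0], cells[death_cell][0]
            if birth > death:
                pairs.append((dim, birth, death))
        else:
            creators.add(k)
    essential = sorted((cells[order[k]][1], cells[order[k]][0]) for k in creators)
    return sorted(pairs), essential


# ---------------------------------------------------------------------------
# signed Manhattan distance by breadth-first search


def bfs_signed_distance(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image).astype(bool)
    h, w = arr.shape
    if arr.all() or not arr.any():
        return np.full(arr.shape, float(w + h) * (1.0 if arr.all() else -1.0))
    out = np.zeros(arr.shape)
    for target in (True, False):
        dist = np.full(arr.shape, -1, dtype=np.int64)
        queue = collections.deque()
        for i in range(h):
            for j in range(w):
                if arr[i, j] != target:
                    dist[i, j] = 0
                    queue.append((i, j))
        while queue:
            i, j = queue.popleft()
            for ni, nj in ((i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)):
                if 0 <= ni < h and 0 <= nj < w and dist[ni, nj] < 0:
                    dist[ni, nj] = dist[i, j] + 1
                    queue.append((ni, nj))
        sign = 1.0 if target else -1.0
        mask = arr == target
        out[mask] = sign * dist[mask]
    return out


# ---------------------------------------------------------------------------
# exhaustive Otsu


def exhaustive_otsu(image: np.ndarray) -> int:
    vals = np.clip(np.rint(np.asarray(image)), 0, 255).astype(np.int64).ravel()
    n = len(vals)
    best_t, best_var = 0, -1.0
    for t in range(256):
        lower = vals[vals <= t]
        upper = vals[vals > t]
        if len(lower) == 0 or len(upper) == 0:
            continue
        w0, w1 = len(lower) / n, len(upper) / n
        var = w0 * w1 * (lower.mean() - upper.mean()) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t


# ---------------------------------------------------------------------------
# exhaustive-sort kNN density


def exhaustive_knn_density(image: np.ndarray, k: int, spacing: int) -> np.ndarray:
    arr = np.asarray(image).astype(bool)
    white = np.argwhere(arr).astype(np.float64)
    n_white = len(white)
    rows = np.arange(0, arr.shape[0], spacing)
    cols = np.arange(0, arr.shape[1], spacing)
    r_k = np.zeros((len(rows), len(cols)))
    for a, i in enumerate(rows):
        for b, j in enumerate(cols):
            d = np.sort(np.sqrt(((white - (i, j)) ** 2).sum(axis=1)))
            r_k[a, b] = d[k - 1]
    positive = r_k[r_k > 0]
    cap = positive.min() if positive.size else 1.0
    r_k = np.where(r_k > 0, r_k, cap)
    return k / (n_white * np.pi * r_k**2)


# ---------------------------------------------------------------------------
# persistence-image mass by fine-grid quadrature


def quadrature_persistence_image(points, cfg, dim: int, sub: int = 40) -> np.ndarray:
    """Midpoint-rule integration of the weighted Gaussian mixture per region."""
    mid_edges, life_edges = cfg.edges(dim)
    nr, nc = cfg.grid
    out = np.zeros((nr, nc))
    pts = [(m, l, min(max(l / cfg.weight_max, 0.0), 1.0)) for m, l in points]
    for r in range(nr):
        xs = np.linspace(mid_edges[r], mid_edges[r + 1], sub + 1)
        xm = (xs[:-1] + xs[1:]) / 2
        dx = xs[1] - xs[0]
        for c in range(nc):
            ys = np.linspace(life_edges[c], life_edges[c + 1], sub + 1)
            ym = (ys[:-1] + ys[1:]) / 2
            dy = ys[1] - ys[0]
            X, Y = np.meshgrid(xm, ym, indexing="ij")
            total = np.zeros_like(X)
            for m, l, w in pts:
                total += w * np.exp(
                    -((X - m) ** 2 + (Y - l) ** 2) / (2 * cfg.sigma**2)
                ) / (2 * np.pi * cfg.sigma**2)
            out[r, c] = total.sum() * dx * dy
    return out


# ---------------------------------------------------------------------------
# bottleneck matching feasibility


def bottleneck_leq(pairs_a, pairs_b, eps: float, slack: float = 1e-9) -> bool:
    """Can every pair be matched within L-inf eps (or to the diagonal)?"""
    import networkx as nx

    A = [tuple(p) for p in pairs_a]
    B = [tuple(p) for p in pairs_b]
    G = nx.Graph()
    left = [("a", i) for i in range(len(A))] + [("da", j) for j in range(len(B))]
    right = [("b", j) for j in range(len(B))] + [("db", i) for i in range(len(A))]
    G.add_nodes_from(left, bipartite=0)
    G.add_nodes_from(right, bipartite=1)
    tol = eps + slack
    for i, (b1, d1) in enumerate(A):
        for j, (b2, d2) in enumerate(B):
            if max(abs(b1 - b2), abs(d1 - d2)) <= tol:
                G.add_edge(("a", i), ("b", j))
        if (b1 - d1) / 2 <= tol:
            G.add_edge(("a", i), ("db", i))
    for j, (b2, d2) in enumerate(B):
        if (b2 - d2) / 2 <= tol:
            G.add_edge(("da", j), ("b", j))
    for j in range(len(B)):
        for i in range(len(A)):
            G.add_edge(("da", j), ("db", i))
    matching = nx.bipartite.maximum_matching(G, top_nodes=left)
    return len(matching) // 2 == len(left)
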