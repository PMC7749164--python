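"""Superlevel-set cubical persistent homology of 2D filtration fields.

Nodes enter the complex in decreasing filtration order.  Connected
components (dim 0) are tracked by union-find under 8-connectivity with the
elder rule; holes (dim 1) are obtained by Alexander duality as bounded
4-connected components of the complement, via a second union-find sweep in
increasing order with a virtual outside node.  Each pair carries the grid
coordinates where the feature appears (birth) and is merged/filled (death).

Zero-persistence pairs (birth == death) correspond to no superlevel set and
are not recorded.  The unique surviving component is marked essential with
the global minimum as its death sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

_COLUMNS = [
    "dim",
    "birth",
    "death",
    "birth_row",
    "birth_col",
    "death_row",
    "death_col",
    "essential",
]

# 8-neighbourhood offsets (foreground), 4-neighbourhood (complement)
_OFFSETS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_OFFSETS4 = [(-1, 0), (0, -1), (0, 1), (1, 0)]


@dataclass
class PersistenceDiagram:
    """Multiset of persistence pairs for one image/field.

    ``pairs`` is a DataFrame with columns dim, birth, death, birth_row,
    birth_col, death_row, death_col, essential.  Positions are grid-node
    indices; multiply by ``grid_spacing`` (and add ``origin``) to recover
    pixel coordinates.
    """

    pairs: pd.DataFrame
    source: str = "field"
    log_scaled: bool = False
    grid_spacing: int = 1
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.pairs.columns]
        if missing:
            raise ValueError(f"diagram missing columns {missing}")

    def subdiagram(self, dim: int, *, include_essential: bool = False) -> pd.DataFrame:
        sel = self.pairs["dim"] == dim
        if not include_essential:
            sel &= ~self.pairs["essential"]
        return self.pairs[sel]

    def betti_at(self, t: float) -> tuple[int, int]:
        """Number of components and holes alive at threshold t.

        A finite pair is alive for death < t <= birth; the essential
        component is alive for every t <= birth (its recorded death is a
        sentinel, not a disappearance).
        """
        p = self.pairs
        finite = ~p["essential"]
        alive = (p["death"] < t) & (t <= p["birth"]) & finite
        alive |= p["essential"] & (t <= p["birth"])
        b0 = int(((p["dim"] == 0) & alive).sum())
        b1 = int(((p["dim"] == 1) & alive).sum())
        return b0, b1

    def to_csv(self, path) -> None:
        out = self.pairs.rename(
            columns={
                "birth_row": "birth_y",
                "birth_col": "birth_x",
                "death_row": "death_y",
                "death_col": "death_x",
            }
        )[["dim", "birth", "death", "birth_x", "birth_y", "death_x", "death_y", "essential"]]
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "PersistenceDiagram":
        df = pd.read_csv(path).rename(
            columns={
                "birth_y": "birth_row",
                "birth_x": "birth_col",
                "death_y": "death_row",
                "death_x": "death_col",
            }
        )
        return cls(pairs=df[_COLUMNS], **kwargs)


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        parent = self.parent
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:  # path compression
            parent[x], x = root, parent[x]
        return root

    def union_into(self, child: int, new_root: int) -> None:
        self.parent[child] = new_root


def _dim0_pairs(vals: np.ndarray) -> list[tuple]:
    """0-dim superlevel pairs: union-find, 8-connectivity, elder rule."""
    h, w = vals.shape
    flat = vals.ravel()
    n = flat.size
    order = np.argsort(-flat, kind="stable")  # ties resolved row-major
    time = np.full(n, -1, dtype=np.int64)
    uf = _UnionFind(n)
    birth_val = np.empty(n)
    birth_pos = np.empty(n, dtype=np.int64)
    birth_time = np.empty(n, dtype=np.int64)
    pairs: list[tuple] = []
    for rank, p in enumerate(order):
        p = int(p)
        time[p] = rank
        birth_val[p] = flat[p]
        birth_pos[p] = p
        birth_time[p] = rank
        i, j = divmod(p, w)
        for di, dj in _OFFSETS8:
            ni, nj = i + di, j + dj
            if 0 <= ni < h and 0 <= nj < w:
                q = ni * w + nj
                if time[q] >= 0:
                    ra, rb = uf.find(p), uf.find(q)
                    if ra == rb:
                        continue
                    # elder rule: component with the larger birth survives;
                    # ties broken toward earlier insertion
                    key_a = (birth_val[ra], -birth_time[ra])
                    key_b = (birth_val[rb], -birth_time[rb])
                    elder, younger = (ra, rb) if key_a >= key_b else (rb, ra)
                    if birth_val[younger] > flat[p]:
                        pairs.append(
                            (0, birth_val[younger], flat[p],
                             int(birth_pos[younger]), p, False)
                        )
                    uf.union_into(younger, elder)
    root = uf.find(int(order[0]))
    p_min = int(order[-1])  # smallest value, last row-major among ties
    pairs.append((0, birth_val[root], flat[p_min], int(birth_pos[root]), p_min, True))
    return pairs


def _dim1_pairs(vals: np.ndarray) -> list[tuple]:
    """1-dim superlevel pairs via the complement sweep (Alexander duality).

    Complement pixels enter in increasing order under 4-connectivity; a
    virtual outside node absorbs the border.  Run backwards in filtration
    time, a merge at value v is the birth of a hole at threshold v, and a
    bounded component's minimum is the threshold at which the hole fills.
    """
    h, w = vals.shape
    flat = vals.ravel()
    n = flat.size
    outside = n
    order = np.argsort(flat, kind="stable")
    time = np.full(n + 1, -1, dtype=np.int64)
    time[outside] = -2  # pre-existing
    uf = _UnionFind(n + 1)
    comp_min = np.empty(n + 1)
    comp_min[outside] = -np.inf
    min_pos = np.full(n + 1, -1, dtype=np.int64)
    comp_time = np.empty(n + 1, dtype=np.int64)
    comp_time[outside] = -2
    pairs: list[tuple] = []
    for rank, p in enumerate(order):
        p = int(p)
        time[p] = rank
        comp_min[p] = flat[p]
        min_pos[p] = p
        comp_time[p] = rank
        i, j = divmod(p, w)
        v = flat[p]
        neighbours = []
        if i == 0 or i == h - 1 or j == 0 or j == w - 1:
            neighbours.append(outside)
        for di, dj in _OFFSETS4:
            ni, nj = i + di, j + dj
            if 0 <= ni < h and 0 <= nj < w:
                q = ni * w + nj
                if time[q] >= 0:
                    neighbours.append(q)
        for q in neighbours:
            ra, rb = uf.find(p), uf.find(q)
            if ra == rb:
                continue
            # elder = smaller minimum (fills later); outside is -inf, eldest
            key_a = (comp_min[ra], comp_time[ra])
            key_b = (comp_min[rb], comp_time[rb])
            elder, younger = (ra, rb) if key_a <= key_b else (rb, ra)
            if v > comp_min[younger]:
                pairs.append(
                    (1, v, comp_min[younger], p, int(min_pos[younger]), False)
                )
            uf.union_into(younger, elder)
    return pairs


def compute_persistence(fld) -> PersistenceDiagram:
    """Compute the 0- and 1-dim superlevel persistence diagram of a field."""
    vals = np.asarray(fld.values, dtype=np.float64)
    if not np.all(np.isfinite(vals)):
        raise ValueError("filtration field must be finite")
    h, w = vals.shape
    raw = _dim0_pairs(vals) + _dim1_pairs(vals)
    rows = []
    for dim, birth, death, bpos, dpos, essential in raw:
        bi, bj = divmod(bpos, w)
        di_, dj_ = divmod(dpos, w)
        rows.append((dim, birth, death, bi, bj, di_, dj_, essential))
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df = df.astype(
        {"dim": np.int64, "birth": np.float64, "death": np.float64,
         "birth_row": np.int64, "birth_col": np.int64,
         "death_row": np.int64, "death_col": np.int64, "essential": bool}
    )
    return PersistenceDiagram(
        pairs=df,
        source=getattr(fld, "name", "field"),
        grid_spacing=getattr(fld, "grid_spacing", 1),
        origin=getattr(fld, "origin", (0, 0)),
    )


def log_scale(diagram: PersistenceDiagram) -> PersistenceDiagram:
    """Replace birth/death by their natural logarithm (positive diagrams only).

    Intended for the kNN density filtration, whose values are strictly
    positive; signed-distance and grayscale diagrams contain non-positive
    thresholds and are refused.
    """
    if diagram.log_scaled:
        raise ValueError("diagram is already log-scaled")
    p = diagram.pairs
    if len(p) and not ((p["birth"] > 0).all() and (p["death"] > 0).all()):
        raise ValueError(
            "log scaling requires strictly positive birth/death values; "
            "keep signed-distance and grayscale diagrams on the raw scale"
        )
    out = p.copy()
    out["birth"] = np.log(out["birth"])
    out["death"] = np.log(out["death"])
    return replace(diagram, pairs=out, log_scaled=True)
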