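"""Fixed-length embeddings of persistence diagrams: region counts and persistence images.

The (mid-life, life-time) plane is partitioned into a 20x20 region grid
whose extent is fitted on the training diagrams only.  The count embedding
counts points per region; the persistence image spreads each point as an
isotropic Gaussian weighted linearly by its life-time (0 on the axis, 1 at
the maximum training life-time) and integrates the mixture over each region
in closed form.  Each homology dimension contributes one 400-entry block;
dim-0 and dim-1 blocks are concatenated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from skintopo.diagram import to_midlife_lifetime

DIMS = (0, 1)


@dataclass
class VectorizerConfig:
    """Fitted embedding settings.

    ``ranges[dim] = (mid_lo, mid_hi, life_lo, life_hi)`` is the training
    extent of each dimension's diagram; ``weight_max`` the maximum
    life-time over all training diagrams (both dims), the 1-point of the
    linear weighting.
    """

    method: str = "persistence_image"
    grid: tuple[int, int] = (20, 20)
    sigma: float = 0.1
    ranges: dict = field(default_factory=dict)
    weight_max: float = 1.0

    def __post_init__(self) -> None:
        if self.method not in ("counts", "persistence_image"):
            raise ValueError(f"unknown vectorization method {self.method!r}")
        if self.grid[0] < 1 or self.grid[1] < 1:
            raise ValueError("grid must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    def edges(self, dim: int) -> tuple[np.ndarray, np.ndarray]:
        mid_lo, mid_hi, life_lo, life_hi = self.ranges[dim]
        return (
            np.linspace(mid_lo, mid_hi, self.grid[0] + 1),
            np.linspace(life_lo, life_hi, self.grid[1] + 1),
        )

    def feature_names(self) -> list[str]:
        prefix = "pi" if self.method == "persistence_image" else "ct"
        return [
            f"{prefix}{dim}_r{r:03d}_c{c:03d}"
            for dim in DIMS
            for r in range(self.grid[0])
            for c in range(self.grid[1])
        ]

    def to_json(self) -> dict:
        return {
            "method": self.method,
            "grid": list(self.grid),
            "sigma": self.sigma,
            "ranges": {str(d): list(v) for d, v in self.ranges.items()},
            "weight_max": self.weight_max,
        }

    @classmethod
    def from_json(cls, data: dict) -> "VectorizerConfig":
        return cls(
            method=data["method"],
            grid=tuple(data["grid"]),
            sigma=data["sigma"],
            ranges={int(d): tuple(v) for d, v in data["ranges"].items()},
            weight_max=data["weight_max"],
        )


def _expand_degenerate(lo: float, hi: float) -> tuple[float, float]:
    if hi > lo:
        return lo, hi
    pad = 0.05 * max(abs(lo), 1.0)  # fixed 5% margin around a degenerate range
    return lo - pad, hi + pad


def fit_range(
    diagrams,
    *,
    method: str = "persistence_image",
    grid: tuple[int, int] = (20, 20),
    sigma: float = 0.1,
) -> VectorizerConfig:
    """Fit the region extent and weight normalizer on training diagrams.

    Ranges are fitted per homology dimension; ``weight_max`` is global.
    Fitting on the training split only and reusing the config unchanged on
    test data avoids leakage.
    """
    points = [to_midlife_lifetime(d) for d in diagrams]
    if not any(len(p) for p in points):
        raise ValueError("cannot fit a vectorizer on all-empty diagrams")
    ranges = {}
    weight_max = 0.0
    for dim in DIMS:
        mids, lifes = [], []
        for p in points:
            sel = p[p["dim"] == dim]
            mids.append(sel["mid_life"].to_numpy())
            lifes.append(sel["life_time"].to_numpy())
        mid = np.concatenate(mids)
        life = np.concatenate(lifes)
        if mid.size == 0:
            ranges[dim] = (0.0, 1.0, 0.0, 1.0)
            continue
        mid_lo, mid_hi = _expand_degenerate(float(mid.min()), float(mid.max()))
        life_lo, life_hi = _expand_degenerate(float(life.min()), float(life.max()))
        ranges[dim] = (mid_lo, mid_hi, life_lo, life_hi)
        weight_max = max(weight_max, float(life.max()))
    if weight_max <= 0:
        weight_max = 1.0
    return VectorizerConfig(
        method=method, grid=grid, sigma=sigma, ranges=ranges, weight_max=weight_max
    )


def _region_index(x: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open region index [low, high), last region closed; out-of-range clipped."""
    n = len(edges) - 1
    width = (edges[-1] - edges[0]) / n
    idx = np.floor((x - edges[0]) / width).astype(np.int64)
    return np.clip(idx, 0, n - 1)


def count_vector(diagram, cfg: VectorizerConfig) -> np.ndarray:
    """Count diagram points per region; conserves the total point count."""
    points = to_midlife_lifetime(diagram)
    blocks = []
    for dim in DIMS:
        sel = points[points["dim"] == dim]
        mid_edges, life_edges = cfg.edges(dim)
        counts = np.zeros(cfg.grid, dtype=np.float64)
        if len(sel):
            ri = _region_index(sel["mid_life"].to_numpy(), mid_edges)
            ci = _region_index(sel["life_time"].to_numpy(), life_edges)
            np.add.at(counts, (ri, ci), 1.0)
        blocks.append(counts.ravel())
    return np.concatenate(blocks)


def persistence_image(diagram, cfg: VectorizerConfig) -> np.ndarray:
    """Integrate the life-time-weighted Gaussian mixture over each region.

    Each point (m, l) contributes a Gaussian N((m, l), sigma^2 I) scaled by
    w = clip(l / weight_max, 0, 1); per-region mass is exact via separable
    Gaussian CDF differences.
    """
    points = to_midlife_lifetime(diagram)
    blocks = []
    for dim in DIMS:
        sel = points[points["dim"] == dim]
        mid_edges, life_edges = cfg.edges(dim)
        img = np.zeros(cfg.grid, dtype=np.float64)
        if len(sel):
            m = sel["mid_life"].to_numpy()[:, None]
            l = sel["life_time"].to_numpy()[:, None]
            w = np.clip(l[:, 0] / cfg.weight_max, 0.0, 1.0)
            cdf_m = norm.cdf((mid_edges[None, :] - m) / cfg.sigma)
            cdf_l = norm.cdf((life_edges[None, :] - l) / cfg.sigma)
            mass_m = np.diff(cdf_m, axis=1)  # (points, grid_rows)
            mass_l = np.diff(cdf_l, axis=1)  # (points, grid_cols)
            img = np.einsum("p,pr,pc->rc", w, mass_m, mass_l)
        blocks.append(img.ravel())
    return np.concatenate(blocks)


def vectorize_diagram(diagram, cfg: VectorizerConfig) -> np.ndarray:
    if cfg.method == "counts":
        return count_vector(diagram, cfg)
    return persistence_image(diagram, cfg)


def drop_near_zero_variance(
    matrix: np.ndarray,
    *,
    freq_cut: float = 95.0 / 5.0,
    unique_cut: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Drop constant and near-constant columns.

    A column is removed when it is constant, or when the ratio of its most
    frequent to second most frequent value exceeds ``freq_cut`` *and* the
    fraction of distinct values is below ``unique_cut`` percent — the
    documented default rule of the near-zero-variance filter used for count
    features.

    Returns the reduced matrix and the integer indices of kept columns.
    """
    X = np.asarray(matrix, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2D matrix with at least 2 rows")
    n = X.shape[0]
    keep = []
    for j in range(X.shape[1]):
        _, counts = np.unique(X[:, j], return_counts=True)
        if counts.size == 1:
            continue  # constant
        top2 = np.sort(counts)[::-1][:2]
        freq_ratio = top2[0] / top2[1]
        pct_unique = 100.0 * counts.size / n
        if freq_ratio > freq_cut and pct_unique < unique_cut:
            continue
        keep.append(j)
    keep_idx = np.asarray(keep, dtype=np.int64)
    return X[:, keep_idx], keep_idx
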