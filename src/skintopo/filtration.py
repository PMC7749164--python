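"""Filtration functions: kNN white-pixel density, signed Manhattan distance, grayscale.

Each function maps a preprocessed image to a :class:`FiltrationField`, a
real value per grid node whose *superlevel* sets (the region above a
decreasing threshold) are tracked by persistent homology.  High values mark
the sulci network (the white set after binarization); low values the crista
interiors.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree


@dataclass
class FiltrationField:
    """A real-valued function on a pixel/grid lattice, superlevel convention.

    ``values[i, j]`` is the filtration value at grid node (row i, col j);
    the node sits at pixel coordinate ``origin + grid_spacing * (i, j)``.
    """

    values: np.ndarray
    grid_spacing: int = 1
    origin: tuple[int, int] = (0, 0)
    name: str = "field"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("filtration field must be a nonempty 2D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("filtration values must be finite")
        if self.grid_spacing < 1:
            raise ValueError("grid_spacing must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def node_to_pixel(self, row, col) -> tuple:
        """Map grid-node indices back to image pixel coordinates."""
        return (
            self.origin[0] + self.grid_spacing * np.asarray(row),
            self.origin[1] + self.grid_spacing * np.asarray(col),
        )

    def to_csv(self, path) -> None:
        header = f"# filtration={self.name} grid_spacing={self.grid_spacing} origin={self.origin[0]},{self.origin[1]}\n"
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.values, delimiter=",")

    @classmethod
    def from_csv(cls, path) -> "FiltrationField":
        with open(path) as fh:
            header = fh.readline()
            meta = dict(
                item.split("=", 1) for item in header.lstrip("# ").split() if "=" in item
            )
            values = np.loadtxt(fh, delimiter=",", ndmin=2)
        oy, ox = (int(v) for v in meta.get("origin", "0,0").split(","))
        return cls(
            values=values,
            grid_spacing=int(meta.get("grid_spacing", 1)),
            origin=(oy, ox),
            name=meta.get("filtration", "field"),
        )


@dataclass(frozen=True)
class KnnConfig:
    """kNN density estimator settings: k-th neighbor and grid spacing (pixels)."""

    k: int = 100
    grid_spacing: int = 10

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.grid_spacing < 1:
            raise ValueError("grid_spacing must be >= 1")


def knn_density(image: np.ndarray, cfg: KnnConfig | None = None) -> FiltrationField:
    """Estimate white-pixel density on a coarse grid via the kth nearest white pixel.

    At each node x the Euclidean distance r_k(x) to the k-th nearest white
    pixel gives the density estimate f(x) = k / (n_white * pi * r_k(x)^2).
    Nodes coinciding with white mass (r_k = 0) are capped by substituting
    the smallest positive r_k observed on the grid, keeping the field
    finite.
    """
    cfg = cfg or KnnConfig()
    arr = np.asarray(image).astype(bool)
    white = np.argwhere(arr)
    n_white = len(white)
    if n_white < cfg.k:
        raise ValueError(
            f"kNN density needs at least k={cfg.k} white pixels, image has {n_white}"
        )
    h, w = arr.shape
    rows = np.arange(0, h, cfg.grid_spacing)
    cols = np.arange(0, w, cfg.grid_spacing)
    nodes = np.stack(
        [np.repeat(rows, len(cols)), np.tile(cols, len(rows))], axis=1
    ).astype(np.float64)
    tree = cKDTree(white.astype(np.float64))
    dist, _ = tree.query(nodes, k=cfg.k)
    r_k = dist if cfg.k == 1 else dist[:, -1]
    positive = r_k[r_k > 0]
    if positive.size == 0:
        # every node sits on white mass; any positive radius yields the same
        # constant field after capping — use one pixel
        r_k = np.ones_like(r_k)
    else:
        r_k = np.where(r_k > 0, r_k, positive.min())
    density = cfg.k / (n_white * np.pi * r_k**2)
    return FiltrationField(
        values=density.reshape(len(rows), len(cols)),
        grid_spacing=cfg.grid_spacing,
        origin=(0, 0),
        name="knn",
    )


def signed_distance(image: np.ndarray) -> FiltrationField:
    """Signed Manhattan distance to the black/white border.

    White pixels get +distance to the nearest black pixel, black pixels
    -distance to the nearest white pixel (a pixel 4-adjacent to the other
    colour gets magnitude 1).  A one-colour image has no border; the field
    is set to the sentinel +/-(width + height).
    """
    arr = np.asarray(image).astype(bool)
    if arr.size == 0:
        raise ValueError("empty raster")
    h, w = arr.shape
    if arr.all() or not arr.any():
        sentinel = float(w + h) * (1.0 if arr.all() else -1.0)
        values = np.full(arr.shape, sentinel)
    else:
        d_white = ndimage.distance_transform_cdt(arr, metric="taxicab")
        d_black = ndimage.distance_transform_cdt(~arr, metric="taxicab")
        values = d_white.astype(np.float64) - d_black.astype(np.float64)
    return FiltrationField(values=values, grid_spacing=1, origin=(0, 0), name="signed")


def grayscale_filtration(image: np.ndarray) -> FiltrationField:
    """Use raw pixel intensities (0 = black .. 255 = white) as the filtration."""
    arr = np.asarray(image, dtype=np.float64)
    return FiltrationField(values=arr, grid_spacing=1, origin=(0, 0), name="gray")


FILTRATIONS = {"knn", "signed", "gray"}


def compute_filtration(
    preprocessed: dict,
    method: str,
    knn_cfg: KnnConfig | None = None,
) -> FiltrationField:
    """Dispatch on the filtration name: ``knn``/``signed`` consume the binary
    image, ``gray`` the grayscale one."""
    if method == "knn":
        return knn_density(preprocessed["binary"], knn_cfg)
    if method == "signed":
        return signed_distance(preprocessed["binary"])
    if method == "gray":
        return grayscale_filtration(preprocessed["gray"])
    raise ValueError(f"unknown filtration {method!r}; expected one of {sorted(FILTRATIONS)}")
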