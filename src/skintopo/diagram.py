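"""Mid-life/life-time coordinates and scalar diagram summaries.

A persistence pair (birth, death) is re-expressed as its mean
(mid-life = (birth + death) / 2) and difference (life-time = birth - death).
Mid-life locates the threshold regime where a feature lives; life-time
measures its robustness.  The univariate screen uses ten per-image scalars:
mean and standard deviation of mid-life and life-time for each homology
dimension, plus the counts of components and holes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from skintopo.persistence import PersistenceDiagram

#: the ten topology summary columns, in manifest order
SUMMARY_COLUMNS = [
    "n_components",
    "n_holes",
    "mean_midlife_0",
    "sd_midlife_0",
    "mean_lifetime_0",
    "sd_lifetime_0",
    "mean_midlife_1",
    "sd_midlife_1",
    "mean_lifetime_1",
    "sd_lifetime_1",
]


def to_midlife_lifetime(
    diagram: PersistenceDiagram, *, include_essential: bool = False
) -> pd.DataFrame:
    """Map pairs to (mid_life, life_time) points, positions carried over.

    The essential component's death is a sentinel (the global minimum), so
    it is excluded by default.
    """
    p = diagram.pairs
    if not include_essential:
        p = p[~p["essential"].astype(bool)]
    out = pd.DataFrame(
        {
            "dim": p["dim"].to_numpy(),
            "mid_life": (p["birth"].to_numpy() + p["death"].to_numpy()) / 2.0,
            "life_time": p["birth"].to_numpy() - p["death"].to_numpy(),
            "birth_row": p["birth_row"].to_numpy(),
            "birth_col": p["birth_col"].to_numpy(),
            "death_row": p["death_row"].to_numpy(),
            "death_col": p["death_col"].to_numpy(),
        }
    )
    return out.reset_index(drop=True)


def _stats(x: np.ndarray) -> tuple[float, float]:
    if x.size == 0:
        return np.nan, np.nan
    if x.size == 1:
        return float(x[0]), 0.0
    return float(np.mean(x)), float(np.std(x, ddof=1))


def summarize(points: pd.DataFrame) -> dict:
    """Scalar summary of a mid-life/life-time point set.

    Uses the sample standard deviation (n-1); a singleton dimension has
    sd 0, an empty one propagates NaN.
    """
    out: dict = {}
    for dim in (0, 1):
        sel = points[points["dim"] == dim]
        mid = sel["mid_life"].to_numpy(dtype=np.float64)
        life = sel["life_time"].to_numpy(dtype=np.float64)
        out[f"mean_midlife_{dim}"], out[f"sd_midlife_{dim}"] = _stats(mid)
        out[f"mean_lifetime_{dim}"], out[f"sd_lifetime_{dim}"] = _stats(life)
    out["n_components"] = int((points["dim"] == 0).sum())
    out["n_holes"] = int((points["dim"] == 1).sum())
    return out


def summarize_diagram(diagram: PersistenceDiagram, **kwargs) -> dict:
    """Convenience: diagram -> mid-life/life-time -> scalar summary."""
    return summarize(to_midlife_lifetime(diagram, **kwargs))
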