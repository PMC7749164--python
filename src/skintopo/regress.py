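"""Univariate screening and the multivariate TEWL prediction pipeline.

The screen fits one simple linear regression of the response on each of 14
explanatory variables (four covariates plus ten topology summaries) and
adjusts the two-sided p-values with the Benjamini-Hochberg step-up.  The
prediction pipeline reduces the vectorized diagrams with PCA (components
with variance contribution > 0.01), appends age/sex/temperature/humidity,
tunes a regressor by repeated subject-grouped 10-fold cross-validation on
RMSE, predicts per image, aggregates to subjects by the median of their
images, and reports R^2/RMSE/MAE.  For tree models the impurity importances
are mapped back to persistence-diagram regions through |PCA loadings|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from statsmodels.stats.multitest import multipletests

from skintopo.diagram import SUMMARY_COLUMNS

COVARIATES = ["age", "sex", "temperature", "humidity"]
#: the 14 explanatory variables of the univariate screen
SCREEN_VARIABLES = COVARIATES + SUMMARY_COLUMNS

ALGORITHMS = (
    "random_forest",
    "svm_rbf",
    "elastic_net",
    "gb_linear",
    "gb_tree",
    "neural_net",
    "linear",
)

#: small fixed tuning grids (RMSE-selected by repeated grouped CV)
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "random_forest": [{"max_features": v} for v in (0.33, "sqrt", 1.0)],
    "svm_rbf": [{"C": c} for c in (1.0, 10.0, 100.0)],
    "elastic_net": [
        {"alpha": a, "l1_ratio": r} for a in (0.01, 0.1, 1.0) for r in (0.25, 0.5, 0.75)
    ],
    "gb_linear": [{"reg_lambda": v} for v in (0.0, 1.0)],
    "gb_tree": [{"max_depth": d} for d in (2, 4)],
    "neural_net": [
        {"hidden_layer_sizes": h, "alpha": a}
        for h in ((8,), (32,))
        for a in (1e-4, 1e-2)
    ],
    "linear": [{}],
}


def _make_estimator(algorithm: str, params: dict, seed: int):
    if algorithm == "random_forest":
        return RandomForestRegressor(
            n_estimators=200, random_state=seed, n_jobs=1, **params
        )
    if algorithm == "svm_rbf":
        return SVR(kernel="rbf", gamma="scale", **params)
    if algorithm == "elastic_net":
        return ElasticNet(max_iter=10_000, random_state=seed, **params)
    if algorithm in ("gb_linear", "gb_tree"):
        from xgboost import XGBRegressor  # heavyweight import kept local

        booster = "gblinear" if algorithm == "gb_linear" else "gbtree"
        return XGBRegressor(
            booster=booster,
            n_estimators=100,
            random_state=seed,
            verbosity=0,
            n_jobs=1,
            **params,
        )
    if algorithm == "neural_net":
        return MLPRegressor(max_iter=2000, random_state=seed, **params)
    if algorithm == "linear":
        return LinearRegression(**params)
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


# ---------------------------------------------------------------------------
# univariate screen


def univariate_screen(
    table: pd.DataFrame,
    response: str = "tewl",
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Simple linear regression of the response on each variable separately.

    Returns one row per variable with slope, t_value, two-sided p_value
    (t distribution, n-2 df) and BH false-discovery rate across the
    screened variables.  Zero-variance predictors are reported with NaN
    statistics and excluded from the FDR adjustment.
    """
    variables = variables if variables is not None else SCREEN_VARIABLES
    rows = []
    for var in variables:
        sub = table[[var, response]].dropna()
        x = sub[var].to_numpy(dtype=np.float64)
        y = sub[response].to_numpy(dtype=np.float64)
        if len(sub) < 3 or np.ptp(x) == 0:
            rows.append((var, np.nan, np.nan, np.nan, len(sub)))
            continue
        res = stats.linregress(x, y)
        t_value = res.slope / res.stderr if res.stderr > 0 else np.inf
        rows.append((var, res.slope, t_value, res.pvalue, len(sub)))
    out = pd.DataFrame(
        rows, columns=["variable", "slope", "t_value", "p_value", "n"]
    ).set_index("variable")
    out["fdr"] = np.nan
    valid = out["p_value"].notna()
    if valid.any():
        out.loc[valid, "fdr"] = multipletests(
            out.loc[valid, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    return out


# ---------------------------------------------------------------------------
# cohort splitting and PCA


def split_cohort(
    table: pd.DataFrame, train_fraction: float = 0.7, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Split *subjects* (not images) into train/test sets.

    All images of a subject end up on the same side, preventing leakage of
    within-subject texture similarity into the test metric.
    """
    subjects = np.asarray(sorted(table["subject_id"].unique()))
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(subjects))
    n_train = int(round(train_fraction * len(subjects)))
    n_train = min(max(n_train, 1), len(subjects) - 1)
    return np.sort(subjects[perm[:n_train]]), np.sort(subjects[perm[n_train:]])


@dataclass
class PcaReduction:
    """Standardize-then-PCA projection fitted on the training block."""

    scaler: StandardScaler
    pca: PCA
    n_kept: int

    @property
    def loadings(self) -> np.ndarray:
        """(n_kept, n_features) component loadings on standardized columns."""
        return self.pca.components_[: self.n_kept]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.pca.transform(self.scaler.transform(X))[:, : self.n_kept]


def pca_reduce(
    train_X: np.ndarray, test_X: np.ndarray | None = None, min_ratio: float = 0.01
) -> tuple[np.ndarray, np.ndarray | None, PcaReduction]:
    """Keep principal components whose variance contribution exceeds min_ratio.

    Columns are standardized to unit variance before the rotation (the
    persistence-image columns differ in scale by orders of magnitude); both
    the centering/scaling and the rotation are fitted on the training block
    only.  At least one component is always kept.
    """
    train_X = np.asarray(train_X, dtype=np.float64)
    if train_X.shape[0] < 2:
        raise ValueError("need at least 2 training rows for PCA")
    scaler = StandardScaler()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant columns scale to 0
        Z = scaler.fit_transform(train_X)
    pca = PCA(random_state=0)
    scores = pca.fit_transform(Z)
    n_kept = max(1, int((pca.explained_variance_ratio_ > min_ratio).sum()))
    red = PcaReduction(scaler=scaler, pca=pca, n_kept=n_kept)
    train_Z = scores[:, :n_kept]
    test_Z = red.transform(np.asarray(test_X, dtype=np.float64)) if test_X is not None else None
    return train_Z, test_Z, red


# ---------------------------------------------------------------------------
# model training


def _group_folds(
    groups: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Partition row indices into folds by (shuffled) group label."""
    uniq = np.asarray(sorted(set(groups)))
    perm = rng.permutation(len(uniq))
    folds = np.array_split(uniq[perm], n_folds)
    return [np.flatnonzero(np.isin(groups, f)) for f in folds if len(f)]


@dataclass
class FittedModel:
    algorithm: str
    estimator: object
    params: dict
    cv_rmse: pd.DataFrame
    seed: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(X), dtype=np.float64)

    @property
    def feature_importances(self) -> np.ndarray:
        imp = getattr(self.estimator, "feature_importances_", None)
        if imp is None:
            raise ValueError(
                f"{self.algorithm} exposes no impurity-based importances; "
                "permutation importance is not supported"
            )
        return np.asarray(imp, dtype=np.float64)


def train_model(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    algorithm: str = "random_forest",
    *,
    seed: int = 0,
    cv_repeats: int = 10,
    cv_folds: int = 10,
    param_grid: list[dict] | None = None,
) -> FittedModel:
    """Tune by repeated subject-grouped k-fold CV on RMSE, then refit on all rows.

    ``groups`` are subject labels; folds never split a subject.  The grid
    candidate with the lowest mean CV RMSE wins (ties toward the first
    candidate, making the choice deterministic under a fixed seed).
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    groups = np.asarray(groups)
    grid = param_grid if param_grid is not None else DEFAULT_GRIDS[algorithm]
    n_folds = min(cv_folds, len(set(groups)))
    records = []
    if len(grid) > 1 and n_folds >= 2:
        for ci, params in enumerate(grid):
            errs = []
            for rep in range(cv_repeats):
                rng = np.random.default_rng(np.random.SeedSequence([seed, 10 + rep]))
                for val_idx in _group_folds(groups, n_folds, rng):
                    train_idx = np.setdiff1d(np.arange(len(y)), val_idx)
                    est = _make_estimator(algorithm, params, seed)
                    est.fit(X[train_idx], y[train_idx])
                    pred = est.predict(X[val_idx])
                    errs.append(float(np.sqrt(np.mean((pred - y[val_idx]) ** 2))))
            records.append({"candidate": ci, **params, "rmse": float(np.mean(errs))})
        cv = pd.DataFrame(records)
        best = grid[int(cv["rmse"].idxmin())]
    else:
        best = grid[0]
        cv = pd.DataFrame([{"candidate": 0, **best, "rmse": np.nan}])
    est = _make_estimator(algorithm, best, seed)
    est.fit(X, y)
    return FittedModel(algorithm=algorithm, estimator=est, params=best, cv_rmse=cv, seed=seed)


def predict_subject(
    predictions: np.ndarray, meta: pd.DataFrame
) -> pd.DataFrame:
    """Aggregate per-image predictions to subjects by the within-session median.

    ``meta`` must align row-wise with ``predictions`` and carry
    subject_id/session plus the observed response columns; observed values
    are aggregated by median as well (they are constant within a session).
    """
    df = meta.copy()
    df["prediction"] = np.asarray(predictions, dtype=np.float64)
    keep = [c for c in df.columns if c not in ("image_index", "image_path")]
    agg = df[keep].groupby(["subject_id", "session"], as_index=False).median(numeric_only=True)
    return agg


def evaluate(predictions: np.ndarray, observations: np.ndarray) -> tuple[float, float, float]:
    """(R^2, RMSE, MAE) of predictions against observations.

    R^2 = 1 - SSE/SST; undefined (NaN) when the observations have zero
    variance.
    """
    pred = np.asarray(predictions, dtype=np.float64)
    obs = np.asarray(observations, dtype=np.float64)
    if pred.shape != obs.shape or pred.size < 2:
        raise ValueError("need at least 2 aligned prediction/observation pairs")
    resid = obs - pred
    sse = float(np.sum(resid**2))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    return r2, rmse, mae


# ---------------------------------------------------------------------------
# importance back-mapping


@dataclass
class ImportanceResult:
    """Region importances averaged over repeated splits.

    ``region`` is the normalized importance over the full concatenated
    region vector (dim-0 block then dim-1 block); ``maps[dim]`` reshapes
    each block to its 20x20 grid; ``per_repeat`` holds the per-split
    normalized vectors.
    """

    region: np.ndarray
    maps: dict
    per_repeat: np.ndarray
    covariates: dict


def region_importance(
    features: np.ndarray,
    covariates: np.ndarray,
    response: np.ndarray,
    subjects: np.ndarray,
    *,
    feature_block_index: np.ndarray | None = None,
    n_regions_total: int | None = None,
    grid: tuple[int, int] = (20, 20),
    algorithm: str = "random_forest",
    params: dict | None = None,
    use_pca: bool = True,
    min_ratio: float = 0.01,
    n_repeats: int = 10,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> ImportanceResult:
    """Average impurity importances over repeated random train/test splits.

    Each repeat redraws the subject split, refits the model on the training
    block, and reads the impurity-based feature importances.  When PCA is
    used, a region's importance is the sum over kept components of the
    component importance weighted by the |loading| of that region, then
    normalized to sum 1.  ``feature_block_index`` scatters reduced columns
    (e.g. after the near-zero-variance filter) back into the full region
    vector of length ``n_regions_total`` (default 2 * grid cells).
    """
    features = np.asarray(features, dtype=np.float64)
    covariates = np.asarray(covariates, dtype=np.float64)
    response = np.asarray(response, dtype=np.float64)
    subjects = np.asarray(subjects)
    n_cells = grid[0] * grid[1]
    total = n_regions_total if n_regions_total is not None else 2 * n_cells
    if feature_block_index is None:
        feature_block_index = np.arange(features.shape[1])
    if features.shape[1] != len(feature_block_index):
        raise ValueError("feature_block_index must match the feature columns")
    meta = pd.DataFrame({"subject_id": subjects})
    per_repeat = np.zeros((n_repeats, total))
    cov_imp = np.zeros(covariates.shape[1])
    for rep in range(n_repeats):
        train_s, _ = split_cohort(meta, train_fraction, seed=seed + rep)
        tr = np.flatnonzero(np.isin(subjects, train_s))
        Xf = features[tr]
        if use_pca:
            Z, _, red = pca_reduce(Xf, None, min_ratio)
        else:
            Z, red = Xf, None
        Xtr = np.hstack([Z, covariates[tr]])
        model = train_model(
            Xtr,
            response[tr],
            subjects[tr],
            algorithm,
            seed=seed + rep,
            param_grid=[params] if params is not None else [DEFAULT_GRIDS[algorithm][0]],
        )
        imp = model.feature_importances
        n_img = Z.shape[1]
        img_imp, cov_part = imp[:n_img], imp[n_img:]
        if red is not None:
            col_imp = np.abs(red.loadings).T @ img_imp  # (n_feature_cols,)
        else:
            col_imp = img_imp
        full = np.zeros(total)
        full[feature_block_index] = col_imp
        s = full.sum()
        if s > 0:
            full /= s
        per_repeat[rep] = full
        cov_imp += cov_part
    region = per_repeat.mean(axis=0)
    s = region.sum()
    if s > 0:
        region = region / s
    maps = {
        dim: region[dim * n_cells : (dim + 1) * n_cells].reshape(grid)
        for dim in (0, 1)
        if (dim + 1) * n_cells <= total
    }
    cov_imp /= max(n_repeats, 1)
    return ImportanceResult(
        region=region,
        maps=maps,
        per_repeat=per_repeat,
        covariates={name: float(v) for name, v in zip(COVARIATES, cov_imp)},
    )


# ---------------------------------------------------------------------------
# generator overlays


def overlay_generators(
    image: np.ndarray,
    diagram,
    region: tuple[int, int],
    cfg,
    *,
    mark_half_width: int = 3,
) -> np.ndarray:
    """Mark the generators of a diagram region on the source image.

    Birth positions of 0-dim pairs (where components appear) are drawn red,
    death positions of 1-dim pairs (where holes fill in) blue, for pairs
    whose (mid-life, life-time) falls in the selected region of the fitted
    20x20 partition.  Grid-node coordinates are scaled back to pixels by
    the diagram's grid spacing.
    """
    from skintopo.diagram import to_midlife_lifetime
    from skintopo.vectorize import _region_index

    arr = np.asarray(image)
    if arr.ndim == 2:
        rgb = np.stack([arr] * 3, axis=-1).astype(np.uint8)
    else:
        rgb = arr.astype(np.uint8).copy()
    points = to_midlife_lifetime(diagram)
    h, w = rgb.shape[:2]
    n_marks = 0
    for dim, pos_cols, colour in (
        (0, ("birth_row", "birth_col"), (255, 0, 0)),
        (1, ("death_row", "death_col"), (0, 0, 255)),
    ):
        sel = points[points["dim"] == dim]
        if not len(sel):
            continue
        mid_edges, life_edges = cfg.edges(dim)
        ri = _region_index(sel["mid_life"].to_numpy(), mid_edges)
        ci = _region_index(sel["life_time"].to_numpy(), life_edges)
        hit = sel[(ri == region[0]) & (ci == region[1])]
        for _, row in hit.iterrows():
            py = diagram.origin[0] + diagram.grid_spacing * int(row[pos_cols[0]])
            px = diagram.origin[1] + diagram.grid_spacing * int(row[pos_cols[1]])
            y0, y1 = max(0, py - mark_half_width), min(h, py + mark_half_width + 1)
            x0, x1 = max(0, px - mark_half_width), min(w, px + mark_half_width + 1)
            rgb[y0:y1, x0:x1] = colour
            n_marks += 1
    if n_marks == 0:
        warnings.warn(f"no generators fall in region {region}; returning unannotated copy")
    return rgb
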