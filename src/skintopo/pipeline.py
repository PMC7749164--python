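"""End-to-end orchestration: images -> filtration -> persistence -> features -> prediction.

Also defines :class:`RunConfig`, a flat serializable record of every knob a
run uses, written beside each run's outputs for provenance.
"""

from __future__ import annotations

import json
import time
import tomllib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from skintopo.diagram import SUMMARY_COLUMNS, summarize_diagram
from skintopo.filtration import KnnConfig, compute_filtration
from skintopo.persistence import PersistenceDiagram, compute_persistence, log_scale
from skintopo.preprocess import PreprocessConfig, load_image, preprocess_image
from skintopo.regress import (
    COVARIATES,
    evaluate,
    pca_reduce,
    predict_subject,
    split_cohort,
    train_model,
)
from skintopo.vectorize import (
    VectorizerConfig,
    drop_near_zero_variance,
    fit_range,
    vectorize_diagram,
)


@dataclass
class RunConfig:
    """Flat, diff-able record of one pipeline run."""

    filtration: str = "knn"
    knn_k: int = 100
    knn_grid_spacing: int = 10
    trim_width: int = 1400
    trim_height: int = 1200
    do_trim: bool = False
    wavelet_levels: tuple[int, ...] | None = None
    erosion_iterations: int = 0
    log_scale_knn: bool = True
    vector_method: str = "persistence_image"
    sigma: float = 0.1
    grid_rows: int = 20
    grid_cols: int = 20
    use_pca: bool = True
    pca_min_ratio: float = 0.01
    algorithm: str = "random_forest"
    response: str = "tewl"
    train_fraction: float = 0.7
    cv_repeats: int = 10
    cv_folds: int = 10
    seed: int = 0

    def preprocess_config(self) -> PreprocessConfig:
        levels = None if self.wavelet_levels is None else frozenset(self.wavelet_levels)
        return PreprocessConfig(
            trim_width=self.trim_width,
            trim_height=self.trim_height,
            wavelet_levels=levels,
            erosion_iterations=self.erosion_iterations,
        )

    def knn_config(self) -> KnnConfig:
        return KnnConfig(k=self.knn_k, grid_spacing=self.knn_grid_spacing)

    def to_toml(self, path) -> None:
        lines = []
        for key, value in asdict(self).items():
            if value is None:
                continue
            if isinstance(value, str):
                lines.append(f'{key} = "{value}"')
            elif isinstance(value, bool):
                lines.append(f"{key} = {str(value).lower()}")
            elif isinstance(value, tuple):
                lines.append(f"{key} = [{', '.join(str(v) for v in value)}]")
            else:
                lines.append(f"{key} = {value}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        data = tomllib.loads(Path(path).read_text())
        if "wavelet_levels" in data:
            data["wavelet_levels"] = tuple(data["wavelet_levels"])
        return cls(**data)


def diagram_for_image(image: np.ndarray, config: RunConfig) -> PersistenceDiagram:
    """Preprocess one raster and compute its persistence diagram."""
    pre = preprocess_image(image, config.preprocess_config(), do_trim=config.do_trim)
    fld = compute_filtration(pre, config.filtration, config.knn_config())
    dgm = compute_persistence(fld)
    if config.filtration == "knn" and config.log_scale_knn:
        dgm = log_scale(dgm)
    return dgm


def diagrams_for_cohort(images, config: RunConfig) -> list[PersistenceDiagram]:
    return [diagram_for_image(img, config) for img in images]


def summary_table(diagrams, table: pd.DataFrame) -> pd.DataFrame:
    """Cohort table extended with the ten per-image topology summaries."""
    if len(diagrams) != len(table):
        raise ValueError("one diagram per cohort row required")
    summaries = pd.DataFrame([summarize_diagram(d) for d in diagrams])[SUMMARY_COLUMNS]
    return pd.concat([table.reset_index(drop=True), summaries], axis=1)


@dataclass
class ModelReport:
    """Outcome of one train/test prediction run."""

    algorithm: str
    response: str
    r2: float
    rmse: float
    mae: float
    params: dict
    subject_predictions: pd.DataFrame
    vectorizer: VectorizerConfig
    kept_columns: np.ndarray
    n_components: int
    train_subjects: np.ndarray
    test_subjects: np.ndarray
    model: object
    pca: object

    def metrics(self) -> dict:
        return {"r2": self.r2, "rmse": self.rmse, "mae": self.mae}


def _feature_blocks(diagrams, train_idx, config: RunConfig):
    """Fit the vectorizer on training diagrams; embed all diagrams.

    Count vectors additionally pass the near-zero-variance filter (fitted
    on the training rows).  Returns (matrix, vectorizer, kept column
    indices into the full region vector).
    """
    vcfg = fit_range(
        [diagrams[i] for i in train_idx],
        method=config.vector_method,
        grid=(config.grid_rows, config.grid_cols),
        sigma=config.sigma,
    )
    X = np.stack([vectorize_diagram(d, vcfg) for d in diagrams])
    kept = np.arange(X.shape[1])
    if config.vector_method == "counts":
        _, kept = drop_near_zero_variance(X[train_idx])
        X = X[:, kept]
    return X, vcfg, kept


def run_prediction(
    diagrams,
    table: pd.DataFrame,
    config: RunConfig,
    *,
    param_grid: list[dict] | None = None,
) -> ModelReport:
    """Train and evaluate the subject-level prediction pipeline.

    Subjects are split 70/30; the vectorizer range, near-zero-variance
    filter and PCA are fitted on the training block only; the regressor is
    tuned by repeated grouped CV, predictions are aggregated per subject by
    the median of that subject's images, and R^2/RMSE/MAE are computed on
    the held-out subjects.
    """
    table = table.reset_index(drop=True)
    train_s, test_s = split_cohort(table, config.train_fraction, seed=config.seed)
    is_train = table["subject_id"].isin(train_s).to_numpy()
    train_idx = np.flatnonzero(is_train)
    test_idx = np.flatnonzero(~is_train)
    X, vcfg, kept = _feature_blocks(diagrams, train_idx, config)
    if config.use_pca:
        Ztr, Zte, red = pca_reduce(X[train_idx], X[test_idx], config.pca_min_ratio)
        n_comp = red.n_kept
    else:
        Ztr, Zte, red = X[train_idx], X[test_idx], None
        n_comp = X.shape[1]
    cov = table[COVARIATES].to_numpy(dtype=np.float64)
    Xtr = np.hstack([Ztr, cov[train_idx]])
    Xte = np.hstack([Zte, cov[test_idx]])
    y = table[config.response].to_numpy(dtype=np.float64)
    model = train_model(
        Xtr,
        y[train_idx],
        table["subject_id"].to_numpy()[train_idx],
        config.algorithm,
        seed=config.seed,
        cv_repeats=config.cv_repeats,
        cv_folds=config.cv_folds,
        param_grid=param_grid,
    )
    pred_img = model.predict(Xte)
    subj = predict_subject(
        pred_img, table.iloc[test_idx][["subject_id", "session", config.response]]
    )
    r2, rmse, mae = evaluate(
        subj["prediction"].to_numpy(), subj[config.response].to_numpy()
    )
    return ModelReport(
        algorithm=config.algorithm,
        response=config.response,
        r2=r2,
        rmse=rmse,
        mae=mae,
        params=model.params,
        subject_predictions=subj,
        vectorizer=vcfg,
        kept_columns=kept,
        n_components=n_comp,
        train_subjects=train_s,
        test_subjects=test_s,
        model=model,
        pca=red,
    )


def permutation_test(
    diagrams,
    table: pd.DataFrame,
    config: RunConfig,
    *,
    n_permutations: int = 20,
) -> dict:
    """One-sided permutation test of the held-out subject-level R^2.

    The observed pipeline R^2 is compared with the R^2 obtained after
    permuting the subject-level response across subjects (images keep
    their textures; only the response-to-subject assignment is shuffled).
    The hyperparameters chosen on the observed run are reused for the
    permuted refits.  The p-value is the plug-in estimate
    count(permuted >= observed) / n_permutations.
    """
    table = table.reset_index(drop=True)
    report = run_prediction(diagrams, table, config)
    null_r2 = []
    subjects = sorted(table["subject_id"].unique())
    resp_by_subject = (
        table.groupby("subject_id")[config.response].first().loc[subjects].to_numpy()
    )
    for b in range(n_permutations):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 100 + b]))
        permuted = dict(zip(subjects, resp_by_subject[rng.permutation(len(subjects))]))
        perm_table = table.copy()
        perm_table[config.response] = perm_table["subject_id"].map(permuted)
        perm_report = run_prediction(
            diagrams, perm_table, config, param_grid=[report.params]
        )
        null_r2.append(perm_report.r2)
    null_r2 = np.asarray(null_r2)
    p_value = float(np.mean(null_r2 >= report.r2))
    return {
        "observed_r2": report.r2,
        "null_r2": null_r2,
        "p_value": p_value,
        "report": report,
    }


def run_pipeline(config: RunConfig, images, table: pd.DataFrame, out_dir=None) -> ModelReport:
    """Execute the full pipeline on in-memory images, optionally writing artifacts.

    Stages run in order (preprocess -> filtration -> persistence ->
    vectorize -> regression); failures carry the stage name.  When
    ``out_dir`` is given, the resolved config, feature summaries, subject
    predictions and metrics are written beside each other.
    """
    timings = {}
    t0 = time.perf_counter()
    try:
        diagrams = diagrams_for_cohort(images, config)
    except Exception as exc:
        raise RuntimeError(f"stage preprocess/filtration/persistence failed: {exc}") from exc
    timings["diagrams_s"] = time.perf_counter() - t0
    t0 = time.perf_counter()
    try:
        report = run_prediction(diagrams, table, config)
    except Exception as exc:
        raise RuntimeError(f"stage regress failed: {exc}") from exc
    timings["regress_s"] = time.perf_counter() - t0
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_toml(out / "run_config.toml")
        summary_table(diagrams, table).to_csv(out / "summaries.csv", index=False)
        report.subject_predictions.to_csv(out / "subject_predictions.csv", index=False)
        payload = {
            **report.metrics(),
            "algorithm": report.algorithm,
            "response": report.response,
            "params": {k: str(v) for k, v in report.params.items()},
            "n_components": report.n_components,
            "timings": timings,
        }
        (out / "report.json").write_text(json.dumps(payload, indent=2))
        (out / "vectorizer.json").write_text(
            json.dumps(report.vectorizer.to_json(), indent=2)
        )
    return report


def load_cohort(table_path, image_root=None) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Read a cohort CSV and the images its ``image_path`` column names."""
    table = pd.read_csv(table_path)
    missing = [c for c in ("subject_id", "session", "image_path") if c not in table.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    root = Path(image_root) if image_root else Path(table_path).parent
    images = []
    absent = []
    for p in table["image_path"]:
        path = root / p
        if not path.exists():
            absent.append(str(path))
            continue
        images.append(load_image(path))
    if absent:
        raise FileNotFoundError(f"missing images: {absent}")
    return images, table
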