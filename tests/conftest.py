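"""Shared fixtures: random fields and session-scoped synthetic cohorts.

The cohort fixtures run the full image -> diagram pipeline once per session
and are shared by the statistical tests; problem sizes follow the study
conditions of the synthetic generator (half-scale frames, 3 images per
subject).
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make _oracles importable

from skintopo.pipeline import RunConfig, diagrams_for_cohort, summary_table
from skintopo.synthetic import SyntheticCohortSpec, TextureParams, generate_cohort


def small_texture_params(**kwargs) -> TextureParams:
    """Reduced frame for fast end-to-end tests."""
    defaults = dict(height=220, width=240, cell_pitch=30.0, ridge_width=6.0)
    defaults.update(kwargs)
    return TextureParams(**defaults)


def knn_run_config(**kwargs) -> RunConfig:
    """The kNN screening pipeline: wavelet levels 4-10, one erosion, log scale."""
    defaults = dict(
        filtration="knn",
        wavelet_levels=tuple(range(4, 11)),
        erosion_iterations=1,
        log_scale_knn=True,
    )
    defaults.update(kwargs)
    return RunConfig(**defaults)


@pytest.fixture(scope="session")
def screen_cohort():
    """150-image cohort (50 subjects x 3) with its topology summary table."""
    spec = SyntheticCohortSpec(n_subjects=50, seed=11)
    images, table = generate_cohort(spec)
    config = knn_run_config()
    diagrams = diagrams_for_cohort(images, config)
    return {"table": summary_table(diagrams, table), "diagrams": diagrams, "config": config}


@pytest.fixture(scope="session")
def recovery_cohort():
    """60-subject cohort for parameter recovery, plus its slope-0 twin table.

    The TEWL noise stream is independent of the image stream, so the
    slope-0 specification shares the images; only the response differs.
    """
    spec = SyntheticCohortSpec(n_subjects=60, seed=23)
    null_spec = SyntheticCohortSpec(n_subjects=60, seed=23, tewl_slope=0.0)
    images, table = generate_cohort(spec)
    _, null_table = generate_cohort(null_spec, render_images=False)
    config = knn_run_config(
        vector_method="persistence_image", sigma=0.1, algorithm="random_forest",
        use_pca=True, seed=7,
    )
    diagrams = diagrams_for_cohort(images, config)
    return {
        "table": table,
        "null_table": null_table,
        "diagrams": diagrams,
        "config": config,
    }


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
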