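"""Synthetic skin-like textures with a generative TEWL link.

Real cheek-skin micro-relief is a network of sulci (furrows) enclosing
polygonal cristae (ridges).  The generator emulates it as the Voronoi
partition of a jittered hexagonal lattice: the sulci network is drawn
bright so that Otsu binarization yields a white network whose loops enclose
the dark crista cells — the configuration in which holes of the superlevel
set correspond to cristae surrounded by sulci.  The ``jitter`` parameter
(site displacement as a fraction of the lattice pitch) controls texture
regularity and drives a simulated transepidermal water loss (TEWL):
irregular texture, high TEWL.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

#: cohort table schema (one row per image)
COHORT_COLUMNS = [
    "subject_id",
    "session",
    "image_index",
    "image_path",
    "tewl",
    "moisture_corneometer",
    "moisture_skicon",
    "age",
    "sex",
    "temperature",
    "humidity",
    "site",
    "jitter",
]


@dataclass(frozen=True)
class TextureParams:
    """Ridge-lattice texture settings.

    The frame defaults to 700x600 px, half the linear scale of a trimmed
    1400x1200 microscope frame, with the lattice pitch scaled to match.
    ``jitter`` in [0, 1] is the standard deviation of Gaussian site
    displacement as a fraction of the pitch.
    """

    height: int = 600
    width: int = 700
    cell_pitch: float = 40.0
    jitter: float = 0.3
    ridge_width: float = 6.0
    brightness_gradient: float = 30.0
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.jitter <= 1.0:
            raise ValueError("jitter must lie in [0, 1]")
        if self.cell_pitch < 4.0 * self.ridge_width:
            raise ValueError("cell_pitch must be at least 4x ridge_width")
        if self.height < 1 or self.width < 1:
            raise ValueError("frame must be at least 1x1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Cohort-level generative model.

    Per subject, a regularity parameter jitter_i ~ U(jitter_range) fixes
    the texture of all of that subject's images, and
    TEWL_i = intercept + slope * jitter_i + N(0, tewl_sd), floored at
    1 g m^-2 h^-1.  Covariates: age uniform 0-64 y, sex Bernoulli(0.5)
    coded {0: F, 1: M}, temperature/humidity narrow normals around the
    controlled test-room conditions (20 degC, 50%).
    """

    n_subjects: int = 40
    images_per_subject: int = 3
    jitter_range: tuple[float, float] = (0.05, 0.85)
    tewl_intercept: float = 8.0
    tewl_slope: float = 15.0
    tewl_sd: float = 2.0
    age_range: tuple[float, float] = (0.0, 64.0)
    temperature_mean: float = 20.0
    temperature_sd: float = 1.0
    humidity_mean: float = 50.0
    humidity_sd: float = 3.0
    texture: TextureParams = field(default_factory=TextureParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("need at least 4 subjects")
        if self.images_per_subject < 1:
            raise ValueError("need at least 1 image per subject")
        if self.tewl_sd <= 0:
            raise ValueError("tewl_sd must be > 0")
        lo, hi = self.jitter_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("jitter_range must satisfy 0 <= lo <= hi <= 1")


def _hex_sites(params: TextureParams, rng: np.random.Generator) -> np.ndarray:
    """Jittered hexagonal lattice covering the frame plus a margin."""
    pitch = params.cell_pitch
    row_step = pitch * np.sqrt(3.0) / 2.0
    margin = 2.0 * pitch
    ys = np.arange(-margin, params.height + margin, row_step)
    sites = []
    for r, y in enumerate(ys):
        offset = (pitch / 2.0) if r % 2 else 0.0
        xs = np.arange(-margin + offset, params.width + margin, pitch)
        sites.append(np.stack([np.full_like(xs, y), xs], axis=1))
    sites = np.concatenate(sites)
    sites = sites + rng.normal(0.0, params.jitter * pitch, size=sites.shape)
    return sites


def generate_texture(params: TextureParams) -> np.ndarray:
    """Render one texture frame as an 8-bit grayscale image.

    Pixels near a Voronoi boundary of the jittered lattice (difference of
    the two nearest-site distances below ``ridge_width``) are bright sulci;
    cell interiors are dark cristae.  An optional linear brightness
    gradient across the frame and Gaussian pixel noise are added, and the
    result is clipped to [0, 255].  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    sites = _hex_sites(params, rng)
    yy, xx = np.mgrid[0 : params.height, 0 : params.width]
    coords = np.stack([yy.ravel(), xx.ravel()], axis=1).astype(np.float64)
    tree = cKDTree(sites)
    dist, _ = tree.query(coords, k=2)
    ridge = (dist[:, 1] - dist[:, 0]) < params.ridge_width
    img = np.where(ridge, 210.0, 70.0).reshape(params.height, params.width)
    if params.brightness_gradient:
        img = img + np.linspace(
            -params.brightness_gradient / 2.0,
            params.brightness_gradient / 2.0,
            params.width,
        )[None, :]
    if params.noise_sd:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _texture_seed(base_seed: int, subject: int, image: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), 2, int(subject), int(image)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def generate_cohort(
    spec: SyntheticCohortSpec, *, render_images: bool = True
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Generate a synthetic cohort: one texture per image row plus its table.

    The subject stream (jitter, covariates) and the TEWL noise stream are
    seeded independently, so two specs differing only in the TEWL link
    (e.g. slope 0 vs slope > 0) produce identical images.  Returns the
    images in table row order and the cohort table; ``render_images=False``
    skips the (costly) texture rendering and returns an empty image list,
    useful when only the table of an image-identical twin spec is needed.
    """
    subj_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    tewl_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    rows = []
    images: list[np.ndarray] = []
    for si in range(spec.n_subjects):
        lo, hi = spec.jitter_range
        jitter = float(subj_rng.uniform(lo, hi))
        age = float(subj_rng.uniform(*spec.age_range))
        sex = int(subj_rng.integers(0, 2))
        temperature = float(subj_rng.normal(spec.temperature_mean, spec.temperature_sd))
        humidity = float(subj_rng.normal(spec.humidity_mean, spec.humidity_sd))
        tewl = spec.tewl_intercept + spec.tewl_slope * jitter + float(
            tewl_rng.normal(0.0, spec.tewl_sd)
        )
        tewl = max(tewl, 1.0)  # physical floor
        # moisture responds mostly to the environment, weakly to texture
        corneometer = (
            45.0 + 0.5 * (humidity - 50.0) - 3.0 * jitter + float(tewl_rng.normal(0, 4.0))
        )
        skicon = (
            150.0 + 5.0 * (humidity - 50.0) - 30.0 * jitter + float(tewl_rng.normal(0, 30.0))
        )
        for ii in range(spec.images_per_subject):
            if render_images:
                params = replace(
                    spec.texture, jitter=jitter, seed=_texture_seed(spec.seed, si, ii)
                )
                images.append(generate_texture(params))
            rows.append(
                {
                    "subject_id": f"S{si:04d}",
                    "session": 1,
                    "image_index": ii,
                    "image_path": "",
                    "tewl": tewl,
                    "moisture_corneometer": corneometer,
                    "moisture_skicon": skicon,
                    "age": age,
                    "sex": sex,
                    "temperature": temperature,
                    "humidity": humidity,
                    "site": "left_cheek",
                    "jitter": jitter,
                }
            )
    table = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    return images, table
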