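"""Image preprocessing: trim, grayscale, wavelet reconstruction, Otsu, erosion.

All functions operate on plain 2D numpy arrays.  Grayscale images hold
intensities in [0, 255]; binary images hold {0, 1} with 1 = white
(foreground).  Only :func:`trim` changes image dimensions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from PIL import Image
from scipy import ndimage

# ITU-R BT.601 luma weights, the convention of standard RGB->gray conversion.
_BT601 = np.array([0.299, 0.587, 0.114])

#: number of wavelet detail scales; level 0 is the approximation (coarsest),
#: level 10 the finest detail band.
WAVELET_DEPTH = 10


@dataclass
class PreprocessConfig:
    """Settings for the raw-image-to-binary pipeline.

    Parameters
    ----------
    trim_width, trim_height
        Size in pixels of the window cut from the top-left corner of the
        frame (removes scale bars and annotation margins).
    wavelet_levels
        Which decomposition levels (0 = coarsest approximation .. 10 =
        finest detail) to keep when reconstructing; ``None`` disables the
        wavelet step entirely.  Removing the coarse levels flattens uneven
        illumination.
    erosion_iterations
        Number of binary erosions (3x3 cross element) applied after Otsu
        thresholding; shrinks the white set to suppress thin noise.
    wavelet
        Wavelet family name understood by PyWavelets (default Haar).
    """

    trim_width: int = 1400
    trim_height: int = 1200
    wavelet_levels: frozenset[int] | None = None
    erosion_iterations: int = 0
    wavelet: str = "db1"
    wavelet_mode: str = "periodization"

    def __post_init__(self) -> None:
        if self.trim_width < 1 or self.trim_height < 1:
            raise ValueError("trim window must be at least 1x1")
        if self.wavelet_levels is not None:
            levels = frozenset(int(v) for v in self.wavelet_levels)
            if any(v < 0 or v > WAVELET_DEPTH for v in levels):
                raise ValueError(
                    f"wavelet levels must lie in 0..{WAVELET_DEPTH}, got {sorted(levels)}"
                )
            object.__setattr__(self, "wavelet_levels", levels)
        if self.erosion_iterations < 0:
            raise ValueError("erosion_iterations must be >= 0")


def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG file as an array (2D gray or 3D RGB)."""
    with Image.open(path) as img:
        if img.mode not in ("L", "RGB"):
            img = img.convert("RGB")
        return np.asarray(img)


def save_image(path, pixels: np.ndarray) -> None:
    """Write a 2D grayscale or binary raster (binary scaled to 0/255) as PNG."""
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValueError("expected a 2D raster")
    if arr.max(initial=0) <= 1:
        arr = arr * 255
    Image.fromarray(np.clip(arr, 0, 255).astype(np.uint8)).save(path)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an RGB raster to 8-bit luminance; pass gray input through.

    Uses BT.601 weights (0.299 R + 0.587 G + 0.114 B), rounded to the
    nearest integer intensity.
    """
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty raster")
    if arr.ndim == 2:
        return arr.astype(np.uint8, copy=True)
    if arr.ndim == 3 and arr.shape[2] == 3:
        lum = arr[..., :3].astype(np.float64) @ _BT601
        return np.clip(np.rint(lum), 0, 255).astype(np.uint8)
    raise ValueError(f"expected 2D gray or HxWx3 RGB raster, got shape {arr.shape}")


def trim(image: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Cut the top-left ``trim_height x trim_width`` window from the frame."""
    cfg = cfg or PreprocessConfig()
    arr = np.asarray(image)
    h, w = arr.shape[:2]
    if h < cfg.trim_height or w < cfg.trim_width:
        raise ValueError(
            f"image {h}x{w} smaller than trim window "
            f"{cfg.trim_height}x{cfg.trim_width}"
        )
    return arr[: cfg.trim_height, : cfg.trim_width].copy()


def wavelet_reconstruct(
    image: np.ndarray,
    levels,
    *,
    wavelet: str = "db1",
    mode: str = "periodization",
) -> np.ndarray:
    """Reconstruct the image from a subset of wavelet decomposition levels.

    The grayscale image is decomposed to 10 levels; level 0 is the
    approximation (coarsest), levels 1..10 the detail bands from coarsest to
    finest.  Coefficients at levels outside ``levels`` are zeroed before the
    inverse transform, and the result is clipped to [0, 255].  Dropping the
    coarse levels removes slowly-varying illumination while preserving the
    texture scales of sulci and cristae.
    """
    levels = frozenset(int(v) for v in levels)
    if any(v < 0 or v > WAVELET_DEPTH for v in levels):
        raise ValueError(f"wavelet levels must lie in 0..{WAVELET_DEPTH}")
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("expected a 2D grayscale raster")
    with warnings.catch_warnings():
        # decomposition depth is fixed at 10 regardless of frame size;
        # pywt warns when that exceeds its advisory maximum level
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec2(arr, wavelet, mode=mode, level=WAVELET_DEPTH)
    # coeffs[0] = approximation (level 0); coeffs[i] = detail bands at level i
    if 0 not in levels:
        coeffs[0] = np.zeros_like(coeffs[0])
    for i in range(1, len(coeffs)):
        if i not in levels:
            coeffs[i] = tuple(np.zeros_like(c) for c in coeffs[i])
    rec = pywt.waverec2(coeffs, wavelet, mode=mode)
    rec = rec[: arr.shape[0], : arr.shape[1]]
    return np.clip(rec, 0, 255)


def binarize_otsu(image: np.ndarray) -> tuple[np.ndarray, int]:
    """Threshold a grayscale image by Otsu's method.

    Returns the binary image (pixel > t -> 1/white) and the threshold t that
    maximizes the between-class variance of the 256-bin intensity histogram.
    Ties are broken toward the smallest maximizing threshold.  A constant
    image yields a single class (all pixels get the same label under the
    strict > rule).
    """
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty raster")
    vals = np.clip(np.rint(arr), 0, 255).astype(np.int64)
    hist = np.bincount(vals.ravel(), minlength=256).astype(np.float64)
    n = hist.sum()
    # cumulative class probability and mean for thresholds t = 0..255
    # (class 0: intensity <= t, class 1: intensity > t)
    w0 = np.cumsum(hist)
    mu = np.cumsum(hist * np.arange(256))
    mu_total = mu[-1]
    w1 = n - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu_total * w0 - n * mu) ** 2 / (w0 * w1)
    between[~np.isfinite(between)] = -1.0  # empty classes cannot maximize
    t = int(np.argmax(between))  # argmax returns the first (smallest) maximizer
    binary = (vals > t).astype(np.uint8)
    return binary, t


#: 3x3 cross (4-connected) structuring element used for erosion
CROSS = ndimage.generate_binary_structure(2, 1)


def erode(image: np.ndarray, iterations: int) -> np.ndarray:
    """Erode the white set with a 3x3 cross element, ``iterations`` times.

    Pixels outside the image are treated as black, so the white set shrinks
    at the border as well.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    arr = np.asarray(image).astype(bool)
    if iterations == 0:
        return arr.astype(np.uint8, copy=True)
    out = ndimage.binary_erosion(
        arr, structure=CROSS, iterations=iterations, border_value=0
    )
    return out.astype(np.uint8)


def preprocess_image(
    image: np.ndarray,
    cfg: PreprocessConfig | None = None,
    *,
    do_trim: bool = True,
) -> dict:
    """Run the full preprocessing chain on a raw raster.

    Returns a dict with keys ``gray`` (after optional trim + wavelet),
    ``binary`` and ``otsu_threshold``.  Binarization is always computed; the
    caller picks ``gray`` or ``binary`` depending on the filtration.
    """
    cfg = cfg or PreprocessConfig()
    gray = to_grayscale(image)
    if do_trim:
        gray = trim(gray, cfg)
    gray_f = gray.astype(np.float64)
    if cfg.wavelet_levels is not None:
        gray_f = wavelet_reconstruct(
            gray_f, cfg.wavelet_levels, wavelet=cfg.wavelet, mode=cfg.wavelet_mode
        )
    binary, t = binarize_otsu(gray_f)
    if cfg.erosion_iterations:
        binary = erode(binary, cfg.erosion_iterations)
    return {"gray": gray_f, "binary": binary, "otsu_threshold": t}
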