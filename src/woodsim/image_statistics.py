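"""Movie-level texture image statistics.

Eleven statistics per sample movie, averaged across frames: six
gray-level moments (min, max, mean, population variance, skewness,
non-excess kurtosis), one gradient-based directionality index, and the
fractions of non-DC spectral power in three radial frequency bands.
These feed the linear regressions that predict similarity dimensions and
attribute ratings from image content alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cross_mapping import RegressionResult, regress_vector
from .errors import DataError, ParameterError

STAT_NAMES = [
    "min", "max", "mean", "variance", "skewness", "kurtosis",
    "directionality", "band_low", "band_mid", "band_high",
]

GRAY_WEIGHTS = (0.2126, 0.7152, 0.0722)  # Rec. 709 luminance


@dataclass
class MovieStats:
    """The image-statistic vector of one sample movie."""

    sample: str
    n_frames: int
    min: float
    max: float
    mean: float
    variance: float
    skewness: float
    kurtosis: float
    directionality: float
    band_low: float
    band_mid: float
    band_high: float

    def vector(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in STAT_NAMES])


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Collapse an (H, W, 3) frame to luminance; pass gray frames through."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim == 3 and frame.shape[-1] == 3:
        return frame @ np.asarray(GRAY_WEIGHTS)
    if frame.ndim == 2:
        return frame
    raise DataError(f"expected a 2-D or HxWx3 frame, got shape {frame.shape}")


def frame_moments(frame: np.ndarray) -> dict[str, float]:
    """Six gray-level moments of one frame.

    Variance is the population form; skewness is m3 / m2^{3/2}; kurtosis
    is the non-excess m4 / m2^2 (3 for a Gaussian).  Constant frames
    return 0 for both shape statistics by convention.
    """
    g = to_grayscale(frame)
    if g.size == 0:
        raise DataError("empty frame")
    flat = g.ravel()
    mean = flat.mean()
    centered = flat - mean
    m2 = np.mean(centered**2)
    if m2 == 0:
        skew = kurt = 0.0  # constant frame convention
    else:
        skew = float(np.mean(centered**3) / m2**1.5)
        kurt = float(np.mean(centered**4) / m2**2)
    return {
        "min": float(flat.min()),
        "max": float(flat.max()),
        "mean": float(mean),
        "variance": float(m2),
        "skewness": skew,
        "kurtosis": kurt,
    }


def directionality(frame: np.ndarray, magnitude_threshold: float = 1e-8) -> float:
    """Orientation anisotropy of the gradient field, in [0, 1].

    Gradients are taken by central differences; each pixel contributes its
    gradient magnitude at twice its gradient angle (so opposite gradient
    directions reinforce), and the statistic is the magnitude-weighted
    resultant length |sum m e^{2i theta}| / sum m.  0 for isotropic
    texture or a flat frame, 1 for a perfectly oriented pattern.
    """
    g = to_grayscale(frame)
    gy, gx = np.gradient(g)
    mag = np.hypot(gx, gy)
    keep = mag > magnitude_threshold
    total = mag[keep].sum()
    if total == 0:
        return 0.0
    angle = np.arctan2(gy[keep], gx[keep])
    resultant = np.abs(np.sum(mag[keep] * np.exp(2j * angle)))
    return float(resultant / total)


def psd_band_energies(frame: np.ndarray) -> tuple[float, float, float]:
    """Fractions of spectral power in three radial frequency bands.

    The 2-D power spectrum is computed by FFT; the DC component and
    frequencies beyond the Nyquist radius (grid corners) are excluded;
    radial frequency (0, 0.5] cycles/pixel is split into three
    equal-width annuli and each band's share of the annulus power is
    returned (fractions sum to 1).
    """
    g = to_grayscale(frame)
    psd = np.abs(np.fft.fft2(g)) ** 2
    f = np.fft.fftfreq(g.shape[0])[:, None] ** 2 + np.fft.fftfreq(g.shape[1])[None, :] ** 2
    f = np.sqrt(f)
    edges = (0.0, 1.0 / 6.0, 1.0 / 3.0, 0.5)
    powers = []
    for b in range(3):
        mask = (f > edges[b]) & (f <= edges[b + 1])
        powers.append(psd[mask].sum())
    total = sum(powers)
    if total == 0:
        raise DataError("frame has no non-DC spectral power (constant image)")
    return tuple(p / total for p in powers)


def movie_stats(frames: np.ndarray | list, sample: str = "") -> MovieStats:
    """Per-frame statistics averaged across the frames of one movie."""
    frames = [np.asarray(f, dtype=float) for f in frames]
    if not frames:
        raise DataError("empty frame stack")
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise DataError(f"heterogeneous frame sizes: {sorted(shapes)}")
    rows = []
    for f in frames:
        moments = frame_moments(f)
        d = directionality(f)
        try:
            low, mid, high = psd_band_energies(f)
        except DataError:  # constant frame: no texture, band shares undefined
            low = mid = high = np.nan
        rows.append(
            [moments[k] for k in ("min", "max", "mean", "variance", "skewness", "kurtosis")]
            + [d, low, mid, high]
        )
    arr = np.asarray(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(arr, axis=0)
    means = np.nan_to_num(means, nan=0.0)
    return MovieStats(sample=sample, n_frames=len(frames), **dict(zip(STAT_NAMES, means)))


def stats_table(movies: dict[str, np.ndarray]) -> pd.DataFrame:
    """One row of the 10 named statistics per sample movie."""
    rows = {name: movie_stats(frames, sample=name).vector() for name, frames in movies.items()}
    return pd.DataFrame.from_dict(rows, orient="index", columns=STAT_NAMES)


def stats_regression(
    stats: pd.DataFrame, targets: pd.DataFrame, intercept: bool = True
) -> dict[str, RegressionResult]:
    """Linear regression of each target column (a similarity dimension or
    an attribute's mean ratings) on the image-statistic columns.  Emits an
    over-fitting warning when predictors reach half the item count."""
    if list(stats.index) != list(targets.index):
        raise DataError("statistics and targets must be indexed by the same samples")
    X = stats.to_numpy(dtype=float)
    if X.shape[1] >= X.shape[0] / 2:
        warnings.warn(
            f"{X.shape[1]} predictors for {X.shape[0]} samples: regression prone to over-fit",
            stacklevel=2,
        )
    results = {}
    for col in targets.columns:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results[col] = regress_vector(
                targets[col].to_numpy(dtype=float), X,
                predictor_labels=list(stats.columns), intercept=intercept,
            )
    return results
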