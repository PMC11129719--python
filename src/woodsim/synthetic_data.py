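"""Synthetic ground truth for the whole pipeline.

The study conditions being emulated: 30 wood-veneer samples judged in a
2AFC triplet similarity task (1218 balanced triplets, four repetitions,
roughly 82% repetition agreement), ten appearance attributes rated by ~45
raters on a 0-100 scale, and 60-frame grayscale movies of each rotating
sample.  The generator plants a sparse non-negative embedding, samples
triplet choices through a softmax decision rule on embedding dot products,
derives ratings as noisy linear read-outs of the embedding, and
synthesizes texture movies as spectrally shaped noise so that every image
statistic the pipeline measures is controllable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .behavioral_stats import RatingTable
from .errors import DesignError, ParameterError
from .triplet_design import TripletDesign

DEFAULT_ATTRIBUTES = [
    "brightness",
    "glossiness",
    "colorfulness",
    "directionality",
    "complexity",
    "contrast",
    "roughness",
    "regularity",
    "line_elongation",
    "spatial_scale",
]

#: Repetition-agreement level of the emulated similarity data.
TARGET_AGREEMENT = 0.82


@dataclass
class GroundTruth:
    """Planted latent structure behind one synthetic study.

    ``embedding`` is the n_items x d_true non-negative sparse loading
    matrix; ``attribute_loadings`` (d_true x n_attributes, signed) maps it
    linearly to rating attributes; ``decision_noise`` is the softmax
    temperature of the triplet decision rule; ``rating_noise_sd`` is the
    per-rating Gaussian noise SD on the 0-100 scale.
    """

    embedding: np.ndarray
    attribute_loadings: np.ndarray
    decision_noise: float
    rating_noise_sd: float
    seed: int
    attributes: list[str] = field(default_factory=lambda: list(DEFAULT_ATTRIBUTES))

    @property
    def n_items(self) -> int:
        return self.embedding.shape[0]

    @property
    def d_true(self) -> int:
        return self.embedding.shape[1]

    def similarity(self) -> np.ndarray:
        """Planted Gram similarity matrix."""
        return self.embedding @ self.embedding.T

    def with_decision_noise(self, tau: float) -> "GroundTruth":
        return replace(self, decision_noise=tau)


def gen_ground_truth(
    n_items: int,
    d_true: int,
    sparsity: float,
    seed: int,
    n_attributes: int | None = None,
    decision_noise: float = 1.0,
    rating_noise_sd: float = 10.0,
    normalize_rows: bool = True,
) -> GroundTruth:
    """Plant a sparse non-negative embedding plus attribute loadings.

    Each column has ``round(sparsity * n_items)`` zero entries (within
    one entry: rows that would end up entirely zero get one planted
    value, since a featureless item is not a meaningful stimulus); the
    non-zero entries are Exponential(1) draws.  By default rows are then
    normalized to unit length, putting every item on the unit sphere of
    the perceptual space: similarity structure then lives in the angular
    configuration, which keeps the dot-product (Gram) similarity of the
    planted embedding monotonically related to the distance-like
    similarity that attribute ratings induce — the geometry the analyses
    assume the two tasks share.  Attribute loadings are standard normal
    (signed).  Bit-reproducible given ``seed``.
    """
    if n_items < 3:
        raise ParameterError(f"n_items must be >= 3, got {n_items}")
    if not 1 <= d_true <= n_items:
        raise ParameterError(f"d_true must be in [1, n_items], got {d_true}")
    if not 0 <= sparsity < 1:
        raise ParameterError(f"sparsity must be in [0, 1), got {sparsity}")
    if decision_noise <= 0:
        raise ParameterError("decision_noise must be positive")
    if rating_noise_sd < 0:
        raise ParameterError("rating_noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n_zero = round(sparsity * n_items)
    embedding = np.zeros((n_items, d_true))
    for j in range(d_true):
        nonzero = rng.choice(n_items, size=n_items - n_zero, replace=False)
        embedding[nonzero, j] = rng.exponential(1.0, size=n_items - n_zero)
    # no item may be featureless: plant one entry in all-zero rows, spreading
    # the plants round-robin over columns so each column gains at most one
    empty_rows = np.flatnonzero(~embedding.any(axis=1))
    col_cycle = rng.permutation(d_true)
    for k, row in enumerate(empty_rows):
        embedding[row, col_cycle[k % d_true]] = rng.exponential(1.0)
    if normalize_rows:
        embedding /= np.linalg.norm(embedding, axis=1, keepdims=True)
    if n_attributes is None:
        attributes = list(DEFAULT_ATTRIBUTES)
    else:
        attributes = [f"attr_{i}" for i in range(n_attributes)]
    loadings = rng.normal(0.0, 1.0, size=(d_true, len(attributes)))
    return GroundTruth(
        embedding=embedding,
        attribute_loadings=loadings,
        decision_noise=decision_noise,
        rating_noise_sd=rating_noise_sd,
        seed=seed,
        attributes=attributes,
    )


# ---------------------------------------------------------------------------
# triplet responses
# ---------------------------------------------------------------------------


def _left_probabilities(gt: GroundTruth, trials: pd.DataFrame) -> np.ndarray:
    for col in ("target", "match_left", "match_right"):
        ids = trials[col].to_numpy(dtype=int)
        if ids.min() < 0 or ids.max() >= gt.n_items:
            raise DesignError(f"column {col} references items outside [0, {gt.n_items})")
    x = gt.embedding
    t = trials["target"].to_numpy(dtype=int)
    l = trials["match_left"].to_numpy(dtype=int)
    r = trials["match_right"].to_numpy(dtype=int)
    s_left = np.einsum("ij,ij->i", x[t], x[l])
    s_right = np.einsum("ij,ij->i", x[t], x[r])
    z = (s_left - s_right) / gt.decision_noise
    return 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))


def simulate_triplet_responses(gt, design, seed: int) -> pd.DataFrame:
    """Fill a trial table with softmax-sampled 2AFC choices.

    The probability of choosing match a over match b for target t is
    ``exp(s_ta / tau) / (exp(s_ta / tau) + exp(s_tb / tau))`` with
    ``s_ij`` the dot product of embedding rows and ``tau`` the decision
    noise.  Catch trials (target duplicated as a match) go through the
    same rule, so they are answered correctly with near certainty at low
    temperature.  ``design`` may be a :class:`TripletDesign` (one
    unswapped trial per triplet, sides randomized) or an already built
    trial table, whose response column is replaced.
    """
    rng = np.random.default_rng(seed)
    if isinstance(design, TripletDesign):
        rows = []
        for i, trip in enumerate(design.triplets):
            a, b = (trip.match_a, trip.match_b) if rng.random() < 0.5 else (trip.match_b, trip.match_a)
            rows.append(("sim", i, trip.target, a, b, 0, 0, 0, ""))
        trials = pd.DataFrame(
            rows,
            columns=[
                "participant_id",
                "trial_index",
                "target",
                "match_left",
                "match_right",
                "swapped",
                "is_catch",
                "is_practice",
                "response",
            ],
        )
    elif isinstance(design, pd.DataFrame):
        trials = design.copy()
    else:
        raise ParameterError(f"unsupported design type {type(design)!r}")
    p_left = _left_probabilities(gt, trials)
    choose_left = rng.random(len(trials)) < p_left
    trials["response"] = np.where(choose_left, "left", "right")
    return trials


def choice_probabilities(gt: GroundTruth, trials: pd.DataFrame) -> np.ndarray:
    """Closed-form p(choose left) per trial under the generator's rule."""
    return _left_probabilities(gt, trials)


def _design_left_probs(gt: GroundTruth, design: TripletDesign) -> np.ndarray:
    x = gt.embedding
    t = np.array([tr.target for tr in design.triplets])
    a = np.array([tr.match_a for tr in design.triplets])
    b = np.array([tr.match_b for tr in design.triplets])
    z = (np.einsum("ij,ij->i", x[t], x[a]) - np.einsum("ij,ij->i", x[t], x[b])) / gt.decision_noise
    return 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))


def expected_agreement(gt: GroundTruth, design: TripletDesign, reps: int = 4) -> float:
    """Closed-form expectation of the repetition-agreement statistic
    (unanimous -> 1, 3-of-4 -> 0.75, even split -> 0.5) under the softmax
    decision rule; the quantity the noise ceiling estimates."""
    if reps != 4:
        raise ParameterError("closed form implemented for reps=4")
    p = _design_left_probs(gt, design)
    q = 1.0 - p
    unanimous = p**4 + q**4
    majority3 = 4 * (p**3 * q + p * q**3)
    split2 = 6 * p**2 * q**2
    return float(np.mean(unanimous + 0.75 * majority3 + 0.5 * split2))


def expected_unanimous_fraction(gt: GroundTruth, design: TripletDesign) -> float:
    p = _design_left_probs(gt, design)
    return float(np.mean(p**4 + (1 - p) ** 4))


def bayes_accuracy(gt: GroundTruth, design: TripletDesign) -> float:
    """Expected accuracy of the ideal predictor (the generating embedding
    itself) against responses sampled at the generator's temperature."""
    p = _design_left_probs(gt, design)
    return float(np.mean(np.maximum(p, 1 - p)))


def calibrate_decision_noise(
    gt: GroundTruth,
    design: TripletDesign,
    target_agreement: float = TARGET_AGREEMENT,
    reps: int = 4,
) -> GroundTruth:
    """Bisect the softmax temperature so the expected repetition agreement
    matches ``target_agreement`` (the emulated studies ran at ~0.82).

    Expected agreement decreases monotonically in temperature from ~1
    (deterministic choices) to 0.6875 (pure chance at reps=4); targets
    outside that range are rejected.
    """
    lo, hi = 1e-6, 1e6
    f = lambda tau: expected_agreement(gt.with_decision_noise(tau), design, reps)
    if not f(lo) >= target_agreement >= f(hi):
        raise ParameterError(
            f"target agreement {target_agreement} unreachable for this ground truth"
        )
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if f(mid) > target_agreement:
            lo = mid
        else:
            hi = mid
    return gt.with_decision_noise(float(np.sqrt(lo * hi)))


# ---------------------------------------------------------------------------
# ratings
# ---------------------------------------------------------------------------


def simulate_ratings(gt: GroundTruth, n_raters: int, seed: int) -> RatingTable:
    """Ratings as noisy linear read-outs of the planted embedding.

    The true score of item i on attribute a is the dot product of the
    item's embedding row with the attribute's loading vector, affinely
    rescaled per attribute so the items span [0, 100]; each rater's rating
    adds independent N(0, rating_noise_sd^2) noise and is clipped to the
    instrument's [0, 100] scale.
    """
    if n_raters < 2:
        raise ParameterError("n_raters must be >= 2 (reliability undefined otherwise)")
    rng = np.random.default_rng(seed)
    scores = gt.embedding @ gt.attribute_loadings  # items x attributes
    lo, hi = scores.min(axis=0), scores.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    true_ratings = np.where(hi > lo, (scores - lo) / span * 100.0, 50.0)
    noise = rng.normal(0.0, gt.rating_noise_sd, size=(n_raters,) + true_ratings.shape)
    values = np.clip(true_ratings[None, :, :] + noise, 0.0, 100.0)
    return RatingTable(
        raters=[f"rater{r:02d}" for r in range(n_raters)],
        items=list(range(gt.n_items)),
        attributes=list(gt.attributes),
        values=values,
    )


# ---------------------------------------------------------------------------
# texture movies
# ---------------------------------------------------------------------------

#: Radial band edges in cycles/pixel: three equal-width annuli over (0, Nyquist].
BAND_EDGES = (0.0, 1.0 / 6.0, 1.0 / 3.0, 0.5)


def synth_texture_movie(
    mean_level: float = 0.5,
    contrast: float = 0.15,
    orientation: float = 0.0,
    directionality_strength: float = 0.0,
    band_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    n_frames: int = 60,
    size: int = 128,
    seed: int = 0,
) -> np.ndarray:
    """Filtered-noise movie with controlled image statistics.

    Frames are Gaussian noise shaped in the Fourier domain by a radial
    envelope (so the fractions of spectral energy in the low/mid/high
    bands approximate ``band_weights``) times a von-Mises orientation
    envelope on the doubled angle (anisotropy grows monotonically with
    ``directionality_strength``; 0 means isotropic).  Every frame is
    renormalized to mean ``mean_level`` and SD ``contrast`` (gray levels
    in [0, 1] units).  Frames evolve by a smooth per-frequency phase
    drift, emulating the slow sample rotation of the source movies.

    Returns an (n_frames, size, size) float array.
    """
    band_weights = np.asarray(band_weights, dtype=float)
    if band_weights.shape != (3,) or abs(band_weights.sum() - 1.0) > 1e-6:
        raise ParameterError("band_weights must be three fractions summing to 1")
    if (band_weights < 0).any():
        raise ParameterError("band_weights must be non-negative")
    if not 0 <= contrast <= 1 or not 0 <= directionality_strength <= 1:
        raise ParameterError("contrast and directionality_strength must be in [0, 1]")
    if n_frames < 1 or size < 8:
        raise ParameterError("need n_frames >= 1 and size >= 8")
    rng = np.random.default_rng(seed)

    fx = np.fft.fftfreq(size)
    fgrid = np.sqrt(fx[None, :] ** 2 + fx[:, None] ** 2)
    theta = np.arctan2(fx[:, None], fx[None, :])

    amp = np.zeros((size, size))
    for b in range(3):
        mask = (fgrid > BAND_EDGES[b]) & (fgrid <= BAND_EDGES[b + 1])
        n_bins = mask.sum()
        if n_bins:
            amp[mask] = np.sqrt(band_weights[b] / n_bins)
    kappa = 10.0 * directionality_strength / max(1e-9, 1.0 - 0.99 * directionality_strength)
    orient = np.exp(kappa * np.cos(2.0 * (theta - np.deg2rad(orientation))))
    envelope = amp * orient

    base = rng.normal(size=(size, size)) + 1j * rng.normal(size=(size, size))
    drift = rng.normal(0.0, 2.0 * np.pi / max(n_frames, 2), size=(size, size))
    frames = np.empty((n_frames, size, size))
    for t in range(n_frames):
        spec = base * envelope * np.exp(1j * t * drift)
        img = np.real(np.fft.ifft2(spec))
        sd = img.std()
        if contrast == 0.0 or sd == 0.0:
            frames[t] = mean_level
        else:
            frames[t] = (img - img.mean()) / sd * contrast + mean_level
    return frames
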