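"""Synthetic observers, ensembles, responses, and toy scrambled images.

The generator emulates a two-part valence-rating design: ``n_observers``
observers each rate ``n_images`` images on the bipolar -5..+5 scale
(Part I), then complete ``n_trials`` four-image trials whose members share
a valence sign, re-rating the cued target (Part II).  The Part II response
follows a linear pull model::

    response = snap(r1 + w * (m - r1) + eps),   eps ~ Normal(0, sigma)

where ``r1`` is the target's Part I rating, ``m`` the mean Part I rating of
the three task-irrelevant distractors, ``w`` the pull weight, and ``snap``
rounds to the nearest legal scale value (half away from zero; a raw value
rounding to the forbidden 0 maps to the nearer of -1/+1, ties to +1; the
result is clamped to [-5, +5]).

Toy gray-level images and the tile scrambler mirror the stimulus
manipulation that destroys configural content while preserving low-level
statistics: the image is cut into a ``grid x grid`` arrangement of tiles
and the tiles are rearranged by a uniformly random permutation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .datamodel import (
    LEGAL_RATINGS,
    EnsembleTrial,
    ObserverDataset,
    ValidationError,
)

__all__ = [
    "GenerativeParams",
    "snap_response",
    "generate_part1",
    "build_ensembles",
    "simulate_part2",
    "generate_observers",
    "simulate_restricted_proportions",
    "simulate_scrambled_ratings",
    "noise_for_target_correlation",
    "generate_toy_image",
    "scramble_image",
    "write_pgm",
    "DEFAULT_GRID",
]

DEFAULT_GRID = 8

_LEGAL_ARRAY = np.array(LEGAL_RATINGS)
_POSITIVE = np.array([1, 2, 3, 4, 5])
_NEGATIVE = np.array([-1, -2, -3, -4, -5])


class ConstructionError(ValueError):
    """An ensemble cannot be built from the available same-sign images."""


@dataclass(frozen=True)
class GenerativeParams:
    """Parameters of the synthetic two-part experiment.

    Attributes
    ----------
    n_observers, n_images, n_trials:
        Design sizes; defaults mirror a 50-observer, 190-image,
        200-trial experiment.
    pull_weight:
        Fraction ``w`` in [0, 1] of the target-to-ensemble difference that
        the Part II response moves toward the ensemble mean.
    response_noise_sd:
        Standard deviation of the Gaussian response noise added before
        snapping to the scale, in rating-scale units.
    rating_marginal:
        Probabilities over the 10 legal scale values, in the order
        (-5, -4, -3, -2, -1, +1, +2, +3, +4, +5); uniform by default.
    seed:
        Root seed; per-observer and per-stage streams are spawned from it.
    """

    n_observers: int = 50
    n_images: int = 190
    n_trials: int = 200
    pull_weight: float = 0.16
    response_noise_sd: float = 0.75
    rating_marginal: tuple[float, ...] = field(default=(0.1,) * 10)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pull_weight <= 1.0:
            raise ValidationError(f"pull_weight {self.pull_weight} outside [0, 1]")
        if self.response_noise_sd < 0:
            raise ValidationError("response_noise_sd must be >= 0")
        marginal = np.asarray(self.rating_marginal, dtype=float)
        if marginal.shape != (10,) or np.any(marginal < 0):
            raise ValidationError("rating_marginal must be 10 non-negative weights")
        if not np.isclose(marginal.sum(), 1.0):
            raise ValidationError(
                f"rating_marginal sums to {marginal.sum():.6f}, expected 1"
            )
        for n, name in [
            (self.n_observers, "n_observers"),
            (self.n_images, "n_images"),
            (self.n_trials, "n_trials"),
        ]:
            if n < 1:
                raise ValidationError(f"{name} must be >= 1")


def _rng(seed: int | np.random.SeedSequence | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def snap_response(raw: np.ndarray | float) -> np.ndarray | int:
    """Map raw real-valued responses onto the legal -5..+5 integer scale.

    Rounds half away from zero; a result of 0 maps to the nearer of -1/+1
    (exact ties to +1); values beyond the ends clamp to -5/+5.
    """
    raw_arr = np.asarray(raw, dtype=float)
    snapped = np.sign(raw_arr) * np.floor(np.abs(raw_arr) + 0.5)
    snapped = np.where(snapped == 0, np.where(raw_arr < 0, -1.0, 1.0), snapped)
    snapped = np.clip(snapped, -5, 5).astype(int)
    return int(snapped) if np.isscalar(raw) else snapped


# ---------------------------------------------------------------------------
# Part I: independent ratings
# ---------------------------------------------------------------------------

def generate_part1(params: GenerativeParams) -> list[ObserverDataset]:
    """Draw each observer's Part I ratings i.i.d. from the rating marginal.

    Image ids are ``img000..`` and shared across observers; observer ids are
    ``obs00..``.  Deterministic given ``params.seed``.
    """
    image_ids = [f"img{i:03d}" for i in range(params.n_images)]
    marginal = np.asarray(params.rating_marginal, dtype=float)
    observers = []
    for i, child in enumerate(
        np.random.SeedSequence(params.seed).spawn(params.n_observers)
    ):
        rng = np.random.default_rng(child)
        ratings = rng.choice(_LEGAL_ARRAY, size=params.n_images, p=marginal)
        observers.append(
            ObserverDataset(
                observer_id=f"obs{i:02d}",
                part1={img: int(r) for img, r in zip(image_ids, ratings)},
            )
        )
    return observers


# ---------------------------------------------------------------------------
# Part II: ensemble construction and the pull model
# ---------------------------------------------------------------------------

def build_ensembles(
    observer: ObserverDataset,
    n_trials: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
    condition: str = "upright",
    side: str = "both",
) -> ObserverDataset:
    """Append ``n_trials`` valence-homogeneous four-image trials to ``observer``.

    Per trial: a valence side is drawn by fair coin (when ``side="both"`` and
    both sides have at least 4 rated images; otherwise the feasible side is
    used), 4 distinct images are sampled without replacement from that side,
    and the target is cued uniformly among the 4.  ``part2_rating`` is set to
    the target's Part I rating as a placeholder until
    :func:`simulate_part2` fills in responses.

    Raises
    ------
    ConstructionError
        If no requested side holds at least 4 same-sign images.
    """
    rng = _rng(seed)
    positive = [i for i, r in observer.part1.items() if r > 0]
    negative = [i for i, r in observer.part1.items() if r < 0]
    pools = {"positive": positive, "negative": negative}
    if side == "both":
        feasible = [s for s in ("positive", "negative") if len(pools[s]) >= 4]
        if not feasible:
            raise ConstructionError(
                f"observer {observer.observer_id}: no valence side has >= 4 images"
            )
    else:
        if len(pools[side]) < 4:
            raise ConstructionError(
                f"observer {observer.observer_id}: only {len(pools[side])} "
                f"{side} images, need >= 4"
            )
        feasible = [side]

    next_id = max((t.trial_id for t in observer.trials), default=-1) + 1
    for k in range(n_trials):
        chosen = feasible[0] if len(feasible) == 1 else ("positive", "negative")[
            rng.integers(2)
        ]
        pool = pools[chosen]
        picks = rng.choice(len(pool), size=4, replace=False)
        images = [pool[j] for j in picks]
        target_idx = rng.integers(4)
        target = images[target_idx]
        distractors = tuple(img for j, img in enumerate(images) if j != target_idx)
        observer.trials.append(
            EnsembleTrial(
                trial_id=next_id + k,
                target_id=target,
                distractor_ids=distractors,  # type: ignore[arg-type]
                condition=condition,
                part2_rating=observer.part1[target],
            )
        )
    return observer


def simulate_part2(
    observer: ObserverDataset,
    params: GenerativeParams,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> ObserverDataset:
    """Fill each trial's Part II response from the linear pull model."""
    rng = _rng(seed)
    w, sigma = params.pull_weight, params.response_noise_sd
    new_trials = []
    for trial in observer.trials:
        r1 = observer.part1[trial.target_id]
        m = np.mean([observer.part1[d] for d in trial.distractor_ids])
        raw = r1 + w * (m - r1) + rng.normal(0.0, sigma)
        new_trials.append(
            dataclasses.replace(trial, part2_rating=snap_response(float(raw)))
        )
    observer.trials = new_trials
    return observer


def generate_observers(
    params: GenerativeParams, condition: str = "upright"
) -> list[ObserverDataset]:
    """Run the full generator: Part I ratings, ensembles, Part II responses.

    One root seed fans out to independent per-observer, per-stage streams,
    so the output is bit-reproducible and observers are independent.
    """
    observers = generate_part1(params)
    for i, obs in enumerate(observers):
        build_ensembles(
            obs,
            params.n_trials,
            np.random.SeedSequence(params.seed, spawn_key=(1, i)),
            condition=condition,
        )
        simulate_part2(obs, params, np.random.SeedSequence(params.seed, spawn_key=(2, i)))
    return observers


# ---------------------------------------------------------------------------
# Fast restricted-skeleton simulation (for calibration studies)
# ---------------------------------------------------------------------------

# pmf of the mean of 3 i.i.d. uniform draws from {1..5}, conditional on the
# restricted inclusion rule |m - 3| > 0.5 (sum <= 7 or >= 11); counts /125
_TRIPLE_SUMS = np.array([3, 4, 5, 6, 7, 11, 12, 13, 14, 15])
_TRIPLE_COUNTS = np.array([1, 3, 6, 10, 15, 15, 10, 6, 3, 1], dtype=float)
_TRIPLE_P = _TRIPLE_COUNTS / _TRIPLE_COUNTS.sum()


def simulate_restricted_proportions(
    n_experiments: int,
    n_observers: int,
    n_trials: int,
    pull_weight: float,
    response_noise_sd: float,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> np.ndarray:
    """Toward-proportions for restricted-analysis trials, fully vectorized.

    Draws, for every observer, ``n_trials`` included restricted trials
    (target Part I rating exactly +-3; ensemble mean the average of three
    same-sign uniform ratings, conditioned on differing from the target by
    more than 0.5) and Part II responses from the pull model, then returns
    the per-observer proportion of trials shifted toward the ensemble,
    shape ``(n_experiments, n_observers)``.

    Equivalent in distribution to running the full object-level generator
    and restricted bias analysis, but suitable for thousands of replicate
    experiments (used for type-I-error calibration).
    """
    rng = _rng(seed)
    shape = (n_experiments, n_observers, n_trials)
    # work on the +3 side; the -3 side is its mirror image
    m = rng.choice(_TRIPLE_SUMS / 3.0, size=shape, p=_TRIPLE_P)
    raw = 3.0 + pull_weight * (m - 3.0) + rng.normal(0.0, response_noise_sd, shape)
    # toward the ensemble = response crosses the first rounding boundary
    # on the ensemble's side of the target (+3): >= 3.5 above, < 2.5 below
    toward = np.where(m > 3.0, raw >= 3.5, raw < 2.5)
    return toward.mean(axis=2)


# ---------------------------------------------------------------------------
# Emulated scrambled-image ratings (for the correlation analysis stage)
# ---------------------------------------------------------------------------

def simulate_scrambled_ratings(
    mean_ratings: np.ndarray,
    attenuation: float,
    noise_sd: float,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> np.ndarray:
    """Emulate per-image mean ratings of scrambled versions of the stimuli.

    ``scrambled_i = attenuation * mean_ratings_i + eps_i`` with Gaussian
    noise: scrambling retains a fraction of each image's valence signal.
    """
    if not 0.0 <= attenuation <= 1.0:
        raise ValidationError(f"attenuation {attenuation} outside [0, 1]")
    rng = _rng(seed)
    x = np.asarray(mean_ratings, dtype=float)
    return attenuation * x + rng.normal(0.0, noise_sd, x.shape)


def noise_for_target_correlation(
    mean_ratings: np.ndarray, attenuation: float, target_r: float
) -> float:
    """Noise level giving an expected original-scrambled Pearson correlation.

    From ``r = a*sigma_x / sqrt(a^2 sigma_x^2 + sigma_eps^2)`` solved for
    ``sigma_eps`` at the empirical sigma_x of ``mean_ratings``.
    """
    if not 0.0 < target_r <= 1.0:
        raise ValidationError("target_r must be in (0, 1]")
    sigma_x = float(np.std(np.asarray(mean_ratings, dtype=float)))
    return attenuation * sigma_x * np.sqrt(1.0 / target_r**2 - 1.0)


# ---------------------------------------------------------------------------
# Toy images and the tile scrambler
# ---------------------------------------------------------------------------

def _check_divisible(height: int, width: int, grid: int) -> None:
    if height % grid or width % grid:
        raise ValidationError(
            f"image dimensions {height}x{width} not divisible by grid size {grid}"
        )


def generate_toy_image(
    seed: int | np.random.SeedSequence | np.random.Generator,
    height: int = 64,
    width: int = 64,
    grid: int = DEFAULT_GRID,
) -> np.ndarray:
    """A deterministic pseudo-random gray-level image (uint8, H x W)."""
    _check_divisible(height, width, grid)
    rng = _rng(seed)
    return rng.integers(0, 256, size=(height, width), dtype=np.uint8)


def scramble_image(
    img: np.ndarray,
    grid: int = DEFAULT_GRID,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
    permutation: np.ndarray | None = None,
) -> np.ndarray:
    """Cut ``img`` into ``grid x grid`` tiles and rearrange them randomly.

    The permutation of the ``grid**2`` tile positions is drawn uniformly
    from ``seed`` unless an explicit ``permutation`` is given.  The pixel
    multiset is conserved exactly.
    """
    img = np.asarray(img)
    height, width = img.shape
    _check_divisible(height, width, grid)
    if permutation is None:
        if seed is None:
            raise ValidationError("either seed or permutation must be given")
        permutation = _rng(seed).permutation(grid * grid)
    permutation = np.asarray(permutation)
    if sorted(permutation.tolist()) != list(range(grid * grid)):
        raise ValidationError("permutation must reorder all tile positions")
    th, tw = height // grid, width // grid
    # (grid, grid, th, tw) tile stack, reordered, then reassembled
    tiles = img.reshape(grid, th, grid, tw).transpose(0, 2, 1, 3).reshape(-1, th, tw)
    tiles = tiles[permutation]
    return (
        tiles.reshape(grid, grid, th, tw).transpose(0, 2, 1, 3).reshape(height, width)
    )


def write_pgm(img: np.ndarray, path) -> None:
    """Write a gray-level image as binary PGM (portable graymap, P5)."""
    Image.fromarray(np.asarray(img, dtype=np.uint8), mode="L").save(path, format="PPM")
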