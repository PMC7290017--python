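"""Toward-the-ensemble bias statistics.

The primary dependent measure: for each observer, the proportion of
included Part II trials on which the re-rating of the cued image moved in
the direction of the mean Part I rating of the three task-irrelevant
distractors (the "irrelevant ensemble").

Conventions, fixed throughout:

* Inclusion ("full" mode): the ensemble mean must differ from the target's
  Part I rating by strictly more than 0.5, so a one-step shift toward it is
  meaningful.  "Restricted" mode additionally keeps only trials whose
  Part I target rating is exactly +-3 (the midpoint of each half-scale),
  removing the response-range artifact that inflates the full-mode chance
  level.
* Unchanged ratings (r2 == r1) count as not-toward but stay in the
  denominator.  Under uniform random responding this makes the restricted
  chance level exactly 45%.
* Group aggregation is per-observer proportion first, then across
  observers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datamodel import (
    LEGAL_RATINGS,
    BiasSummary,
    ChanceEstimate,
    EnsembleTrial,
    ObserverDataset,
    ReferentialIntegrityError,
    UndefinedSummaryError,
    ValidationError,
)

__all__ = [
    "Mode",
    "PullMagnitude",
    "SamplingNullResult",
    "ensemble_mean",
    "include_trial",
    "shift_direction",
    "trial_table",
    "observer_bias",
    "bias_table",
    "make_restricted_skeletons",
    "monte_carlo_chance",
    "exact_chance",
    "analytic_chance_restricted",
    "pull_model_chance",
    "single_item_null",
    "pull_magnitude",
    "pull_percentage",
    "memory_consistency",
    "estimate_pull_weight",
]

Mode = Literal["full", "restricted"]
_LEGAL_ARRAY = np.array(LEGAL_RATINGS)


@dataclass(frozen=True)
class PullMagnitude:
    """Magnitude of the pull, expressed as a fraction of the maximum possible.

    ``mean_available_diff`` is the mean absolute difference between the
    ensemble mean and the target's Part I rating; ``mean_shift`` the mean
    Part I -> Part II shift signed toward the ensemble; ``pct_of_max``
    their ratio in percent (100% would mean reporting the ensemble mean
    instead of the target).
    """

    mean_available_diff: float
    mean_shift: float
    n_trials: int

    @property
    def pct_of_max(self) -> float:
        return 100.0 * self.mean_shift / self.mean_available_diff


@dataclass(frozen=True)
class SamplingNullResult:
    """Single-item resampling null for one observer."""

    observer_id: str
    n_iterations: int
    mean_proportion: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_proportion <= 1.0:
            raise ValidationError("mean_proportion outside [0, 1]")


# ---------------------------------------------------------------------------
# Per-trial primitives
# ---------------------------------------------------------------------------

def ensemble_mean(trial: EnsembleTrial, part1: dict[str, int]) -> float:
    """Mean Part I rating of the three distractors (the target is excluded)."""
    try:
        return float(np.mean([part1[d] for d in trial.distractor_ids]))
    except KeyError as exc:
        raise ReferentialIntegrityError(
            f"trial {trial.trial_id}: distractor {exc.args[0]!r} has no Part I rating"
        ) from None


def include_trial(
    trial: EnsembleTrial, part1: dict[str, int], mode: Mode = "full"
) -> bool:
    """Inclusion filter: |m - r1| > 0.5, plus |r1| == 3 in restricted mode."""
    _check_mode(mode)
    r1 = part1[trial.target_id]
    if mode == "restricted" and abs(r1) != 3:
        return False
    return abs(ensemble_mean(trial, part1) - r1) > 0.5


def shift_direction(r1: int, r2: int, m: float) -> str:
    """Classify the Part I -> Part II shift relative to the ensemble mean.

    Returns ``"toward"`` if the rating moved to the ensemble's side of the
    original rating, ``"away"`` if it moved the other way, ``"none"`` if
    unchanged.
    """
    if r2 == r1:
        return "none"
    return "toward" if np.sign(r2 - r1) == np.sign(m - r1) else "away"


def trial_table(observer: ObserverDataset, mode: Mode = "full") -> pd.DataFrame:
    """Per-trial analysis frame: r1, r2, ensemble mean, inclusion, direction."""
    _check_mode(mode)
    rows = []
    for trial in observer.trials:
        r1 = observer.part1[trial.target_id]
        r2 = trial.part2_rating
        m = ensemble_mean(trial, observer.part1)
        included = include_trial(trial, observer.part1, mode)
        rows.append(
            {
                "trial_id": trial.trial_id,
                "r1": r1,
                "r2": r2,
                "m": m,
                "included": included,
                "direction": shift_direction(r1, r2, m) if included else "",
            }
        )
    return pd.DataFrame(
        rows, columns=["trial_id", "r1", "r2", "m", "included", "direction"]
    )


# ---------------------------------------------------------------------------
# Per-observer and group bias
# ---------------------------------------------------------------------------

def observer_bias(observer: ObserverDataset, mode: Mode = "full") -> BiasSummary:
    """Toward-the-ensemble proportion over this observer's included trials.

    Raises
    ------
    UndefinedSummaryError
        If no trial passes the inclusion filter.
    """
    table = trial_table(observer, mode)
    included = table[table["included"]]
    if included.empty:
        raise UndefinedSummaryError(
            f"observer {observer.observer_id}: no trials passed the "
            f"{mode}-mode inclusion filter"
        )
    return BiasSummary(
        observer_id=observer.observer_id,
        n_included=len(included),
        n_toward=int((included["direction"] == "toward").sum()),
    )


def bias_table(
    observers: Iterable[ObserverDataset], mode: Mode = "full"
) -> tuple[pd.DataFrame, list[str]]:
    """Per-observer bias summaries as a frame, plus ids of flagged observers.

    Observers with zero included trials are flagged and excluded from the
    frame (and hence from group-level tests).
    """
    rows, flagged = [], []
    for obs in observers:
        try:
            summary = observer_bias(obs, mode)
        except UndefinedSummaryError:
            flagged.append(obs.observer_id)
            continue
        rows.append(
            {
                "observer_id": summary.observer_id,
                "mode": mode,
                "n_included": summary.n_included,
                "n_toward": summary.n_toward,
                "proportion": summary.proportion,
            }
        )
    columns = ["observer_id", "mode", "n_included", "n_toward", "proportion"]
    return pd.DataFrame(rows, columns=columns), flagged


# ---------------------------------------------------------------------------
# Chance levels
# ---------------------------------------------------------------------------

def make_restricted_skeletons(
    n_trials: int = 20,
    seed: int | np.random.SeedSequence | np.random.Generator | None = 0,
) -> list[tuple[int, float]]:
    """Balanced restricted-analysis trial skeletons ``(r1, m)``.

    Targets alternate between +3 and -3; ensemble means sit above/below the
    target with exactly equal frequency (``n_trials`` must be even), are
    means of three same-sign ratings, and always pass the 0.5 inclusion
    rule.  Used to probe chance levels free of response-range artifacts.
    """
    if n_trials % 2:
        raise ValidationError("n_trials must be even for a balanced skeleton")
    rng = np.random.default_rng(seed)
    # legal triple-means above/below +3 by more than 0.5 (sums of 3 in 1..5)
    above = np.arange(11, 16) / 3.0
    below = np.arange(3, 8) / 3.0
    skeletons = []
    for i in range(n_trials):
        sign = 1 if i % 2 == 0 else -1
        pool = above if (i // 2) % 2 == 0 else below
        m = float(rng.choice(pool))
        skeletons.append((3 * sign, m * sign))
    return skeletons


def _toward_counts(skeletons: Sequence[tuple[int, float]], mode: Mode) -> np.ndarray:
    """Per included trial, how many of the 10 legal responses count as toward."""
    counts = []
    for r1, m in skeletons:
        if mode == "restricted" and abs(r1) != 3:
            continue
        if abs(m - r1) <= 0.5:
            continue
        side = np.sign(m - r1)
        counts.append(int(np.sum(np.sign(_LEGAL_ARRAY - r1) == side)))
    if not counts:
        raise ValidationError("no skeleton trial passes the inclusion filter")
    return np.array(counts)


def monte_carlo_chance(
    skeletons: Sequence[tuple[int, float]] | Sequence[Sequence[tuple[int, float]]],
    mode: Mode = "restricted",
    n_sim: int = 10_000,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> ChanceEstimate:
    """Chance bias level of random responders, by Monte-Carlo simulation.

    ``skeletons`` is either one trial design (a sequence of ``(r1, m)``
    pairs) or one design per real observer; each of the ``n_sim`` simulated
    observers takes a design (cycling through them) and answers every
    included trial uniformly at random over the 10 legal scale values.  The
    returned level is the mean simulated toward-proportion.
    """
    _check_mode(mode)
    designs = _as_designs(skeletons)
    rng = np.random.default_rng(seed)
    counts_per_design = [_toward_counts(d, mode) for d in designs]
    per_design_sims = [
        (n_sim - k + len(designs) - 1) // len(designs) for k in range(len(designs))
    ]
    total = 0.0
    for counts, reps in zip(counts_per_design, per_design_sims):
        if reps == 0:
            continue
        # uniform response over 10 values -> toward with prob counts/10 per trial
        draws = rng.integers(0, 10, size=(reps, counts.size))
        total += (draws < counts).mean(axis=1).sum()
    seed_repr = seed if isinstance(seed, (int, np.integer)) else None
    return ChanceEstimate(
        level=total / n_sim, n_sim=n_sim, seed=seed_repr, mode=mode
    )


def exact_chance(
    skeletons: Sequence[tuple[int, float]] | Sequence[Sequence[tuple[int, float]]],
    mode: Mode = "restricted",
) -> ChanceEstimate:
    """Exact expectation of the random-responder chance level.

    Enumerates the 10 equiprobable responses per included trial; the
    Monte-Carlo estimate converges to this as ``n_sim`` grows.
    """
    _check_mode(mode)
    designs = _as_designs(skeletons)
    levels = [float(np.mean(_toward_counts(d, mode) / 10.0)) for d in designs]
    return ChanceEstimate(
        level=float(np.mean(levels)), n_sim=0, seed=None, mode=mode
    )


def analytic_chance_restricted(p_above: float = 0.5) -> float:
    """Closed-form restricted chance level under uniform random responding.

    With the target at +-3, a uniform response lands toward an ensemble
    mean above the target on 2 of the 10 scale values (+4, +5) and toward
    one below on 7 of 10; with ``p_above`` the above-fraction the level is
    ``p_above * 0.2 + (1 - p_above) * 0.7`` — 0.45 for a balanced design.
    """
    if not 0.0 <= p_above <= 1.0:
        raise ValidationError("p_above outside [0, 1]")
    return (2.0 * p_above + 7.0 * (1.0 - p_above)) / 10.0


def _snap_probabilities(mu: float, sigma: float) -> np.ndarray:
    """P(snap(mu + eps) = v) for the 10 legal v, with eps ~ Normal(0, sigma)."""
    # raw-value bin edges for (-5, -4, ..., -1, +1, ..., +5); the -1/+1 bins
    # absorb the forbidden 0 (nearer-of-+-1 rule), the end bins the clamp
    edges = np.array(
        [-np.inf, -4.5, -3.5, -2.5, -1.5, 0.0, 1.5, 2.5, 3.5, 4.5, np.inf]
    )
    cdf = norm.cdf(edges, loc=mu, scale=sigma)
    return np.diff(cdf)


def pull_model_chance(
    response_noise_sd: float,
    mode: Mode = "restricted",
    skeletons: Sequence[tuple[int, float]] | None = None,
) -> ChanceEstimate:
    """Chance level matched to the pull response model with no pull (w = 0).

    This is the no-bias reference for data whose responses follow
    ``snap(r1 + eps)``: unlike the uniform random responder (45% in the
    restricted analysis), a w = 0 responder mostly repeats its Part I
    rating, so its toward-proportion is ``Phi(-0.5 / sigma)`` per
    restricted trial — exactly, since with the target at +-3 any crossing
    of the first rounding boundary on the ensemble's side is a toward
    response.  For arbitrary skeletons the level is computed from the
    snap-bin Gaussian probabilities.
    """
    _check_mode(mode)
    if response_noise_sd <= 0:
        raise ValidationError("response_noise_sd must be > 0 for a chance level")
    if skeletons is None:
        if mode != "restricted":
            raise ValidationError("full-mode chance requires explicit skeletons")
        level = float(norm.sf(0.5 / response_noise_sd))
    else:
        probs = []
        for r1, m in skeletons:
            if mode == "restricted" and abs(r1) != 3:
                continue
            if abs(m - r1) <= 0.5:
                continue
            p = _snap_probabilities(r1, response_noise_sd)
            side = np.sign(m - r1)
            probs.append(float(p[np.sign(_LEGAL_ARRAY - r1) == side].sum()))
        if not probs:
            raise ValidationError("no skeleton trial passes the inclusion filter")
        level = float(np.mean(probs))
    return ChanceEstimate(level=level, n_sim=0, seed=None, mode=mode)


# ---------------------------------------------------------------------------
# Single-item sampling null
# ---------------------------------------------------------------------------

def single_item_null(
    observer: ObserverDataset,
    n_iterations: int = 5000,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    mode: Mode = "full",
    reuse_ensemble_inclusion: bool = False,
) -> SamplingNullResult:
    """Bias proportion when one random distractor stands in for the ensemble.

    Per iteration, each trial's reference value is the Part I rating of one
    uniformly chosen distractor; inclusion and shift direction are
    recomputed against that single rating, and the per-iteration
    toward-proportions are averaged.  If the whole ensemble (not any single
    item) drives the bias, this proportion falls below the ensemble-based
    one.

    With ``reuse_ensemble_inclusion`` the trial set is frozen to the trials
    included by the ensemble-mean rule and only the shift direction is
    recomputed per sampled item.
    """
    _check_mode(mode)
    if not observer.trials:
        raise UndefinedSummaryError(
            f"observer {observer.observer_id}: no trials to resample"
        )
    rng = np.random.default_rng(seed)
    r1 = np.array([observer.part1[t.target_id] for t in observer.trials])
    r2 = np.array([t.part2_rating for t in observer.trials])
    dist = np.array(
        [[observer.part1[d] for d in t.distractor_ids] for t in observer.trials]
    )
    n_trials = r1.size
    picks = rng.integers(0, 3, size=(n_iterations, n_trials))
    sampled = dist[np.arange(n_trials)[None, :], picks]  # (n_iter, n_trials)

    if reuse_ensemble_inclusion:
        ensemble_included = np.array(
            [include_trial(t, observer.part1, mode) for t in observer.trials]
        )
        included = np.broadcast_to(ensemble_included, sampled.shape)
    else:
        included = np.abs(sampled - r1) > 0.5
        if mode == "restricted":
            included = included & (np.abs(r1) == 3)

    toward = (np.sign(r2 - r1) == np.sign(sampled - r1)) & (r2 != r1)
    n_inc = included.sum(axis=1)
    if not n_inc.any():
        raise UndefinedSummaryError(
            f"observer {observer.observer_id}: zero included trials "
            "in every iteration"
        )
    with np.errstate(invalid="ignore"):
        proportions = (toward & included).sum(axis=1) / n_inc
    return SamplingNullResult(
        observer_id=observer.observer_id,
        n_iterations=n_iterations,
        mean_proportion=float(np.nanmean(proportions)),
    )


# ---------------------------------------------------------------------------
# Pull magnitude, memory consistency, pull-weight recovery
# ---------------------------------------------------------------------------

def _pooled_table(
    observers: Iterable[ObserverDataset], mode: Mode
) -> pd.DataFrame:
    tables = [trial_table(obs, mode) for obs in observers]
    if not tables:
        raise ValidationError("no observers given")
    return pd.concat(tables, ignore_index=True)


def pull_magnitude(
    observers: Iterable[ObserverDataset],
    mode: Mode = "full",
    trials: Literal["toward", "included"] = "toward",
) -> PullMagnitude:
    """Pull magnitude as a percentage of the maximum possible shift.

    Pooled over observers: the mean available ensemble-target difference
    |m - r1| and the mean Part I -> Part II shift signed toward the
    ensemble, over toward-trials (default) or over all included trials.
    """
    pooled = _pooled_table(observers, mode)
    if trials == "toward":
        sel = pooled[pooled["direction"] == "toward"]
    elif trials == "included":
        sel = pooled[pooled["included"]]
    else:
        raise ValidationError(f"unknown trials selection {trials!r}")
    if sel.empty:
        raise UndefinedSummaryError(f"no {trials} trials in {mode} mode")
    d = sel["m"] - sel["r1"]
    shift = np.sign(d) * (sel["r2"] - sel["r1"])
    return PullMagnitude(
        mean_available_diff=float(np.abs(d).mean()),
        mean_shift=float(shift.mean()),
        n_trials=len(sel),
    )


def pull_percentage(mean_available_diff: float, mean_shift: float) -> float:
    """Shift as a percentage of the available difference (100 * shift / diff)."""
    if mean_available_diff <= 0:
        raise ValidationError("mean_available_diff must be > 0")
    return 100.0 * mean_shift / mean_available_diff


def memory_consistency(observers: Iterable[ObserverDataset]) -> float:
    """Mean absolute Part I -> Part II difference of the target rating.

    Averaged over all trials (no inclusion filter) within observer, then
    across observers; an index of how consistently the target is re-rated.
    """
    per_observer = []
    for obs in observers:
        table = trial_table(obs, "full")
        if table.empty:
            raise UndefinedSummaryError(f"observer {obs.observer_id}: no trials")
        per_observer.append(float(np.abs(table["r2"] - table["r1"]).mean()))
    if not per_observer:
        raise ValidationError("no observers given")
    return float(np.mean(per_observer))


def estimate_pull_weight(
    observers: Iterable[ObserverDataset], mode: Mode = "full"
) -> float:
    """Moment estimator of the pull weight w.

    Over included trials pooled across observers:
    ``w_hat = mean(signed shift toward the ensemble) / mean(|m - r1|)``.
    Unbiased for the linear pull model up to snap distortion, because the
    signed shift averages the symmetric response noise away.
    """
    pooled = _pooled_table(observers, mode)
    sel = pooled[pooled["included"]]
    if sel.empty:
        raise UndefinedSummaryError(f"no included trials in {mode} mode")
    d = sel["m"] - sel["r1"]
    shift = np.sign(d) * (sel["r2"] - sel["r1"])
    return float(shift.mean() / np.abs(d).mean())


def _check_mode(mode: str) -> None:
    if mode not in ("full", "restricted"):
        raise ValidationError(f"unknown mode {mode!r}; expected full or restricted")


def _as_designs(skeletons) -> list[Sequence[tuple[int, float]]]:
    if not len(skeletons):
        raise ValidationError("empty skeleton")
    first = skeletons[0]
    if len(first) == 2 and np.isscalar(first[0]):
        return [skeletons]
    return list(skeletons)
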