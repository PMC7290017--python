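"""Domain types and delimited-text I/O for two-part valence-rating experiments.

The experimental design these types describe: in Part I an observer rates
every image in a stimulus pool on a bipolar integer valence scale from -5
(very negative) to +5 (very positive), with 0 excluded.  In Part II the
observer sees four-image sets whose members all share the sign of their
Part I rating (valence-homogeneous sets), one image is cued, and the
observer re-rates the cued image on the same scale.

Data are stored as two CSV files, mirroring the two experimental phases:

* ratings file:  ``observer_id,image_id,rating``
* trials file:   ``observer_id,trial_id,target_id,distractor1_id,
  distractor2_id,distractor3_id,condition,part2_rating``
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

#: The ten legal values of the bipolar valence scale; zero is forbidden.
LEGAL_RATINGS: tuple[int, ...] = (-5, -4, -3, -2, -1, 1, 2, 3, 4, 5)
_LEGAL_SET = frozenset(LEGAL_RATINGS)

#: Allowed Part II presentation conditions.
CONDITIONS: tuple[str, ...] = ("upright", "inverted", "scrambled")

RATINGS_COLUMNS = ["observer_id", "image_id", "rating"]
TRIALS_COLUMNS = [
    "observer_id",
    "trial_id",
    "target_id",
    "distractor1_id",
    "distractor2_id",
    "distractor3_id",
    "condition",
    "part2_rating",
]


class ValidationError(ValueError):
    """A field value violates a domain-type invariant."""


class ReferentialIntegrityError(ValueError):
    """A trial references an image with no Part I rating."""


class ParseError(ValueError):
    """A data file is malformed; the message names the offending location."""


class UndefinedSummaryError(ValueError):
    """A per-observer summary is undefined (e.g. zero included trials)."""


def validate_rating(value: int) -> int:
    """Check that ``value`` is on the legal bipolar scale and return it.

    Raises
    ------
    ValidationError
        If ``value`` is 0 or outside [-5, 5].
    """
    if not isinstance(value, (int,)) or isinstance(value, bool):
        raise ValidationError(f"rating must be an integer, got {value!r}")
    if value not in _LEGAL_SET:
        raise ValidationError(
            f"rating {value} not on the legal scale {{-5..-1, +1..+5}} (0 excluded)"
        )
    return value


@dataclass(frozen=True)
class ImageRecord:
    """A stimulus image; ``latent_valence`` exists only for synthetic data."""

    image_id: str
    latent_valence: float | None = None


@dataclass(frozen=True)
class EnsembleTrial:
    """One Part II trial: a cued target among three task-irrelevant distractors."""

    trial_id: int
    target_id: str
    distractor_ids: tuple[str, str, str]
    condition: str
    part2_rating: int

    def __post_init__(self) -> None:
        if len(self.distractor_ids) != 3:
            raise ValidationError(
                f"trial {self.trial_id}: exactly 3 distractors required, "
                f"got {len(self.distractor_ids)}"
            )
        ids = (self.target_id, *self.distractor_ids)
        if len(set(ids)) != 4:
            raise ValidationError(
                f"trial {self.trial_id}: the 4 image ids must be pairwise distinct: {ids}"
            )
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"trial {self.trial_id}: condition {self.condition!r} not in {CONDITIONS}"
            )
        validate_rating(self.part2_rating)

    @property
    def image_ids(self) -> tuple[str, str, str, str]:
        return (self.target_id, *self.distractor_ids)


@dataclass
class ObserverDataset:
    """One observer's Part I ratings keyed by image, plus their Part II trials."""

    observer_id: str
    part1: dict[str, int] = field(default_factory=dict)
    trials: list[EnsembleTrial] = field(default_factory=list)

    def validate(self) -> "ObserverDataset":
        """Check all invariants; raise on the first violation, return self."""
        for image_id, rating in self.part1.items():
            try:
                validate_rating(rating)
            except ValidationError as exc:
                raise ValidationError(
                    f"observer {self.observer_id}, image {image_id}: {exc}"
                ) from None
        for trial in self.trials:
            for image_id in trial.image_ids:
                if image_id not in self.part1:
                    raise ReferentialIntegrityError(
                        f"observer {self.observer_id}, trial {trial.trial_id}: "
                        f"image {image_id!r} has no Part I rating"
                    )
            signs = {1 if self.part1[i] > 0 else -1 for i in trial.image_ids}
            if len(signs) != 1:
                raise ValidationError(
                    f"observer {self.observer_id}, trial {trial.trial_id}: "
                    "set is not valence-homogeneous (mixed Part I rating signs)"
                )
        return self


@dataclass(frozen=True)
class BiasSummary:
    """Per-observer toward-the-ensemble proportion and the counts behind it."""

    observer_id: str
    n_included: int
    n_toward: int

    def __post_init__(self) -> None:
        if self.n_included <= 0:
            raise UndefinedSummaryError(
                f"observer {self.observer_id}: no trials passed the inclusion filter"
            )
        if not 0 <= self.n_toward <= self.n_included:
            raise ValidationError(
                f"observer {self.observer_id}: n_toward={self.n_toward} "
                f"outside [0, {self.n_included}]"
            )

    @property
    def proportion(self) -> float:
        return self.n_toward / self.n_included


@dataclass(frozen=True)
class ChanceEstimate:
    """A no-bias reference level for the toward-proportion.

    ``mode`` is the trial filter the level refers to ("full" or "restricted");
    ``n_sim`` is 0 for closed-form (non-simulated) levels.
    """

    level: float
    n_sim: int
    seed: int | None
    mode: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.level <= 1.0:
            raise ValidationError(f"chance level {self.level} outside [0, 1]")


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def _ratings_path(path: str | Path) -> Path:
    return Path(path) / "ratings.csv" if Path(path).is_dir() else Path(path)


def read_dataset(
    ratings_path: str | Path, trials_path: str | Path
) -> list[ObserverDataset]:
    """Read ratings and trials CSV files into validated observer datasets.

    Observers appear in the output in order of first appearance in the
    ratings file; trials keep their file order within each observer.

    Raises
    ------
    ParseError
        Malformed file, missing columns, or an unparsable row (named by line).
    ValidationError
        A rating of 0 / out of range, or a non-homogeneous trial set.
    ReferentialIntegrityError
        A trial referencing an image with no Part I rating.
    """
    ratings = _read_csv(ratings_path, RATINGS_COLUMNS)
    trials = _read_csv(trials_path, TRIALS_COLUMNS)

    observers: dict[str, ObserverDataset] = {}
    for row in ratings.itertuples():
        obs = observers.setdefault(
            str(row.observer_id), ObserverDataset(observer_id=str(row.observer_id))
        )
        rating = _parse_int(row.rating, ratings_path, row.Index)
        image_id = str(row.image_id)
        if image_id in obs.part1:
            raise ParseError(
                f"{ratings_path}, line {row.Index + 2}: duplicate rating for "
                f"observer {obs.observer_id}, image {image_id}"
            )
        obs.part1[image_id] = rating

    for row in trials.itertuples():
        observer_id = str(row.observer_id)
        if observer_id not in observers:
            raise ReferentialIntegrityError(
                f"{trials_path}, line {row.Index + 2}: observer {observer_id!r} "
                "has no Part I ratings"
            )
        trial = EnsembleTrial(
            trial_id=_parse_int(row.trial_id, trials_path, row.Index),
            target_id=str(row.target_id),
            distractor_ids=(
                str(row.distractor1_id),
                str(row.distractor2_id),
                str(row.distractor3_id),
            ),
            condition=str(row.condition),
            part2_rating=_parse_int(row.part2_rating, trials_path, row.Index),
        )
        observers[observer_id].trials.append(trial)

    return [obs.validate() for obs in observers.values()]


def write_dataset(
    observers: Iterable[ObserverDataset],
    ratings_path: str | Path,
    trials_path: str | Path,
) -> None:
    """Write observers to the two-file CSV layout read by :func:`read_dataset`."""
    observers = list(observers)
    for obs in observers:
        obs.validate()
    ratings_rows = [
        {"observer_id": o.observer_id, "image_id": i, "rating": r}
        for o in observers
        for i, r in o.part1.items()
    ]
    trials_rows = [
        {
            "observer_id": o.observer_id,
            "trial_id": t.trial_id,
            "target_id": t.target_id,
            "distractor1_id": t.distractor_ids[0],
            "distractor2_id": t.distractor_ids[1],
            "distractor3_id": t.distractor_ids[2],
            "condition": t.condition,
            "part2_rating": t.part2_rating,
        }
        for o in observers
        for t in o.trials
    ]
    pd.DataFrame(ratings_rows, columns=RATINGS_COLUMNS).to_csv(
        ratings_path, index=False
    )
    pd.DataFrame(trials_rows, columns=TRIALS_COLUMNS).to_csv(trials_path, index=False)


def _read_csv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df[columns]


def _parse_int(value: str, path: str | Path, row_index: int) -> int:
    try:
        return int(str(value))
    except ValueError:
        # +2: one for the header row, one for 0- vs 1-based line numbers
        raise ParseError(
            f"{path}, line {row_index + 2}: {value!r} is not an integer"
        ) from None
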