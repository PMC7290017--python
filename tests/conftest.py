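import pytest

from ensemblepull import EnsembleTrial, ObserverDataset


def make_trial(trial_id, target, distractors, part2, condition="upright"):
    return EnsembleTrial(
        trial_id=trial_id,
        target_id=target,
        distractor_ids=tuple(distractors),
        condition=condition,
        part2_rating=part2,
    )


@pytest.fixture
def toy_observer():
    """Six hand-built trials: 3 toward, 1 away, 1 none, 1 excluded (full mode).

    Part I: a=+3, b=+4, c=+5, d=+2, e=+1, f=+3.
    """
    part1 = {"a": 3, "b": 4, "c": 5, "d": 2, "e": 1, "f": 3}
    trials = [
        # r1=3, m=(4+5+2)/3=11/3>3.5 -> included; r2=4 toward
        make_trial(0, "a", ("b", "c", "d"), 4),
        # r1=3, m=(2+1+3)/3=2.0 -> included; r2=2 toward
        make_trial(1, "a", ("d", "e", "f"), 2),
        # r1=1, m=(4+5+3)/3=4.0 -> included; r2=3 toward
        make_trial(2, "e", ("b", "c", "a"), 3),
        # r1=3, m=(4+5+1)/3=10/3 -> excluded (1/3 <= 0.5)
        make_trial(3, "f", ("b", "c", "e"), 5),
        # r1=5, m=(3+2+1)/3=2.0 -> included; r2=5 none
        make_trial(4, "c", ("a", "d", "e"), 5),
        # r1=2, m=(3+3+1)/3=7/3 -> excluded? |7/3-2|=1/3 -> excluded
        # use distractors (b, c, f): m=(4+5+3)/3=4.0 -> included; r2=1 away
        make_trial(5, "d", ("b", "c", "f"), 1),
    ]
    return ObserverDataset(observer_id="toy", part1=part1, trials=trials).validate()


@pytest.fixture
def tiny_observers(toy_observer):
    """Two observers with identical structure but distinct ids."""
    import copy

    other = copy.deepcopy(toy_observer)
    other.observer_id = "toy2"
    return [toy_observer, other]
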