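"""Experimental designs for the single-digit numeral comparison task.

Participants pick the larger of two numerals drawn from {2,3,5,7,8}
(positive, negative, or 1/positive form).  Difficulty is the logarithmic
distance ln(a) - ln(b) between the underlying digits; ten digit pairs span
ten unique log distances.  Dummy trials (digits up to 15, including the
anchors 1 and 9) mask the design and never enter analysis.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NumeralType",
    "NumeralPair",
    "ExperimentDesign",
    "log_distance",
    "build_design",
    "design_to_frame",
    "CORE_DIGIT_PAIRS",
]


class NumeralType(str, enum.Enum):
    """The three within-trial numeral formats."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    ONE_OVER = "one_over"


#: The ten digit pairs of the fixed designs (larger digit first).  Their log
#: distances are 0.134, 0.336, 0.405, 0.470, 0.511, 0.847, 0.916, 0.981,
#: 1.253, 1.386 (3 dp), each realised by exactly one pair.
CORE_DIGIT_PAIRS: tuple[tuple[int, int], ...] = (
    (8, 7),
    (7, 5),
    (3, 2),
    (8, 5),
    (5, 3),
    (7, 3),
    (5, 2),
    (8, 3),
    (7, 2),
    (8, 2),
)

_CORE_DIGITS = (2, 3, 5, 7, 8)


def log_distance(num_a: int, num_b: int) -> float:
    """Logarithmic numerical distance ln(num_a) - ln(num_b).

    Parameters
    ----------
    num_a, num_b
        Positive integers with ``num_a >= num_b``.

    Returns
    -------
    float
        Non-negative distance in natural-log units.
    """
    if num_a <= 0 or num_b <= 0:
        raise ValueError("digits must be positive")
    if num_a < num_b:
        raise ValueError("num_a must be the larger (or equal) digit")
    return math.log(num_a) - math.log(num_b)


@dataclass(frozen=True)
class NumeralPair:
    """A stimulus pair: two digits in one of three numeral formats.

    ``num_a`` is the larger *digit*; for negative and 1/n formats the
    displayed value derived from ``num_b`` (-b or 1/b) is the larger one,
    so the objectively correct response maps through the format.
    """

    num_a: int
    num_b: int
    numeral_type: NumeralType
    log_distance: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.num_a <= self.num_b:
            raise ValueError("num_a must exceed num_b")
        d = log_distance(self.num_a, self.num_b)
        if self.log_distance is None:
            object.__setattr__(self, "log_distance", d)
        elif abs(self.log_distance - d) > 1e-12:
            raise ValueError("log_distance inconsistent with digits")

    @property
    def larger_displayed_digit(self) -> int:
        """Digit whose displayed numeral is the larger magnitude."""
        if self.numeral_type is NumeralType.POSITIVE:
            return self.num_a
        return self.num_b  # -b > -a and 1/b > 1/a


@dataclass(frozen=True)
class ExperimentDesign:
    """A full trial list specification for one experiment."""

    pairs: tuple[NumeralPair, ...]
    trials_per_pair_per_type: int
    n_dummy: int
    deadline_s: float = 3.0
    experiment_label: str = "exp1"

    @property
    def n_analyzable(self) -> int:
        return len(self.pairs) * self.trials_per_pair_per_type

    @property
    def n_total(self) -> int:
        return self.n_analyzable + self.n_dummy


def _core_pairs(numeral_types: Sequence[NumeralType]) -> list[NumeralPair]:
    return [
        NumeralPair(a, b, t)
        for t in numeral_types
        for (a, b) in CORE_DIGIT_PAIRS
    ]


def _sampled_pairs(
    rng: np.random.Generator, numeral_types: Sequence[NumeralType], n_pairs: int
) -> list[NumeralPair]:
    # exp3 protocol: digits 2-8 sampled randomly to form (unequal) pairs
    digits = np.arange(2, 9)
    pairs = []
    for t in numeral_types:
        for _ in range(n_pairs):
            a, b = rng.choice(digits, size=2, replace=False)
            a, b = int(max(a, b)), int(min(a, b))
            pairs.append(NumeralPair(a, b, t))
    return pairs


def build_design(
    experiment_label: str = "exp1",
    trials_per_pair_per_type: int | None = None,
    n_dummy: int | None = None,
    seed: int | None = None,
) -> ExperimentDesign:
    """Build an experiment design.

    ``exp1``/``exp2`` use the ten fixed digit pairs per numeral type
    (defaults: 24 and 12 repetitions, 150 and 75 dummies, giving 720 and
    360 analyzable trials).  ``exp3`` draws pairs uniformly from digits
    2-8 (one list per numeral type, repetitions = 1 by construction).
    """
    defaults = {
        "exp1": (24, 150),
        "exp2": (12, 75),
        "exp3": (12, 75),
    }
    if experiment_label not in defaults:
        raise ValueError(f"unknown experiment label: {experiment_label!r}")
    d_trials, d_dummy = defaults[experiment_label]
    if trials_per_pair_per_type is None:
        trials_per_pair_per_type = d_trials
    if n_dummy is None:
        n_dummy = d_dummy
    if trials_per_pair_per_type < 1:
        raise ValueError("trials_per_pair_per_type must be >= 1")
    if n_dummy < 0:
        raise ValueError("n_dummy must be >= 0")

    types = list(NumeralType)
    if experiment_label in ("exp1", "exp2"):
        pairs = _core_pairs(types)
    else:
        rng = np.random.default_rng(seed)
        # ten random exemplars per type, mirroring the fixed designs' size
        pairs = _sampled_pairs(rng, types, 10)
    return ExperimentDesign(
        pairs=tuple(pairs),
        trials_per_pair_per_type=trials_per_pair_per_type,
        n_dummy=n_dummy,
        experiment_label=experiment_label,
    )


def design_to_frame(
    design: ExperimentDesign, seed: int | None = None, subject: int = 0
) -> pd.DataFrame:
    """Expand a design into a shuffled trial table.

    Columns: trial_index, subject, numeral_type, num_a, num_b,
    log_distance, is_dummy, correct_side.  The side holding the larger
    displayed numeral is randomized 0.5/0.5 per trial.  Dummy trials use
    random digits 2-15 and carry no analyzable difficulty
    (``log_distance`` is NaN).
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for pair in design.pairs:
        for _ in range(design.trials_per_pair_per_type):
            rows.append(
                {
                    "numeral_type": pair.numeral_type.value,
                    "num_a": pair.num_a,
                    "num_b": pair.num_b,
                    "log_distance": pair.log_distance,
                    "is_dummy": False,
                }
            )
    for _ in range(design.n_dummy):
        a, b = rng.choice(np.arange(2, 16), size=2, replace=False)
        a, b = int(max(a, b)), int(min(a, b))
        rows.append(
            {
                "numeral_type": rng.choice([t.value for t in NumeralType]),
                "num_a": a,
                "num_b": b,
                "log_distance": np.nan,
                "is_dummy": True,
            }
        )
    frame = pd.DataFrame(rows)
    order = rng.permutation(len(frame))
    frame = frame.iloc[order].reset_index(drop=True)
    frame.insert(0, "trial_index", np.arange(len(frame)))
    frame.insert(1, "subject", subject)
    frame["correct_side"] = rng.choice(["left", "right"], size=len(frame))
    return frame
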