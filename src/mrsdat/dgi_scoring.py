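"""Dietary Guideline Index (DGI / DGI-CA) scoring.

The score has eleven indicators summing to 100 points:

==========================  ===========  =======================================
indicator                   max points   rule
==========================  ===========  =======================================
vegetables                  10           proportional to recommended serves
fruit                       10           proportional to recommended serves
breads_cereals_intake       5            proportional to recommended serves
wholegrain_quality          5            step {0, 2.5, 5} on wholegrain fraction
meat                        10           proportional to recommended serves
dairy                       10           proportional (excluded under 2 years)
variety                     10           proportional to food-group coverage
healthy_fats                10           graded 0-1 use (binary mode optional)
plain_water                 5            consumed or not
ssb                         5            linear penalty, 0 at the limit
discretionary               20           linear penalty, 0 at the limit
==========================  ===========  =======================================

Proportional indicators award ``max_points x min(1, intake/recommended)``:
half the recommended serves earns half the points, capped at the maximum.
Penalty indicators award the full points at zero intake, falling linearly to
zero at the configured limit. Children under two years have the dairy
indicator excluded (maximum raw total 90); their raw total is multiplied by
10/9 so every participant's rescaled score is out of 100.

Scores are kept in full precision; rounding to two decimals happens only in
the reporting layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .adg_reference import AgeLifeStageGroup, RecommendationTable
from .errors import ConfigError, MissingDataError
from .intake_model import FoodGroupIntake

UNDER_TWO_RESCALE = 10.0 / 9.0

#: indicator ids in reporting order with their maximum points
INDICATOR_MAX_POINTS: dict[str, float] = {
    "vegetables": 10.0,
    "fruit": 10.0,
    "breads_cereals_intake": 5.0,
    "wholegrain_quality": 5.0,
    "meat": 10.0,
    "dairy": 10.0,
    "variety": 10.0,
    "healthy_fats": 10.0,
    "plain_water": 5.0,
    "ssb": 5.0,
    "discretionary": 20.0,
}

#: default step thresholds for the wholegrain-quality indicator
WHOLEGRAIN_LOW_CUT = 1e-9
WHOLEGRAIN_HIGH_CUT = 0.5

#: default denominator for the variety indicator (five core food groups)
VARIETY_MAX_COUNT = 5


@dataclass(frozen=True)
class IndicatorScore:
    indicator_id: str
    points: float
    max_points: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.points <= self.max_points + 1e-12):
            raise ValueError(
                f"{self.indicator_id}: points {self.points} outside "
                f"[0, {self.max_points}]"
            )


@dataclass(frozen=True)
class DgiScore:
    participant_id: str
    method: str
    indicators: tuple[IndicatorScore, ...]
    raw_total: float
    rescaled_total: float
    max_possible_raw: float
    under_two: bool

    def indicator(self, indicator_id: str) -> IndicatorScore:
        for ind in self.indicators:
            if ind.indicator_id == indicator_id:
                return ind
        raise KeyError(indicator_id)

    @property
    def indicator_ids(self) -> tuple[str, ...]:
        return tuple(i.indicator_id for i in self.indicators)


# ---------------------------------------------------------------------------
# indicator primitives


def proportional_indicator(
    intake_serves: float, recommended_serves: float, max_points: float
) -> float:
    """Points proportional to intake relative to the recommendation, capped.

    E.g. 2 serves against a 4-serve recommendation earns 5 of 10 points.
    """
    if not recommended_serves > 0:
        raise ConfigError(f"recommended_serves must be > 0, got {recommended_serves}")
    if intake_serves < 0 or not math.isfinite(intake_serves):
        raise ValueError(f"intake_serves must be finite and >= 0, got {intake_serves}")
    return max_points * min(1.0, intake_serves / recommended_serves)


def penalty_indicator(intake_serves: float, limit: float, max_points: float) -> float:
    """Full points at zero intake, linearly down to zero at ``limit`` serves."""
    if not limit > 0:
        raise ConfigError(f"limit must be > 0, got {limit}")
    if intake_serves < 0 or not math.isfinite(intake_serves):
        raise ValueError(f"intake_serves must be finite and >= 0, got {intake_serves}")
    return max_points * max(0.0, 1.0 - intake_serves / limit)


def wholegrain_indicator(
    wholegrain_fraction: float,
    low_cut: float = WHOLEGRAIN_LOW_CUT,
    high_cut: float = WHOLEGRAIN_HIGH_CUT,
    max_points: float = 5.0,
) -> float:
    """Step score on the wholegrain share of breads-and-cereals intake.

    0 below ``low_cut`` (no wholegrain), half points up to ``high_cut``,
    full points at or above it.
    """
    if not (0.0 <= wholegrain_fraction <= 1.0):
        raise ValueError(f"wholegrain_fraction must be in [0, 1], got {wholegrain_fraction}")
    if wholegrain_fraction < low_cut:
        return 0.0
    if wholegrain_fraction < high_cut:
        return 0.5 * max_points
    return max_points


def binary_indicator(flag: bool, max_points: float) -> float:
    return max_points if flag else 0.0


def variety_indicator(
    variety_count: int, max_count: int = VARIETY_MAX_COUNT, max_points: float = 10.0
) -> float:
    """Points for eating across the core food groups, proportional to coverage."""
    if max_count < 1:
        raise ConfigError(f"max_count must be >= 1, got {max_count}")
    if variety_count < 0:
        raise ValueError(f"variety_count must be >= 0, got {variety_count}")
    return max_points * min(1.0, variety_count / max_count)


def healthy_fats_indicator(
    value: float | bool, max_points: float = 10.0, mode: str = "graded"
) -> float:
    """Healthy-fats points from a 0-1 use value.

    ``graded`` (default) scores ``max_points x value``; ``binary`` scores all
    or nothing on truthiness.
    """
    if mode == "binary":
        return binary_indicator(bool(value), max_points)
    if mode != "graded":
        raise ConfigError(f"healthy-fats mode must be 'graded' or 'binary', got {mode!r}")
    v = float(value)
    if not (0.0 <= v <= 1.0):
        raise ValueError(f"healthy-fats value must be in [0, 1], got {v}")
    return max_points * v


# ---------------------------------------------------------------------------
# total score


def total_dgi(
    intake: FoodGroupIntake,
    group: AgeLifeStageGroup,
    recs: RecommendationTable | None = None,
    healthy_fats_mode: str = "graded",
    wholegrain_cuts: tuple[float, float] = (WHOLEGRAIN_LOW_CUT, WHOLEGRAIN_HIGH_CUT),
    variety_max_count: int = VARIETY_MAX_COUNT,
) -> DgiScore:
    """Score one intake record against its age/life-stage recommendations.

    Sums the eleven indicators (ten for under-2s, whose dairy indicator is
    excluded and whose raw total — maximum 90 — is rescaled by 10/9 to be
    out of 100). ``recs`` is accepted for symmetry with loaders but the
    per-group values on ``group`` drive every denominator.
    """
    serves = intake.serves
    missing = [
        fg
        for fg in ("vegetables", "fruit", "breads_cereals", "meat", "ssb", "discretionary")
        if fg not in serves
    ]
    if not group.under_two and "dairy" not in serves:
        missing.append("dairy")
    if missing:
        raise MissingDataError(
            f"participant {intake.participant_id!r} intake missing food groups "
            f"required for scoring: {missing}"
        )

    rec = group.recommended_serves
    indicators = [
        IndicatorScore(
            "vegetables",
            proportional_indicator(serves["vegetables"], rec["vegetables"], 10.0),
            10.0,
        ),
        IndicatorScore(
            "fruit", proportional_indicator(serves["fruit"], rec["fruit"], 10.0), 10.0
        ),
        IndicatorScore(
            "breads_cereals_intake",
            proportional_indicator(serves["breads_cereals"], rec["breads_cereals"], 5.0),
            5.0,
        ),
        IndicatorScore(
            "wholegrain_quality",
            wholegrain_indicator(
                intake.wholegrain_fraction, wholegrain_cuts[0], wholegrain_cuts[1], 5.0
            ),
            5.0,
        ),
        IndicatorScore(
            "meat", proportional_indicator(serves["meat"], rec["meat"], 10.0), 10.0
        ),
    ]
    if group.dairy_applicable:
        indicators.append(
            IndicatorScore(
                "dairy", proportional_indicator(serves["dairy"], rec["dairy"], 10.0), 10.0
            )
        )
    indicators += [
        IndicatorScore(
            "variety", variety_indicator(intake.variety_count, variety_max_count), 10.0
        ),
        IndicatorScore(
            "healthy_fats",
            healthy_fats_indicator(intake.healthy_fats, mode=healthy_fats_mode),
            10.0,
        ),
        IndicatorScore("plain_water", binary_indicator(intake.plain_water, 5.0), 5.0),
        IndicatorScore(
            "ssb", penalty_indicator(serves["ssb"], group.ssb_limit, 5.0), 5.0
        ),
        IndicatorScore(
            "discretionary",
            penalty_indicator(serves["discretionary"], group.discretionary_limit, 20.0),
            20.0,
        ),
    ]
    raw_total = sum(i.points for i in indicators)
    under_two = group.under_two
    max_raw = 90.0 if under_two else 100.0
    rescaled = raw_total * UNDER_TWO_RESCALE if under_two else raw_total
    return DgiScore(
        participant_id=intake.participant_id,
        method=intake.method,
        indicators=tuple(indicators),
        raw_total=raw_total,
        rescaled_total=rescaled,
        max_possible_raw=max_raw,
        under_two=under_two,
    )


def scores_to_frame(scores: Iterable[DgiScore]) -> pd.DataFrame:
    """Tidy export: one row per participant x method x indicator."""
    rows = []
    for s in scores:
        for ind in s.indicators:
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "method": s.method,
                    "indicator_id": ind.indicator_id,
                    "points": ind.points,
                    "max_points": ind.max_points,
                }
            )
    return pd.DataFrame(
        rows, columns=["participant_id", "method", "indicator_id", "points", "max_points"]
    )


def totals_to_frame(scores: Iterable[DgiScore]) -> pd.DataFrame:
    """One row per participant x method with raw and rescaled totals."""
    rows = [
        {
            "participant_id": s.participant_id,
            "method": s.method,
            "raw_total": s.raw_total,
            "rescaled_total": s.rescaled_total,
            "max_possible_raw": s.max_possible_raw,
            "under_two": s.under_two,
        }
        for s in scores
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "method",
            "raw_total",
            "rescaled_total",
            "max_possible_raw",
            "under_two",
        ],
    )


def perfect_intake(
    group: AgeLifeStageGroup, participant_id: str = "perfect", method: str = "mrsdat"
) -> FoodGroupIntake:
    """An intake meeting every recommendation with zero penalty-food intake:
    scores the maximum on every applicable indicator. Useful for audits."""
    serves: Mapping[str, float] = {
        **{fg: v for fg, v in group.recommended_serves.items()},
        "ssb": 0.0,
        "discretionary": 0.0,
    }
    return FoodGroupIntake(
        participant_id=participant_id,
        method=method,
        serves=serves,
        wholegrain_fraction=1.0,
        plain_water=True,
        healthy_fats=1.0,
        variety_count=VARIETY_MAX_COUNT,
        n_days_averaged=1,
    )
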