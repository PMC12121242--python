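"""Convert FFQ responses and 24-h recall days to comparable daily intakes.

Both dietary assessment methods end up as a :class:`FoodGroupIntake` — one
record per participant per method holding daily serves for each food group
plus the quality inputs (wholegrain fraction, plain water, healthy fats,
variety). The FFQ path maps each selected response option to a serves/day
value (range midpoint; open-top options use their floor; fortnightly
frequencies are divided by 14). The recall path averages the participant's
recall days arithmetically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .adg_reference import CORE_FOOD_GROUPS, FOOD_GROUPS
from .errors import ConfigError, MissingDataError, SchemaError

DAYS_PER_FORTNIGHT = 14.0
_SCHEMA_RESOURCE = "ffq_schema.yaml"

QUESTION_KINDS = ("serves", "fraction", "boolean")
FREQUENCY_BASES = ("per_day", "per_fortnight")


@dataclass(frozen=True)
class FfqOption:
    label: str
    lo: float
    hi: float

    @property
    def value(self) -> float:
        # Open-top / point options carry lo == hi and map to that value;
        # ranges map to their midpoint.
        return self.lo if self.lo == self.hi else 0.5 * (self.lo + self.hi)


@dataclass(frozen=True)
class FfqQuestion:
    question_id: str
    kind: str
    frequency_basis: str
    options: tuple[FfqOption, ...]
    food_group: str | None = None  # for kind == "serves"
    target: str | None = None  # for kind in {"fraction", "boolean"}
    prompt: str = ""

    def option(self, label: str) -> FfqOption:
        for opt in self.options:
            if opt.label == label:
                return opt
        raise SchemaError(
            f"question {self.question_id!r} has no option {label!r}; "
            f"valid: {[o.label for o in self.options]}"
        )

    def daily_value(self, label: str) -> float:
        value = self.option(label).value
        if self.frequency_basis == "per_fortnight":
            value /= DAYS_PER_FORTNIGHT
        return value

    def option_for_value(self, daily_value: float) -> FfqOption:
        """Closest option for a serves/day value (used when simulating responses).

        Options are treated as intervals; the trailing open-top option (lo ==
        hi at the end of a serves question) is unbounded above. Ties go to the
        lower option.
        """
        v = daily_value
        if self.frequency_basis == "per_fortnight":
            v = daily_value * DAYS_PER_FORTNIGHT
        best, best_dist = self.options[0], math.inf
        for i, opt in enumerate(self.options):
            hi = opt.hi
            if i == len(self.options) - 1 and opt.lo == opt.hi and self.kind == "serves":
                hi = math.inf
            dist = max(opt.lo - v, v - hi, 0.0)
            if dist < best_dist:
                best, best_dist = opt, dist
        return best


@dataclass(frozen=True)
class FfqSchema:
    questions: tuple[FfqQuestion, ...]

    def __iter__(self):
        return iter(self.questions)

    def question(self, question_id: str) -> FfqQuestion:
        for q in self.questions:
            if q.question_id == question_id:
                return q
        raise SchemaError(f"unknown question_id {question_id!r}")

    def serves_questions(self) -> list[FfqQuestion]:
        return [q for q in self.questions if q.kind == "serves"]


@dataclass(frozen=True)
class FfqResponseSet:
    """One participant's selected option per question."""

    participant_id: str
    selections: Mapping[str, str]  # question_id -> option_label
    timestamp: str | None = None


@dataclass(frozen=True)
class RecallDay:
    """Daily serves for one 24-h recall, already expressed as food-group serves."""

    participant_id: str
    recall_index: int
    serves: Mapping[str, float]
    wholegrain_fraction: float = 0.0
    plain_water: bool = False
    healthy_fats: bool = False
    variety_count: int = 0
    day_type: str | None = None


@dataclass(frozen=True)
class FoodGroupIntake:
    """One participant-method's comparable daily intake."""

    participant_id: str
    method: str  # "mrsdat" | "recall_average"
    serves: Mapping[str, float]
    wholegrain_fraction: float
    plain_water: bool
    healthy_fats: float  # graded 0-1 use of healthy fats (bool-compatible)
    variety_count: int
    n_days_averaged: int


def variety_from_serves(serves: Mapping[str, float]) -> int:
    """Count of the five core food groups with any intake (the default
    operationalisation of dietary variety)."""
    return sum(1 for fg in CORE_FOOD_GROUPS if serves.get(fg, 0.0) > 0.0)


# ---------------------------------------------------------------------------
# schema loading


def load_ffq_schema(source: str | Path | IO[str] | None = None) -> FfqSchema:
    """Load an FFQ schema from YAML (packaged default when ``source`` is None)."""
    if source is None:
        raw = yaml.safe_load(
            resources.files("mrsdat.data").joinpath(_SCHEMA_RESOURCE).read_text()
        )
    elif isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = yaml.safe_load(source)
    if not isinstance(raw, Mapping) or "questions" not in raw:
        raise ConfigError("FFQ schema must be a mapping with a 'questions' list")
    questions = []
    for q in raw["questions"]:
        kind = q.get("kind", "serves")
        if kind not in QUESTION_KINDS:
            raise ConfigError(f"{q.get('question_id')}: bad kind {kind!r}")
        basis = q.get("frequency_basis", "per_day")
        if basis not in FREQUENCY_BASES:
            raise ConfigError(f"{q.get('question_id')}: bad frequency_basis {basis!r}")
        options = tuple(
            FfqOption(label=str(o["label"]), lo=float(o["lo"]), hi=float(o["hi"]))
            for o in q["options"]
        )
        _validate_options(q["question_id"], options)
        questions.append(
            FfqQuestion(
                question_id=str(q["question_id"]),
                kind=kind,
                frequency_basis=basis,
                options=options,
                food_group=q.get("food_group"),
                target=q.get("target"),
                prompt=q.get("prompt", ""),
            )
        )
    schema = FfqSchema(questions=tuple(questions))
    for q in schema.serves_questions():
        if q.food_group not in FOOD_GROUPS:
            raise ConfigError(
                f"{q.question_id}: unknown food_group {q.food_group!r}"
            )
    return schema


def _validate_options(question_id: str, options: Sequence[FfqOption]) -> None:
    if not options:
        raise ConfigError(f"{question_id}: no response options")
    for opt in options:
        if opt.hi < opt.lo:
            raise ConfigError(f"{question_id}: option {opt.label!r} has hi < lo")
    # Ranged options must be ordered and non-overlapping (shared boundaries ok).
    ranged = [o for o in options if o.hi > o.lo]
    for a, b in zip(ranged, ranged[1:]):
        if b.lo < a.hi:
            raise ConfigError(
                f"{question_id}: options {a.label!r} and {b.label!r} overlap"
            )


# ---------------------------------------------------------------------------
# operations


def ffq_to_serves(
    responses: FfqResponseSet,
    schema: FfqSchema,
    missing: str = "error",
) -> FoodGroupIntake:
    """Map a response set to daily food-group serves.

    ``missing`` policy for an unanswered question: ``"error"`` (default)
    aborts with :class:`MissingDataError`; ``"zero"`` imputes zero serves /
    the lowest option with a logged warning — silent imputation would bias
    scores invisibly, so the warning is not suppressible.
    """
    if missing not in ("error", "zero"):
        raise ConfigError(f"missing policy must be 'error' or 'zero', got {missing!r}")
    for qid in responses.selections:
        schema.question(qid)  # unknown question id -> SchemaError
    serves: dict[str, float] = {fg: 0.0 for fg in FOOD_GROUPS}
    wholegrain = 0.0
    water = False
    fats = 0.0
    for q in schema:
        label = responses.selections.get(q.question_id)
        if label is None:
            if missing == "error":
                raise MissingDataError(
                    f"participant {responses.participant_id!r} did not answer "
                    f"{q.question_id!r}"
                )
            warnings.warn(
                f"imputing zero for unanswered {q.question_id!r} "
                f"(participant {responses.participant_id!r})",
                stacklevel=2,
            )
            value = 0.0
        else:
            value = q.daily_value(label)
        if q.kind == "serves":
            serves[q.food_group] = serves.get(q.food_group, 0.0) + value
        elif q.target == "wholegrain_fraction":
            wholegrain = value
        elif q.target == "plain_water":
            water = value > 0.0
        elif q.target == "healthy_fats":
            fats = value
        else:
            raise ConfigError(f"{q.question_id}: unhandled target {q.target!r}")
    return FoodGroupIntake(
        participant_id=responses.participant_id,
        method="mrsdat",
        serves=serves,
        wholegrain_fraction=wholegrain,
        plain_water=water,
        healthy_fats=fats,
        variety_count=variety_from_serves(serves),
        n_days_averaged=1,
    )


def average_recalls(days: Sequence[RecallDay]) -> FoodGroupIntake:
    """Arithmetic mean of a participant's recall days.

    Plain water is "any day yes"; healthy fats averages to the fraction of
    days with healthy-fat use; the variety count averages then rounds half-up.
    """
    if not days:
        raise MissingDataError("average_recalls requires at least one recall day")
    pids = {d.participant_id for d in days}
    if len(pids) > 1:
        raise SchemaError(f"recall days mix participants: {sorted(pids)}")
    n = len(days)
    groups = sorted({fg for d in days for fg in d.serves})
    serves = {fg: sum(d.serves.get(fg, 0.0) for d in days) / n for fg in groups}
    for fg, v in serves.items():
        if not math.isfinite(v) or v < 0:
            raise SchemaError(f"non-finite or negative serves for {fg!r}")
    mean_variety = sum(d.variety_count for d in days) / n
    return FoodGroupIntake(
        participant_id=days[0].participant_id,
        method="recall_average",
        serves=serves,
        wholegrain_fraction=sum(d.wholegrain_fraction for d in days) / n,
        plain_water=any(d.plain_water for d in days),
        healthy_fats=sum(1.0 for d in days if d.healthy_fats) / n,
        variety_count=int(math.floor(mean_variety + 0.5)),
        n_days_averaged=n,
    )


#: Generous per-group daily-serve plausibility bounds for analyst review.
DEFAULT_PLAUSIBILITY_BOUNDS: dict[str, tuple[float, float]] = {
    "vegetables": (0.0, 15.0),
    "fruit": (0.0, 15.0),
    "breads_cereals": (0.0, 20.0),
    "meat": (0.0, 15.0),
    "dairy": (0.0, 15.0),
    "ssb": (0.0, 20.0),
    "discretionary": (0.0, 25.0),
}

NEAR_ZERO_TOTAL_SERVES = 0.5


@dataclass(frozen=True)
class PlausibilityFlag:
    participant_id: str
    kind: str  # "bound" | "near_zero_total"
    food_group: str | None
    value: float
    message: str


def plausibility_check(
    intake: FoodGroupIntake,
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> list[PlausibilityFlag]:
    """Flag (never drop) implausible records for analyst review.

    Returns a flag per food group outside its configured bound, plus a
    near-zero-total flag when the summed serves across all groups fall below
    :data:`NEAR_ZERO_TOTAL_SERVES` — the signature of a day with almost no
    reported food intake.
    """
    bounds = DEFAULT_PLAUSIBILITY_BOUNDS if bounds is None else bounds
    flags: list[PlausibilityFlag] = []
    for fg, value in intake.serves.items():
        lo, hi = bounds.get(fg, (0.0, math.inf))
        if not (lo <= value <= hi):
            flags.append(
                PlausibilityFlag(
                    participant_id=intake.participant_id,
                    kind="bound",
                    food_group=fg,
                    value=value,
                    message=f"{fg}={value:g} serves/day outside [{lo:g}, {hi:g}]",
                )
            )
    total = sum(intake.serves.values())
    if total < NEAR_ZERO_TOTAL_SERVES:
        flags.append(
            PlausibilityFlag(
                participant_id=intake.participant_id,
                kind="near_zero_total",
                food_group=None,
                value=total,
                message=f"near-zero total intake ({total:g} serves/day)",
            )
        )
    return flags


# ---------------------------------------------------------------------------
# tabular I/O

RECALL_COLUMNS = (
    ["participant_id", "recall_index", "day_type"]
    + list(FOOD_GROUPS)
    + ["wholegrain_fraction", "plain_water", "healthy_fats", "variety_count"]
)

FFQ_RESPONSE_COLUMNS = ["participant_id", "question_id", "option_label"]


def read_recall_days(path: str | Path, lax: bool = False) -> list[RecallDay]:
    """Read recall days from CSV with the documented column set."""
    df = pd.read_csv(path, comment="#")
    _check_columns(df, RECALL_COLUMNS, lax=lax, what="recall-day CSV")
    days = []
    for _, row in df.iterrows():
        days.append(
            RecallDay(
                participant_id=str(row["participant_id"]),
                recall_index=int(row["recall_index"]),
                day_type=None if pd.isna(row.get("day_type")) else str(row["day_type"]),
                serves={fg: float(row[fg]) for fg in FOOD_GROUPS},
                wholegrain_fraction=float(row["wholegrain_fraction"]),
                plain_water=bool(row["plain_water"]),
                healthy_fats=bool(row["healthy_fats"]),
                variety_count=int(row["variety_count"]),
            )
        )
    return days


def read_ffq_responses(path: str | Path, lax: bool = False) -> list[FfqResponseSet]:
    """Read long-format FFQ responses (participant_id, question_id, option_label)."""
    df = pd.read_csv(path, comment="#")
    _check_columns(df, FFQ_RESPONSE_COLUMNS, lax=lax, what="FFQ response CSV")
    out = []
    for pid, sub in df.groupby("participant_id", sort=False):
        dup = sub["question_id"].duplicated()
        if dup.any():
            raise SchemaError(
                f"participant {pid!r} answered "
                f"{sorted(sub.loc[dup, 'question_id'])} more than once"
            )
        out.append(
            FfqResponseSet(
                participant_id=str(pid),
                selections=dict(
                    zip(sub["question_id"].astype(str), sub["option_label"].astype(str))
                ),
            )
        )
    return out


def recall_days_to_frame(days: Iterable[RecallDay]) -> pd.DataFrame:
    rows = []
    for d in days:
        row = {
            "participant_id": d.participant_id,
            "recall_index": d.recall_index,
            "day_type": d.day_type,
            **{fg: d.serves.get(fg, 0.0) for fg in FOOD_GROUPS},
            "wholegrain_fraction": d.wholegrain_fraction,
            "plain_water": int(d.plain_water),
            "healthy_fats": int(d.healthy_fats),
            "variety_count": d.variety_count,
        }
        rows.append(row)
    return pd.DataFrame(rows, columns=RECALL_COLUMNS)


def ffq_responses_to_frame(responses: Iterable[FfqResponseSet]) -> pd.DataFrame:
    rows = [
        {"participant_id": r.participant_id, "question_id": qid, "option_label": label}
        for r in responses
        for qid, label in r.selections.items()
    ]
    return pd.DataFrame(rows, columns=FFQ_RESPONSE_COLUMNS)


def _check_columns(
    df: pd.DataFrame, expected: Sequence[str], lax: bool, what: str
) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} missing columns: {missing}")
    unknown = [c for c in df.columns if c not in expected]
    if unknown and not lax:
        raise SchemaError(
            f"{what} has unknown columns {unknown}; pass lax=True to ignore"
        )
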