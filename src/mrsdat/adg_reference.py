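"""Age/life-stage taxonomy and recommended daily serves.

Every diet-quality indicator denominator comes from an Australian Dietary
Guidelines (ADG) style recommendation table: for each age/sex/life-stage
group, the recommended daily serves of the five food groups plus the
penalty-food limits (discretionary foods, sugar-sweetened beverages).
The table ships as an editable YAML file so scoring is always reproducible
under a declared reference table rather than hard-coded constants.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Mapping

import yaml

from .errors import ConfigError, UnsupportedAgeError

#: The five core food groups scored proportionally, plus the two penalised ones.
CORE_FOOD_GROUPS = ("vegetables", "fruit", "breads_cereals", "meat", "dairy")
PENALTY_FOOD_GROUPS = ("ssb", "discretionary")
FOOD_GROUPS = CORE_FOOD_GROUPS + PENALTY_FOOD_GROUPS

SEXES = ("male", "female", "any")
LIFE_STAGES = ("child", "adult", "pregnant_breastfeeding")

_DEFAULT_RESOURCE = "adg_recommendations.yaml"


@dataclass(frozen=True)
class AgeLifeStageGroup:
    """One age/sex/life-stage category with its recommended serves.

    Ages are months; the interval is half-open ``[age_lo_months,
    age_hi_months)`` so "6-<24 months" style boundaries are unambiguous.
    ``under_two`` groups have the dairy indicator excluded from scoring.
    """

    group_id: str
    label: str
    age_lo_months: int
    age_hi_months: int
    sex: str
    life_stage: str
    recommended_serves: Mapping[str, float]
    discretionary_limit: float
    ssb_limit: float
    dairy_applicable: bool

    @property
    def under_two(self) -> bool:
        return self.age_hi_months <= 24

    def contains(self, age_months: float, sex: str) -> bool:
        in_age = self.age_lo_months <= age_months < self.age_hi_months
        in_sex = self.sex == "any" or sex == "any" or self.sex == sex
        return in_age and in_sex


@dataclass(frozen=True)
class Participant:
    """Minimal participant record used to stratify and subset analyses."""

    participant_id: str
    group_id: str
    region: str | None = None
    n_recalls: int = 0


@dataclass
class RecommendationTable:
    """Validated collection of :class:`AgeLifeStageGroup` rows."""

    groups: dict[str, AgeLifeStageGroup] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate()

    def __len__(self) -> int:
        return len(self.groups)

    def __iter__(self):
        return iter(self.groups.values())

    def group(self, group_id: str) -> AgeLifeStageGroup:
        try:
            return self.groups[group_id]
        except KeyError:
            raise ConfigError(f"unknown group_id {group_id!r}") from None

    def resolve_group(
        self, age_months: float, sex: str = "any", life_stage: str = "child"
    ) -> AgeLifeStageGroup:
        """Return the unique group matching an age, sex and life stage.

        A pregnant/breastfeeding life stage supersedes the age/sex lookup
        and always maps to the dedicated group. For everything else the
        half-open age intervals plus the sex field determine the match.
        """
        if sex not in SEXES:
            raise ConfigError(f"sex must be one of {SEXES}, got {sex!r}")
        if life_stage not in LIFE_STAGES:
            raise ConfigError(
                f"life_stage must be one of {LIFE_STAGES}, got {life_stage!r}"
            )
        if life_stage == "pregnant_breastfeeding":
            for g in self.groups.values():
                if g.life_stage == "pregnant_breastfeeding":
                    return g
            raise UnsupportedAgeError("no pregnant/breastfeeding group configured")
        matches = [
            g
            for g in self.groups.values()
            if g.life_stage == life_stage and g.contains(age_months, sex)
        ]
        if not matches:
            raise UnsupportedAgeError(
                f"no {life_stage} group covers age {age_months} months (sex={sex})"
            )
        if len(matches) > 1:
            # Partition validation at load time should make this unreachable
            # unless the caller passed sex='any' for a sex-specific age band.
            raise UnsupportedAgeError(
                f"age {age_months} months is ambiguous without a sex: "
                + ", ".join(g.group_id for g in matches)
            )
        return matches[0]

    def recommended(self, group_id: str, food_group: str) -> float:
        group = self.group(group_id)
        try:
            return group.recommended_serves[food_group]
        except KeyError:
            raise ConfigError(
                f"group {group_id!r} has no recommendation for {food_group!r}"
            ) from None

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "groups": [
                {
                    "group_id": g.group_id,
                    "label": g.label,
                    "age_lo_months": g.age_lo_months,
                    "age_hi_months": g.age_hi_months,
                    "sex": g.sex,
                    "life_stage": g.life_stage,
                    "dairy_applicable": g.dairy_applicable,
                    "recommended_serves": dict(g.recommended_serves),
                    "discretionary_limit": g.discretionary_limit,
                    "ssb_limit": g.ssb_limit,
                }
                for g in self.groups.values()
            ],
        }

    def to_yaml(self, stream: IO[str] | None = None) -> str | None:
        return yaml.safe_dump(self.to_dict(), stream, sort_keys=False)

    # -- validation ----------------------------------------------------

    def _validate(self) -> None:
        problems: list[str] = []
        for g in self.groups.values():
            if g.age_lo_months >= g.age_hi_months:
                problems.append(f"{g.group_id}: age_lo >= age_hi")
            if g.sex not in SEXES:
                problems.append(f"{g.group_id}: bad sex {g.sex!r}")
            if g.life_stage not in LIFE_STAGES:
                problems.append(f"{g.group_id}: bad life_stage {g.life_stage!r}")
            if g.dairy_applicable == g.under_two:
                problems.append(
                    f"{g.group_id}: dairy_applicable must be false exactly for "
                    "under-2 groups"
                )
            for fg in CORE_FOOD_GROUPS:
                if fg not in g.recommended_serves:
                    problems.append(f"{g.group_id}: missing recommendation for {fg}")
                elif not g.recommended_serves[fg] > 0:
                    problems.append(
                        f"{g.group_id}: non-positive recommendation for {fg}"
                    )
            if not g.discretionary_limit > 0:
                problems.append(f"{g.group_id}: discretionary_limit must be > 0")
            if not g.ssb_limit > 0:
                problems.append(f"{g.group_id}: ssb_limit must be > 0")
        # Age bands must not overlap within a sex/life-stage stratum.
        for sex in ("male", "female"):
            for stage in ("child", "adult"):
                bands = sorted(
                    (g.age_lo_months, g.age_hi_months, g.group_id)
                    for g in self.groups.values()
                    if g.life_stage == stage and g.sex in ("any", sex)
                )
                for (lo1, hi1, id1), (lo2, hi2, id2) in zip(bands, bands[1:]):
                    if lo2 < hi1:
                        problems.append(
                            f"overlapping {stage}/{sex} age bands: {id1}, {id2}"
                        )
        if problems:
            raise ConfigError("invalid recommendation table:\n  " + "\n  ".join(problems))


def _parse_group(row: Mapping) -> AgeLifeStageGroup:
    required = {
        "group_id",
        "label",
        "age_lo_months",
        "age_hi_months",
        "sex",
        "life_stage",
        "dairy_applicable",
        "recommended_serves",
        "discretionary_limit",
        "ssb_limit",
    }
    missing = required - set(row)
    if missing:
        raise ConfigError(
            f"group {row.get('group_id', '<no id>')!r} missing fields: "
            + ", ".join(sorted(missing))
        )
    return AgeLifeStageGroup(
        group_id=str(row["group_id"]),
        label=str(row["label"]),
        age_lo_months=int(row["age_lo_months"]),
        age_hi_months=int(row["age_hi_months"]),
        sex=str(row["sex"]),
        life_stage=str(row["life_stage"]),
        recommended_serves={k: float(v) for k, v in row["recommended_serves"].items()},
        discretionary_limit=float(row["discretionary_limit"]),
        ssb_limit=float(row["ssb_limit"]),
        dairy_applicable=bool(row["dairy_applicable"]),
    )


def load_recommendations(
    source: str | Path | IO[str] | None = None,
) -> RecommendationTable:
    """Load and validate a recommendation table.

    ``source`` may be a path, an open text stream, or ``None`` for the
    packaged default taxonomy (14 groups spanning 6 months to 120 years).
    Any schema violation raises :class:`ConfigError` naming every
    offending row, never a partial table.
    """
    if source is None:
        text = (
            resources.files("mrsdat.data").joinpath(_DEFAULT_RESOURCE).read_text()
        )
        raw = yaml.safe_load(text)
    elif isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    elif isinstance(source, io.TextIOBase) or hasattr(source, "read"):
        raw = yaml.safe_load(source)
    else:
        raise ConfigError(f"cannot load recommendations from {type(source)!r}")
    if not isinstance(raw, Mapping) or "groups" not in raw:
        raise ConfigError("recommendation config must be a mapping with a 'groups' list")
    groups = {}
    for row in raw["groups"]:
        g = _parse_group(row)
        if g.group_id in groups:
            raise ConfigError(f"duplicate group_id {g.group_id!r}")
        groups[g.group_id] = g
    return RecommendationTable(groups=groups)
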