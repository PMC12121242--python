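"""Synthetic cohorts with the statistical structure the analysis assumes.

Real FFQ-vs-recall validation data of this kind are typically restricted, so
the generator emulates the features that drive the statistics: a mix of
age/life-stage groups from infants to older adults, one to three recall days
per participant, right-skewed (log-normal) usual intakes, zero-intake days
for episodic foods (sugary drinks, discretionary foods), multiplicative
day-to-day variability in what is actually eaten, and method-specific FFQ
reporting error (per-food-group bias plus within-person noise, snapped to
the FFQ's response options).

The generative model per participant i and food group g:

* usual intake  U_ig ~ LogNormal(ln median_g, dispersion_g)
* recall day d  R_igd = U_ig x exp(N(-s^2/2, s)) x Z_gd / (1 - p_g)
  with Z_gd ~ Bernoulli(1 - p_g) the episodic-consumption indicator, so a
  day's expected intake equals the usual intake;
* FFQ report    F_ig = snap(U_ig x bias_g x exp(N(-t^2/2, t)))
  where snap() selects the nearest response option of the FFQ schema.

All randomness flows from one seed through named per-participant substreams,
so output is invariant to generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .adg_reference import (
    CORE_FOOD_GROUPS,
    FOOD_GROUPS,
    Participant,
    RecommendationTable,
    load_recommendations,
)
from .dgi_scoring import total_dgi
from .errors import ConfigError
from .intake_model import (
    FfqResponseSet,
    FfqSchema,
    FoodGroupIntake,
    RecallDay,
    average_recalls,
    ffq_to_serves,
    load_ffq_schema,
    variety_from_serves,
)

#: group mix matching a cohort of young children, pregnant/breastfeeding
#: women and adults (proportions of participants per group).
DEFAULT_GROUP_MIX: dict[str, float] = {
    "child_6_24m": 0.07,
    "child_2_4y": 0.13,
    "child_4_6y": 0.11,
    "pregnant_breastfeeding": 0.23,
    "male_19_50": 0.12,
    "female_19_50": 0.23,
    "male_51_70": 0.03,
    "female_51_70": 0.08,
}

#: most participants complete one or two recalls; a few manage three.
DEFAULT_RECALLS_DIST: dict[int, float] = {1: 0.36, 2: 0.60, 3: 0.04}

#: log-normal usual-intake parameters (median serves/day, log-scale dispersion),
#: on the scale typical of remote-community food-group intakes.
DEFAULT_USUAL_INTAKE: dict[str, tuple[float, float]] = {
    "vegetables": (1.4, 0.7),
    "fruit": (0.8, 0.9),
    "breads_cereals": (5.0, 0.5),
    "meat": (2.5, 0.6),
    "dairy": (1.3, 0.7),
    "ssb": (0.5, 1.0),
    "discretionary": (3.0, 0.7),
}

#: probability a recall day has zero intake of an episodic food group
DEFAULT_EPISODIC_ZERO_PROB: dict[str, float] = {
    "fruit": 0.25,
    "ssb": 0.40,
    "discretionary": 0.20,
}

#: wholegrain habit levels (share of breads/cereals that are wholegrain) and
#: their population mix — most people eat none or some wholegrain
WHOLEGRAIN_LEVELS = (0.0, 0.3, 0.7, 1.0)
WHOLEGRAIN_LEVEL_PROBS = (0.35, 0.35, 0.2, 0.1)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Generative parameters for one synthetic cohort."""

    n_participants: int = 100
    group_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_MIX)
    )
    recalls_per_participant: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_RECALLS_DIST)
    )
    usual_intake_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_USUAL_INTAKE)
    )
    episodic_zero_prob: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EPISODIC_ZERO_PROB)
    )
    day_effect_sd: float = 0.4  # log-scale day-to-day multiplicative noise
    ffq_bias: Mapping[str, float] = field(default_factory=dict)  # default 1.0
    ffq_noise_sd: float = 0.25  # log-scale within-person FFQ error
    plain_water_prob: float = 0.98
    healthy_fats_prev: float = 0.5  # prevalence of habitual healthy-fat use
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if abs(sum(self.group_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("group_mix proportions must sum to 1")
        if abs(sum(self.recalls_per_participant.values()) - 1.0) > 1e-9:
            raise ConfigError("recalls_per_participant probabilities must sum to 1")
        if any(k < 1 for k in self.recalls_per_participant):
            raise ConfigError("recall counts must be >= 1")
        for fg in FOOD_GROUPS:
            if fg not in self.usual_intake_params:
                raise ConfigError(f"usual_intake_params missing {fg!r}")
            med, disp = self.usual_intake_params[fg]
            if med <= 0 or disp < 0:
                raise ConfigError(f"bad usual-intake params for {fg!r}")
        for fg, p in self.episodic_zero_prob.items():
            if not (0.0 <= p < 1.0):
                raise ConfigError(f"episodic_zero_prob[{fg!r}] must be in [0, 1)")
        if self.day_effect_sd < 0 or self.ffq_noise_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        if not (0.0 <= self.plain_water_prob <= 1.0):
            raise ConfigError("plain_water_prob must be in [0, 1]")
        if not (0.0 <= self.healthy_fats_prev <= 1.0):
            raise ConfigError("healthy_fats_prev must be in [0, 1]")


@dataclass
class SyntheticCohort:
    """Generator output: inputs for both methods plus the generating truth."""

    spec: SyntheticCohortSpec
    participants: list[Participant]
    ffq_responses: list[FfqResponseSet]
    recall_days: list[RecallDay]
    truth: pd.DataFrame  # participant_id, group_id, usual serves, true_dgi


def _lognormal(rng: np.random.Generator, median: float, dispersion: float) -> float:
    return float(median * math.exp(rng.normal(0.0, dispersion))) if dispersion > 0 else median


def _mean_one_noise(rng: np.random.Generator, sd: float) -> float:
    """Multiplicative noise with expectation 1 (log-normal, mean-corrected)."""
    if sd == 0:
        return 1.0
    return float(math.exp(rng.normal(-0.5 * sd * sd, sd)))


def generate_cohort(
    spec: SyntheticCohortSpec,
    schema: FfqSchema | None = None,
    recs: RecommendationTable | None = None,
) -> SyntheticCohort:
    """Draw one cohort: participants, FFQ responses, recall days, and truth.

    Deterministic given ``spec.seed``; each participant consumes an
    independent substream spawned from the root seed.
    """
    spec.validate()
    schema = schema or load_ffq_schema()
    recs = recs or load_recommendations()
    for gid in spec.group_mix:
        recs.group(gid)  # unknown group -> ConfigError

    group_ids = list(spec.group_mix)
    group_p = np.array([spec.group_mix[g] for g in group_ids])
    recall_ks = list(spec.recalls_per_participant)
    recall_p = np.array([spec.recalls_per_participant[k] for k in recall_ks])

    substreams = np.random.SeedSequence(spec.seed).spawn(spec.n_participants)
    participants: list[Participant] = []
    ffq_responses: list[FfqResponseSet] = []
    recall_days: list[RecallDay] = []
    truth_rows: list[dict] = []
    width = len(str(spec.n_participants))

    for i, ss in enumerate(substreams):
        rng = np.random.default_rng(ss)
        pid = f"P{i + 1:0{width}d}"
        gid = group_ids[rng.choice(len(group_ids), p=group_p)]
        group = recs.group(gid)
        n_recalls = int(recall_ks[rng.choice(len(recall_ks), p=recall_p)])

        usual = {
            fg: _lognormal(rng, *spec.usual_intake_params[fg]) for fg in FOOD_GROUPS
        }
        # Habit-level quality traits. Wholegrain behaviour sits at the FFQ's
        # own response levels; healthy-fat use is a binary habit. Day-to-day
        # departures from habit are governed by day_effect_sd, so the
        # noise-free spec is genuinely degenerate.
        wholegrain = float(rng.choice(WHOLEGRAIN_LEVELS, p=WHOLEGRAIN_LEVEL_PROBS))
        water = bool(rng.random() < spec.plain_water_prob)
        fats_use = bool(rng.random() < spec.healthy_fats_prev)
        fats_flip = min(0.45, 0.5 * spec.day_effect_sd)
        wg_jitter_sd = 0.25 * spec.day_effect_sd

        # --- recall days -------------------------------------------------
        for d in range(1, n_recalls + 1):
            serves = {}
            for fg in FOOD_GROUPS:
                p_zero = spec.episodic_zero_prob.get(fg, 0.0)
                if p_zero > 0 and rng.random() < p_zero:
                    serves[fg] = 0.0
                else:
                    day = usual[fg] * _mean_one_noise(rng, spec.day_effect_sd)
                    serves[fg] = day / (1.0 - p_zero) if p_zero > 0 else day
            day_wholegrain = wholegrain
            if wg_jitter_sd > 0:
                day_wholegrain = float(
                    np.clip(wholegrain + rng.normal(0.0, wg_jitter_sd), 0.0, 1.0)
                )
            day_fats = fats_use
            if fats_flip > 0 and rng.random() < fats_flip:
                day_fats = not day_fats
            recall_days.append(
                RecallDay(
                    participant_id=pid,
                    recall_index=d,
                    serves=serves,
                    wholegrain_fraction=day_wholegrain,
                    plain_water=water,
                    healthy_fats=day_fats,
                    variety_count=variety_from_serves(serves),
                )
            )

        # --- FFQ response: usual x bias x noise, snapped to options ------
        selections: dict[str, str] = {}
        for q in schema:
            if q.kind == "serves":
                bias = spec.ffq_bias.get(q.food_group, 1.0)
                reported = usual[q.food_group] * bias * _mean_one_noise(
                    rng, spec.ffq_noise_sd
                )
                selections[q.question_id] = q.option_for_value(reported).label
            elif q.target == "wholegrain_fraction":
                selections[q.question_id] = q.option_for_value(wholegrain).label
            elif q.target == "plain_water":
                selections[q.question_id] = q.option_for_value(1.0 if water else 0.0).label
            elif q.target == "healthy_fats":
                selections[q.question_id] = q.option_for_value(
                    1.0 if fats_use else 0.0
                ).label
        ffq_responses.append(FfqResponseSet(participant_id=pid, selections=selections))

        participants.append(
            Participant(participant_id=pid, group_id=gid, n_recalls=n_recalls)
        )
        true_intake = FoodGroupIntake(
            participant_id=pid,
            method="truth",
            serves=usual,
            wholegrain_fraction=wholegrain,
            plain_water=water,
            healthy_fats=1.0 if fats_use else 0.0,
            variety_count=variety_from_serves(usual),
            n_days_averaged=1,
        )
        true_score = total_dgi(true_intake, group)
        truth_rows.append(
            {
                "participant_id": pid,
                "group_id": gid,
                **{f"usual_{fg}": usual[fg] for fg in FOOD_GROUPS},
                "true_dgi": true_score.rescaled_total,
            }
        )

    truth = pd.DataFrame(truth_rows)
    return SyntheticCohort(
        spec=spec,
        participants=participants,
        ffq_responses=ffq_responses,
        recall_days=recall_days,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# scoring and recovery


def score_cohort(
    cohort: SyntheticCohort,
    schema: FfqSchema | None = None,
    recs: RecommendationTable | None = None,
) -> pd.DataFrame:
    """Score every participant with both methods.

    Returns one row per participant: group, number of recalls, and the
    rescaled FFQ and recall-average totals.
    """
    schema = schema or load_ffq_schema()
    recs = recs or load_recommendations()
    days_by_pid: dict[str, list[RecallDay]] = {}
    for day in cohort.recall_days:
        days_by_pid.setdefault(day.participant_id, []).append(day)
    rows = []
    responses = {r.participant_id: r for r in cohort.ffq_responses}
    for p in cohort.participants:
        group = recs.group(p.group_id)
        ffq_intake = ffq_to_serves(responses[p.participant_id], schema)
        recall_intake = average_recalls(days_by_pid[p.participant_id])
        s_ffq = total_dgi(ffq_intake, group)
        s_rec = total_dgi(recall_intake, group)
        rows.append(
            {
                "participant_id": p.participant_id,
                "group_id": p.group_id,
                "n_recalls": p.n_recalls,
                "mrsdat_total": s_ffq.rescaled_total,
                "recall_total": s_rec.rescaled_total,
            }
        )
    return pd.DataFrame(rows)


def recovery_experiment(
    spec: SyntheticCohortSpec, n_reps: int = 50, seed: int | None = None
) -> pd.DataFrame:
    """Generate-score-compare over ``n_reps`` replicates.

    Each replicate draws a fresh cohort (independent substream of ``seed``,
    defaulting to ``spec.seed``), scores both methods, and records the mean
    FFQ-minus-recall score difference, Lin's CCC and the weighted tertile
    kappa. The returned frame has one row per replicate plus a trailing
    ``"summary"`` row holding means with Monte-Carlo standard errors in
    ``*_se`` columns.
    """
    from .concordance import PairedSample, assign_tertiles, lins_ccc, weighted_kappa

    if n_reps < 1:
        raise ConfigError("n_reps must be >= 1")
    root = seed if seed is not None else spec.seed
    rep_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(root).spawn(n_reps)
    ]
    rows = []
    for rep, rep_seed in enumerate(rep_seeds):
        cohort = generate_cohort(replace(spec, seed=rep_seed))
        totals = score_cohort(cohort)
        sample = PairedSample(
            participant_ids=tuple(totals["participant_id"]),
            x=totals["mrsdat_total"].to_numpy(),
            y=totals["recall_total"].to_numpy(),
        )
        rc, _ = lins_ccc(sample)
        kappa = weighted_kappa(assign_tertiles(sample.x), assign_tertiles(sample.y))
        rows.append(
            {
                "replicate": rep,
                "seed": rep_seed,
                "n": sample.n,
                "bias": float(np.mean(sample.x - sample.y)),
                "rc": rc,
                "kappa_w": kappa,
            }
        )
    df = pd.DataFrame(rows)
    summary = {
        "replicate": "summary",
        "seed": root,
        "n": df["n"].mean(),
        "bias": df["bias"].mean(),
        "rc": df["rc"].mean(),
        "kappa_w": df["kappa_w"].mean(),
        "bias_se": df["bias"].std(ddof=1) / math.sqrt(n_reps) if n_reps > 1 else 0.0,
        "rc_se": df["rc"].std(ddof=1) / math.sqrt(n_reps) if n_reps > 1 else 0.0,
        "kappa_w_se": df["kappa_w"].std(ddof=1) / math.sqrt(n_reps) if n_reps > 1 else 0.0,
    }
    return pd.concat([df, pd.DataFrame([summary])], ignore_index=True)
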