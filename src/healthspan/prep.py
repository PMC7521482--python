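"""Cohort preparation: cognitive-state classification, derived exposures,
risk profiles, post-stratification weights, and panel assembly.

Cognitive status is classified from the Chinese MMSE (cMMSE, 0–30) with the
education-specific cutoffs in common use in China: 17/18 for no formal
education, 20/21 for primary school (1–6 years), 24/25 for middle school or
higher (7+ years).  Exposures (smoking, alcohol, diet, marriage, four
leisure activities) combine into a 0–3 component risk profile.  Designed
oversampling of the oldest old is corrected by post-stratification weights
against a target age × sex × residence distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

STATE_CI_FREE = 1
STATE_CI = 2
STATE_DEAD = 3


class EducationBand(str, Enum):
    """Education bands carrying the cMMSE cutoff for probable dementia."""

    NONE = "none"          # 0 years of schooling
    PRIMARY = "primary"    # 1-6 years
    MIDDLE_PLUS = "middle_plus"  # 7+ years


#: highest cMMSE score still classified as cognitively impaired, per band
CMMSE_CUTOFFS: dict[EducationBand, int] = {
    EducationBand.NONE: 17,
    EducationBand.PRIMARY: 20,
    EducationBand.MIDDLE_PLUS: 24,
}

DIET_FOODS = ("fruit", "vegetables", "legumes", "fish")
DIET_FREQUENCIES = ("daily", "weekly", "monthly", "occasionally", "rarely")
#: frequencies counting as "at least once per week"
_WEEKLY_OR_MORE = {"daily", "weekly"}

RISK_LABELS = {0: "high", 1: "medium_high", 2: "medium_low", 3: "low"}


class InvalidScoreError(ValueError):
    """cMMSE score outside the 0–30 range."""


class InvalidCategoryError(ValueError):
    """Unknown categorical level in a derived-variable input."""


class UnsupportedStratumError(ValueError):
    """Target stratum with positive share has no sampled subjects."""


def classify_cognition(score, education: EducationBand | str):
    """Map a cMMSE score to a cognitive state using education-based cutoffs.

    Returns ``STATE_CI`` (2) at or below the band's cutoff, ``STATE_CI_FREE``
    (1) above it, and NaN for a missing score (test not completed).  Items a
    respondent was unable to answer are assumed already scored as incorrect
    in ``score``.
    """
    band = EducationBand(education)
    if score is None or (isinstance(score, float) and np.isnan(score)):
        return np.nan
    s = float(score)
    if not s.is_integer() or not 0 <= s <= 30:
        raise InvalidScoreError(f"cMMSE score must be an integer in [0, 30], got {score!r}")
    return STATE_CI if s <= CMMSE_CUTOFFS[band] else STATE_CI_FREE


UNABLE_TO_ANSWER = "unable"


def cmmse_score(item_points: Sequence) -> int:
    """Total a cMMSE test from per-item points (0-30 overall).

    Each entry is the points earned on an item; ``UNABLE_TO_ANSWER`` (or
    None) counts as incorrect, i.e. zero points.  Use this upstream of
    :func:`classify_cognition`, which expects the final score.
    """
    total = 0
    for p in item_points:
        if p is None or p == UNABLE_TO_ANSWER:
            continue
        if not float(p).is_integer() or p < 0:
            raise InvalidScoreError(f"invalid item points {p!r}")
        total += int(p)
    if total > 30:
        raise InvalidScoreError(f"item points total {total} exceeds the 0-30 scale")
    return total


def classify_diet(frequencies: Mapping[str, str]) -> str:
    """Dietary pattern: healthy iff ≥3 of fruit / green leafy vegetables /
    legumes / fish are eaten at least once per week."""
    missing = set(DIET_FOODS) - set(frequencies)
    if missing:
        raise InvalidCategoryError(f"missing food frequencies: {sorted(missing)}")
    n = 0
    for food in DIET_FOODS:
        level = frequencies[food]
        if level not in DIET_FREQUENCIES:
            raise InvalidCategoryError(f"unknown frequency {level!r} for {food}")
        n += level in _WEEKLY_OR_MORE
    return "healthy" if n >= 3 else "unhealthy"


@dataclass(frozen=True)
class ExposureProfile:
    """Baseline modifiable factors for one subject (all fields required)."""

    smoking: str           # never / former / current
    alcohol: str           # drinker / non_drinker
    diet: str              # healthy / unhealthy
    marital: str           # in_marriage / not_in_marriage
    physical: bool
    mental: bool
    social: bool
    productive: bool

    def __post_init__(self) -> None:
        checks = {
            "smoking": ("never", "former", "current"),
            "alcohol": ("drinker", "non_drinker"),
            "diet": ("healthy", "unhealthy"),
            "marital": ("in_marriage", "not_in_marriage"),
        }
        for name, levels in checks.items():
            if getattr(self, name) not in levels:
                raise InvalidCategoryError(
                    f"{name} must be one of {levels}, got {getattr(self, name)!r}"
                )


@dataclass(frozen=True)
class RiskProfile:
    """Count of protective components and its deterministic risk label."""

    n_components: int

    def __post_init__(self) -> None:
        if self.n_components not in RISK_LABELS:
            raise ValueError("n_components must be in 0..3")

    @property
    def label(self) -> str:
        return RISK_LABELS[self.n_components]


def build_risk_profile(exposures: ExposureProfile) -> RiskProfile:
    """Combine exposures into the three-component risk profile.

    Components: (1) healthy lifestyle = never smoking AND healthy diet;
    (2) in marriage with spouse present; (3) at least one of the four
    leisure activities.  0 components → high risk ... 3 → low risk.
    """
    healthy_lifestyle = exposures.smoking == "never" and exposures.diet == "healthy"
    married = exposures.marital == "in_marriage"
    any_leisure = (
        exposures.physical or exposures.mental or exposures.social or exposures.productive
    )
    return RiskProfile(int(healthy_lifestyle) + int(married) + int(any_leisure))


# ---------------------------------------------------------------------------
# post-stratification weights
# ---------------------------------------------------------------------------

#: default 5-year age bands 65–99 plus an open 100+ band (census granularity)
DEFAULT_AGE_BANDS: tuple[tuple[float, float], ...] = tuple(
    (a, a + 5) for a in range(65, 100, 5)
) + ((100, 200),)


def age_band_label(age: float, bands: Sequence[tuple[float, float]] = DEFAULT_AGE_BANDS) -> str:
    for lo, hi in bands:
        if lo <= age < hi:
            return f"{int(lo)}+" if hi >= 200 else f"{int(lo)}-{int(hi) - 1}"
    raise ValueError(f"age {age} outside all bands")


def post_stratification_weights(
    sample_counts: pd.Series, target_props: pd.Series
) -> pd.Series:
    """Per-stratum weights aligning the sample to a target distribution.

    weight(stratum) = target proportion / sample proportion, normalised so
    the mean weight over subjects is 1.  After weighting, the weighted
    stratum proportions equal the target exactly.
    """
    sample_counts = sample_counts.astype(float)
    if (sample_counts <= 0).any():
        raise ValueError("sample counts must be positive")
    missing = set(sample_counts.index) - set(target_props.index)
    if missing:
        raise ValueError(f"no target proportion for strata: {sorted(missing)}")
    extra = target_props.reindex(
        sorted(set(target_props.index) - set(sample_counts.index))
    ).dropna()
    if (extra > 0).any():
        raise UnsupportedStratumError(
            f"target strata absent from the sample: {sorted(extra.index)}"
        )
    n = sample_counts.sum()
    target = target_props.reindex(sample_counts.index).astype(float)
    target = target / target.sum()
    w = target / (sample_counts / n)
    # normalise to mean 1 over subjects
    w = w * n / (w * sample_counts).sum()
    return w


def subject_weights(
    subjects: pd.DataFrame,
    target: pd.DataFrame,
    age_bands: Sequence[tuple[float, float]] = DEFAULT_AGE_BANDS,
) -> pd.Series:
    """Post-stratification weights per subject by age band × sex × residence.

    ``subjects`` needs columns ``subject_id``, ``age``, ``sex``,
    ``residence``; ``target`` needs ``age_band``, ``sex``, ``residence``,
    ``proportion`` (e.g. a census tabulation).
    """
    df = subjects.copy()
    df["age_band"] = [age_band_label(a, age_bands) for a in df["age"]]
    key = ["age_band", "sex", "residence"]
    counts = df.groupby(key).size()
    tgt = target.set_index(key)["proportion"]
    counts.index = counts.index.map(lambda t: "|".join(map(str, t)))
    tgt.index = tgt.index.map(lambda t: "|".join(map(str, t)))
    w = post_stratification_weights(counts, tgt)
    subject_key = df[key].astype(str).agg("|".join, axis=1)
    out = subject_key.map(w)
    out.index = df["subject_id"].values
    out.name = "weight"
    return out


def cohort_flow(
    recruited: Sequence[int], exclusions: Mapping[str, int]
) -> dict[str, int]:
    """Inclusion/exclusion accounting for a multi-wave recruitment design.

    ``recruited`` lists the subjects added at each wave; ``exclusions`` maps
    exclusion reasons to counts.  Returns totals and the analytical sample.
    """
    if any(r < 0 for r in recruited) or any(e < 0 for e in exclusions.values()):
        raise ValueError("counts must be non-negative")
    total = int(sum(recruited))
    excluded = int(sum(exclusions.values()))
    if excluded > total:
        raise ValueError("cannot exclude more subjects than were recruited")
    return {
        "recruited": total,
        "excluded": excluded,
        "analytical_sample": total - excluded,
    }


def baseline_composition(counts: Mapping[str, int]) -> dict[str, float]:
    """Percentage share of each group among the given baseline counts."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    return {k: 100.0 * v / total for k, v in counts.items()}


# ---------------------------------------------------------------------------
# panel assembly and sensitivity filters
# ---------------------------------------------------------------------------


def assemble_panel(raw: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Turn raw per-subject records into an analysis-ready panel.

    Rules applied per subject, in age order:

    * subjects whose baseline cognitive state is missing are excluded
      (counted in the exclusion log);
    * apparent recoveries (a CI-free state observed after a CI state) are
      treated as recording error: the later CI-free observation is set to
      missing rather than overwritten;
    * a final missing living state becomes a ``right_censor`` record;
    * death records keep their exact age and always come last.

    Returns the panel with an added ``record_kind`` column (``wave`` /
    ``death`` / ``right_censor``) and a log of exclusion/recode counts.
    """
    required = {"subject_id", "age", "state", "is_death_record"}
    if required - set(raw.columns):
        raise ValueError(f"raw records missing columns: {sorted(required - set(raw.columns))}")
    out_frames: list[pd.DataFrame] = []
    log = {"excluded_missing_baseline": 0, "recoveries_censored": 0, "subjects_kept": 0}
    for sid, grp in raw.groupby("subject_id", sort=True):
        g = grp.sort_values("age").copy()
        ages = g["age"].to_numpy(dtype=float)
        if np.any(np.diff(ages) <= 0):
            raise ValueError(f"ages not strictly increasing for subject {sid!r}")
        death_mask = g["is_death_record"].to_numpy().astype(bool)
        if death_mask.sum() > 1 or (death_mask.any() and not death_mask[-1]):
            raise ValueError(f"subject {sid!r}: death record must be unique and last")
        states = g["state"].to_numpy(dtype=float)
        living = ~death_mask
        first_living = np.flatnonzero(living)
        if len(first_living) == 0 or np.isnan(states[first_living[0]]):
            log["excluded_missing_baseline"] += 1
            continue
        seen_ci = False
        for i in np.flatnonzero(living):
            if states[i] == STATE_CI:
                seen_ci = True
            elif seen_ci and states[i] == STATE_CI_FREE:
                states[i] = np.nan
                log["recoveries_censored"] += 1
        g["state"] = states
        kind = np.array(["death" if d else "wave" for d in death_mask], dtype=object)
        # a trailing missing living state right-censors the subject there
        if not death_mask[-1] and np.isnan(states[-1]):
            kind[-1] = "right_censor"
        g["record_kind"] = kind
        out_frames.append(g)
        log["subjects_kept"] += 1
    panel = (
        pd.concat(out_frames, ignore_index=True)
        if out_frames
        else raw.iloc[0:0].assign(record_kind=pd.Series(dtype=str))
    )
    return panel, log


def sensitivity_filter(
    panel: pd.DataFrame,
    drop_first_interval_onsets: bool = False,
    drop_first_year_deaths: bool = False,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove subjects per the reverse-causation sensitivity rules.

    Rule 1 removes subjects CI-free at baseline whose first follow-up
    observation with a known state shows CI (onset during the first
    follow-up interval).  Rule 2 removes subjects who died within one year
    of their baseline age.  With both rules off this is the identity.
    """
    drop: set = set()
    counts = {"first_interval_onsets": 0, "first_year_deaths": 0}
    for sid, grp in panel.groupby("subject_id", sort=False):
        g = grp.sort_values("age")
        base_age = float(g["age"].iloc[0])
        if drop_first_interval_onsets:
            living = g[(g["is_death_record"] == 0) & g["state"].notna()]
            if (
                len(living) >= 2
                and living["state"].iloc[0] == STATE_CI_FREE
                and living["state"].iloc[1] == STATE_CI
            ):
                drop.add(sid)
                counts["first_interval_onsets"] += 1
                continue
        if drop_first_year_deaths:
            deaths = g[g["is_death_record"] == 1]
            if len(deaths) and float(deaths["age"].iloc[0]) - base_age <= 1.0:
                drop.add(sid)
                counts["first_year_deaths"] += 1
    out = panel[~panel["subject_id"].isin(drop)].reset_index(drop=True)
    return out, counts
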