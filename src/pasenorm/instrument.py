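"""PASE questionnaire scoring.

The Physical Activity Scale for the Elderly (PASE) is a 7-day-recall
questionnaire.  Leisure items record a frequency category (never / seldom /
sometimes / often) and, when not "never", a duration category; household
items are dichotomous yes/no; the work/volunteer item records hours per
week and whether the work involves standing or walking.  Each activity has
a predetermined weight from the PASE administration manual, and the total
score is

    total = sum_leisure  w_a * avg_daily_hours(freq, dur)
          + sum_household w_a * 1{yes}
          + w_work * (hours_per_week / 7) * 1{standing or walking}

where avg_daily_hours converts the category pair to hours per day via
configurable midpoints: (freq midpoint in days/week / 7) * duration
midpoint in hours.  Sedentary items (sitting activities, mainly-sitting
work) are accepted on input but never contribute to the total.

Weights and midpoints are configuration, not constants: the default
:data:`DEFAULT_CONFIG` carries the published manual weights, but any
weight table can be supplied, so the scoring engine is testable
independently of a particular instrument revision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "FrequencyCategory",
    "DurationCategory",
    "LeisureResponse",
    "PaseItems",
    "ScoringConfig",
    "DEFAULT_CONFIG",
    "ScoringError",
    "MissingResponse",
    "avg_daily_hours",
    "score_pase",
    "score_items_frame",
]

# frequency categories (days of activity in the past week)
NEVER, SELDOM, SOMETIMES, OFTEN = 0, 1, 2, 3
FrequencyCategory = int
# duration categories (hours per active day)
DurationCategory = int  # 1: <1h, 2: 1-2h, 3: 2-4h, 4: >4h

_FREQ_NAMES = {NEVER: "never", SELDOM: "seldom", SOMETIMES: "sometimes", OFTEN: "often"}
_DUR_NAMES = {1: "<1h", 2: "1-2h", 3: "2-4h", 4: ">4h"}


class ScoringError(ValueError):
    """Invalid item response or scoring configuration."""


class MissingResponse(ScoringError):
    """A required item response is absent and the policy is to reject."""


@dataclass(frozen=True)
class LeisureResponse:
    activity_id: str
    frequency: FrequencyCategory
    duration: DurationCategory | None = None

    def __post_init__(self):
        if self.frequency not in _FREQ_NAMES:
            raise ScoringError(f"unknown frequency category {self.frequency!r}")
        if self.frequency == NEVER:
            if self.duration is not None:
                raise ScoringError(
                    f"{self.activity_id}: duration given for frequency 'never'")
        else:
            if self.duration not in _DUR_NAMES:
                raise ScoringError(
                    f"{self.activity_id}: unknown duration category {self.duration!r}")


@dataclass(frozen=True)
class PaseItems:
    """One participant's item responses.  ``None`` marks a missing response."""

    leisure: Sequence[LeisureResponse | None] = ()
    household: Mapping[str, bool | None] = field(default_factory=dict)
    work_hours_per_week: float | None = 0.0
    work_standing_or_walking: bool | None = False
    # parsed but never scored
    sedentary: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        h = self.work_hours_per_week
        if h is not None and not 0.0 <= float(h) <= 168.0:
            raise ScoringError(f"work hours/week {h} outside [0, 168]")


@dataclass(frozen=True)
class ScoringConfig:
    """Activity weights plus category-midpoint conversion tables."""

    weights: Mapping[str, float]
    freq_midpoints: Mapping[FrequencyCategory, float]
    dur_midpoints: Mapping[DurationCategory, float]
    work_activity_id: str = "work"

    def __post_init__(self):
        for a, w in self.weights.items():
            if not w > 0:
                raise ScoringError(f"weight for {a!r} must be > 0, got {w}")
        for c, m in self.freq_midpoints.items():
            if c != NEVER and not m > 0:
                raise ScoringError(f"frequency midpoint for category {c} must be > 0")
        for c, m in self.dur_midpoints.items():
            if not m > 0:
                raise ScoringError(f"duration midpoint for category {c} must be > 0")

    def weight(self, activity_id: str) -> float:
        try:
            return float(self.weights[activity_id])
        except KeyError:
            raise ScoringError(f"no weight configured for activity {activity_id!r}") from None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoringConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            weights={str(k): float(v) for k, v in raw["weights"].items()},
            freq_midpoints={int(k): float(v) for k, v in raw["freq_midpoints"].items()},
            dur_midpoints={int(k): float(v) for k, v in raw["dur_midpoints"].items()},
            work_activity_id=str(raw.get("work_activity_id", "work")),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({
            "weights": dict(self.weights),
            "freq_midpoints": {int(k): float(v) for k, v in self.freq_midpoints.items()},
            "dur_midpoints": {int(k): float(v) for k, v in self.dur_midpoints.items()},
            "work_activity_id": self.work_activity_id,
        }))


#: Manual-derived default weights (Washburn et al. instrument manual) and the
#: conventional category midpoints: seldom = 1.5 d/wk, sometimes = 3.5 d/wk,
#: often = 6 d/wk; durations 0.5 h, 1.5 h, 3 h, 5 h.
DEFAULT_CONFIG = ScoringConfig(
    weights={
        "walking": 20.0,
        "light_sport": 21.0,
        "moderate_sport": 23.0,
        "strenuous_sport": 23.0,
        "muscle_strength": 30.0,
        "light_housework": 25.0,
        "heavy_housework": 25.0,
        "home_repairs": 30.0,
        "lawn_work": 36.0,
        "gardening": 20.0,
        "caring_for_others": 35.0,
        "work": 21.0,
    },
    freq_midpoints={NEVER: 0.0, SELDOM: 1.5, SOMETIMES: 3.5, OFTEN: 6.0},
    dur_midpoints={1: 0.5, 2: 1.5, 3: 3.0, 4: 5.0},
)

LEISURE_ACTIVITIES = ("walking", "light_sport", "moderate_sport",
                     "strenuous_sport", "muscle_strength")
HOUSEHOLD_ACTIVITIES = ("light_housework", "heavy_housework", "home_repairs",
                        "lawn_work", "gardening", "caring_for_others")


def avg_daily_hours(frequency: FrequencyCategory,
                    duration: DurationCategory | None,
                    config: ScoringConfig = DEFAULT_CONFIG) -> float:
    """Average hours/day implied by a (frequency, duration) category pair."""
    if frequency not in _FREQ_NAMES:
        raise ScoringError(f"unknown frequency category {frequency!r}")
    if frequency == NEVER:
        return 0.0
    if duration not in _DUR_NAMES:
        raise ScoringError(f"unknown duration category {duration!r}")
    return (config.freq_midpoints[frequency] / 7.0) * config.dur_midpoints[duration]


def score_pase(items: PaseItems,
               config: ScoringConfig = DEFAULT_CONFIG,
               missing_policy: str = "reject") -> float | None:
    """Total PASE score for one participant.

    ``missing_policy`` is ``"reject"`` (default: any missing response raises
    :class:`MissingResponse`, mirroring exclusion of incomplete records) or
    ``"partial"`` (missing items contribute nothing; no imputation).
    """
    if missing_policy not in ("reject", "partial"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    total = 0.0
    for resp in items.leisure:
        if resp is None:
            if missing_policy == "reject":
                raise MissingResponse("missing leisure item response")
            continue
        total += config.weight(resp.activity_id) * avg_daily_hours(
            resp.frequency, resp.duration, config)
    for activity, answer in items.household.items():
        if answer is None:
            if missing_policy == "reject":
                raise MissingResponse(f"missing household response for {activity!r}")
            continue
        if answer:
            total += config.weight(activity)
    h = items.work_hours_per_week
    standing = items.work_standing_or_walking
    if h is None or standing is None:
        if missing_policy == "reject":
            raise MissingResponse("missing work/volunteer response")
    elif standing and h > 0:
        total += config.weight(config.work_activity_id) * (float(h) / 7.0)
    return total


def score_items_frame(frame: pd.DataFrame,
                      config: ScoringConfig = DEFAULT_CONFIG,
                      missing_policy: str = "reject") -> pd.Series:
    """Score a wide item-response table (one row per subject).

    Expected columns: ``<activity>_freq`` / ``<activity>_dur`` for each
    leisure activity, ``<activity>`` (0/1) for each household activity, and
    ``work_hours`` / ``work_standing`` for the work item.  NaN cells are
    missing responses.  With the default reject policy, rows with missing
    items get a NaN total (the record is incomplete, not zero-active).
    Returns a Series named ``pase_total``.
    """
    out = []
    for _, row in frame.iterrows():
        try:
            items = _items_from_row(row)
            out.append(score_pase(items, config, missing_policy))
        except MissingResponse:
            out.append(float("nan"))
    return pd.Series(out, index=frame.index, name="pase_total")


def _items_from_row(row: pd.Series) -> PaseItems:
    leisure: list[LeisureResponse | None] = []
    for act in LEISURE_ACTIVITIES:
        f = row.get(f"{act}_freq")
        if pd.isna(f):
            leisure.append(None)
            continue
        f = int(f)
        dur = row.get(f"{act}_dur")
        if f != NEVER and pd.isna(dur):
            leisure.append(None)
            continue
        leisure.append(LeisureResponse(act, f, None if f == NEVER else int(dur)))
    household = {}
    for act in HOUSEHOLD_ACTIVITIES:
        v = row.get(act)
        household[act] = None if pd.isna(v) else bool(v)
    wh = row.get("work_hours")
    ws = row.get("work_standing")
    return PaseItems(
        leisure=leisure,
        household=household,
        work_hours_per_week=None if pd.isna(wh) else float(wh),
        work_standing_or_walking=None if pd.isna(ws) else bool(ws),
    )
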