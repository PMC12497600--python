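"""Rule-based sleep-study categorisation and the cohort exclusion flow.

Categories are assigned from the video-surrogate labels (snoring, discrete
obstructive episodes, associated arousals) combined with the oximetry
score:

* **normal** — no snoring, no obstruction, score 1;
* **primary snoring** — snoring but fewer than 3 obstructive episodes,
  score 1;
* **UARS/mild OSA** — ≥3 episodes with associated arousals, score 1;
* **moderate OSA** — obstruction with arousals, score 2 or 3;
* **severe OSA** — obstruction with arousals, score 4;
* **abnormal other** — score ≥2 without video evidence of obstruction.

Exclusions mirror the study flow: technical failures first (<4 h of
artefact-free oximetry, <3 h of artefact-free PTT), then "abnormal other",
then incomplete feature rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import pandas as pd

from .oximetry import OximetrySummary
from .ptt import PttSummary
from .types import Category

#: Minimum obstructive episodes with arousal for UARS/mild OSA.
UARS_MIN_EPISODES = 3
#: Minimum episodes with arousal for moderate/severe OSA (obstruction with
#: "associated arousals"; no count is attached to the score ≥2 definitions).
OSA_MIN_AROUSAL_EPISODES = 1

EXCL_OXIMETRY = "insufficient oximetry data"
EXCL_PTT = "insufficient PTT data"
EXCL_ABNORMAL = "abnormal other"
EXCL_INCOMPLETE = "incomplete data"


@dataclass
class StudyAssessment:
    """Everything the categoriser and exclusion flow need for one subject."""

    snoring_present: bool
    n_obstructive_episodes: int
    episodes_with_arousal: int
    oximetry: OximetrySummary
    ptt: PttSummary
    features: dict = field(default_factory=dict)
    category: Category | None = None
    exclusion_reason: str | None = None

    def validate(self) -> None:
        if self.episodes_with_arousal > self.n_obstructive_episodes:
            raise ValueError(
                "episodes_with_arousal cannot exceed n_obstructive_episodes")
        if min(self.episodes_with_arousal, self.n_obstructive_episodes) < 0:
            raise ValueError("episode counts cannot be negative")


def assign_category(assessment: StudyAssessment) -> Category:
    """Map one assessment to exactly one of the six categories."""
    assessment.validate()
    score = assessment.oximetry.score
    n_epi = assessment.n_obstructive_episodes
    n_arousal = assessment.episodes_with_arousal
    if score == 1:
        if n_epi >= UARS_MIN_EPISODES and n_arousal >= UARS_MIN_EPISODES:
            cat = Category.UARS_MILD_OSA
        elif assessment.snoring_present or n_epi > 0:
            cat = Category.PRIMARY_SNORING
        else:
            cat = Category.NORMAL
    else:
        if n_epi == 0 or n_arousal < OSA_MIN_AROUSAL_EPISODES:
            cat = Category.ABNORMAL_OTHER
        elif score == 4:
            cat = Category.SEVERE_OSA
        else:
            cat = Category.MODERATE_OSA
    assessment.category = cat
    return cat


def _is_incomplete(assessment: StudyAssessment) -> bool:
    feats = assessment.features
    if not feats:
        return False
    return any(v is None or (isinstance(v, float) and math.isnan(v))
               for v in feats.values())


def apply_exclusions(cohort: list[StudyAssessment],
                     min_ptt_hours: float = 3.0,
                     min_oximetry_hours: float = 4.0,
                     ) -> tuple[list[StudyAssessment], pd.DataFrame]:
    """Apply the cohort exclusion flow.

    Precedence: technical failure (oximetry then PTT duration), abnormal
    other, incomplete data.  Returns the included assessments and a
    reasons table whose counts sum to the number excluded.
    """
    included: list[StudyAssessment] = []
    reasons: dict[str, int] = {
        EXCL_OXIMETRY: 0, EXCL_PTT: 0, EXCL_ABNORMAL: 0, EXCL_INCOMPLETE: 0}
    for a in cohort:
        if a.category is None:
            assign_category(a)
        if a.oximetry.valid_hours < min_oximetry_hours:
            a.exclusion_reason = EXCL_OXIMETRY
        elif a.ptt.ptt_duration_hours < min_ptt_hours:
            a.exclusion_reason = EXCL_PTT
        elif a.category is Category.ABNORMAL_OTHER:
            a.exclusion_reason = EXCL_ABNORMAL
        elif _is_incomplete(a):
            a.exclusion_reason = EXCL_INCOMPLETE
        else:
            a.exclusion_reason = None
            included.append(a)
            continue
        reasons[a.exclusion_reason] += 1
    table = pd.DataFrame(
        {"reason": list(reasons), "n": list(reasons.values())})
    table = pd.concat([
        table,
        pd.DataFrame({"reason": ["total excluded", "included"],
                      "n": [len(cohort) - len(included), len(included)]}),
    ], ignore_index=True)
    return included, table
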