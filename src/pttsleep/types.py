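"""Core domain types: diagnostic categories, subject profiles and recordings.

A *recording* bundles one subject's overnight multi-channel sleep study:
ECG R-peak times, a plethysmograph (pulse) waveform, an SpO2 trace at 1 Hz,
and video-derived obstructive-episode labels. In synthetic mode the
generating :class:`SubjectProfile` travels with the recording as ground
truth; in real mode ``truth`` is ``None`` and the labels come from an
annotation table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from enum import Enum

import numpy as np


class Category(str, Enum):
    """Six-way sleep-study outcome used throughout the pipeline."""

    NORMAL = "normal"
    PRIMARY_SNORING = "primary_snoring"
    UARS_MILD_OSA = "uars_mild_osa"
    MODERATE_OSA = "moderate_osa"
    SEVERE_OSA = "severe_osa"
    ABNORMAL_OTHER = "abnormal_other"


#: Categories counted as sleep-disordered for the binary outcome
#: (normal + primary snoring form the no-disorder group).
DISORDER_CATEGORIES = frozenset(
    {Category.UARS_MILD_OSA, Category.MODERATE_OSA, Category.SEVERE_OSA}
)

#: The five categories retained after cohort exclusions.
INCLUDED_CATEGORIES = (
    Category.NORMAL,
    Category.PRIMARY_SNORING,
    Category.UARS_MILD_OSA,
    Category.MODERATE_OSA,
    Category.SEVERE_OSA,
)


def is_disorder(category: Category) -> bool:
    """Binary outcome: UARS/mild, moderate or severe OSA counts as disorder."""
    return Category(category) in DISORDER_CATEGORIES


class ProfileError(ValueError):
    """A subject profile field violates its physiological bounds."""


@dataclass
class SubjectProfile:
    """Generator-side truth for one synthetic subject.

    Units: milliseconds for PTT quantities, events/hour for rates,
    percentage points for saturation, hours for durations.
    """

    category: Category = Category.NORMAL
    ptt_baseline: float = 250.0        # ms, centre of the 150-500 ms valid band
    swing_amplitude: float = 14.0      # ms trough-to-peak respiratory swing
    arousal_rate: float = 5.0          # PTT arousals per hour
    arousal_drop: float = 25.0         # ms drop per arousal
    desat_rate: float = 1.0            # desaturation events per hour
    desat_depth: float = 4.0           # % fall from baseline saturation
    desat_duration: float = 30.0       # s
    baseline_spo2: float = 97.0        # %
    heart_rate: float = 95.0           # bpm
    respiratory_rate: float = 11.0     # breaths/min (slow-wave sleep)
    artefact_fraction: float = 0.0     # proportion of study time corrupted
    study_hours: float = 6.0
    age_months: float = 78.0
    weight_kg: float = 27.0
    height_cm: float = 119.0
    sex: str = "M"

    def validate(self) -> None:
        if self.swing_amplitude < 0:
            raise ProfileError("swing_amplitude must be >= 0")
        if not 0 <= self.artefact_fraction < 1:
            raise ProfileError("artefact_fraction must be in [0, 1)")
        if not 150 <= self.ptt_baseline <= 500:
            raise ProfileError("ptt_baseline must be within 150-500 ms")
        if self.study_hours <= 0:
            raise ProfileError("study_hours must be > 0")
        if self.desat_depth < 0:
            raise ProfileError("desat_depth must be >= 0")
        if self.baseline_spo2 > 100:
            raise ProfileError("baseline_spo2 must be <= 100")
        if self.heart_rate <= 0:
            raise ProfileError("heart_rate must be > 0")
        if self.respiratory_rate <= 0:
            raise ProfileError("respiratory_rate must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["category"] = Category(self.category).value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectProfile":
        d = dict(d)
        d["category"] = Category(d["category"])
        return cls(**d)


@dataclass
class ObstructiveEpisode:
    """A discrete period of obstructed breathing identified on video/sound.

    ``has_arousal`` is the video surrogate for a cortical arousal: movement
    plus a pulse-rate rise terminating the episode.
    """

    start: float
    end: float
    has_arousal: bool = True

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("episode end must be after start")


@dataclass
class Recording:
    """One subject's synchronized sleep-study signals.

    ``r_peak_times`` are in seconds from study start and strictly increasing;
    ``pleth`` is sampled at ``pleth_rate`` Hz; ``spo2`` is a 1 Hz percentage
    trace.  ``snoring`` reports whether snoring was heard at any point (used
    with the episode labels to separate normal studies from primary snoring).
    """

    r_peak_times: np.ndarray
    pleth: np.ndarray
    pleth_rate: float
    spo2: np.ndarray
    video_labels: list[ObstructiveEpisode] = field(default_factory=list)
    snoring: bool = False
    truth: SubjectProfile | None = None
    #: generator-side truth event onsets (synthetic mode only)
    injected_arousals: list[float] = field(default_factory=list)
    injected_desats: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r_peak_times = np.asarray(self.r_peak_times, dtype=float)
        self.pleth = np.asarray(self.pleth, dtype=float)
        self.spo2 = np.asarray(self.spo2, dtype=float)
        if self.r_peak_times.size and np.any(np.diff(self.r_peak_times) <= 0):
            raise ValueError("r_peak_times must be strictly increasing")
        if np.any((self.spo2 < 0) | (self.spo2 > 100)):
            raise ValueError("spo2 values must lie in [0, 100]")

    @property
    def duration(self) -> float:
        """Study length in seconds (plethysmograph coverage)."""
        return self.pleth.size / self.pleth_rate
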