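"""Oximetry feature extraction: desaturation events, ODI3/ODI4, the 1-4
oximetry severity score, artefact handling and the 4-h validity rule.

A desaturation event is a fall of the 1 Hz SpO2 trace below a running
baseline by more than the dip threshold (>3% for ODI3, >4% for ODI4 — on
integer-valued oximeter data these read as falls of ≥4 and ≥5 percentage
points), lasting more than 5 s and less than 180 s.  The dip indices are
qualifying events per artefact-free hour.  Artefact is handled the way a
physiologist works: per 20-min epoch — an epoch with more than half of its
samples flagged is dropped wholesale.

The oximetry score grades severity:

1. neither ODI3 ≥ 7 nor ODI4 ≥ 4 (normal or inconclusive);
2. ODI gate met, minimum saturation ≥ 80%;
3. ODI gate met, 1-2 events with nadir < 80%;
4. ODI gate met, ≥3 events with nadir < 80%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ODI3_DIP_PERCENT = 3.0
ODI4_DIP_PERCENT = 4.0
DESAT_MIN_S = 5.0        # strict: duration must exceed this
DESAT_MAX_S = 180.0      # strict: duration must stay under this
ODI3_SCORE_GATE = 7.0    # events/h
ODI4_SCORE_GATE = 4.0
NADIR_SEVERE_PERCENT = 80.0
MIN_OXIMETRY_HOURS = 4.0
EPOCH_S = 1200           # 20-min artefact-review epochs
BASELINE_WINDOW_S = 120
BASELINE_QUANTILE = 0.9


@dataclass
class DesatEvent:
    """One qualifying desaturation dip."""

    start: float      # s
    end: float        # s (exclusive)
    baseline: float   # % saturation at event onset
    nadir: float      # % minimum within the event
    depth: float      # baseline - nadir

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class OximetrySummary:
    """Per-subject oximetry indices and the severity score."""

    mean_spo2: float
    min_spo2: float
    mean_nadir: float | None     # None when no events occurred
    odi3: float
    odi4: float
    n_below_80: int
    valid_hours: float
    score: int
    included: bool
    events_odi3: list[DesatEvent] = field(default_factory=list)
    events_odi4: list[DesatEvent] = field(default_factory=list)


def detect_spo2_artefact(spo2: np.ndarray, guard_s: int = 3) -> np.ndarray:
    """Automated surrogate for manual SpO2 artefact scoring.

    Flags physiologically implausible samples (< 65%) and motion-like
    jumps (|Δ| > 6 %/s — faster than any real desaturation), extending each
    flag by a short guard.  Returns a boolean mask, True = artefact.
    """
    x = np.asarray(spo2, dtype=float)
    mask = (x < 65.0) | ~np.isfinite(x)
    jump = np.abs(np.diff(x)) > 6.0
    mask[:-1] |= jump
    mask[1:] |= jump
    if guard_s > 0 and mask.any():
        idx = np.nonzero(mask)[0]
        out = mask.copy()
        for i in idx:
            out[max(0, i - guard_s):i + guard_s + 1] = True
        mask = out
    return mask


def apply_epoch_rule(mask: np.ndarray, epoch_s: int = EPOCH_S,
                     drop_fraction: float = 0.5) -> np.ndarray:
    """Drop whole 20-min epochs whose artefact fraction exceeds the limit."""
    mask = np.asarray(mask, dtype=bool).copy()
    for start in range(0, mask.size, epoch_s):
        epoch = mask[start:start + epoch_s]
        if epoch.mean() > drop_fraction:
            mask[start:start + epoch_s] = True
    return mask


def _running_baseline(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """90th percentile of the preceding 120 s of unmasked samples."""
    s = pd.Series(np.where(mask, np.nan, x))
    base = s.shift(1).rolling(BASELINE_WINDOW_S, min_periods=10).quantile(
        BASELINE_QUANTILE)
    # early samples: fall back to the expanding percentile, then first value
    expanding = s.shift(1).expanding(min_periods=1).quantile(BASELINE_QUANTILE)
    base = base.fillna(expanding).bfill().ffill()
    return base.to_numpy()


def detect_desats(spo2: np.ndarray, drop_threshold: float,
                  mask: np.ndarray | None = None,
                  integer_convention: bool = True) -> list[DesatEvent]:
    """Detect desaturation events deeper than ``drop_threshold`` percent.

    ``drop_threshold`` is the dip index definition (3 for ODI3, 4 for
    ODI4).  Under the integer convention a strict ">3%" fall on
    integer-valued SpO2 means a drop of at least ``threshold + 1`` points;
    with ``integer_convention=False`` any fall strictly greater than the
    threshold qualifies.  Events must last more than 5 s and less than
    180 s and contain no masked sample.  The baseline is a running 90th
    percentile of the preceding 120 s, frozen at event onset.
    """
    x = np.asarray(spo2, dtype=float)
    if mask is None:
        mask = np.zeros(x.size, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.all() or x.size == 0:
        return []
    eff = drop_threshold + 1.0 if integer_convention else drop_threshold
    baseline = _running_baseline(x, mask)
    events: list[DesatEvent] = []
    i = 0
    n = x.size
    while i < n:
        if mask[i] or not (baseline[i] - x[i] >= eff if integer_convention
                           else baseline[i] - x[i] > eff):
            i += 1
            continue
        b0 = baseline[i]
        j = i
        touched_mask = False
        while j < n and (b0 - x[j] >= eff if integer_convention
                         else b0 - x[j] > eff):
            touched_mask |= bool(mask[j])
            j += 1
        dur = float(j - i)
        if not touched_mask and DESAT_MIN_S < dur < DESAT_MAX_S:
            nadir = float(np.min(x[i:j]))
            events.append(DesatEvent(start=float(i), end=float(j),
                                     baseline=float(b0), nadir=nadir,
                                     depth=float(b0 - nadir)))
        i = j
    return events


def oximetry_score(odi3: float, odi4: float, min_spo2: float,
                   n_below_80: int) -> int:
    """Four-level severity score combining the ODI gate and sub-80% events."""
    gate = odi3 >= ODI3_SCORE_GATE or odi4 >= ODI4_SCORE_GATE
    if not gate:
        return 1
    if n_below_80 >= 3:
        return 4
    if n_below_80 >= 1 or min_spo2 < NADIR_SEVERE_PERCENT:
        return 3
    return 2


def compute_oximetry_summary(spo2: np.ndarray,
                             mask: np.ndarray | None = None,
                             min_hours: float = MIN_OXIMETRY_HOURS,
                             integer_convention: bool = True,
                             ) -> OximetrySummary:
    """Full oximetry work-up of a 1 Hz trace.

    If no artefact mask is supplied one is derived automatically; the
    20-min epoch rule is then applied before event counting.  ``odi3`` and
    ``odi4`` are events per artefact-free hour; ``mean_nadir`` averages the
    nadirs of ODI3 events and is None when there are none.
    """
    x = np.asarray(spo2, dtype=float)
    if x.size == 0:
        raise ValueError("empty SpO2 trace")
    if mask is None:
        mask = detect_spo2_artefact(x)
    mask = apply_epoch_rule(np.asarray(mask, dtype=bool))
    valid_hours = float((~mask).sum()) / 3600.0
    if mask.all():
        return OximetrySummary(
            mean_spo2=float("nan"), min_spo2=float("nan"), mean_nadir=None,
            odi3=0.0, odi4=0.0, n_below_80=0, valid_hours=0.0, score=1,
            included=False)
    ev3 = detect_desats(x, ODI3_DIP_PERCENT, mask, integer_convention)
    ev4 = detect_desats(x, ODI4_DIP_PERCENT, mask, integer_convention)
    odi3 = len(ev3) / valid_hours if valid_hours > 0 else 0.0
    odi4 = len(ev4) / valid_hours if valid_hours > 0 else 0.0
    clean = x[~mask]
    n_below = sum(1 for e in ev3 if e.nadir < NADIR_SEVERE_PERCENT)
    nadirs = [e.nadir for e in ev3]
    min_spo2 = float(clean.min())
    score = oximetry_score(odi3, odi4, min_spo2, n_below)
    return OximetrySummary(
        mean_spo2=float(clean.mean()), min_spo2=min_spo2,
        mean_nadir=float(np.mean(nadirs)) if nadirs else None,
        odi3=odi3, odi4=odi4, n_below_80=n_below,
        valid_hours=valid_hours, score=score,
        included=valid_hours >= min_hours,
        events_odi3=ev3, events_odi4=ev4)
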