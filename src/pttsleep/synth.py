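"""Synthetic overnight sleep-recording and cohort generators.

Two generators live here.

* A **signal-level** generator (:func:`simulate_subject`,
  :func:`simulate_cohort`) that emits full multi-channel recordings:
  jittered R-peak times, a plethysmograph waveform whose pulse onsets lag
  each R-peak by a time-varying pulse transit time (PTT), a 1 Hz SpO2 trace
  with scripted desaturation events, and video-surrogate obstructive-episode
  labels.  Respiratory effort modulates PTT sinusoidally; cortical arousals
  appear as transient PTT dips; motion artefact can corrupt a configurable
  fraction of the study.

* A **feature-level** generator (:func:`simulate_features`,
  :func:`simulate_logistic_cohort`) that draws the 15-variable per-subject
  feature table directly from per-category distributions.  It is used for
  cohort-scale statistical experiments where simulating hours of waveform
  per subject would add nothing.

The per-category parameter tables encode the study conditions: category
prevalences 174/239/132/63/21 over 629 subjects, category PTTrs means/SDs
(13.68/5.16, the snoring mixture, 20.73/7.31, 23.69/8.05, 26.68/9.07 ms),
and demographic distributions.  Because the respiratory PTT swing is
defined *after* 1 Hz interpolation and 3-sample smoothing, the raw
modulation amplitude is calibrated per subject so that the configured
``swing_amplitude`` is what the extraction chain recovers (see
``docs/methods.md``).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .types import Category, ObstructiveEpisode, ProfileError, Recording, SubjectProfile
from . import ptt as _ptt

PLETH_RATE = 100.0        # Hz; 10 ms granularity, finer than every rule threshold
PULSE_UPSTROKE_S = 0.150  # raised-cosine foot-to-peak time; 50% point at +75 ms
PULSE_DECAY_TAU = 0.25    # s, exponential fall after the pulse peak
RR_JITTER_CV = 0.03       # beat-to-beat R-R coefficient of variation
DRIFT_AMPLITUDE_MS = 2.0  # slow baseline PTT wander
DRIFT_PERIOD_S = 1800.0

#: Included-cohort category prevalences (n = 174/239/132/63/21 of 629).
TABLE1_MIX: dict[Category, float] = {
    Category.NORMAL: 174 / 629,
    Category.PRIMARY_SNORING: 239 / 629,
    Category.UARS_MILD_OSA: 132 / 629,
    Category.MODERATE_OSA: 63 / 629,
    Category.SEVERE_OSA: 21 / 629,
}

#: Target extracted PTTrs (mean, SD) in ms per category.  Primary snoring is
#: a two-component mixture (occasional 15.16/5.73 weight 157, regular
#: 18.65/7.34 weight 82); "abnormal other" has no reported value and uses a
#: plausible default.
PTTRS_BY_CATEGORY: dict[Category, tuple[float, float]] = {
    Category.NORMAL: (13.68, 5.16),
    Category.UARS_MILD_OSA: (20.73, 7.31),
    Category.MODERATE_OSA: (23.69, 8.05),
    Category.SEVERE_OSA: (26.68, 9.07),
    Category.ABNORMAL_OTHER: (16.0, 6.0),
}
PRIMARY_SNORING_MIX = ((15.16, 5.73, 157.0), (18.65, 7.34, 82.0))

#: Per-category generator defaults that the study's index definitions imply
#: but whose distributions are not reported: PTT-arousal rate (events/h),
#: desaturation rate (events/h), typical desaturation depth (%), male
#: fraction, and demographics (age yr, weight kg, height cm as mean/SD).
CATEGORY_PARAMS: dict[Category, dict] = {
    Category.NORMAL: dict(
        arousal_rate=(10, 6), desat_rate=(1.0, 0.8), desat_depth=5.0,
        male=0.48, age=(6.8, 3.2), weight=(27.9, 15.0), height=(120.9, 20.0),
        episode_rate=0.0, baseline_spo2=97.5,
    ),
    Category.PRIMARY_SNORING: dict(
        arousal_rate=(11, 6), desat_rate=(1.5, 1.0), desat_depth=5.0,
        male=0.59, age=(7.0, 3.2), weight=(30.1, 18.3), height=(122.0, 20.8),
        episode_rate=0.0, baseline_spo2=97.5,
    ),
    Category.UARS_MILD_OSA: dict(
        arousal_rate=(13, 7), desat_rate=(2.5, 1.2), desat_depth=5.0,
        male=0.52, age=(5.8, 2.6), weight=(23.3, 13.7), height=(114.2, 18.2),
        episode_rate=8.0, baseline_spo2=97.0,
    ),
    Category.MODERATE_OSA: dict(
        arousal_rate=(13, 7), desat_rate=(12, 3), desat_depth=6.0,
        male=0.51, age=(5.8, 3.1), weight=(26.1, 20.0), height=(115.3, 21.4),
        episode_rate=10.0, baseline_spo2=97.0,
    ),
    Category.SEVERE_OSA: dict(
        arousal_rate=(14, 8), desat_rate=(16, 4), desat_depth=20.0,
        male=0.57, age=(4.3, 1.5), weight=(18.8, 6.6), height=(105.2, 13.5),
        episode_rate=12.0, baseline_spo2=96.5,
    ),
    Category.ABNORMAL_OTHER: dict(
        arousal_rate=(11, 6), desat_rate=(10, 3), desat_depth=6.0,
        male=0.55, age=(5.6, 3.0), weight=(25.9, 15.0), height=(108.3, 20.0),
        episode_rate=0.0, baseline_spo2=97.0,
    ),
}


def _draw_pttrs(category: Category, rng: np.random.Generator) -> float:
    """Draw a subject's target respiratory swing from its category."""
    if category is Category.PRIMARY_SNORING:
        w = np.array([c[2] for c in PRIMARY_SNORING_MIX])
        m, s, _ = PRIMARY_SNORING_MIX[rng.choice(len(PRIMARY_SNORING_MIX), p=w / w.sum())]
    else:
        m, s = PTTRS_BY_CATEGORY[category]
    return float(np.clip(rng.normal(m, s), 2.0, 40.0))


def _place_events(rng: np.random.Generator, n: int, duration: float,
                  min_gap: float, margin: float = 60.0) -> np.ndarray:
    """Greedy random placement of n event start times with a minimum gap."""
    starts: list[float] = []
    lo, hi = margin, max(margin + 1.0, duration - margin)
    for _ in range(n * 30):
        if len(starts) == n:
            break
        t = rng.uniform(lo, hi)
        if all(abs(t - s) >= min_gap for s in starts):
            starts.append(t)
    return np.sort(np.array(starts))


def _arousal_dip(t: np.ndarray, start: float, fall: float, plateau: float,
                 recovery: float) -> np.ndarray:
    """Unit-depth arousal dip: linear fall, flat bottom, linear recovery."""
    out = np.zeros_like(t)
    rel = t - start
    seg = (rel >= 0) & (rel < fall)
    out[seg] = rel[seg] / fall
    seg = (rel >= fall) & (rel < fall + plateau)
    out[seg] = 1.0
    seg = (rel >= fall + plateau) & (rel < fall + plateau + recovery)
    out[seg] = 1.0 - (rel[seg] - fall - plateau) / recovery
    return out


def _respiratory_gain(beat_times: np.ndarray, resp_unit: np.ndarray) -> float:
    """Attenuation of a unit trough-to-peak respiratory modulation.

    The respiratory swing is defined on the derived channel (1 Hz linear
    interpolation + 3-sample moving mean), which attenuates breath-frequency
    oscillations.  The factor is measured by pushing the subject's actual
    modulation waveform through the extraction chain, so the generator can
    pre-compensate and the configured swing is what extraction recovers.
    """
    probe_swing = 20.0
    series = 300.0 + (probe_swing / 2.0) * resp_unit
    grid, resp, mask = _ptt.derive_resp_channel(
        beat_times, series, np.ones_like(series, dtype=bool))
    measured = _ptt.compute_pttrs(resp, mask).pttrs
    if measured <= 0.1:
        return 1.0
    return measured / probe_swing


def _build_pleth(r_peaks: np.ndarray, ptt_ms: np.ndarray, duration: float,
                 rng: np.random.Generator, fs: float = PLETH_RATE) -> np.ndarray:
    """Render the plethysmograph: one pulse per beat, onset lagged by PTT.

    Each pulse is a raised-cosine upstroke (foot to peak in 150 ms, so the
    50%-amplitude crossing sits exactly PTT after the R wave) followed by an
    exponential decay until the next pulse foot.
    """
    n = int(round(duration * fs))
    pleth = np.zeros(n)
    foot = r_peaks + ptt_ms / 1000.0 - PULSE_UPSTROKE_S / 2.0
    amps = rng.uniform(0.9, 1.1, size=len(foot))
    for i, ft in enumerate(foot):
        i0 = int(np.ceil(ft * fs))
        if i0 < 0 or i0 >= n:
            continue
        peak_t = ft + PULSE_UPSTROKE_S
        i1 = min(int(np.ceil(peak_t * fs)), n)
        # evaluate the upstroke at exact sample offsets so pulse timing is
        # not quantised to the sample grid
        tt = np.arange(i0, i1) / fs
        pleth[i0:i1] = amps[i] * 0.5 * (
            1.0 - np.cos(np.pi * (tt - ft) / PULSE_UPSTROKE_S))
        nxt = foot[i + 1] if i + 1 < len(foot) else ft + 1.2
        j1 = min(int(np.ceil(nxt * fs)), n)
        if i1 < j1:
            td = np.arange(i1, j1) / fs
            pleth[i1:j1] = amps[i] * np.exp(-(td - peak_t) / PULSE_DECAY_TAU)
    return pleth


def simulate_subject(profile: SubjectProfile, seed: int) -> Recording:
    """Generate one subject's recording from a profile; deterministic in seed."""
    profile.validate()
    rng = np.random.default_rng(seed)
    duration = profile.study_hours * 3600.0

    # Beat times: jittered R-R intervals around the profile heart rate.
    rr_mean = 60.0 / profile.heart_rate
    n_beats = int(duration / rr_mean) + 8
    rr = rng.normal(rr_mean, RR_JITTER_CV * rr_mean, n_beats)
    rr = np.clip(rr, 0.5 * rr_mean, 1.5 * rr_mean)
    beats = 0.5 + np.cumsum(rr)
    beats = beats[beats < duration - 1.5]

    # Respiratory modulation, calibrated so the extracted swing matches.
    phase = rng.uniform(0, 2 * np.pi)
    f_resp = profile.respiratory_rate / 60.0
    resp_unit = np.sin(2 * np.pi * f_resp * beats + phase)
    ptt = np.full_like(beats, profile.ptt_baseline)
    if profile.swing_amplitude > 0:
        gain = _respiratory_gain(beats, resp_unit)
        ptt = ptt + (profile.swing_amplitude / gain / 2.0) * resp_unit

    drift_phase = rng.uniform(0, 2 * np.pi)
    ptt = ptt + DRIFT_AMPLITUDE_MS * np.sin(
        2 * np.pi * beats / DRIFT_PERIOD_S + drift_phase)

    # Arousal dips: fall over 8-28 s, plateau long enough to survive the
    # 17-beat smoothing, then recovery.
    n_arousal = rng.poisson(profile.arousal_rate * profile.study_hours)
    plateau = 17.0 * rr_mean + 2.0
    arousal_starts = _place_events(rng, n_arousal, duration,
                                   min_gap=90.0 + plateau)
    for s in arousal_starts:
        fall = rng.uniform(8.0, 28.0)
        ptt = ptt - profile.arousal_drop * _arousal_dip(
            beats, s, fall, plateau, recovery=20.0)

    pleth = _build_pleth(beats, ptt, duration, rng)

    # SpO2 at 1 Hz with scripted desaturation events.
    n_sp = int(round(duration))
    spo2 = np.full(n_sp, profile.baseline_spo2)
    t_sp = np.arange(n_sp, dtype=float)
    n_desat = rng.poisson(profile.desat_rate * profile.study_hours)
    desat_starts = _place_events(
        rng, n_desat, duration, min_gap=profile.desat_duration + 60.0)
    for s in desat_starts:
        d = float(np.clip(rng.uniform(0.85, 1.15) * profile.desat_duration,
                          15.0, 170.0))
        depth = max(1.0, rng.normal(profile.desat_depth,
                                    0.05 * profile.desat_depth))
        spo2 = spo2 - depth * _desat_shape(t_sp, s, d, depth)
    spo2 = np.rint(np.clip(spo2, 0.0, 100.0))

    episodes = _draw_episodes(profile.category, duration, rng)
    rec = Recording(
        r_peak_times=beats, pleth=pleth, pleth_rate=PLETH_RATE, spo2=spo2,
        video_labels=episodes, snoring=profile.category is not Category.NORMAL,
        truth=profile,
        injected_arousals=[float(s) for s in arousal_starts],
        injected_desats=[float(s) for s in desat_starts],
    )
    if profile.artefact_fraction > 0:
        rec = inject_artefacts(rec, profile.artefact_fraction,
                               seed=int(rng.integers(0, 2**31 - 1)))
    return rec


def _desat_shape(t: np.ndarray, start: float, dur: float,
                 depth: float = 4.0) -> np.ndarray:
    """Unit-depth desaturation: raised-cosine edges, flat nadir.

    Edge length grows with depth so the fall never exceeds the
    physiological rate (~5 %/s) that separates desaturation from motion
    artefact.
    """
    edge = max(3.0, depth / 3.0)
    edge = min(edge, dur / 2.5)
    out = np.zeros_like(t)
    rel = t - start
    seg = (rel >= 0) & (rel < edge)
    out[seg] = 0.5 * (1 - np.cos(np.pi * rel[seg] / edge))
    seg = (rel >= edge) & (rel < dur - edge)
    out[seg] = 1.0
    seg = (rel >= dur - edge) & (rel < dur)
    out[seg] = 0.5 * (1 - np.cos(np.pi * (dur - rel[seg]) / edge))
    return out


def _draw_episodes(category: Category, duration: float,
                   rng: np.random.Generator) -> list[ObstructiveEpisode]:
    rate = CATEGORY_PARAMS[category]["episode_rate"]
    hours = duration / 3600.0
    if rate > 0:
        n = max(3, int(rng.poisson(rate * hours)))
        arousal = True
    elif category is Category.PRIMARY_SNORING:
        n = int(rng.integers(0, 3))
        arousal = False
    else:
        return []
    starts = _place_events(rng, n, duration, min_gap=45.0, margin=30.0)
    return [ObstructiveEpisode(float(s), float(s + rng.uniform(15.0, 30.0)),
                               has_arousal=arousal) for s in starts]


def draw_profiles(n: int, mix: dict[Category, float] | None = None,
                  seed: int = 0, artefact_level: float = 0.0,
                  study_hours: tuple[float, float] = (6.8, 1.2),
                  ) -> list[SubjectProfile]:
    """Draw n subject profiles from per-category distributions.

    ``artefact_level`` is the cohort-mean artefact fraction; per-subject
    fractions follow a Beta distribution with that mean and concentration 2,
    giving the wide between-subject spread that makes roughly that share of
    studies fail the 3-h artefact-free PTT rule.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    mix = dict(mix or TABLE1_MIX)
    mix = {Category(k): v for k, v in mix.items()}
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"category proportions must sum to 1 (got {total})")
    rng = np.random.default_rng(seed)
    cats = list(mix)
    draws = rng.choice(len(cats), size=n, p=np.array([mix[c] for c in cats]))
    profiles = []
    for idx in draws:
        cat = cats[idx]
        p = CATEGORY_PARAMS[cat]
        age_y = float(np.clip(rng.normal(*p["age"]), 0.5, 18.0))
        if artefact_level > 0:
            af = float(rng.beta(2.0 * artefact_level,
                                2.0 * (1.0 - artefact_level)))
            af = min(af, 0.97)
        else:
            af = 0.0
        profiles.append(SubjectProfile(
            category=cat,
            ptt_baseline=float(np.clip(rng.normal(260, 35), 170, 420)),
            swing_amplitude=_draw_pttrs(cat, rng),
            arousal_rate=float(max(0.0, rng.normal(*p["arousal_rate"]))),
            arousal_drop=float(np.clip(rng.normal(26, 4), 18, 45)),
            desat_rate=float(max(0.0, rng.normal(*p["desat_rate"]))),
            desat_depth=float(max(4.0, rng.normal(p["desat_depth"],
                                                  0.1 * p["desat_depth"]))),
            desat_duration=float(np.clip(rng.normal(30, 6), 16, 120)),
            baseline_spo2=float(np.clip(rng.normal(p["baseline_spo2"], 0.5),
                                        94.0, 99.0)),
            heart_rate=float(np.clip(118 - 3.3 * age_y + rng.normal(0, 6),
                                     75, 150)),
            respiratory_rate=float(np.clip(rng.normal(11.0, 0.8),
                                           9.5, 12.0)),
            artefact_fraction=af,
            study_hours=float(np.clip(
                rng.normal(*study_hours),
                max(0.05, study_hours[0] - 2.5 * study_hours[1]),
                study_hours[0] + 2.5 * study_hours[1])),
            age_months=age_y * 12.0,
            weight_kg=float(max(5.0, rng.normal(*p["weight"]))),
            height_cm=float(np.clip(rng.normal(*p["height"]), 60.0, 200.0)),
            sex="M" if rng.random() < p["male"] else "F",
        ))
    return profiles


def simulate_cohort(n: int, mix: dict[Category, float] | None = None,
                    seed: int = 0, artefact_level: float = 0.0,
                    study_hours: tuple[float, float] = (6.8, 1.2),
                    ) -> list[Recording]:
    """Simulate a cohort of recordings (profiles drawn per category)."""
    profiles = draw_profiles(n, mix, seed, artefact_level, study_hours)
    rng = np.random.default_rng(seed + 1)
    return [simulate_subject(p, seed=int(rng.integers(0, 2**31 - 1)))
            for p in profiles]


def inject_artefacts(recording: Recording, fraction: float,
                     seed: int = 0) -> Recording:
    """Corrupt ≈``fraction`` of the study with motion/dropout artefact.

    Within artefact segments, pleth pulse timing is block-shifted by
    60-200 ms (producing raw-PTT jumps well above the 50 ms spike rule, with
    occasional dropout).  SpO2 motion artefact (jumpy implausible values) is
    added in only a minority of segments: PTT is far more artefact-prone
    than oximetry, which is why the duration rules differ (3 h vs 4 h).
    Returns a new recording; the input is untouched.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    rec = Recording(
        r_peak_times=recording.r_peak_times.copy(),
        pleth=recording.pleth.copy(), pleth_rate=recording.pleth_rate,
        spo2=recording.spo2.copy(), video_labels=list(recording.video_labels),
        snoring=recording.snoring, truth=recording.truth,
    )
    if fraction == 0:
        return rec
    rng = np.random.default_rng(seed)
    duration = rec.duration
    target = fraction * duration
    segments: list[tuple[float, float]] = []
    covered = 0.0
    for _ in range(2000):
        if covered >= target:
            break
        length = min(rng.uniform(30.0, 300.0), target - covered + 30.0)
        start = rng.uniform(0.0, max(1.0, duration - length))
        if any(start < e + 10 and s - 10 < start + length for s, e in segments):
            continue
        segments.append((start, start + length))
        covered += length
    fs = rec.pleth_rate
    for start, end in segments:
        i0, i1 = int(start * fs), min(int(end * fs), rec.pleth.size)
        block = int(2.0 * fs)
        for b0 in range(i0, i1, block):
            b1 = min(b0 + block, i1)
            if rng.random() < 0.2:
                rec.pleth[b0:b1] = 0.0      # photoplethysmography dropout
            else:
                shift = int(rng.choice([-1, 1]) * rng.uniform(0.06, 0.2) * fs)
                rec.pleth[b0:b1] = np.roll(rec.pleth[b0:b1], shift)
        if rng.random() < 0.15:
            j0, j1 = int(start), min(int(end), rec.spo2.size)
            if j1 > j0:
                vals = rng.uniform(40.0, 92.0, size=j1 - j0)
                rec.spo2[j0:j1] = np.rint(vals)
    if rec.truth is not None:
        rec.truth = dataclasses.replace(rec.truth, artefact_fraction=fraction)
    return rec


# ---------------------------------------------------------------------------
# Feature-level cohort generator
# ---------------------------------------------------------------------------

#: The 15 candidate predictors of the binary sleep-disorder models.
MODEL_VARIABLES = [
    "pttrs", "ptt_ai", "ptt_duration", "oximetry_score", "odi3", "odi4",
    "min_spo2", "mean_spo2", "mean_nadir", "study_duration", "sex",
    "weight", "height", "heart_rate", "heart_rate_sd",
]

#: Per-category ODI3 draws: (shift, gamma shape, gamma scale).  Moderate and
#: severe start above the score gate; the score-1 categories have long right
#: tails that occasionally cross it (their score-1 grading is the McGill
#: normal-or-inconclusive judgement, not a hard ODI cut).
_ODI3_PARAMS: dict[Category, tuple[float, float, float]] = {
    Category.NORMAL: (0.0, 2.0, 0.8),
    Category.PRIMARY_SNORING: (0.0, 2.0, 1.2),
    Category.UARS_MILD_OSA: (0.0, 3.0, 1.6),
    Category.MODERATE_OSA: (7.5, 2.0, 2.5),
    Category.SEVERE_OSA: (10.0, 2.5, 6.0),
    Category.ABNORMAL_OTHER: (7.5, 2.0, 2.5),
}


def simulate_features(n: int, mix: dict[Category, float] | None = None,
                      seed: int = 0):
    """Draw a per-subject 15-variable feature table plus outcome columns.

    Returns a pandas DataFrame with the model variables, ``age_months``,
    ``category`` and the binary ``disorder`` flag, mimicking the joint
    structure the signal pipeline produces on an included cohort (all rows
    have ≥3 h of artefact-free PTT).  ODI3 and PTTrs carry the dominant
    signal; the remaining saturation summaries are largely redundant given
    ODI3, and PTT-AI overlaps heavily between categories (the arousal index
    discriminates poorly), so extra covariates add little model accuracy.
    """
    import pandas as pd

    profiles = draw_profiles(n, mix, seed)
    rng = np.random.default_rng(seed + 17)
    rows = []
    for p in profiles:
        cat = Category(p.category)
        shift, shape, scale = _ODI3_PARAMS[cat]
        odi3 = shift + float(rng.gamma(shape, scale))
        if cat is Category.MODERATE_OSA:
            score = 2 if rng.random() < 0.8 else 3
        elif cat is Category.SEVERE_OSA:
            score = 4
        else:
            score = 1
        ptt_dur = float(np.clip(rng.normal(4.79, 1.32), 3.0, 9.5))
        rows.append(dict(
            pttrs=p.swing_amplitude,
            ptt_ai=p.arousal_rate,
            ptt_duration=ptt_dur,
            oximetry_score=score,
            odi3=odi3,
            odi4=float(max(0.0, odi3 * rng.uniform(0.35, 0.7))),
            # saturation summaries track ODI3 (redundant given it)
            min_spo2=float(np.clip(97.5 - 0.9 * odi3 + rng.normal(0, 5.0),
                                   45, 99)),
            mean_spo2=float(np.clip(97.6 - 0.04 * odi3 + rng.normal(0, 0.5),
                                    90, 99.5)),
            mean_nadir=float(np.clip(94.5 - 0.45 * odi3 + rng.normal(0, 3.0),
                                     55, 99)),
            study_duration=ptt_dur + abs(rng.normal(1.2, 0.6)),
            sex=1 if p.sex == "M" else 0,
            weight=p.weight_kg,
            height=p.height_cm,
            heart_rate=p.heart_rate,
            heart_rate_sd=float(max(2.0, rng.normal(10, 3))),
            age_months=p.age_months,
            category=cat.value,
            disorder=int(cat in {Category.UARS_MILD_OSA, Category.MODERATE_OSA,
                                 Category.SEVERE_OSA}),
        ))
    return pd.DataFrame(rows)


def simulate_logistic_cohort(n: int, coefs: dict[str, float], seed: int = 0,
                             noise_variables: bool = True):
    """Simulate a cohort whose binary outcome follows a known logistic model.

    ``coefs`` maps variable names (a subset of :data:`MODEL_VARIABLES`) plus
    ``"intercept"`` to true coefficients; the named covariates get
    cohort-like marginals (ODI3 gamma-distributed, PTTrs normal), every
    other model variable is pure noise, and the outcome is Bernoulli in the
    linear predictor.  Used for parameter-recovery and variable-selection
    calibration experiments.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    df = pd.DataFrame(index=range(n))
    marginals = {
        "odi3": lambda: rng.gamma(1.6, 2.8, n),
        "pttrs": lambda: np.clip(rng.normal(17.6, 7.5, n), 1.0, None),
    }
    lp = np.full(n, float(coefs.get("intercept", 0.0)))
    for var in MODEL_VARIABLES:
        if var in coefs and var != "intercept":
            draw = marginals.get(var, lambda: rng.normal(0.0, 1.0, n))
            df[var] = draw()
            lp = lp + coefs[var] * df[var].to_numpy()
        elif noise_variables:
            df[var] = rng.normal(0.0, 1.0, n)
    p = 1.0 / (1.0 + np.exp(-lp))
    df["disorder"] = (rng.random(n) < p).astype(int)
    return df
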