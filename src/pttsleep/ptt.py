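"""Pulse-transit-time feature extraction.

PTT is measured per heart beat from the mid-point of the ECG R wave to the
50%-amplitude point of the next plethysmograph pulse upstroke.  From the
beat-wise series this module derives:

* **PTT2** — a centred 17-beat moving average (~3.5 s) used for arousal
  detection;
* **PTT arousals / PTT-AI** — drops in PTT2 of at least 15 ms developing
  over 5-45 s while PTT2 is inside the 150-500 ms validity band, counted
  per artefact-free hour;
* the **derived respiratory channel** — valid raw PTT linearly interpolated
  onto a 1 Hz grid and smoothed with a 3-sample moving mean;
* **PTTrs** — the mean respiratory rise from an inspiratory trough to the
  following expiratory peak on that channel, in ms;
* artefact masking (raw-PTT spikes above 50 ms with a guard interval) and
  the minimum artefact-free-duration inclusion rule (3 h by default, 4 h
  for sensitivity re-analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .types import Recording

PTT_VALID_MIN_MS = 150.0
PTT_VALID_MAX_MS = 500.0
PTT2_WINDOW_BEATS = 17
AROUSAL_DROP_MS = 15.0
AROUSAL_FALL_MIN_S = 5.0
AROUSAL_FALL_MAX_S = 45.0
SPIKE_THRESHOLD_MS = 50.0
SPIKE_GUARD_S = 10.0
MIN_PTT_HOURS = 3.0


@dataclass
class BeatSeries:
    """Per-beat raw PTT with validity flags (150-500 ms band, dropouts)."""

    beat_time: np.ndarray   # s, strictly increasing
    ptt_raw: np.ndarray     # ms; NaN where no pulse was found
    valid: np.ndarray       # bool

    def __len__(self) -> int:
        return self.beat_time.size


@dataclass
class ArousalEvent:
    """One PTT arousal: the fall from a PTT2 peak to the following trough."""

    start: float
    end: float
    drop_ms: float

    @property
    def fall_time(self) -> float:
        return self.end - self.start


@dataclass
class PttChannels:
    """Derived PTT channels and masks for one recording."""

    beats: BeatSeries
    ptt2: np.ndarray                 # ms per beat; NaN where undefined
    beat_artefact: np.ndarray        # bool per beat
    artefact_intervals: list[tuple[float, float]]
    resp_time: np.ndarray            # 1 Hz grid, s
    resp_channel: np.ndarray         # ms
    resp_mask: np.ndarray            # bool, True = masked
    artefact_free_hours: float


@dataclass
class PttSummary:
    """Per-subject PTT indices."""

    pttrs: float                 # ms
    ptt_ai: float                # events / artefact-free hour (NaN if 0 h)
    n_arousals: int
    ptt_duration_hours: float
    included: bool
    flags: list[str] = field(default_factory=list)


def compute_ptt(r_peaks: np.ndarray, pleth: np.ndarray,
                sampling_rate: float) -> BeatSeries:
    """Measure raw PTT for every R-peak.

    For each beat the next plethysmograph pulse is located; PTT is the time
    from the R-peak to where the upstroke crosses 50% of the pulse
    amplitude (foot-to-peak), found by linear interpolation between
    samples.  Beats with no pulse within 2 s are marked invalid (signal
    dropout), as are PTTs outside the 150-500 ms validity band.
    """
    r_peaks = np.asarray(r_peaks, dtype=float)
    pleth = np.asarray(pleth, dtype=float)
    if r_peaks.size == 0 or pleth.size == 0:
        raise ValueError("r_peaks and pleth must be non-empty")
    if np.any(np.diff(r_peaks) <= 0):
        raise ValueError("r_peaks must be strictly increasing")

    lo, hi = np.percentile(pleth, [5, 95])
    if hi <= lo:  # sparse pulses: fall back to the overall excursion
        hi = float(pleth.max())
    prominence = 0.25 * (hi - lo)
    if prominence > 0:
        peaks, _ = find_peaks(pleth, distance=max(1, int(0.25 * sampling_rate)),
                              prominence=prominence)
    else:
        peaks = np.array([], dtype=int)
    peak_t = peaks / sampling_rate

    n = r_peaks.size
    ptt = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for b, r in enumerate(r_peaks):
        k = np.searchsorted(peak_t, r, side="right")
        if k >= peaks.size or peak_t[k] - r > 2.0:
            continue
        p = peaks[k]
        i_r = max(0, int(round(r * sampling_rate)))
        if p - i_r < 2:
            continue
        seg = pleth[i_r:p + 1]
        f = i_r + int(np.argmin(seg))
        half = pleth[f] + 0.5 * (pleth[p] - pleth[f])
        up = pleth[f:p + 1]
        above = np.nonzero(up >= half)[0]
        if above.size == 0:
            continue
        c = f + int(above[0])
        if c == f:
            t_cross = c / sampling_rate
        else:
            frac = (half - pleth[c - 1]) / (pleth[c] - pleth[c - 1])
            t_cross = (c - 1 + frac) / sampling_rate
        ptt[b] = (t_cross - r) * 1000.0
        valid[b] = PTT_VALID_MIN_MS <= ptt[b] <= PTT_VALID_MAX_MS
    return BeatSeries(beat_time=r_peaks, ptt_raw=ptt, valid=valid)


def smooth_ptt2(beats: BeatSeries,
                artefact: np.ndarray | None = None) -> np.ndarray:
    """Centred 17-beat moving mean over valid (and unmasked) beats.

    The window shrinks at the edges; where it contains no usable beat the
    output is NaN.
    """
    x = np.asarray(beats.ptt_raw, dtype=float)
    good = np.asarray(beats.valid, dtype=bool) & np.isfinite(x)
    if artefact is not None:
        good = good & ~np.asarray(artefact, dtype=bool)
    vals = np.where(good, x, 0.0)
    half = PTT2_WINDOW_BEATS // 2
    csum = np.concatenate(([0.0], np.cumsum(vals)))
    ccnt = np.concatenate(([0], np.cumsum(good.astype(int))))
    n = x.size
    idx = np.arange(n)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n, idx + half + 1)
    s = csum[hi] - csum[lo]
    c = ccnt[hi] - ccnt[lo]
    out = np.full(n, np.nan)
    np.divide(s, c, out=out, where=c > 0)
    return out


def remove_ptt_artefact(beats: BeatSeries,
                        spike_threshold: float = SPIKE_THRESHOLD_MS,
                        guard_s: float = SPIKE_GUARD_S,
                        duration: float | None = None,
                        ) -> tuple[list[tuple[float, float]], np.ndarray, float]:
    """Mask raw-PTT spike artefact and compute artefact-free time.

    Consecutive-beat jumps above ``spike_threshold`` (and dropout beats with
    no measurable PTT) seed artefact intervals extended by ``guard_s`` on
    each side, mimicking manual exclusion of a corrupted region.  Returns
    ``(intervals, per_beat_mask, artefact_free_hours)``; overlapping
    intervals are merged and clipped to the study span.
    """
    t = beats.beat_time
    x = beats.ptt_raw
    if duration is None:
        duration = float(t[-1]) if t.size else 0.0
    raw: list[tuple[float, float]] = []
    finite = np.isfinite(x)
    for i in np.nonzero(~finite)[0]:
        raw.append((t[i] - guard_s, t[i] + guard_s))
    jump = np.abs(np.diff(np.where(finite, x, np.nan)))
    for i in np.nonzero(jump > spike_threshold)[0]:
        raw.append((t[i] - guard_s, t[i + 1] + guard_s))
    intervals: list[tuple[float, float]] = []
    for s, e in sorted((max(0.0, s), min(duration, e)) for s, e in raw):
        if intervals and s <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], e))
        else:
            intervals.append((s, e))
    covered = sum(e - s for s, e in intervals)
    mask = np.zeros(t.size, dtype=bool)
    for s, e in intervals:
        mask |= (t >= s) & (t <= e)
    hours = max(0.0, duration - covered) / 3600.0
    return intervals, mask, hours


def _alternating_extrema(x: np.ndarray, prominence: float
                         ) -> list[tuple[int, str]]:
    """Prominence-filtered peak/trough sequence, cleaned to alternate."""
    kw = dict(prominence=prominence, plateau_size=(1, None))
    pk, pk_props = find_peaks(x, **kw)
    tr, tr_props = find_peaks(-x, **kw)
    # Use the left edge of flat extrema so fall times start/stop at the turn.
    pk = pk_props.get("left_edges", pk)
    tr = tr_props.get("left_edges", tr)
    ext = sorted([(int(i), "peak") for i in pk] + [(int(i), "trough") for i in tr])
    cleaned: list[tuple[int, str]] = []
    for i, kind in ext:
        if cleaned and cleaned[-1][1] == kind:
            j, _ = cleaned[-1]
            better = x[i] > x[j] if kind == "peak" else x[i] < x[j]
            if better:
                cleaned[-1] = (i, kind)
        else:
            cleaned.append((i, kind))
    return cleaned


def detect_ptt_arousals(beats: BeatSeries, ptt2: np.ndarray,
                        artefact: np.ndarray | None = None,
                        artefact_free_hours: float | None = None,
                        drop_threshold: float = AROUSAL_DROP_MS,
                        prominence: float = 5.0,
                        fall_fraction: float = 0.8,
                        ) -> tuple[list[ArousalEvent], float]:
    """Detect PTT arousals on the smoothed PTT2 series.

    An arousal is a fall of at least ``drop_threshold`` ms from a local
    PTT2 maximum to the following minimum, completed in 5-45 s, with every
    sample on the way inside the 150-500 ms validity band and outside
    artefact.  The running maximum resets at each detected dip minimum, so
    one physiological arousal yields one event.  Returns the events and the
    PTT arousal index (events per artefact-free hour; NaN when no
    artefact-free time exists).
    """
    t = beats.beat_time
    x = np.asarray(ptt2, dtype=float)
    usable = np.isfinite(x) & (x >= PTT_VALID_MIN_MS) & (x <= PTT_VALID_MAX_MS)
    if artefact is not None:
        usable &= ~np.asarray(artefact, dtype=bool)
    events: list[ArousalEvent] = []
    # scan contiguous usable segments independently
    boundaries = np.nonzero(np.diff(usable.astype(int)))[0] + 1
    start = 0
    for stop in list(boundaries) + [usable.size]:
        if usable[start:stop].any() and usable[start]:
            seg = slice(start, stop)
            xs, ts = x[seg], t[seg]
            ext = _alternating_extrema(xs, prominence)
            scan_from = 0
            for k, (j, kind) in enumerate(ext):
                if kind != "trough":
                    continue
                # fall starts at the preceding peak extremum (or the start
                # of the scan when the series was flat before the dip)
                prev = ext[k - 1][0] if k > 0 else 0
                lo = max(prev, scan_from)
                window = xs[lo:j + 1]
                drop = float(np.max(window) - xs[j])
                # Fall time, estimated ripple-robustly: time taken for the
                # deepest `fall_fraction` of the drop (a level safely below
                # breath-to-breath ripple), rescaled assuming a roughly
                # linear descent.
                level = xs[j] + fall_fraction * drop
                above = np.nonzero(window >= level)[0]
                i = lo + int(above[-1])
                fall = (ts[j] - ts[i]) / fall_fraction
                if drop >= drop_threshold and \
                        AROUSAL_FALL_MIN_S <= fall <= AROUSAL_FALL_MAX_S:
                    events.append(ArousalEvent(float(ts[i]), float(ts[j]),
                                               float(drop)))
                    scan_from = j     # running max resets at the dip minimum
        start = stop
    if artefact_free_hours is None:
        artefact_free_hours = (t[-1] - t[0]) / 3600.0 if t.size > 1 else 0.0
    ptt_ai = len(events) / artefact_free_hours if artefact_free_hours > 0 \
        else float("nan")
    return events, ptt_ai


def derive_resp_channel(beat_times: np.ndarray, ptt_raw: np.ndarray,
                        valid: np.ndarray,
                        duration: float | None = None,
                        artefact_intervals: list[tuple[float, float]] | None = None,
                        max_gap_s: float = 5.0,
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interpolate valid raw PTT onto a 1 Hz grid and 3-sample smooth it.

    Returns ``(grid_times, values, mask)`` where ``mask`` is True for grid
    samples without a valid source beat within ``max_gap_s`` or inside a
    masked artefact interval.  Requires at least two valid beats.
    """
    t = np.asarray(beat_times, dtype=float)
    x = np.asarray(ptt_raw, dtype=float)
    good = np.asarray(valid, dtype=bool) & np.isfinite(x)
    if artefact_intervals:
        for s, e in artefact_intervals:
            good &= ~((t >= s) & (t <= e))
    if good.sum() < 2:
        raise ValueError("need at least two valid beats for the respiratory channel")
    tg, xg = t[good], x[good]
    if duration is None:
        duration = float(t[-1])
    grid = np.arange(0.0, np.floor(duration) + 1.0)
    interp = np.interp(grid, tg, xg)
    # 3-sample centred moving mean, window shrinking at the edges
    smooth = interp.copy()
    if interp.size >= 3:
        smooth[1:-1] = (interp[:-2] + interp[1:-1] + interp[2:]) / 3.0
        smooth[0] = interp[:2].mean()
        smooth[-1] = interp[-2:].mean()
    # mask where no valid beat is nearby or inside artefact intervals
    idx = np.searchsorted(tg, grid)
    left = np.abs(grid - tg[np.clip(idx - 1, 0, tg.size - 1)])
    right = np.abs(tg[np.clip(idx, 0, tg.size - 1)] - grid)
    mask = np.minimum(left, right) > max_gap_s
    mask |= (grid < tg[0]) | (grid > tg[-1])
    if artefact_intervals:
        for s, e in artefact_intervals:
            mask |= (grid >= s) & (grid <= e)
    return grid, smooth, mask


@dataclass
class PttrsResult:
    pttrs: float
    n_pairs: int
    no_breaths: bool = False


def compute_pttrs(resp_channel: np.ndarray, mask: np.ndarray | None = None,
                  min_prominence: float = 1.0, min_separation_s: float = 1.0,
                  sample_period_s: float = 1.0) -> PttrsResult:
    """Mean respiratory rise (trough to following peak) of the PTT channel.

    Breath extrema are detected per unmasked segment with a minimum
    prominence (1 ms default) and minimum spacing; PTTrs is the mean of
    ``peak - trough`` over successive pairs.  With no detectable breath
    cycle the result is 0 ms with ``no_breaths`` flagged.
    """
    x = np.asarray(resp_channel, dtype=float)
    if mask is None:
        mask = ~np.isfinite(x)
    else:
        mask = np.asarray(mask, dtype=bool) | ~np.isfinite(x)
    rises: list[float] = []
    dist = max(1, int(round(min_separation_s / sample_period_s)))
    start = 0
    boundaries = np.nonzero(np.diff(mask.astype(int)))[0] + 1
    for stop in list(boundaries) + [mask.size]:
        if not mask[start] and stop - start >= 3:
            xs = x[start:stop]
            kw = dict(prominence=min_prominence, distance=dist,
                      plateau_size=(1, None))
            pk, pkp = find_peaks(xs, **kw)
            tr, trp = find_peaks(-xs, **kw)
            ext = sorted([(int(i), "peak") for i in pk]
                         + [(int(i), "trough") for i in tr])
            for (i, k1), (j, k2) in zip(ext, ext[1:]):
                if k1 == "trough" and k2 == "peak":
                    rises.append(float(xs[j] - xs[i]))
        start = stop
    if not rises:
        return PttrsResult(0.0, 0, no_breaths=True)
    return PttrsResult(float(np.mean(rises)), len(rises))


def apply_duration_rule(artefact_free_hours: float,
                        min_hours: float = MIN_PTT_HOURS) -> bool:
    """Inclusion rule: at least ``min_hours`` of artefact-free PTT data.

    The boundary is inclusive (the exclusion is stated as "< 3 h"); the
    4-h variant is used for the duration sensitivity re-analysis.
    """
    if artefact_free_hours < 0:
        raise ValueError("artefact-free hours cannot be negative")
    return artefact_free_hours >= min_hours


def extract_ptt(recording: Recording, min_hours: float = MIN_PTT_HOURS,
                ) -> tuple[PttSummary, PttChannels]:
    """Run the full PTT chain on one recording."""
    beats = compute_ptt(recording.r_peak_times, recording.pleth,
                        recording.pleth_rate)
    intervals, beat_mask, hours = remove_ptt_artefact(
        beats, duration=recording.duration)
    ptt2 = smooth_ptt2(beats, artefact=beat_mask)
    events, ptt_ai = detect_ptt_arousals(beats, ptt2, artefact=beat_mask,
                                         artefact_free_hours=hours)
    flags: list[str] = []
    if not np.isfinite(ptt_ai):
        flags.append("no artefact-free PTT time")
    try:
        grid, resp, resp_mask = derive_resp_channel(
            beats.beat_time, beats.ptt_raw, beats.valid,
            duration=recording.duration, artefact_intervals=intervals)
        res = compute_pttrs(resp, resp_mask)
        if res.no_breaths:
            flags.append("no detectable breath cycle")
    except ValueError:
        grid = np.array([])
        resp = np.array([])
        resp_mask = np.array([], dtype=bool)
        res = PttrsResult(0.0, 0, no_breaths=True)
        flags.append("too few valid beats")
    summary = PttSummary(
        pttrs=res.pttrs, ptt_ai=ptt_ai, n_arousals=len(events),
        ptt_duration_hours=hours,
        included=apply_duration_rule(hours, min_hours), flags=flags)
    channels = PttChannels(
        beats=beats, ptt2=ptt2, beat_artefact=beat_mask,
        artefact_intervals=intervals, resp_time=grid, resp_channel=resp,
        resp_mask=resp_mask, artefact_free_hours=hours)
    return summary, channels
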