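"""Minimal EDF+ reader/writer for sleep recordings.

No EDF *writer* is available among the supported dependencies, so this
module implements the small subset of EDF+C needed here: 16-bit signals at
fixed rates plus one annotation channel carrying time-stamped events
(R-peaks, obstructive episodes, snoring).  Files written here are readable
by standard EDF tools (mne's reader is used as a cross-check in the test
suite).

Recording-level helpers store the plethysmograph as signal ``Pleth``
(100 Hz), the oximeter trace as ``SpO2`` (1 Hz), R-peaks as ``rpeak``
annotations (millisecond onsets) and episodes as ``obstruction`` /
``obstruction+arousal`` annotations.  The generating profile, when
present, goes to a JSON truth sidecar next to the EDF.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from .types import ObstructiveEpisode, Recording, SubjectProfile

_DIG_MIN, _DIG_MAX = -32768, 32767


class EdfError(IOError):
    pass


class MissingChannelError(EdfError):
    """A required signal is absent from the file."""


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise EdfError(f"header field too long: {text!r}")
    return b.ljust(width)


def write_edf(path: str | Path,
              signals: list[dict],
              annotations: list[tuple[float, float, str]] = (),
              ) -> None:
    """Write an EDF+C file with 1-s data records.

    Each signal dict needs ``label``, ``rate`` (samples/s, integer),
    ``data`` (1-D array in physical units), ``physical_min``,
    ``physical_max`` and optional ``unit``.  Annotations are
    ``(onset_s, duration_s, text)`` tuples.
    """
    path = Path(path)
    n_records = max(
        int(math.ceil(len(s["data"]) / s["rate"])) for s in signals)
    # build per-record annotation byte blocks (TALs)
    ann_by_record: list[bytes] = []
    anns = sorted(annotations, key=lambda a: a[0])
    k = 0
    for r in range(n_records):
        block = f"+{r}\x14\x14\x00".encode("ascii")
        while k < len(anns) and anns[k][0] < r + 1:
            onset, dur, text = anns[k]
            tal = f"+{onset:.3f}"
            if dur > 0:
                tal += f"\x15{dur:.3f}"
            tal += f"\x14{text}\x14\x00"
            block += tal.encode("utf-8")
            k += 1
        ann_by_record.append(block)
    ann_samples = max(16, int(math.ceil(max(len(b) for b in ann_by_record) / 2)))

    n_sig = len(signals) + 1
    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate 01-JAN-2000 X X X", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (n_sig + 1)), 8),
        _pad("EDF+C", 44),
        _pad(str(n_records), 8),
        _pad("1", 8),
        _pad(str(n_sig), 4),
    ])

    def field(fmt_values: list[str], width: int) -> bytes:
        return b"".join(_pad(v, width) for v in fmt_values)

    labels = [s["label"] for s in signals] + ["EDF Annotations"]
    units = [s.get("unit", "") for s in signals] + [""]
    pmins = [f"{s['physical_min']:g}"[:8] for s in signals] + ["-32768"]
    pmaxs = [f"{s['physical_max']:g}"[:8] for s in signals] + ["32767"]
    rates = [str(int(s["rate"])) for s in signals] + [str(ann_samples)]
    header += field(labels, 16)
    header += field(["" for _ in range(n_sig)], 80)          # transducer
    header += field(units, 8)
    header += field(pmins, 8)
    header += field(pmaxs, 8)
    header += field([str(_DIG_MIN)] * n_sig, 8)
    header += field([str(_DIG_MAX)] * n_sig, 8)
    header += field(["" for _ in range(n_sig)], 80)          # prefilter
    header += field(rates, 8)
    header += field(["" for _ in range(n_sig)], 32)          # reserved

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for s in signals:
                rate = int(s["rate"])
                seg = np.asarray(s["data"][r * rate:(r + 1) * rate],
                                 dtype=float)
                if seg.size < rate:
                    fill = seg[-1] if seg.size else s["physical_min"]
                    seg = np.concatenate([seg, np.full(rate - seg.size, fill)])
                pmin, pmax = s["physical_min"], s["physical_max"]
                scaled = (seg - pmin) / (pmax - pmin) * (_DIG_MAX - _DIG_MIN) \
                    + _DIG_MIN
                dig = np.clip(np.rint(scaled), _DIG_MIN, _DIG_MAX).astype("<i2")
                fh.write(dig.tobytes())
            block = ann_by_record[r].ljust(2 * ann_samples, b"\x00")
            fh.write(block)


def read_edf(path: str | Path) -> dict:
    """Read an EDF/EDF+ file written by :func:`write_edf`.

    Returns ``{"signals": {label: {"rate": r, "data": array}},
    "annotations": [(onset, duration, text), ...]}``.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 256:
        raise EdfError(f"not an EDF file: {path}")
    n_records = int(raw[236:244].decode("ascii").strip())
    n_sig = int(raw[252:256].decode("ascii").strip())
    off = 256

    def sfield(width: int) -> list[str]:
        nonlocal off
        vals = [raw[off + i * width: off + (i + 1) * width].decode(
            "ascii", errors="replace").strip() for i in range(n_sig)]
        off += n_sig * width
        return vals

    labels = sfield(16)
    sfield(80)
    sfield(8)                      # units
    pmins = [float(v) for v in sfield(8)]
    pmaxs = [float(v) for v in sfield(8)]
    dmins = [float(v) for v in sfield(8)]
    dmaxs = [float(v) for v in sfield(8)]
    sfield(80)
    rates = [int(v) for v in sfield(8)]
    sfield(32)

    data_off = int(raw[184:192].decode("ascii").strip())
    rec_len = sum(rates) * 2
    chunks: list[list[bytes]] = [[] for _ in range(n_sig)]
    for r in range(n_records):
        pos = data_off + r * rec_len
        for i in range(n_sig):
            chunks[i].append(raw[pos:pos + rates[i] * 2])
            pos += rates[i] * 2
    signals: dict[str, dict] = {}
    annotations: list[tuple[float, float, str]] = []
    for i, label in enumerate(labels):
        blob = b"".join(chunks[i])
        if label == "EDF Annotations":
            for tal in blob.split(b"\x00"):
                if not tal or b"\x14" not in tal:
                    continue
                head, *texts = tal.split(b"\x14")
                if b"\x15" in head:
                    onset_b, dur_b = head.split(b"\x15")
                    dur = float(dur_b)
                else:
                    onset_b, dur = head, 0.0
                onset = float(onset_b)
                for text in texts:
                    if text:
                        annotations.append((onset, dur, text.decode("utf-8")))
            continue
        dig = np.frombuffer(blob, dtype="<i2").astype(float)
        scale = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
        signals[label] = {
            "rate": rates[i],
            "data": (dig - dmins[i]) * scale + pmins[i],
        }
    return {"signals": signals, "annotations": annotations}


def write_recording(path: str | Path, recording: Recording) -> None:
    """Serialise a recording (EDF + JSON truth sidecar if truth present)."""
    path = Path(path)
    anns: list[tuple[float, float, str]] = [
        (float(t), 0.0, "rpeak") for t in recording.r_peak_times]
    for e in recording.video_labels:
        label = "obstruction+arousal" if e.has_arousal else "obstruction"
        anns.append((e.start, e.end - e.start, label))
    if recording.snoring:
        anns.append((0.0, 0.0, "snoring"))
    lo = float(recording.pleth.min())
    hi = float(recording.pleth.max())
    if hi <= lo:
        hi = lo + 1.0
    write_edf(path, signals=[
        dict(label="Pleth", rate=int(recording.pleth_rate),
             data=recording.pleth, physical_min=lo - 0.05 * (hi - lo),
             physical_max=hi + 0.05 * (hi - lo), unit="au"),
        dict(label="SpO2", rate=1, data=recording.spo2,
             physical_min=0.0, physical_max=100.0, unit="%"),
    ], annotations=anns)
    if recording.truth is not None:
        sidecar = path.with_suffix(path.suffix + ".truth.json")
        sidecar.write_text(json.dumps(recording.truth.to_dict(), indent=1))


def read_recording(path: str | Path) -> Recording:
    """Load a recording written by :func:`write_recording`."""
    path = Path(path)
    if not path.exists():
        raise EdfError(f"no such file: {path}")
    content = read_edf(path)
    signals = content["signals"]
    for required in ("Pleth", "SpO2"):
        if required not in signals:
            raise MissingChannelError(
                f"missing channel {required!r} in {path.name}")
    r_peaks = sorted(o for o, _, t in content["annotations"] if t == "rpeak")
    if not r_peaks:
        raise MissingChannelError(f"no R-peak annotations in {path.name}")
    episodes = [
        ObstructiveEpisode(o, o + d, has_arousal=(t == "obstruction+arousal"))
        for o, d, t in content["annotations"]
        if t.startswith("obstruction")]
    snoring = any(t == "snoring" for _, _, t in content["annotations"])
    truth = None
    sidecar = path.with_suffix(path.suffix + ".truth.json")
    if sidecar.exists():
        truth = SubjectProfile.from_dict(json.loads(sidecar.read_text()))
    spo2 = np.clip(signals["SpO2"]["data"], 0.0, 100.0)
    return Recording(
        r_peak_times=np.asarray(r_peaks), pleth=signals["Pleth"]["data"],
        pleth_rate=float(signals["Pleth"]["rate"]), spo2=spo2,
        video_labels=episodes, snoring=snoring, truth=truth)
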