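"""Minimal EDF+C reader/writer for annotated device recordings.

European Data Format stores each signal as 16-bit integers in fixed-duration
data records, with per-signal physical/digital calibration ranges in the
header; EDF+ adds an "EDF Annotations" signal carrying timestamped event
lists (TALs).  This module implements the subset the pipeline needs: one
continuous recording, a 1-second record duration, EEG channels plus one
impedance channel per electrode (labelled ``IMP <name>``), and text
annotations.

Round-tripping preserves sample values to within one quantization step of
each signal's physical range (the 16-bit resolution of the format), all
annotations exactly, and the declared sampling rate.
"""

from __future__ import annotations

import math

from pathlib import Path

import numpy as np

from .recording import Annotation, RawRecording

__all__ = ["write_edf", "read_edf", "EdfError"]

_RECORD_S = 1.0  # data record duration, seconds
_IMP_PREFIX = "IMP "


class EdfError(IOError):
    """Malformed EDF content or an unwritable/unreadable path."""


def _ascii(value: str, width: int) -> bytes:
    s = value[:width].ljust(width)
    return s.encode("ascii")


def _num(value: float, width: int) -> bytes:
    for fmt in (f"{value:.10g}", f"{value:.6g}", f"{value:.4g}"):
        if len(fmt) <= width:
            return _ascii(fmt, width)
    raise EdfError(f"cannot encode {value} in {width} ascii chars")


def _snap(value: float, outward: int) -> float:
    """Round to a value exactly representable in an 8-char header field.

    ``outward`` = -1 floors, +1 ceils, so a snapped [lo, hi] range always
    contains the data; digitization then uses the *snapped* bounds, keeping
    the round-trip error within one true quantization step.
    """
    for digits in (10, 6, 4, 2):
        s = f"{value:.{digits}g}"
        if len(s) <= 8:
            parsed = float(s)
            if (outward < 0 and parsed <= value) or (outward > 0 and parsed >= value):
                return parsed
            # nudge by one unit in the last significant place
            step = abs(parsed) * 10.0 ** (-digits + 1) or 10.0 ** (-digits + 1)
            nudged = float(f"{parsed + outward * step:.{digits}g}")
            if len(f"{nudged:.{digits}g}") <= 8:
                return nudged
    raise EdfError(f"cannot encode {value} in 8 ascii chars")


def _phys_range(x: np.ndarray) -> tuple[float, float]:
    lo, hi = float(np.min(x)), float(np.max(x))
    if not (math.isfinite(lo) and math.isfinite(hi)):
        raise EdfError("non-finite samples cannot be stored in EDF")
    if lo == hi:  # flat signal: the format requires distinct bounds
        lo, hi = lo - 1.0, hi + 1.0
    return _snap(lo, -1), _snap(hi, +1)


def _tal(onset: float, duration: float | None, text: str) -> bytes:
    out = f"{'+' if onset >= 0 else ''}{onset:.4f}".rstrip("0").rstrip(".")
    if not out.lstrip("+-"):
        out = "+0"
    payload = out
    if duration is not None and duration > 0:
        payload += "\x15" + f"{duration:.4f}".rstrip("0").rstrip(".")
    payload += "\x14" + text + "\x14\x00"
    return payload.encode("utf-8")


def write_edf(recording: RawRecording, path: str | Path) -> None:
    """Write a recording (signals, impedance stream, annotations) as EDF+C.

    The signal is padded with its final sample value up to a whole number of
    1-second records; simulated sessions are always whole seconds long, so in
    practice nothing is padded.
    """
    path = Path(path)
    fs = recording.sfreq
    spr = int(round(fs * _RECORD_S))
    if abs(spr - fs * _RECORD_S) > 1e-9:
        raise EdfError(f"sampling rate {fs} does not fill whole {_RECORD_S}-s records")
    n_records = max(1, math.ceil(recording.n_samples / spr))

    streams: list[tuple[str, np.ndarray]] = [
        (name, recording.data[i]) for i, name in enumerate(recording.ch_names)
    ]
    if recording.impedance is not None:
        streams += [
            (_IMP_PREFIX + name, recording.impedance[i])
            for i, name in enumerate(recording.ch_names)
        ]

    # digitize every stream to int16 against its own physical range
    digitized, phys = [], []
    for _, x in streams:
        pad = n_records * spr - x.size
        if pad:
            x = np.concatenate([x, np.full(pad, x[-1])])
        lo, hi = _phys_range(x)
        scale = 65535.0 / (hi - lo)
        d = np.round((x - lo) * scale) - 32768.0
        digitized.append(np.clip(d, -32768, 32767).astype("<i2"))
        phys.append((lo, hi))

    # annotations: the TAL stream for each record = its timestamp TAL plus
    # the TALs of every event whose onset falls inside that record
    per_record: list[bytearray] = []
    events = sorted(recording.annotations, key=lambda a: a.onset)
    for rec in range(n_records):
        chunk = bytearray(_tal(rec * _RECORD_S, None, ""))
        per_record.append(chunk)
    for ev in events:
        rec = min(int(ev.onset // _RECORD_S), n_records - 1)
        per_record[rec] += _tal(ev.onset, ev.duration, ev.description)
    ann_bytes = max(len(c) for c in per_record)
    ann_spr = math.ceil(ann_bytes / 2)  # 2 bytes per "sample"

    n_signals = len(streams) + 1
    header = bytearray()
    header += _ascii("0", 8)
    header += _ascii("X X X X", 80)
    header += _ascii("Startdate 01-JAN-2000 X X X", 80)
    header += _ascii("01.01.00", 8)
    header += _ascii("00.00.00", 8)
    header += _num(256 * (n_signals + 1), 8)
    header += _ascii("EDF+C", 44)
    header += _num(n_records, 8)
    header += _num(_RECORD_S, 8)
    header += _num(n_signals, 4)

    labels = [name for name, _ in streams] + ["EDF Annotations"]
    header += b"".join(_ascii(lbl, 16) for lbl in labels)
    header += b"".join(_ascii("", 80) for _ in labels)  # transducer
    header += b"".join(_ascii("", 8) for _ in labels)  # physical dimension
    header += b"".join(_num(lo, 8) for lo, _ in phys) + _num(-1, 8)
    header += b"".join(_num(hi, 8) for _, hi in phys) + _num(1, 8)
    header += b"".join(_num(-32768, 8) for _ in streams) + _num(-32768, 8)
    header += b"".join(_num(32767, 8) for _ in streams) + _num(32767, 8)
    header += b"".join(_ascii("", 80) for _ in labels)  # prefiltering
    header += b"".join(_num(spr, 8) for _ in streams) + _num(ann_spr, 8)
    header += b"".join(_ascii("", 32) for _ in labels)

    try:
        with open(path, "wb") as fh:
            fh.write(bytes(header))
            for rec in range(n_records):
                sl = slice(rec * spr, (rec + 1) * spr)
                for d in digitized:
                    fh.write(d[sl].tobytes())
                chunk = bytes(per_record[rec]).ljust(2 * ann_spr, b"\x00")
                fh.write(chunk)
    except OSError as exc:
        raise EdfError(f"cannot write EDF to {path}: {exc}") from exc


def _parse_tals(raw: bytes) -> list[Annotation]:
    out: list[Annotation] = []
    for tal in raw.split(b"\x00"):
        tal = tal.strip(b"\x00")
        if not tal:
            continue
        try:
            head, *texts = tal.split(b"\x14")
            if b"\x15" in head:
                onset_b, dur_b = head.split(b"\x15")
                duration = float(dur_b)
            else:
                onset_b, duration = head, 0.0
            onset = float(onset_b)
        except ValueError as exc:
            raise EdfError(f"malformed annotation TAL: {tal!r}") from exc
        for text in texts:
            if text:  # empty text = record timestamp marker
                out.append(Annotation(onset, duration, text.decode("utf-8")))
    return out


def read_edf(path: str | Path) -> RawRecording:
    """Read an EDF/EDF+ file written by :func:`write_edf`.

    Channels labelled ``IMP <name>`` are returned as the impedance stream of
    the matching data channel; the annotation signal becomes the
    ``annotations`` list.
    """
    path = Path(path)
    try:
        blob = path.read_bytes()
    except OSError as exc:
        raise EdfError(f"cannot read EDF from {path}: {exc}") from exc
    if len(blob) < 256:
        raise EdfError(f"{path} is too short to be an EDF file")

    def fields(offset: int, width: int, n: int) -> list[str]:
        return [
            blob[offset + i * width : offset + (i + 1) * width].decode("ascii", "replace").strip()
            for i in range(n)
        ]

    try:
        n_records = int(blob[236:244].decode().strip())
        record_s = float(blob[244:252].decode().strip())
        ns = int(blob[252:256].decode().strip())
    except ValueError as exc:
        raise EdfError(f"malformed EDF header in {path}") from exc

    off = 256
    labels = fields(off, 16, ns); off += 16 * ns
    off += 80 * ns  # transducer
    off += 8 * ns  # dimension
    pmin = [float(v) for v in fields(off, 8, ns)]; off += 8 * ns
    pmax = [float(v) for v in fields(off, 8, ns)]; off += 8 * ns
    dmin = [int(v) for v in fields(off, 8, ns)]; off += 8 * ns
    dmax = [int(v) for v in fields(off, 8, ns)]; off += 8 * ns
    off += 80 * ns  # prefiltering
    spr = [int(v) for v in fields(off, 8, ns)]; off += 8 * ns
    off += 32 * ns
    header_len = int(blob[184:192].decode().strip())
    if header_len != off:
        raise EdfError(f"header length field {header_len} != parsed length {off}")

    record_len = sum(spr) * 2
    body = blob[header_len:]
    if len(body) < n_records * record_len:
        raise EdfError(f"{path}: truncated data records")

    ann_idx = [i for i, lbl in enumerate(labels) if lbl == "EDF Annotations"]
    sig_idx = [i for i in range(ns) if i not in ann_idx]

    raw_sig = {i: np.empty(n_records * spr[i], dtype=float) for i in sig_idx}
    ann_raw = bytearray()
    offsets = np.cumsum([0] + [2 * s for s in spr])
    for rec in range(n_records):
        base = rec * record_len
        for i in sig_idx:
            chunk = body[base + offsets[i] : base + offsets[i + 1]]
            dig = np.frombuffer(chunk, dtype="<i2").astype(float)
            gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
            raw_sig[i][rec * spr[i] : (rec + 1) * spr[i]] = (dig - dmin[i]) * gain + pmin[i]
        for i in ann_idx:
            ann_raw += body[base + offsets[i] : base + offsets[i + 1]]

    annotations = _parse_tals(bytes(ann_raw))
    data_ch = [i for i in sig_idx if not labels[i].startswith(_IMP_PREFIX)]
    imp_ch = {labels[i][len(_IMP_PREFIX):]: i for i in sig_idx if labels[i].startswith(_IMP_PREFIX)}

    names = tuple(labels[i] for i in data_ch)
    sfreq = spr[data_ch[0]] / record_s if data_ch else 1.0 / record_s
    data = np.vstack([raw_sig[i] for i in data_ch])
    impedance = None
    if imp_ch:
        if set(imp_ch) != set(names):
            raise EdfError("impedance channels do not match data channels")
        impedance = np.vstack([raw_sig[imp_ch[n]] for n in names])
    return RawRecording(
        data=data,
        sfreq=sfreq,
        ch_names=names,
        annotations=annotations,
        impedance=impedance,
    )
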