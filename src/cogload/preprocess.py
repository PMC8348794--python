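"""Preprocessing steps 1–4: filtering, channel rejection, epoching, epoch rejection.

The pipeline mirrors automatic cleaning for a consumer-grade 14-channel
headset at 128 Hz:

1. zero-phase band-pass filtering (1–40 Hz nominal edges) to strip slow
   electrode drift and power-line contamination;
2. whole-channel rejection by normalized kurtosis — a channel whose sample
   kurtosis, standardized across channels, exceeds a threshold (default 5) is
   treated as corrupted and dropped;
3. stimulus-locked epoching into 1500 ms (192-sample) windows, with fixation
   baseline blocks tiled into non-overlapping windows of the same length
   (condition L0);
4. per-epoch rejection by three criteria applied in order — kurtosis outlier,
   absolute amplitude above 1500 device units, electrode impedance below 100
   device units — each epoch receiving the first matching reason.

Every rejection is counted, per (subject, day, condition) and per reason, so
the fraction of discarded data can be reported as a data-quality index.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, firwin
from scipy.stats import kurtosis as _kurtosis

from .recording import RawRecording

__all__ = [
    "FilterSpec",
    "EpochSet",
    "RejectionStats",
    "bandpass",
    "reject_channels",
    "extract_epochs",
    "reject_epochs",
    "rejection_stats",
    "EPOCH_SAMPLES",
    "AMPLITUDE_LIMIT",
    "IMPEDANCE_LIMIT",
    "KURTOSIS_Z",
]

EPOCH_S = 1.5
EPOCH_SAMPLES = 192  # 1500 ms at 128 Hz
AMPLITUDE_LIMIT = 1500.0  # device units
IMPEDANCE_LIMIT = 100.0  # device units
KURTOSIS_Z = 5.0

_STIM_RE = re.compile(r"^stim (L\d)/d(\d)/t([01])/r([01])$")
_BASE_RE = re.compile(r"^baseline (L\d)$")


def _robust_z(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Standardize by median and scaled MAD instead of mean and SD.

    With only 14 channels (or in the presence of several extreme epochs) the
    ordinary z-score is bounded by the outliers' own leverage — one corrupted
    channel among 14 can never exceed |z| ~ 3.6 — so the deviation detector
    standardizes robustly.  Zero MAD (identical values) yields z = 0.
    """
    med = np.median(values, axis=axis, keepdims=True)
    mad = np.median(np.abs(values - med), axis=axis, keepdims=True)
    scale = 1.4826 * mad  # consistent with SD under normality
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(scale > 0, (values - med) / scale, 0.0)
    return z


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase windowed-sinc band-pass design.

    ``hp_edge``/``lp_edge`` are the nominal pass edges (1 and 40 Hz); the -6 dB
    cutoffs are placed at the midpoint of each transition so that the stopband
    requirements (>= 30 dB at ``stop_lo`` and ``stop_hi``) are met with a
    Hamming-window FIR of ``numtaps`` taps applied once, centered (symmetric
    taps => exactly zero phase).
    """

    hp_edge: float = 1.0
    lp_edge: float = 40.0
    stop_lo: float = 0.25
    stop_hi: float = 50.0
    numtaps: int = 845
    window: str = "hamming"

    def __post_init__(self) -> None:
        if not 0 < self.hp_edge < self.lp_edge:
            raise ValueError("need 0 < high-pass edge < low-pass edge")
        if self.numtaps % 2 == 0:
            raise ValueError("numtaps must be odd for a zero-phase type-I FIR")

    def taps(self, sfreq: float) -> np.ndarray:
        nyq = sfreq / 2.0
        if not self.lp_edge < nyq:
            raise ValueError(f"low-pass edge {self.lp_edge} must be below Nyquist {nyq}")
        lo_cut = (self.hp_edge + self.stop_lo) / 2.0
        hi_cut = min((self.lp_edge + self.stop_hi) / 2.0, self.lp_edge + 1.0)
        return firwin(
            self.numtaps, [lo_cut, hi_cut], pass_zero=False, window=self.window, fs=sfreq
        )


def bandpass(raw: RawRecording, spec: FilterSpec = FilterSpec()) -> RawRecording:
    """Zero-phase band-pass; annotations and impedance pass through untouched."""
    if raw.n_samples < spec.numtaps:
        raise ValueError(
            f"signal of {raw.n_samples} samples shorter than the filter warm-up; "
            f"need at least {spec.numtaps} samples"
        )
    taps = spec.taps(raw.sfreq)
    filtered = fftconvolve(raw.data, taps[np.newaxis, :], mode="same", axes=-1)
    return RawRecording(
        data=filtered,
        sfreq=raw.sfreq,
        ch_names=raw.ch_names,
        annotations=list(raw.annotations),
        impedance=None if raw.impedance is None else raw.impedance.copy(),
    )


def reject_channels(
    raw: RawRecording, z_threshold: float = KURTOSIS_Z
) -> tuple[RawRecording, pd.DataFrame]:
    """Drop *persistently* corrupted channels by normalized kurtosis.

    The per-channel statistic is the median over 1.5 s windows of the
    window's sample kurtosis: a channel contaminated throughout (e.g. a
    loose electrode spiking continuously) scores high in most windows, while
    a channel with a handful of bad stretches — which epoch rejection will
    handle — keeps a clean median.  The statistic is standardized across
    channels (robust z: median/MAD) and channels with |z| above the
    threshold *and* a clearly non-Gaussian median (|kurtosis| > 0.5) are
    removed.  Flat (zero-variance) channels are removed with reason ``flat``
    rather than entering the standardization.  Returns the retained
    recording and a log frame with one row per channel (kurtosis, z, removed
    flag, reason).
    """
    if raw.n_channels < 3:
        raise ValueError("channel rejection needs at least 3 channels")
    variances = raw.data.var(axis=1)
    flat = variances <= 1e-12 * np.maximum(np.square(raw.data.mean(axis=1)), 1.0)
    n_win = raw.n_samples // EPOCH_SAMPLES
    kurt = np.full(raw.n_channels, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # degenerate windows handled below
        if n_win >= 3:
            windows = raw.data[:, : n_win * EPOCH_SAMPLES].reshape(
                raw.n_channels, n_win, EPOCH_SAMPLES
            )
            win_k = _kurtosis(windows, axis=2, fisher=True, bias=True)
            kurt[~flat] = np.median(np.where(np.isfinite(win_k), win_k, 0.0), axis=1)[~flat]
        else:  # recording shorter than a few windows: whole-channel kurtosis
            kurt[~flat] = _kurtosis(raw.data[~flat], axis=1, fisher=True, bias=True)
    z = np.zeros(raw.n_channels)
    z[~flat] = _robust_z(kurt[~flat])
    # upper tail only: kurtosis flags spiky (leptokurtic) corruption
    removed = flat | ((z > z_threshold) & (kurt > 0.5))
    reasons = np.where(flat, "flat", np.where(removed, "kurtosis", ""))
    log = pd.DataFrame(
        {
            "channel": list(raw.ch_names),
            "kurtosis": kurt,
            "z": z,
            "removed": removed,
            "reason": reasons,
        }
    )
    kept = [ch for ch, rm in zip(raw.ch_names, removed) if not rm]
    return raw.pick(kept), log


@dataclass
class EpochSet:
    """Stimulus-locked 1500 ms epochs with per-epoch metadata.

    ``data`` is (n_epochs, n_channels, 192); ``metadata`` has one row per
    epoch with columns ``condition`` (L0–L3), ``is_target``, ``responded``,
    ``onset_s``, ``status`` (``retained`` or ``rejected:<reason>``).
    ``impedance_min`` holds the lowest impedance reading per epoch/channel
    (NaN when no impedance stream was recorded).
    """

    data: np.ndarray
    metadata: pd.DataFrame
    ch_names: tuple[str, ...]
    sfreq: float
    subject: str = "S00"
    day: int = 1
    impedance_min: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata rows must match epoch count")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def retained(self) -> "EpochSet":
        keep = (self.metadata["status"] == "retained").to_numpy()
        return replace(
            self,
            data=self.data[keep],
            metadata=self.metadata.loc[keep].reset_index(drop=True),
            impedance_min=None if self.impedance_min is None else self.impedance_min[keep],
        )


def extract_epochs(
    raw: RawRecording,
    *,
    subject: str = "S00",
    day: int = 1,
    epoch_samples: int = EPOCH_SAMPLES,
) -> EpochSet:
    """Cut stimulus-locked and baseline epochs out of an annotated recording.

    One epoch per ``stim`` annotation, ``epoch_samples`` samples starting at
    the onset sample (half-open window); ``baseline`` annotations are tiled
    into non-overlapping windows of the same length, labelled condition L0.
    Epochs running past the end of the recording are kept in the metadata
    with status ``rejected:truncated`` and zero-filled data.
    """
    rows = []
    windows = []
    for ann in raw.annotations:
        m = _STIM_RE.match(ann.description)
        if m:
            cond, digit, targ, resp = m.groups()
            rows.append(
                {
                    "condition": cond,
                    "digit": int(digit),
                    "is_target": bool(int(targ)),
                    "responded": bool(int(resp)),
                    "onset_s": ann.onset,
                }
            )
            windows.append(int(round(ann.onset * raw.sfreq)))
            continue
        m = _BASE_RE.match(ann.description)
        if m:
            n_tiles = int(ann.duration * raw.sfreq) // epoch_samples
            for k in range(n_tiles):
                onset = ann.onset + k * epoch_samples / raw.sfreq
                rows.append(
                    {
                        "condition": "L0",
                        "digit": 0,
                        "is_target": False,
                        "responded": False,
                        "onset_s": onset,
                    }
                )
                windows.append(int(round(onset * raw.sfreq)))

    if not rows:
        raise ValueError("no stimulus or baseline annotations found")
    order = np.argsort([r["onset_s"] for r in rows])
    rows = [rows[i] for i in order]
    windows = [windows[i] for i in order]

    data = np.zeros((len(rows), raw.n_channels, epoch_samples))
    imp = (
        np.full((len(rows), raw.n_channels), np.nan)
        if raw.impedance is None
        else np.empty((len(rows), raw.n_channels))
    )
    status = []
    for i, start in enumerate(windows):
        stop = start + epoch_samples
        if stop > raw.n_samples:
            status.append("rejected:truncated")
            if raw.impedance is not None:
                imp[i] = np.nan
            continue
        data[i] = raw.data[:, start:stop]
        if raw.impedance is not None:
            imp[i] = raw.impedance[:, start:stop].min(axis=1)
        status.append("retained")

    meta = pd.DataFrame(rows)
    meta["status"] = status
    meta["subject"] = subject
    meta["day"] = day
    return EpochSet(
        data=data,
        metadata=meta,
        ch_names=raw.ch_names,
        sfreq=raw.sfreq,
        subject=subject,
        day=day,
        impedance_min=imp,
    )


def reject_epochs(
    epochs: EpochSet,
    *,
    kurtosis_z: float = KURTOSIS_Z,
    amplitude_limit: float = AMPLITUDE_LIMIT,
    impedance_limit: float = IMPEDANCE_LIMIT,
) -> EpochSet:
    """Apply the three epoch-rejection criteria, in order, to retained epochs.

    (a) per-epoch per-channel kurtosis standardized across epochs within
    each channel (robust z), rejected when any channel's z exceeds the
    threshold on the upper (leptokurtic, spike-artifact) tail;
    (b) any sample with absolute amplitude above ``amplitude_limit``;
    (c) any channel impedance below ``impedance_limit`` during the epoch.
    Each rejected epoch gets the first matching reason; the order affects only
    reason attribution, not the retained set.
    """
    meta = epochs.metadata.copy()
    active = (meta["status"] == "retained").to_numpy()
    idx = np.flatnonzero(active)
    if idx.size == 0:
        return replace(epochs, metadata=meta)
    seg = epochs.data[idx]  # (n_active, n_ch, n_samp)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # flat epochs handled below
        k = _kurtosis(seg, axis=2, fisher=True, bias=True)  # (n_active, n_ch)
    k = np.where(np.isfinite(k), k, 0.0)
    z = _robust_z(k, axis=0)  # per channel, across epochs
    # upper tail only: spike artifacts are leptokurtic; low-kurtosis epochs
    # (e.g. a large sinusoidal excursion) fall to the amplitude criterion
    bad_kurt = (z > kurtosis_z).any(axis=1)

    bad_amp = (np.abs(seg) > amplitude_limit).any(axis=(1, 2))

    if epochs.impedance_min is not None:
        imp = epochs.impedance_min[idx]
        bad_imp = np.nanmin(imp, axis=1) < impedance_limit
    else:
        bad_imp = np.zeros(idx.size, dtype=bool)

    status = meta["status"].to_numpy(dtype=object)
    for j, ei in enumerate(idx):
        if bad_kurt[j]:
            status[ei] = "rejected:kurtosis"
        elif bad_amp[j]:
            status[ei] = "rejected:amplitude"
        elif bad_imp[j]:
            status[ei] = "rejected:impedance"
    meta["status"] = status
    return replace(epochs, metadata=meta)


def save_epochs(epochs: EpochSet, out_dir) -> None:
    """Write an epoch set as a directory: metadata CSV + JSON + array file."""
    from pathlib import Path
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    epochs.metadata.to_csv(out / "metadata.csv", index=False)
    np.savez_compressed(
        out / "epochs.npz",
        data=epochs.data,
        impedance_min=np.array([]) if epochs.impedance_min is None else epochs.impedance_min,
    )
    (out / "epochs.json").write_text(
        json.dumps(
            {
                "ch_names": list(epochs.ch_names),
                "sfreq": epochs.sfreq,
                "subject": epochs.subject,
                "day": epochs.day,
            },
            indent=2,
        )
    )


def load_epochs(in_dir) -> EpochSet:
    from pathlib import Path
    import json

    src = Path(in_dir)
    meta = pd.read_csv(src / "metadata.csv")
    arrays = np.load(src / "epochs.npz")
    info = json.loads((src / "epochs.json").read_text())
    imp = arrays["impedance_min"]
    return EpochSet(
        data=arrays["data"],
        metadata=meta,
        ch_names=tuple(info["ch_names"]),
        sfreq=float(info["sfreq"]),
        subject=info["subject"],
        day=int(info["day"]),
        impedance_min=None if imp.size == 0 else imp,
    )


@dataclass(frozen=True)
class RejectionStats:
    """Per (subject, day, condition) counts at each pipeline step."""

    table: pd.DataFrame = field(repr=False)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.table.to_string(index=False)


def rejection_stats(
    epoch_sets: list[EpochSet],
    threshold_counts: dict[tuple[str, int, str], int] | None = None,
) -> RejectionStats:
    """Tabulate rejection accounting across epoch sets.

    ``threshold_counts`` maps (subject, day, condition) to the number of
    epochs removed later by the band-power threshold, so the table covers all
    six pipeline steps.  Retained + per-reason counts always sum to the raw
    epoch count.
    """
    threshold_counts = threshold_counts or {}
    rows = []
    for es in epoch_sets:
        for cond, grp in es.metadata.groupby("condition"):
            reasons = grp["status"].str.replace("rejected:", "", regex=False)
            n_thresh = threshold_counts.get((es.subject, es.day, cond), 0)
            n_raw = len(grp)
            n_ret = int((grp["status"] == "retained").sum()) - n_thresh
            rows.append(
                {
                    "subject": es.subject,
                    "day": es.day,
                    "condition": cond,
                    "n_raw": n_raw,
                    "n_truncated": int((reasons == "truncated").sum()),
                    "n_kurtosis": int((reasons == "kurtosis").sum()),
                    "n_amplitude": int((reasons == "amplitude").sum()),
                    "n_impedance": int((reasons == "impedance").sum()),
                    "n_threshold": n_thresh,
                    "n_retained": n_ret,
                    "pct_rejected": 100.0 * (n_raw - n_ret) / n_raw if n_raw else 0.0,
                }
            )
    return RejectionStats(pd.DataFrame(rows))
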