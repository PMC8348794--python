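"""Band-power feature extraction: steps 5–6 of the preprocessing pipeline.

For every retained 1500 ms epoch (192 samples at 128 Hz) a Hann-windowed
periodogram is computed per channel, and power is summed over the four
classical bands — delta (1–3.5 Hz), theta (3.5–7.5 Hz), alpha (7.5–12.5 Hz)
and beta (12.5–30 Hz); bins are half-open ``[low, high)`` so no bin is
counted twice.  Band powers are log10-scaled and normalized by the similarly
scaled average full-band (1–40 Hz) power of the subject's same-day baseline
(L0) epochs, giving the 4 bands x 14 channels = 56-dimensional relative
log-power feature vector.

Two normalization conventions are supported and recorded in the output:

``ratio`` (default)
    value = log10(P) / log10(P_baseline) — a division of the two log-scaled
    quantities;
``difference``
    value = log10(P) - log10(P_baseline) — the log of the power ratio, linear
    in simulated log-power offsets and therefore the convention used for
    parameter-recovery checks.

Epochs with any relative band value strictly above 1.3 are rejected as
band-power outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from .montage import MontageSpec, DEFAULT_MONTAGE
from .preprocess import EpochSet

__all__ = [
    "BandScheme",
    "BANDS",
    "BaselineNorm",
    "band_power",
    "epoch_band_powers",
    "compute_baseline_norm",
    "relative_log_power",
    "extract_features",
    "threshold_filter",
    "FEATURE_THRESHOLD",
]

FEATURE_THRESHOLD = 1.3  # relative band value above which an epoch is an outlier
_EPS_POWER = 1e-12  # floor for zero band powers before log-scaling


@dataclass(frozen=True)
class BandScheme:
    """Frequency-band edges in Hz; bins half-open [low, high)."""

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "delta": (1.0, 3.5),
            "theta": (3.5, 7.5),
            "alpha": (7.5, 12.5),
            "beta": (12.5, 30.0),
        }
    )
    full: tuple[float, float] = (1.0, 40.0)

    def __post_init__(self) -> None:
        lo_f, hi_f = self.full
        edges = sorted(self.bands.values())
        for (a1, b1), (a2, b2) in zip(edges, edges[1:]):
            if b1 > a2:
                raise ValueError("bands overlap")
        for name, (lo, hi) in self.bands.items():
            if not (lo_f <= lo < hi <= hi_f):
                raise ValueError(f"band {name} outside the full range {self.full}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.bands)


BANDS = BandScheme()


def band_power(segment: np.ndarray, band: tuple[float, float], sfreq: float = 128.0) -> float:
    """Power of one channel segment within ``[low, high)``, device units².

    Hann-windowed single-taper periodogram; the band power is the sum of
    spectral density times bin width over bins inside the band.
    """
    segment = np.asarray(segment, dtype=float)
    if not np.all(np.isfinite(segment)):
        raise ValueError("segment contains non-finite samples")
    freqs, psd = periodogram(segment, fs=sfreq, window="hann", detrend=False)
    lo, hi = band
    sel = (freqs >= lo) & (freqs < hi)
    df = freqs[1] - freqs[0]
    return float(np.sum(psd[sel]) * df)


def _psd_matrix(epochs: np.ndarray, sfreq: float) -> tuple[np.ndarray, np.ndarray]:
    freqs, psd = periodogram(epochs, fs=sfreq, window="hann", detrend=False, axis=-1)
    return freqs, psd


def epoch_band_powers(
    epochs: np.ndarray,
    sfreq: float = 128.0,
    scheme: BandScheme = BANDS,
) -> dict[str, np.ndarray]:
    """Band powers for an (n_epochs, n_channels, n_samples) stack.

    Returns a dict mapping each band name (plus ``"full"``) to an
    (n_epochs, n_channels) power array.
    """
    freqs, psd = _psd_matrix(np.asarray(epochs, dtype=float), sfreq)
    df = freqs[1] - freqs[0]
    out: dict[str, np.ndarray] = {}
    for name, (lo, hi) in list(scheme.bands.items()) + [("full", scheme.full)]:
        sel = (freqs >= lo) & (freqs < hi)
        out[name] = psd[..., sel].sum(axis=-1) * df
    return out


@dataclass(frozen=True)
class BaselineNorm:
    """Log-scaled average full-band baseline power, one value per channel.

    Computed from the retained L0 epochs of one subject on one day and never
    shared across subjects or days.  ``pooled=True`` collapses channels to a
    single scalar (a config alternative for devices with uneven coverage).
    """

    log_norm: np.ndarray  # (n_channels,) log10 of mean full-band baseline power
    subject: str
    day: int
    pooled: bool = False

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.log_norm) <= 0):
            raise ValueError(
                "baseline norm log-power <= 0; device-unit scaling must keep "
                "log arguments well above 1 for the ratio convention"
            )


def compute_baseline_norm(
    epochs: EpochSet,
    *,
    scheme: BandScheme = BANDS,
    pooled: bool = False,
) -> BaselineNorm:
    """Average full-band power over retained L0 epochs, log10-scaled."""
    meta = epochs.metadata
    sel = (meta["condition"] == "L0") & (meta["status"] == "retained")
    if not sel.any():
        raise ValueError(
            "no retained baseline (L0) epochs for "
            f"subject={epochs.subject!r} day={epochs.day}; recompute the "
            "baseline before feature extraction"
        )
    powers = epoch_band_powers(epochs.data[sel.to_numpy()], epochs.sfreq, scheme)
    mean_full = powers["full"].mean(axis=0)  # per channel
    if pooled:
        mean_full = np.full_like(mean_full, mean_full.mean())
    return BaselineNorm(
        log_norm=np.log10(np.maximum(mean_full, _EPS_POWER)),
        subject=epochs.subject,
        day=epochs.day,
        pooled=pooled,
    )


def relative_log_power(
    powers: dict[str, np.ndarray],
    norm: BaselineNorm,
    *,
    convention: str = "ratio",
    scheme: BandScheme = BANDS,
) -> np.ndarray:
    """Relative log band powers, shape (n_epochs, n_bands * n_channels).

    ``ratio``: log10(P) / log10(norm); ``difference``: log10(P) − log10(norm).
    Columns are ordered band-major: all channels of delta, then theta, etc.
    Zero powers are floored at a small epsilon before the log.
    """
    if convention not in ("ratio", "difference"):
        raise ValueError("convention must be 'ratio' or 'difference'")
    cols = []
    for name in scheme.names:
        logp = np.log10(np.maximum(powers[name], _EPS_POWER))
        if convention == "ratio":
            cols.append(logp / norm.log_norm)
        else:
            cols.append(logp - norm.log_norm)
    return np.concatenate(cols, axis=1)


def feature_columns(montage: MontageSpec = DEFAULT_MONTAGE, scheme: BandScheme = BANDS) -> list[str]:
    return [f"{band}_{ch}" for band in scheme.names for ch in montage.channels]


def extract_features(
    epochs: EpochSet,
    *,
    montage: MontageSpec = DEFAULT_MONTAGE,
    scheme: BandScheme = BANDS,
    convention: str = "ratio",
    pooled_baseline: bool = False,
    threshold: float = FEATURE_THRESHOLD,
    norm: BaselineNorm | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Assemble the feature matrix for one subject/day epoch set.

    Returns ``(features, info)`` where ``features`` has one row per retained
    epoch — 4 x 14 = 56 feature columns plus label columns (subject, day,
    condition, is_target, responded) — and ``info`` records the convention,
    the threshold-rejection count and the baseline norm.  Epochs whose
    channels differ from the montage (after channel rejection) keep their 56
    columns, with missing channels' columns set to NaN and listed in
    ``info["masked_channels"]``.
    """
    if tuple(epochs.ch_names) != tuple(montage.channels):
        masked = [ch for ch in montage.channels if ch not in epochs.ch_names]
    else:
        masked = []
    if norm is None:
        norm = compute_baseline_norm(epochs, scheme=scheme, pooled=pooled_baseline)

    meta = epochs.metadata
    retained = (meta["status"] == "retained").to_numpy()
    powers = epoch_band_powers(epochs.data[retained], epochs.sfreq, scheme)
    values = relative_log_power(powers, norm, convention=convention, scheme=scheme)

    # place into the full 56-column frame, NaN for rejected channels
    n = values.shape[0]
    full = np.full((n, len(scheme.names) * montage.n_channels), np.nan)
    col_of = {c: j for j, c in enumerate(feature_columns(montage, scheme))}
    for bi, band in enumerate(scheme.names):
        for ci, ch in enumerate(epochs.ch_names):
            full[:, col_of[f"{band}_{ch}"]] = values[:, bi * len(epochs.ch_names) + ci]

    features = pd.DataFrame(full, columns=feature_columns(montage, scheme))
    lab = meta.loc[retained, ["condition", "is_target", "responded"]].reset_index(drop=True)
    features.insert(0, "subject", epochs.subject)
    features.insert(1, "day", epochs.day)
    features.insert(2, "condition", lab["condition"])
    features.insert(3, "is_target", lab["is_target"])
    features.insert(4, "responded", lab["responded"])

    features, n_thresh = threshold_filter(features, threshold=threshold)
    info = {
        "convention": convention,
        "threshold": threshold,
        "n_threshold_rejected": n_thresh,
        "masked_channels": masked,
        "log_norm": norm.log_norm.tolist(),
        "pooled_baseline": pooled_baseline,
    }
    return features, info


def threshold_filter(
    features: pd.DataFrame,
    threshold: float = FEATURE_THRESHOLD,
) -> tuple[pd.DataFrame, int]:
    """Drop epochs with any relative band value strictly above ``threshold``.

    NaN columns (rejected channels) are ignored.  Returns the filtered frame
    and the number of removed epochs.
    """
    value_cols = [c for c in features.columns if "_" in c and c.split("_")[0] in BANDS.names]
    vals = features[value_cols].to_numpy()
    with np.errstate(invalid="ignore"):
        bad = np.nanmax(vals, axis=1) > threshold
    bad = np.where(np.isnan(vals).all(axis=1), True, bad)
    return features.loc[~bad].reset_index(drop=True), int(bad.sum())
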