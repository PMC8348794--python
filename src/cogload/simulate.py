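"""Synthetic mobile-EEG sessions with known ground truth.

The study's recordings are not publicly distributable, so every downstream
stage is exercised on simulated sessions that reproduce the *structure* of
the real data: 14 channels at 128 Hz in device units, one fixation baseline
block before each task condition, a stimulus annotation every 1600 ms,
impedance side-channels, button-press logs, and the artifact modes the
cleaning steps are built to catch.

The signal model is additive and spectral: each channel is 1/f (pink)
background noise plus four band-limited Gaussian components whose expected
power is a channel baseline power scaled by ``10**offset`` for the channel's
lobe, the band, and the running condition.  The analysis consumes only epoch
band powers, so matching the power spectrum is sufficient — no oscillatory
bursts or dipole forward modelling.  Only the *signs* of the default
condition effects follow the experimentally observed directionality
(frontal/parietal/occipital theta and delta increase with load, occipital
alpha decreases, parietal beta increases); their magnitudes (0.05–0.3 log10
units, graded L1 < L2 < L3) are simulation configuration.

Artifacts are planted with retrievable ground truth: whole corrupted
channels (sparse high-kurtosis spike trains), per-epoch amplitude bursts
well above the 1500-unit rejection level, and impedance dropouts below the
100-unit level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import BANDS, BandScheme
from .montage import DEFAULT_MONTAGE, MontageSpec
from .recording import Annotation, RawRecording
from .seeds import child_seed
from .task import (
    DEFAULT_PERFORMANCE,
    ResponseLog,
    SessionPlan,
    StimulusSequence,
    make_session_plan,
    simulate_responses,
)

__all__ = [
    "LoadEffectProfile",
    "ArtifactSpec",
    "PlantedArtifact",
    "SimulatedSession",
    "simulate_signal",
    "simulate_session",
    "simulate_dataset",
    "performance_from_fraction_correct",
    "BASELINE_BAND_POWER",
    "PINK_VARIANCE",
]

CONDITIONS = ("L0", "L1", "L2", "L3")

#: Baseline power of each band-limited component, device units squared.  The
#: resulting clean-signal standard deviation (~52 units) sits far below the
#: 1500-unit amplitude rejection level, and in-band pink background is under
#: ~5% of component power, so configured log-power offsets survive into
#: measured band powers nearly unattenuated.
BASELINE_BAND_POWER = {"delta": 900.0, "theta": 600.0, "alpha": 700.0, "beta": 400.0}
PINK_VARIANCE = 100.0

_DEFAULT_OFFSETS: dict[tuple[str, str], tuple[float, float, float]] = {
    # (lobe, band) -> offsets for (L1, L2, L3) in log10 power units
    ("frontal", "theta"): (0.10, 0.20, 0.30),
    ("parietal", "theta"): (0.05, 0.12, 0.18),
    ("occipital", "theta"): (0.05, 0.12, 0.18),
    ("occipital", "alpha"): (-0.07, -0.15, -0.22),
    ("frontal", "delta"): (0.08, 0.16, 0.24),
    ("occipital", "delta"): (0.05, 0.10, 0.18),
    ("parietal", "delta"): (0.05, 0.10, 0.15),
    ("parietal", "beta"): (0.04, 0.08, 0.12),
}


@dataclass(frozen=True)
class LoadEffectProfile:
    """Per (lobe, band, condition) log10 band-power offsets relative to baseline."""

    offsets: dict[tuple[str, str], tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_OFFSETS)
    )

    def __post_init__(self) -> None:
        for key, vals in self.offsets.items():
            if len(vals) != 3 or not all(np.isfinite(vals)):
                raise ValueError(f"offsets for {key} must be three finite values (L1..L3)")

    def offset(self, lobe: str, band: str, condition: str) -> float:
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        if condition == "L0":
            return 0.0
        vals = self.offsets.get((lobe, band))
        return 0.0 if vals is None else vals[int(condition[1]) - 1]

    @classmethod
    def null(cls) -> "LoadEffectProfile":
        return cls(offsets={})

    def scaled(self, factor: float) -> "LoadEffectProfile":
        return LoadEffectProfile(
            offsets={
                k: tuple(factor * v for v in vals) for k, vals in self.offsets.items()
            }
        )

    def jittered(self, sd: float, seed: int) -> "LoadEffectProfile":
        """Add subject-level N(0, sd) noise to every configured offset."""
        rng = np.random.default_rng(child_seed(seed, "profile-jitter"))
        return LoadEffectProfile(
            offsets={
                k: tuple(v + rng.normal(0.0, sd) for v in vals)
                for k, vals in self.offsets.items()
            }
        )


@dataclass(frozen=True)
class PlantedArtifact:
    """Ground-truth record of one planted artifact."""

    kind: str  # "channel" | "amplitude" | "impedance"
    condition: str
    epoch_index: int  # -1 for whole-channel artifacts
    channel: str


@dataclass(frozen=True)
class ArtifactSpec:
    """What to plant: corrupted channels, amplitude bursts, impedance dropouts.

    ``amplitude_epochs`` / ``impedance_epochs`` list (condition, epoch_index,
    channel) triples; epoch indices refer to the stimulus order within the
    condition block.  Overlapping plants on the same samples simply add (they
    are merged, never silently dropped).

    Amplitude plants are an in-band (10 Hz) sinusoid spanning the whole epoch
    window, so they exceed the 1500-unit amplitude level without becoming
    kurtosis outliers — rejection attributes them to the amplitude criterion.
    Corrupted-channel plants are the opposite: sparse spikes large in
    kurtosis but below the amplitude level.
    """

    corrupted_channels: tuple[str, ...] = ()
    amplitude_epochs: tuple[tuple[str, int, str], ...] = ()
    impedance_epochs: tuple[tuple[str, int, str], ...] = ()
    spike_amplitude: float = 3000.0  # device units, far above the 1500 level
    spike_freq_hz: float = 10.0
    channel_spike_amplitude: float = 800.0  # big kurtosis, below the 1500 level
    channel_spike_rate_hz: float = 1.0
    impedance_drop_value: float = 40.0  # below the 100-unit rejection level

    def planted(self) -> list[PlantedArtifact]:
        out = [PlantedArtifact("channel", "*", -1, ch) for ch in self.corrupted_channels]
        out += [PlantedArtifact("amplitude", c, i, ch) for c, i, ch in self.amplitude_epochs]
        out += [PlantedArtifact("impedance", c, i, ch) for c, i, ch in self.impedance_epochs]
        return out


def _component_psd(
    freqs: np.ndarray,
    lobe: str,
    profile: LoadEffectProfile,
    condition: str,
    scheme: BandScheme,
) -> np.ndarray:
    psd = np.zeros_like(freqs)
    # pink background, power spectral density ~ 1/f (flattened below 0.5 Hz)
    pink = 1.0 / np.maximum(freqs, 0.5)
    pink[0] = 0.0
    df = freqs[1] - freqs[0]
    pink *= PINK_VARIANCE / (pink.sum() * df)
    psd += pink
    for band, (lo, hi) in scheme.bands.items():
        power = BASELINE_BAND_POWER[band] * 10.0 ** profile.offset(lobe, band, condition)
        sel = (freqs >= lo) & (freqs < hi)
        psd[sel] += power / (hi - lo)
    return psd


def simulate_signal(
    montage: MontageSpec,
    profile: LoadEffectProfile,
    condition: str,
    duration_s: float,
    seed: int,
    *,
    scheme: BandScheme = BANDS,
    channel_gain_log10: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate one condition block, shape (n_channels, n_samples).

    Each channel is a Gaussian process whose one-sided PSD is the pink
    background plus flat-in-band components with expected band power
    ``BASELINE_BAND_POWER[band] * 10**offset(lobe, band, condition)``,
    synthesized in the frequency domain (random phases and Rayleigh
    amplitudes per bin) — so the expected periodogram equals the target PSD.
    ``channel_gain_log10`` optionally scales each channel's total power by
    ``10**gain`` (subject-level electrode variability).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    fs = montage.sfreq
    n = int(round(duration_s * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    out = np.empty((montage.n_channels, n))
    gains = (
        np.zeros(montage.n_channels) if channel_gain_log10 is None else channel_gain_log10
    )
    for ci, ch in enumerate(montage.channels):
        psd = _component_psd(freqs, montage.lobe_of(ch), profile, condition, scheme)
        psd = psd * 10.0 ** gains[ci]
        rng = np.random.default_rng(child_seed(seed, "sig", condition, ch))
        sigma = np.sqrt(n * fs * psd / 2.0)
        z = sigma * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
        z /= np.sqrt(2.0)
        z[0] = 0.0
        if n % 2 == 0:
            z[-1] = z[-1].real * np.sqrt(2.0)
        out[ci] = np.fft.irfft(z, n)
    return out


def performance_from_fraction_correct(
    fraction_correct: float,
    rt_mean_ms: float,
    rt_sd_ms: float,
    n_stimuli: int = 150,
    n_targets: int = 50,
    miss_share: float = 2.0 / 3.0,
) -> dict:
    """Convert a target fraction-correct into (hit, false-alarm) probabilities.

    Errors are split ``miss_share`` to misses and the rest to false alarms, so
    the expected scored fraction correct equals ``fraction_correct``.
    """
    n_err = (1.0 - fraction_correct) * n_stimuli
    hit_p = 1.0 - miss_share * n_err / n_targets
    fa_p = (1.0 - miss_share) * n_err / (n_stimuli - n_targets)
    return {
        "hit_p": float(np.clip(hit_p, 0.0, 1.0)),
        "fa_p": float(np.clip(fa_p, 0.0, 1.0)),
        "rt_mean_ms": rt_mean_ms,
        "rt_sd_ms": rt_sd_ms,
    }


def default_performance(n_stimuli: int = 150, n_targets: int = 50) -> dict[str, dict]:
    """Per-condition response model matching the group-mean behavioral data."""
    return {
        cond: performance_from_fraction_correct(
            p["fraction_correct"], p["rt_mean_ms"], p["rt_sd_ms"], n_stimuli, n_targets
        )
        for cond, p in DEFAULT_PERFORMANCE.items()
    }


@dataclass
class SimulatedSession:
    """A simulated recording plus everything needed to verify it.

    Holds the EDF-serializable recording, the per-condition stimulus
    sequences and response logs, and ground truth (effect profile, artifact
    placements, seeds) for test oracles.
    """

    recording: RawRecording
    plan: SessionPlan
    responses: dict[str, ResponseLog]
    profile: LoadEffectProfile
    artifacts: ArtifactSpec
    seed: int
    subject: str = "S00"
    day: int = 1

    def planted(self) -> list[PlantedArtifact]:
        return self.artifacts.planted()


def _epoch_window(block_start_s: float, epoch_index: int, soa_s: float, fs: float, n_samp: int):
    onset = block_start_s + epoch_index * soa_s
    start = int(round(onset * fs))
    return start, start + n_samp


def simulate_session(
    montage: MontageSpec = DEFAULT_MONTAGE,
    profile: LoadEffectProfile | None = None,
    artifacts: ArtifactSpec = ArtifactSpec(),
    plan: SessionPlan | None = None,
    performance: dict[str, dict] | None = None,
    seed: int = 0,
    *,
    subject: str = "S00",
    day: int = 1,
    scheme: BandScheme = BANDS,
    channel_gain_log10: np.ndarray | None = None,
    impedance_base: float = 400.0,
) -> SimulatedSession:
    """Simulate one full session: baselines, task blocks, responses, artifacts.

    The layout follows the session plan: for each condition in randomized
    order, a fixation baseline block (condition L0 for analysis) followed by
    the 150-stimulus block at 1600 ms SOA.  Annotations mark each baseline
    block (with duration) and every stimulus onset with condition, digit,
    target flag and responded flag.
    """
    profile = LoadEffectProfile() if profile is None else profile
    if plan is None:
        plan = make_session_plan(child_seed(seed, "plan", subject, day), version="A" if day == 1 else "B")
    if performance is None:
        performance = default_performance()

    fs = montage.sfreq
    epoch_samples = int(round(1.5 * fs))
    pieces: list[np.ndarray] = []
    annotations: list[Annotation] = []
    responses: dict[str, ResponseLog] = {}
    block_starts: dict[str, float] = {}
    t = 0.0
    for kind, cond, payload in plan.blocks():
        if kind == "baseline":
            dur = float(payload)
            sig = simulate_signal(
                montage, profile, "L0", dur, child_seed(seed, "block", cond, "baseline"),
                scheme=scheme, channel_gain_log10=channel_gain_log10,
            )
            annotations.append(Annotation(t, dur, f"baseline {cond}"))
        else:
            seq: StimulusSequence = payload
            dur = seq.duration_s
            sig = simulate_signal(
                montage, profile, cond, dur, child_seed(seed, "block", cond, "task"),
                scheme=scheme, channel_gain_log10=channel_gain_log10,
            )
            perf = performance[cond]
            resp = simulate_responses(
                seq, perf["hit_p"], perf["fa_p"], perf["rt_mean_ms"], perf["rt_sd_ms"],
                child_seed(seed, "resp", cond),
            )
            responses[cond] = resp
            block_starts[cond] = t
            soa_s = seq.soa_ms / 1000.0
            for i, (digit, targ) in enumerate(zip(seq.digits, seq.mask)):
                annotations.append(
                    Annotation(
                        t + i * soa_s,
                        0.0,
                        f"stim {cond}/d{digit}/t{int(targ)}/r{int(resp.pressed[i])}",
                    )
                )
        pieces.append(sig)
        t += dur

    data = np.concatenate(pieces, axis=1)
    n_total = data.shape[1]

    # impedance: slowly varying around the base level, well above the limit
    imp_rng = np.random.default_rng(child_seed(seed, "impedance"))
    walk = imp_rng.standard_normal((montage.n_channels, max(2, n_total // 1280)))
    t_coarse = np.linspace(0, 1, walk.shape[1])
    t_fine = np.linspace(0, 1, n_total)
    impedance = np.vstack(
        [np.interp(t_fine, t_coarse, impedance_base + 30.0 * np.cumsum(w) / np.sqrt(len(w)))
         for w in walk]
    )
    impedance = np.clip(impedance, 2 * IMPEDANCE_FLOOR, None)

    ch_index = {ch: i for i, ch in enumerate(montage.channels)}
    soa_s = 1.6

    # whole corrupted channels: sparse spike train over the entire session
    spike_rng = np.random.default_rng(child_seed(seed, "chan-artifact"))
    for ch in artifacts.corrupted_channels:
        n_spikes = max(1, int(artifacts.channel_spike_rate_hz * n_total / fs))
        locs = spike_rng.choice(n_total, size=n_spikes, replace=False)
        signs = spike_rng.choice([-1.0, 1.0], size=n_spikes)
        data[ch_index[ch], locs] += signs * artifacts.channel_spike_amplitude

    # amplitude excursions spanning specific task epochs
    for cond, ei, ch in artifacts.amplitude_epochs:
        start, stop = _epoch_window(block_starts[cond], ei, soa_s, fs, epoch_samples)
        tt = np.arange(stop - start) / fs
        data[ch_index[ch], start:stop] += artifacts.spike_amplitude * np.sin(
            2 * np.pi * artifacts.spike_freq_hz * tt
        )

    # impedance dropouts during specific task epochs
    for cond, ei, ch in artifacts.impedance_epochs:
        start, stop = _epoch_window(block_starts[cond], ei, soa_s, fs, epoch_samples)
        impedance[ch_index[ch], start:stop] = artifacts.impedance_drop_value

    recording = RawRecording(
        data=data,
        sfreq=fs,
        ch_names=montage.channels,
        annotations=annotations,
        impedance=impedance,
    )
    return SimulatedSession(
        recording=recording,
        plan=plan,
        responses=responses,
        profile=profile,
        artifacts=artifacts,
        seed=seed,
        subject=subject,
        day=day,
    )


IMPEDANCE_FLOOR = 100.0  # the epoch-rejection impedance limit, device units


def simulate_dataset(
    n_subjects: int,
    n_days: int = 2,
    *,
    montage: MontageSpec = DEFAULT_MONTAGE,
    profile: LoadEffectProfile | None = None,
    artifacts: ArtifactSpec = ArtifactSpec(),
    seed: int = 0,
    subject_offset_sd: float = 0.03,
    subject_gain_sd_log10: float = 0.05,
    baseline_s: float = 60.0,
    n_stimuli: int = 150,
    n_targets: int = 50,
):
    """Yield simulated sessions for a cohort, with subject-level variability.

    Each subject gets (a) a jittered copy of the effect profile (band-power
    effects differ across people) and (b) per-channel log-gains (electrode
    placement and impedance differ across people); both persist across the
    subject's days.  Half the cohort runs task version A on day 1 and B on
    day 2, the other half the reverse.
    """
    profile = LoadEffectProfile() if profile is None else profile
    for s in range(n_subjects):
        subject = f"S{s + 1:02d}"
        subj_seed = child_seed(seed, "subject", subject)
        subj_profile = (
            profile.jittered(subject_offset_sd, subj_seed) if subject_offset_sd else profile
        )
        gain_rng = np.random.default_rng(child_seed(subj_seed, "gain"))
        gains = gain_rng.normal(0.0, subject_gain_sd_log10, montage.n_channels)
        for day in range(1, n_days + 1):
            version = ("A", "B")[(s + day - 1) % 2]
            plan = make_session_plan(
                child_seed(subj_seed, "plan", day),
                version=version,
                baseline_s=baseline_s,
                n_stimuli=n_stimuli,
                n_targets=n_targets,
            )
            yield simulate_session(
                montage,
                subj_profile,
                artifacts,
                plan,
                seed=child_seed(subj_seed, "day", day),
                subject=subject,
                day=day,
                channel_gain_log10=gains,
            )
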