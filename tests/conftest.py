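"""Shared fixtures and synthetic-feature helpers for the test suite.

``condition_features`` is the fast path used by classifier and statistics
tests: it simulates per-condition signal blocks, tiles them into 192-sample
epochs, and assembles the labelled 56-column feature frame exactly as the
full pipeline would (baseline norm from a separate simulated L0 block),
skipping filtering and artifact rejection, which have their own tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cogload.features import (
    BaselineNorm,
    epoch_band_powers,
    feature_columns,
    relative_log_power,
)
from cogload.montage import DEFAULT_MONTAGE
from cogload.seeds import child_seed
from cogload.simulate import LoadEffectProfile, simulate_signal

EPOCH_SAMPLES = 192


def tile_epochs(signal: np.ndarray, n_epochs: int) -> np.ndarray:
    """(n_ch, n_samples) -> (n_epochs, n_ch, 192) non-overlapping tiles."""
    n_ch = signal.shape[0]
    return (
        signal[:, : n_epochs * EPOCH_SAMPLES]
        .reshape(n_ch, n_epochs, EPOCH_SAMPLES)
        .transpose(1, 0, 2)
    )


def condition_features(
    profile: LoadEffectProfile,
    conditions: list[str],
    n_epochs: int,
    seed: int,
    *,
    subject: str = "S01",
    day: int = 1,
    n_baseline: int = 40,
    convention: str = "ratio",
    channel_gain_log10: np.ndarray | None = None,
) -> pd.DataFrame:
    """Labelled feature frame for the given conditions of one subject/day."""
    montage = DEFAULT_MONTAGE
    base_sig = simulate_signal(
        montage, profile, "L0", n_baseline * 1.5, child_seed(seed, "norm", subject, day),
        channel_gain_log10=channel_gain_log10,
    )
    base_powers = epoch_band_powers(tile_epochs(base_sig, n_baseline))
    norm = BaselineNorm(
        log_norm=np.log10(base_powers["full"].mean(axis=0)), subject=subject, day=day
    )
    frames = []
    for cond in conditions:
        sig = simulate_signal(
            montage, profile, cond, n_epochs * 1.5, child_seed(seed, "cond", cond, subject, day),
            channel_gain_log10=channel_gain_log10,
        )
        powers = epoch_band_powers(tile_epochs(sig, n_epochs))
        vals = relative_log_power(powers, norm, convention=convention)
        df = pd.DataFrame(vals, columns=feature_columns())
        df.insert(0, "subject", subject)
        df.insert(1, "day", day)
        df.insert(2, "condition", cond)
        df.insert(3, "is_target", False)
        df.insert(4, "responded", False)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def cohort_features(
    n_subjects: int,
    conditions: list[str],
    n_epochs: int,
    seed: int,
    *,
    n_days: int = 2,
    profile: LoadEffectProfile | None = None,
    subject_sd: float = 0.05,
    day_sd: float = 0.0,
    day_gain_sd: float = 0.03,
    convention: str = "ratio",
) -> pd.DataFrame:
    """Multi-subject feature frames with planted subject- and day-level variability.

    ``subject_sd`` jitters the effect profile per subject (people differ in
    their band-power responses); ``day_sd`` jitters it again per session
    (electrode placement shifts band-specific sensitivity between days);
    ``day_gain_sd`` adds per-channel broadband gain noise per session.
    """
    profile = LoadEffectProfile() if profile is None else profile
    frames = []
    for s in range(n_subjects):
        subject = f"S{s + 1:02d}"
        subj_seed = child_seed(seed, "subject", subject)
        subj_profile = profile.jittered(subject_sd, subj_seed) if subject_sd else profile
        for day in range(1, n_days + 1):
            day_profile = (
                subj_profile.jittered(day_sd, child_seed(subj_seed, "dayprof", day))
                if day_sd
                else subj_profile
            )
            rng = np.random.default_rng(child_seed(subj_seed, "daygain", day))
            gains = rng.normal(0.0, day_gain_sd, DEFAULT_MONTAGE.n_channels)
            frames.append(
                condition_features(
                    day_profile, conditions, n_epochs, child_seed(subj_seed, "day", day),
                    subject=subject, day=day, convention=convention,
                    channel_gain_log10=gains,
                )
            )
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def default_profile() -> LoadEffectProfile:
    return LoadEffectProfile()


@pytest.fixture(scope="session")
def null_profile() -> LoadEffectProfile:
    return LoadEffectProfile.null()
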