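"""Extract band-power features and recover the simulated load effects.

Simulates baseline (L0) and high-load (L3) epochs with known log10
band-power offsets, runs the feature pipeline under the difference
convention, and compares the measured lobe-average differences with the
configured ground truth.
"""

import numpy as np

from cogload.features import (
    BaselineNorm,
    epoch_band_powers,
    feature_columns,
    relative_log_power,
)
from cogload.montage import DEFAULT_MONTAGE as MONTAGE
from cogload.simulate import LoadEffectProfile, simulate_signal

profile = LoadEffectProfile(
    offsets={
        ("frontal", "theta"): (0.1, 0.2, 0.3),
        ("occipital", "alpha"): (-0.07, -0.15, -0.22),
    }
)
n_epochs = 200


def band_values(condition, seed):
    sig = simulate_signal(MONTAGE, profile, condition, n_epochs * 1.5, seed)
    epochs = sig[:, : n_epochs * 192].reshape(14, n_epochs, 192).transpose(1, 0, 2)
    powers = epoch_band_powers(epochs)
    norm = BaselineNorm(np.log10(np.full(14, 2700.0)), subject="S01", day=1)
    return relative_log_power(powers, norm, convention="difference")


cols = feature_columns()
v0 = band_values("L0", seed=1).mean(axis=0)
v3 = band_values("L3", seed=2).mean(axis=0)
print(f"{'lobe':10s}{'band':7s}{'true':>7s}{'measured':>10s}")
for (lobe, band), offs in profile.offsets.items():
    idx = [cols.index(f"{band}_{ch}") for ch in MONTAGE.lobes[lobe]]
    est = (v3 - v0)[idx].mean()
    print(f"{lobe:10s}{band:7s}{offs[2]:+7.2f}{est:+10.3f}")
print("\nmeasured values are mean log10 band-power differences (L3 - L0) per "
      "lobe; they track the configured offsets to within spectral-leakage "
      "and Monte-Carlo error.")
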