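"""Filtering, channel rejection, epoching, and epoch rejection."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import periodogram

from cogload.preprocess import (
    AMPLITUDE_LIMIT,
    EPOCH_SAMPLES,
    FilterSpec,
    bandpass,
    extract_epochs,
    reject_channels,
    reject_epochs,
    rejection_stats,
)
from cogload.recording import Annotation, RawRecording
from cogload.simulate import ArtifactSpec, simulate_session

FS = 128.0
CH3 = ("a", "b", "c")


def _rec(data, annotations=None, impedance=None, names=None):
    names = names or tuple(f"c{i}" for i in range(data.shape[0]))
    return RawRecording(data, FS, names, annotations or [], impedance)


class TestBandpass:
    def _tone(self, freq, n=int(60 * FS), amp=1.0):
        t = np.arange(n) / FS
        return amp * np.sin(2 * np.pi * freq * t)

    def test_passband_tone_preserved_within_1db(self):
        x = self._tone(10.0)
        y = bandpass(_rec(x[np.newaxis, :])).data[0]
        core = slice(int(10 * FS), int(50 * FS))  # avoid edge transients
        ratio = y[core].std() / x[core].std()
        assert 10 ** (-1 / 20) < ratio < 10 ** (1 / 20)

    def test_dc_removed(self):
        x = np.full(int(60 * FS), 7.0)
        y = bandpass(_rec(x[np.newaxis, :])).data[0]
        core = slice(int(10 * FS), int(50 * FS))
        assert np.abs(y[core]).max() < 0.07  # < 1% of the input level

    def test_drift_attenuated_30db_tone_kept(self):
        """0.1 Hz drift + 10 Hz tone: output power concentrates at 10 Hz."""
        n = int(120 * FS)
        t = np.arange(n) / FS
        x = 5.0 * np.sin(2 * np.pi * 0.1 * t) + 1.0 * np.sin(2 * np.pi * 10.0 * t)
        y = bandpass(_rec(x[np.newaxis, :])).data[0]
        core = slice(int(20 * FS), int(100 * FS))
        f, pxx = periodogram(y[core], fs=FS)
        f_in, pxx_in = periodogram(x[core], fs=FS)
        drift_band = (f > 0.02) & (f < 0.3)
        atten = pxx[drift_band].sum() / pxx_in[drift_band].sum()
        assert 10 * np.log10(atten) < -30
        tone_band = (f > 9) & (f < 11)
        assert pxx[tone_band].sum() / pxx.sum() > 0.95

    def test_stopband_50hz(self):
        x = self._tone(50.0)
        y = bandpass(_rec(x[np.newaxis, :])).data[0]
        core = slice(int(10 * FS), int(50 * FS))
        assert 20 * np.log10(y[core].std() / x[core].std()) < -30

    def test_idempotent_in_passband(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(int(60 * FS))
        once = bandpass(_rec(x[np.newaxis, :]))
        twice = bandpass(once)
        core = slice(int(15 * FS), int(45 * FS))
        resid = twice.data[0][core] - once.data[0][core]
        assert resid.std() < 0.05 * once.data[0][core].std()

    def test_too_short_signal_names_minimum(self):
        with pytest.raises(ValueError, match="845"):
            bandpass(_rec(np.zeros((1, 100))))

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            FilterSpec(hp_edge=40.0, lp_edge=1.0)
        with pytest.raises(ValueError):
            FilterSpec(numtaps=100)  # even taps
        with pytest.raises(ValueError, match="Nyquist"):
            FilterSpec(lp_edge=70.0).taps(FS)


class TestRejectChannels:
    def test_iid_gaussian_none_removed(self):
        rng = np.random.default_rng(1)
        rec = _rec(rng.standard_normal((14, int(120 * FS))))
        kept, log = reject_channels(rec)
        assert kept.n_channels == 14
        assert not log["removed"].any()

    def test_planted_spike_channel_removed(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((14, int(120 * FS)))
        spikes = rng.choice(data.shape[1], 150, replace=False)
        data[5, spikes] += 25.0
        kept, log = reject_channels(_rec(data))
        assert list(log.loc[log["removed"], "channel"]) == ["c5"]
        assert kept.n_channels == 13

    def test_identical_channels_none_removed(self):
        x = np.sin(2 * np.pi * 8 * np.arange(int(30 * FS)) / FS)
        rec = _rec(np.tile(x, (5, 1)))
        kept, log = reject_channels(rec)
        assert kept.n_channels == 5
        assert (log["z"] == 0).all()

    def test_flat_channel_removed_with_reason(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((5, int(30 * FS)))
        data[2] = 4.2
        kept, log = reject_channels(_rec(data))
        assert log.loc[log["channel"] == "c2", "reason"].item() == "flat"
        assert "c2" not in kept.ch_names

    def test_needs_three_channels(self):
        with pytest.raises(ValueError, match="3 channels"):
            reject_channels(_rec(np.zeros((2, 1000))))


class TestExtractEpochs:
    def _annotated(self, n_stim=10, extra_s=2.0):
        dur = 60.0 + n_stim * 1.6 + extra_s
        n = int(round(dur * FS))
        rng = np.random.default_rng(7)
        anns = [Annotation(0.0, 60.0, "baseline L1")]
        anns += [
            Annotation(60.0 + i * 1.6, 0.0, f"stim L1/d{(i % 8) + 1}/t{i % 2}/r{i % 2}")
            for i in range(n_stim)
        ]
        return _rec(rng.standard_normal((3, n)), anns, names=CH3)

    def test_counts_and_labels(self):
        es = extract_epochs(self._annotated(), subject="S09", day=2)
        meta = es.metadata
        assert (meta["condition"] == "L0").sum() == 40  # floor(60 / 1.5)
        assert (meta["condition"] == "L1").sum() == 10
        assert es.data.shape[1:] == (3, EPOCH_SAMPLES)
        assert es.subject == "S09" and es.day == 2
        targ = meta.loc[meta["condition"] == "L1", "is_target"]
        assert list(targ) == [bool(i % 2) for i in range(10)]

    def test_simulated_condition_gives_150_epochs(self):
        sess = simulate_session(seed=2)
        es = extract_epochs(sess.recording)
        counts = es.metadata["condition"].value_counts()
        assert all(counts[c] == 150 for c in ("L1", "L2", "L3"))
        assert counts["L0"] == 3 * 40

    def test_truncated_epoch_flagged(self):
        """A stimulus 100 ms before the end cannot fill its window."""
        rec = self._annotated(n_stim=10, extra_s=0.0)
        short = RawRecording(
            rec.data[:, : int(round((60.0 + 9 * 1.6 + 0.1) * FS))],
            FS, rec.ch_names, rec.annotations,
        )
        es = extract_epochs(short)
        statuses = es.metadata.loc[es.metadata["condition"] == "L1", "status"]
        assert list(statuses) == ["retained"] * 9 + ["rejected:truncated"]

    def test_no_annotations_raises(self):
        with pytest.raises(ValueError, match="annotations"):
            extract_epochs(_rec(np.zeros((3, 1000)), [], names=CH3))


class TestRejectEpochs:
    def _clean_epochs(self, n=60, seed=0, scale=40.0):
        rng = np.random.default_rng(seed)
        dur = 60.0 + n * 1.6 + 2.0
        anns = [Annotation(60.0 + i * 1.6, 0.0, "stim L1/d2/t0/r0") for i in range(n)]
        data = scale * rng.standard_normal((3, int(round(dur * FS))))
        imp = np.full_like(data, 400.0)
        return _rec(data, anns, impedance=imp, names=CH3)

    def test_amplitude_epoch_rejected_with_reason(self):
        rec = self._clean_epochs()
        # whole-epoch amplitude excursion: crosses 1500 without a kurtosis spike
        s0 = int(round(60.0 * FS))
        rec.data[1, s0 : s0 + EPOCH_SAMPLES] += 1600.0 * np.sin(
            2 * np.pi * 10 * np.arange(EPOCH_SAMPLES) / FS
        )
        es = reject_epochs(extract_epochs(rec))
        assert es.metadata.loc[0, "status"] == "rejected:amplitude"
        assert (es.metadata.loc[1:, "status"] == "retained").mean() > 0.9

    def test_impedance_epoch_rejected_with_reason(self):
        rec = self._clean_epochs()
        s0 = int(round((60.0 + 3 * 1.6) * FS))
        rec.impedance[2, s0 : s0 + EPOCH_SAMPLES] = 50.0
        es = reject_epochs(extract_epochs(rec))
        assert es.metadata.loc[3, "status"] == "rejected:impedance"

    def test_kurtosis_outlier_rejected_first(self):
        rec = self._clean_epochs()
        s0 = int(round((60.0 + 5 * 1.6) * FS))
        rec.data[0, s0 + 90 : s0 + 94] += 2000.0  # sparse spike: kurtosis AND amplitude
        es = reject_epochs(extract_epochs(rec))
        assert es.metadata.loc[5, "status"] == "rejected:kurtosis"

    def test_clean_epochs_mostly_retained(self):
        es = reject_epochs(extract_epochs(self._clean_epochs(seed=5)))
        assert (es.metadata["status"] == "retained").mean() > 0.9

    def test_threshold_is_strict_inequality_at_limit(self):
        rec = self._clean_epochs(scale=1.0)
        s0 = int(round(60.0 * FS))
        rec.data[:, s0 : s0 + EPOCH_SAMPLES] = 0.0
        rec.data[1, s0 : s0 + EPOCH_SAMPLES] = AMPLITUDE_LIMIT  # exactly at the limit
        es = reject_epochs(extract_epochs(rec))
        assert es.metadata.loc[0, "status"] == "retained"


class TestRejectionAccounting:
    def test_counts_partition_raw_epochs(self):
        art = ArtifactSpec(
            amplitude_epochs=(("L1", 0, "F3"), ("L1", 10, "O1")),
            impedance_epochs=(("L2", 5, "P8"),),
        )
        sess = simulate_session(artifacts=art, seed=23)
        es = reject_epochs(extract_epochs(bandpass(sess.recording)))
        stats = rejection_stats([es], {("S00", 1, "L1"): 2}).table
        reason_cols = ["n_truncated", "n_kurtosis", "n_amplitude", "n_impedance", "n_threshold"]
        assert (stats[reason_cols].sum(axis=1) + stats["n_retained"] == stats["n_raw"]).all()
        assert stats["n_raw"].sum() == es.n_epochs

    def test_retained_subset(self):
        sess = simulate_session(seed=29)
        es = reject_epochs(extract_epochs(bandpass(sess.recording)))
        kept = es.retained()
        assert (kept.metadata["status"] == "retained").all()
        assert kept.n_epochs == (es.metadata["status"] == "retained").sum()
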