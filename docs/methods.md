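# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `cogload`, in the order the pipeline runs.

## Task generation

Sequences are drawn by constrained sequential sampling. At each position the
sampler enumerates the digits (1–8) that respect the no-adjacent-repeat
constraint, classifies each as target-creating or not under the active rule,
and discards candidates that would make the remaining target budget
unattainable. Attainability is checked with an exact per-rule upper bound on
the targets still reachable (e.g. for the three-even rule, a tail of *e*
trailing even digits allows at most `r − max(0, 2 − e)` targets in `r`
remaining positions). Because the bound is exact and a zero-target
continuation always exists, dead ends are rare; a bounded number of restarts
(50) with derived sub-seeds covers them, after which a `GenerationError`
names the infeasible constraint. Target-creating digits are chosen with
probability `remaining_targets / remaining_positions`, which keeps targets
close to uniformly spread.

The three-even rule uses the overlapping-run convention: position *i* is a
target iff the three digits ending at *i* are all even, so a run of four
even digits contains two targets. This is the only reading under which a
fixed per-sequence target count is well defined.

Task versions A and B are fixed sub-seed offsets of the master seed: the
condition order is derived from the seed alone (both versions of a session
share it), the digits from seed + version.

Responses are modelled per stimulus: press with probability `hit_p` on
targets and `fa_p` on non-targets, latency truncated-normal in (0, SOA]. A
press counts for the stimulus on screen when it occurs. Default
per-condition parameters are chosen to reproduce the group-mean behavioral
pattern (fraction correct 0.998 / 0.98 / 0.93, mean RT 596.9 / 656.9 /
675.4 ms across the three difficulty levels), with errors split 2:1 between
misses and false alarms — the split is a simulation choice; only the
marginal fraction correct is constrained.

The SUS composite applies the standard odd/even item recoding (odd items
score `rating − 1`, even items `5 − rating`) before the ×2.5 scaling; the
0–100 range only holds with the recoding.

## Signal model

Each channel is a Gaussian process synthesized in the frequency domain from
a target one-sided PSD: a pink (1/f) background of total variance 100
device-units², flattened below 0.5 Hz, plus four flat band-limited
components with baseline powers delta 900, theta 600, alpha 700, beta 400
device-units². Under condition *k* the component power in band *b* of a
channel in lobe *ℓ* is multiplied by `10^offset(ℓ, b, k)`. The defaults
follow the experimentally observed directionality — frontal/parietal/
occipital theta and delta increase with load, occipital alpha decreases,
parietal beta increases — with invented graded magnitudes 0.04–0.3 log₁₀
units (L1 < L2 < L3); L0 offsets are identically zero. The synthesis
scaling makes the expected periodogram equal the target PSD, so configured
offsets appear directly in measured band powers.

The clean-signal standard deviation (≈52 device units) sits far below the
1500-unit amplitude rejection level, and baseline full-band powers (~2700)
keep `log₁₀` arguments well above 1 so the ratio normalization is
well-behaved. In-band pink power is under ~5% of component power, which
bounds the background's dilution of configured offsets.

This is a spectral model only: the analysis consumes epoch band powers, so
matching second-order statistics suffices. It does **not** emulate
oscillatory bursts, evoked (phase-locked) responses, 1/f slope changes,
eye-blink/EMG waveform morphology, or electrode drift; passing tests
therefore demonstrate correct *pipeline mechanics and calibration*, not
robustness to those real-data phenomena.

Artifacts are planted with retrievable ground truth: corrupted channels get
a sparse ±800-unit spike train (high kurtosis, below the amplitude level) at
1 spike/s; amplitude plants are 10 Hz sinusoids of amplitude 3000 spanning
one epoch window (above the level, but *platykurtic*, so they are caught by
the amplitude criterion rather than the kurtosis one); impedance dropouts
hold one channel's impedance at 40 units (below the 100 limit) for one
epoch. Impedance otherwise follows a smoothed random walk around 400 units,
clipped above 200.

Subject-level variability in cohort simulations: each subject's effect
profile is jittered with N(0, 0.03) noise and each subject gets per-channel
log-gains N(0, 0.05) persisting across days.

## EDF serialization

Recordings are written as EDF+C with 1-second data records: 14 EEG signals,
14 impedance signals (`IMP <channel>`), and one annotation signal carrying
timestamped event lists. Physical ranges are snapped to 8-character
header-representable values *before* 16-bit digitization so the round-trip
error stays within one true quantization step. Baseline blocks are
annotated with their duration; stimulus annotations encode condition,
digit, target flag and response flag in a compact text form. `mne` reads
the files identically (cross-checked in the test suite).

## Preprocessing

**Filter.** A zero-phase windowed-sinc band-pass (Hamming, 845 taps at
128 Hz, applied once and center-aligned — symmetric taps give exactly zero
phase). The −6 dB cutoffs sit at the transition midpoints (0.625 Hz and
41 Hz), which yields ≥30 dB attenuation at 0.25 Hz and 50 Hz and <1 dB
ripple across 2–38 Hz. Signals shorter than the filter length are refused
with the minimum stated.

**Channel rejection.** The per-channel statistic is the *median over 1.5 s
windows* of the window's sample kurtosis. A persistently corrupted channel
scores high in most windows; a channel with a few bad epochs — epoch
rejection's job — keeps a clean median, so transient artifacts are not
misattributed to the channel. The statistic is standardized across channels
with a robust z-score (median/MAD, scaled 1.4826): with only 14 channels an
ordinary z-score of a single outlier is algebraically bounded near 3.6 and
a threshold of 5 could never fire. Channels are removed when z > 5 *and*
the median kurtosis exceeds 0.5 (an absolute non-Gaussianity guard that
protects the all-clean case); flat channels are removed with reason
`flat`. Rejection is upper-tail only: kurtosis is a spike detector.

**Epoching.** One epoch per stimulus annotation, 192 samples (1500 ms)
starting at the onset sample, half-open window; baseline blocks are tiled
into non-overlapping 192-sample segments labelled L0 (a 60 s block gives
40). Epochs running past the recording end are kept in the metadata as
`rejected:truncated` with zeroed data.

**Epoch rejection.** Three criteria in fixed order — kurtosis, amplitude,
impedance — each epoch receiving the first matching reason (the order
affects attribution only, not the retained set). Epoch kurtosis is computed
per channel, standardized robustly across epochs within each channel,
upper tail z > 5, any-channel rejection (the per-channel-vs-pooled choice
is an assumption; pooled epoch data would hide single-channel spikes).
Amplitude: any |sample| > 1500 on the filtered signal. Impedance: the
minimum impedance reading inside the epoch window below 100. At these
defaults the false-rejection rate on clean synthetic epochs is ~5%
(dominated by the right tail of the kurtosis distribution over 192-sample
windows); the suite enforces <10%.

Rejection accounting tabulates, per (subject, day, condition), raw counts
and counts per reason including the later band-power threshold; retained +
rejected always equals raw.

## Features

Per epoch and channel a Hann-windowed single-taper periodogram (no Welch
sub-segmentation — 192 samples are too short); band power is spectral
density summed over bins in the half-open band [low, high), so the bin at
3.5 Hz belongs to theta, 7.5 Hz to alpha, 12.5 Hz to beta. Band edges:
delta 1–3.5, theta 3.5–7.5, alpha 7.5–12.5, beta 12.5–30, full 1–40 Hz.

The baseline norm is the log₁₀ of the mean full-band power over the
subject's retained same-day L0 epochs, per channel (a pooled-channel
variant is a config switch); it is never shared across subjects or days,
and a missing baseline raises with instructions rather than borrowing one.
The default normalization divides log-scaled values
(`log₁₀P / log₁₀norm` — both operands "similarly scaled"); the
log-difference convention (`log₁₀P − log₁₀norm`) is selectable and is the
convention that is linear in simulated offsets, hence used for
parameter-recovery checks. The convention is recorded in the output. Zero
powers are floored at 1e−12 before the log; a baseline norm with
non-positive log is refused.

Epochs with any of their 56 values strictly above 1.3 are removed (a value
of exactly 1.3 is retained). Columns of rejected channels are NaN and
excluded from thresholding and from classifier input.

**Known limitation — spectral leakage.** With 0.667 Hz bins and a Hann
taper, a few percent of each band component's power leaks into neighboring
bands. Isolated offsets are recovered with ≤~10% bias, but when neighboring
bands are co-modulated (e.g. theta flanked by rising delta and falling
alpha) the measured offset is pulled toward the neighbors by up to ~15–20%
of the effect. The recovery acceptance test therefore configures one
modulated band per lobe; recovery of the fully co-modulated default profile
is verified qualitatively (monotone, correct signs).

## Statistics

Epoch features are averaged within (subject, day, condition, channel, band)
— epochs of one recording are not independent observations — then across
each lobe's channels (frontal 8, temporal/parietal/occipital 2 each;
NaN channels skipped). The ANOVA is the classical balanced fully-crossed
within-subject decomposition, computed from marginal means by
inclusion–exclusion; each effect is tested against its interaction with the
subject factor, `partial η² = SS_effect / (SS_effect + SS_error)`. The
implementation is validated against `statsmodels` `AnovaRM` to 1e−8 and the
sums of squares are checked to partition the total exactly. No sphericity
correction is applied (degrees of freedom are reported uncorrected, and the
result object says so). Effects whose SS is below 1e−12 of the total (e.g.
duplicated factor levels) are reported as F = 0, p = 1 rather than a ratio
of rounding noise. Unbalanced designs raise, listing missing cells; nothing
is imputed.

Post hoc comparisons average days within subject first (matching reported
t(23)-style degrees of freedom at n = 24), then run paired two-sided
t-tests for all six condition pairs within each (lobe, band), flagged at
p < 0.01 uncorrected; multiplicity correction is deliberately off by
default to mirror the reporting convention, and identical inputs short-
circuit to t = 0, p = 1.

## Classification

Networks are scikit-learn `MLPClassifier`s: ReLU hidden units, softmax
output, Adam on cross-entropy, initial learning rate 5e−3, minibatch 32.
Training loops one epoch at a time with early stopping on *explicit*
validation accuracy (patience 10, max 150 epochs, best weights restored) —
the validation set is the one the division scheme defines, not an internal
split. Features are z-scored per column with statistics fit on the training
split only (the log-feature ranges make this necessary for stable
training), and the training rows are permuted before entering the network.

Division schemes: random subject partition 16/4/4 (requires ≥24 subjects);
day 1 train with day 2 halved into validation/test; day 1 + half of day 2
train with the remaining half-day split evenly; and leave-one-subject-out
with a fixed 10% stratified validation slice carved from the training pool.
"Half of day 2" is chronological *within each condition*: conditions run in
contiguous blocks, so halving raw presentation order would put whole
conditions on one side and leave single-class validation sets.

The grid search averages validation accuracy over repeated trainings
(default 30) for every architecture in the 1–3 layer × 12-width grid and
breaks ties toward fewer layers, then fewer nodes. The voting ensemble
trains 10 members from derived sub-seeds; prediction is the majority vote,
with vote ties resolved by the highest mean class score. ROC curves use the
ensemble's mean positive-class score with tied scores collapsed to a single
threshold, making the trapezoidal AUC equal the pairwise concordance
probability; the higher-load class is the positive class.

Every stochastic element — splits, repeats, members, subsampling,
simulation — derives its seed from the master seed through a SHA-256 hash
of a token path (`cogload.seeds.child_seed`), so any reported number can be
regenerated from one integer.

## Problem sizes

Defaults reproduce the study-scale settings (150 stimuli, 50 targets,
1600 ms SOA, 60 s baselines, 14 channels at 128 Hz, the full architecture
grid with 30 repeats and 10-net ensembles). The test suite and examples run
reduced sizes as a deliberate choice to keep feedback fast: cohorts of 3–8
subjects (24 where a scheme requires it), 30–60 epochs per condition for
classifier checks, 300 epochs per condition and two seeds for parameter
recovery, a reduced 1-layer × {5, 20} grid with 5 repeats where an
architecture search is exercised, and 600 null replicates of a reduced
4 × 2 × 2 × 2 design with 12 subjects for ANOVA calibration.

## Limitations

- The simulator's effect magnitudes are configuration, not measurements;
  only their signs follow the documented physiology. Absolute classifier
  accuracies on synthetic cohorts say nothing about real-data accuracy.
- Spectral leakage bias on co-modulated neighboring bands (above).
- The baseline tiling yields 40 epochs per 1-minute fixation block; the
  per-session baseline epoch count is exposed as configuration because
  recording-protocol details (extra fixation time, discarded warm-up) vary.
- Fraction correct is defined as correct responses over total stimuli; an
  alternative reading (over responses given) exists in the field and is
  *not* implemented.
- No ICA or regression-based ocular/muscular artifact removal: out of scope
  by design; filtering, thresholds and the band-power outlier rule are the
  only cleaning stages.
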