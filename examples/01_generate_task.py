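"""Generate constrained N-back stimulus sequences and score responses.

Builds one sequence per difficulty rule, simulates a moderately accurate
responder, and scores it; finally scores a usability questionnaire.
"""

from cogload.task import generate_sequence, score_responses, simulate_responses, sus_composite

for rule in ("L1", "L2", "L3"):
    seq = generate_sequence(rule, n_stimuli=150, n_targets=50, seed=7)
    print(f"{rule}: {seq.n_stimuli} stimuli, {seq.n_targets} targets, "
          f"{seq.duration_s:.0f} s, first digits {seq.digits[:10]}")

# a responder who hits 90% of targets and rarely false-alarms
seq = generate_sequence("L3", seed=7)
resp = simulate_responses(seq, hit_p=0.9, fa_p=0.02, rt_mean_ms=675.0, rt_sd_ms=60.0, seed=1)
summary = score_responses(seq, resp)
print(f"\ntwo-back scoring: fraction correct {summary.fraction_correct:.3f} "
      f"({summary.n_hits} hits, {summary.n_misses} misses, "
      f"{summary.n_false_alarms} false alarms), mean RT {summary.mean_rt_ms:.0f} ms")
print("fraction correct counts hits plus correct rejections over all 150 stimuli.")

score = sus_composite([4, 2, 5, 1, 4, 2, 4, 2, 5, 1])
print(f"\nSUS composite: {score} (0-100; above ~70 is conventionally 'good' usability)")
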