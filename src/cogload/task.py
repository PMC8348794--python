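"""N-back task generation and behavioral scoring.

The working-memory task shows a stream of digits (1–8) and asks for a button
press whenever the current digit is a target under one of three rules of
increasing difficulty:

``L1`` (zero-back)
    press whenever the digit ``1`` is shown;
``L2`` (three-even)
    press whenever three consecutive digits are all even — runs overlap, so a
    run of four even digits contains two targets;
``L3`` (two-back)
    press whenever the digit equals the one shown two stimuli earlier.

Each condition presents 150 digits at a 1600 ms stimulus-onset asynchrony
(240 s per condition) with exactly 50 targets (a 33% target rate), and no
digit is ever repeated back-to-back.  Sequences are generated by constrained
sequential sampling: at every position the sampler only considers digits that
leave the remaining target budget attainable, which makes dead ends rare; a
bounded number of restarts with derived sub-seeds covers the rest.

Scoring follows the "fraction correct" convention: a press counts for the
stimulus on screen when it occurs (latency at most one SOA), a hit is a press
on a target, a correct rejection is the absence of a press on a non-target,
and fraction correct is (hits + correct rejections) / total stimuli.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .seeds import child_seed

__all__ = [
    "TaskRule",
    "RULES",
    "StimulusSequence",
    "ResponseLog",
    "BehavioralSummary",
    "SusResponse",
    "SessionPlan",
    "GenerationError",
    "target_mask",
    "generate_sequence",
    "make_session_plan",
    "simulate_responses",
    "score_responses",
    "sus_composite",
    "write_sequence_csv",
    "read_sequence_csv",
    "write_responses_csv",
    "read_responses_csv",
]

DIGITS = tuple(range(1, 9))
DEFAULT_N_STIMULI = 150
DEFAULT_N_TARGETS = 50
DEFAULT_SOA_MS = 1600.0

#: Group-mean performance per condition (fraction correct, mean RT ms, RT sd ms)
#: used as simulation defaults for the behavioral response model.
DEFAULT_PERFORMANCE = {
    "L1": {"fraction_correct": 0.998, "rt_mean_ms": 596.9, "rt_sd_ms": 59.4},
    "L2": {"fraction_correct": 0.98, "rt_mean_ms": 656.9, "rt_sd_ms": 95.6},
    "L3": {"fraction_correct": 0.93, "rt_mean_ms": 675.4, "rt_sd_ms": 59.4},
}


class GenerationError(RuntimeError):
    """Raised when no sequence satisfying the constraints can be produced."""


@dataclass(frozen=True)
class TaskRule:
    """One of the three difficulty rules, mapping digits to a target mask."""

    id: str
    description: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.id


RULES: dict[str, TaskRule] = {
    "L1": TaskRule("L1", "zero-back: target iff the digit is 1"),
    "L2": TaskRule("L2", "three-even: target iff the last three digits are all even"),
    "L3": TaskRule("L3", "two-back: target iff the digit equals the second-to-last digit"),
}


def _as_rule(rule: TaskRule | str) -> TaskRule:
    if isinstance(rule, TaskRule):
        return rule
    try:
        return RULES[rule]
    except KeyError:
        raise ValueError(f"unknown rule {rule!r}; expected one of {sorted(RULES)}") from None


def target_mask(digits, rule: TaskRule | str) -> list[bool]:
    """Apply a task rule to a digit sequence, yielding a boolean target mask.

    The first two positions are never targets under L2 or L3 (their rules
    reference stimuli that do not exist yet).
    """
    rule = _as_rule(rule)
    digits = list(digits)
    if not digits:
        raise ValueError("digits must be nonempty")
    for d in digits:
        if d not in DIGITS:
            raise ValueError(f"digit {d!r} out of range 1..8")
    if rule.id == "L1":
        return [d == 1 for d in digits]
    if rule.id == "L2":
        even = [d % 2 == 0 for d in digits]
        return [
            i >= 2 and even[i] and even[i - 1] and even[i - 2]
            for i in range(len(digits))
        ]
    # L3 two-back
    return [i >= 2 and digits[i] == digits[i - 2] for i in range(len(digits))]


# ---------------------------------------------------------------------------
# constrained generation


def _trailing_evens(digits: list[int]) -> int:
    e = 0
    for d in reversed(digits):
        if d % 2 == 0:
            e += 1
        else:
            break
    return min(e, 2)


def _max_remaining_targets(rule_id: str, digits: list[int], r: int) -> int:
    """Exact upper bound on targets attainable in the next ``r`` positions."""
    if r <= 0:
        return 0
    if rule_id == "L1":
        # 1s cannot repeat back-to-back; best case alternates 1,x,1,x,...
        if digits and digits[-1] == 1:
            return r // 2
        return (r + 1) // 2
    if rule_id == "L2":
        setup = max(0, 2 - _trailing_evens(digits))
        return max(0, r - setup)
    # L3: once two digits exist, every position can match its lag-2 digit
    setup = max(0, 2 - len(digits))
    return max(0, r - setup)


def _creates_target(rule_id: str, digits: list[int], candidate: int) -> bool:
    i = len(digits)
    if rule_id == "L1":
        return candidate == 1
    if rule_id == "L2":
        return (
            i >= 2
            and candidate % 2 == 0
            and digits[-1] % 2 == 0
            and digits[-2] % 2 == 0
        )
    return i >= 2 and candidate == digits[i - 2]


def _sample_digits(rule_id: str, n: int, k: int, rng: np.random.Generator) -> list[int] | None:
    """One sequential-sampling attempt; returns None on a dead end."""
    digits: list[int] = []
    budget = k
    for i in range(n):
        r_after = n - i - 1
        prev = digits[-1] if digits else None
        targets: list[int] = []
        fillers: list[int] = []
        for c in DIGITS:
            if c == prev:
                continue
            t = _creates_target(rule_id, digits, c)
            b_after = budget - (1 if t else 0)
            if b_after < 0:
                continue
            digits.append(c)
            ok = b_after <= _max_remaining_targets(rule_id, digits, r_after)
            digits.pop()
            if not ok:
                continue
            (targets if t else fillers).append(c)
        if targets and fillers:
            # aim the per-position target probability at the remaining rate
            pool = targets if rng.random() < budget / (n - i) else fillers
        elif targets or fillers:
            pool = targets or fillers
        else:
            return None
        choice = int(pool[rng.integers(len(pool))])
        digits.append(choice)
        if _creates_target(rule_id, digits[:-1], choice):
            budget -= 1
    return digits if budget == 0 else None


@dataclass(frozen=True)
class StimulusSequence:
    """An ordered digit stream with its target mask and generation metadata."""

    digits: tuple[int, ...]
    mask: tuple[bool, ...]
    rule: TaskRule
    soa_ms: float = DEFAULT_SOA_MS
    version: str = "A"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.digits) != len(self.mask):
            raise ValueError("digits and mask length mismatch")
        if tuple(target_mask(self.digits, self.rule)) != tuple(self.mask):
            raise ValueError("target mask inconsistent with rule")
        for a, b in zip(self.digits, self.digits[1:]):
            if a == b:
                raise ValueError("adjacent repeated digits")

    @property
    def n_stimuli(self) -> int:
        return len(self.digits)

    @property
    def n_targets(self) -> int:
        return int(sum(self.mask))

    @property
    def duration_s(self) -> float:
        """Nominal presentation time of the whole stream in seconds."""
        return self.n_stimuli * self.soa_ms / 1000.0

    def onsets_s(self) -> np.ndarray:
        return np.arange(self.n_stimuli) * self.soa_ms / 1000.0


def generate_sequence(
    rule: TaskRule | str,
    n_stimuli: int = DEFAULT_N_STIMULI,
    n_targets: int = DEFAULT_N_TARGETS,
    seed: int = 0,
    *,
    soa_ms: float = DEFAULT_SOA_MS,
    version: str = "A",
    max_restarts: int = 50,
) -> StimulusSequence:
    """Generate a pseudo-random digit sequence with an exact target count.

    Constraints: digits in 1..8, no digit repeated back-to-back, exactly
    ``n_targets`` targets under ``rule``.  Identical arguments always return
    the identical sequence.

    Raises
    ------
    GenerationError
        If the (rule, n_stimuli, n_targets) combination is infeasible, or no
        valid sequence is found within ``max_restarts`` restarts.
    """
    rule = _as_rule(rule)
    if n_stimuli < 1:
        raise GenerationError("n_stimuli must be >= 1")
    upper = _max_remaining_targets(rule.id, [], n_stimuli)
    if not 0 <= n_targets <= upper:
        raise GenerationError(
            f"{n_targets} targets unattainable for rule {rule.id} with "
            f"{n_stimuli} stimuli (feasible range 0..{upper})"
        )
    for attempt in range(max_restarts):
        rng = np.random.default_rng(child_seed(seed, "seq", rule.id, version, attempt))
        digits = _sample_digits(rule.id, n_stimuli, n_targets, rng)
        if digits is not None:
            return StimulusSequence(
                digits=tuple(digits),
                mask=tuple(target_mask(digits, rule)),
                rule=rule,
                soa_ms=soa_ms,
                version=version,
                seed=seed,
            )
    raise GenerationError(
        f"no sequence found for rule {rule.id}, n={n_stimuli}, "
        f"targets={n_targets} after {max_restarts} restarts"
    )


# ---------------------------------------------------------------------------
# session plan


@dataclass(frozen=True)
class SessionPlan:
    """Randomized condition order with per-condition sequences and baselines.

    Each task condition is preceded by a fixation baseline block (1 min by
    default); version labels A/B select disjoint sub-seeds so the two parallel
    task versions share structure but not digits.
    """

    version: str
    order: tuple[str, ...]
    sequences: dict[str, StimulusSequence]
    baseline_s: float
    seed: int

    def blocks(self):
        """Yield (kind, condition, payload) in presentation order."""
        for cond in self.order:
            yield ("baseline", cond, self.baseline_s)
            yield ("task", cond, self.sequences[cond])


def make_session_plan(
    seed: int,
    version: str = "A",
    *,
    n_stimuli: int = DEFAULT_N_STIMULI,
    n_targets: int = DEFAULT_N_TARGETS,
    soa_ms: float = DEFAULT_SOA_MS,
    baseline_s: float = 60.0,
) -> SessionPlan:
    """Build a session: randomized L1/L2/L3 order, baselines, fresh sequences."""
    if version not in ("A", "B"):
        raise ValueError("version must be 'A' or 'B'")
    order_rng = np.random.default_rng(child_seed(seed, "order"))
    order = tuple(order_rng.permutation(["L1", "L2", "L3"]).tolist())
    sequences = {
        rid: generate_sequence(
            rid,
            n_stimuli,
            n_targets,
            seed=child_seed(seed, "version", version),
            soa_ms=soa_ms,
            version=version,
        )
        for rid in ("L1", "L2", "L3")
    }
    return SessionPlan(
        version=version,
        order=order,
        sequences=sequences,
        baseline_s=float(baseline_s),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# responses and scoring


@dataclass(frozen=True)
class ResponseLog:
    """Per-stimulus button presses; latency is from stimulus onset, in ms."""

    pressed: tuple[bool, ...]
    latency_ms: tuple[float, ...]  # NaN where not pressed
    soa_ms: float = DEFAULT_SOA_MS

    def __post_init__(self) -> None:
        if len(self.pressed) != len(self.latency_ms):
            raise ValueError("pressed and latency_ms length mismatch")
        for p, lat in zip(self.pressed, self.latency_ms):
            if p:
                if not (0.0 < lat <= self.soa_ms):
                    raise ValueError(
                        f"latency {lat} ms outside (0, {self.soa_ms}]; a press is "
                        "attributed to the stimulus on screen when it occurs"
                    )
            elif not math.isnan(lat):
                raise ValueError("latency present without a press")

    def __len__(self) -> int:
        return len(self.pressed)


@dataclass(frozen=True)
class BehavioralSummary:
    """Hit/miss/false-alarm counts, fraction correct, and mean hit RT."""

    n_hits: int
    n_misses: int
    n_false_alarms: int
    n_correct_rejections: int
    fraction_correct: float
    mean_rt_ms: float  # NaN when there are no hits

    @property
    def n_stimuli(self) -> int:
        return self.n_hits + self.n_misses + self.n_false_alarms + self.n_correct_rejections


def simulate_responses(
    sequence: StimulusSequence,
    hit_p: float,
    fa_p: float,
    rt_mean_ms: float,
    rt_sd_ms: float,
    seed: int,
) -> ResponseLog:
    """Sample a response log: presses on targets with probability ``hit_p``,
    on non-targets with probability ``fa_p``; latencies are truncated-normal
    within (0, SOA]."""
    for name, p in (("hit_p", hit_p), ("fa_p", fa_p)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(child_seed(seed, "resp", sequence.rule.id, sequence.version))
    pressed, latency = [], []
    for is_target in sequence.mask:
        p = hit_p if is_target else fa_p
        if rng.random() < p:
            lat = float(np.clip(rng.normal(rt_mean_ms, rt_sd_ms), 1.0, sequence.soa_ms))
            pressed.append(True)
            latency.append(lat)
        else:
            pressed.append(False)
            latency.append(float("nan"))
    return ResponseLog(tuple(pressed), tuple(latency), soa_ms=sequence.soa_ms)


def score_responses(sequence: StimulusSequence, responses: ResponseLog) -> BehavioralSummary:
    """Score a response log against a stimulus sequence.

    fraction correct = (hits + correct rejections) / total stimuli; mean RT is
    over hit latencies only.
    """
    if len(responses) != sequence.n_stimuli:
        raise ValueError(
            f"response log length {len(responses)} != sequence length {sequence.n_stimuli}"
        )
    hits = misses = fas = crs = 0
    rts: list[float] = []
    for is_target, p, lat in zip(sequence.mask, responses.pressed, responses.latency_ms):
        if is_target and p:
            hits += 1
            rts.append(lat)
        elif is_target:
            misses += 1
        elif p:
            fas += 1
        else:
            crs += 1
    return BehavioralSummary(
        n_hits=hits,
        n_misses=misses,
        n_false_alarms=fas,
        n_correct_rejections=crs,
        fraction_correct=(hits + crs) / sequence.n_stimuli,
        mean_rt_ms=float(np.mean(rts)) if rts else float("nan"),
    )


# ---------------------------------------------------------------------------
# usability questionnaire


@dataclass(frozen=True)
class SusResponse:
    """A System Usability Scale response: ten items on a 1..5 Likert scale."""

    ratings: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.ratings) != 10:
            raise ValueError("SUS has exactly 10 items")
        for r in self.ratings:
            if not (isinstance(r, (int, np.integer)) and 1 <= r <= 5):
                raise ValueError(f"rating {r!r} outside the 1..5 scale")


def sus_composite(response: SusResponse | list[int] | tuple[int, ...]) -> float:
    """SUS composite on 0–100.

    Standard scoring: odd items (1st, 3rd, ...) contribute ``rating - 1``,
    even items ``5 - rating`` (they are negatively phrased), and the sum of
    the ten adjusted 0–4 scores is multiplied by 2.5.
    """
    if not isinstance(response, SusResponse):
        response = SusResponse(tuple(response))
    adjusted = [
        (r - 1) if i % 2 == 0 else (5 - r)  # i is 0-based: even index = odd item
        for i, r in enumerate(response.ratings)
    ]
    return 2.5 * sum(adjusted)


# ---------------------------------------------------------------------------
# serialization


def _seq_frame(sequence: StimulusSequence, responses: ResponseLog | None) -> pd.DataFrame:
    data = {
        "index": np.arange(sequence.n_stimuli),
        "digit": list(sequence.digits),
        "is_target": [int(t) for t in sequence.mask],
    }
    if responses is not None:
        data["pressed"] = [int(p) for p in responses.pressed]
        data["latency_ms"] = list(responses.latency_ms)
    return pd.DataFrame(data)


def write_sequence_csv(
    sequence: StimulusSequence,
    path: str | Path,
    responses: ResponseLog | None = None,
) -> None:
    """Write a sequence (and optionally responses) to CSV + JSON sidecar."""
    path = Path(path)
    _seq_frame(sequence, responses).to_csv(path, index=False)
    sidecar = {
        "rule": sequence.rule.id,
        "version": sequence.version,
        "seed": sequence.seed,
        "soa_ms": sequence.soa_ms,
        "n_stimuli": sequence.n_stimuli,
        "n_targets": sequence.n_targets,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_sequence_csv(path: str | Path) -> StimulusSequence:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return StimulusSequence(
        digits=tuple(int(d) for d in df["digit"]),
        mask=tuple(bool(t) for t in df["is_target"]),
        rule=RULES[meta["rule"]],
        soa_ms=float(meta["soa_ms"]),
        version=meta["version"],
        seed=int(meta["seed"]),
    )


def write_responses_csv(responses: ResponseLog, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "index": np.arange(len(responses)),
            "pressed": [int(p) for p in responses.pressed],
            "latency_ms": list(responses.latency_ms),
        }
    )
    df.to_csv(path, index=False)


def read_responses_csv(path: str | Path, soa_ms: float = DEFAULT_SOA_MS) -> ResponseLog:
    df = pd.read_csv(path)
    return ResponseLog(
        pressed=tuple(bool(p) for p in df["pressed"]),
        latency_ms=tuple(float(x) for x in df["latency_ms"]),
        soa_ms=soa_ms,
    )
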