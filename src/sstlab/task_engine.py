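"""Stop Signal Task mechanics: trial scheduling, staircase SSD tracking, scoring.

The task presents a stream of two-choice "go" trials; on a fixed fraction of
trials a delayed stop signal instructs the participant to withhold the
response.  The stop signal delay (SSD) is adapted by four interleaved
staircases so that stop trials sample the inhibition-probability-by-SSD
space.  A points variant of the task layers a bonus-multiplier scoring rule
on top of the same trial stream.

Everything here is deterministic given a seed; no timing or rendering is
simulated — fixation/display/ITI durations are carried as metadata only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

GO = "go"
STOP = "stop"

#: Trial outcome labels used throughout the trial logs.
OUTCOMES = (
    "go_success",
    "go_error",
    "go_omission",
    "stop_inhibit",
    "stop_respond",
    "stop_presignal",
)

#: Outcomes in which a keypress occurred (an RT is present).
RESPONSE_OUTCOMES = frozenset(
    {"go_success", "go_error", "stop_respond", "stop_presignal"}
)

#: Go-type responses for scoring: the participant saw (to all appearances) an
#: ordinary go trial and responded.  stop_presignal responses occurred before
#: the signal would have been shown, so they look and score like go responses.
_GO_LIKE_FOR_SCORING = frozenset({"go_success", "go_error", "stop_presignal"})


@dataclass(frozen=True)
class TaskConfig:
    """Structural and scoring parameters of one task variant.

    Timing fields (``fixation_ms``, ``display_ms``, ``iti_range_ms``) are
    metadata describing the task as presented to participants; they do not
    affect any computation here.
    """

    n_blocks: int = 5
    trials_per_block: int = 48
    stop_fraction: float = 0.25
    staircase_start_ms: tuple[float, ...] = (50.0, 150.0, 250.0, 350.0)
    staircase_step_ms: float = 50.0
    staircase_bounds_ms: tuple[float, float] = (0.0, 800.0)
    score_rate: float = 0.2
    score_rt_ceiling_ms: float = 800.0
    bonus_increment_every: int = 3
    bonus_penalty: int = 3
    bonus_floor: int = 1
    fixation_ms: float = 500.0
    display_ms: float = 900.0
    iti_range_ms: tuple[float, float] = (500.0, 1000.0)


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered go/stop plan for one session."""

    entries: tuple[tuple[int, str], ...]  # (block_index 1-based, "go"|"stop")
    n_blocks: int
    trials_per_block: int
    stop_fraction: float

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_stop(self) -> int:
        return sum(1 for _, t in self.entries if t == STOP)


def generate_schedule(
    n_blocks: int, trials_per_block: int, stop_fraction: float, seed
) -> TrialSchedule:
    """Build a session schedule with an exact per-block stop-trial count.

    The stop count per block is ``round(stop_fraction * trials_per_block)``
    (half-up), not a Bernoulli draw, so a 25% stop fraction yields exactly
    12 stop trials in every 48-trial block.  Stop positions are shuffled
    uniformly within each block.  The same seed always yields the same
    schedule.
    """
    if not 0.0 <= stop_fraction <= 1.0:
        raise ValueError(f"stop_fraction must be in [0, 1], got {stop_fraction}")
    if n_blocks < 1 or trials_per_block < 1:
        raise ValueError("n_blocks and trials_per_block must be >= 1")
    rng = np.random.default_rng(seed)
    n_stop = int(np.floor(stop_fraction * trials_per_block + 0.5))
    entries: list[tuple[int, str]] = []
    for block in range(1, n_blocks + 1):
        types = np.array([STOP] * n_stop + [GO] * (trials_per_block - n_stop))
        rng.shuffle(types)
        entries.extend((block, t) for t in types)
    return TrialSchedule(
        entries=tuple(entries),
        n_blocks=n_blocks,
        trials_per_block=trials_per_block,
        stop_fraction=stop_fraction,
    )


@dataclass(frozen=True)
class StaircaseBank:
    """Four (or more) independent 1-up/1-down SSD staircases, drawn round-robin.

    A successful inhibition makes the next stop trial on that staircase harder
    (SSD up one step); a failed stop makes it easier (SSD down).  SSDs are
    clipped to ``bounds_ms``.
    """

    ssd_ms: tuple[float, ...] = (50.0, 150.0, 250.0, 350.0)
    step_ms: float = 50.0
    bounds_ms: tuple[float, float] = (0.0, 800.0)
    next_index: int = 1  # 1-based round-robin pointer

    def __post_init__(self):
        lo, hi = self.bounds_ms
        if not all(lo <= s <= hi for s in self.ssd_ms):
            raise ValueError(f"staircase SSDs {self.ssd_ms} outside bounds {self.bounds_ms}")
        if not 1 <= self.next_index <= len(self.ssd_ms):
            raise ValueError("next_index out of range")

    @classmethod
    def from_config(cls, config: TaskConfig) -> "StaircaseBank":
        return cls(
            ssd_ms=tuple(config.staircase_start_ms),
            step_ms=config.staircase_step_ms,
            bounds_ms=config.staircase_bounds_ms,
        )


def next_stop_ssd(bank: StaircaseBank) -> tuple[float, int, StaircaseBank]:
    """Draw the SSD for the next stop trial and advance the round-robin pointer."""
    idx = bank.next_index
    ssd = bank.ssd_ms[idx - 1]
    nxt = 1 if idx == len(bank.ssd_ms) else idx + 1
    return ssd, idx, replace(bank, next_index=nxt)


def update_staircase(bank: StaircaseBank, staircase_id: int, inhibited: bool) -> StaircaseBank:
    """1-up/1-down update of one staircase after a stop trial, clipped to bounds."""
    if not 1 <= staircase_id <= len(bank.ssd_ms):
        raise ValueError(f"unknown staircase_id {staircase_id}")
    lo, hi = bank.bounds_ms
    delta = bank.step_ms if inhibited else -bank.step_ms
    new = float(np.clip(bank.ssd_ms[staircase_id - 1] + delta, lo, hi))
    ssds = list(bank.ssd_ms)
    ssds[staircase_id - 1] = new
    return replace(bank, ssd_ms=tuple(ssds))


@dataclass(frozen=True)
class ScoringState:
    """Points-variant scoring state.

    The bonus multiplier rises by 1 for every ``bonus_increment_every`` go-type
    responses and drops by ``bonus_penalty`` (floored) when a stop trial is
    failed after the signal appeared.  Successful inhibitions award no points
    but keep the bonus; responses made before the signal would have appeared
    score exactly like go responses (the participant never saw a stop trial).
    Scores reset per session; the high score persists across sessions.
    """

    bonus: int = 1
    trials_since_increment: int = 0
    total_score: float = 0.0
    high_score: float = 0.0


def apply_scoring(
    state: ScoringState,
    outcome: str,
    rt_ms: Optional[float] = None,
    config: TaskConfig = TaskConfig(),
) -> tuple[ScoringState, float]:
    """Apply one trial's outcome to the scoring state; return (state', points).

    Points on a successful go-type response are
    ``score_rate * bonus * (rt_ceiling - rt)``, floored at zero for responses
    slower than the ceiling.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    if rt_ms is not None and rt_ms < 0:
        raise ValueError(f"rt_ms must be non-negative, got {rt_ms}")
    if outcome in ("go_success", "stop_presignal") and rt_ms is None:
        raise ValueError(f"{outcome} requires rt_ms to score points")

    bonus = state.bonus
    counter = state.trials_since_increment
    points = 0.0

    if outcome in _GO_LIKE_FOR_SCORING:
        if outcome in ("go_success", "stop_presignal"):
            points = max(0.0, config.score_rate * bonus * (config.score_rt_ceiling_ms - rt_ms))
        counter += 1
        if counter >= config.bonus_increment_every:
            counter = 0
            bonus += 1
    elif outcome == "stop_respond":
        bonus = max(config.bonus_floor, bonus - config.bonus_penalty)
    # stop_inhibit, go_omission: no points, bonus and counter unchanged

    total = state.total_score + points
    return (
        ScoringState(
            bonus=bonus,
            trials_since_increment=counter,
            total_score=total,
            high_score=max(state.high_score, total),
        ),
        points,
    )


def display_points(points: float) -> int:
    """Round real-valued points half-up for on-screen display."""
    return int(np.floor(points + 0.5))


@dataclass(frozen=True)
class TrialRecord:
    """One logged task trial."""

    index: int  # 1-based position in the session
    block: int
    trial_type: str  # "go" | "stop"
    outcome: str
    ssd_ms: Optional[float] = None  # stop trials only
    rt_ms: Optional[float] = None  # present iff a response occurred
    staircase_id: Optional[int] = None  # stop trials only
    points: float = 0.0
    bonus_after: int = 1

    def __post_init__(self):
        if (self.rt_ms is not None) != (self.outcome in RESPONSE_OUTCOMES):
            raise ValueError(f"rt_ms presence inconsistent with outcome {self.outcome}")
        if (self.ssd_ms is not None) != (self.trial_type == STOP):
            raise ValueError("ssd_ms must be present iff trial_type == 'stop'")
        if self.outcome == "stop_presignal" and not self.rt_ms < self.ssd_ms:
            raise ValueError("stop_presignal requires rt_ms < ssd_ms")


#: Column order of the trial-log CSV (one row per TrialRecord).
TRIAL_CSV_COLUMNS = [
    "participant_id",
    "session_number",
    "block",
    "trial_index",
    "trial_type",
    "ssd_ms",
    "staircase_id",
    "outcome",
    "rt_ms",
    "points",
    "bonus_after",
]
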