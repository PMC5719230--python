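"""Synthetic cohort generation with recoverable ground truth.

Simulates participants performing a longitudinal web-based Stop Signal Task
under the independent horse-race model: on every trial a go process (ex-Gaussian
finishing time) races a stop process (normal latency, triggered at the SSD).
A response is emitted iff the go process finishes first.  Each participant
carries a latent profile — go-RT distribution, true stop latency (the
ground-truth SSRT), daily dropout hazard, questionnaire means, loss-of-focus
rate — so every quantity the analysis pipeline later estimates has a known
truth to recover.

The study design emulated: four compulsory daily sessions followed by up to
six optional days, with a per-day dropout decision in the optional phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .task_engine import (
    GO,
    STOP,
    TRIAL_CSV_COLUMNS,
    ScoringState,
    StaircaseBank,
    TaskConfig,
    TrialRecord,
    apply_scoring,
    generate_schedule,
    next_stop_ssd,
    update_staircase,
)

VARIANTS = ("nongame", "points", "theme")

#: Sessions delivering the full 10-item questionnaire; others get the short form.
LONG_FORM_SESSIONS = frozenset({1, 4, 7, 10})
LONG_FORM_ITEMS = tuple(range(1, 11))
SHORT_FORM_ITEMS = (1, 2, 5, 8, 9)
REVERSE_SCORED_ITEMS = frozenset({2, 3, 6, 8})


@dataclass(frozen=True)
class ParticipantProfile:
    """Latent simulator truth for one participant.

    ``stop_mean`` is the true SSRT generator: stop-process latencies are
    N(stop_mean, stop_sd) truncated at zero.  Go finishing times are
    ex-Gaussian(mu, sigma, tau).  ``dropout_hazard`` is the per-day probability
    of quitting during the optional phase.
    """

    participant_id: str
    variant: str
    go_mu: float = 380.0
    go_sigma: float = 50.0
    go_tau: float = 120.0
    stop_mean: float = 270.0
    stop_sd: float = 20.0
    lapse_prob: float = 0.02
    choice_error_prob: float = 0.02
    dropout_hazard: float = 0.15
    questionnaire_base: float = 55.0  # VAS mean at session 1, 0-100
    questionnaire_slope: float = -1.5  # per-session drift of the VAS mean
    questionnaire_sd: float = 12.0
    focus_rate: float = 0.95  # expected loss-of-focus events per session

    def __post_init__(self):
        for name in ("go_mu", "go_sigma", "go_tau", "stop_mean", "stop_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("lapse_prob", "choice_error_prob", "dropout_hazard"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.questionnaire_base <= 100.0:
            raise ValueError("questionnaire_base must be in [0, 100]")


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and between-variant parameters of a simulated cohort."""

    n_per_variant: int = 97
    compulsory_sessions: int = 4
    max_sessions: int = 10
    seed: int = 0
    # Per-variant constant daily dropout hazards for the optional phase.
    dropout_hazard: dict = field(
        default_factory=lambda: {"nongame": 0.160, "points": 0.155, "theme": 0.115}
    )
    # Per-variant VAS questionnaire means at session 1 and per-session drift.
    questionnaire_base: dict = field(
        default_factory=lambda: {"nongame": 56.0, "points": 59.0, "theme": 53.0}
    )
    questionnaire_slope: dict = field(
        default_factory=lambda: {"nongame": -2.0, "points": -2.0, "theme": -0.67}
    )
    # Between-participant SD of latent means (0 -> homogeneous cohort).
    stop_mean_center: float = 270.0
    stop_mean_sd: float = 25.0
    go_mu_sd: float = 30.0
    focus_rate: dict = field(
        default_factory=lambda: {"nongame": 0.85, "points": 0.82, "theme": 1.21}
    )
    # Probability a compulsory-phase day is missed, injecting non-conformance;
    # a 1-day slip yields a loosely conforming participant, a 2-day slip a
    # non-conforming one.
    miss_day_prob: float = 0.0
    miss_two_day_frac: float = 0.3
    reset_staircases_per_session: bool = False

    def __post_init__(self):
        if self.n_per_variant < 1:
            raise ValueError("n_per_variant must be >= 1")
        for v, h in self.dropout_hazard.items():
            if not 0.0 <= h <= 1.0:
                raise ValueError(f"hazard for {v} must be in [0, 1]")


@dataclass
class SessionRecord:
    """One participant-day: trial log, questionnaire, loss-of-focus count."""

    participant_id: str
    variant: str
    session_number: int
    calendar_day: int
    completed: bool
    trials: list  # list[TrialRecord]
    questionnaire: dict  # item number -> VAS score 0-100 (form-dependent)
    loss_of_focus_count: int
    score: float  # session total (points variant semantics; logged for all)


def sample_ex_gaussian(rng: np.random.Generator, mu: float, sigma: float, tau: float, size=None):
    """Ex-Gaussian finishing times: normal(mu, sigma) + exponential(tau)."""
    return rng.normal(mu, sigma, size=size) + rng.exponential(tau, size=size)


def simulate_trial_response(
    profile: ParticipantProfile,
    trial_type: str,
    ssd_ms: Optional[float],
    rng: np.random.Generator,
    display_ms: float = 900.0,
) -> tuple[str, Optional[float]]:
    """Simulate one trial under the independent race model.

    Go trials: the go finishing time is ex-Gaussian, resampled into
    (0, display_ms]; with ``lapse_prob`` the trial is an omission.  Stop
    trials: a response is emitted iff the sampled go time beats
    ``ssd + stop latency`` and lands within the display window; responses
    faster than the SSD never saw the signal (``stop_presignal``).
    """
    if (ssd_ms is not None) != (trial_type == STOP):
        raise ValueError("ssd_ms must be present iff stop trial")
    lapsed = rng.random() < profile.lapse_prob
    if trial_type == GO:
        if lapsed:
            return "go_omission", None
        rt = sample_ex_gaussian(rng, profile.go_mu, profile.go_sigma, profile.go_tau)
        for _ in range(100):
            if 0.0 < rt <= display_ms:
                break
            rt = sample_ex_gaussian(rng, profile.go_mu, profile.go_sigma, profile.go_tau)
        else:
            return "go_omission", None
        if rng.random() < profile.choice_error_prob:
            return "go_error", float(rt)
        return "go_success", float(rt)
    # stop trial
    if lapsed:
        return "stop_inhibit", None
    t_go = sample_ex_gaussian(rng, profile.go_mu, profile.go_sigma, profile.go_tau)
    t_stop = max(0.0, rng.normal(profile.stop_mean, profile.stop_sd))
    if t_go < ssd_ms + t_stop and 0.0 < t_go <= display_ms:
        outcome = "stop_presignal" if t_go < ssd_ms else "stop_respond"
        return outcome, float(t_go)
    return "stop_inhibit", None


def simulate_session(
    profile: ParticipantProfile,
    task_config: TaskConfig,
    bank: StaircaseBank,
    session_number: int,
    high_score: float,
    rng: np.random.Generator,
) -> tuple[list[TrialRecord], StaircaseBank, float]:
    """Run one full session through schedule, race model, staircases and scoring."""
    schedule = generate_schedule(
        task_config.n_blocks,
        task_config.trials_per_block,
        task_config.stop_fraction,
        rng.integers(0, 2**31 - 1),
    )
    scoring = ScoringState(high_score=high_score)
    records: list[TrialRecord] = []
    for i, (block, trial_type) in enumerate(schedule.entries, start=1):
        if trial_type == STOP:
            ssd, sc_id, bank = next_stop_ssd(bank)
        else:
            ssd, sc_id = None, None
        outcome, rt = simulate_trial_response(
            profile, trial_type, ssd, rng, display_ms=task_config.display_ms
        )
        if trial_type == STOP:
            inhibited = outcome == "stop_inhibit"
            bank = update_staircase(bank, sc_id, inhibited)
        scoring, points = apply_scoring(scoring, outcome, rt, task_config)
        records.append(
            TrialRecord(
                index=i,
                block=block,
                trial_type=trial_type,
                outcome=outcome,
                ssd_ms=ssd,
                rt_ms=rt,
                staircase_id=sc_id,
                points=points,
                bonus_after=scoring.bonus,
            )
        )
    return records, bank, scoring.total_score


def _sample_questionnaire(
    profile: ParticipantProfile, session_number: int, rng: np.random.Generator
) -> dict:
    """Draw VAS item scores; reverse-keyed items are drawn around 100 - mean so
    the scored (reversed) mean matches the latent mean."""
    items = LONG_FORM_ITEMS if session_number in LONG_FORM_SESSIONS else SHORT_FORM_ITEMS
    m = float(
        np.clip(
            profile.questionnaire_base + profile.questionnaire_slope * (session_number - 1),
            0.0,
            100.0,
        )
    )
    out = {}
    for item in items:
        loc = 100.0 - m if item in REVERSE_SCORED_ITEMS else m
        out[item] = float(np.clip(rng.normal(loc, profile.questionnaire_sd), 0.0, 100.0))
    return out


def sample_sessions_completed(
    hazard: float,
    n: int,
    rng: np.random.Generator,
    compulsory: int = 4,
    max_sessions: int = 10,
) -> np.ndarray:
    """Vectorized draw of sessions-completed counts under a constant daily hazard.

    Every participant completes the compulsory sessions; from the next day on
    they continue each day with probability ``1 - hazard`` until the study cap.
    """
    optional_days = max_sessions - compulsory
    cont = rng.random((n, optional_days)) < (1.0 - hazard)
    # sessions beyond compulsory = length of initial run of continuations
    stopped = np.argmin(cont, axis=1)
    all_cont = cont.all(axis=1)
    extra = np.where(all_cont, optional_days, stopped)
    return compulsory + extra


def simulate_participant(
    profile: ParticipantProfile,
    cohort_config: CohortConfig,
    task_config: TaskConfig,
    seed,
) -> list[SessionRecord]:
    """Simulate a participant's full study trajectory.

    Compulsory sessions always occur (possibly on slipped calendar days when
    non-conformance injection is enabled); each optional day the participant
    drops out with probability ``dropout_hazard``.
    """
    rng = np.random.default_rng(seed)
    n_comp = cohort_config.compulsory_sessions

    # calendar days of the compulsory sessions
    days = list(range(1, n_comp + 1))
    if cohort_config.miss_day_prob > 0 and rng.random() < cohort_config.miss_day_prob:
        slip = 2 if rng.random() < cohort_config.miss_two_day_frac else 1
        pos = int(rng.integers(1, n_comp))  # slip applies from the 2nd..4th session
        days = days[:pos] + [d + slip for d in days[pos:]]

    n_sessions = n_comp
    for _ in range(cohort_config.max_sessions - n_comp):
        if rng.random() < profile.dropout_hazard:
            break
        n_sessions += 1

    bank = StaircaseBank.from_config(task_config)
    high_score = 0.0
    out: list[SessionRecord] = []
    for s in range(1, n_sessions + 1):
        if cohort_config.reset_staircases_per_session:
            bank = StaircaseBank.from_config(task_config)
        trials, bank, score = simulate_session(
            profile, task_config, bank, s, high_score, rng
        )
        high_score = max(high_score, score)
        day = days[s - 1] if s <= n_comp else days[-1] + (s - n_comp)
        out.append(
            SessionRecord(
                participant_id=profile.participant_id,
                variant=profile.variant,
                session_number=s,
                calendar_day=day,
                completed=True,
                trials=trials,
                questionnaire=_sample_questionnaire(profile, s, rng),
                loss_of_focus_count=int(rng.poisson(profile.focus_rate)),
                score=score,
            )
        )
    return out


@dataclass
class CohortDataset:
    """Tidy frames for a simulated cohort: trial log, session log, latent truth."""

    trials: pd.DataFrame
    sessions: pd.DataFrame
    truth: pd.DataFrame

    def to_csv(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "trials": outdir / "trials.csv",
            "sessions": outdir / "sessions.csv",
            "truth": outdir / "truth.csv",
        }
        self.trials.to_csv(paths["trials"], index=False, float_format="%.6g")
        self.sessions.to_csv(paths["sessions"], index=False, float_format="%.6g")
        self.truth.to_csv(paths["truth"], index=False, float_format="%.6g")
        return paths

    @classmethod
    def from_csv(cls, trials_path, sessions_path, truth_path=None) -> "CohortDataset":
        trials = pd.read_csv(trials_path)
        sessions = pd.read_csv(sessions_path)
        truth = pd.read_csv(truth_path) if truth_path else pd.DataFrame()
        return cls(trials=trials, sessions=sessions, truth=truth)


def _profiles(cohort_config: CohortConfig, rng: np.random.Generator) -> list[ParticipantProfile]:
    profiles = []
    i = 0
    for variant in VARIANTS:
        for _ in range(cohort_config.n_per_variant):
            i += 1
            profiles.append(
                ParticipantProfile(
                    participant_id=f"P{i:04d}",
                    variant=variant,
                    go_mu=float(max(150.0, rng.normal(380.0, cohort_config.go_mu_sd))),
                    stop_mean=float(
                        max(50.0, rng.normal(cohort_config.stop_mean_center, cohort_config.stop_mean_sd))
                    ),
                    dropout_hazard=cohort_config.dropout_hazard[variant],
                    questionnaire_base=float(
                        np.clip(rng.normal(cohort_config.questionnaire_base[variant], 8.0), 0, 100)
                    ),
                    questionnaire_slope=cohort_config.questionnaire_slope[variant],
                    focus_rate=cohort_config.focus_rate[variant],
                )
            )
    return profiles


def sessions_to_frames(records: Sequence[SessionRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten SessionRecords into (trials, sessions) DataFrames on the CSV schemas."""
    trial_rows = []
    session_rows = []
    for rec in records:
        for t in rec.trials:
            trial_rows.append(
                {
                    "participant_id": rec.participant_id,
                    "session_number": rec.session_number,
                    "block": t.block,
                    "trial_index": t.index,
                    "trial_type": t.trial_type,
                    "ssd_ms": t.ssd_ms,
                    "staircase_id": t.staircase_id,
                    "outcome": t.outcome,
                    "rt_ms": t.rt_ms,
                    "points": t.points,
                    "bonus_after": t.bonus_after,
                }
            )
        row = {
            "participant_id": rec.participant_id,
            "variant": rec.variant,
            "session_number": rec.session_number,
            "calendar_day": rec.calendar_day,
            "completed": rec.completed,
            "loss_of_focus_count": rec.loss_of_focus_count,
            "score": rec.score,
        }
        for item in range(1, 11):
            row[f"q{item}"] = rec.questionnaire.get(item, np.nan)
        session_rows.append(row)
    trials = pd.DataFrame(trial_rows, columns=TRIAL_CSV_COLUMNS)
    sessions = pd.DataFrame(session_rows)
    return trials, sessions


def generate_cohort(
    cohort_config: CohortConfig, task_config: TaskConfig = TaskConfig()
) -> CohortDataset:
    """Generate a full cohort: trial log, session log, and ground-truth table.

    Reproducible under ``cohort_config.seed``: all randomness flows from one
    root seed via spawned substreams, one per participant.
    """
    root = np.random.SeedSequence(cohort_config.seed)
    profile_rng = np.random.default_rng(root.spawn(1)[0])
    profiles = _profiles(cohort_config, profile_rng)
    participant_seeds = root.spawn(len(profiles))

    all_records: list[SessionRecord] = []
    for profile, seed in zip(profiles, participant_seeds):
        all_records.extend(
            simulate_participant(profile, cohort_config, task_config, seed)
        )
    trials, sessions = sessions_to_frames(all_records)
    truth = pd.DataFrame(
        [
            {
                "participant_id": p.participant_id,
                "variant": p.variant,
                "true_ssrt_ms": p.stop_mean,
                "go_mu": p.go_mu,
                "go_sigma": p.go_sigma,
                "go_tau": p.go_tau,
                "stop_sd": p.stop_sd,
                "dropout_hazard": p.dropout_hazard,
                "questionnaire_base": p.questionnaire_base,
                "questionnaire_slope": p.questionnaire_slope,
                "focus_rate": p.focus_rate,
            }
            for p in profiles
        ]
    )
    return CohortDataset(trials=trials, sessions=sessions, truth=truth)
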