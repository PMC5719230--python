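"""Subjective engagement scoring, conformance classification, attrition tables.

The enjoyment-and-engagement questionnaire is a set of 0-100 visual-analog
items; four items are negatively keyed (frustrating, hard-to-concentrate,
boring, repetitive) and reverse-scored before averaging.  Attrition is
summarized as mean sessions completed per variant and as the fraction of
participants completing at least k sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    LONG_FORM_ITEMS,
    LONG_FORM_SESSIONS,
    REVERSE_SCORED_ITEMS,
    SHORT_FORM_ITEMS,
)

VAS_LINE_PIXELS = 500  # raw response line length; scores are normalized to 0-100


def normalize_vas(pixels: float, line_pixels: int = VAS_LINE_PIXELS) -> float:
    """Map a raw click position on the response line to the 0-100 scale."""
    if not 0 <= pixels <= line_pixels:
        raise ValueError(f"pixel position {pixels} outside line [0, {line_pixels}]")
    return 100.0 * pixels / line_pixels


def form_items(session_number: int) -> tuple[int, ...]:
    return LONG_FORM_ITEMS if session_number in LONG_FORM_SESSIONS else SHORT_FORM_ITEMS


def score_questionnaire(
    response: Mapping[int, float], session_number: int
) -> Optional[float]:
    """Mean engagement score for one response, reverse-keyed items flipped.

    Negatively keyed items (2, 3, 6, 8) are mapped x -> 100 - x before
    averaging over the items of the delivered form.  Returns None (response
    excluded) when any expected item is missing.
    """
    items = form_items(session_number)
    values = []
    for item in items:
        v = response.get(item)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"item {item} score {v} outside [0, 100]")
        values.append(100.0 - v if item in REVERSE_SCORED_ITEMS else v)
    return float(np.mean(values))


def combined_score(score_s1: Optional[float], score_s4: Optional[float]) -> Optional[float]:
    """Mean of the session-1 and session-4 scores; None if either is missing."""
    if score_s1 is None or score_s4 is None:
        return None
    return (score_s1 + score_s4) / 2.0


def session_scores(sessions: pd.DataFrame) -> pd.DataFrame:
    """Score every questionnaire row of a session log.

    Returns participant_id, variant, session_number, engagement_score (NaN for
    incomplete responses, which are excluded from analyses).
    """
    rows = []
    for _, row in sessions.iterrows():
        response = {
            item: (None if pd.isna(row.get(f"q{item}")) else float(row[f"q{item}"]))
            for item in range(1, 11)
        }
        s = score_questionnaire(response, int(row["session_number"]))
        rows.append(
            {
                "participant_id": row["participant_id"],
                "variant": row.get("variant"),
                "session_number": int(row["session_number"]),
                "engagement_score": np.nan if s is None else s,
            }
        )
    return pd.DataFrame(rows)


CONFORMING = "conforming"
LOOSE = "loose"
NON = "non"


def classify_conformance(
    session_days: Iterable[int], required_sessions: int = 4, loose_window: int = 5
) -> str:
    """Classify a participant's compulsory-phase adherence.

    ``conforming``: the first ``required_sessions`` completed sessions fell on
    consecutive days 1..4 of participation.  ``loose``: four sessions were
    completed within the first ``loose_window`` days.  Anything else — fewer
    than four sessions, or a slower spread — is ``non``.
    """
    days = sorted(set(int(d) for d in session_days))
    if len(days) < required_sessions:
        return NON
    first = days[: required_sessions]
    if first == list(range(1, required_sessions + 1)):
        return CONFORMING
    if first[0] == 1 and first[-1] <= loose_window:
        return LOOSE
    return NON


@dataclass(frozen=True)
class AttritionRecord:
    participant_id: str
    variant: str
    sessions_completed: int
    conformance: str


def build_attrition_records(sessions: pd.DataFrame) -> pd.DataFrame:
    """Per-participant sessions-completed counts and conformance classes.

    Only completed sessions count (started-but-unfinished sessions are
    excluded upstream or via the ``completed`` flag).
    """
    s = sessions
    if "completed" in s:
        s = s[s["completed"].astype(bool)]
    rows = []
    for (pid, variant), grp in s.groupby(["participant_id", "variant"], sort=True):
        days = grp["calendar_day"].tolist()
        rows.append(
            {
                "participant_id": pid,
                "variant": variant,
                "sessions_completed": int(grp["session_number"].nunique()),
                "conformance": classify_conformance(days),
            }
        )
    return pd.DataFrame(rows)


def _mean_ci(x: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """Mean with t-based confidence interval."""
    x = np.asarray(x, dtype=float)
    m = float(x.mean())
    if len(x) < 2:
        return m, np.nan, np.nan
    se = x.std(ddof=1) / np.sqrt(len(x))
    tcrit = stats.t.ppf(0.5 + level / 2.0, len(x) - 1)
    return m, m - tcrit * se, m + tcrit * se


def attrition_summary(
    attrition: pd.DataFrame, max_sessions: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-variant attrition tables.

    Returns (means, survival): mean sessions completed per variant with 95%
    t-intervals, and the percentage of participants completing at least k
    sessions for k = 1..max_sessions.  Empty variants are omitted with a
    warning.
    """
    mean_rows, surv_rows = [], []
    for variant, grp in attrition.groupby("variant", sort=True):
        n = len(grp)
        if n == 0:
            warnings.warn(f"variant {variant} has no participants; omitted", RuntimeWarning)
            continue
        counts = grp["sessions_completed"].to_numpy(dtype=float)
        m, lo, hi = _mean_ci(counts)
        mean_rows.append(
            {"variant": variant, "n": n, "mean_sessions": m, "ci_low": lo, "ci_high": hi}
        )
        for k in range(1, max_sessions + 1):
            surv_rows.append(
                {
                    "variant": variant,
                    "k": k,
                    "pct_at_least_k": 100.0 * float((counts >= k).mean()),
                }
            )
    return pd.DataFrame(mean_rows), pd.DataFrame(surv_rows)
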