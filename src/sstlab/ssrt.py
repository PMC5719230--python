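"""Per-session SSRT estimation via the inhibition-function (SSD50) method.

The horse-race model of response inhibition treats the go and stop processes
as independent racers: a response escapes inhibition iff the go process
finishes before the stop process (triggered SSD ms after go onset).  Under
this model the probability of responding rises monotonically with SSD, and
the stop-signal reaction time (SSRT) can be estimated as

    SSRT = median go RT - SSD50,

where SSD50 is the stop-signal delay at which the participant inhibits 50%
of stop signals, read off a fitted logistic inhibition function.

Sessions are screened first: anticipatory responses (< 150 ms) are dropped,
and sessions violating race-model signatures (failed-stop responses must be
faster than go responses; failed-stop RTs must increase with SSD; stop
accuracy must decrease with SSD) are excluded with a recorded reason.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

EXCLUSION_REASONS = (
    "none",
    "race_rt_order",
    "ssd_rt_corr",
    "ssd_acc_corr",
    "insufficient_data",
)


@dataclass(frozen=True)
class SSRTConfig:
    """Switches and thresholds for the estimation pipeline.

    ``verbatim_rt_rule`` applies the RT-order exclusion in its inverted form
    (excluding sessions whose go RTs exceed failed-stop RTs — the literal
    reading of how study protocols sometimes word the rule, backwards
    relative to the race-model prediction); the default excludes sessions whose median failed-stop RT is
    not faster than the median go RT, the standard race-model consistency
    check.  ``presignal_as_response`` counts responses emitted before the stop
    signal appeared as stop-trial responses in the inhibition function (the go
    process won the race); switching it off drops those trials from the fit.
    """

    rt_filter_ms: float = 150.0
    min_stop_responses: int = 8
    min_distinct_ssd: int = 3
    min_go_responses: int = 2
    verbatim_rt_rule: bool = False
    presignal_as_response: bool = True
    aggregate_first_k: int = 4
    outlier_iqr_multiplier: float = 4.0


@dataclass(frozen=True)
class InhibitionFit:
    """Fitted logistic inhibition function P(respond | SSD)."""

    slope: float  # logit slope per ms, >= 0
    intercept: float
    ssd50_ms: float  # SSD at which P(respond) = P(inhibit) = 0.5
    n_stop_trials: int
    converged: bool

    def prob_respond(self, ssd_ms):
        return special.expit(self.intercept + self.slope * np.asarray(ssd_ms, dtype=float))


@dataclass(frozen=True)
class SessionSummary:
    """Derived metrics for one completed session."""

    participant_id: str
    session_number: int
    valid: bool
    exclusion_reason: str  # one of EXCLUSION_REASONS
    median_go_rt_ms: Optional[float] = None
    ssd50_ms: Optional[float] = None
    ssrt_ms: Optional[float] = None
    cv_percent: Optional[float] = None
    score: Optional[float] = None


_STOP_RESPONSE_OUTCOMES = {"stop_respond", "stop_presignal"}
_GO_RESPONSE_OUTCOMES = {"go_success", "go_error"}


def filter_trials(trials: pd.DataFrame, rt_filter_ms: float = 150.0) -> pd.DataFrame:
    """Drop anticipatory response trials (RT strictly below the cutoff).

    Trials without a response (omissions, successful inhibitions) are kept.
    """
    if trials.empty:
        return trials
    rt = pd.to_numeric(trials["rt_ms"], errors="coerce")
    keep = rt.isna() | (rt >= rt_filter_ms)
    return trials.loc[keep]


def _stop_response_mask(trials: pd.DataFrame, config: SSRTConfig) -> pd.Series:
    outcomes = _STOP_RESPONSE_OUTCOMES if config.presignal_as_response else {"stop_respond"}
    return trials["outcome"].isin(outcomes)


def check_race_model(
    session_trials: pd.DataFrame, config: SSRTConfig = SSRTConfig()
) -> tuple[bool, str]:
    """Screen one session's trials against race-model signatures.

    Checks, in order: (1) median failed-stop RT faster than median go RT
    (direction controlled by ``verbatim_rt_rule``); (2) Spearman correlation of
    SSD with per-SSD median failed-stop RT strictly positive; (3) Spearman
    correlation of SSD with per-SSD inhibition proportion strictly negative.
    The first failed check is the recorded reason.  Too few stop responses or
    fewer than ``min_distinct_ssd`` visited SSDs yield ``insufficient_data``.
    """
    t = session_trials
    stop = t[t["trial_type"] == "stop"]
    stop_resp = stop[_stop_response_mask(stop, config)]
    go_rts = pd.to_numeric(
        t.loc[t["outcome"].isin(_GO_RESPONSE_OUTCOMES), "rt_ms"], errors="coerce"
    ).dropna()

    if (
        len(stop_resp) < config.min_stop_responses
        or len(go_rts) < config.min_go_responses
        or stop["ssd_ms"].nunique() < config.min_distinct_ssd
    ):
        return False, "insufficient_data"

    med_go = float(go_rts.median())
    med_failed = float(pd.to_numeric(stop_resp["rt_ms"]).median())
    if config.verbatim_rt_rule:
        # the inverted wording, taken literally
        if med_go > med_failed:
            return False, "race_rt_order"
    else:
        # standard race-model prediction: failed-stop responses are fast
        if med_failed >= med_go:
            return False, "race_rt_order"

    by_ssd_rt = stop_resp.groupby("ssd_ms")["rt_ms"].median()
    if len(by_ssd_rt) < config.min_distinct_ssd:
        return False, "insufficient_data"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant input -> nan rho
        rho_rt, _ = stats.spearmanr(by_ssd_rt.index.to_numpy(), by_ssd_rt.to_numpy())
    if not np.isfinite(rho_rt):
        return False, "insufficient_data"
    if rho_rt <= 0:
        return False, "ssd_rt_corr"

    inhibited = stop.assign(inh=(stop["outcome"] == "stop_inhibit").astype(float))
    by_ssd_acc = inhibited.groupby("ssd_ms")["inh"].mean()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho_acc, _ = stats.spearmanr(by_ssd_acc.index.to_numpy(), by_ssd_acc.to_numpy())
    if not np.isfinite(rho_acc):
        return False, "insufficient_data"
    if rho_acc >= 0:
        return False, "ssd_acc_corr"

    return True, "none"


class InhibitionModel:
    """Monotone logistic inhibition function fitted by maximum likelihood.

    Parameters
    ----------
    ssd_ms : array-like
        Stop-signal delay of each stop trial.
    responded : array-like of bool
        Whether the participant responded (failed to stop) on each trial.

    The slope is constrained non-negative so the fitted P(respond | SSD) is
    non-decreasing.  Complete separation (every response SSD above every
    inhibition SSD) cannot be fitted; ``fit`` then returns a non-converged
    result with SSD50 set to the midpoint between the highest all-inhibit SSD
    and the lowest all-respond SSD.
    """

    def __init__(self, ssd_ms, responded):
        self.ssd = np.asarray(ssd_ms, dtype=float)
        self.responded = np.asarray(responded, dtype=bool)
        if self.ssd.shape != self.responded.shape:
            raise ValueError("ssd_ms and responded must have equal length")
        if len(self.ssd) == 0:
            raise ValueError("no stop trials supplied")
        if self.responded.all() or (~self.responded).all():
            raise ValueError("both responded and inhibited trials are required")

    def _nll(self, params):
        b0, b1 = params
        z = b0 + b1 * self.ssd
        # log-likelihood of Bernoulli with logit link, numerically stable
        return float(np.sum(np.logaddexp(0.0, z) - self.responded * z))

    def fit(self) -> InhibitionFit:
        n = len(self.ssd)
        max_inh = self.ssd[~self.responded].max()
        min_resp = self.ssd[self.responded].min()
        if min_resp > max_inh:
            # complete separation: likelihood increases without bound
            return InhibitionFit(
                slope=np.inf,
                intercept=-np.inf,
                ssd50_ms=float((max_inh + min_resp) / 2.0),
                n_stop_trials=n,
                converged=False,
            )
        scale = max(self.ssd.std(), 1.0)
        x0 = np.array([-self.ssd.mean() / scale * 0.02, 0.02])
        res = optimize.minimize(
            self._nll,
            x0,
            method="L-BFGS-B",
            bounds=[(None, None), (0.0, None)],
        )
        b0, b1 = res.x
        converged = bool(res.success) and b1 > 1e-8
        ssd50 = float(-b0 / b1) if b1 > 1e-8 else np.nan
        return InhibitionFit(
            slope=float(b1),
            intercept=float(b0),
            ssd50_ms=ssd50,
            n_stop_trials=n,
            converged=converged,
        )


def fit_inhibition_function(
    stop_trials: pd.DataFrame, config: SSRTConfig = SSRTConfig()
) -> InhibitionFit:
    """Fit the inhibition function from a stop-trial log slice."""
    stop = stop_trials[stop_trials["trial_type"] == "stop"]
    if stop["ssd_ms"].nunique() < config.min_distinct_ssd:
        raise ValueError("need >= %d distinct SSDs" % config.min_distinct_ssd)
    responded = _stop_response_mask(stop, config)
    if not config.presignal_as_response:
        stop = stop[stop["outcome"] != "stop_presignal"]
        responded = stop["outcome"].isin({"stop_respond"})
    return InhibitionModel(stop["ssd_ms"].to_numpy(dtype=float), responded.to_numpy()).fit()


def session_cv(session_trials: pd.DataFrame) -> Optional[float]:
    """Coefficient of variation of go-trial response RTs, in percent.

    100 x sample SD (n-1 denominator) / mean; undefined (None) below 2 RTs.
    """
    rts = pd.to_numeric(
        session_trials.loc[
            session_trials["outcome"].isin(_GO_RESPONSE_OUTCOMES), "rt_ms"
        ],
        errors="coerce",
    ).dropna()
    if len(rts) < 2:
        return None
    return float(100.0 * rts.std(ddof=1) / rts.mean())


def estimate_ssrt(
    session_trials: pd.DataFrame,
    participant_id: str = "",
    session_number: int = 0,
    config: SSRTConfig = SSRTConfig(),
    score: Optional[float] = None,
) -> SessionSummary:
    """Full per-session pipeline: filter, screen, fit, subtract.

    SSRT = median go-response RT minus the fitted SSD50.  Invalid sessions
    carry no SSRT but keep their exclusion reason and descriptive metrics.
    """
    t = filter_trials(session_trials, config.rt_filter_ms)
    go_rts = pd.to_numeric(
        t.loc[t["outcome"].isin(_GO_RESPONSE_OUTCOMES), "rt_ms"], errors="coerce"
    ).dropna()
    median_go = float(go_rts.median()) if len(go_rts) else None
    cv = session_cv(t)

    valid, reason = check_race_model(t, config)
    ssd50 = ssrt = None
    if valid:
        fit = fit_inhibition_function(t, config)
        if np.isfinite(fit.ssd50_ms):
            ssd50 = float(fit.ssd50_ms)
            ssrt = float(median_go - ssd50)
        else:
            valid, reason = False, "insufficient_data"
    return SessionSummary(
        participant_id=participant_id,
        session_number=session_number,
        valid=valid,
        exclusion_reason=reason,
        median_go_rt_ms=median_go,
        ssd50_ms=ssd50,
        ssrt_ms=ssrt,
        cv_percent=cv,
        score=score,
    )


def summarize_cohort(
    trials: pd.DataFrame,
    sessions: Optional[pd.DataFrame] = None,
    config: SSRTConfig = SSRTConfig(),
) -> pd.DataFrame:
    """Run the session pipeline over a whole trial log.

    Sessions flagged as started-but-not-completed in the session log are
    dropped before estimation.  Returns one row per completed session.
    """
    completed = None
    if sessions is not None and "completed" in sessions:
        completed = set(
            map(
                tuple,
                sessions.loc[sessions["completed"].astype(bool), ["participant_id", "session_number"]].itertuples(
                    index=False, name=None
                ),
            )
        )
    rows = []
    for (pid, snum), grp in trials.groupby(["participant_id", "session_number"], sort=True):
        if completed is not None and (pid, snum) not in completed:
            continue
        summary = estimate_ssrt(grp, participant_id=pid, session_number=int(snum), config=config)
        rows.append(summary.__dict__)
    return pd.DataFrame(rows)


def aggregate_participant(
    summaries: pd.DataFrame,
    sessions: Optional[pd.DataFrame] = None,
    k: int = 4,
) -> pd.DataFrame:
    """Participant-level means over the first ``k`` sessions.

    SSRT averages only the valid sessions among the first ``k``; participants
    with no valid session there get NaN mean SSRT and ``ssrt_excluded=True``
    (they drop out of SSRT comparisons, not out of the cohort).  CV and
    loss-of-focus average whatever is defined in the first ``k`` sessions.
    """
    first_k = summaries[summaries["session_number"] <= k]
    rows = []
    for pid, grp in first_k.groupby("participant_id", sort=True):
        valid = grp[grp["valid"].astype(bool)]
        mean_ssrt = float(valid["ssrt_ms"].mean()) if len(valid) else np.nan
        cvs = pd.to_numeric(grp["cv_percent"], errors="coerce").dropna()
        rows.append(
            {
                "participant_id": pid,
                "n_sessions_used": len(grp),
                "n_valid": len(valid),
                "mean_ssrt_ms": mean_ssrt,
                "ssrt_excluded": len(valid) == 0,
                "mean_cv_percent": float(cvs.mean()) if len(cvs) else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    if sessions is not None and "loss_of_focus_count" in sessions:
        lof = (
            sessions[sessions["session_number"] <= k]
            .groupby("participant_id")["loss_of_focus_count"]
            .mean()
            .rename("mean_loss_of_focus")
        )
        out = out.merge(lof, on="participant_id", how="left")
    return out


def participant_performance(trials: pd.DataFrame, k: int = 4) -> pd.DataFrame:
    """Mean go-response RT and go-trial categorization accuracy per participant
    over the first ``k`` sessions — the quantities screened for outliers."""
    t = trials[trials["session_number"] <= k]
    go = t[t["trial_type"] == "go"]
    rows = []
    for pid, grp in go.groupby("participant_id", sort=True):
        rts = pd.to_numeric(
            grp.loc[grp["outcome"].isin(_GO_RESPONSE_OUTCOMES), "rt_ms"], errors="coerce"
        ).dropna()
        responded = grp["outcome"].isin(_GO_RESPONSE_OUTCOMES)
        acc = float((grp["outcome"] == "go_success").sum() / max(len(grp), 1))
        rows.append(
            {
                "participant_id": pid,
                "mean_go_rt_ms": float(rts.mean()) if len(rts) else np.nan,
                "accuracy": acc,
            }
        )
    return pd.DataFrame(rows)


def exclude_outlier_participants(
    perf: pd.DataFrame,
    columns: tuple[str, ...] = ("mean_go_rt_ms", "accuracy"),
    iqr_multiplier: float = 4.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove participants lying more than ``iqr_multiplier`` interquartile
    ranges from the group median on any screened column.

    Returns (retained, removed).  A degenerate IQR of zero keeps only
    exact-median values on that column and emits a warning.
    """
    if len(perf) < 4:
        raise ValueError("need >= 4 participants to form quartiles")
    keep = pd.Series(True, index=perf.index)
    for col in columns:
        x = pd.to_numeric(perf[col], errors="coerce")
        med = x.median()
        iqr = x.quantile(0.75) - x.quantile(0.25)
        if iqr == 0:
            warnings.warn(
                f"degenerate IQR on {col}; retaining exact-median values only",
                RuntimeWarning,
            )
            keep &= (x == med) | x.isna()
        else:
            keep &= ((x - med).abs() <= iqr_multiplier * iqr) | x.isna()
    return perf[keep], perf[~keep]
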