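"""Cohort-level analysis: one object tying the whole pipeline together.

``CohortAnalysis`` is built from a trial log and a session log (simulated or
external), and ``fit()`` runs the full analysis the study design calls for:
conformance classification, attrition survival comparison, questionnaire
mixed ANOVA with post hoc and Bayesian pairwise tests, objective engagement
ANOVAs (coefficient of variation, loss-of-focus), the SSRT pipeline with its
race-model exclusions and outlier screen, and the next-day-return logistic
regression.  The returned ``CohortResults`` carries tidy tables, a dict of
test results, ``summary()`` text and JSON serialization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import engagement as eng
from . import ssrt as ssrt_mod
from . import stats as st
from .ssrt import SSRTConfig


@dataclass
class AnalysisConfig:
    """Analysis switches threaded through the pipeline."""

    ssrt: SSRTConfig = field(default_factory=SSRTConfig)
    censor_last: bool = True  # right-censor participants who reach the final session
    max_sessions: int = 10
    welch: bool = False
    bayes_prior_scale: float = 0.707
    include_loose: bool = False  # admit loosely conforming participants
    compulsory_sessions: int = 4


class CohortAnalysis:
    """Fit the full attrition / engagement / SSRT analysis to a cohort.

    Parameters
    ----------
    trials, sessions : DataFrame
        Trial-level and session-level logs on the package CSV schemas.
    config : AnalysisConfig
    """

    def __init__(self, trials: pd.DataFrame, sessions: pd.DataFrame, config: Optional[AnalysisConfig] = None):
        if trials.empty or sessions.empty:
            raise ValueError("empty cohort: trials and sessions must be non-empty")
        self.trials = trials
        self.sessions = sessions
        self.config = config or AnalysisConfig()

    # -- pieces ----------------------------------------------------------

    def _conforming_ids(self, attrition: pd.DataFrame) -> pd.Index:
        classes = {eng.CONFORMING}
        if self.config.include_loose:
            classes.add(eng.LOOSE)
        return attrition.loc[attrition["conformance"].isin(classes), "participant_id"]

    def _next_day_return_frame(self, sess: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
        """Pairs (day-k questionnaire score, returned day k+1) over the
        optional-phase decision days (sessions 4..9)."""
        merged = sess.merge(scores, on=["participant_id", "session_number"], how="left")
        days = sess.groupby("participant_id")["calendar_day"].apply(set).to_dict()
        rows = []
        for _, row in merged.iterrows():
            s = int(row["session_number"])
            if not 4 <= s <= 9:
                continue
            score = row.get("engagement_score")
            if pd.isna(score):
                continue
            returned = (row["calendar_day"] + 1) in days.get(row["participant_id"], set())
            rows.append({"score": float(score), "returned": int(returned)})
        return pd.DataFrame(rows)

    # -- fit -------------------------------------------------------------

    def fit(self) -> "CohortResults":
        cfg = self.config
        sess = self.sessions
        if "completed" in sess:
            sess = sess[sess["completed"].astype(bool)]

        attrition = eng.build_attrition_records(sess)
        keep_ids = self._conforming_ids(attrition)
        attrition_kept = attrition[attrition["participant_id"].isin(keep_ids)]
        sess_kept = sess[sess["participant_id"].isin(keep_ids)]
        trials_kept = self.trials[self.trials["participant_id"].isin(keep_ids)]

        # outlier screen on mean RT / accuracy over the compulsory sessions
        perf = ssrt_mod.participant_performance(trials_kept, k=cfg.compulsory_sessions)
        outlier_removed = pd.DataFrame(columns=perf.columns)
        if len(perf) >= 4:
            perf_kept, outlier_removed = ssrt_mod.exclude_outlier_participants(
                perf, iqr_multiplier=cfg.ssrt.outlier_iqr_multiplier
            )
            keep_ids = perf_kept["participant_id"]
            attrition_kept = attrition_kept[attrition_kept["participant_id"].isin(keep_ids)]
            sess_kept = sess_kept[sess_kept["participant_id"].isin(keep_ids)]
            trials_kept = trials_kept[trials_kept["participant_id"].isin(keep_ids)]

        tests: dict[str, object] = {}
        variants = sorted(attrition_kept["variant"].unique())

        # --- attrition ---------------------------------------------------
        means, survival = eng.attrition_summary(attrition_kept, cfg.max_sessions)
        groups = {
            v: g["sessions_completed"].tolist()
            for v, g in attrition_kept.groupby("variant")
        }
        km_curves = {
            v: st.km_estimate(ts) for v, ts in groups.items() if len(ts) > 0
        }
        if len(groups) >= 2:
            tests["logrank"] = st.logrank_test(
                groups, censor_at=cfg.max_sessions, censor_last=cfg.censor_last
            )
            tests["sessions_anova"] = st.oneway_anova(
                attrition_kept["sessions_completed"].to_numpy(dtype=float),
                attrition_kept["variant"].to_numpy(),
                name="sessions_anova",
            )
            for a, b in combinations(variants, 2):
                tests[f"sessions_bayes_{a}_vs_{b}"] = st.jzs_bayes_t(
                    groups[a], groups[b],
                    prior_scale=cfg.bayes_prior_scale,
                    name=f"sessions_bayes_{a}_vs_{b}",
                )

        # --- subjective engagement ---------------------------------------
        scores = eng.session_scores(sess_kept)
        s14 = scores[scores["session_number"].isin([1, cfg.compulsory_sessions])].rename(
            columns={"engagement_score": "score"}
        )
        if s14["session_number"].nunique() == 2 and s14["variant"].nunique() >= 2:
            tests.update(
                {
                    f"engagement_{k}": v
                    for k, v in st.rm_anova_2x3(s14).items()
                }
            )
            combined = (
                s14.dropna(subset=["score"])
                .groupby(["participant_id", "variant"])
                .filter(lambda g: g["session_number"].nunique() == 2)
                .groupby(["participant_id", "variant"])["score"]
                .mean()
                .reset_index()
            )
            for a, b in combinations(variants, 2):
                ga = combined.loc[combined["variant"] == a, "score"]
                gb = combined.loc[combined["variant"] == b, "score"]
                if len(ga) >= 2 and len(gb) >= 2:
                    tests[f"engagement_t_{a}_vs_{b}"] = st.posthoc_t(
                        ga, gb, name=f"engagement_t_{a}_vs_{b}", welch=cfg.welch
                    )
        else:
            combined = pd.DataFrame()

        # --- SSRT pipeline ------------------------------------------------
        summaries = ssrt_mod.summarize_cohort(trials_kept, sess_kept, cfg.ssrt)
        participants = ssrt_mod.aggregate_participant(
            summaries, sess_kept, k=cfg.compulsory_sessions
        ).merge(
            attrition_kept[["participant_id", "variant"]], on="participant_id", how="left"
        )
        ssrt_ok = participants[~participants["ssrt_excluded"]]
        if ssrt_ok["variant"].nunique() >= 2:
            tests["ssrt_anova"] = st.oneway_anova(
                ssrt_ok["mean_ssrt_ms"].to_numpy(dtype=float),
                ssrt_ok["variant"].to_numpy(),
                name="ssrt_anova",
            )
            for a, b in combinations(variants, 2):
                ga = ssrt_ok.loc[ssrt_ok["variant"] == a, "mean_ssrt_ms"]
                gb = ssrt_ok.loc[ssrt_ok["variant"] == b, "mean_ssrt_ms"]
                if len(ga) >= 2 and len(gb) >= 2:
                    tests[f"ssrt_t_{a}_vs_{b}"] = st.posthoc_t(
                        ga, gb, name=f"ssrt_t_{a}_vs_{b}", welch=cfg.welch
                    )
                    tests[f"ssrt_bayes_{a}_vs_{b}"] = st.jzs_bayes_t(
                        ga, gb,
                        prior_scale=cfg.bayes_prior_scale,
                        name=f"ssrt_bayes_{a}_vs_{b}",
                    )

        # --- objective engagement ----------------------------------------
        cv_ok = participants.dropna(subset=["mean_cv_percent"])
        if cv_ok["variant"].nunique() >= 2:
            tests["cv_anova"] = st.oneway_anova(
                cv_ok["mean_cv_percent"].to_numpy(dtype=float),
                cv_ok["variant"].to_numpy(),
                name="cv_anova",
            )
        if "mean_loss_of_focus" in participants:
            lof_ok = participants.dropna(subset=["mean_loss_of_focus"])
            if lof_ok["variant"].nunique() >= 2:
                tests["loss_of_focus_anova"] = st.oneway_anova(
                    lof_ok["mean_loss_of_focus"].to_numpy(dtype=float),
                    lof_ok["variant"].to_numpy(),
                    name="loss_of_focus_anova",
                )

        # --- next-day return ----------------------------------------------
        ret = self._next_day_return_frame(sess_kept, scores)
        if len(ret) >= 10 and ret["returned"].nunique() == 2:
            try:
                tests["logistic_return"] = st.logistic_return_model(
                    ret["score"], ret["returned"]
                )
            except ValueError:
                pass

        exclusion_tally = (
            summaries["exclusion_reason"].value_counts().to_dict() if len(summaries) else {}
        )
        return CohortResults(
            config=cfg,
            attrition=attrition,
            attrition_analyzed=attrition_kept,
            attrition_means=means,
            survival=survival,
            km_curves=km_curves,
            session_summaries=summaries,
            participants=participants,
            combined_engagement=combined,
            outliers_removed=outlier_removed,
            exclusion_tally=exclusion_tally,
            tests=tests,
        )


@dataclass
class CohortResults:
    """Everything the fitted cohort analysis produced."""

    config: AnalysisConfig
    attrition: pd.DataFrame  # all participants, with conformance class
    attrition_analyzed: pd.DataFrame  # analysis sample after screens
    attrition_means: pd.DataFrame
    survival: pd.DataFrame
    km_curves: dict
    session_summaries: pd.DataFrame
    participants: pd.DataFrame
    combined_engagement: pd.DataFrame
    outliers_removed: pd.DataFrame
    exclusion_tally: dict
    tests: dict

    def to_report_dict(self) -> dict:
        conf_counts = self.attrition["conformance"].value_counts().to_dict()
        rep = {
            "n_participants": int(self.attrition["participant_id"].nunique()),
            "n_analyzed": int(self.attrition_analyzed["participant_id"].nunique()),
            "conformance_counts": {k: int(v) for k, v in conf_counts.items()},
            "outliers_removed": int(len(self.outliers_removed)),
            "session_exclusion_tally": {
                k: int(v) for k, v in self.exclusion_tally.items()
            },
            "attrition_means": _round_records(self.attrition_means),
            "survival_pct": _round_records(self.survival),
            "tests": {k: _round_tree(v.to_dict()) for k, v in self.tests.items()},
        }
        return rep

    def to_json(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(self.to_report_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def summary(self) -> str:
        lines = ["Cohort analysis summary", "=" * 23]
        rep = self.to_report_dict()
        lines.append(
            f"participants: {rep['n_participants']} total, {rep['n_analyzed']} analyzed "
            f"({rep['conformance_counts']})"
        )
        lines.append(f"session exclusions: {rep['session_exclusion_tally']}")
        for _, r in self.attrition_means.iterrows():
            lines.append(
                f"  {r['variant']}: mean sessions {r['mean_sessions']:.2f} "
                f"(95% CI {r['ci_low']:.2f}-{r['ci_high']:.2f}, n={int(r['n'])})"
            )
        for key, t in self.tests.items():
            d = t.to_dict()
            if "bf10" in d:
                lines.append(
                    f"  {key}: BF10={d['bf10']:.3g} ({d['interpretation']}, favors {d['favors']})"
                )
            elif "odds_ratio" in d:
                lines.append(
                    f"  {key}: beta={d['beta']:.4g}, Wald chi2={d['wald_chi2']:.3g}, "
                    f"p={d['p_value']:.3g}, OR={d['odds_ratio']:.4g}"
                )
            else:
                df = ",".join(f"{x:g}" for x in d["df"])
                es = f", {d.get('effect_size_name')}={d.get('effect_size'):.3g}" if d.get("effect_size") is not None else ""
                lines.append(
                    f"  {key}: stat={d['statistic']:.4g} (df={df}), p={d['p_value']:.3g}{es}"
                )
        return "\n".join(lines)

    def plot_attrition(self, ax=None):
        """Step plot of per-variant survival (% completing at least k sessions)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for variant, grp in self.survival.groupby("variant"):
            ax.step(grp["k"], grp["pct_at_least_k"], where="post", label=variant)
        ax.set_xlabel("sessions completed (k)")
        ax.set_ylabel("% of participants completing >= k sessions")
        ax.set_ylim(0, 105)
        ax.legend(title="variant")
        return ax


def _round_tree(obj, ndigits: int = 6):
    """Round all floats for byte-stable JSON serialization."""
    if isinstance(obj, float):
        if not np.isfinite(obj):
            return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_tree(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_tree(v, ndigits) for v in obj]
    return obj


def _round_records(df: pd.DataFrame, ndigits: int = 6) -> list:
    return _round_tree(df.to_dict(orient="records"), ndigits)
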