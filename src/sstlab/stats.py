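"""Inferential layer: survival comparison, ANOVAs, Bayes factors, power.

Frequentist machinery follows the reporting conventions of behavioral
attrition studies: Kaplan-Meier survival over sessions completed with a
log-rank comparison, one-way and mixed (2 within x 3 between) ANOVAs with
partial eta-squared, pooled-variance post hoc t tests with Cohen's d, and a
logistic regression of next-day return.  The Bayesian layer is the default
Jeffreys-Zellner-Siow (JZS) two-sample t test: a Cauchy prior (scale r,
default 0.707) on the standardized effect size, integrated numerically
against the noncentral-t likelihood.  Sample-size planning inverts the
noncentral chi-square power function for an effect size phi.

No multiplicity correction is applied anywhere; each test is reported as
run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test


@dataclass(frozen=True)
class TestResult:
    """Generic frequentist test output."""

    name: str
    statistic: float
    df: tuple  # one or two components
    p_value: float
    effect_size: Optional[float] = None
    effect_size_name: Optional[str] = None
    ci_95: Optional[tuple] = None
    note: str = ""

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "statistic": self.statistic,
            "df": list(self.df),
            "p_value": self.p_value,
        }
        if self.effect_size is not None:
            d["effect_size"] = self.effect_size
            d["effect_size_name"] = self.effect_size_name
        if self.ci_95 is not None:
            d["ci_95"] = list(self.ci_95)
        if self.note:
            d["note"] = self.note
        return d


# Evidence bands for BF10 with H0 "effect size is 0" vs H1 "effect size within
# the Cauchy prior": symmetric on the log scale around BF = 1.
_BF_BANDS = (
    (1 / 3.0, 3.0, "No support either way", "neither"),
    (0.1, 1 / 3.0, "Positive", "null"),
    (3.0, 10.0, "Positive", "alternative"),
    (0.01, 0.1, "Strong", "null"),
    (10.0, 100.0, "Strong", "alternative"),
)


def interpret_bf(bf10: float) -> tuple[str, str]:
    """Map a Bayes factor to its evidence band and the hypothesis it favors."""
    if bf10 <= 0:
        raise ValueError("BF10 must be positive")
    for lo, hi, label, favors in _BF_BANDS:
        if lo <= bf10 <= hi:
            return label, favors
    return ("Decisive", "null" if bf10 < 0.01 else "alternative")


@dataclass(frozen=True)
class BayesResult:
    """JZS Bayes-factor output with its evidence-band interpretation."""

    name: str
    bf10: float
    prior_scale: float
    interpretation: str = ""
    favors: str = ""
    t_statistic: Optional[float] = None
    n: Optional[tuple] = None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "bf10": self.bf10,
            "bf01": 1.0 / self.bf10,
            "prior_scale": self.prior_scale,
            "interpretation": self.interpretation,
            "favors": self.favors,
            "t_statistic": self.t_statistic,
            "n": list(self.n) if self.n else None,
        }


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a chi-square power / sample-size calculation."""

    effect_size_phi: float
    df: int = 2
    alpha: float = 0.05
    power: float = 0.95

    def __post_init__(self):
        if self.effect_size_phi <= 0:
            raise ValueError("effect size phi must be > 0")
        if self.df < 1:
            raise ValueError("df must be >= 1")
        if not 0 < self.alpha < self.power < 1:
            raise ValueError("need 0 < alpha < power < 1")


# ---------------------------------------------------------------------------
# survival


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier product-limit estimate as a right-continuous step function."""

    times: np.ndarray  # event times, ascending
    survival: np.ndarray  # S(t) just after each time

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, event_observed=None) -> KMCurve:
    """Kaplan-Meier estimate of the survival function.

    With all events observed (the default) this equals the empirical survivor
    function.  ``times`` here are sessions completed; "death" is dropout.
    """
    times = np.asarray(list(times), dtype=float)
    if len(times) == 0:
        raise ValueError("no observations")
    if np.any(times < 1):
        raise ValueError("times must be >= 1 session")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=event_observed)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = t > 0
    return KMCurve(times=t[keep], survival=s[keep])


def logrank_test(
    groups: Mapping[str, Sequence[float]],
    censor_at: Optional[float] = 10,
    censor_last: bool = True,
) -> TestResult:
    """Log-rank comparison of dropout distributions across task variants.

    ``groups`` maps variant label to sessions-completed times.  Participants
    reaching the study cap (``censor_at``) are right-censored there when
    ``censor_last`` (the study ended; they did not "drop out"); set it False
    to treat them as events.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    times, labels, events = [], [], []
    for label, ts in groups.items():
        for t in ts:
            times.append(float(t))
            labels.append(label)
            observed = not (censor_last and censor_at is not None and t >= censor_at)
            events.append(1 if observed else 0)
    res = multivariate_logrank_test(
        np.asarray(times), np.asarray(labels), np.asarray(events)
    )
    df = len(groups) - 1
    return TestResult(
        name="logrank",
        statistic=float(res.test_statistic),
        df=(df,),
        p_value=float(res.p_value),
    )


# ---------------------------------------------------------------------------
# ANOVA family


def oneway_anova(values, labels, name: str = "oneway_anova") -> TestResult:
    """One-way between-subjects ANOVA with partial eta-squared.

    Computed from the sums-of-squares decomposition; partial eta^2 =
    SS_between / (SS_between + SS_within) (equal to eta^2 in the one-way
    design).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    grand = values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(values) - len(groups)
    if ss_within == 0:
        return TestResult(
            name=name,
            statistic=np.inf,
            df=(df_b, df_w),
            p_value=0.0 if ss_between > 0 else 1.0,
            effect_size=1.0 if ss_between > 0 else 0.0,
            effect_size_name="partial_eta_sq",
            note="zero within-group variance",
        )
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    eta = float(ss_between / (ss_between + ss_within))
    return TestResult(
        name=name,
        statistic=float(f),
        df=(df_b, df_w),
        p_value=p,
        effect_size=eta,
        effect_size_name="partial_eta_sq",
    )


def rm_anova_2x3(data: pd.DataFrame, name_prefix: str = "engagement") -> dict:
    """Mixed ANOVA: session (within, 2 levels) x task variant (between).

    ``data`` needs columns participant_id, variant, session_number, score.
    Participants missing either time point are dropped listwise.  With only
    two within-subject levels sphericity holds trivially, so no correction is
    applied.  Returns TestResults keyed 'between', 'within', 'interaction'.
    """
    import pingouin as pg

    d = data.dropna(subset=["score"]).copy()
    counts = d.groupby("participant_id")["session_number"].nunique()
    complete = counts[counts == d["session_number"].nunique()].index
    dropped = len(counts) - len(complete)
    d = d[d["participant_id"].isin(complete)]
    if dropped:
        warnings.warn(f"{dropped} participants dropped listwise (missing a time point)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(
            data=d,
            dv="score",
            within="session_number",
            subject="participant_id",
            between="variant",
        )
    key = {"variant": "between", "session_number": "within", "Interaction": "interaction"}
    out = {}
    for _, row in aov.iterrows():
        which = key.get(row["Source"])
        if which is None:
            continue
        p_unc = row["p_unc"] if "p_unc" in row else row["p-unc"]
        out[which] = TestResult(
            name=f"{name_prefix}_rm_anova_{which}",
            statistic=float(row["F"]),
            df=(float(row["DF1"]), float(row["DF2"])),
            p_value=float(p_unc),
            effect_size=float(row["np2"]),
            effect_size_name="partial_eta_sq",
        )
    return out


def posthoc_t(
    group_a, group_b, name: str = "posthoc_t", welch: bool = False
) -> TestResult:
    """Two-sample t test with Cohen's d and a CI on the mean difference.

    Default is Student's pooled-variance t (df = n1 + n2 - 2, matching the
    convention in the reported analyses); ``welch=True`` switches to the
    unequal-variance form.  No multiplicity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per group")
    n1, n2 = len(a), len(b)
    diff = a.mean() - b.mean()
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        return TestResult(
            name=name,
            statistic=np.inf if diff != 0 else 0.0,
            df=(n1 + n2 - 2,),
            p_value=0.0 if diff != 0 else 1.0,
            effect_size=np.inf if diff != 0 else 0.0,
            effect_size_name="cohen_d",
            note="zero pooled variance",
        )
    if welch:
        t, p = stats.ttest_ind(a, b, equal_var=False)
        df = (a.var(ddof=1) / n1 + b.var(ddof=1) / n2) ** 2 / (
            (a.var(ddof=1) / n1) ** 2 / (n1 - 1) + (b.var(ddof=1) / n2) ** 2 / (n2 - 1)
        )
        se = np.sqrt(a.var(ddof=1) / n1 + b.var(ddof=1) / n2)
    else:
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        t = diff / se
        df = n1 + n2 - 2
        p = 2.0 * stats.t.sf(abs(t), df)
    d = diff / np.sqrt(sp2)
    tcrit = stats.t.ppf(0.975, df)
    return TestResult(
        name=name,
        statistic=float(t),
        df=(float(df),),
        p_value=float(p),
        effect_size=float(d),
        effect_size_name="cohen_d",
        ci_95=(float(diff - tcrit * se), float(diff + tcrit * se)),
    )


# ---------------------------------------------------------------------------
# JZS Bayes factor


def jzs_bf10_from_t(t: float, n1: int, n2: int, prior_scale: float = 0.707) -> float:
    """JZS two-sample Bayes factor from a t statistic.

    BF10 is the ratio of the marginal likelihood of t under H1 (standardized
    effect delta ~ Cauchy(0, r), giving a noncentral-t likelihood with
    noncentrality delta * sqrt(n1 n2 / (n1 + n2))) to its density under H0
    (central t).  Integration by adaptive quadrature (tolerance 1e-8) over the
    effect-size prior, split at zero to keep the integrand well-behaved.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if prior_scale <= 0:
        raise ValueError("prior_scale must be > 0")
    nu = n1 + n2 - 2
    eff_n = np.sqrt(n1 * n2 / (n1 + n2))

    def integrand(delta):
        # nct.pdf is numerically fragile at extreme noncentrality (returns
        # nan where the true density has underflowed); work on the log scale
        # and treat non-finite values as zero density.
        with np.errstate(all="ignore"):
            logp = stats.nct.logpdf(t, nu, np.asarray(delta) * eff_n)
        like = np.where(np.isfinite(logp), np.exp(logp), 0.0)
        return like * stats.cauchy.pdf(delta, scale=prior_scale)

    kwargs = dict(epsabs=1e-8, epsrel=1e-8, limit=200)
    m1, err1 = integrate.quad(integrand, -np.inf, 0.0, **kwargs)
    m2, err2 = integrate.quad(integrand, 0.0, np.inf, **kwargs)
    m1h = m1 + m2
    if not np.isfinite(m1h) or m1h <= 0:
        # adaptive fallback on a wide finite window
        grid = np.linspace(-30 * prior_scale, 30 * prior_scale, 20001)
        m1h = float(np.trapezoid(integrand(grid), grid))
    m0 = stats.t.pdf(t, nu)
    return float(m1h / m0)


def jzs_bayes_t(
    group_a=None,
    group_b=None,
    t: Optional[float] = None,
    n1: Optional[int] = None,
    n2: Optional[int] = None,
    prior_scale: float = 0.707,
    name: str = "jzs_bayes_t",
) -> BayesResult:
    """JZS Bayesian two-sample t test (Cauchy prior on effect size).

    Supply either raw samples or a precomputed (t, n1, n2) triple.  H0 states
    the effect size is zero; H1 that it lies within the Cauchy prior of scale
    ``prior_scale``.  The interpretation label follows the conventional
    evidence bands (BF between 1/3 and 3: no support either way; 1/3 down to
    1/10: positive evidence for equality; and so on).
    """
    if group_a is not None:
        a = np.asarray(group_a, dtype=float)
        b = np.asarray(group_b, dtype=float)
        res = posthoc_t(a, b, welch=False)
        t = res.statistic
        n1, n2 = len(a), len(b)
    if t is None or n1 is None or n2 is None:
        raise ValueError("supply either raw groups or (t, n1, n2)")
    bf10 = jzs_bf10_from_t(t, n1, n2, prior_scale)
    label, favors = interpret_bf(bf10)
    return BayesResult(
        name=name,
        bf10=bf10,
        prior_scale=prior_scale,
        interpretation=label,
        favors=favors,
        t_statistic=float(t),
        n=(n1, n2),
    )


# ---------------------------------------------------------------------------
# logistic next-day-return model


@dataclass(frozen=True)
class LogisticReturnResult:
    """Logit fit of next-day return on the previous day's engagement score."""

    beta: float
    se: float
    wald_chi2: float
    p_value: float
    odds_ratio: float
    or_ci_95: tuple
    n: int
    separation: bool = False

    def to_dict(self) -> dict:
        return {
            "name": "logistic_return",
            "beta": self.beta,
            "se": self.se,
            "wald_chi2": self.wald_chi2,
            "df": [1],
            "p_value": self.p_value,
            "odds_ratio": self.odds_ratio,
            "or_ci_95": list(self.or_ci_95),
            "n": self.n,
            "separation": self.separation,
        }


def logistic_return_model(scores, returned) -> LogisticReturnResult:
    """Maximum-likelihood logistic regression of return-next-day on score.

    Wald chi-square is (beta / SE)^2; the odds ratio is exp(beta) with a
    profile-free Wald CI.  Complete separation is detected and reported
    rather than silently fitted.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    x = np.asarray(scores, dtype=float)
    y = np.asarray(returned, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant")
    X = sm.add_constant(x)
    # complete separation: a threshold on x splits the outcomes perfectly
    separation = bool(
        x[y == 0].max() < x[y == 1].min() or x[y == 1].max() < x[y == 0].min()
    )
    try:
        with warnings.catch_warnings():
            if separation:  # non-convergence is expected and reported
                warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        fit = sm.Logit(y, X).fit_regularized(alpha=1e-4, disp=0)
        separation = True
    beta = float(fit.params[1])
    try:
        se = float(np.sqrt(np.asarray(fit.cov_params())[1, 1]))
    except Exception:
        se = np.nan
    wald = (beta / se) ** 2 if np.isfinite(se) and se > 0 else np.nan
    p = float(stats.chi2.sf(wald, 1)) if np.isfinite(wald) else np.nan
    zcrit = stats.norm.ppf(0.975)
    with np.errstate(over="ignore"):
        ci = (float(np.exp(beta - zcrit * se)), float(np.exp(beta + zcrit * se)))
    return LogisticReturnResult(
        beta=beta,
        se=se,
        wald_chi2=float(wald),
        p_value=p,
        odds_ratio=float(np.exp(beta)),
        or_ci_95=ci,
        n=len(x),
        separation=separation,
    )


# ---------------------------------------------------------------------------
# chi-square power / sample size


def chisq_power(n: float, phi: float, df: int = 2, alpha: float = 0.05) -> float:
    """Power of a chi-square test of effect size phi at total sample size n."""
    crit = stats.chi2.ppf(1.0 - alpha, df)
    return float(stats.ncx2.sf(crit, df, n * phi * phi))


def chisq_power_n(
    spec: PowerSpec, multiple_of: Optional[int] = None, n_max: int = 10_000_000
) -> int:
    """Smallest total n achieving the target power for a chi-square test.

    Solves power(n) >= target on the noncentral chi-square distribution with
    noncentrality n * phi^2, then rounds up to an integer (optionally to the
    next multiple of the group count, the usual equal-group convenience).
    """
    phi, df, alpha, target = (
        spec.effect_size_phi,
        spec.df,
        spec.alpha,
        spec.power,
    )
    if chisq_power(n_max, phi, df, alpha) < target:
        raise ValueError("target power unattainable within n_max")
    lo, hi = 1, 2
    while chisq_power(hi, phi, df, alpha) < target:
        hi *= 2
    while lo < hi:
        mid = (lo + hi) // 2
        if chisq_power(mid, phi, df, alpha) >= target:
            hi = mid
        else:
            lo = mid + 1
    n = lo
    if multiple_of:
        n = int(np.ceil(n / multiple_of) * multiple_of)
    return int(n)
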