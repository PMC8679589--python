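"""Prognostic layer: TMTV cutoff finding and survival analysis.

Given per-subject TMTV and right-censored follow-up, the analysis mirrors the
standard prognostic workflow for metabolic tumor burden:

1. a 4-year-horizon ROC over TMTV cutoffs, censoring-aware by default
   (cumulative/dynamic ROC with inverse-probability-of-censoring weights from
   the Kaplan-Meier estimate of the censoring distribution), with the
   operating cutoff chosen by maximizing the Youden index
   (sensitivity + specificity - 1, ties broken toward the smaller cutoff);
2. dichotomization into low/high-TMTV groups at that cutoff;
3. Kaplan-Meier survival per group with the 4-year rate read off the step
   function, a two-group log-rank test, and a univariate Cox
   proportional-hazards fit (Efron tie handling) giving the hazard ratio of
   high versus low TMTV with a 95% Wald confidence interval.

The model-fitting surface is ``PrognosticModel(records).fit() ->
PrognosticResults`` with ``summary()`` and KM/ROC plotting; KM, log-rank and
Cox estimation are delegated to lifelines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import ConvergenceError, DegenerateDataError

DEFAULT_HORIZON_YEARS = 4.0


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject's follow-up: time (years), event indicator, TMTV covariate."""

    subject_id: str
    time_years: float
    event: int
    tmtv_cm3: float

    def __post_init__(self) -> None:
        if self.time_years < 0:
            raise ValueError("time_years must be >= 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in records],
                "time_years": [r.time_years for r in records],
                "event": [r.event for r in records],
                "tmtv_cm3": [r.tmtv_cm3 for r in records],
            }
        )
    required = {"time_years", "event", "tmtv_cm3"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records frame missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Time-horizon ROC and Youden cutoff
# ---------------------------------------------------------------------------

@dataclass
class CutoffResult:
    """ROC over TMTV cutoffs at a fixed horizon, with the Youden-optimal cutoff."""

    points: pd.DataFrame  # columns: cutoff, sensitivity, specificity
    auc: float
    youden_optimal_cutoff: float
    horizon_years: float
    method: str

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fpr = 1.0 - self.points["specificity"].to_numpy()
        ax.plot(fpr, self.points["sensitivity"].to_numpy(), drawstyle="steps-post")
        ax.plot([0, 1], [0, 1], ls="--", c="gray")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"{self.horizon_years:g}-y ROC (AUC = {self.auc:.2f})")
        return ax


def _censoring_survival(time: np.ndarray, event: np.ndarray):
    """KM estimate of the censoring distribution G(t) = P(censoring > t)."""
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=1 - event)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)

    def g_left(t: np.ndarray) -> np.ndarray:
        # left-continuous limit G(t-): value just before t
        idx = np.searchsorted(times, t, side="left") - 1
        out = np.where(idx >= 0, surv[np.maximum(idx, 0)], 1.0)
        return out

    return g_left


def four_year_roc(
    records,
    horizon_years: float = DEFAULT_HORIZON_YEARS,
    method: str = "km_weighted",
) -> CutoffResult:
    """ROC for predicting an event within the horizon from TMTV.

    ``method="km_weighted"`` (default) is the cumulative/dynamic time-dependent
    ROC: cases are subjects with an observed event by the horizon, weighted by
    the inverse KM censoring survival at their event time; controls are
    subjects still under observation past the horizon. ``method="naive"``
    drops subjects censored event-free before the horizon and computes a plain
    binary ROC; on censoring-free data the two coincide exactly.
    """
    if method not in ("km_weighted", "naive"):
        raise ValueError(f"unknown ROC method {method!r}")
    df = records_to_frame(records)
    time = df["time_years"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=int)
    marker = df["tmtv_cm3"].to_numpy(dtype=float)

    is_case = (event == 1) & (time <= horizon_years)
    is_control = time > horizon_years
    if not is_case.any():
        raise DegenerateDataError("no events before the horizon: ROC undefined")
    if not is_control.any():
        raise DegenerateDataError("no event-free subjects at the horizon: ROC undefined")

    if method == "km_weighted":
        g_left = _censoring_survival(time, event)
        w_case = 1.0 / g_left(time[is_case])
    else:
        w_case = np.ones(int(is_case.sum()))

    case_marker = marker[is_case]
    ctrl_marker = marker[is_control]
    w_total = w_case.sum()
    n_ctrl = len(ctrl_marker)

    cutoffs = np.unique(marker)
    sens = np.array([w_case[case_marker > c].sum() / w_total for c in cutoffs])
    spec = np.array([(ctrl_marker <= c).sum() / n_ctrl for c in cutoffs])

    # AUC by trapezoid over the full curve including the (1,0) endpoint.
    fpr = np.concatenate([[1.0], 1.0 - spec, [0.0]])
    tpr = np.concatenate([[1.0], sens, [0.0]])
    order = np.lexsort((tpr, fpr))  # ties in FPR resolved upward: upper staircase
    auc = float(np.trapezoid(tpr[order], fpr[order]))

    youden = sens + spec - 1.0
    best = np.flatnonzero(youden == youden.max())[0]  # ties -> smaller cutoff
    points = pd.DataFrame({"cutoff": cutoffs, "sensitivity": sens, "specificity": spec})
    return CutoffResult(
        points=points,
        auc=auc,
        youden_optimal_cutoff=float(cutoffs[best]),
        horizon_years=horizon_years,
        method=method,
    )


# ---------------------------------------------------------------------------
# KM, log-rank, Cox
# ---------------------------------------------------------------------------

def km_estimate(records, groups) -> dict:
    """Kaplan-Meier product-limit fit per group.

    Returns ``{group: KaplanMeierFitter}``; read ``S(t)`` with
    :func:`km_rate_at` (right-continuous step convention: the value at the
    largest event time <= t).
    """
    df = records_to_frame(records)
    groups = np.asarray(groups)
    out = {}
    for g in pd.unique(groups):
        sel = groups == g
        if not sel.any():
            raise DegenerateDataError(f"empty group {g!r}")
        kmf = KaplanMeierFitter(label=str(g))
        kmf.fit(df.loc[sel, "time_years"], df.loc[sel, "event"])
        out[g] = kmf
    return out


def km_rate_at(kmf: KaplanMeierFitter, t: float) -> float:
    """Survival probability at time t from the KM step function."""
    return float(kmf.predict(t))


def logrank_test(records, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p)."""
    df = records_to_frame(records)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise DegenerateDataError(f"log-rank test needs exactly 2 groups, got {len(levels)}")
    if df["event"].sum() == 0:
        raise DegenerateDataError("no events: log-rank test undefined")
    a = groups == levels[0]
    res = _ll_logrank(
        df.loc[a, "time_years"], df.loc[~a, "time_years"],
        df.loc[a, "event"], df.loc[~a, "event"],
    )
    return float(res.test_statistic), float(res.p_value)


def _breslow_fit(time, event, x, tol=1e-9, max_iter=50):
    """Newton maximization of the Breslow-ties partial likelihood (scalar x).

    Returns (beta, se). Raises ConvergenceError on a monotone likelihood
    (complete separation of events by the covariate).
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    event_times = np.unique(time[event == 1])
    beta = 0.0
    for _ in range(max_iter):
        score, info = 0.0, 0.0
        eta = np.exp(beta * x)
        for te in event_times:
            at_risk = time >= te
            deaths = (time == te) & (event == 1)
            dk = int(deaths.sum())
            s0 = float(np.sum(eta[at_risk]))
            s1 = float(np.sum((eta * x)[at_risk]))
            s2 = float(np.sum((eta * x * x)[at_risk]))
            score += float(np.sum(x[deaths])) - dk * s1 / s0
            info += dk * (s2 / s0 - (s1 / s0) ** 2)
        if info <= 1e-12:
            raise ConvergenceError("monotone partial likelihood: Cox fit does not converge")
        step = score / info
        beta += step
        if abs(step) < tol:
            return beta, 1.0 / math.sqrt(info)
    raise ConvergenceError(f"Breslow Cox fit did not converge in {max_iter} iterations")


def cox_univariate(
    records, high_group, ties: str = "efron"
) -> tuple[float, float, float, float]:
    """Univariate Cox PH fit on a binary covariate.

    Returns ``(hazard_ratio, ci_low, ci_high, wald_p)`` for high vs low group
    (95% Wald interval). Tie handling is Efron by default (``ties="breslow"``
    switches to an in-package Breslow Newton fit).
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie handling {ties!r}")
    df = records_to_frame(records)
    x = np.asarray(high_group, dtype=float)
    if len(np.unique(x)) < 2:
        raise DegenerateDataError("covariate has a single level: hazard ratio undefined")
    if df["event"].sum() == 0:
        raise DegenerateDataError("no events: Cox fit undefined")
    if ties == "breslow":
        beta, se = _breslow_fit(df["time_years"], df["event"], x)
    else:
        fit_df = pd.DataFrame(
            {"time_years": df["time_years"].to_numpy(), "event": df["event"].to_numpy(), "high": x}
        )
        cph = CoxPHFitter()
        try:
            cph.fit(fit_df, duration_col="time_years", event_col="event")
        except Exception as exc:  # lifelines raises on monotone likelihood
            raise ConvergenceError(f"Cox fit did not converge: {exc}") from exc
        beta = float(cph.params_["high"])
        se = float(cph.standard_errors_["high"])
    from scipy import stats as _sps

    p = float(2.0 * _sps.norm.sf(abs(beta / se)))
    return math.exp(beta), math.exp(beta - 1.96 * se), math.exp(beta + 1.96 * se), p


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """Low-vs-high group comparison at a fixed TMTV cutoff."""

    cutoff_cm3: float
    km_fits: dict
    rate_low: float
    rate_high: float
    logrank_chi2: float
    logrank_p: float
    hazard_ratio: float
    hr_ci: tuple[float, float]
    wald_p: float


class PrognosticModel:
    """Survival model of outcome against TMTV burden.

    Parameters
    ----------
    records : list[SurvivalRecord] or DataFrame
        Follow-up times (years), event indicators and TMTV per subject.
    endpoint : str
        Label only (e.g. ``"PFS"`` or ``"OS"``); carried into the results.
    """

    def __init__(self, records, endpoint: str = "PFS"):
        self.frame = records_to_frame(records)
        self.endpoint = endpoint

    def fit(
        self,
        horizon_years: float = DEFAULT_HORIZON_YEARS,
        roc_method: str = "km_weighted",
        cutoff_cm3: float | None = None,
        ties: str = "efron",
    ) -> "PrognosticResults":
        """Find the cutoff (unless given), dichotomize, and fit KM/log-rank/Cox."""
        df = self.frame
        if df["tmtv_cm3"].nunique() < 2:
            raise DegenerateDataError("all TMTV values equal: cannot dichotomize")
        roc = four_year_roc(df, horizon_years, roc_method)
        if cutoff_cm3 is None:
            cutoff_cm3 = roc.youden_optimal_cutoff
        high = df["tmtv_cm3"].to_numpy() > cutoff_cm3
        if high.all() or not high.any():
            raise DegenerateDataError("cutoff does not split the cohort into two groups")
        groups = np.where(high, "high", "low")
        km = km_estimate(df, groups)
        chi2, lr_p = logrank_test(df, groups)
        hr, lo, hi, wald_p = cox_univariate(df, high, ties=ties)
        comparison = GroupComparison(
            cutoff_cm3=float(cutoff_cm3),
            km_fits=km,
            rate_low=km_rate_at(km["low"], horizon_years),
            rate_high=km_rate_at(km["high"], horizon_years),
            logrank_chi2=chi2,
            logrank_p=lr_p,
            hazard_ratio=hr,
            hr_ci=(lo, hi),
            wald_p=wald_p,
        )
        return PrognosticResults(self, roc, comparison, horizon_years)


@dataclass
class PrognosticResults:
    """Fitted prognostic analysis: ROC/cutoff, KM rates, log-rank, Cox HR."""

    model: PrognosticModel
    roc: CutoffResult
    comparison: GroupComparison
    horizon_years: float
    extras: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """One-row table: AUC, cutoff, HR (CI), per-group horizon rates, p."""
        c = self.comparison
        return pd.DataFrame(
            [
                {
                    "endpoint": self.model.endpoint,
                    "auc": self.roc.auc,
                    "cutoff_cm3": c.cutoff_cm3,
                    "hazard_ratio": c.hazard_ratio,
                    "hr_ci_low": c.hr_ci[0],
                    "hr_ci_high": c.hr_ci[1],
                    f"high_tmtv_{self.horizon_years:g}y_survival": c.rate_high,
                    f"low_tmtv_{self.horizon_years:g}y_survival": c.rate_low,
                    "logrank_p": c.logrank_p,
                }
            ]
        )

    def to_dict(self) -> dict:
        c = self.comparison
        return {
            "endpoint": self.model.endpoint,
            "horizon_years": self.horizon_years,
            "auc": self.roc.auc,
            "cutoff_cm3": c.cutoff_cm3,
            "hazard_ratio": c.hazard_ratio,
            "hr_ci": list(c.hr_ci),
            "wald_p": c.wald_p,
            "logrank_chi2": c.logrank_chi2,
            "logrank_p": c.logrank_p,
            "rate_high": c.rate_high,
            "rate_low": c.rate_low,
            "n_subjects": int(len(self.model.frame)),
            "n_events": int(self.model.frame["event"].sum()),
        }

    def plot_km(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name, kmf in self.comparison.km_fits.items():
            kmf.plot_survival_function(ax=ax, label=f"{name} TMTV")
        ax.set_xlabel("years")
        ax.set_ylabel("survival probability")
        ax.set_title(f"{self.model.endpoint}: cutoff {self.comparison.cutoff_cm3:.0f} cm³")
        return ax

    def plot_roc(self, ax=None):
        return self.roc.plot(ax=ax)


def run_prognostic_analysis(
    records,
    endpoint: str = "PFS",
    horizon_years: float = DEFAULT_HORIZON_YEARS,
    roc_method: str = "km_weighted",
) -> PrognosticResults:
    """Convenience wrapper: ``PrognosticModel(records, endpoint).fit(...)``."""
    return PrognosticModel(records, endpoint).fit(horizon_years, roc_method)
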