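"""Score-dichotomized survival comparison: Kaplan-Meier curves, two-sample
log-rank test, and a univariate proportional-hazards hazard ratio for the
high- vs low-score groups.

The cutpoint comes from the response-classification Youden scan and is
reused unchanged here; "high" means score >= cutpoint, and with responders
scoring high a protective effect appears as HR < 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from .errors import SurvivalError

log = logging.getLogger(__name__)

HIGH, LOW = "high", "low"


@dataclass(frozen=True)
class SurvivalComparison:
    km_curves: dict[str, pd.DataFrame]   # group -> (time, survival, n_at_risk)
    logrank_statistic: float
    logrank_p: float
    hazard_ratio: float                  # high vs low
    hr_ci: tuple[float, float]
    hr_wald_p: float
    hr_reliable: bool                    # False when a group has no events
    n_events: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "logrank_statistic": self.logrank_statistic,
            "logrank_p": self.logrank_p,
            "hazard_ratio": self.hazard_ratio,
            "hr_ci": list(self.hr_ci),
            "hr_wald_p": self.hr_wald_p,
            "hr_reliable": self.hr_reliable,
            "n_events": self.n_events,
        }


def dichotomize(scores: pd.Series | np.ndarray, cutpoint: float) -> np.ndarray:
    """Group labels: high iff score >= cutpoint."""
    s = np.asarray(scores, dtype=float)
    return np.where(s >= cutpoint, HIGH, LOW)


def _validate(groups: np.ndarray, time: np.ndarray, event: np.ndarray) -> None:
    if len(set(groups)) < 2:
        raise SurvivalError("both high and low groups must be non-empty")
    if (time < 0).any():
        raise SurvivalError("survival times must be non-negative")
    if len(groups) != len(time) or len(time) != len(event):
        raise SurvivalError("groups, time and event must have equal length")


def km_logrank(groups: np.ndarray, time: np.ndarray, event: np.ndarray
               ) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Product-limit curves per group and the two-sample log-rank test."""
    groups = np.asarray(groups)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    _validate(groups, time, event)

    curves = {}
    for g in (HIGH, LOW):
        mask = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask], label=g)
        tab = kmf.event_table
        curves[g] = pd.DataFrame({
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_[g].to_numpy(),
            "n_at_risk": tab["at_risk"].reindex(kmf.survival_function_.index).to_numpy(),
        })
    hi = groups == HIGH
    res = logrank_test(time[hi], time[~hi], event_observed_A=event[hi],
                       event_observed_B=event[~hi])
    return curves, float(res.test_statistic), float(res.p_value)


def cox_hr(groups: np.ndarray, time: np.ndarray, event: np.ndarray
           ) -> tuple[float, tuple[float, float], float, bool]:
    """Univariate PH fit of the high-vs-low indicator (low = reference),
    Efron tie handling.  Returns (HR, 95% CI, Wald p, reliable)."""
    groups = np.asarray(groups)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    _validate(groups, time, event)

    events_per_group = {g: int(event[groups == g].sum()) for g in (HIGH, LOW)}
    if min(events_per_group.values()) == 0:
        log.warning("no events in one group; Cox likelihood is monotone and the "
                    "hazard-ratio CI is unreliable")
    reliable = min(events_per_group.values()) > 0
    if sum(events_per_group.values()) == 0:
        raise SurvivalError("no events observed in either group")

    df = pd.DataFrame({"time": time, "event": event,
                       "high": (groups == HIGH).astype(float)})
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    beta = float(cph.params_["high"])
    se = float(cph.standard_errors_["high"])
    hr = float(np.exp(beta))
    ci = (float(np.exp(beta - 1.959963984540054 * se)),
          float(np.exp(beta + 1.959963984540054 * se)))
    p = float(cph.summary.loc["high", "p"])
    return hr, ci, p, reliable


def compare_survival(scores: pd.Series | np.ndarray, cutpoint: float,
                     time: np.ndarray, event: np.ndarray) -> SurvivalComparison:
    """Dichotomize at the cutpoint and run KM + log-rank + Cox."""
    groups = dichotomize(scores, cutpoint)
    curves, stat, p = km_logrank(groups, time, event)
    hr, ci, wald_p, reliable = cox_hr(groups, time, event)
    events = {g: int(np.asarray(event)[groups == g].sum()) for g in (HIGH, LOW)}
    return SurvivalComparison(km_curves=curves, logrank_statistic=stat,
                              logrank_p=p, hazard_ratio=hr, hr_ci=ci,
                              hr_wald_p=wald_p, hr_reliable=reliable,
                              n_events=events)
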