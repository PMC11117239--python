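"""Kaplan-Meier survival estimation with right censoring.

Survival time runs from the time of neoplasia diagnosis, in months;
animals still alive are right-censored at their last known survival time.
The product-limit point estimates and risk tables are computed with
lifelines' ``KaplanMeierFitter`` (the field-standard implementation, using
the convention that at tied times deaths precede censorings); the
complementary log-log Greenwood confidence bands, median scan, and the
malignancy-by-treatment grouping scheme are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.stats import norm

from .cohort import Cohort, Malignancy, Outcome, PURSUED_TREATMENTS

GROUP_NEOPLASIA_NO_TREATMENT = "neoplasia_no_treatment"
GROUP_NEOPLASIA_WITH_TREATMENT = "neoplasia_with_treatment"
GROUP_DIED_NON_NEOPLASTIC = "died_non_neoplastic"


@dataclass(frozen=True)
class KMCurve:
    """Product-limit step function with risk table and Greenwood terms.

    ``variance`` holds the cumulative Greenwood sum
    ``sum d_i / (n_i (n_i - d_i))`` at each time, from which the log-log
    95% band is formed.  ``censor_marks`` are the censored observation
    times (for "+" plot symbols).
    """

    times: np.ndarray          # distinct observed times, ascending
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n_censored: np.ndarray
    survival: np.ndarray       # S(t) just after each time
    variance: np.ndarray       # cumulative Greenwood sum
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None
    censor_marks: np.ndarray | None = None
    label: str | None = None

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t (S=1 before the first time)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "time": self.times,
            "n_risk": self.n_at_risk,
            "n_event": self.n_events,
            "n_censor": self.n_censored,
            "S": self.survival,
        })
        if self.ci_lower is not None:
            df["lo"] = self.ci_lower
            df["hi"] = self.ci_upper
        return df


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    ``events[i]`` is True for an observed death at ``times[i]`` and False
    for right censoring.  At tied times deaths are processed before
    censorings.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty input: at least one observation is required")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times < 0):
        raise ValueError("survival times must be >= 0")

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    # event_table includes a synthetic time-0 row when no observation is at 0.
    mask = np.isin(np.asarray(table.index, dtype=float), np.unique(times))
    table = table[mask]
    t = np.asarray(table.index, dtype=float)
    d = table["observed"].to_numpy(dtype=float)
    c = table["censored"].to_numpy(dtype=float)
    n = table["at_risk"].to_numpy(dtype=float)
    S = kmf.survival_function_at_times(t).to_numpy(dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where((n - d) > 0, d / (n * (n - d)), 0.0)
    variance = np.cumsum(terms)

    return KMCurve(
        times=t,
        n_at_risk=n.astype(int),
        n_events=d.astype(int),
        n_censored=c.astype(int),
        survival=S,
        variance=variance,
        censor_marks=np.sort(times[~events]),
    )


def greenwood_ci(curve: KMCurve, level: float = 0.95) -> KMCurve:
    """Complementary log-log Greenwood confidence band.

    For 0 < S < 1 the band is ``exp(-exp(log(-log S) -+ z * se))`` with
    ``se = sqrt(V) / |log S|`` and V the cumulative Greenwood sum; the
    transform keeps both limits inside [0, 1].  The band degenerates to
    the point estimate where S is exactly 1 or 0.
    """
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    z = norm.ppf(0.5 + level / 2.0)
    S = curve.survival
    lo = np.empty_like(S)
    hi = np.empty_like(S)
    interior = (S > 0) & (S < 1)
    lo[~interior] = S[~interior]
    hi[~interior] = S[~interior]
    if np.any(interior):
        s = S[interior]
        se = np.sqrt(curve.variance[interior]) / np.abs(np.log(s))
        cll = np.log(-np.log(s))
        lo[interior] = np.exp(-np.exp(cll + z * se))
        hi[interior] = np.exp(-np.exp(cll - z * se))
    return replace(curve, ci_lower=np.clip(lo, 0, 1), ci_upper=np.clip(hi, 0, 1))


def median_survival(curve: KMCurve) -> float | None:
    """Smallest time with S(t) <= 0.5, or None if never reached."""
    below = np.flatnonzero(curve.survival <= 0.5)
    return None if below.size == 0 else float(curve.times[below[0]])


@dataclass
class GroupedCurves:
    """Named per-group curves plus the count of records excluded for
    unknown survival time."""

    curves: dict[tuple[str, str], KMCurve]
    n_excluded_unknown_survival: int


def group_survival(cohort: Cohort, ci_level: float = 0.95) -> GroupedCurves:
    """Kaplan-Meier curves by malignancy and neoplasia/treatment status.

    Groups are (malignancy in {malignant, benign}) x status, where status
    is ``died_non_neoplastic`` for deaths from non-neoplastic (or unknown)
    causes, and otherwise ``neoplasia_with_treatment`` /
    ``neoplasia_no_treatment`` by whether any treatment was pursued;
    animals still alive are censored within their treatment-status group.
    Records with unknown survival time or undetermined malignancy are
    excluded; the unknown-survival count is reported.
    """
    groups: dict[tuple[str, str], list[tuple[float, bool]]] = {}
    n_excluded = 0
    for r in cohort:
        if r.survival_months is None:
            n_excluded += 1
            continue
        if r.malignancy is Malignancy.undetermined:
            continue
        if r.outcome is Outcome.unknown:
            continue
        if r.outcome in (Outcome.died_other, Outcome.died_unknown_cause):
            status = GROUP_DIED_NON_NEOPLASTIC
        elif r.treatment in PURSUED_TREATMENTS:
            status = GROUP_NEOPLASIA_WITH_TREATMENT
        else:
            status = GROUP_NEOPLASIA_NO_TREATMENT
        event = r.outcome is not Outcome.alive
        groups.setdefault((r.malignancy.value, status), []).append(
            (r.survival_months, event)
        )
    curves = {}
    for key, obs in sorted(groups.items()):
        times = [t for t, _ in obs]
        events = [e for _, e in obs]
        curve = greenwood_ci(km_estimate(times, events), ci_level)
        curves[key] = replace(curve, label=f"{key[0]}:{key[1]}")
    return GroupedCurves(curves=curves, n_excluded_unknown_survival=n_excluded)


def plot_km(curves: dict, path, title: str | None = None) -> None:
    """Step plot of one or more curves with shaded 95% bands and '+'
    censor marks, written to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for name, curve in curves.items():
        t = np.r_[0.0, curve.times]
        s = np.r_[1.0, curve.survival]
        label = curve.label or (":".join(name) if isinstance(name, tuple) else str(name))
        (line,) = ax.step(t, 100 * s, where="post", label=label)
        if curve.ci_lower is not None:
            lo = np.r_[1.0, curve.ci_lower]
            hi = np.r_[1.0, curve.ci_upper]
            ax.fill_between(t, 100 * lo, 100 * hi, step="post", alpha=0.2,
                            color=line.get_color())
        if curve.censor_marks is not None and curve.censor_marks.size:
            marks_s = [100 * curve.survival_at(t_c) for t_c in curve.censor_marks]
            ax.plot(curve.censor_marks, marks_s, "+", color=line.get_color())
    ax.set_xlabel("Months from diagnosis")
    ax.set_ylabel("Survival (%)")
    ax.set_ylim(-2, 102)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
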