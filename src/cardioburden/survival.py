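"""Stage-3 engine: Kaplan-Meier curves and the Gehan-Breslow two-group test.

The product-limit estimator is computed from its defining formula,
``S(t_j) = prod_{i<=j} (1 - d_i/n_i)`` with Greenwood's variance; at tied
times events are processed before censorings (censored subjects at t are
still in the risk set at t).

The two-group comparison is the Breslow (generalized Wilcoxon / Gehan)
weighted log-rank statistic: over pooled distinct event times,

    U   = sum_j w_j (d_1j - d_j n_1j / n_j)
    Var = sum_j w_j^2 d_j (n_j - d_j) n_1j n_2j / (n_j^2 (n_j - 1))

with weight ``w_j = n_j`` (the total number at risk), which up-weights early
event times relative to the standard log-rank (``w_j = 1``, also available
via ``weights="logrank"``).  ``U^2/Var`` is referred to chi-square with one
degree of freedom; p-values are two-sided with no continuity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateStatisticsWarning, InputError

__all__ = [
    "KMCurve",
    "km_estimate",
    "GehanBreslowResult",
    "gehan_breslow_test",
    "TwoGroupSurvival",
    "TwoGroupSurvivalResults",
    "survival_report",
]


@dataclass
class KMCurve:
    """A Kaplan-Meier curve over the distinct event times of one group."""

    times: np.ndarray  # distinct event times, increasing
    n_risk: np.ndarray  # at-risk counts just before each event time
    n_events: np.ndarray
    survival: np.ndarray  # S(t_j), non-increasing, S=1 before the first event
    greenwood_var: np.ndarray
    n_subjects: int = 0

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "n_risk": self.n_risk,
                "n_events": self.n_events,
                "survival": self.survival,
                "greenwood_var": self.greenwood_var,
            }
        )

    def plot(self, ax=None, label: str | None = None, **step_kwargs):
        """Draw the survival step function (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xs = np.concatenate([[0.0], self.times])
        ys = np.concatenate([[1.0], self.survival])
        ax.step(xs, ys, where="post", label=label, **step_kwargs)
        ax.set_xlabel("time (years)")
        ax.set_ylabel("transplant-free survival S(t)")
        ax.set_ylim(0, 1.05)
        return ax


def km_estimate(time: np.ndarray, event: np.ndarray) -> KMCurve:
    """Product-limit estimate for one group.

    ``time``: follow-up times (>= 0); ``event``: 1/True = death-or-transplant,
    0/False = censored.  Censored subjects leave the risk set after their
    time, so a subject censored at an event time still counts as at risk.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if time.size == 0:
        raise InputError("km_estimate requires at least one record")
    if (time < 0).any():
        raise InputError("negative follow-up time")
    event_times = np.unique(time[event])
    n_risk = np.array([(time >= t).sum() for t in event_times])
    n_events = np.array([((time == t) & event).sum() for t in event_times])
    with np.errstate(divide="ignore", invalid="ignore"):
        survival = np.cumprod(1.0 - n_events / n_risk)
        greenwood_terms = np.where(
            n_risk > n_events, n_events / (n_risk * (n_risk - n_events)), np.inf
        )
        greenwood_var = survival**2 * np.cumsum(greenwood_terms)
    greenwood_var = np.where(survival == 0.0, 0.0, greenwood_var)
    return KMCurve(
        times=event_times,
        n_risk=n_risk,
        n_events=n_events,
        survival=survival,
        greenwood_var=greenwood_var,
        n_subjects=int(time.size),
    )


@dataclass(frozen=True)
class GehanBreslowResult:
    statistic: float  # U^2 / Var, chi-square(1) under H0
    p_value: float
    U: float
    variance: float
    weights: str


def gehan_breslow_test(
    time: np.ndarray,
    event: np.ndarray,
    group: np.ndarray,
    weights: str = "breslow",
) -> GehanBreslowResult:
    """Breslow (generalized Wilcoxon) two-group weighted log-rank test.

    ``group`` holds exactly two labels; ``U`` is accumulated for the
    lexicographically first label.  ``weights="logrank"`` switches the weight
    to 1 at every event time, recovering the standard log-rank statistic.
    Zero variance (no events, or one group never at risk at event times)
    yields p = 1 with a :class:`DegenerateStatisticsWarning`.
    """
    if weights not in ("breslow", "logrank"):
        raise InputError(f"unknown weights {weights!r}")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group)
    labels = np.unique(group)
    if labels.size != 2:
        raise InputError(f"need exactly two groups, got {labels.tolist()}")
    g1 = group == labels[0]
    event_times = np.unique(time[event])
    U = 0.0
    var = 0.0
    for t in event_times:
        at_risk = time >= t
        n_j = int(at_risk.sum())
        n1j = int((at_risk & g1).sum())
        d_j = int(((time == t) & event).sum())
        d1j = int(((time == t) & event & g1).sum())
        w = float(n_j) if weights == "breslow" else 1.0
        U += w * (d1j - d_j * n1j / n_j)
        if n_j > 1:
            var += (
                w * w * d_j * (n_j - d_j) * n1j * (n_j - n1j) / (n_j**2 * (n_j - 1))
            )
    if var <= 0.0:
        warnings.warn(
            "zero variance in Gehan-Breslow test (no informative event times)",
            DegenerateStatisticsWarning,
        )
        return GehanBreslowResult(
            statistic=0.0, p_value=1.0, U=U, variance=var, weights=weights
        )
    statistic = U * U / var
    p = float(stats.chi2.sf(statistic, df=1))
    return GehanBreslowResult(
        statistic=statistic, p_value=p, U=U, variance=var, weights=weights
    )


class TwoGroupSurvival:
    """Two-group transplant-free survival comparison, statsmodels-style.

    Built from a survival table (subject_id, group, time_years, event and
    optionally age_years); an age-eligibility floor — the study design
    analysed subjects aged six years or older — is applied at construction.
    ``fit`` estimates both Kaplan-Meier curves and runs the Gehan-Breslow
    test.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        min_age: float | None = None,
        time_col: str = "time_years",
        event_col: str = "event",
        group_col: str = "group",
        age_col: str = "age_years",
    ):
        data = data.copy()
        required = {time_col, event_col, group_col}
        missing = required - set(data.columns)
        if missing:
            raise InputError(f"survival data lacks columns {sorted(missing)}")
        groups_before = set(data[group_col].unique())
        if min_age is not None:
            if age_col not in data.columns:
                raise InputError(
                    f"min_age filter requested but no {age_col!r} column present"
                )
            data = data[data[age_col] >= min_age]
            if data.empty:
                raise InputError("age filter removed every subject")
            emptied = groups_before - set(data[group_col].unique())
            if emptied:
                raise InputError(f"age filter emptied group(s) {sorted(emptied)}")
        if (data[time_col] < 0).any():
            raise InputError("negative follow-up time")
        if data[group_col].nunique() != 2:
            raise InputError("need exactly two groups")
        self.data = data
        self.time_col, self.event_col, self.group_col = time_col, event_col, group_col

    @classmethod
    def from_table(cls, path, min_age: float | None = None) -> "TwoGroupSurvival":
        from .io import read_survival_table

        return cls(read_survival_table(path), min_age=min_age)

    def fit(self, weights: str = "breslow") -> "TwoGroupSurvivalResults":
        d = self.data
        curves: dict[str, KMCurve] = {}
        group_sizes: dict[str, int] = {}
        median_followup: dict[str, float] = {}
        for label, sub in d.groupby(self.group_col, sort=True):
            curves[str(label)] = km_estimate(
                sub[self.time_col].to_numpy(), sub[self.event_col].to_numpy()
            )
            group_sizes[str(label)] = len(sub)
            median_followup[str(label)] = float(sub[self.time_col].median())
        test = gehan_breslow_test(
            d[self.time_col].to_numpy(),
            d[self.event_col].to_numpy(),
            d[self.group_col].to_numpy(),
            weights=weights,
        )
        return TwoGroupSurvivalResults(
            model=self,
            curves=curves,
            group_sizes=group_sizes,
            median_followup=median_followup,
            test=test,
        )


@dataclass
class TwoGroupSurvivalResults:
    model: TwoGroupSurvival
    curves: dict[str, KMCurve]
    group_sizes: dict[str, int]
    median_followup: dict[str, float]
    test: GehanBreslowResult

    @property
    def statistic(self) -> float:
        return self.test.statistic

    @property
    def p_value(self) -> float:
        return self.test.p_value

    def curves_frame(self) -> pd.DataFrame:
        """Long-format (group, time, survival) table suitable for plotting."""
        frames = []
        for label, curve in self.curves.items():
            f = curve.to_frame()
            f.insert(0, "group", label)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def plot(self, ax=None):
        for label, curve in self.curves.items():
            ax = curve.plot(ax=ax, label=f"{label} (n={self.group_sizes[label]})")
        ax.legend()
        return ax

    def summary(self) -> str:
        lines = ["Transplant-free survival comparison", "=" * 40]
        for label in self.group_sizes:
            lines.append(
                f"{label}: n = {self.group_sizes[label]}, "
                f"median follow-up {self.median_followup[label]:.2f} y, "
                f"events {int(self.curves[label].n_events.sum())}"
            )
        lines.append(
            f"Gehan-Breslow ({self.test.weights} weights) "
            f"chi2(1) = {self.test.statistic:.3f}, p = {self.test.p_value:.3g}"
        )
        return "\n".join(lines)


def survival_report(
    records: pd.DataFrame, min_age: float | None = 6.0
) -> TwoGroupSurvivalResults:
    """Age-filter, estimate both curves, and test — one-call report."""
    return TwoGroupSurvival(records, min_age=min_age).fit()
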