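"""Kaplan-Meier estimation, log-rank comparison, and Mantel-Haenszel hazard ratio.

Time-to-event analysis of score-defined groups (PFS and OS measured in months
from the first anti-PD-1 dose; alive / lost-to-follow-up subjects are
censored). The product-limit curve is fitted with lifelines; the log-rank
statistic and the (O/E)-based Mantel-Haenszel hazard ratio are tabulated from
the pooled risk sets, the hazard-ratio convention followed by Prism-style
log-rank output. Ties at an event time are processed in a single risk-set
step; subjects censored at t remain at risk at t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from scipy.stats import chi2, norm

from .errors import ValidationError


@dataclass
class SurvivalCurve:
    """Product-limit estimate: right-continuous step function S(t)."""

    times: np.ndarray       # distinct observed times (events and censorings)
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray    # S(t) just after each time
    median: float           # smallest t with S(t) <= 0.5; NaN when never reached

    @property
    def median_defined(self) -> bool:
        return bool(np.isfinite(self.median))

    def survival_at(self, t: float) -> float:
        """S(t) of the right-continuous step function."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _check_dataset(times, events, name="dataset"):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValidationError(f"{name} is empty")
    if (times <= 0).any():
        raise ValidationError(f"{name} has non-positive times")
    if not np.isin(events, (0, 1)).all():
        raise ValidationError(f"{name} event flags must be 0/1")
    return times, events


def km_curve(times, events) -> SurvivalCurve:
    """Kaplan-Meier curve for a single group."""
    times, events = _check_dataset(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 else kmf.event_table
    med = float(kmf.median_survival_time_)
    return SurvivalCurve(
        times=table.index.to_numpy(dtype=float),
        at_risk=table["at_risk"].to_numpy(dtype=int),
        events=table["observed"].to_numpy(dtype=int),
        survival=kmf.survival_function_["KM_estimate"].iloc[1:].to_numpy(dtype=float)
        if kmf.survival_function_.index[0] == 0
        else kmf.survival_function_["KM_estimate"].to_numpy(dtype=float),
        median=med if np.isfinite(med) else float("nan"),
    )


def _logrank_tabulate(times_a, events_a, times_b, events_b):
    """Observed/expected events in group A and hypergeometric variance."""
    all_event_times = np.unique(np.concatenate([
        times_a[events_a == 1], times_b[events_b == 1]
    ]))
    if len(all_event_times) == 0:
        raise ValidationError("no events in either group")
    o_a = e_a = var = 0.0
    o_b = e_b = 0.0
    for t in all_event_times:
        n_a = int((times_a >= t).sum())
        n_b = int((times_b >= t).sum())
        d_a = int(((times_a == t) & (events_a == 1)).sum())
        d_b = int(((times_b == t) & (events_b == 1)).sum())
        n, d = n_a + n_b, d_a + d_b
        o_a += d_a
        o_b += d_b
        e_a += d * n_a / n
        e_b += d * n_b / n
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    return o_a, e_a, o_b, e_b, var


def logrank_test(times_a, events_a, times_b, events_b):
    """Two-group log-rank (Mantel-Cox) test: (chi_square, p) with 1 df."""
    times_a, events_a = _check_dataset(times_a, events_a, "group A")
    times_b, events_b = _check_dataset(times_b, events_b, "group B")
    o_a, e_a, _, _, var = _logrank_tabulate(times_a, events_a, times_b, events_b)
    if var <= 0:
        raise ValidationError("degenerate log-rank variance")
    stat = (o_a - e_a) ** 2 / var
    return float(stat), float(chi2.sf(stat, df=1))


def mh_hazard_ratio(times_a, events_a, times_b, events_b, level: float = 0.95):
    """Mantel-Haenszel hazard ratio (O_A/E_A)/(O_B/E_B) with log-scale CI.

    hr < 1 means group A has the lower hazard. The confidence interval is
    exp(ln hr +/- z * sqrt(1/E_A + 1/E_B)).
    """
    times_a, events_a = _check_dataset(times_a, events_a, "group A")
    times_b, events_b = _check_dataset(times_b, events_b, "group B")
    o_a, e_a, o_b, e_b, _ = _logrank_tabulate(times_a, events_a, times_b, events_b)
    if e_a <= 0 or e_b <= 0:
        raise ValidationError("zero expected events in one group")
    if o_a == 0 or o_b == 0:
        raise ValidationError("zero observed events in one group; hazard ratio degenerate")
    hr = (o_a / e_a) / (o_b / e_b)
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(1.0 / e_a + 1.0 / e_b)
    return float(hr), float(hr * np.exp(-half)), float(hr * np.exp(half))
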