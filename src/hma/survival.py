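"""Kaplan–Meier estimation and two-group log-rank comparison.

Both statistics are implemented directly from their defining formulas:

* Product-limit estimator  S(t) = Π_{tᵢ ≤ t} (1 − dᵢ/nᵢ)  with Greenwood's
  variance  Var[S(t)] = S(t)² Σ dᵢ / (nᵢ (nᵢ − dᵢ)).
* Unweighted log-rank: at each distinct event time the expected number of
  group-1 events under the null is the hypergeometric mean d·n₁/n with
  variance d (n₁/n)(n₂/n)(n − d)/(n − 1); the statistic
  (Σ(O₁ − E₁))² / ΣV is referred to χ²₁.

Ties between an event and a censoring at the same time follow the standard
convention: events are processed first, so subjects censored at t are still
at risk at t.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["KMCurve", "LogrankResult", "km_estimate", "logrank_test", "bonferroni"]


@dataclass
class KMCurve:
    """A Kaplan–Meier step function over the distinct event times."""

    event_times: np.ndarray  # distinct event times, ascending
    at_risk: np.ndarray  # nᵢ just before each event time
    events: np.ndarray  # dᵢ at each event time
    survival: np.ndarray  # S(tᵢ)
    greenwood_var: np.ndarray  # Var[S(tᵢ)]

    def survival_at(self, t: float) -> float:
        """S(t) of the right-continuous step function (S = 1 before the first event)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
                "greenwood_var": self.greenwood_var,
            }
        )


class LogrankResult(NamedTuple):
    chi_square: float
    p_value: float


def _clean(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    if t.shape != e.shape:
        raise ValueError("time and event must have equal length")
    if t.size == 0:
        raise ValueError("at least one record required")
    if (t <= 0).any() or not np.isfinite(t).all():
        raise ValueError("follow-up times must be positive and finite")
    return t, e


def km_estimate(time: Sequence[float], event: Sequence[bool]) -> KMCurve:
    """Product-limit survival estimate from right-censored follow-up data.

    ``event`` is True where death was observed, False where the subject was
    censored.  The estimate is invariant to record order.
    """
    t, e = _clean(time, event)
    ev_times = np.unique(t[e])
    at_risk = np.empty(ev_times.size, dtype=np.int64)
    d = np.empty(ev_times.size, dtype=np.int64)
    for i, ti in enumerate(ev_times):
        at_risk[i] = int((t >= ti).sum())  # censored at ti still at risk
        d[i] = int((e & (t == ti)).sum())
    surv = np.cumprod(1.0 - d / at_risk)
    # Greenwood terms are undefined once n == d (S drops to 0); variance is 0 there.
    terms = np.where(at_risk > d, d / (at_risk * np.maximum(at_risk - d, 1)), 0.0)
    var = surv**2 * np.cumsum(terms)
    return KMCurve(
        event_times=ev_times, at_risk=at_risk, events=d, survival=surv, greenwood_var=var
    )


def logrank_test(
    time: Sequence[float],
    event: Sequence[bool],
    group: Sequence[str],
    weighting: str = "logrank",
) -> LogrankResult:
    """Two-group log-rank test (optionally Gehan–Wilcoxon weighted).

    ``weighting='logrank'`` uses unit weights; ``'wilcoxon'`` weights each
    event time by the total number at risk (Gehan–Breslow), emphasising
    early differences.  Returns the χ² statistic (1 df) and its p-value.
    """
    if weighting not in ("logrank", "wilcoxon"):
        raise ValueError(f"unknown weighting {weighting!r}")
    t, e = _clean(time, event)
    g = np.asarray(group)
    if g.shape != t.shape:
        raise ValueError("group must have the same length as time")
    names = np.unique(g)
    if names.size != 2:
        raise ValueError(f"exactly two groups required, got {list(names)}")
    in1 = g == names[0]
    if in1.all() or not in1.any():
        raise ValueError("each group needs at least one subject")
    if not e.any():
        raise ValueError("at least one observed event is required")

    u = 0.0  # Σ w (O₁ − E₁)
    var = 0.0  # Σ w² V
    for ti in np.unique(t[e]):
        at = t >= ti
        n = int(at.sum())
        n1 = int((at & in1).sum())
        d = int((e & (t == ti)).sum())
        d1 = int((e & (t == ti) & in1).sum())
        w = float(n) if weighting == "wilcoxon" else 1.0
        u += w * (d1 - d * n1 / n)
        if n > 1:
            var += w**2 * d * (n1 / n) * (1.0 - n1 / n) * (n - d) / (n - 1)
    if var == 0.0:
        return LogrankResult(0.0, 1.0)
    chi2 = u**2 / var
    return LogrankResult(float(chi2), float(stats.chi2.sf(chi2, df=1)))


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni-adjusted p-values (optional; no correction is applied by default)."""
    k = len(p_values)
    return [min(1.0, float(p) * k) for p in p_values]
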