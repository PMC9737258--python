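"""Phenotype metrics (drug response, proliferation, invasion) and rank concordance.

Three scalar metrics are computed per patient-derived line:

* ``resistance`` — normalised area under the dose–viability curve on a
  log10-dose axis (mean viability over the tested dose range, in [0, 1]);
  1 is fully resistant, 0 fully sensitive.  Chosen over an IC50 fit because
  it stays defined for flat (fully resistant) curves and few doses.
* ``growth_rate`` — least-squares slope of ln(OD) against time (h⁻¹),
  insensitive to seeding density.
* ``invasion_change`` — relative change in invaded area from 0 h to 72 h.

Metrics are ranked with the same semantics as the spatial ranking (rank 1 =
most sensitive / slowest / least invasive) and compared to the spatial rank
table by Spearman correlation and subgroup agreement.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import rank_table

__all__ = [
    "resistance_metric",
    "growth_rate",
    "invasion_change",
    "compute_phenotype_metrics",
    "rank_and_split",
    "concordance",
]


def resistance_metric(doses_uM, viability) -> float:
    """Trapezoidal mean viability over log10(dose), clipped to [0, 1].

    Replicate rows are averaged per dose first.  A dose-0 row, when present,
    is used only to normalise the positive-dose viabilities and is excluded
    from the integration (log scale).  Negative doses are rejected.
    """
    d = np.asarray(doses_uM, dtype=float)
    v = np.asarray(viability, dtype=float)
    if d.shape != v.shape:
        raise ValueError("doses and viabilities must have equal length")
    if (d < 0).any():
        raise ValueError("non-positive doses other than the 0-dose control are not allowed")
    df = pd.DataFrame({"d": d, "v": v}).groupby("d", sort=True)["v"].mean()
    if len(df) < 3:
        raise ValueError(f"at least 3 distinct doses required, got {len(df)}")
    if 0.0 in df.index:
        v0 = df.loc[0.0]
        df = df.drop(index=0.0)
        if v0 > 0:
            df = df / v0
    if len(df) < 2:
        raise ValueError("at least 2 positive doses required for the log-dose trapezoid")
    x = np.log10(df.index.to_numpy())
    y = df.to_numpy()
    auc = np.trapezoid(y, x) / (x[-1] - x[0])
    return float(np.clip(auc, 0.0, 1.0))


def growth_rate(time_h, od) -> float:
    """Least-squares slope of ln(OD) versus time, in h⁻¹.

    Non-positive OD readings are dropped with a warning; fewer than three
    usable points leave the metric missing (NaN).
    """
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.shape != y.shape:
        raise ValueError("time and od must have equal length")
    ok = y > 0
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} non-positive OD reading(s)", stacklevel=2)
    t, y = t[ok], y[ok]
    if t.size < 3:
        warnings.warn("fewer than 3 positive OD readings; growth rate missing", stacklevel=2)
        return float("nan")
    slope, _ = np.polyfit(t, np.log(y), 1)
    return float(slope)


def invasion_change(time_h, area_um2, t_start: float = 0.0, t_end: float = 72.0) -> float:
    """Relative change in invaded area between ``t_start`` and ``t_end``.

    Replicates are averaged per time point.  A zero starting area leaves
    the metric missing (NaN) with a warning.
    """
    t = np.asarray(time_h, dtype=float)
    a = np.asarray(area_um2, dtype=float)
    if t.shape != a.shape:
        raise ValueError("time and area must have equal length")
    if (a < 0).any():
        raise ValueError("areas must be non-negative")
    series = pd.DataFrame({"t": t, "a": a}).groupby("t", sort=True)["a"].mean()
    for needed in (t_start, t_end):
        if needed not in series.index:
            raise ValueError(f"area at {needed} h is required but absent")
    a0, a1 = float(series.loc[t_start]), float(series.loc[t_end])
    if a0 == 0.0:
        warnings.warn("invaded area at start time is 0; invasion change missing", stacklevel=2)
        return float("nan")
    return (a1 - a0) / a0


def compute_phenotype_metrics(
    doses: pd.DataFrame, growth: pd.DataFrame, invasion: pd.DataFrame
) -> pd.DataFrame:
    """Per-label metrics from the three long-format phenotype tables.

    Expected columns — doses: label, dose_uM, viability; growth: label,
    time_h, od; invasion: label, time_h, area_um2.  Labels absent from a
    table get NaN for that metric.
    """
    labels = sorted(
        set(doses["label"]) | set(growth["label"]) | set(invasion["label"])
    )
    rows = []
    for label in labels:
        ds = doses[doses["label"] == label]
        gr = growth[growth["label"] == label]
        iv = invasion[invasion["label"] == label]
        rows.append(
            {
                "label": label,
                "resistance": (
                    resistance_metric(ds["dose_uM"], ds["viability"]) if len(ds) else float("nan")
                ),
                "growth_rate": growth_rate(gr["time_h"], gr["od"]) if len(gr) else float("nan"),
                "invasion_change": (
                    invasion_change(iv["time_h"], iv["area_um2"]) if len(iv) else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)


def rank_and_split(
    metrics: Mapping[str, float], high_last: bool = True, split: int | None = None
) -> pd.DataFrame:
    """Rank a metric with the spatial-ranking semantics.

    With ``high_last=True`` (default) high metric values receive the last
    ranks — resistant / fast-growing / highly invasive lines rank last, the
    same orientation as external spatial types.  Missing metrics are
    excluded with a warning and the subgroup split shrinks accordingly.
    """
    return rank_table(metrics, ascending=high_last, split=split)


def concordance(a: pd.DataFrame, b: pd.DataFrame) -> tuple[float, float]:
    """Spearman rank correlation and subgroup agreement of two rank tables.

    Both tables must carry columns label, rank, subgroup over the same
    label set.  Returns ``(spearman_rho, group_agreement)`` where
    agreement is the fraction of labels with matching subgroup.
    """
    for name, t in (("a", a), ("b", b)):
        missing = {"label", "rank", "subgroup"} - set(t.columns)
        if missing:
            raise ValueError(f"table {name} missing columns: {sorted(missing)}")
    la, lb = set(a["label"]), set(b["label"])
    if la != lb:
        raise ValueError(
            f"rank tables cover different labels: only-in-a={sorted(la - lb)}, "
            f"only-in-b={sorted(lb - la)}"
        )
    merged = a.merge(b, on="label", suffixes=("_a", "_b"))
    rho = stats.spearmanr(merged["rank_a"], merged["rank_b"]).statistic
    agreement = float((merged["subgroup_a"] == merged["subgroup_b"]).mean())
    return float(rho), agreement
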