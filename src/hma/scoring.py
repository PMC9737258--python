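"""Radial spatial-configuration scores, reference classification and ranking.

The zone profile of a population is summarised by the area-weighted mean
zone index (Σ k·f_k over zones k = 1..n): 1 means all signal in the
innermost zone, n all signal at the rim.  Scores are compared against the
two reference cell lines (U251, strongly self-adhesive and internal; U87,
weakly adhesive and external) to call a test population internal,
intermediate or external, and populations are ranked from 1 (most internal,
strongest homotypic affinity) upward, then split into internal/external
subgroups at the median rank — the 4/4 split when eight patient lines are
ranked.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "radial_score",
    "classify_configuration",
    "rank_populations",
    "rank_table",
    "score_profiles",
]


def radial_score(fractions) -> float:
    """Area-weighted mean zone index of a zone-occupancy profile.

    Returns NaN for a missing profile (``None`` or any non-finite entry);
    otherwise requires the fractions to be non-negative and sum to 1.
    """
    if fractions is None:
        return float("nan")
    f = np.asarray(fractions, dtype=float)
    if not np.isfinite(f).all():
        return float("nan")
    if (f < 0).any():
        raise ValueError(f"fractions must be non-negative, got {f}")
    if abs(float(f.sum()) - 1.0) > 1e-6:
        raise ValueError(f"fractions must sum to 1, got sum={f.sum()!r}")
    k = np.arange(1, len(f) + 1, dtype=float)
    return float(k @ f)


def classify_configuration(
    test_score: float,
    ref_inner_score: float,
    ref_outer_score: float,
    margin: float = 0.0,
) -> str:
    """Call a population internal/intermediate/external against the references.

    ``internal`` when the test score lies below the inner reference by more
    than ``margin``; ``external`` symmetric above the outer reference;
    ``intermediate`` otherwise (ties with a reference are intermediate).
    """
    if margin < 0:
        raise ValueError(f"margin must be >= 0, got {margin}")
    for name, v in (
        ("test_score", test_score),
        ("ref_inner_score", ref_inner_score),
        ("ref_outer_score", ref_outer_score),
    ):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")
    if ref_inner_score > ref_outer_score:
        warnings.warn(
            "ref_inner score exceeds ref_outer score; swapping references",
            stacklevel=2,
        )
        ref_inner_score, ref_outer_score = ref_outer_score, ref_inner_score
    if abs(ref_outer_score - ref_inner_score) <= 2.0 * margin:
        raise ValueError(
            "reference scores are indistinguishable at this margin "
            f"(|{ref_inner_score} - {ref_outer_score}| <= 2*{margin})"
        )
    if test_score < ref_inner_score - margin:
        return "internal"
    if test_score > ref_outer_score + margin:
        return "external"
    return "intermediate"


def rank_table(
    scores: Mapping[str, float],
    ascending: bool = True,
    split: int | None = None,
) -> pd.DataFrame:
    """Rank labels by score and split into internal/external subgroups.

    Ranks are 1..n ascending in score (or descending when
    ``ascending=False``); ties are broken by label lexicographic order so
    the table is deterministic.  Labels with missing (NaN) scores are
    excluded with a warning.  Subgroup is ``internal`` for rank ≤ split
    (default ⌈n/2⌉, the median split), ``external`` otherwise.
    """
    items = []
    for label, score in scores.items():
        if score is None or not math.isfinite(score):
            warnings.warn(f"label {label!r} has no score; excluded from ranking", stacklevel=2)
            continue
        items.append((label, float(score)))
    if len(items) < 2:
        raise ValueError(f"at least two scored labels required, got {len(items)}")
    sign = 1.0 if ascending else -1.0
    items.sort(key=lambda t: (sign * t[1], t[0]))
    n = len(items)
    if split is None:
        split = math.ceil(n / 2)
    if not 0 <= split <= n:
        raise ValueError(f"split must be in [0, {n}], got {split}")
    return pd.DataFrame(
        {
            "label": [l for l, _ in items],
            "score": [s for _, s in items],
            "rank": np.arange(1, n + 1),
            "subgroup": ["internal" if r <= split else "external" for r in range(1, n + 1)],
        }
    )


def rank_populations(scores: Mapping[str, float], split: int | None = None) -> pd.DataFrame:
    """Rank populations from 1 (most internal) to n (most external)."""
    return rank_table(scores, ascending=True, split=split)


def score_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-population radial scores from a long-format zone-profile table.

    Expects columns ``well_id, channel, zone, fraction`` (one row per
    channel and zone per well).  A radial score is computed per
    (well, channel); replicate wells are averaged per channel and their
    spread reported.  Returns columns label, score, score_sd, n_wells.
    """
    required = {"well_id", "channel", "zone", "fraction"}
    missing = required - set(profiles.columns)
    if missing:
        raise ValueError(f"profile table missing columns: {sorted(missing)}")
    per_well = []
    for (well, channel), grp in profiles.groupby(["well_id", "channel"], sort=True):
        grp = grp.sort_values("zone")
        fr = grp["fraction"].to_numpy(dtype=float)
        score = float("nan") if np.isnan(fr).any() else radial_score(fr)
        per_well.append({"well_id": well, "label": channel, "score": score})
    pw = pd.DataFrame(per_well)
    out = (
        pw.groupby("label")["score"]
        .agg(score="mean", score_sd="std", n_wells="count")
        .reset_index()
    )
    return out
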