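"""Average daily gain (ADG) from weekly weights, outlier removal and
quartile grouping.

ADG = (end weight - start weight) / (end age - start age), in g/day over
the full production period, which corrects for rounds of unequal length.
Extreme ADG values (beyond four within-round SDs) remove the bird
entirely — row-wise — from all downstream tables.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "average_daily_gain",
    "growth_records",
    "adg_outlier_filter",
    "adg_quartile_groups",
]

ADG_OUTLIER_K = 4.0


def average_daily_gain(start_weight_g: float, end_weight_g: float,
                       start_age: float, end_age: float) -> float:
    """(we - ws) / (ae - as), g/day."""
    if end_age <= start_age:
        raise ValueError("end age must exceed start age")
    if start_weight_g < 0 or end_weight_g < 0:
        raise ValueError("weights must be non-negative")
    return (end_weight_g - start_weight_g) / (end_age - start_age)


def growth_records(weights: pd.DataFrame, rounds, roster) -> pd.DataFrame:
    """Per-bird growth table from a weight table.

    ``weights`` has columns bird_id, age_days, weight_g; the start/end
    weights are those recorded at each round's start and end ages. Birds
    lacking either weight are dropped (e.g. removed from the pen before
    the end of the round, so no end weight exists).
    """
    by_round_age = {r.round_id: (r.start_age, r.end_age) for r in rounds}
    bird_round = {tag: rid for rid, tags in roster.items() for tag in tags}
    rows = []
    for bird, sub in weights.groupby("bird_id", sort=True):
        rid = bird_round.get(bird)
        if rid is None:
            continue
        sa, ea = by_round_age[rid]
        w = dict(zip(sub["age_days"], sub["weight_g"]))
        if sa not in w or ea not in w:
            continue
        rows.append({
            "bird_id": bird, "round_id": rid,
            "start_weight_g": float(w[sa]), "end_weight_g": float(w[ea]),
            "start_age": sa, "end_age": ea,
            "adg": average_daily_gain(w[sa], w[ea], sa, ea),
        })
    return pd.DataFrame(rows, columns=["bird_id", "round_id", "start_weight_g",
                                       "end_weight_g", "start_age", "end_age", "adg"])


def adg_outlier_filter(records: pd.DataFrame, k: float = ADG_OUTLIER_K):
    """Remove birds whose ADG lies beyond k within-round SDs, row-wise.

    Mean and SD (n-1 denominator) are computed from all birds in the
    round, including the candidate. Returns (retained, removed) frames.
    """
    adg = records["adg"].to_numpy(dtype=float)
    rounds = records["round_id"].to_numpy()
    flag = np.zeros(len(records), dtype=bool)
    for rid in pd.unique(rounds):
        sel = rounds == rid
        if sel.sum() < 2:
            continue
        mu, sd = adg[sel].mean(), adg[sel].std(ddof=1)
        flag[sel] = np.abs(adg[sel] - mu) > k * sd
    return (records.loc[~flag].reset_index(drop=True),
            records.loc[flag].reset_index(drop=True))


def adg_quartile_groups(records: pd.DataFrame, min_birds: int = 8):
    """Label the ADG tails, pooled across rounds.

    low: ADG <= 25th percentile; high: ADG >= 75th percentile (linear
    interpolation between order statistics); everything else mid. Ties at
    a threshold are inclusive on both tails. Returns (labelled records,
    thresholds dict). When all ADG values tie, both quantiles coincide
    and every bird falls in both tails — flagged degenerate with a
    warning rather than an error.
    """
    if len(records) < min_birds:
        raise ValueError(f"need at least {min_birds} birds for quartile groups")
    adg = records["adg"].to_numpy(dtype=float)
    q25, q75 = np.percentile(adg, [25, 75])
    labels = np.where(adg <= q25, "low", np.where(adg >= q75, "high", "mid"))
    degenerate = bool(q25 == q75)
    if degenerate:
        warnings.warn("ADG quartile thresholds coincide; tail groups overlap "
                      "and are not usable", stacklevel=2)
    out = records.copy()
    out["quartile"] = labels
    thresholds = {"low_max": float(q25), "high_min": float(q75),
                  "degenerate": degenerate,
                  "n_low": int((adg <= q25).sum()),
                  "n_high": int((adg >= q75).sum())}
    return out, thresholds
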