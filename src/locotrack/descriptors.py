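"""Per-bird activity descriptors over the first two weeks of life.

Five scalars summarise each bird's daily activity series (ages up to and
including 15 d):

* **MD** — mean of the daily average distance moved per hour (m/h);
* **Skew** — skewness of the daily values (moment ratio scaled by
  ((n-1)/n)^{3/2}, the default of the R package ``e1071``);
* **RMSE** — root mean square (divisor n) of residuals from the bird's
  own OLS line of DADM on age: day-to-day variability around its trend;
* **AC** — lag-1 autocorrelation of those residuals, computed as the
  Pearson correlation over complete consecutive-age pairs;
* **ENT** — mean daily sample entropy of a 64-point sequence of 15-min
  activity classes derived from minute-level antenna switches.

Missing days are excluded per bird; extreme values (beyond four within-
round SDs) are masked to missing cell-wise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DaySchedule

__all__ = [
    "TrendFit",
    "ActivityClassSeries",
    "CLASS_BOUNDS",
    "mean_distance",
    "activity_skewness",
    "fit_individual_trend",
    "activity_rmse",
    "lag1_autocorrelation",
    "minute_activity_classes",
    "classes_from_switch_minutes",
    "sample_entropy",
    "bird_entropy",
    "flag_outliers",
    "descriptor_table",
    "mask_descriptor_outliers",
]

#: Fixed class cut-offs for active minutes per 15-min bin:
#: 1 = very inactive (0-2), 2 = inactive (3-4), 3 = active (5-7),
#: 4 = very active (8-15). Derived from observed quantiles; kept fixed by
#: default so values are comparable across datasets.
CLASS_BOUNDS = ((0, 2), (3, 4), (5, 7), (8, 15))

MIN_DAYS = 3        # minimum observed days for Skew and the trend fit
MIN_AC_PAIRS = 3    # minimum consecutive-age residual pairs for AC
OUTLIER_K = 4.0     # within-round outlier threshold, in SDs


def _clean(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return v[np.isfinite(v)]


def mean_distance(values) -> float:
    """Arithmetic mean of the non-missing daily DADM values (m/h)."""
    v = _clean(values)
    return float(v.mean()) if v.size else float("nan")


def activity_skewness(values, min_days: int = MIN_DAYS) -> float:
    """Sample skewness b1 = m3 / s^3 (s with n-1 denominator).

    Equivalently g1 * ((n-1)/n)^{3/2} with g1 = m3 / m2^{3/2}. Requires at
    least ``min_days`` observed days and non-zero variance, otherwise the
    value is missing.
    """
    v = _clean(values)
    n = v.size
    if n < min_days:
        return float("nan")
    d = v - v.mean()
    scale = float(np.max(np.abs(d)))  # skewness is scale-invariant; avoid
    if scale == 0.0:                  # overflow/underflow in the moments
        return float("nan")
    d = d / scale
    m2 = float((d * d).mean())
    if m2 == 0.0:
        return float("nan")
    m3 = float((d * d * d).mean())
    g1 = m3 / m2 ** 1.5
    return g1 * ((n - 1) / n) ** 1.5


@dataclass
class TrendFit:
    """Per-bird OLS line DADM ~ age, with residuals indexed by age."""

    bird_id: str
    slope: float
    intercept: float
    ages: np.ndarray       # observed ages (days)
    residuals: np.ndarray  # observed - predicted, same order as ages
    n: int


def fit_individual_trend(ages, values, bird_id: str = "", min_days: int = MIN_DAYS) -> TrendFit | None:
    """OLS with intercept on (age, DADM) pairs; missing days simply absent.

    Returns None when fewer than ``min_days`` days are observed (or the
    observed ages are all equal), in which case RMSE and AC are missing.
    """
    a = np.asarray(ages, dtype=float)
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(v) & np.isfinite(a)
    a, v = a[ok], v[ok]
    if a.size < min_days or np.ptp(a) == 0:
        return None
    am, vm = a.mean(), v.mean()
    slope = float(((a - am) * (v - vm)).sum() / ((a - am) ** 2).sum())
    intercept = float(vm - slope * am)
    resid = v - (intercept + slope * a)
    return TrendFit(bird_id, slope, intercept, a.astype(int), resid, int(a.size))


def activity_rmse(fit: TrendFit | None) -> float:
    """Root of the mean squared residual, divisor n (not n-2)."""
    if fit is None:
        return float("nan")
    return float(np.sqrt((fit.residuals ** 2).mean()))


def lag1_autocorrelation(fit: TrendFit | None, min_pairs: int = MIN_AC_PAIRS) -> float:
    """Pearson correlation of residual pairs on consecutive ages.

    Only complete cases enter: a pair (day d, day d+1) is used when both
    ages were observed. Fewer than ``min_pairs`` pairs, or zero variance
    in either pair coordinate, yields a missing value.
    """
    if fit is None:
        return float("nan")
    by_age = dict(zip(fit.ages.tolist(), fit.residuals.tolist()))
    x = [by_age[d] for d in by_age if d + 1 in by_age]
    y = [by_age[d + 1] for d in by_age if d + 1 in by_age]
    if len(x) < min_pairs:
        return float("nan")
    x, y = np.asarray(x), np.asarray(y)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# Entropy of within-day activity


@dataclass
class ActivityClassSeries:
    """64 fifteen-minute activity classes of one bird-day (07:00-23:00).

    ``counts`` are active minutes (0-15) per bin — a minute is active when
    at least one registration lands on a different antenna than the
    immediately preceding registration. ``complete`` is True only when the
    day has full light-period coverage (no exclusion overlap).
    """

    bird_id: str
    age_days: int
    counts: np.ndarray   # (64,) int
    classes: np.ndarray  # (64,) int in 1..4
    complete: bool


def classes_from_counts(counts: np.ndarray, bounds=CLASS_BOUNDS) -> np.ndarray:
    edges = [hi + 0.5 for _, hi in bounds[:-1]]
    return np.digitize(counts, edges) + 1


def classes_from_switch_minutes(switch_minute_flags: np.ndarray, bird_id: str = "",
                                age_days: int = 0, complete: bool = True,
                                bounds=CLASS_BOUNDS) -> ActivityClassSeries:
    """Build the class series from per-minute switch flags (length 960)."""
    flags = np.asarray(switch_minute_flags, dtype=bool)
    if flags.size % 15 != 0:
        raise ValueError("minute flags must cover whole 15-min bins")
    counts = flags.reshape(-1, 15).sum(axis=1)
    return ActivityClassSeries(bird_id, age_days, counts.astype(int),
                               classes_from_counts(counts, bounds), complete)


def minute_activity_classes(stream, schedule: DaySchedule | None = None,
                            bounds=CLASS_BOUNDS) -> ActivityClassSeries:
    """Minute-level antenna-switch flags binned to 15-min activity classes.

    A switch is a registration on a different antenna than the immediately
    preceding one within the same observed segment. Days with reduced
    coverage are flagged incomplete here and excluded from the per-bird
    entropy mean downstream (entropy is only accurate on full days).
    """
    schedule = schedule or DaySchedule()
    light_start, light_end = schedule.light_period
    n_min = (light_end - light_start) // 60
    flags = np.zeros(n_min, dtype=bool)
    if stream.n_events >= 2:
        ant = stream.antennas
        seg = stream.segments
        switch = (ant[1:] != ant[:-1]) & (seg[1:] == seg[:-1])
        mins = (stream.times[1:][switch] - light_start) // 60
        flags[np.unique(mins)] = True
    complete = stream.effective_seconds == schedule.light_seconds
    return classes_from_switch_minutes(flags, stream.bird_id, stream.age_days,
                                       complete, bounds)


def sample_entropy(x, m: int = 2, r: float = 0.2) -> float:
    """Sample entropy -ln(A/B) of a 1-D series.

    B counts unordered pairs of distinct length-m templates whose
    Chebyshev distance is <= r; A does the same for length m+1. Templates
    of length L start at positions 0..N-L-1 (N-L templates), and
    self-matches are excluded. Returns NaN when A or B is zero (entropy
    undefined).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= m + 1:
        raise ValueError(f"series of length {n} too short for m={m}")

    # running Chebyshev distance between templates via a max over shifted
    # diagonals: cheb[i, j] after L steps is the distance between the
    # length-L templates starting at i and j
    d = np.abs(x[:, None] - x[None, :])
    cheb = d
    counts = {}
    for length in range(2, m + 2):
        cheb = np.maximum(cheb[:-1, :-1], d[length - 1:, length - 1:])
        if length in (m, m + 1):
            k = n - length  # templates at starts 0..n-length-1
            sub = cheb[:k, :k] <= r
            counts[length] = (int(sub.sum()) - k) // 2  # drop self-matches
    if m == 1:
        k = n - 1
        sub = d[:k, :k] <= r
        counts[1] = (int(sub.sum()) - k) // 2
    b = counts[m]
    a = counts[m + 1]
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def default_entropy_r(classes, factor: float = 0.2) -> float:
    """Tolerance r = factor * SD (n-1 denominator) of the day's classes."""
    return factor * float(np.std(np.asarray(classes, dtype=float), ddof=1))


def bird_entropy(class_days, m: int = 2, r_rule=default_entropy_r) -> float:
    """Mean daily SampEn over the bird's complete days; NaN if none.

    ``r_rule`` maps one day's class sequence to its tolerance r (default
    0.2 x the day's SD). Days where entropy is undefined (no template
    matches) are skipped.
    """
    vals = []
    for day in class_days:
        if not day.complete:
            continue
        se = sample_entropy(day.classes, m=m, r=r_rule(day.classes))
        if np.isfinite(se):
            vals.append(se)
    return float(np.mean(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# Outlier masking and the per-bird descriptor table


def flag_outliers(values, groups, k: float = OUTLIER_K) -> np.ndarray:
    """Boolean mask of values beyond k within-group SDs of the group mean.

    The mean and SD (n-1 denominator) are computed from all non-missing
    values in the group, including the candidate itself — a single huge
    value therefore inflates the SD and can mask itself in small groups,
    matching the plain threshold rule.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    mask = np.zeros(v.shape, dtype=bool)
    for grp in pd.unique(g):
        sel = (g == grp) & np.isfinite(v)
        if sel.sum() < 2:
            continue
        mu = v[sel].mean()
        sd = v[sel].std(ddof=1)
        mask[sel] = np.abs(v[sel] - mu) > k * sd
    return mask


def descriptor_table(daily: pd.DataFrame, class_days: dict | None = None,
                     max_age: int = 15, min_days: int = MIN_DAYS,
                     min_ac_pairs: int = MIN_AC_PAIRS,
                     entropy_m: int = 2, entropy_r_rule=default_entropy_r,
                     ent_exclude_rounds=()) -> pd.DataFrame:
    """Per-bird descriptor table (bird_id, round_id, md, skew, rmse, ac, ent).

    ``daily`` holds bird_id, round_id, age_days, dadm_m_per_h (NaN when
    missing); ``class_days`` maps bird_id to its list of
    :class:`ActivityClassSeries`. Rounds listed in ``ent_exclude_rounds``
    get missing ENT for all their birds (used when a round's registration
    quality makes full days too rare, as with systemic outages).
    """
    rows = []
    daily = daily[daily["age_days"] <= max_age]
    for (bird, round_id), sub in daily.groupby(["bird_id", "round_id"], sort=True):
        vals = sub["dadm_m_per_h"].to_numpy()
        ages = sub["age_days"].to_numpy()
        fit = fit_individual_trend(ages, vals, bird_id=bird, min_days=min_days)
        if class_days is not None and round_id not in ent_exclude_rounds:
            ent = bird_entropy(class_days.get(bird, ()), m=entropy_m, r_rule=entropy_r_rule)
        else:
            ent = float("nan")
        rows.append({
            "bird_id": bird,
            "round_id": round_id,
            "md": mean_distance(vals),
            "skew": activity_skewness(vals, min_days=min_days),
            "rmse": activity_rmse(fit),
            "ac": lag1_autocorrelation(fit, min_pairs=min_ac_pairs),
            "ent": ent,
        })
    return pd.DataFrame(rows, columns=["bird_id", "round_id", "md", "skew", "rmse", "ac", "ent"])


def mask_descriptor_outliers(table: pd.DataFrame, k: float = OUTLIER_K):
    """Set within-round outliers (beyond k SDs) to missing, cell-wise.

    Returns the masked table and a report DataFrame listing each masked
    (bird, descriptor, value).
    """
    out = table.copy()
    report = []
    for col in ("md", "skew", "rmse", "ac", "ent"):
        mask = flag_outliers(out[col].to_numpy(), out["round_id"].to_numpy(), k=k)
        for i in np.flatnonzero(mask):
            report.append({"bird_id": out.iloc[i]["bird_id"], "descriptor": col,
                           "value": out.iloc[i][col]})
        out.loc[mask, col] = np.nan
    return out, pd.DataFrame(report, columns=["bird_id", "descriptor", "value"])
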