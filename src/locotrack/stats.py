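"""Statistical layer: rank correlations with bootstrap CIs, quartile-group
comparisons, and the sum-to-zero linear model with backward selection.

The descriptors and ADG are generally non-normal and tied, so
relationships are assessed with Kendall's tau-b (tie-corrected) plus a
percentile bootstrap CI, and group contrasts with Wilcoxon rank-sum
tests. The confounders round and start weight are handled in an OLS
model of ADG under sum-to-zero contrasts, reduced by backward stepwise
F-tests (two stages: main effects, then two-way interactions among the
survivors, respecting marginality).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "ModelFit",
    "kendall_tau_b",
    "bootstrap_tau_ci",
    "correlation_table",
    "wilcoxon_rank_sum",
    "compare_quartile_groups",
    "fit_adg_model",
]

ALPHA = 0.05


@dataclass(frozen=True)
class CorrelationResult:
    name: str
    tau: float
    z: float
    p: float
    ci_low: float
    ci_high: float
    ci_level: float
    n: int


def _complete_pairs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def kendall_tau_b(x, y):
    """Tau-b with tie correction; returns (tau, z, p).

    p is two-sided from the tie-corrected normal approximation; z is the
    corresponding normal deviate with the sign of tau. Pairs with a
    missing value on either side are dropped; zero variance on either
    side leaves the correlation undefined (NaNs).
    """
    x, y = _complete_pairs(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan"), float("nan")
    res = sps.kendalltau(x, y, variant="b", method="asymptotic")
    tau, p = float(res.statistic), float(res.pvalue)
    if np.isnan(tau):
        return float("nan"), float("nan"), float("nan")
    z = float(np.sign(tau) * sps.norm.isf(min(p, 1.0) / 2.0)) if tau != 0 else 0.0
    return tau, z, p


def bootstrap_tau_ci(x, y, n_boot: int = 1000, level: float = 0.95,
                     rng=None, max_redraws: int = 1000):
    """Percentile bootstrap CI for tau-b over pair resampling.

    Degenerate resamples (zero variance on either side) are redrawn; the
    number of redraws is returned alongside the interval as
    ((low, high), n_redrawn).
    """
    x, y = _complete_pairs(x, y)
    rng = np.random.default_rng(rng)
    taus = np.empty(n_boot)
    redrawn = 0
    for b in range(n_boot):
        for _ in range(max_redraws + 1):
            idx = rng.integers(0, x.size, size=x.size)
            if np.ptp(x[idx]) > 0 and np.ptp(y[idx]) > 0:
                break
            redrawn += 1
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap resample")
        taus[b] = sps.kendalltau(x[idx], y[idx], variant="b").statistic
    lo, hi = np.percentile(taus, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return (float(lo), float(hi)), redrawn


def correlation_table(table: pd.DataFrame, response: str = "adg",
                      descriptors=("md", "skew", "rmse", "ac", "ent"),
                      n_boot: int = 1000, level: float = 0.95,
                      seed: int | None = 0) -> pd.DataFrame:
    """Tau-b of each descriptor against the response, with bootstrap CIs.

    Each correlation uses its own pairwise-complete set (cell-wise outlier
    masking makes per-descriptor n differ).
    """
    rows = []
    rng = np.random.default_rng(seed)
    for name in descriptors:
        x, y = _complete_pairs(table[name], table[response])
        tau, z, p = kendall_tau_b(x, y)
        (lo, hi), _ = bootstrap_tau_ci(x, y, n_boot=n_boot, level=level, rng=rng)
        rows.append(CorrelationResult(name, tau, z, p, lo, hi, level, x.size))
    return pd.DataFrame([r.__dict__ for r in rows])


def wilcoxon_rank_sum(a, b):
    """Rank-sum test; returns (W, p) with W = rank sum of ``a`` minus
    n_a(n_a+1)/2 (the Mann-Whitney U of the first sample).

    Exact p when both groups are small (<= 50) and untied, otherwise the
    tie-corrected normal approximation. Identical samples give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and max(a.size, b.size) <= 50) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_quartile_groups(table: pd.DataFrame,
                            descriptors=("md", "skew", "rmse", "ac", "ent"),
                            group_col: str = "quartile") -> pd.DataFrame:
    """Wilcoxon rank-sum of each descriptor between the low- and high-ADG
    tails, with group means for context."""
    low = table[table[group_col] == "low"]
    high = table[table[group_col] == "high"]
    rows = []
    for name in descriptors:
        a = low[name].dropna().to_numpy()
        b = high[name].dropna().to_numpy()
        if a.size == 0 or b.size == 0:
            rows.append({"descriptor": name, "W": np.nan, "p": np.nan,
                         "mean_low": np.nan, "mean_high": np.nan,
                         "n_low": a.size, "n_high": b.size})
            continue
        w, p = wilcoxon_rank_sum(a, b)
        rows.append({"descriptor": name, "W": w, "p": p,
                     "mean_low": a.mean(), "mean_high": b.mean(),
                     "n_low": a.size, "n_high": b.size})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sum-to-zero linear model with backward stepwise selection


@dataclass
class ModelFit:
    """Final model with its selection history.

    ``round_effects`` includes the implied last level, so the full set of
    round deviations sums to zero by construction.
    """

    response: str
    terms: list
    formula: str
    coefficients: pd.DataFrame   # estimate, se, t, p per parameter
    anova: pd.DataFrame          # sequential (Type I) F-table
    round_effects: pd.Series
    r2: float
    adj_r2: float
    n: int
    trace: list = field(default_factory=list)


def _fit(formula: str, data: pd.DataFrame):
    return smf.ols(formula, data=data).fit()


def _f_test_drop(full, data, response: str, terms: list, drop: str):
    """F-test of dropping one term (factors as whole blocks)."""
    reduced_terms = [t for t in terms if t != drop]
    reduced_formula = f"{response} ~ " + (" + ".join(reduced_terms) if reduced_terms else "1")
    reduced = _fit(reduced_formula, data)
    df_num = reduced.df_resid - full.df_resid
    if df_num <= 0:
        return 1.0
    f = (reduced.ssr - full.ssr) / df_num / (full.ssr / full.df_resid)
    return float(sps.f.sf(f, df_num, full.df_resid))


def _contains_main(interaction: str, main: str) -> bool:
    return main in interaction.split(":")


def _backward(data: pd.DataFrame, response: str, terms: list, alpha: float,
              trace: list, stage: str):
    """Iteratively remove the term with the largest F-test p above alpha,
    never removing a main effect while one of its interactions remains."""
    terms = list(terms)
    while terms:
        formula = f"{response} ~ " + " + ".join(terms)
        full = _fit(formula, data)
        removable = [t for t in terms
                     if ":" in t or not any(":" in o and _contains_main(o, t) for o in terms)]
        pvals = {t: _f_test_drop(full, data, response, terms, t) for t in removable}
        worst = max(pvals, key=pvals.get) if pvals else None
        if worst is None or pvals[worst] <= alpha:
            return terms, full
        trace.append({"stage": stage, "removed": worst, "p": pvals[worst]})
        terms.remove(worst)
    return terms, _fit(f"{response} ~ 1", data)


def fit_adg_model(table: pd.DataFrame, response: str = "adg",
                  include_rounds=(2, 3, 4, 5),
                  descriptors=("skew", "rmse", "ac", "ent"),
                  include_start_weight: bool = True,
                  alpha: float = ALPHA, interactions: bool = True) -> ModelFit:
    """Two-stage backward-selected OLS of ADG under sum-to-zero contrasts.

    Stage 1 starts from round + start weight + the listed descriptors
    (MD is excluded by default: it is strongly rank-correlated with RMSE
    and the two carry overlapping information) and removes the least
    significant term (p > alpha, factors as blocks) until all survive.
    Stage 2 adds all two-way interactions among the survivors and runs
    backward selection again, respecting marginality.

    Listwise-complete rows on the included variables are used. Raises on
    rank deficiency, naming the aliased columns.
    """
    data = table[table["round_id"].isin(include_rounds)].copy()
    cols = [response, "round_id"] + list(descriptors)
    if include_start_weight:
        cols.append("start_weight_g")
    data = data[cols + [c for c in ("bird_id",) if c in table.columns]].dropna(
        subset=cols).reset_index(drop=True)

    terms = ["C(round_id, Sum)"]
    if include_start_weight:
        terms.append("start_weight_g")
    terms += list(descriptors)
    n_params = len(data["round_id"].unique()) + len(terms)
    if len(data) < n_params + 10:
        raise ValueError(f"too few complete rows ({len(data)}) for {n_params} parameters")

    trace: list = []
    survivors, fit1 = _backward(data, response, terms, alpha, trace, "main")
    if np.linalg.matrix_rank(fit1.model.exog) < fit1.model.exog.shape[1]:
        raise ValueError(f"rank-deficient design; aliased terms among {survivors}")

    final_terms, fit = survivors, fit1
    if interactions and len(survivors) >= 2:
        inter = [f"{a}:{b}" for i, a in enumerate(survivors) for b in survivors[i + 1:]]
        final_terms, fit = _backward(data, response, survivors + inter, alpha,
                                     trace, "interaction")

    coef = pd.DataFrame({
        "estimate": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues,
    })

    round_effects = pd.Series(dtype=float)
    if any(t.startswith("C(round_id") for t in final_terms):
        levels = sorted(data["round_id"].unique())
        eff = {}
        for name, val in fit.params.items():
            m = re.fullmatch(r"C\(round_id, Sum\)\[S\.([0-9.]+)\]", name)
            if m:
                eff[int(float(m.group(1)))] = float(val)
        implied = [l for l in levels if l not in eff]
        if len(implied) == 1:
            eff[implied[0]] = -sum(eff.values())
        round_effects = pd.Series(eff).sort_index()

    formula = f"{response} ~ " + (" + ".join(final_terms) if final_terms else "1")
    anova = sm.stats.anova_lm(fit, typ=1) if final_terms else pd.DataFrame()
    return ModelFit(
        response=response, terms=list(final_terms), formula=formula,
        coefficients=coef, anova=anova, round_effects=round_effects,
        r2=float(fit.rsquared), adj_r2=float(fit.rsquared_adj),
        n=int(fit.nobs), trace=trace,
    )
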