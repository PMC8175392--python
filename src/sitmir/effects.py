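"""Weighted treatment-effect estimation and two-step biomarker selection.

The average treatment effect (ATE) of the sitting phenotype on a microRNA is
the difference in stabilized-IPTW-weighted mean relative expression between
the Super-Sitter side (T=1) and the Interrupted-Sitter side (T=0).  Its
standard deviation comes from a stratified bootstrap that *re-fits the
propensity model within every resample*, so uncertainty in the weights
propagates into the interval.

Screening ranks the 84-assay panel by |standardized ATE| = |ATE| / boot SD,
keeps the top 10, and then retains the 5 of those with the largest
unweighted expression SD — a guard against assays whose tiny variance
inflates the standardized effect.  Validation calls an effect significant
when the 95% CI excludes zero strictly (lower bound > 0 or upper bound < 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .weighting import FitError, cbps_fit, stabilized_weights

Z_95 = 1.959963984540054  # standard-normal 97.5% quantile


@dataclass
class AteRecord:
    """Per-miR weighted effect estimate with bootstrap uncertainty."""

    mir: str
    ate: float
    boot_sd: float
    std_ate: float
    ci_low: float
    ci_high: float
    significant: bool
    unweighted_sd: float
    estimable: bool = True


@dataclass
class SelectionResult:
    """Two-step screening outcome: ranked table, top 10, and the selected set."""

    ranked: pd.DataFrame
    top10: list[str]
    selected: list[str]


def weighted_ate(y, t, w) -> float:
    """Difference of weighted means (T=1 minus T=0), NaN-aware.

    Returns NaN when either arm has fewer than 2 usable observations.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    w = np.asarray(w, dtype=float)
    valid = np.isfinite(y)
    means = []
    for arm in (1, 0):
        sel = valid & (t == arm)
        if sel.sum() < 2:
            return np.nan
        means.append(np.average(y[sel], weights=w[sel]))
    return float(means[0] - means[1])


def _ate_matrix(Y: np.ndarray, t: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise weighted ATE for an (assays x samples) matrix."""
    valid = np.isfinite(Y)
    Yz = np.where(valid, Y, 0.0)
    out = np.full(Y.shape[0], np.nan)
    num1 = (Yz * w)[:, t == 1].sum(axis=1)
    den1 = (valid * w)[:, t == 1].sum(axis=1)
    num0 = (Yz * w)[:, t == 0].sum(axis=1)
    den0 = (valid * w)[:, t == 0].sum(axis=1)
    n1 = valid[:, t == 1].sum(axis=1)
    n0 = valid[:, t == 0].sum(axis=1)
    ok = (n1 >= 2) & (n0 >= 2)
    out[ok] = num1[ok] / den1[ok] - num0[ok] / den0[ok]
    return out


def bootstrap_ate_table(
    expr: pd.DataFrame,
    X: pd.DataFrame,
    t,
    B: int = 1000,
    seed: int = 0,
    ci_method: str = "normal",
    max_fail_frac: float = 0.1,
    on_infeasible: str = "error",
) -> pd.DataFrame:
    """Weighted ATE, bootstrap SD, standardized ATE and 95% CI for every row.

    ``expr`` is (assays x samples); ``X`` the per-sample covariates; ``t`` the
    binary group.  Each bootstrap resample draws with replacement within each
    arm (arm sizes preserved), re-fits CBPS, re-derives stabilized weights,
    and recomputes all row ATEs; resamples where the propensity fit fails are
    redrawn, and more than ``max_fail_frac * B`` failures raise an error.

    ``ci_method``: "normal" (ATE +/- 1.96 boot SD) or "percentile".
    """
    t = np.asarray(t, dtype=float)
    Y = expr.to_numpy(dtype=float)
    if Y.shape[1] != len(t):
        raise ValueError("expression columns and treatment vector differ in length")
    rng = np.random.default_rng(seed)
    idx1 = np.flatnonzero(t == 1)
    idx0 = np.flatnonzero(t == 0)
    if len(idx1) < 2 or len(idx0) < 2:
        raise ValueError("need at least 2 samples per arm")

    fit = cbps_fit(X, t, on_infeasible=on_infeasible)
    w = stabilized_weights(fit, t)
    ate = _ate_matrix(Y, t, w)

    boot = np.empty((B, Y.shape[0]))
    failures = 0
    b = 0
    while b < B:
        take = np.concatenate([rng.choice(idx1, size=len(idx1)), rng.choice(idx0, size=len(idx0))])
        Xb = X.iloc[take] if isinstance(X, pd.DataFrame) else X[take]
        tb = t[take]
        try:
            fb = cbps_fit(Xb, tb, on_infeasible=on_infeasible)
        except (FitError, ValueError):
            failures += 1
            if failures > max_fail_frac * B:
                raise FitError(
                    f"more than {max_fail_frac:.0%} of bootstrap resamples failed the propensity fit"
                )
            continue
        wb = stabilized_weights(fb, tb)
        boot[b] = _ate_matrix(Y[:, take], tb, wb)
        b += 1

    boot_sd = np.nanstd(boot, axis=0, ddof=1)
    if ci_method == "normal":
        lo = ate - Z_95 * boot_sd
        hi = ate + Z_95 * boot_sd
    elif ci_method == "percentile":
        lo = np.nanpercentile(boot, 2.5, axis=0)
        hi = np.nanpercentile(boot, 97.5, axis=0)
    else:
        raise ValueError("ci_method must be 'normal' or 'percentile'")

    with np.errstate(invalid="ignore", divide="ignore"):
        std_ate = ate / boot_sd
    table = pd.DataFrame(
        {
            "ate": ate,
            "boot_sd": boot_sd,
            "std_ate": std_ate,
            "ci_low": lo,
            "ci_high": hi,
            "significant": (lo > 0) | (hi < 0),
            "unweighted_sd": np.nanstd(Y, axis=1, ddof=1),
            "estimable": np.isfinite(ate),
        },
        index=expr.index,
    )
    table.attrs["n_boot_failures"] = failures
    return table


def weighted_ate_bootstrap(
    y,
    X: pd.DataFrame,
    t,
    B: int = 1000,
    seed: int = 0,
    ci_method: str = "normal",
    mir: str = "miR",
) -> AteRecord:
    """Single-outcome convenience wrapper around :func:`bootstrap_ate_table`."""
    expr = pd.DataFrame([np.asarray(y, dtype=float)], index=[mir])
    row = bootstrap_ate_table(expr, X, t, B=B, seed=seed, ci_method=ci_method).iloc[0]
    return AteRecord(
        mir=mir,
        ate=row["ate"],
        boot_sd=row["boot_sd"],
        std_ate=row["std_ate"],
        ci_low=row["ci_low"],
        ci_high=row["ci_high"],
        significant=bool(row["significant"]),
        unweighted_sd=row["unweighted_sd"],
        estimable=bool(row["estimable"]),
    )


def _rank_key(table: pd.DataFrame) -> pd.DataFrame:
    key = pd.DataFrame(index=table.index)
    key["abs_std"] = table["std_ate"].abs()
    key["abs_ate"] = table["ate"].abs()
    key["name"] = table.index.astype(str)
    return key


def rank_and_select(table: pd.DataFrame, n_top: int = 10, n_select: int = 5) -> SelectionResult:
    """Two-step selection: rank by |standardized ATE|, then keep largest-SD.

    Ties in |standardized ATE| break by |ATE| (descending) then name
    (ascending); the SD step uses the same chain after the SD itself.
    Inestimable rows (NaN standardized ATE) sort last.
    """
    est = table[table["std_ate"].notna()] if "std_ate" in table else table
    if est.empty:
        raise ValueError("no estimable records to rank")
    key = _rank_key(est)
    order = key.sort_values(
        ["abs_std", "abs_ate", "name"], ascending=[False, False, True]
    ).index
    ranked = est.loc[order].copy()
    ranked["std_ate_rank"] = np.arange(1, len(ranked) + 1)
    top10 = list(ranked.index[: min(n_top, len(ranked))])

    top = ranked.loc[top10].copy()
    sd_key = _rank_key(top)
    sd_key["sd"] = top["unweighted_sd"]
    sd_order = sd_key.sort_values(
        ["sd", "abs_std", "abs_ate", "name"], ascending=[False, False, False, True]
    ).index
    selected = list(sd_order[: min(n_select, len(top10))])
    return SelectionResult(ranked=ranked, top10=top10, selected=selected)


def validate_significance(table: pd.DataFrame) -> pd.Series:
    """Significance flags: the 95% CI excludes zero strictly."""
    return (table["ci_low"] > 0) | (table["ci_high"] < 0)


def pearson_correlation(x, y, groups=None) -> dict[str, float]:
    """Pearson r combined and (optionally) per group stratum.

    Strata with fewer than 3 complete pairs or zero variance report NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def _r(a, b) -> float:
        ok = np.isfinite(a) & np.isfinite(b)
        a, b = a[ok], b[ok]
        if len(a) < 3 or a.std() == 0 or b.std() == 0:
            return np.nan
        return float(stats.pearsonr(a, b)[0])

    out = {"combined": _r(x, y)}
    if groups is not None:
        groups = np.asarray(groups)
        for g in pd.unique(groups):
            sel = groups == g
            out[str(g)] = _r(x[sel], y[sel])
    return out


def interaction_wls(y, t, hispanic, w) -> pd.DataFrame:
    """Weighted linear regression of expression on group x ethnicity.

    Fits y ~ 1 + group + hispanic + group:hispanic by weighted least squares
    with the stabilized IPTW weights, reporting HC0 (sandwich) standard
    errors and the Wald p-value per coefficient.  All four group-by-ethnicity
    cells must be nonempty.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    h = np.asarray(hispanic, dtype=float)
    w = np.asarray(w, dtype=float)
    for tv in (0, 1):
        for hv in (0, 1):
            if not np.any((t == tv) & (h == hv)):
                raise ValueError(f"empty design cell: group={tv}, hispanic={hv}")
    X = np.column_stack([np.ones_like(t), t, h, t * h])
    res = sm.WLS(y, X, weights=w).fit(cov_type="HC0")
    return pd.DataFrame(
        {"coef": res.params, "se": res.bse, "p": res.pvalues},
        index=["intercept", "group", "hispanic", "group:hispanic"],
    )
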