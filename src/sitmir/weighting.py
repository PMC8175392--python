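"""Covariate-balancing propensity scores and inverse-probability weighting.

The exposure contrast (Super-Sitter side T=1 vs Interrupted-Sitter side T=0)
is not randomized, so microRNA comparisons are confounded by physical
functioning, MVPA, device wear, adiposity and age.  This module estimates a
logistic propensity score whose coefficients solve the *just-identified*
covariate-balancing (CBPS) moment conditions for the average treatment
effect,

    (1/n) sum_i [ T_i/pi(x_i) - (1-T_i)/(1-pi(x_i)) ] x_i = 0 ,

with x including an intercept.  At the solution, inverse-probability weights
balance every covariate's first moment *exactly* (up to the root-finder
tolerance), which is the property the downstream tests assert.

Weights are stabilized by the marginal treated fraction and normalized to
mean 1 within each arm (Hajek form); ratio-of-means estimators downstream
are unchanged by the normalization.

Missing covariates are completed by a single chained-equations imputation
with predictive mean matching (PMM) before any propensity fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: covariates used for IPTW at both stages
DEFAULT_COVARIATES = (
    "physical_functioning",
    "mvpa",
    "wear_days",
    "wear_time",
    "waist",
    "bmi",
    "age",
)


class FitError(RuntimeError):
    """Propensity-score estimation failed."""

    def __init__(self, message: str, residual_norm: float | None = None):
        super().__init__(message)
        self.residual_norm = residual_norm


@dataclass
class PropensityFit:
    """A converged CBPS fit: coefficients on the original covariate scale."""

    beta: np.ndarray  # intercept first
    propensities: np.ndarray
    residual_norm: float
    converged: bool
    n_iter: int
    covariate_names: tuple[str, ...] = ()


def _design(X: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        names = tuple(str(c) for c in X.columns)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        names = tuple(f"x{i}" for i in range(arr.shape[1]))
    return arr, names


def _logistic_mle(Z: np.ndarray, t: np.ndarray, max_iter: int = 50, ridge: float = 0.0) -> np.ndarray:
    """Newton/IRLS logistic fit on a standardized design with intercept.

    ``ridge > 0`` penalizes the log-likelihood to keep coefficients finite
    under (quasi-)separation; with ``ridge == 0`` separation raises.
    """
    beta = np.zeros(Z.shape[1])
    beta[0] = np.log(t.mean() / (1 - t.mean()))
    for _ in range(max_iter):
        eta = Z @ beta
        pi = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = pi * (1 - pi)
        grad = Z.T @ (t - pi) - ridge * beta
        hess = (Z * w[:, None]).T @ Z + (ridge + 1e-10) * np.eye(Z.shape[1])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if ridge == 0 and np.linalg.norm(beta) > 1e4:
            raise FitError(
                "perfect or quasi-perfect separation in the propensity model; "
                "reduce the covariate set or pool categories"
            )
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def _cbps_moment(Z: np.ndarray, t: np.ndarray, beta: np.ndarray):
    eta = np.clip(Z @ beta, -35, 35)
    pi = 1.0 / (1.0 + np.exp(-eta))
    pi = np.clip(pi, 1e-12, 1 - 1e-12)
    d = t / pi - (1 - t) / (1 - pi)
    g = Z.T @ d / len(t)
    # dg/dbeta = -(1/n) Z' diag(t(1-pi)/pi + (1-t)pi/(1-pi)) Z
    h = t * (1 - pi) / pi + (1 - t) * pi / (1 - pi)
    J = -(Z * h[:, None]).T @ Z / len(t)
    return g, J, pi


def cbps_fit(
    X: pd.DataFrame | np.ndarray,
    t,
    tol: float = 1e-8,
    max_iter: int = 200,
    on_infeasible: str = "error",
) -> PropensityFit:
    """Solve the just-identified ATE balance moment conditions.

    Covariates are standardized internally; the returned coefficients are on
    the original scale.  Damped Newton iteration starts from the logistic
    maximum-likelihood estimate, with a trust-region root finder as backup.

    Exact balance can be infeasible when one arm is tiny relative to the
    covariate dimension (no convex combination of its points matches the
    other arm's weighted mean).  ``on_infeasible`` controls what happens
    then: ``"error"`` raises :class:`FitError` carrying the residual norm;
    ``"best"`` returns the minimum-residual (GMM) fit with
    ``converged=False``, which weights covariates as well as the data allow.
    """
    arr, names = _design(X)
    t = np.asarray(t, dtype=float)
    if arr.shape[0] != t.shape[0]:
        raise ValueError("covariates and treatment must have equal length")
    if not (np.any(t == 1) and np.any(t == 0)):
        raise FitError("both treatment levels must be present")
    mu = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=0)
    if np.any(sd == 0):
        const = [names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant covariates cannot enter the propensity model: {const}")
    Zs = (arr - mu) / sd
    Z = np.column_stack([np.ones(len(t)), Zs])

    try:
        beta = _logistic_mle(Z, t)
    except FitError:
        if on_infeasible != "best":
            raise
        beta = _logistic_mle(Z, t, ridge=1.0)
    g, J, pi = _cbps_moment(Z, t, beta)
    norm = float(np.linalg.norm(g))
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if norm < tol:
            break
        try:
            step = np.linalg.solve(J, -g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, -g, rcond=None)[0]
        # step halving on the residual norm
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            g_new, J_new, pi_new = _cbps_moment(Z, t, cand)
            norm_new = float(np.linalg.norm(g_new))
            if norm_new < norm or not np.isfinite(norm):
                break
            scale *= 0.5
        else:
            break
        beta, g, J, pi, norm = cand, g_new, J_new, pi_new, norm_new
    converged = norm < tol
    if not converged:
        # Newton stalled; hand the system to a trust-region root finder,
        # trying both the stalled iterate and the MLE start
        from scipy import optimize

        for start in (beta, _logistic_mle(Z, t, ridge=1.0)):
            sol = optimize.root(
                lambda b: _cbps_moment(Z, t, b)[0],
                start,
                jac=lambda b: _cbps_moment(Z, t, b)[1],
                method="hybr",
            )
            g_new, _, pi_new = _cbps_moment(Z, t, sol.x)
            norm_new = float(np.linalg.norm(g_new))
            if norm_new < norm:
                beta, pi, norm = sol.x, pi_new, norm_new
            if norm < tol:
                converged = True
                break
    if not converged:
        if on_infeasible == "best":
            from scipy import optimize

            sol = optimize.least_squares(
                lambda b: _cbps_moment(Z, t, b)[0],
                beta,
                jac=lambda b: _cbps_moment(Z, t, b)[1],
                method="lm",
                max_nfev=2000,
            )
            g_new, _, pi_new = _cbps_moment(Z, t, sol.x)
            norm_new = float(np.linalg.norm(g_new))
            if norm_new < norm:
                beta, pi, norm = sol.x, pi_new, norm_new
        else:
            raise FitError(
                f"CBPS moment conditions did not converge (residual norm {norm:.3g})",
                residual_norm=norm,
            )
    # map coefficients back to the original covariate scale
    beta_orig = np.empty_like(beta)
    beta_orig[1:] = beta[1:] / sd
    beta_orig[0] = beta[0] - np.sum(beta[1:] * mu / sd)
    return PropensityFit(
        beta=beta_orig,
        propensities=np.clip(pi, 1e-12, 1 - 1e-12),
        residual_norm=norm,
        converged=converged,
        n_iter=n_iter,
        covariate_names=names,
    )


def stabilized_weights(fit: PropensityFit, t, normalize: bool = True) -> np.ndarray:
    """Stabilized IPTW weights: pbar/pi for treated, (1-pbar)/(1-pi) for controls.

    With ``normalize`` (default) weights are rescaled to mean 1 within each
    arm; ratio-of-means (Hajek) estimators are invariant to this.
    """
    t = np.asarray(t, dtype=float)
    pi = np.asarray(fit.propensities, dtype=float)
    if np.any((pi <= 0) | (pi >= 1)):
        raise FitError("propensities at 0 or 1 cannot be weighted")
    pbar = t.mean()
    w = np.where(t == 1, pbar / pi, (1 - pbar) / (1 - pi))
    if normalize:
        w = w.copy()
        w[t == 1] /= w[t == 1].mean()
        w[t == 0] /= w[t == 0].mean()
    return w


def impute_pmm(
    table: pd.DataFrame,
    columns: list[str] | None = None,
    k_donors: int = 5,
    n_cycles: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Single chained-equations imputation with predictive mean matching.

    Each variable with missing cells is regressed (OLS) on all other
    candidate columns using currently-complete values; each missing entry is
    replaced by the observed value of one of the ``k_donors`` donors whose
    predicted means are nearest to the missing entry's prediction (random
    choice among them, seeded).  Imputed values are therefore always members
    of the observed support.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    if columns is None:
        columns = [c for c in out.columns if pd.api.types.is_numeric_dtype(out[c])]
    work = out[columns].astype(float)
    miss = {c: work[c].isna().to_numpy() for c in columns if work[c].isna().any()}
    if not miss:
        return out
    for c, m in miss.items():
        n_obs = int((~m).sum())
        if n_obs == 0:
            raise ValueError(f"variable {c!r} is entirely missing and cannot be imputed")
        if n_obs < k_donors:
            raise ValueError(f"variable {c!r} has fewer observed values than k_donors")
        # initialize with the observed mean
        work.loc[m, c] = work.loc[~m, c].mean()

    predictors = {c: [p for p in columns if p != c] for c in miss}
    for _ in range(n_cycles):
        for c, m in miss.items():
            X = work[predictors[c]].to_numpy()
            X = np.column_stack([np.ones(len(X)), X])
            y = work[c].to_numpy()
            beta, *_ = np.linalg.lstsq(X[~m], y[~m], rcond=None)
            pred = X @ beta
            obs_pred = pred[~m]
            obs_val = y[~m]
            for i in np.flatnonzero(m):
                dist = np.abs(obs_pred - pred[i])
                donors = np.argpartition(dist, k_donors - 1)[:k_donors]
                work.iloc[i, work.columns.get_loc(c)] = obs_val[donors[rng.integers(k_donors)]]
    out[columns] = work
    return out


def balance_report(
    X: pd.DataFrame,
    t,
    w,
    include_interactions: bool = True,
) -> pd.DataFrame:
    """Weighted covariate-balance diagnostics.

    For every covariate, its square, and every pairwise product, reports the
    unweighted and weighted standardized average difference
    (weighted mean difference between arms over the pooled *unweighted* SD,
    pooled as sqrt((s1^2 + s0^2)/2)); for raw covariates also the weighted
    Kolmogorov-Smirnov statistic (max gap between arm-wise weighted ECDFs).
    Terms with zero pooled SD are skipped with a warning.
    """
    import warnings

    t = np.asarray(t, dtype=float)
    w = np.asarray(w, dtype=float)
    cols = list(X.columns)
    terms: list[tuple[str, str, np.ndarray]] = []
    for c in cols:
        terms.append((c, "covariate", X[c].to_numpy(dtype=float)))
    for c in cols:
        terms.append((f"{c}^2", "square", X[c].to_numpy(dtype=float) ** 2))
    if include_interactions:
        for i, a in enumerate(cols):
            for b in cols[i + 1 :]:
                terms.append(
                    (f"{a}*{b}", "interaction", X[a].to_numpy(float) * X[b].to_numpy(float))
                )

    rows = []
    for name, kind, v in terms:
        s1 = v[t == 1].std(ddof=1)
        s0 = v[t == 0].std(ddof=1)
        pooled = np.sqrt((s1**2 + s0**2) / 2)
        if pooled == 0:
            warnings.warn(f"term {name!r} has zero pooled SD; skipped")
            continue
        raw = v[t == 1].mean() - v[t == 0].mean()
        wmean1 = np.average(v[t == 1], weights=w[t == 1])
        wmean0 = np.average(v[t == 0], weights=w[t == 0])
        rec = {
            "term": name,
            "kind": kind,
            "std_diff_unweighted": raw / pooled,
            "std_diff_weighted": (wmean1 - wmean0) / pooled,
        }
        if kind == "covariate":
            rec["ks_weighted"] = weighted_ks(v[t == 1], v[t == 0], w[t == 1], w[t == 0])
        rows.append(rec)
    return pd.DataFrame(rows).set_index("term")


def weighted_ks(x1, x0, w1, w0) -> float:
    """Max gap between two weighted empirical distribution functions."""
    x1, x0 = np.asarray(x1, float), np.asarray(x0, float)
    w1 = np.asarray(w1, float) / np.sum(w1)
    w0 = np.asarray(w0, float) / np.sum(w0)
    grid = np.concatenate([x1, x0])
    order = np.argsort(grid, kind="mergesort")
    grid = grid[order]
    cdf1 = np.array([w1[x1 <= g].sum() for g in grid])
    cdf0 = np.array([w0[x0 <= g].sum() for g in grid])
    return float(np.max(np.abs(cdf1 - cdf0)))
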