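"""End-to-end screening -> selection -> validation orchestration.

Screening: summarize minute epochs, classify Interrupted/Super Sitters by
quartile cross-tabulation, plan RNA pools, pool Ct values, normalize against
the array control panel, balance pool-level covariates by CBPS/IPTW, and rank
all panel microRNAs by bootstrap-standardized weighted effect, keeping the
five largest-SD members of the top ten.

Validation: augment the groups with Hispanic women from the second MVPA
quartile, normalize individual-sample Ct against SNORD61 and the cel-miR-39
spike-in, re-weight at the individual level, flag effects whose 95% CI
excludes zero, and report correlations and a group-by-ethnicity interaction
regression for the selected microRNAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from . import accelerometry as acc
from . import effects as eff
from . import expression as xp
from . import groups as grp
from . import weighting as wt

logger = logging.getLogger("sitmir.pipeline")


@dataclass
class RunConfig:
    """Tunable analysis settings with explicit seeds (no wall-clock seeding)."""

    min_wear: int = acc.MIN_WEAR_MINUTES
    min_days: int = acc.MIN_WEAR_DAYS
    choi: acc.ChoiParams = field(default_factory=acc.ChoiParams)
    cutpoint: int = acc.MVPA_CUTPOINT
    bout_mean_per_day: bool = False
    covariates: tuple[str, ...] = wt.DEFAULT_COVARIATES
    B: int = 1000
    ci_method: str = "normal"
    pool_covariate_agg: str = "mean"  # or "median"
    k_donors: int = 5
    n_impute_cycles: int = 10
    n_top: int = 10
    n_select: int = 5
    seed_pools: int = 11
    seed_impute: int = 13
    seed_boot: int = 17
    # pool-level exact balance can be infeasible (few pools, 7 covariates);
    # "best" falls back to the minimum-residual CBPS fit instead of aborting
    cbps_on_infeasible: str = "best"


@dataclass
class ScreeningResult:
    summaries: pd.DataFrame
    assignments: pd.DataFrame
    pools: list
    expression: pd.DataFrame
    participant_covariates: pd.DataFrame
    pool_covariates: pd.DataFrame
    pool_treatment: np.ndarray
    balance: pd.DataFrame
    ate_table: pd.DataFrame
    selection: eff.SelectionResult
    log: list = field(default_factory=list)


@dataclass
class ValidationResult:
    assignments: pd.DataFrame
    expression: pd.DataFrame
    covariates: pd.DataFrame
    treatment: np.ndarray
    weights: np.ndarray
    balance: pd.DataFrame
    ate_table: pd.DataFrame
    significant: pd.Series
    correlations: pd.DataFrame
    interactions: dict[str, pd.DataFrame]
    log: list = field(default_factory=list)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(log: list, stage: str, **info) -> None:
    log.append({"stage": stage, **info})
    logger.info("%s: %s", stage, info)


def _drop_constant(X: pd.DataFrame) -> pd.DataFrame:
    """Drop zero-variance covariate columns (they cannot enter the CBPS fit)."""
    sd = X.std(ddof=0)
    dead = list(sd.index[sd == 0])
    if dead:
        logger.warning("dropping constant covariates from the propensity model: %s", dead)
        X = X.drop(columns=dead)
    return X


def build_covariate_table(
    covariates: pd.DataFrame, summaries: pd.DataFrame, config: RunConfig
) -> pd.DataFrame:
    """Merge demographic covariates with device-derived ones and impute.

    Produces one row per adherent participant with the IPTW covariate set
    (physical functioning, MVPA, wear days, wear time, waist, BMI, age),
    completed by chained-equations PMM imputation across the cohort.
    """
    s = summaries[summaries["adherent"]].copy()
    merged = s.merge(covariates, on="participant_id", how="left", validate="1:1")
    merged = merged.rename(columns={"mean_wear_time": "wear_time"})
    table = merged.set_index("participant_id")[list(config.covariates)].astype(float)
    table = wt.impute_pmm(
        table.reset_index(),
        columns=list(config.covariates),
        k_donors=config.k_donors,
        n_cycles=config.n_impute_cycles,
        seed=config.seed_impute,
    ).set_index("participant_id")
    return table


def run_screening(
    epochs: pd.DataFrame,
    covariates: pd.DataFrame,
    ct: xp.CtMatrix,
    config: RunConfig | None = None,
) -> ScreeningResult:
    """Pooled-sample screening stage; returns the ranked panel and selection."""
    config = config or RunConfig()
    log: list = []
    try:
        summaries = acc.summarize_cohort(
            epochs,
            min_wear=config.min_wear,
            min_days=config.min_days,
            choi=config.choi,
            cutpoint=config.cutpoint,
            bout_mean_per_day=config.bout_mean_per_day,
        )
        _stage(log, "summarize_activity", participants=len(summaries), adherent=int(summaries["adherent"].sum()))
    except Exception as e:
        raise StageError(f"summarize_activity: {e}") from e

    try:
        assignments = grp.classify_is_ss(summaries)
        n_is = int((assignments["group"] == grp.GROUP_IS).sum())
        n_ss = int((assignments["group"] == grp.GROUP_SS).sum())
        _stage(log, "classify_is_ss", n_is=n_is, n_ss=n_ss)
    except Exception as e:
        raise StageError(f"classify_is_ss: {e}") from e

    study_of = covariates.set_index(covariates["participant_id"].astype(str))["parent_study"]
    pools = []
    try:
        for side, offset in ((grp.GROUP_IS, 0), (grp.GROUP_SS, 1)):
            members = grp.group_members(assignments, side)
            pools.extend(
                grp.make_pools(
                    members,
                    [study_of.get(m, "unknown") for m in members],
                    side,
                    seed=config.seed_pools + offset,
                )
            )
        _stage(log, "make_pools", n_pools=len(pools))
    except Exception as e:
        raise StageError(f"make_pools: {e}") from e

    try:
        pooled = xp.pool_ct(ct, pools)
        expr = xp.relative_expression(pooled, "screening")
        _stage(log, "relative_expression", assays=expr.shape[0], pools=expr.shape[1])
    except Exception as e:
        raise StageError(f"expression: {e}") from e

    try:
        cov_table = build_covariate_table(covariates, summaries, config)
        agg = config.pool_covariate_agg
        pool_rows = {
            p.pool_id: getattr(cov_table.loc[p.members], agg)(axis=0) for p in pools
        }
        Xpool = _drop_constant(pd.DataFrame(pool_rows).T.loc[[p.pool_id for p in pools]])
        t = np.array([1.0 if p.group == grp.GROUP_SS else 0.0 for p in pools])
        _stage(log, "pool_covariates", pools=len(Xpool))
    except Exception as e:
        raise StageError(f"covariates: {e}") from e

    try:
        fit = wt.cbps_fit(Xpool, t, on_infeasible=config.cbps_on_infeasible)
        w = wt.stabilized_weights(fit, t)
        balance = wt.balance_report(Xpool, t, w)
        ate_table = eff.bootstrap_ate_table(
            expr, Xpool, t, B=config.B, seed=config.seed_boot,
            ci_method=config.ci_method, on_infeasible=config.cbps_on_infeasible,
        )
        selection = eff.rank_and_select(ate_table, config.n_top, config.n_select)
        _stage(
            log,
            "screen",
            B=config.B,
            max_abs_std_diff=float(balance.loc[balance["kind"] == "covariate", "std_diff_weighted"].abs().max()),
            selected=selection.selected,
        )
    except Exception as e:
        raise StageError(f"weighted_screening: {e}") from e

    return ScreeningResult(
        summaries=summaries,
        assignments=assignments,
        pools=pools,
        expression=expr,
        participant_covariates=cov_table,
        pool_covariates=Xpool,
        pool_treatment=t,
        balance=balance,
        ate_table=ate_table,
        selection=selection,
        log=log,
    )


def run_validation(
    assignments: pd.DataFrame,
    covariates: pd.DataFrame,
    summaries: pd.DataFrame,
    ct: xp.CtMatrix,
    selected: list[str],
    config: RunConfig | None = None,
) -> ValidationResult:
    """Individual-sample validation of the selected microRNAs."""
    config = config or RunConfig()
    log: list = []
    if not selected:
        raise StageError("validation: no selected miRs supplied")

    try:
        aug = grp.augment_hispanic(assignments, covariates)
        is_plus = grp.group_members(aug, grp.GROUP_IS, augmented=True)
        ss_plus = grp.group_members(aug, grp.GROUP_SS, augmented=True)
        _stage(log, "augment_hispanic", n_is_plus=len(is_plus), n_ss_plus=len(ss_plus))
    except Exception as e:
        raise StageError(f"augment_hispanic: {e}") from e

    members = is_plus + ss_plus
    t = np.array([0.0] * len(is_plus) + [1.0] * len(ss_plus))

    try:
        expr_all = xp.relative_expression(ct, "validation")
        missing = [m for m in selected if m not in expr_all.index]
        if missing:
            raise ValueError(f"selected miRs absent from the validation assay: {missing}")
        expr = expr_all.loc[selected, members]
        _stage(log, "relative_expression", assays=len(selected), samples=len(members))
    except Exception as e:
        raise StageError(f"expression: {e}") from e

    try:
        cov_table = build_covariate_table(covariates, summaries, config)
        X = _drop_constant(cov_table.loc[members])
    except Exception as e:
        raise StageError(f"covariates: {e}") from e

    try:
        fit = wt.cbps_fit(X, t, on_infeasible=config.cbps_on_infeasible)
        w = wt.stabilized_weights(fit, t)
        balance = wt.balance_report(X, t, w)
        ate_table = eff.bootstrap_ate_table(
            expr, X, t, B=config.B, seed=config.seed_boot + 1,
            ci_method=config.ci_method, on_infeasible=config.cbps_on_infeasible,
        )
        significant = eff.validate_significance(ate_table)
        _stage(log, "validate", B=config.B, n_significant=int(significant.sum()))
    except Exception as e:
        raise StageError(f"weighted_validation: {e}") from e

    # unadjusted correlations among the validated candidates, per stratum
    group_label = np.where(t == 1, "SS+", "IS+")
    corr_rows = []
    for a, b in combinations(selected, 2):
        r = eff.pearson_correlation(expr.loc[a], expr.loc[b], groups=group_label)
        corr_rows.append({"mir_a": a, "mir_b": b, **r})
    correlations = pd.DataFrame(corr_rows)

    hisp = (
        covariates.set_index(covariates["participant_id"].astype(str))["hispanic"]
        .reindex(members)
        .astype(float)
        .to_numpy()
    )
    interactions: dict[str, pd.DataFrame] = {}
    for mir in selected:
        try:
            interactions[mir] = eff.interaction_wls(expr.loc[mir], t, hisp, w)
        except ValueError as e:
            logger.warning("interaction model skipped for %s: %s", mir, e)

    return ValidationResult(
        assignments=aug,
        expression=expr,
        covariates=X,
        treatment=t,
        weights=w,
        balance=balance,
        ate_table=ate_table,
        significant=significant,
        correlations=correlations,
        interactions=interactions,
        log=log,
    )


def run_study(data, config: RunConfig | None = None) -> tuple[ScreeningResult, ValidationResult]:
    """Both stages on one input bundle (e.g. from ``simulate_study``)."""
    config = config or RunConfig()
    screening = run_screening(data.epochs, data.covariates, data.ct_screening, config)
    validation = run_validation(
        screening.assignments,
        data.covariates,
        screening.summaries,
        data.ct_validation,
        screening.selection.selected,
        config,
    )
    return screening, validation
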