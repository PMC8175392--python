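"""Synthetic cohorts with the behavioral, covariate, and qPCR structure of a
device-measured sitting-pattern / EC-EV microRNA study.

The generator emulates overweight/obese postmenopausal women wearing a hip
accelerometer for about a week: per-participant mean sitting-bout duration is
lognormal around a 39-minute median with spread covering the ~25-minute
(Interrupted Sitter) to ~64-minute (Super Sitter) contrast; total sitting is
around 10 h of a 14-16 h wear day; MVPA averages a few minutes per day and is
weakly negatively related to sitting.  A single latent *sitting propensity*
per participant drives bout duration, total sitting, and (for designated
microRNAs) log2 expression, while a shared covariate factor creates
confounding between behavior and expression whose strength is one scalar.

Every generated cohort carries a :class:`TruthRecord` with the latent
propensities, per-miR effects, and pre-missingness covariates so that
downstream modules can be tested for parameter recovery.  Analysis modules
never consume the truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import (
    ROLE_ARRAY_CONTROL,
    ROLE_SNORD61,
    ROLE_SPIKE_IN,
    ROLE_TARGET,
    CtMatrix,
)

PARENT_STUDIES = ("CoM", "RFH", "MENU")

# posture codes used internally by the day simulator
POSTURE_CATEGORIES = ("sit", "stand", "move", "walk")
CODE_SIT, CODE_STAND, CODE_MOVE, CODE_WALK = 0, 1, 2, 3
PARENT_STUDY_PROBS = (0.30, 0.59, 0.11)

# canonical cardiovascular-disease-related microRNAs to head the panel;
# remaining assays get generic simulated names
_CVD_MIRS = (
    "miR-133b", "miR-140-5p", "miR-142-3p", "let-7d-5p", "miR-199a-5p",
    "miR-146a-5p", "miR-103a-3p", "miR-424-5p", "let-7e-5p", "miR-155-5p",
    "miR-1", "miR-21-5p", "miR-22-3p", "miR-23a-3p", "miR-26a-5p",
    "miR-29a-3p", "miR-30c-5p", "miR-92a-3p", "miR-100-5p", "miR-125b-5p",
    "miR-126-3p", "miR-143-3p", "miR-145-5p", "miR-150-5p", "miR-208a-3p",
    "miR-210-3p", "miR-221-3p", "miR-222-3p", "miR-27a-3p", "miR-195-5p",
)


def default_panel(n_mirs: int = 84) -> list[str]:
    """Panel of target assay names (canonical CVD miRs, then simulated ones)."""
    names = list(_CVD_MIRS[:n_mirs])
    names += [f"miR-sim-{i:02d}" for i in range(1, n_mirs - len(names) + 1)]
    return names


class ConfigError(ValueError):
    """A cohort configuration field is invalid."""


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Behavioral defaults follow the population the pipeline models: mean
    sitting-bout duration lognormal with median ``bout_mean_median`` = 39 min
    and log-SD ``bout_mean_sigma`` = 0.45 (so +/-1 SD of latent propensity
    spans roughly 25-61 min); total sitting near 603 min/day of a ~15 h wear
    window; MVPA centered at 3.5 min/day; 34% Hispanic.
    """

    n_participants: int
    n_days: int = 7
    min_days: int = 4  # worn days vary per participant in [min_days, n_days]
    n_mirs: int = 84
    true_effect_mirs: dict[str, float] = field(default_factory=dict)
    confounding_strength: float = 0.0
    bout_mean_median: float = 39.0
    bout_mean_sigma: float = 0.45
    bout_day_sigma: float = 0.20  # day-to-day spread of a person's bout mean
    bout_within_sigma: float = 0.60  # within-day spread of bout durations
    hispanic_fraction: float = 0.34
    missing_rate: float = 0.0
    age_mean: float = 65.9
    age_sd: float = 6.6
    age_min: float = 55.0
    bmi_mean: float = 32.8
    bmi_sd: float = 5.0
    bmi_min: float = 25.0
    sitting_time_mean: float = 603.0
    sitting_time_spread: float = 110.0
    mvpa_center: float = 3.5
    walking_center: float = 32.7
    wear_mean: float = 900.0  # minutes/day, 14-16 h window
    wear_sd: float = 30.0
    nonwear_run_minutes: int = 0  # injected all-zero run inside the wear window
    expr_sigma: float = 0.5  # log2 expression noise SD
    ct_control_baseline: float = 25.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 8:
            raise ConfigError("n_participants must be >= 8 so quartiles are formable")
        if self.n_days < 1:
            raise ConfigError("n_days must be >= 1")
        if not 1 <= self.min_days <= self.n_days:
            raise ConfigError("min_days must lie in [1, n_days]")
        if self.n_mirs < 1:
            raise ConfigError("n_mirs must be >= 1")
        for name in ("hispanic_fraction", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        panel = set(default_panel(self.n_mirs))
        extra = set(self.true_effect_mirs) - panel
        if extra:
            raise ConfigError(f"true_effect_mirs not on the panel: {sorted(extra)}")
        for name in ("bout_mean_median", "bout_mean_sigma", "wear_mean", "expr_sigma"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


@dataclass
class TruthRecord:
    """Ground truth stored alongside a generated cohort (never analyzed)."""

    panel: list[str]
    latent_propensity: pd.Series  # per participant, ~N(0,1)
    confounder: pd.Series  # shared covariate factor z
    bout_mean: pd.Series  # per-participant mean sitting bout, minutes
    mvpa_mean: pd.Series  # per-participant MVPA, min/day
    walking_mean: pd.Series
    sitting_target: pd.Series  # per-participant total sitting, min/day
    effects: dict[str, float]  # log2-expression shift per unit latent propensity
    baseline_log2: pd.Series  # per-miR baseline log2 expression
    true_covariates: pd.DataFrame  # pre-missingness covariate table

    def to_json(self, path) -> None:
        payload = {
            "panel": self.panel,
            "latent_propensity": self.latent_propensity.to_dict(),
            "confounder": self.confounder.to_dict(),
            "bout_mean": self.bout_mean.to_dict(),
            "mvpa_mean": self.mvpa_mean.to_dict(),
            "walking_mean": self.walking_mean.to_dict(),
            "sitting_target": self.sitting_target.to_dict(),
            "effects": self.effects,
            "baseline_log2": self.baseline_log2.to_dict(),
            "true_covariates": self.true_covariates.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _participant_ids(n: int) -> list[str]:
    return [f"P{i:04d}" for i in range(1, n + 1)]


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, TruthRecord]:
    """Draw participant covariates and latent behavioral parameters.

    Returns the covariate table (with MCAR missingness applied to waist and
    physical functioning at ``missing_rate``) and the :class:`TruthRecord`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    pids = _participant_ids(n)

    z = rng.normal(size=n)  # shared confounder factor
    cs = float(np.clip(config.confounding_strength, -1.0, 1.0))
    s = cs * z + np.sqrt(max(0.0, 1 - cs**2)) * rng.normal(size=n)

    a = (config.age_min - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(
        a, np.inf, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )
    # BMI loads weakly on the confounder factor; lower-truncated at bmi_min
    bmi_raw = config.bmi_mean + config.bmi_sd * (0.35 * z + 0.937 * rng.normal(size=n))
    bmi = np.where(bmi_raw < config.bmi_min, 2 * config.bmi_min - bmi_raw, bmi_raw)
    waist = 101.4 + 2.2 * (bmi - config.bmi_mean) + rng.normal(0, 6.0, size=n)
    pf = np.clip(
        61.2 + 28.9 * (-0.55 * s + 0.835 * rng.normal(size=n)), 0.0, 100.0
    )
    hispanic = rng.random(n) < config.hispanic_fraction
    study = rng.choice(PARENT_STUDIES, size=n, p=PARENT_STUDY_PROBS)

    covariates = pd.DataFrame(
        {
            "participant_id": pids,
            "age": age,
            "bmi": bmi,
            "waist": waist,
            "physical_functioning": pf,
            "hispanic": hispanic,
            "parent_study": study,
        }
    )
    truth_cov = covariates.copy()

    if config.missing_rate > 0:
        for col in ("waist", "physical_functioning"):
            gone = rng.random(n) < config.missing_rate
            covariates.loc[gone, col] = np.nan

    bout_mean = config.bout_mean_median * np.exp(config.bout_mean_sigma * s)
    # weak negative sitting->MVPA loading: a ~1.4x MVPA ratio between the
    # shortest- and longest-bout extremes, most MVPA variation idiosyncratic
    mvpa_mean = config.mvpa_center * np.exp(-0.15 * s + 0.45 * rng.normal(size=n))
    walking_mean = config.walking_center * np.exp(-0.35 * s + 0.30 * rng.normal(size=n))
    sitting_target = np.clip(
        config.sitting_time_mean
        + config.sitting_time_spread * s
        + rng.normal(0, 40.0, size=n),
        240.0,
        config.wear_mean - 60.0,
    )

    panel = default_panel(config.n_mirs)
    effects = {m: float(e) for m, e in config.true_effect_mirs.items()}
    baseline = pd.Series(rng.normal(3.0, 0.7, size=len(panel)), index=panel)

    idx = pd.Index(pids, name="participant_id")
    truth = TruthRecord(
        panel=panel,
        latent_propensity=pd.Series(s, index=idx),
        confounder=pd.Series(z, index=idx),
        bout_mean=pd.Series(bout_mean, index=idx),
        mvpa_mean=pd.Series(mvpa_mean, index=idx),
        walking_mean=pd.Series(walking_mean, index=idx),
        sitting_target=pd.Series(sitting_target, index=idx),
        effects=effects,
        baseline_log2=baseline,
        true_covariates=truth_cov,
    )
    return covariates, truth


def _simulate_day(
    rng: np.random.Generator,
    config: CohortConfig,
    bout_mean: float,
    sit_target: float,
    mvpa_mean: float,
    walking_mean: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One day of 1440 minute epochs: (counts, posture labels)."""
    wear = int(np.clip(rng.normal(config.wear_mean, config.wear_sd), 840, 960))
    start = int(rng.integers(330, 450))  # device on between ~5:30 and 7:30

    bm_day = bout_mean * np.exp(config.bout_day_sigma * rng.normal())
    frac = float(np.clip(sit_target / config.wear_mean, 0.30, 0.90))
    break_mean = max(1.0, bm_day * (1 - frac) / frac)

    sigma = config.bout_within_sigma

    def draw(mean: float, k: int) -> np.ndarray:
        mu = np.log(mean) - sigma**2 / 2
        return np.maximum(1, np.round(rng.lognormal(mu, sigma, size=k))).astype(int)

    # alternating renewal of sit / non-sit runs until the wear window fills
    starts_sitting = bool(rng.random() < frac)
    pair_mean = bm_day + break_mean
    k = max(4, int(np.ceil(2.5 * wear / pair_mean)) + 4)
    while True:
        sits = draw(bm_day, k)
        breaks = draw(break_mean, k)
        durations = np.empty(2 * k, dtype=int)
        if starts_sitting:
            durations[0::2], durations[1::2] = sits, breaks
        else:
            durations[0::2], durations[1::2] = breaks, sits
        ends = np.cumsum(durations)
        if ends[-1] >= wear:
            break
        k *= 2
    n_runs = int(np.searchsorted(ends, wear)) + 1
    durations = durations[:n_runs].copy()
    durations[-1] -= int(ends[n_runs - 1] - wear)
    is_sit_run = np.zeros(n_runs, dtype=bool)
    is_sit_run[0::2] = starts_sitting
    is_sit_run[1::2] = not starts_sitting

    sit_mask = np.repeat(is_sit_run, durations)
    posture_window = np.full(wear, CODE_SIT, dtype=np.int8)
    nonsit_idx = np.flatnonzero(~sit_mask)

    n_nonsit = len(nonsit_idx)
    n_mvpa = min(n_nonsit, rng.poisson(mvpa_mean))
    n_walk = min(n_nonsit - n_mvpa, rng.poisson(walking_mean))
    n_stand = int(round((n_nonsit - n_mvpa - n_walk) * 0.6))
    n_move = n_nonsit - n_mvpa - n_walk - n_stand
    labels = np.concatenate(
        [
            np.full(n_mvpa + n_walk, CODE_WALK, dtype=np.int8),
            np.full(n_stand, CODE_STAND, dtype=np.int8),
            np.full(n_move, CODE_MOVE, dtype=np.int8),
        ]
    )
    is_mvpa = np.zeros(n_nonsit, dtype=bool)
    is_mvpa[:n_mvpa] = True
    perm = rng.permutation(n_nonsit)
    posture_window[nonsit_idx] = labels[perm]
    mvpa_mask_window = np.zeros(wear, dtype=bool)
    mvpa_mask_window[nonsit_idx] = is_mvpa[perm]

    counts_window = np.empty(wear, dtype=np.int64)
    for code, lo, hi in ((CODE_SIT, 0, 100), (CODE_STAND, 0, 100), (CODE_MOVE, 100, 760)):
        m = posture_window == code
        counts_window[m] = rng.integers(lo, hi, size=int(m.sum()))
    walk_only = (posture_window == CODE_WALK) & ~mvpa_mask_window
    counts_window[walk_only] = rng.integers(760, 1952, size=int(walk_only.sum()))
    counts_window[mvpa_mask_window] = rng.integers(1952, 5000, size=int(mvpa_mask_window.sum()))

    if config.nonwear_run_minutes > 0 and config.nonwear_run_minutes < wear:
        at = int(rng.integers(0, wear - config.nonwear_run_minutes))
        counts_window[at : at + config.nonwear_run_minutes] = 0

    counts = np.zeros(1440, dtype=np.int64)
    posture = np.full(1440, CODE_STAND, dtype=np.int8)
    stop = min(1440, start + wear)
    counts[start:stop] = counts_window[: stop - start]
    posture[start:stop] = posture_window[: stop - start]
    return counts, posture


def generate_activity(truth: TruthRecord, config: CohortConfig, seed_offset: int = 1) -> pd.DataFrame:
    """Minute-epoch table for every participant and day.

    Columns: participant_id, day_index, minute_index, counts, posture.  Each
    day is 1440 minutes; minutes outside the worn window carry zero counts
    (and are flagged non-wear by the Choi-style detector downstream).  The
    number of worn days varies per participant between ``min_days`` and
    ``n_days``, as in protocols asking for at least 4 and up to 14 days.
    """
    rng = np.random.default_rng(config.seed + seed_offset)
    pids = list(truth.latent_propensity.index)
    pid_codes, day_blocks, counts_blocks, posture_blocks = [], [], [], []
    minute = np.arange(1440)
    for code, pid in enumerate(pids):
        n_days = int(rng.integers(config.min_days, config.n_days + 1))
        for day in range(n_days):
            counts, posture = _simulate_day(
                rng,
                config,
                float(truth.bout_mean[pid]),
                float(truth.sitting_target[pid]),
                float(truth.mvpa_mean[pid]),
                float(truth.walking_mean[pid]),
            )
            pid_codes.append(code)
            day_blocks.append(day)
            counts_blocks.append(counts)
            posture_blocks.append(posture)
    n_blocks = len(pid_codes)
    return pd.DataFrame(
        {
            "participant_id": pd.Categorical.from_codes(
                np.repeat(np.array(pid_codes), 1440), categories=pids
            ),
            "day_index": np.repeat(np.array(day_blocks), 1440),
            "minute_index": np.tile(minute, n_blocks),
            "counts": np.concatenate(counts_blocks),
            "posture": pd.Categorical.from_codes(
                np.concatenate(posture_blocks), categories=POSTURE_CATEGORIES
            ),
        }
    )


def generate_ct(
    truth: TruthRecord, config: CohortConfig, seed_offset: int = 2
) -> CtMatrix:
    """Individual-sample Ct matrix for the full panel plus control assays.

    log2 expression of miR j in participant i is
    ``baseline_j + effect_j * s_i + confounding_strength * effect_sign_j * z_i
    + noise``, where the effect and confounding paths act only on the
    designated true-effect miRs; Ct = control baseline - log2(expression).
    Control assays (array control panel, SNORD61, cel-miR-39) sit at the
    control baseline with low variance.
    """
    rng = np.random.default_rng(config.seed + seed_offset)
    pids = list(truth.latent_propensity.index)
    s = truth.latent_propensity.to_numpy()
    z = truth.confounder.to_numpy()
    cs = config.confounding_strength

    rows = {}
    for mir in truth.panel:
        eff = truth.effects.get(mir, 0.0)
        conf_path = cs * (np.sign(eff) if eff != 0 else 0.0)
        log2e = (
            truth.baseline_log2[mir]
            + eff * s
            + conf_path * z
            + rng.normal(0, config.expr_sigma, size=len(pids))
        )
        rows[mir] = config.ct_control_baseline - log2e
    roles = {mir: ROLE_TARGET for mir in truth.panel}

    for name, role in (
        ("array_ctrl_1", ROLE_ARRAY_CONTROL),
        ("array_ctrl_2", ROLE_ARRAY_CONTROL),
        ("SNORD61", ROLE_SNORD61),
        ("cel-miR-39", ROLE_SPIKE_IN),
    ):
        rows[name] = config.ct_control_baseline + rng.normal(0, 0.1, size=len(pids))
        roles[name] = role

    values = pd.DataFrame(rows, index=pids).T.clip(1.0, 49.0)
    values.columns = pids
    return CtMatrix(values, pd.Series(roles))


@dataclass
class StudyData:
    """A full synthetic input bundle: behavior, covariates, and two Ct assays."""

    covariates: pd.DataFrame
    epochs: pd.DataFrame
    ct_screening: CtMatrix
    ct_validation: CtMatrix
    truth: TruthRecord
    config: CohortConfig


def simulate_study(config: CohortConfig) -> StudyData:
    """Generate the complete input bundle for one end-to-end pipeline run.

    Screening and validation Ct matrices are independent measurements of the
    same participants (separate assay noise), mirroring a pooled array run
    followed by individual-sample qPCR.
    """
    covariates, truth = generate_cohort(config)
    epochs = generate_activity(truth, config, seed_offset=1)
    ct_screen = generate_ct(truth, config, seed_offset=2)
    ct_valid = generate_ct(truth, config, seed_offset=3)
    return StudyData(covariates, epochs, ct_screen, ct_valid, truth, config)


def generate_confounded_trial(
    n: int, effect: float = 1.0, confounding: float = 0.8, seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, dict]:
    """A single-outcome confounded trial with known average treatment effect.

    Covariates come from the cohort generator; the treatment propensity is
    logistic in a standardized covariate score (so the propensity model is
    correctly specified), and the outcome is
    ``effect * T + confounding * score + N(0, 1)``.  Returns
    ``(X, t, y, truth)`` with ``truth["true_ate"] == effect``; used for
    bias and confidence-interval coverage checks of the weighted estimator.
    """
    cfg = CohortConfig(n_participants=n, missing_rate=0.0, seed=seed)
    cov, truth = generate_cohort(cfg)
    rng = np.random.default_rng(seed + 7_000_003)
    X = pd.DataFrame(
        {
            "physical_functioning": cov["physical_functioning"].to_numpy(),
            "mvpa": truth.mvpa_mean.to_numpy(),
            "wear_days": 4 + rng.binomial(3, 0.6, size=n).astype(float),
            "wear_time": rng.normal(900, 30, size=n),
            "waist": cov["waist"].to_numpy(),
            "bmi": cov["bmi"].to_numpy(),
            "age": cov["age"].to_numpy(),
        }
    )
    zcols = ["physical_functioning", "bmi", "age"]
    zs = (X[zcols] - X[zcols].mean()) / X[zcols].std(ddof=0)
    score = (-zs["physical_functioning"] + zs["bmi"] + zs["age"]).to_numpy() / np.sqrt(3)
    pi = 1.0 / (1.0 + np.exp(-confounding * score))
    t = (rng.random(n) < pi).astype(float)
    y = effect * t + confounding * score + rng.normal(0, 1, size=n)
    return X, t, y, {"true_ate": float(effect), "score": score}
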