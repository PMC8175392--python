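"""Minute-epoch accelerometer processing.

Derives wear time (Choi-style non-wear detection), sitting bouts, MVPA and
walking minutes, and per-participant activity summaries from minute-level
activity counts with posture labels (``sit``, ``stand``, ``move``, ``walk``).

Conventions follow common practice for hip-worn ActiGraph data in older
adults: non-wear is a long run of zero counts with a short spike tolerance,
an adherent day has at least 10 h (600 min) of wear, and moderate-to-vigorous
physical activity (MVPA) is any wear minute at or above 1952 counts/min.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

POSTURES = ("sit", "stand", "move", "walk")

#: default MVPA cut point, ActiGraph vertical-axis counts per minute
MVPA_CUTPOINT = 1952

#: default adherence thresholds: >=10 h wear per day, >=4 adherent days
MIN_WEAR_MINUTES = 600
MIN_WEAR_DAYS = 4


@dataclass(frozen=True)
class ChoiParams:
    """Non-wear detection parameters.

    window
        minimum run length (minutes) of zeros to call non-wear.
    spike_tolerance
        maximum consecutive nonzero minutes tolerated inside a non-wear run.
    flank
        minimum consecutive zero minutes required on both sides of a
        tolerated spike.
    """

    window: int = 90
    spike_tolerance: int = 2
    flank: int = 30


@dataclass
class ActivitySummary:
    """Per-participant daily-mean activity metrics over adherent days."""

    participant_id: str
    adherent: bool
    wear_days: int
    mean_wear_time: float = np.nan
    total_sitting_time: float = np.nan
    mean_sitting_bout: float = np.nan
    mvpa: float = np.nan
    walking: float = np.nan

    def to_dict(self) -> dict:
        return asdict(self)


def choi_wear_mask(counts: Sequence[int], params: ChoiParams | None = None) -> np.ndarray:
    """Classify each minute as wear (True) / non-wear (False).

    A minute is non-wear iff it lies in a run of at least ``params.window``
    minutes consisting of zero counts, where runs of up to
    ``params.spike_tolerance`` consecutive nonzero minutes are absorbed
    provided they are flanked by at least ``params.flank`` consecutive zeros
    on both sides.
    """
    params = params or ChoiParams()
    c = np.asarray(counts)
    if c.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any(c < 0):
        raise ValueError("activity counts must be nonnegative")

    zero = c == 0
    # maximal zero runs as (start, stop) half-open intervals
    padded = np.concatenate([[False], zero, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)

    wear = np.ones(c.size, dtype=bool)
    if starts.size == 0:
        return wear

    # merge zero runs across short spikes with sufficient zero flanks
    i = 0
    n_runs = starts.size
    while i < n_runs:
        run_start = starts[i]
        run_stop = stops[i]
        j = i
        while j + 1 < n_runs:
            gap = starts[j + 1] - stops[j]
            left_flank = stops[j] - starts[j]
            right_flank = stops[j + 1] - starts[j + 1]
            if (
                gap <= params.spike_tolerance
                and left_flank >= params.flank
                and right_flank >= params.flank
            ):
                j += 1
                run_stop = stops[j]
            else:
                break
        if run_stop - run_start >= params.window:
            wear[run_start:run_stop] = False
        i = j + 1
    return wear


def sitting_bouts(posture: Sequence[str], wear: Sequence[bool]) -> list[int]:
    """Durations (minutes) of maximal runs of sit-labelled wear minutes.

    A non-sit or non-wear minute terminates a bout; there is no minimum
    duration and no tolerance, so a single sitting minute is a bout of 1.
    """
    posture = np.asarray(posture, dtype=object)
    wear = np.asarray(wear, dtype=bool)
    if posture.shape != wear.shape:
        raise ValueError("posture and wear mask must have equal length")
    sitting = (posture == "sit") & wear
    padded = np.concatenate([[False], sitting, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list((stops - starts).astype(int))


def mvpa_minutes(
    counts: Sequence[int], wear: Sequence[bool], cutpoint: int = MVPA_CUTPOINT
) -> int:
    """Number of wear minutes at or above the MVPA cut point (inclusive)."""
    counts = np.asarray(counts)
    wear = np.asarray(wear, dtype=bool)
    if np.any(counts < 0):
        raise ValueError("activity counts must be nonnegative")
    return int(np.sum(wear & (counts >= cutpoint)))


def _walking_minutes(posture: np.ndarray, wear: np.ndarray) -> int:
    return int(np.sum(wear & (posture == "walk")))


def summarize_activity(
    days: Iterable[pd.DataFrame] | pd.DataFrame,
    participant_id: str | None = None,
    min_wear: int = MIN_WEAR_MINUTES,
    min_days: int = MIN_WEAR_DAYS,
    choi: ChoiParams | None = None,
    cutpoint: int = MVPA_CUTPOINT,
    bout_mean_per_day: bool = False,
) -> ActivitySummary:
    """Summarize one participant's minute-epoch days into daily-mean metrics.

    ``days`` is either a single long DataFrame with columns
    ``day_index, counts, posture`` (and optionally ``participant_id``) or an
    iterable of per-day frames.  A day is adherent when its wear time is at
    least ``min_wear`` minutes; participants with fewer than ``min_days``
    adherent days are flagged non-adherent and their metric fields left NaN.

    Sitting metrics are means over adherent days; the mean sitting bout
    duration pools bout durations across adherent days before averaging
    (set ``bout_mean_per_day=True`` for the mean-of-daily-means variant).
    """
    if isinstance(days, pd.DataFrame):
        frame = days
        if participant_id is None:
            ids = frame["participant_id"].unique()
            if len(ids) != 1:
                raise ValueError("frame contains multiple participants; pass one")
            participant_id = str(ids[0])
        day_frames = [g for _, g in frame.groupby("day_index", sort=True)]
    else:
        day_frames = list(days)
        if participant_id is None:
            participant_id = "unknown"
    if not day_frames:
        raise ValueError("at least one day of data is required")

    wear_times, sit_times, mvpas, walks = [], [], [], []
    all_bouts: list[int] = []
    daily_bout_means: list[float] = []
    for day in day_frames:
        counts = day["counts"].to_numpy()
        posture = day["posture"].to_numpy(dtype=object)
        wear = choi_wear_mask(counts, choi)
        wear_min = int(wear.sum())
        if wear_min < min_wear:
            continue
        bouts = sitting_bouts(posture, wear)
        wear_times.append(wear_min)
        sit_times.append(sum(bouts))
        all_bouts.extend(bouts)
        if bouts:
            daily_bout_means.append(float(np.mean(bouts)))
        mvpas.append(mvpa_minutes(counts, wear, cutpoint))
        walks.append(_walking_minutes(posture, wear))

    n_adherent = len(wear_times)
    if n_adherent < min_days:
        return ActivitySummary(participant_id, adherent=False, wear_days=n_adherent)

    if bout_mean_per_day:
        mean_bout = float(np.mean(daily_bout_means)) if daily_bout_means else 0.0
    else:
        mean_bout = float(np.mean(all_bouts)) if all_bouts else 0.0
    return ActivitySummary(
        participant_id,
        adherent=True,
        wear_days=n_adherent,
        mean_wear_time=float(np.mean(wear_times)),
        total_sitting_time=float(np.mean(sit_times)),
        mean_sitting_bout=mean_bout,
        mvpa=float(np.mean(mvpas)),
        walking=float(np.mean(walks)),
    )


def summarize_cohort(
    epochs: pd.DataFrame,
    min_wear: int = MIN_WEAR_MINUTES,
    min_days: int = MIN_WEAR_DAYS,
    choi: ChoiParams | None = None,
    cutpoint: int = MVPA_CUTPOINT,
    bout_mean_per_day: bool = False,
) -> pd.DataFrame:
    """Apply :func:`summarize_activity` to every participant in a long table.

    Returns one row per participant (adherent and non-adherent alike); the
    ``adherent`` column marks who enters downstream analyses.
    """
    rows = []
    for pid, g in epochs.groupby("participant_id", sort=True, observed=True):
        s = summarize_activity(
            g,
            participant_id=str(pid),
            min_wear=min_wear,
            min_days=min_days,
            choi=choi,
            cutpoint=cutpoint,
            bout_mean_per_day=bout_mean_per_day,
        )
        rows.append(s.to_dict())
    return pd.DataFrame(rows)


def read_epochs_csv(path) -> pd.DataFrame:
    """Read a minute-epoch CSV (participant_id, day_index, minute_index, counts, posture)."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    required = {"participant_id", "day_index", "counts", "posture"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"epoch table missing columns: {sorted(missing)}")
    return df
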