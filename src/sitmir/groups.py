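"""Sitter-phenotype classification and RNA pooling plans.

Participants are cross-tabulated by cohort-wide quartiles of mean sitting
bout duration and MVPA.  Interrupted Sitters (IS) sit in short bouts with
low MVPA (bout Q1 x MVPA Q1); Super Sitters (SS) sit in long bouts with low
MVPA (bout Q4 x MVPA Q1).  The augmented groups IS+/SS+ additionally admit
Hispanic women from the second-lowest MVPA quartile at the same bout-duration
extremes, enlarging the groups for ethnicity-stratified validation.

Pooling plans partition a group into pools of three RNA samples (one pool of
two when the group size is 2 mod 3), drawing members from distinct parent
studies when possible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

GROUP_IS = "IS"
GROUP_SS = "SS"
GROUP_NONE = "none"


def quartile_thresholds(values: Sequence[float]) -> tuple[float, float, float]:
    """25th/50th/75th percentile cuts (linear interpolation between order stats)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 4:
        raise ValueError("at least 4 finite values are required to form quartiles")
    q1, q2, q3 = np.percentile(v, [25, 50, 75], method="linear")
    return float(q1), float(q2), float(q3)


def assign_quartiles(values: Sequence[float]) -> np.ndarray:
    """Quartile index (1-4) per value; ties at a cut go to the lower quartile.

    values <= q1 -> 1, (q1, q2] -> 2, (q2, q3] -> 3, above q3 -> 4.
    NaN values get quartile 0 (unassigned).
    """
    q1, q2, q3 = quartile_thresholds(values)
    v = np.asarray(values, dtype=float)
    out = np.zeros(v.size, dtype=int)
    finite = np.isfinite(v)
    out[finite] = 1 + (v[finite] > q1).astype(int) + (v[finite] > q2) + (v[finite] > q3)
    return out


def classify_is_ss(summaries: pd.DataFrame) -> pd.DataFrame:
    """Assign IS/SS labels from an adherent-participant activity summary table.

    Quartiles of ``mean_sitting_bout`` and ``mvpa`` are computed cohort-wide
    over the adherent participants supplied.  Returns a table with columns
    ``participant_id, group, bout_quartile, mvpa_quartile``.
    """
    df = summaries
    if "adherent" in df.columns:
        df = df[df["adherent"]].copy()
    if len(df) < 8:
        raise ValueError("need >=8 adherent participants to form quartile cells")
    bout_q = assign_quartiles(df["mean_sitting_bout"].to_numpy())
    mvpa_q = assign_quartiles(df["mvpa"].to_numpy())
    group = np.full(len(df), GROUP_NONE, dtype=object)
    group[(bout_q == 1) & (mvpa_q == 1)] = GROUP_IS
    group[(bout_q == 4) & (mvpa_q == 1)] = GROUP_SS
    return pd.DataFrame(
        {
            "participant_id": df["participant_id"].astype(str).to_numpy(),
            "group": group,
            "bout_quartile": bout_q,
            "mvpa_quartile": mvpa_q,
        }
    )


def augment_hispanic(assignments: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Add Hispanic, MVPA-Q2 participants at the bout-duration extremes.

    IS+ = IS union {Hispanic, MVPA Q2, bout Q1}; SS+ = SS union {Hispanic,
    MVPA Q2, bout Q4}.  Returns the assignment table with an added
    ``group_plus`` column (values IS, SS, IS_plus_only, SS_plus_only, none).
    Participants with missing ethnicity are skipped with a warning.
    """
    import warnings

    cov = covariates.set_index(covariates["participant_id"].astype(str))
    out = assignments.copy()
    plus = out["group"].to_numpy(dtype=object).copy()
    for i, row in enumerate(out.itertuples(index=False)):
        if row.group != GROUP_NONE:
            continue
        pid = str(row.participant_id)
        if pid not in cov.index or pd.isna(cov.at[pid, "hispanic"]):
            warnings.warn(f"participant {pid}: missing ethnicity, skipped in augmentation")
            continue
        if not bool(cov.at[pid, "hispanic"]) or row.mvpa_quartile != 2:
            continue
        if row.bout_quartile == 1:
            plus[i] = "IS_plus_only"
        elif row.bout_quartile == 4:
            plus[i] = "SS_plus_only"
    out["group_plus"] = plus
    return out


def group_members(assignments: pd.DataFrame, side: str, augmented: bool = False) -> list[str]:
    """Participant ids on one side ('IS' or 'SS'), optionally with + additions."""
    col = "group_plus" if augmented else "group"
    labels = {side} | ({f"{side}_plus_only"} if augmented else set())
    mask = assignments[col].isin(labels)
    return assignments.loc[mask, "participant_id"].astype(str).tolist()


@dataclass
class PoolPlan:
    """One RNA pool: 2-4 members sharing a group label."""

    pool_id: str
    group: str
    members: list[str]
    parent_studies: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "pool_id": self.pool_id,
            "group": self.group,
            "members": list(self.members),
            "parent_studies": list(self.parent_studies),
        }


def _pool_sizes(n: int, remainder_one: str = "four") -> list[int]:
    # pools of 3; n % 3 == 2 -> one pool of 2; n % 3 == 1 -> one pool of 4
    # (or two pools of 2 with remainder_one="two_twos")
    if n < 2:
        raise ValueError("need at least 2 members to pool")
    r = n % 3
    if r == 0:
        return [3] * (n // 3)
    if r == 2:
        return [3] * (n // 3) + [2]
    if remainder_one == "two_twos" and n >= 4:
        return [3] * (n // 3 - 1) + [2, 2]
    return [3] * (n // 3 - 1) + [4]


def make_pools(
    members: Sequence[str],
    parent_studies: Sequence[str],
    group: str,
    seed: int,
    remainder_one: str = "four",
) -> list[PoolPlan]:
    """Partition a group into RNA pools maximizing parent-study diversity.

    Greedy assignment: each pool draws its members from the parent studies
    with the most unassigned samples remaining (so pools of 3 contain one
    sample from each of three studies when possible); order within a study
    is randomized by ``seed``.
    """
    members = [str(m) for m in members]
    studies = [str(s) for s in parent_studies]
    if len(members) != len(studies):
        raise ValueError("members and parent_studies must have equal length")
    rng = np.random.default_rng(seed)

    by_study: dict[str, list[str]] = {}
    for m, s in zip(members, studies):
        by_study.setdefault(s, []).append(m)
    for s in by_study:
        order = rng.permutation(len(by_study[s]))
        by_study[s] = [by_study[s][i] for i in order]

    plans: list[PoolPlan] = []
    for k, size in enumerate(_pool_sizes(len(members), remainder_one)):
        chosen: list[str] = []
        chosen_st: list[str] = []
        for _ in range(size):
            # prefer studies not yet in this pool, then the largest backlog;
            # random tie-break via rng
            candidates = [s for s in by_study if by_study[s]]
            fresh = [s for s in candidates if s not in chosen_st]
            source = fresh if fresh else candidates
            sizes = np.array([len(by_study[s]) for s in source])
            best = [s for s, n in zip(source, sizes) if n == sizes.max()]
            pick = best[rng.integers(len(best))] if len(best) > 1 else best[0]
            chosen.append(by_study[pick].pop())
            chosen_st.append(pick)
        plans.append(PoolPlan(f"{group}_pool{k + 1:02d}", group, chosen, chosen_st))
    return plans


def write_pool_plans(plans: Sequence[PoolPlan], path) -> None:
    with open(path, "w") as fh:
        json.dump([p.to_dict() for p in plans], fh, indent=2)


def read_pool_plans(path) -> list[PoolPlan]:
    with open(path) as fh:
        raw = json.load(fh)
    return [PoolPlan(d["pool_id"], d["group"], d["members"], d.get("parent_studies", [])) for d in raw]
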