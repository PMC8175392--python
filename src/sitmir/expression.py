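"""qPCR cycle-threshold handling: pooling and delta-Ct relative expression.

A :class:`CtMatrix` holds raw Ct values for 84 cardiovascular-disease-related
target microRNAs plus control assays, one column per sample (or RNA pool).
Relative expression is 2^-dCt, where dCt normalizes each target against the
mean Ct of the stage's control assays: the array control panel during
screening of pooled samples, and SNORD61 + the cel-miR-39 spike-in during
individual-sample validation.

Pooling equal RNA masses averages molecule abundance on the *linear* scale,
so a pooled Ct is -log2 of the mean of 2^-Ct over the detected members.
Not-detected reactions are carried as NaN and excluded from control means
and pooling; they are never imputed to a ceiling cycle by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ROLE_TARGET = "target"
ROLE_ARRAY_CONTROL = "array_control"
ROLE_SNORD61 = "snord61"
ROLE_SPIKE_IN = "cel_mir_39"

STAGE_CONTROLS = {
    "screening": (ROLE_ARRAY_CONTROL,),
    "validation": (ROLE_SNORD61, ROLE_SPIKE_IN),
}


@dataclass
class CtMatrix:
    """Ct values (assays x samples) with per-assay role annotations."""

    values: pd.DataFrame  # index: assay names; columns: sample/pool ids
    roles: pd.Series  # index: assay names; values: role strings

    def __post_init__(self) -> None:
        self.roles = self.roles.reindex(self.values.index)
        if self.roles.isna().any():
            missing = self.roles.index[self.roles.isna()].tolist()
            raise ValueError(f"assays without a role annotation: {missing}")
        detected = self.values.to_numpy(dtype=float)
        bad = np.isfinite(detected) & ((detected <= 0) | (detected >= 50))
        if bad.any():
            raise ValueError("detected Ct values must lie in (0, 50)")

    @property
    def targets(self) -> list[str]:
        return list(self.roles.index[self.roles == ROLE_TARGET])

    def control_assays(self, stage: str) -> list[str]:
        if stage not in STAGE_CONTROLS:
            raise ValueError(f"stage must be one of {sorted(STAGE_CONTROLS)}, got {stage!r}")
        wanted = STAGE_CONTROLS[stage]
        return list(self.roles.index[self.roles.isin(wanted)])

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "role", self.roles.to_numpy())
        out.to_csv(path, index_label="assay")

    @classmethod
    def from_csv(cls, path) -> "CtMatrix":
        df = pd.read_csv(path, index_col="assay")
        roles = df.pop("role")
        return cls(df.astype(float), roles)


def pool_ct(ct: CtMatrix, pools: Iterable) -> CtMatrix:
    """Combine member sample columns into pooled columns.

    Equal-mass pooling: pooled linear abundance per assay is the arithmetic
    mean of the members' 2^-Ct; pooled Ct = -log2(mean).  Members that are
    not detected (NaN) for an assay are excluded from that assay's mean; a
    pool where no member detects the assay is not detected.
    """
    cols = {}
    for pool in pools:
        missing = [m for m in pool.members if m not in ct.values.columns]
        if missing:
            raise ValueError(f"pool {pool.pool_id}: member columns not found: {missing}")
        member_ct = ct.values[list(pool.members)].to_numpy(dtype=float)
        linear = np.power(2.0, -member_ct)
        detected = np.isfinite(linear)
        n_det = detected.sum(axis=1)
        total = np.nansum(np.where(detected, linear, 0.0), axis=1)
        pooled = np.full(member_ct.shape[0], np.nan)
        ok = n_det > 0
        pooled[ok] = -np.log2(total[ok] / n_det[ok])
        cols[pool.pool_id] = pooled
    values = pd.DataFrame(cols, index=ct.values.index)
    return CtMatrix(values, ct.roles.copy())


def relative_expression(ct: CtMatrix, stage: str) -> pd.DataFrame:
    """Relative expression 2^-dCt of every target assay, per column.

    dCt(target, column) = Ct(target) - mean Ct of the stage's control assays
    in that column.  Raises if a column has no detected control.
    """
    controls = ct.control_assays(stage)
    if not controls:
        raise ValueError(f"Ct matrix carries no control assays for stage {stage!r}")
    ctrl = ct.values.loc[controls]
    ctrl_mean = ctrl.mean(axis=0, skipna=True)
    dead = ctrl_mean.index[ctrl_mean.isna()]
    if len(dead):
        raise ValueError(f"columns without any detected control assay: {list(dead)}")
    target_ct = ct.values.loc[ct.targets]
    delta = target_ct.sub(ctrl_mean, axis=1)
    expr = np.power(2.0, -delta)
    expr.attrs["stage"] = stage
    return expr
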