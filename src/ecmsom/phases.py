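"""Nutritional-phase detection from culture chemistry.

The incubation passes through four phases: active growth (AG, glucose
and ammonium both present), ammonium depletion (ND), carbon/glucose
depletion (CD, glucose below the 1 mg C L^-1 detection limit), and
prolonged carbon depletion (pCD). One analysis time point is selected
per phase from the sampled chemistry grid by threshold rules:

* t1 (AG):  latest sampled time with glucose AND ammonium above threshold
* t2 (ND):  earliest sampled time with ammonium depleted, glucose present
* t3 (CD):  earliest sampled time with glucose depleted
* t4 (pCD): earliest sampled time at least ``pcd_lag`` hours after t3

Replicate trajectories are averaged before thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import IncompletePhaseError, InvalidDesignError, PhaseOrderError

__all__ = ["PhaseAssignment", "detect_phases", "PHASE_LABELS"]

PHASE_LABELS = ("AG", "ND", "CD", "pCD")

DEFAULT_GLUCOSE_THRESHOLD = 1.0      # mg C L^-1, the glucose detection limit
DEFAULT_AMMONIUM_FRAC = 0.02         # ammonium threshold as fraction of initial
DEFAULT_PCD_LAG = 150.0              # h between CD onset and the pCD time point


@dataclass(frozen=True)
class PhaseAssignment:
    """Selected analysis time points and the thresholds that produced them."""

    t1: float
    t2: float
    t3: float
    t4: float
    glucose_threshold: float
    ammonium_threshold: float
    pcd_lag: float
    labels: tuple[str, ...] = PHASE_LABELS

    @property
    def times(self) -> tuple[float, float, float, float]:
        return (self.t1, self.t2, self.t3, self.t4)

    def to_dict(self) -> dict:
        return {
            "times": dict(zip(self.labels, self.times)),
            "glucose_threshold": self.glucose_threshold,
            "ammonium_threshold": self.ammonium_threshold,
            "pcd_lag": self.pcd_lag,
        }


def _mean_trajectory(traj: pd.DataFrame) -> pd.DataFrame:
    needed = {"time", "glucose_C", "ammonium_N"}
    missing = needed - set(traj.columns)
    if missing:
        raise InvalidDesignError(f"trajectory missing columns: {sorted(missing)}")
    mean = traj.groupby("time", sort=True)[["glucose_C", "ammonium_N"]].mean()
    times = mean.index.to_numpy(dtype=float)
    if len(times) < 2 or not np.all(np.diff(times) > 0):
        raise InvalidDesignError("trajectory times must be strictly increasing")
    return mean


def detect_phases(
    traj: pd.DataFrame,
    glucose_threshold: float = DEFAULT_GLUCOSE_THRESHOLD,
    ammonium_threshold: float | None = None,
    pcd_lag: float = DEFAULT_PCD_LAG,
) -> PhaseAssignment:
    """Assign the four analysis time points from a chemistry trajectory.

    Parameters
    ----------
    traj:
        Tidy chemistry frame with ``time``, ``glucose_C``, ``ammonium_N``
        columns (replicates stacked; they are averaged per time).
    glucose_threshold:
        Glucose-C detection limit in mg C L^-1.
    ammonium_threshold:
        Ammonium-N depletion threshold in mg N L^-1. Defaults to 2% of
        the initial (first-time-point) ammonium level, a scale-free rule.
    pcd_lag:
        Hours after CD onset at which the pCD time point is taken.

    Raises
    ------
    IncompletePhaseError
        If glucose (or ammonium) never crosses its threshold, or no
        sampled time lies ``pcd_lag`` after CD onset.
    PhaseOrderError
        If ammonium depletes at or after glucose depletion.
    """
    mean = _mean_trajectory(traj)
    times = mean.index.to_numpy(dtype=float)
    glc = mean["glucose_C"].to_numpy()
    amm = mean["ammonium_N"].to_numpy()
    if ammonium_threshold is None:
        ammonium_threshold = DEFAULT_AMMONIUM_FRAC * float(amm[0])

    glc_dep = glc <= glucose_threshold
    amm_dep = amm <= ammonium_threshold
    if not glc_dep.any():
        raise IncompletePhaseError("CD", "glucose never crosses its threshold: no CD phase")
    if not amm_dep.any():
        raise IncompletePhaseError("ND", "ammonium never crosses its threshold: no ND phase")

    i3 = int(np.argmax(glc_dep))                      # earliest glucose depletion
    i_amm = int(np.argmax(amm_dep))                   # earliest ammonium depletion
    if i_amm >= i3:
        raise PhaseOrderError(
            "ammonium depletes at/after glucose depletion; phase order AG<ND<CD is violated")

    nd_mask = amm_dep & ~glc_dep
    if not nd_mask.any():
        raise IncompletePhaseError("ND", "no sampled time with ammonium depleted but glucose present")
    i2 = int(np.argmax(nd_mask))

    ag_mask = (~amm_dep) & (~glc_dep)
    ag_mask[i2:] = False                              # AG must precede ND
    if not ag_mask.any():
        raise IncompletePhaseError("AG", "no sampled time with both nutrients above threshold")
    i1 = int(np.nonzero(ag_mask)[0][-1])              # latest AG time

    t3 = times[i3]
    pcd_mask = times >= t3 + pcd_lag
    if not pcd_mask.any():
        raise IncompletePhaseError("pCD", f"no sampled time >= {t3 + pcd_lag} h for pCD")
    i4 = int(np.argmax(pcd_mask))

    t1, t2, t4 = times[i1], times[i2], times[i4]
    if not (t1 < t2 < t3 < t4):
        raise PhaseOrderError(f"selected times not strictly ordered: {(t1, t2, t3, t4)}")
    return PhaseAssignment(
        t1=float(t1), t2=float(t2), t3=float(t3), t4=float(t4),
        glucose_threshold=float(glucose_threshold),
        ammonium_threshold=float(ammonium_threshold),
        pcd_lag=float(pcd_lag))
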