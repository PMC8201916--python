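"""Dynamic segregation–integration state measures on window trajectories.

Each sliding-window FC yields a balance value H_B^t; a recording is thereby
reduced to a trajectory that visits the integrated state (H_B^t >= 0, the
boundary counts as integrated) and the segregated state (H_B^t < 0).  The
summary measures are

    dwell times      T_In = t(H_B^t >= 0)/t_all,  T_Se = t(H_B^t < 0)/t_all,
    switching rate   f_IS = n / t_all, n = #{t : H_B^t · H_B^{t+1} <= 0},
    deviations       D_In = mean of H_B^t on the integrated side,
                     D_Se = mean of |H_B^t| on the segregated side,

with T_B = T_In − T_Se and D_IS = D_In + D_Se.  Every window contributes tr
seconds, so t_all = window count × tr.  An empty side leaves its deviation
at 0 (with a warning); runs of consecutive zeros count one crossing per
adjacent zero product.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .calibration import calibrate_dynamic
from .core import nsp_profile
from .fc import DynamicFCSeries

logger = logging.getLogger("nspbalance")

__all__ = [
    "DynamicTrajectory",
    "DynamicSummary",
    "balance_trajectory",
    "dwell_times",
    "switching_frequency",
    "deviations",
    "summarize_trajectory",
]


@dataclass
class DynamicTrajectory:
    """Per-window balance values H_B^t with their time base."""

    hbt: np.ndarray
    tr: float
    window_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.hbt = np.asarray(self.hbt, dtype=float)
        if self.hbt.size == 0:
            raise ValueError("empty balance trajectory")
        if not np.all(np.isfinite(self.hbt)):
            raise ValueError("trajectory contains non-finite values")
        if not self.tr > 0:
            raise ValueError("tr must be positive")

    @property
    def n_windows(self) -> int:
        return self.hbt.size

    @property
    def t_all(self) -> float:
        """Total dynamic-analysis time in seconds (window count × tr)."""
        return self.n_windows * self.tr


@dataclass
class DynamicSummary:
    t_in: float
    t_se: float
    t_b: float
    f_is: float
    d_in: float
    d_se: float
    d_is: float


def balance_trajectory(
    dyn: DynamicFCSeries,
    static_h_se: float | None = None,
    static_h_in: float | None = None,
) -> DynamicTrajectory:
    """Per-window balance trajectory of a dynamic FC series.

    Each window FC is scored with the nested-spectral profile.  When the
    subject's calibrated static components are supplied, both per-window
    streams are rescaled to them before the balance is formed; otherwise the
    raw streams are used.
    """
    h_se = np.empty(dyn.n_windows)
    h_in = np.empty(dyn.n_windows)
    for k, window in enumerate(dyn.windows):
        profile = nsp_profile(window)
        h_se[k] = profile.segregation
        h_in[k] = profile.integration
    if (static_h_se is None) != (static_h_in is None):
        raise ValueError("supply both calibrated static components or neither")
    if static_h_se is not None:
        h_se, h_in = calibrate_dynamic(h_se, h_in, static_h_se, static_h_in)
    starts = np.asarray(dyn.start_frames, dtype=float)
    return DynamicTrajectory(
        hbt=h_in - h_se,
        tr=dyn.spec.tr,
        window_times=starts * dyn.spec.tr,
    )


def dwell_times(traj: DynamicTrajectory) -> tuple[float, float, float]:
    """Fractions of total time spent integrated / segregated, and T_B.

    H_B^t = 0 counts as integrated; T_In + T_Se = 1 by construction.
    """
    integrated = traj.hbt >= 0
    t_in = float(integrated.mean())
    t_se = 1.0 - t_in
    return t_in, t_se, t_in - t_se


def switching_frequency(traj: DynamicTrajectory) -> float:
    """Sign-change rate f_IS = n / t_all (per second).

    n counts adjacent window pairs whose balance product is <= 0; a window
    sitting exactly at zero therefore registers a crossing with each
    neighbour.
    """
    if traj.n_windows < 2:
        raise ValueError("switching frequency needs at least 2 windows")
    products = traj.hbt[:-1] * traj.hbt[1:]
    n = int(np.count_nonzero(products <= 0))
    return n / traj.t_all


def deviations(traj: DynamicTrajectory) -> tuple[float, float, float]:
    """Mean excursion amplitudes on each side of balance, and their sum.

    D_In averages H_B^t over integrated windows; D_Se averages |H_B^t| over
    segregated windows; a side that is never visited contributes 0.
    """
    pos = traj.hbt[traj.hbt >= 0]
    neg = traj.hbt[traj.hbt < 0]
    if pos.size == 0:
        warnings.warn("no integrated windows; D_In set to 0", stacklevel=2)
        d_in = 0.0
    else:
        d_in = float(pos.mean())
    if neg.size == 0:
        warnings.warn("no segregated windows; D_Se set to 0", stacklevel=2)
        d_se = 0.0
    else:
        d_se = float(np.abs(neg).mean())
    return d_in, d_se, d_in + d_se


def summarize_trajectory(traj: DynamicTrajectory) -> DynamicSummary:
    """All dynamic state measures of one trajectory."""
    t_in, t_se, t_b = dwell_times(traj)
    f_is = switching_frequency(traj)
    d_in, d_se, d_is = deviations(traj)
    return DynamicSummary(
        t_in=t_in, t_se=t_se, t_b=t_b, f_is=f_is, d_in=d_in, d_se=d_se, d_is=d_is
    )
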