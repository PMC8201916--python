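"""Length-bias calibration of segregation/integration components.

Short fMRI series inflate segregation estimates, so raw components are not
comparable across scan lengths.  The correction is proportional: the cohort
vectors of segregation and integration components are each rescaled so their
cohort means equal a reference integration level H_In^S (0.18 for the
long-run stable FC of the reference cohort, which coincides with the model's
integration at the balanced coupling).  After static calibration the cohort
mean balance is exactly zero and every subject keeps their rank.  Dynamic
(per-window) components are then rescaled per subject so that each stream's
window mean equals that subject's calibrated static value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("nspbalance")

__all__ = [
    "CohortComponents",
    "CalibrationParams",
    "calibrate_static",
    "calibrate_dynamic",
]


@dataclass
class CohortComponents:
    """Per-subject segregation and integration components of a cohort."""

    subjects: list[str]
    h_se: np.ndarray
    h_in: np.ndarray

    def __post_init__(self) -> None:
        self.h_se = np.asarray(self.h_se, dtype=float)
        self.h_in = np.asarray(self.h_in, dtype=float)
        if not (len(self.subjects) == self.h_se.size == self.h_in.size):
            raise ValueError("subjects, h_se and h_in must have equal length")
        if self.h_se.size < 1:
            raise ValueError("cohort must contain at least one subject")
        if np.any(self.h_se < 0) or np.any(self.h_in < 0):
            raise ValueError("components must be non-negative")

    @property
    def h_b(self) -> np.ndarray:
        return self.h_in - self.h_se


@dataclass(frozen=True)
class CalibrationParams:
    """Reference integration level H_In^S the cohort means are scaled to."""

    reference_integration: float = 0.18

    def __post_init__(self) -> None:
        if not self.reference_integration > 0:
            raise ValueError("reference integration must be positive")


@dataclass
class StaticCalibration:
    """Calibrated cohort plus the two scale factors that were applied."""

    cohort: CohortComponents
    factor_se: float
    factor_in: float


def calibrate_static(
    cohort: CohortComponents, params: CalibrationParams = CalibrationParams()
) -> StaticCalibration:
    """Rescale cohort components so both cohort means equal H_In^S.

    HSe'_i = HSe_i · H_In^S / <HSe>  and  HIn'_i = HIn_i · H_In^S / <HIn>.
    Rank order within each stream is preserved (positive scaling) and the
    cohort mean of the calibrated balance is exactly zero.  Idempotent:
    calibrating a calibrated cohort changes nothing.
    """
    mean_se = float(cohort.h_se.mean())
    mean_in = float(cohort.h_in.mean())
    if mean_se <= 0 or mean_in <= 0:
        raise ValueError("calibration undefined: cohort mean component is zero")
    if len(cohort.subjects) == 1:
        warnings.warn(
            "calibrating a single-subject cohort: the scale factors are "
            "computed from that subject alone",
            stacklevel=2,
        )
    ref = params.reference_integration
    factor_se = ref / mean_se
    factor_in = ref / mean_in
    calibrated = CohortComponents(
        subjects=list(cohort.subjects),
        h_se=cohort.h_se * factor_se,
        h_in=cohort.h_in * factor_in,
    )
    logger.info(
        "static calibration: n=%d factors se=%.6g in=%.6g ref=%.4g",
        len(cohort.subjects), factor_se, factor_in, ref,
    )
    return StaticCalibration(cohort=calibrated, factor_se=factor_se, factor_in=factor_in)


def calibrate_dynamic(
    traj_h_se: np.ndarray,
    traj_h_in: np.ndarray,
    static_h_se: float,
    static_h_in: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale per-window component streams to a subject's calibrated statics.

    Each stream is multiplied by ``static' / <stream>`` so its window mean
    equals the subject's calibrated static component; window-to-window
    ordering is untouched.
    """
    traj_h_se = np.asarray(traj_h_se, dtype=float)
    traj_h_in = np.asarray(traj_h_in, dtype=float)
    if traj_h_se.shape != traj_h_in.shape:
        raise ValueError("segregation and integration trajectories differ in length")
    mean_se = float(traj_h_se.mean())
    mean_in = float(traj_h_in.mean())
    if mean_se <= 0 or mean_in <= 0:
        raise ValueError("calibration undefined: window mean component is zero")
    return (
        traj_h_se * (static_h_se / mean_se),
        traj_h_in * (static_h_in / mean_in),
    )
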