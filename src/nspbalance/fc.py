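"""Functional-connectivity construction from regional BOLD series.

Static FC is the Pearson correlation between regional time series over all
frames, with negative correlations clipped to zero and the diagonal forced to
one — no further cleaning is applied.  Dynamic FC tiles the series with a
sliding window and applies the identical construction inside every window.

The window count for ``n_frames`` frames, width ``w`` and step ``s`` is
``floor((n_frames - w) / s)`` — note NOT the ``n - w + 1`` of many sliding
implementations.  For the reference resting-state protocol (4 sessions of
1200 frames at TR 0.72 s, width 83 frames, step 1) this yields 4,717 windows
of 59.76 s covering 3,396.24 s of analysis time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np

logger = logging.getLogger("nspbalance")

__all__ = [
    "BoldSeries",
    "FCMatrix",
    "WindowSpec",
    "DynamicFCSeries",
    "build_static_fc",
    "sliding_windows",
    "build_dynamic_fc",
    "save_dynamic_fc",
    "load_dynamic_fc",
]


@dataclass
class BoldSeries:
    """Region x frame activity matrix with acquisition metadata.

    Parameters
    ----------
    data
        ``(n_regions, n_frames)`` real matrix, regions in rows.
    tr
        Seconds per frame (repetition time).
    session_breaks
        Frame indices where independent sessions were concatenated;
        bookkeeping only — correlations are always computed over the
        concatenated series.
    """

    data: np.ndarray
    tr: float = 0.72
    session_breaks: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] < 2:
            raise ValueError("BOLD series needs at least 2 regions")
        if self.data.shape[1] < 3:
            raise ValueError("BOLD series needs at least 3 frames")
        if not self.tr > 0:
            raise ValueError("tr must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD series contains non-finite values")
        flat = np.flatnonzero(np.ptp(self.data, axis=1) == 0)
        if flat.size:
            raise ValueError(
                f"region {flat[0] + 1} has zero variance (constant series)"
            )

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


@dataclass
class FCMatrix:
    """Symmetric correlation matrix with unit diagonal and entries in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("FC matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ValueError("FC matrix diagonal must be 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("FC entries must lie in [0, 1] after clipping")

    @classmethod
    def from_array(cls, values: np.ndarray, clip: bool = True) -> "FCMatrix":
        """Coerce a raw correlation matrix: symmetrize to tolerance, clip
        negatives to zero, force the diagonal to exactly one."""
        v = np.asarray(values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("FC matrix must be symmetric")
        v = 0.5 * (v + v.T)
        if clip:
            v = np.clip(v, 0.0, None)
        np.fill_diagonal(v, 1.0)
        return cls(v)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: width and step in frames, tr in seconds."""

    width: int
    step: int = 1
    tr: float = 0.72

    def __post_init__(self) -> None:
        if self.width < 2:
            raise ValueError("window width must be >= 2 frames")
        if self.step < 1:
            raise ValueError("window step must be >= 1 frame")
        if not self.tr > 0:
            raise ValueError("tr must be positive")

    @property
    def duration(self) -> float:
        """Window length in seconds (width x tr)."""
        return self.width * self.tr


@dataclass
class DynamicFCSeries:
    """Ordered per-window FC matrices with their start frames."""

    windows: list[FCMatrix]
    start_frames: np.ndarray
    spec: WindowSpec

    def __post_init__(self) -> None:
        self.start_frames = np.asarray(self.start_frames, dtype=int)
        if len(self.windows) != len(self.start_frames):
            raise ValueError("windows and start_frames length mismatch")
        if len(self.windows):
            n = self.windows[0].n_regions
            if any(w.n_regions != n for w in self.windows):
                raise ValueError("all window FC matrices must share one size")
        steps = np.diff(self.start_frames)
        if steps.size and not np.all(steps == self.spec.step):
            raise ValueError("start frames must increase by exactly the step")

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def n_regions(self) -> int:
        return self.windows[0].n_regions

    @property
    def total_time(self) -> float:
        """Total dynamic-analysis time in seconds: window count x tr."""
        return self.n_windows * self.spec.tr


def _pearson_fc(data: np.ndarray, context: str = "") -> FCMatrix:
    flat = np.flatnonzero(np.ptp(data, axis=1) == 0)
    if flat.size:
        raise ValueError(
            f"region {flat[0] + 1} has zero variance{context}; "
            "correlation undefined"
        )
    corr = np.corrcoef(data)
    return FCMatrix.from_array(corr, clip=True)


def build_static_fc(bold: BoldSeries) -> FCMatrix:
    """Pearson-correlation FC over all frames, negatives clipped to zero.

    Session breaks are ignored here by design: sessions are concatenated
    before correlating, which is what makes long-run FC estimates stable.
    """
    fc = _pearson_fc(bold.data)
    logger.info("static FC built: %d regions, %d frames", bold.n_regions, bold.n_frames)
    return fc


def sliding_windows(n_frames: int, spec: WindowSpec) -> np.ndarray:
    """Start frames of every sliding window.

    The adopted count is ``floor((n_frames - width) / step)``; window ``k``
    covers frames ``[k*step, k*step + width - 1]`` (0-based).
    """
    if n_frames <= spec.width:
        raise ValueError(
            f"series too short: {n_frames} frames <= window width {spec.width}"
        )
    n_windows = (n_frames - spec.width) // spec.step
    return np.arange(n_windows, dtype=int) * spec.step


def build_dynamic_fc(bold: BoldSeries, spec: WindowSpec) -> DynamicFCSeries:
    """Per-window FC matrices, each built exactly like the static FC."""
    starts = sliding_windows(bold.n_frames, spec)
    windows: list[FCMatrix] = []
    for k, s in enumerate(starts):
        segment = bold.data[:, s : s + spec.width]
        try:
            windows.append(_pearson_fc(segment, context=f" in window {k + 1}"))
        except ValueError as exc:
            raise ValueError(str(exc)) from None
    logger.info(
        "dynamic FC built: %d windows of width %d (step %d)",
        len(windows), spec.width, spec.step,
    )
    return DynamicFCSeries(windows=windows, start_frames=starts, spec=spec)


def save_dynamic_fc(dyn: DynamicFCSeries, path: str) -> None:
    """Store a window stack in one HDF5 container instead of many small files."""
    stack = np.stack([w.values for w in dyn.windows])
    with h5py.File(path, "w") as fh:
        fh.create_dataset("fc_stack", data=stack, compression="gzip")
        fh.create_dataset("start_frames", data=dyn.start_frames)
        fh.attrs["width"] = dyn.spec.width
        fh.attrs["step"] = dyn.spec.step
        fh.attrs["tr"] = dyn.spec.tr


def load_dynamic_fc(path: str) -> DynamicFCSeries:
    with h5py.File(path, "r") as fh:
        stack = fh["fc_stack"][()]
        starts = fh["start_frames"][()]
        spec = WindowSpec(
            width=int(fh.attrs["width"]),
            step=int(fh.attrs["step"]),
            tr=float(fh.attrs["tr"]),
        )
    windows = [FCMatrix(values=m) for m in stack]
    return DynamicFCSeries(windows=windows, start_frames=starts, spec=spec)
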