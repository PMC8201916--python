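"""Synthetic structural connectomes, model cohorts, and worked fixtures.

The generator emulates the statistical structure the analysis assumes:

* modular, weighted, symmetric SC matrices — block-constant means (strong
  within-block, weak between-block weights) plus truncated Gaussian noise;
* stationary model BOLD series whose long-run correlation matches the
  diffusion model's analytic FC;
* cohorts of synthetic individuals spanning the segregation→integration
  axis by varying the single physiological dial the model has, the global
  coupling c, on a grid bracketing the SC's balanced coupling c*.

All randomness flows from one master seed through per-subject spawned
seeds, so any individual subject is reproducible in isolation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .core import ComponentProfile
from .fc import BoldSeries, FCMatrix
from .model import StructuralMatrix, coupling_sweep, sample_bold

logger = logging.getLogger("nspbalance")

__all__ = [
    "SyntheticSpec",
    "Cohort",
    "make_modular_sc",
    "make_cohort",
    "worked_example_fixture",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth parameters of the synthetic study conditions.

    Defaults describe the canonical desk-scale cohort: a 10-region SC with
    two equal modules (within-block weight 1.0, between-block 0.2, noise sd
    0.1), 20 subjects of 2×10⁴ frames at TR 0.72 s, integration step 0.05
    model-time units.  ``coupling_range`` of ``None`` means "derive a range
    bracketing the SC's own balanced coupling c*" (0.25·c* to 2.5·c*).
    """

    n_regions: int = 10
    block_sizes: tuple[int, ...] = (5, 5)
    within_strength: float = 1.0
    between_strength: float = 0.2
    weight_noise: float = 0.1
    coupling: float | None = None
    coupling_range: tuple[float, float] | None = None
    n_subjects: int = 20
    n_frames: int = 20_000
    tr: float = 0.72
    dt: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.block_sizes) != self.n_regions:
            raise ValueError("block sizes must sum to n_regions")
        if self.within_strength < 0 or self.between_strength < 0:
            raise ValueError("strengths must be non-negative")
        if self.within_strength <= self.between_strength:
            raise ValueError(
                "within-block strength must exceed between-block strength "
                "for modular ground truth"
            )
        if self.weight_noise < 0:
            raise ValueError("weight noise must be non-negative")


def make_modular_sc(spec: SyntheticSpec, max_retries: int = 20) -> StructuralMatrix:
    """Block-structured SC: block means plus truncated (clipped-at-zero)
    Gaussian noise on the upper triangle, symmetrised, zero diagonal.

    Disconnected draws are resampled with fresh spawned seeds up to
    ``max_retries`` times before erroring.
    """
    n = spec.n_regions
    block_of = np.repeat(np.arange(len(spec.block_sizes)), spec.block_sizes)
    means = np.where(
        block_of[:, None] == block_of[None, :],
        spec.within_strength,
        spec.between_strength,
    ).astype(float)
    ss = np.random.SeedSequence(spec.seed)
    attempts = [ss] + list(ss.spawn(max_retries - 1))
    for attempt, child in enumerate(attempts):
        rng = np.random.default_rng(child)
        noise = rng.normal(0.0, spec.weight_noise, size=(n, n))
        noise = np.triu(noise, k=1)
        w = np.clip(means + noise + noise.T, 0.0, None)
        np.fill_diagonal(w, 0.0)
        sc = StructuralMatrix(values=w)
        if sc.is_connected():
            logger.info("modular SC generated: N=%d attempt=%d", n, attempt + 1)
            return sc
    raise RuntimeError(
        f"could not draw a connected SC in {max_retries} attempts; "
        "raise between_strength or lower weight_noise"
    )


@dataclass
class Cohort:
    """Synthetic individuals: one model BOLD series per coupling value."""

    sc: StructuralMatrix
    bold: list[BoldSeries]
    couplings: np.ndarray
    seeds: list[int]
    spec: SyntheticSpec

    @property
    def n_subjects(self) -> int:
        return len(self.bold)


def _default_coupling_range(sc: StructuralMatrix) -> tuple[float, float]:
    """Range bracketing the SC's balanced coupling: (0.25·c*, 2.5·c*)."""
    # coarse geometric grid; c* of desk-scale SCs falls well inside it
    grid = np.geomspace(1e-3, 1e3, 61)
    sweep = coupling_sweep(sc, grid)
    if sweep.balance_coupling is None:
        raise RuntimeError("no balanced coupling found on the probe grid")
    c_star = sweep.balance_coupling
    return (0.25 * c_star, 2.5 * c_star)


def make_cohort(spec: SyntheticSpec, sc: StructuralMatrix | None = None) -> Cohort:
    """Simulate a cohort spanning the segregation→integration axis.

    Subject k is integrated at coupling c_k, a linear grid over the coupling
    range; when the range does not bracket the SC's balanced coupling the
    cohort is one-sided and a warning is raised.
    """
    if sc is None:
        sc = make_modular_sc(spec)
    c_range = spec.coupling_range
    if c_range is None:
        c_range = _default_coupling_range(sc)
    lo, hi = c_range
    if not 0 <= lo < hi:
        raise ValueError("coupling range must satisfy 0 <= lo < hi")
    probe = coupling_sweep(sc, np.linspace(max(lo, 1e-6), hi, 31))
    c_star = probe.balance_coupling
    if c_star is None:
        warnings.warn(
            "coupling range does not bracket the balanced coupling; "
            "the cohort will sit on one side of balance",
            stacklevel=2,
        )
    couplings = np.linspace(lo, hi, spec.n_subjects)
    # domain-separated from the SC draw so subject noise never reuses it
    children = np.random.SeedSequence([spec.seed, 1]).spawn(spec.n_subjects)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    bold = [
        sample_bold(sc, c_k, spec.n_frames, dt=spec.dt, seed=s_k, tr=spec.tr)
        for c_k, s_k in zip(couplings, seeds)
    ]
    logger.info(
        "cohort generated: %d subjects, c in [%.4g, %.4g], c*=%s",
        spec.n_subjects, lo, hi, c_star,
    )
    return Cohort(sc=sc, bold=bold, couplings=couplings, seeds=seeds, spec=spec)


def worked_example_fixture() -> tuple[FCMatrix, dict]:
    """Four-region FC with closed-form spectrum and component values.

    Two strongly coupled pairs (r = 0.9 and 0.8) weakly tied to each other
    (r = 0.1).  In the symmetric two-dimensional subspace the matrix reduces
    to [[1.9, 0.2], [0.2, 1.8]], giving eigenvalues 1.85 ± sqrt(0.0425); the
    antisymmetric within-pair modes contribute 1 − 0.9 and 1 − 0.8.  The
    expected partition and components follow by hand from those closed
    forms, independently of any eigensolver.
    """
    values = np.array(
        [
            [1.0, 0.9, 0.1, 0.1],
            [0.9, 1.0, 0.1, 0.1],
            [0.1, 0.1, 1.0, 0.8],
            [0.1, 0.1, 0.8, 1.0],
        ]
    )
    fc = FCMatrix(values=values)
    root = np.sqrt(0.0425)
    lam = np.array([1.85 + root, 1.85 - root, 0.2, 0.1])
    # levels: 1 module; {1,2}|{3,4}; {1,2}|{3}|{4}; singletons
    m = np.array([1, 2, 3, 4])
    p = np.array([0.0, 0.0, (2 / 3 + 1 / 3 + 1 / 3) / 4, 0.0])
    h = lam**2 * m * (1 - p) / 4
    expected = {
        "eigenvalues": lam,
        "module_counts": m,
        "corrections": p,
        "components": h,
        "h_in": float(h[0] / 4),
        "h_se": float(h[1:].sum() / 4),
    }
    expected["h_b"] = expected["h_in"] - expected["h_se"]
    expected["level2_modules"] = [np.array([0, 1]), np.array([2, 3])]
    return fc, expected
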