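"""Gaussian linear diffusion model on a structural connectome.

Neural activity x on an SC graph A relaxes under the network Laplacian
H = D − A (D the diagonal strength matrix) with global coupling c and white
noise:

    dx/dt = −(I + cH) x + noise .

Averaging over the noise ensemble, with Q = (I + cH)⁻¹, the model covariance
is Cov = 2QQᵀ and the simulated FC is its correlation matrix.  At c = 0 the
regions are independent (identity FC); as c grows the network synchronises
and FC approaches all-ones.  Somewhere in between the segregation and
integration components of the model FC cross: that coupling c* is the
model's balanced operating point.

``sample_bold`` integrates the stochastic dynamics by Euler–Maruyama with
the noise covariance chosen per mode (amplitude 2·sqrt(dt/λ) along each
eigenvector of I + cH) so that the stationary covariance of the simulated
process equals the analytic ensemble covariance 2QQᵀ; a literal unit-noise
Ornstein–Uhlenbeck process would instead converge to (I + cH)⁻¹ and
systematically disagree with the analytic FC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.signal import lfilter
from scipy.sparse.csgraph import connected_components

from .core import ComponentProfile, nsp_profile
from .fc import BoldSeries, FCMatrix

logger = logging.getLogger("nspbalance")

__all__ = [
    "StructuralMatrix",
    "FCSimilarity",
    "SweepResult",
    "symmetrize_probabilities",
    "laplacian",
    "analytic_fc",
    "sample_bold",
    "fc_similarity",
    "coupling_sweep",
]


@dataclass
class StructuralMatrix:
    """Symmetric, non-negative, zero-diagonal structural connectivity matrix."""

    values: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.values, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("SC matrix must be square")
        if not np.allclose(a, a.T, atol=1e-10):
            raise ValueError("SC matrix must be symmetric")
        if a.min() < 0:
            raise ValueError("SC weights must be non-negative")
        if not np.allclose(np.diag(a), 0.0):
            raise ValueError("SC diagonal must be zero")
        self.values = 0.5 * (a + a.T)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def is_connected(self) -> bool:
        n_comp, _ = connected_components(self.values > 0, directed=False)
        return n_comp == 1


def symmetrize_probabilities(p: np.ndarray) -> StructuralMatrix:
    """Build an SC matrix from directed tract probabilities: w = (pᵢⱼ+pⱼᵢ)/2,
    zero diagonal."""
    p = np.asarray(p, dtype=float)
    w = 0.5 * (p + p.T)
    np.fill_diagonal(w, 0.0)
    return StructuralMatrix(values=w)


def laplacian(sc: StructuralMatrix) -> np.ndarray:
    """Graph Laplacian H = D − A of the SC matrix (strength minus adjacency)."""
    a = sc.values
    return np.diag(a.sum(axis=1)) - a


def analytic_fc(sc: StructuralMatrix, c: float) -> FCMatrix:
    """Analytic model FC at coupling c: correlation of Cov = 2QQᵀ,
    Q = (I + cH)⁻¹."""
    if c < 0:
        raise ValueError("coupling must be non-negative")
    n = sc.n_regions
    a = np.eye(n) + c * laplacian(sc)
    q = np.linalg.inv(a)
    cov = 2.0 * q @ q.T
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    return FCMatrix.from_array(corr, clip=True)


def _mode_system(sc: StructuralMatrix, c: float) -> tuple[np.ndarray, np.ndarray]:
    a = np.eye(sc.n_regions) + c * laplacian(sc)
    lam, vecs = np.linalg.eigh(a)
    return lam, vecs


def sample_bold(
    sc: StructuralMatrix,
    c: float,
    n_frames: int,
    dt: float = 0.05,
    seed: int | None = None,
    tr: float = 0.72,
    burn_in: float = 10.0,
) -> BoldSeries:
    """Simulate model activity by Euler–Maruyama, one frame per step.

    Parameters
    ----------
    sc, c
        Structural matrix and coupling strength.
    n_frames
        Frames recorded after the burn-in.
    dt
        Integration step in model time units; must satisfy
        ``dt · λ_max(I + cH) < 2`` for stability (an error states the bound).
    seed
        Seeds all noise; same seed, same series.
    tr
        Seconds-per-frame label attached to the output (used only by
        sliding-window bookkeeping downstream).
    burn_in
        Model time units discarded before recording; the slowest mode relaxes
        on 1 time unit, so the default forgets the x=0 start to exp(-10).
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if dt <= 0:
        raise ValueError("dt must be positive")
    lam, vecs = _mode_system(sc, c)
    lam_max = float(lam.max())
    if dt * lam_max >= 2.0:
        raise ValueError(
            f"unstable integration step: dt={dt} with max eigenvalue "
            f"{lam_max:.4g} requires dt < {2.0 / lam_max:.4g}"
        )
    n_burn = int(np.ceil(burn_in / dt))
    n_steps = n_burn + n_frames
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((sc.n_regions, n_steps))
    # decoupled AR(1) per mode: y_{k+1} = (1 - λ dt) y_k + 2 sqrt(dt/λ) ξ_k,
    # whose stationary covariance matches the analytic 2/λ² up to O(dt)
    y = np.empty_like(noise)
    for i, lam_i in enumerate(lam):
        phi = 1.0 - lam_i * dt
        sigma = 2.0 * np.sqrt(dt / lam_i)
        y[i] = lfilter([sigma], [1.0, -phi], noise[i])
    x = vecs @ y[:, n_burn:]
    logger.info(
        "sampled model BOLD: N=%d c=%g frames=%d dt=%g seed=%s",
        sc.n_regions, c, n_frames, dt, seed,
    )
    return BoldSeries(data=x, tr=tr)


@dataclass
class FCSimilarity:
    """Similarity of two FC matrices: mean off-diagonal levels, upper-triangle
    Euclidean distance, and mean absolute regional-strength difference."""

    mean_offdiag_a: float
    mean_offdiag_b: float
    euclidean: float
    strength_difference: float


def fc_similarity(fc_a: FCMatrix, fc_b: FCMatrix) -> FCSimilarity:
    if fc_a.n_regions != fc_b.n_regions:
        raise ValueError("FC matrices must share the same size")
    a, b = fc_a.values, fc_b.values
    n = fc_a.n_regions
    iu = np.triu_indices(n, k=1)
    strengths_a = a.sum(axis=1) - 1.0  # off-diagonal strengths
    strengths_b = b.sum(axis=1) - 1.0
    return FCSimilarity(
        mean_offdiag_a=float(a[iu].mean()),
        mean_offdiag_b=float(b[iu].mean()),
        euclidean=float(np.linalg.norm(a[iu] - b[iu])),
        strength_difference=float(np.abs(strengths_a - strengths_b).mean()),
    )


@dataclass
class SweepResult:
    """Component profiles along a coupling grid, with the balanced coupling."""

    grid: np.ndarray
    profiles: list[ComponentProfile]
    integration: np.ndarray
    segregation: np.ndarray
    balance: np.ndarray
    similarity: list[FCSimilarity] | None
    balance_coupling: float | None
    n_sign_changes: int


def coupling_sweep(
    sc: StructuralMatrix,
    grid: np.ndarray,
    reference_fc: FCMatrix | None = None,
    refine: bool = False,
) -> SweepResult:
    """Sweep the coupling, scoring the analytic FC at each grid point.

    ``balance_coupling`` is the zero crossing of H_B(c), located by linear
    interpolation between the first bracketing grid pair (or by Brent's
    method inside that bracket when ``refine`` is set).  A disconnected SC
    has no synchronised limit and is rejected.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size < 3 or np.any(np.diff(grid) <= 0):
        raise ValueError("coupling grid must be strictly increasing, >= 3 points")
    if not sc.is_connected():
        raise ValueError("SC graph is disconnected; sweep undefined")

    profiles = [nsp_profile(analytic_fc(sc, c)) for c in grid]
    h_in = np.array([p.integration for p in profiles])
    h_se = np.array([p.segregation for p in profiles])
    h_b = h_in - h_se

    similarity = None
    if reference_fc is not None:
        similarity = [fc_similarity(analytic_fc(sc, c), reference_fc) for c in grid]

    sign = np.sign(h_b)
    sign[sign == 0] = 1  # exact zero counts as the integrated side
    changes = np.flatnonzero(np.diff(sign) != 0)
    c_star: float | None = None
    if changes.size:
        k = changes[0]
        c0, c1 = grid[k], grid[k + 1]
        b0, b1 = h_b[k], h_b[k + 1]
        if refine:
            c_star = float(
                brentq(lambda c: nsp_profile(analytic_fc(sc, c)).balance, c0, c1,
                       xtol=1e-8)
            )
        else:
            c_star = float(c0 - b0 * (c1 - c0) / (b1 - b0))
    logger.info(
        "coupling sweep: %d points, %d balance sign changes, c*=%s",
        grid.size, changes.size, c_star,
    )
    return SweepResult(
        grid=grid,
        profiles=profiles,
        integration=h_in,
        segregation=h_se,
        balance=h_b,
        similarity=similarity,
        balance_coupling=c_star,
        n_sign_changes=int(changes.size),
    )
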