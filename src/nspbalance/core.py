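"""Nested-spectral partition (NSP) of functional connectivity networks.

The FC matrix ``C`` is decomposed as ``C = U Λ Uᵀ``.  Each eigenmode's
squared eigenvalue ``Λᵢ²`` measures its contribution to the functional
organisation; since ``C`` is a correlation matrix the raw eigenvalues sum to
``N`` regardless of synchronisation level, while ``ΣΛᵢ²`` grows with it.
The few negative eigenvalues that can arise are set to zero.

Modules are detected hierarchically by eigenvector sign: the first mode,
sign-uniform for a positive FC, defines one whole-network module; mode ``i``
splits every level-``(i-1)`` module into its positive-sign and negative-sign
subsets.  Level ``i`` carries a size-corrected, eigenvalue-weighted module
count

    Hᵢ = Λᵢ² · Mᵢ · (1 − pᵢ) / N,      pᵢ = Σⱼ |mⱼ − N/Mᵢ| / N,

where ``Mᵢ`` is the module count and ``mⱼ`` the module sizes; ``pᵢ``
penalises heterogeneous module sizes (a 1/(N−1) split at level two is nearly
global integration, not real segregation).  Global integration is the
level-1 component ``H_In = H₁/N ∈ [0, 1]``; total segregation accumulates
the deeper levels ``H_Se = Σᵢ₌₂..N Hᵢ / N``; their difference
``H_B = H_In − H_Se`` is the segregation–integration balance, zero at the
balanced operating point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fc import FCMatrix

logger = logging.getLogger("nspbalance")

__all__ = [
    "EigenSpectrum",
    "HierarchicalPartition",
    "ComponentProfile",
    "decompose_fc",
    "nested_partition",
    "size_correction",
    "component_profile",
    "nsp_profile",
]


@dataclass
class EigenSpectrum:
    """Eigenmodes of an FC matrix, sorted by descending raw eigenvalue.

    ``eigenvalues`` holds Λ with negatives zeroed; ``trace_check`` keeps the
    raw-eigenvalue sum, which must equal N for a correlation matrix.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    trace_check: float

    @property
    def n_regions(self) -> int:
        return self.eigenvalues.shape[0]


@dataclass
class HierarchicalPartition:
    """Nested module labels over N levels.

    ``labels[i, r]`` is the module id of region ``r`` at level ``i+1``
    (module ids are ordered by each module's smallest region index, so they
    are deterministic).  Level-``i`` modules always refine level-``(i-1)``
    modules.
    """

    labels: np.ndarray
    module_counts: np.ndarray
    module_sizes: list[np.ndarray]
    corrections: np.ndarray

    @property
    def n_regions(self) -> int:
        return self.labels.shape[1]

    @property
    def n_levels(self) -> int:
        return self.labels.shape[0]


@dataclass
class ComponentProfile:
    """Per-level components and the summary triple (H_In, H_Se, H_B)."""

    components: np.ndarray
    integration: float
    segregation: float

    @property
    def balance(self) -> float:
        return self.integration - self.segregation


def decompose_fc(fc: FCMatrix | np.ndarray, atol: float = 1e-8) -> EigenSpectrum:
    """Full symmetric eigendecomposition of an FC matrix.

    Eigenpairs are sorted by descending raw eigenvalue before the negative
    eigenvalues are zeroed, so zeroed modes occupy the tail levels.  The
    first eigenvector is canonicalised to a positive component sum; the sign
    of the remaining eigenvectors is immaterial to every downstream measure.
    """
    values = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("FC matrix must be square")
    if not np.allclose(values, values.T, atol=atol):
        raise ValueError("FC matrix is asymmetric beyond tolerance")
    raw, vectors = np.linalg.eigh(0.5 * (values + values.T))
    order = np.argsort(raw, kind="stable")[::-1]
    raw = raw[order]
    vectors = vectors[:, order]
    if vectors[:, 0].sum() < 0:
        vectors[:, 0] = -vectors[:, 0]
    eigenvalues = np.where(raw < 0, 0.0, raw)
    return EigenSpectrum(
        eigenvalues=eigenvalues,
        eigenvectors=vectors,
        trace_check=float(raw.sum()),
    )


def size_correction(sizes: np.ndarray, n_regions: int) -> float:
    """Module-size heterogeneity penalty p = Σⱼ |mⱼ − N/M| / N.

    Zero for perfectly homogeneous sizes (including all singletons); grows
    toward 1 as one module dominates.
    """
    sizes = np.asarray(sizes)
    if sizes.size == 0 or np.any(sizes <= 0):
        raise ValueError("module sizes must be positive integers")
    if int(sizes.sum()) != n_regions:
        raise ValueError(
            f"module sizes sum to {int(sizes.sum())}, expected {n_regions}"
        )
    m = sizes.size
    return float(np.abs(sizes - n_regions / m).sum() / n_regions)


def nested_partition(
    spectrum: EigenSpectrum, zero_tol: float = 1e-12
) -> HierarchicalPartition:
    """Recursive sign-split of modules by successive eigenvectors.

    Level ``i`` splits each level-``(i-1)`` module into the regions with
    non-negative and negative components of eigenvector ``i`` (restricted to
    that module).  Zero components go to the non-negative group — a
    deterministic tie rule that real data essentially never exercises;
    ``zero_tol`` (relative to the vector's largest component) absorbs the
    solver's rounding of analytically-zero entries.  Because an eigenvector
    is defined only up to sign, each one is first oriented so its
    largest-magnitude component is positive; together with the zero rule
    this makes the partition invariant to the solver's arbitrary sign
    choices even when a vector's nonzero entries all share one sign.
    Sign-uniform modules pass through intact.  Once every module is a
    singleton the remaining levels keep ``Mᵢ = N`` and ``pᵢ = 0``.
    """
    u = spectrum.eigenvectors
    n = spectrum.n_regions
    labels = np.empty((n, n), dtype=int)
    counts = np.empty(n, dtype=int)
    sizes: list[np.ndarray] = []
    corrections = np.empty(n)

    modules: list[np.ndarray] = [np.arange(n)]
    for level in range(n):
        if len(modules) < n:
            vec = u[:, level]
            if vec[np.argmax(np.abs(vec))] < 0:
                vec = -vec
            cutoff = -zero_tol * np.abs(vec).max()
            split: list[np.ndarray] = []
            for mod in modules:
                pos = mod[vec[mod] >= cutoff]
                neg = mod[vec[mod] < cutoff]
                if pos.size:
                    split.append(pos)
                if neg.size:
                    split.append(neg)
            modules = split
        modules.sort(key=lambda m: int(m[0]))
        for mid, mod in enumerate(modules):
            labels[level, mod] = mid
        counts[level] = len(modules)
        level_sizes = np.array([m.size for m in modules])
        sizes.append(level_sizes)
        corrections[level] = size_correction(level_sizes, n)
    logger.debug("nested partition module counts: %s", counts.tolist())
    return HierarchicalPartition(
        labels=labels,
        module_counts=counts,
        module_sizes=sizes,
        corrections=corrections,
    )


def component_profile(
    spectrum: EigenSpectrum, partition: HierarchicalPartition
) -> ComponentProfile:
    """Hierarchical components Hᵢ and the (H_In, H_Se, H_B) summary.

    ``Hᵢ = Λᵢ²·Mᵢ·(1−pᵢ)/N``; ``H_In = H₁/N``; ``H_Se = Σᵢ₌₂..N Hᵢ/N``.
    Spectrum and partition must come from the same FC matrix.
    """
    n = spectrum.n_regions
    if partition.n_regions != n:
        raise ValueError("spectrum and partition dimension mismatch")
    lam = spectrum.eigenvalues
    h = lam**2 * partition.module_counts * (1.0 - partition.corrections) / n
    integration = float(h[0] / n)
    segregation = float(h[1:].sum() / n)
    return ComponentProfile(
        components=h, integration=integration, segregation=segregation
    )


def nsp_profile(fc: FCMatrix | np.ndarray) -> ComponentProfile:
    """Convenience pipeline: decompose, partition, and score one FC matrix."""
    spectrum = decompose_fc(fc)
    return component_profile(spectrum, nested_partition(spectrum))
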