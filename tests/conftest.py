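"""Shared fixtures: worked 4-node FC, small SCs, and the synthetic cohort
study (computed once per session — it is the expensive piece)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import nspbalance as nb


@pytest.fixture(scope="session")
def worked_fixture():
    """Four-node FC with hand-derived spectrum/partition/components."""
    return nb.worked_example_fixture()


@pytest.fixture()
def two_node_sc() -> nb.StructuralMatrix:
    return nb.StructuralMatrix(values=np.array([[0.0, 1.0], [1.0, 0.0]]))


@pytest.fixture(scope="session")
def canonical_sc() -> nb.StructuralMatrix:
    """The default 10-region two-block SC of the synthetic study."""
    return nb.make_modular_sc(nb.SyntheticSpec(seed=0))


def random_fc(rng: np.random.Generator, n: int) -> nb.FCMatrix:
    """Random valid FC: correlations of a short random series, clipped."""
    data = rng.standard_normal((n, 3 * n))
    # mild common signal keeps the leading eigenvector sign-uniform sometimes
    data += 0.3 * rng.standard_normal((1, 3 * n))
    return nb.FCMatrix.from_array(np.corrcoef(data), clip=True)


@dataclass
class CohortStudy:
    """End-to-end results of the default synthetic cohort."""

    cohort: nb.Cohort
    static_h_se: np.ndarray
    static_h_in: np.ndarray
    calibrated: nb.CohortComponents
    summaries: list[nb.DynamicSummary]

    @property
    def calibrated_h_b(self) -> np.ndarray:
        return self.calibrated.h_b


@pytest.fixture(scope="session")
def cohort_study() -> CohortStudy:
    """Default study conditions: 20 subjects on the canonical 10-region SC,
    2e4 frames each, couplings bracketing the balanced coupling; windows of
    83 frames sliding by 10."""
    spec = nb.SyntheticSpec(seed=0)
    cohort = nb.make_cohort(spec)
    h_se = np.empty(cohort.n_subjects)
    h_in = np.empty(cohort.n_subjects)
    for k, series in enumerate(cohort.bold):
        profile = nb.nsp_profile(nb.build_static_fc(series))
        h_se[k] = profile.segregation
        h_in[k] = profile.integration
    calibrated = nb.calibrate_static(
        nb.CohortComponents([f"s{k}" for k in range(cohort.n_subjects)], h_se, h_in)
    ).cohort
    window_spec = nb.WindowSpec(width=83, step=10, tr=spec.tr)
    summaries = []
    for k, series in enumerate(cohort.bold):
        dyn = nb.build_dynamic_fc(series, window_spec)
        with np.errstate(all="ignore"):
            traj = nb.balance_trajectory(
                dyn, static_h_se=calibrated.h_se[k], static_h_in=calibrated.h_in[k]
            )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # one-sided subjects warn on D
            summaries.append(nb.summarize_trajectory(traj))
    return CohortStudy(
        cohort=cohort,
        static_h_se=h_se,
        static_h_in=h_in,
        calibrated=calibrated,
        summaries=summaries,
    )
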