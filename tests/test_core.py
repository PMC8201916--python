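import numpy as np
import pytest

import nspbalance as nb
from conftest import random_fc


def oracle_profile(fc_values: np.ndarray):
    """Independent reimplementation of the hierarchical components.

    Instead of recursively splitting modules, it observes that a region's
    module at level i is fully determined by the signs of its first i
    eigenvector components: two regions share a level-i module iff their
    sign prefixes of length i agree.  Components are then accumulated with
    explicit loops from the printed formulas.
    """
    raw, u = np.linalg.eigh(fc_values)
    order = np.argsort(-raw, kind="stable")
    raw, u = raw[order], u[:, order]
    if u[:, 0].sum() < 0:
        u[:, 0] *= -1
    n = fc_values.shape[0]
    lam = np.where(raw < 0, 0.0, raw)
    tol = 1e-12
    signs = np.empty((n, n), dtype=bool)
    for i in range(n):
        v = u[:, i]
        if v[np.abs(v).argmax()] < 0:  # shared orientation convention
            v = -v
        cutoff = -tol * np.abs(v).max()
        signs[:, i] = v >= cutoff

    h = np.zeros(n)
    m_counts = np.zeros(n, dtype=int)
    p_vec = np.zeros(n)
    for level in range(1, n + 1):
        patterns = {}
        for region in range(n):
            key = tuple(signs[region, :level])
            patterns.setdefault(key, []).append(region)
        sizes = [len(v) for v in patterns.values()]
        m = len(sizes)
        if m >= n:
            m, sizes = n, [1] * n
        p = sum(abs(s - n / m) for s in sizes) / n
        m_counts[level - 1] = m
        p_vec[level - 1] = p
        h[level - 1] = lam[level - 1] ** 2 * m * (1 - p) / n
    h_in = h[0] / n
    h_se = sum(h[1:]) / n
    return lam, m_counts, p_vec, h, h_in, h_se


class TestDecompose:
    def test_rank_one_spectrum_of_all_ones(self):
        spec = nb.decompose_fc(np.ones((4, 4)))
        assert np.allclose(spec.eigenvalues, [4, 0, 0, 0], atol=1e-12)

    def test_raw_eigenvalue_sum_equals_n(self):
        rng = np.random.default_rng(11)
        for n in (5, 7, 8):
            fc = random_fc(rng, n)
            spec = nb.decompose_fc(fc)
            assert spec.trace_check == pytest.approx(n, abs=1e-10)

    def test_chain_fc_closed_form_with_negative_mode_zeroed(self):
        fc = np.array([[1, 0.9, 0], [0.9, 1, 0.9], [0, 0.9, 1]])
        spec = nb.decompose_fc(fc)
        assert np.allclose(
            spec.eigenvalues, [1 + 0.9 * np.sqrt(2), 1.0, 0.0], atol=1e-12
        )
        # the raw third eigenvalue 1 - 0.9*sqrt(2) < 0 is kept in the trace
        assert spec.trace_check == pytest.approx(3.0, abs=1e-12)

    def test_eigenvectors_orthonormal(self):
        rng = np.random.default_rng(4)
        spec = nb.decompose_fc(random_fc(rng, 6))
        assert np.allclose(spec.eigenvectors.T @ spec.eigenvectors, np.eye(6), atol=1e-10)

    def test_asymmetric_input_rejected(self):
        m = np.eye(3)
        m[0, 1] = 0.5
        with pytest.raises(ValueError, match="asymmetric"):
            nb.decompose_fc(m)


class TestNestedPartition:
    def test_positive_fc_has_single_top_module(self):
        rng = np.random.default_rng(9)
        fc_values = random_fc(rng, 6).values + 0.05
        np.fill_diagonal(fc_values, 1.0)
        fc_values = np.clip(fc_values, 0, 1)
        part = nb.nested_partition(nb.decompose_fc(fc_values))
        assert part.module_counts[0] == 1  # Perron eigenvector is sign-uniform

    def test_worked_fixture_partition(self, worked_fixture):
        fc, expected = worked_fixture
        part = nb.nested_partition(nb.decompose_fc(fc))
        assert np.array_equal(part.module_counts, expected["module_counts"])
        level2 = part.labels[1]
        assert level2[0] == level2[1] and level2[2] == level2[3]
        assert level2[0] != level2[2]
        assert np.allclose(part.corrections, expected["corrections"], atol=1e-12)

    def test_sign_flip_leaves_measures_unchanged(self):
        rng = np.random.default_rng(21)
        for n in (5, 6, 8):
            spec = nb.decompose_fc(random_fc(rng, n))
            base = nb.nested_partition(spec)
            for col in range(1, n):
                flipped = nb.EigenSpectrum(
                    eigenvalues=spec.eigenvalues.copy(),
                    eigenvectors=spec.eigenvectors.copy(),
                    trace_check=spec.trace_check,
                )
                flipped.eigenvectors[:, col] *= -1
                part = nb.nested_partition(flipped)
                assert np.array_equal(part.module_counts, base.module_counts)
                for a, b in zip(part.module_sizes, base.module_sizes):
                    assert sorted(a) == sorted(b)
                assert np.allclose(part.corrections, base.corrections, atol=1e-12)

    def test_partitions_are_nested_refinements(self):
        rng = np.random.default_rng(33)
        for _ in range(10):
            n = int(rng.integers(4, 9))
            part = nb.nested_partition(nb.decompose_fc(random_fc(rng, n)))
            for level in range(1, n):
                coarse, fine = part.labels[level - 1], part.labels[level]
                # every fine module sits inside one coarse module
                for mid in np.unique(fine):
                    assert np.unique(coarse[fine == mid]).size == 1
                m_prev, m_curr = part.module_counts[level - 1], part.module_counts[level]
                assert m_prev <= m_curr <= min(2 * m_prev, n)
            for sizes in part.module_sizes:
                assert sizes.sum() == n
            assert part.corrections[0] == 0.0
            assert np.all(part.corrections >= 0) and np.all(part.corrections < 1)


class TestSizeCorrection:
    @pytest.mark.parametrize(
        "sizes,n,expected",
        [
            ((3, 3), 6, 0.0),
            ((1, 5), 6, 2 / 3),
            ((1, 1, 1, 1), 4, 0.0),
            ((2, 1, 1), 4, 1 / 3),
        ],
    )
    def test_printed_formula(self, sizes, n, expected):
        assert nb.size_correction(np.array(sizes), n) == pytest.approx(expected)

    def test_heterogeneous_split_scores_lower_components(self):
        """At equal eigenvalue and module count, a (1,5) split is weaker
        segregation than (3,3) because p is larger."""
        p_even = nb.size_correction(np.array([3, 3]), 6)
        p_skew = nb.size_correction(np.array([1, 5]), 6)
        assert (1 - p_skew) < (1 - p_even)

    def test_sizes_must_sum_to_n(self):
        with pytest.raises(ValueError, match="sum"):
            nb.size_correction(np.array([2, 2]), 6)


class TestComponentProfile:
    def test_fully_synchronized_limit(self):
        profile = nb.nsp_profile(np.ones((4, 4)))
        assert profile.integration == pytest.approx(1.0)
        assert profile.segregation == pytest.approx(0.0)
        assert profile.balance == pytest.approx(1.0)

    def test_worked_fixture_components(self, worked_fixture):
        fc, expected = worked_fixture
        profile = nb.nsp_profile(fc)
        assert profile.integration == pytest.approx(expected["h_in"], abs=1e-10)
        assert profile.segregation == pytest.approx(expected["h_se"], abs=1e-10)
        assert profile.balance == pytest.approx(expected["h_b"], abs=1e-10)

    def test_integration_is_top_eigenvalue_squared_over_n_squared(self):
        rng = np.random.default_rng(2)
        for n in (5, 6):
            fc = random_fc(rng, n)
            spec = nb.decompose_fc(fc)
            prof = nb.nsp_profile(fc)
            part = nb.nested_partition(spec)
            expected = spec.eigenvalues[0] ** 2 * part.module_counts[0] / n**2
            assert prof.integration == pytest.approx(expected, abs=1e-12)
            assert 0.0 <= prof.integration <= 1.0

    def test_dimension_mismatch_rejected(self):
        spec5 = nb.decompose_fc(random_fc(np.random.default_rng(0), 5))
        part6 = nb.nested_partition(nb.decompose_fc(random_fc(np.random.default_rng(1), 6)))
        with pytest.raises(ValueError, match="mismatch"):
            nb.component_profile(spec5, part6)

    def test_agrees_with_sign_pattern_oracle(self):
        """Dual-route check on random FC matrices: recursive splitting vs the
        sign-prefix formulation plus longhand component sums."""
        rng = np.random.default_rng(99)
        for _ in range(40):
            n = int(rng.integers(5, 9))
            fc = random_fc(rng, n)
            lam_o, m_o, p_o, h_o, h_in_o, h_se_o = oracle_profile(fc.values)
            spec = nb.decompose_fc(fc)
            part = nb.nested_partition(spec)
            prof = nb.component_profile(spec, part)
            assert np.allclose(spec.eigenvalues, lam_o, atol=1e-10)
            assert np.array_equal(part.module_counts, m_o)
            assert np.allclose(part.corrections, p_o, atol=1e-10)
            assert np.allclose(prof.components, h_o, atol=1e-10)
            assert prof.integration == pytest.approx(h_in_o, abs=1e-10)
            assert prof.segregation == pytest.approx(h_se_o, abs=1e-10)
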