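"""Instantaneous phases, PL matrices, leading eigenvectors, pooling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from leida import (
    RoiTimeSeries,
    canonical_sign,
    eigenvector_series,
    instantaneous_phase,
    leading_eigenvector,
    phase_locking_matrix,
    pool_eigenvectors,
)


def scan_from(data, tr=2.0, subject="s", session="baseline"):
    return RoiTimeSeries(data=data, tr=tr, subject_id=subject, session=session)


class TestInstantaneousPhase:
    def test_cosine_phase_tracks_argument(self):
        t = np.arange(2000) * 2.0
        arg = 2 * np.pi * 0.04 * t
        scan = scan_from(np.cos(arg)[:, None])
        theta = instantaneous_phase(scan)[:, 0]
        interior = slice(200, -200)
        err = np.angle(np.exp(1j * (theta[interior] - arg[interior])))
        assert np.max(np.abs(err)) < 0.05

    def test_quadrature_pair_is_half_pi_apart(self):
        t = np.arange(1000) * 2.0
        w = 2 * np.pi * 0.03
        data = np.column_stack([np.cos(w * t), np.sin(w * t)])
        theta = instantaneous_phase(scan_from(data))
        diff = np.angle(np.exp(1j * (theta[200:-200, 0] - theta[200:-200, 1])))
        assert np.allclose(diff, np.pi / 2, atol=0.05)

    def test_identical_columns_get_identical_phases(self):
        x = np.sin(np.linspace(0, 20, 300))
        theta = instantaneous_phase(scan_from(np.column_stack([x, x])))
        assert np.array_equal(theta[:, 0], theta[:, 1])

    def test_all_zero_region_rejected(self):
        data = np.column_stack([np.sin(np.linspace(0, 9, 50)), np.zeros(50)])
        with pytest.raises(ValueError, match="all-zero"):
            instantaneous_phase(scan_from(data))


class TestPhaseLockingMatrix:
    @pytest.mark.parametrize(
        "lag,expected", [(0.0, 1.0), (np.pi, -1.0), (np.pi / 2, 0.0)]
    )
    def test_canonical_phase_lags(self, lag, expected):
        pl = phase_locking_matrix(np.array([0.3, 0.3 + lag]))
        assert pl[0, 1] == pytest.approx(expected, abs=1e-12)

    @given(
        hnp.arrays(
            float,
            st.integers(2, 12),
            elements=st.floats(-np.pi, np.pi, allow_nan=False),
        )
    )
    def test_symmetric_unit_diagonal_bounded(self, theta):
        pl = phase_locking_matrix(theta)
        assert np.array_equal(pl, pl.T)
        assert np.all(np.diag(pl) == 1.0)
        assert np.all(np.abs(pl) <= 1.0 + 1e-12)


class TestLeadingEigenvector:
    def test_all_equal_phases_give_uniform_negative_vector(self):
        n = 7
        pl = phase_locking_matrix(np.full(n, 0.9))
        v = leading_eigenvector(pl)
        assert np.allclose(v, -1 / np.sqrt(n), atol=1e-10)

    def test_two_against_one_sign_pattern(self):
        # phases (0, 0, pi): dense 3x3 eigendecomposition oracle
        pl = phase_locking_matrix(np.array([0.0, 0.0, np.pi]))
        v = leading_eigenvector(pl)
        vals, vecs = np.linalg.eig(pl)  # independent full-spectrum oracle
        top = vecs[:, np.argmax(vals)]
        assert abs(abs(v @ top) - 1.0) < 1e-10
        assert np.sign(v[0]) == np.sign(v[1]) != np.sign(v[2])

    def test_agrees_with_dense_oracle_on_random_matrices(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 30))
            a = rng.standard_normal((n, n))
            a = (a + a.T) / 2
            v = leading_eigenvector(a)
            vals, vecs = np.linalg.eig(a)
            top = np.real(vecs[:, np.argmax(np.real(vals))])
            assert abs(abs(v @ top) / np.linalg.norm(top) - 1.0) < 1e-8

    def test_rayleigh_quotient_is_maximal(self, rng):
        theta = rng.uniform(-np.pi, np.pi, 15)
        pl = phase_locking_matrix(theta)
        v = leading_eigenvector(pl)
        quad_v = v @ pl @ v
        for _ in range(100):
            u = rng.standard_normal(15)
            u /= np.linalg.norm(u)
            assert quad_v >= u @ pl @ u - 1e-10

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            leading_eigenvector(np.array([[1.0, 0.2], [0.5, 1.0]]))


class TestCanonicalSign:
    def test_majority_of_elements_negative(self, rng):
        for _ in range(20):
            v = rng.standard_normal(9)
            out = canonical_sign(v)
            assert (out < 0).sum() >= (out > 0).sum()

    def test_tie_broken_by_largest_magnitude_element(self):
        v = np.array([3.0, -1.0, 2.0, -0.5])  # two positive, two negative
        out = canonical_sign(v)
        assert out[np.argmax(np.abs(out))] < 0


class TestEigenvectorSeries:
    def _scan(self, rng, frames=204, regions=10):
        data = rng.standard_normal((frames, regions))
        data -= data.mean(axis=0)
        return scan_from(data)

    def test_rank2_path_matches_per_frame_dense_solver(self, rng):
        scan = self._scan(rng, frames=60, regions=12)
        theta = instantaneous_phase(scan)
        fast = eigenvector_series(scan, theta=theta)
        for t in range(60):
            dense = leading_eigenvector(phase_locking_matrix(theta[t]))
            assert abs(abs(fast[t] @ dense) - 1.0) < 1e-8
            assert np.allclose(fast[t], dense, atol=1e-6)

    def test_unit_norm_rows(self, rng):
        fast = eigenvector_series(self._scan(rng))
        assert np.allclose(np.linalg.norm(fast, axis=1), 1.0, atol=1e-8)

    @pytest.mark.parametrize("trim,expected", [(0, 204), (1, 202), (5, 194)])
    def test_edge_trimming_counts(self, rng, trim, expected):
        assert eigenvector_series(self._scan(rng), trim_edges=trim).shape[0] == expected

    def test_overtrimming_rejected(self, rng):
        with pytest.raises(ValueError):
            eigenvector_series(self._scan(rng, frames=10), trim_edges=5)

    def test_deterministic(self, rng):
        scan = self._scan(rng)
        assert np.array_equal(eigenvector_series(scan), eigenvector_series(scan))


class TestPooling:
    def _cohort(self, rng, n_subjects, frames=204, regions=8):
        scans = []
        for i in range(n_subjects):
            for session in ("baseline", "follow_up"):
                data = rng.standard_normal((frames, regions))
                data -= data.mean(axis=0)
                scans.append(scan_from(data, subject=f"s{i}", session=session))
        return scans

    @pytest.mark.parametrize("n_subjects,expected", [(11, 4488), (17, 6936)])
    def test_pool_sizes_match_design(self, rng, n_subjects, expected):
        pool = pool_eigenvectors(self._cohort(rng, n_subjects))
        assert len(pool) == expected
        assert len(pool.index) == expected

    def test_single_scan_pool_equals_its_series(self, rng):
        scans = self._cohort(rng, 1)[:1]
        pool = pool_eigenvectors(scans)
        assert np.array_equal(pool.vectors, eigenvector_series(scans[0]))

    def test_mixed_region_counts_rejected(self, rng):
        scans = self._cohort(rng, 1, regions=8)
        scans += self._cohort(rng, 1, regions=9)
        with pytest.raises(ValueError, match="regions"):
            pool_eigenvectors(scans)
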