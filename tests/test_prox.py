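"""Proximal operators, including the PSD-constrained stacked nuclear prox."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from lscggm.prox import (
    project_psd,
    prox_l1,
    prox_stacked_nuclear_psd,
    svd_soft_threshold,
)
from lscggm.sdp import prox_psd_nuclear_reference


class TestProxL1:
    def test_hand_example(self):
        np.testing.assert_allclose(prox_l1(np.array([[2.0, -0.5]]), 1.0), [[1.0, 0.0]])

    def test_zero_threshold_is_identity(self, rng):
        m = rng.standard_normal((4, 3))
        np.testing.assert_allclose(prox_l1(m, 0.0), m)

    def test_matches_scalar_minimization(self, rng):
        m = rng.standard_normal((3, 4))
        t = 0.3
        out = prox_l1(m, t)
        for idx in np.ndindex(m.shape):
            r = minimize_scalar(
                lambda x: 0.5 * (x - m[idx]) ** 2 + t * abs(x),
                bounds=(-5, 5), method="bounded",
                options={"xatol": 1e-10},
            )
            assert out[idx] == pytest.approx(r.x, abs=1e-6)

    def test_mask_passes_entries_through(self, rng):
        m = rng.standard_normal((3, 3))
        mask = np.eye(3, dtype=bool)
        out = prox_l1(m, 10.0, mask=mask)
        np.testing.assert_allclose(np.diag(out), np.diag(m))
        assert np.all(out[~mask] == 0)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            prox_l1(np.ones((2, 2)), -0.1)

    def test_nonexpansive(self, rng):
        for _ in range(100):
            a = rng.standard_normal((4, 3))
            b = rng.standard_normal((4, 3))
            t = rng.uniform(0, 2)
            d_out = np.linalg.norm(prox_l1(a, t) - prox_l1(b, t))
            assert d_out <= np.linalg.norm(a - b) + 1e-12


finite = st.floats(min_value=-50, max_value=50, allow_nan=False)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(x=finite, t=st.floats(min_value=0, max_value=10))
def test_prox_l1_scalar_properties(x, t):
    """Soft-thresholding shrinks toward zero by exactly t, never crosses it,
    and is odd in its argument."""
    out = float(prox_l1(np.array([[x]]), t)[0, 0])
    assert abs(out) == pytest.approx(max(abs(x) - t, 0.0))
    assert out * x >= 0.0
    neg = float(prox_l1(np.array([[-x]]), t)[0, 0])
    assert neg == pytest.approx(-out)


class TestSvdSoftThreshold:
    def test_diagonal_example(self):
        np.testing.assert_allclose(
            svd_soft_threshold(np.diag([3.0, 1.0]), 2.0), np.diag([1.0, 0.0]),
            atol=1e-12,
        )

    def test_large_threshold_zeroes(self, rng):
        m = rng.standard_normal((4, 3))
        t = np.linalg.svd(m, compute_uv=False)[0]
        np.testing.assert_allclose(svd_soft_threshold(m, t + 1e-9), 0.0, atol=1e-9)

    def test_local_optimality(self, rng):
        m = rng.standard_normal((5, 3))
        t = 0.7
        x = svd_soft_threshold(m, t)

        def obj(y):
            return 0.5 * np.linalg.norm(y - m) ** 2 + t * np.linalg.svd(
                y, compute_uv=False
            ).sum()

        base = obj(x)
        for _ in range(500):
            pert = x + 1e-3 * rng.standard_normal(x.shape)
            assert obj(pert) >= base - 1e-12


class TestProjectPsd:
    def test_psd_unchanged(self, rng):
        a = rng.standard_normal((3, 3))
        m = a @ a.T
        np.testing.assert_allclose(project_psd(m), m, atol=1e-12)

    def test_clips_negative_eigenvalue(self):
        np.testing.assert_allclose(
            project_psd(np.diag([1.0, -1.0])), np.diag([1.0, 0.0]), atol=1e-14
        )

    def test_variational_optimality_with_floor(self, rng):
        """Nearest matrix with floored spectrum: the projection P satisfies
        <M - P, Q - P> <= 0 for every feasible Q."""
        floor = 1e-6
        m = rng.standard_normal((4, 4))
        m = 0.5 * (m + m.T)
        proj = project_psd(m, floor=floor)
        assert np.linalg.eigvalsh(proj).min() >= floor - 1e-12
        for _ in range(50):
            a = rng.standard_normal((4, 4))
            q = a @ a.T + floor * np.eye(4)
            assert np.sum((m - proj) * (q - proj)) <= 1e-10


class TestProxStackedNuclearPsd:
    def test_reduces_to_svt_when_constraint_inactive(self, rng):
        # a stacked matrix whose soft-thresholded top block is exactly
        # symmetric PSD (zero bottom rows keep the SVT in the symmetric cone)
        a = rng.standard_normal((3, 3))
        top = a @ a.T + 3 * np.eye(3)
        m = np.vstack([top, np.zeros((2, 3))])
        t = 0.2
        free = svd_soft_threshold(m, t)
        assert np.abs(free[:3] - free[:3].T).max() < 1e-12
        assert np.linalg.eigvalsh(free[:3]).min() > 0
        res = prox_stacked_nuclear_psd(m, t, p=3)
        np.testing.assert_allclose(res.value, free, atol=1e-8)

    def test_large_threshold_zeroes(self, rng):
        m = rng.standard_normal((5, 3))
        t = np.linalg.svd(m, compute_uv=False)[0] + 0.1
        res = prox_stacked_nuclear_psd(m, t, p=3)
        np.testing.assert_allclose(res.value, 0.0, atol=1e-10)

    def test_p_zero_coincides_with_svt(self, rng):
        m = rng.standard_normal((4, 3))
        res = prox_stacked_nuclear_psd(m, 0.4, p=0)
        np.testing.assert_allclose(res.value, svd_soft_threshold(m, 0.4), atol=1e-8)

    def test_matches_conic_reference(self, rng):
        """Generic instance (p=3, m=3): agree with an interior-point solution
        of the same constrained minimization."""
        m = rng.standard_normal((6, 3))
        m[:3] = 0.5 * (m[:3] + m[:3].T) - 0.3 * np.eye(3)  # make constraint bite
        t = 0.5
        res = prox_stacked_nuclear_psd(m, t, p=3, tol=1e-12, max_iter=2000)
        ref = prox_psd_nuclear_reference(m, t, p=3)
        np.testing.assert_allclose(res.value, ref, atol=1e-5)

    def test_nonexpansive(self, rng):
        for _ in range(100):
            a = rng.standard_normal((4, 2))
            b = rng.standard_normal((4, 2))
            pa = prox_stacked_nuclear_psd(a, 0.3, p=2, tol=1e-11, max_iter=500).value
            pb = prox_stacked_nuclear_psd(b, 0.3, p=2, tol=1e-11, max_iter=500).value
            assert np.linalg.norm(pa - pb) <= np.linalg.norm(a - b) + 1e-6

    def test_nuclear_norm_monotone_in_threshold(self, rng):
        m = rng.standard_normal((5, 3))
        norms = []
        for t in [0.0, 0.2, 0.5, 1.0, 2.0]:
            v = prox_stacked_nuclear_psd(m, t, p=3).value
            norms.append(np.linalg.svd(v, compute_uv=False).sum())
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_reports_inner_iterations(self, rng):
        m = rng.standard_normal((5, 3))
        res = prox_stacked_nuclear_psd(m, 0.3, p=3)
        assert res.inner_iterations >= 1
        assert res.inner_residual <= 1e-8 or not res.converged
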