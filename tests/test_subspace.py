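"""Hankel/shift machinery, LS/TLS solvers, pole extraction, linear fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from decspec import (
    HankelSpec,
    NongenericTLSError,
    Peak,
    SinusoidModel,
    build_hankel,
    default_dims,
    dominant_eigenvalues,
    fit_linear_params,
    pole_from_params,
    preset,
    rank_truncate,
    shift_pair,
    solve_shift_ls,
    solve_shift_tls,
    synthesize,
    undecimate_pole,
)


class TestDims:
    @pytest.mark.parametrize(
        "N,D,L,M,rows",
        [(128, 2, 65, 64, 63), (5, 1, 3, 3, 2), (128, 3, 65, 64, 62)],
    )
    def test_default_sizing(self, N, D, L, M, rows):
        spec = default_dims(N, D)
        assert (spec.L, spec.M, spec.rows) == (L, M, rows)

    def test_infeasible_order_rejected(self):
        with pytest.raises(ValueError):
            default_dims(8, 2, p=4)  # needs p < L - D = 3
        with pytest.raises(ValueError):
            HankelSpec(L=3, M=3, D=1, N=6)  # L + M - 1 != N
        with pytest.raises(ValueError):
            HankelSpec(L=6, M=3, D=1, N=8)  # L - D > M


class TestHankel:
    def test_index_arithmetic(self):
        spec = HankelSpec(L=3, M=3, D=1, N=5)
        H = build_hankel(np.arange(5.0), spec)
        np.testing.assert_array_equal(H, [[0, 1, 2], [1, 2, 3], [2, 3, 4]])

    def test_constant_signal_is_rank_one(self):
        spec = HankelSpec(L=4, M=4, D=1, N=7)
        H = build_hankel(np.ones(7, complex), spec)
        sv = np.linalg.svd(H, compute_uv=False)
        assert sv[1] < 1e-12 * sv[0]

    @pytest.mark.parametrize("name", ["two_peak", "five_peak_31p", "eleven_peak_31p"])
    def test_noise_free_rank_equals_model_order(self, name, clean_series):
        # Vandermonde decomposition oracle: rank of the data Hankel is p.
        ps = preset(name)
        spec = default_dims(128, 1)
        H = build_hankel(clean_series[name], spec)
        sv = np.linalg.svd(H, compute_uv=False)
        assert sv[ps.model.p] < 1e-8 * sv[0]
        assert sv[ps.model.p - 1] > 1e-7 * sv[0]

    def test_shift_pair_indexing(self):
        spec = HankelSpec(L=3, M=3, D=1, N=5)
        H = build_hankel(np.arange(5.0), spec)
        pair = shift_pair(H, 1, spec)
        np.testing.assert_array_equal(pair.up, H[:2])
        np.testing.assert_array_equal(pair.down, H[1:])

    def test_shift_pair_advances_by_D_samples(self, clean_series):
        s = clean_series["two_peak"].samples
        spec = default_dims(128, 3)
        pair = shift_pair(build_hankel(s, spec), 3, spec)
        # down[i, j] = s(i + D + j): direct indexing oracle
        i, j = 5, 11
        assert pair.down[i, j] == s[i + 3 + j]
        assert pair.up[i, j] == s[i + j]

    def test_single_row_boundary_and_errors(self):
        spec = HankelSpec(L=3, M=3, D=2, N=5)
        H = build_hankel(np.arange(5.0), spec)
        pair = shift_pair(H, 2, spec)
        assert pair.up.shape == (1, 3)
        with pytest.raises(ValueError):
            shift_pair(H, 3)
        with pytest.raises(ValueError):
            build_hankel(np.arange(4.0), spec)


class TestRankTruncate:
    def test_idempotent_on_exact_rank(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(6, 3)) @ rng.normal(size=(3, 8))
        np.testing.assert_allclose(rank_truncate(A, 3), A, rtol=1e-10, atol=1e-12)

    def test_identity_truncates_to_unit_spectral_norm(self):
        T = rank_truncate(np.eye(3), 1)
        assert np.linalg.matrix_rank(T, tol=1e-10) == 1
        assert np.linalg.norm(T, 2) == pytest.approx(1.0)

    def test_eckart_young_error(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(6, 8)) + 1j * rng.normal(size=(6, 8))
        sv = np.linalg.svd(A, compute_uv=False)
        err = np.linalg.norm(A - rank_truncate(A, 2), "fro")
        assert err == pytest.approx(np.sqrt(np.sum(sv[2:] ** 2)), rel=1e-12)

    def test_order_out_of_range(self):
        with pytest.raises(ValueError):
            rank_truncate(np.eye(3), 4)


class TestShiftSolvers:
    def test_ls_identity_and_zero(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(4, 4)) + np.eye(4) * 4
        np.testing.assert_allclose(solve_shift_ls(A, A), np.eye(4), atol=1e-10)
        np.testing.assert_allclose(solve_shift_ls(A, np.zeros((4, 4))), 0, atol=1e-12)

    def test_rank_of_X_bounded_by_enhancement_order(self, clean_series):
        # With the up-matrix truncated to p, X = down pinv(up_e) has rank <= p.
        spec = default_dims(128, 2)
        pair = shift_pair(build_hankel(clean_series["five_peak_31p"], spec), 2, spec)
        up_e, usv = rank_truncate(pair.up, 5, return_svd=True)
        X = solve_shift_ls(up_e, pair.down, svd=usv)
        sv = np.linalg.svd(X, compute_uv=False)
        assert sv[5] < 1e-10 * sv[0]
        w = np.sort(np.abs(np.linalg.eigvals(X)))[::-1]
        assert w[5] < 1e-8 * w[0] and w[4] > 1e-8

    def test_tls_zero_residual_recovers_exact_solution(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(7, 3)) + 1j * rng.normal(size=(7, 3))
        Q0 = rng.normal(size=(3, 2))
        Q = solve_shift_tls(A, A @ Q0)
        np.testing.assert_allclose(Q, Q0, atol=1e-10)

    def test_tls_scalar_closed_form(self):
        # Scalar TLS oracle: smallest eigenvector of [[a.a, a.b], [b.a, b.b]].
        rng = np.random.default_rng(4)
        a = rng.normal(size=(6, 1))
        b = rng.normal(size=(6, 1)) * 0.5 + a * 2.0
        M = np.block([[a.T @ a, a.T @ b], [b.T @ a, b.T @ b]])
        w, V = np.linalg.eigh(M)
        v = V[:, 0]  # eigenvector of the smallest eigenvalue
        expected = -v[0] / v[1]
        assert solve_shift_tls(a, b)[0, 0] == pytest.approx(expected, rel=1e-10)

    def test_tls_matches_brute_force_minimization(self):
        # TLS minimizes ||[dA dB]||_F over perturbations making (A+dA)q = B+dB.
        # Oracle: scan q and compute the closed-form minimal residual
        # ||Aq - B||^2 / (1 + q^2) for the scalar case.
        rng = np.random.default_rng(5)
        a = rng.normal(size=(5, 1))
        b = rng.normal(size=(5, 1))
        qs = np.linspace(-5, 5, 200_001)
        resid = np.sum((a * qs - b) ** 2, axis=0) / (1 + qs**2)
        q_star = qs[np.argmin(resid)]
        assert solve_shift_tls(a, b)[0, 0] == pytest.approx(q_star, abs=1e-4)

    def test_tls_nongeneric_raises(self):
        A = np.array([[1.0], [0.0]])
        B = np.array([[0.0], [2.0]])
        with pytest.raises(NongenericTLSError):
            solve_shift_tls(A, B)

    def test_tls_equals_ls_on_zero_residual_shift_system(self, clean_series):
        spec = default_dims(128, 1)
        pair = shift_pair(build_hankel(clean_series["two_peak"], spec), 1, spec)
        U, _, _ = np.linalg.svd(pair.up, full_matrices=False)
        Up = U[:, :2]
        A, B = Up[:-1], Up[1:]
        np.testing.assert_allclose(
            solve_shift_tls(A, B), solve_shift_ls(A, B, side="right"), atol=1e-10
        )


class TestPoles:
    def test_diagonal_matrix(self):
        ps = dominant_eigenvalues(np.diag([2.0, 1.0, 0.0, 0.0]), 2)
        np.testing.assert_allclose(ps.poles, [2.0, 1.0])

    def test_companion_matrix_roots(self):
        coeffs = [1.0, -2.0, -5.0, 6.0]  # roots 3, 1, -2
        C = np.polynomial.polynomial.polycompanion(coeffs[::-1])
        ps = dominant_eigenvalues(np.asarray(C), 3)
        np.testing.assert_allclose(
            sorted(ps.poles.real), [-2, 1, 3], atol=1e-10
        )

    def test_two_peak_poles_from_theorem(self, clean_series):
        spec = default_dims(128, 1)
        pair = shift_pair(build_hankel(clean_series["two_peak"], spec), 1, spec)
        up_e, usv = rank_truncate(pair.up, 2, return_svd=True)
        X = solve_shift_ls(up_e, pair.down, svd=usv)
        ps = dominant_eigenvalues(X, 2)
        expected = sorted(
            [np.exp(-0.01 + 2j * np.pi * 0.2), np.exp(-0.02 + 2j * np.pi * 0.22)],
            key=abs, reverse=True,
        )
        np.testing.assert_allclose(ps.poles, expected, rtol=1e-8)

    @pytest.mark.parametrize(
        "lam,D,fs,expected",
        [
            (1.0, 3, 2.0, (0.0, 0.0)),
            (np.exp((-0.01 + 2j * np.pi * 0.2) * 2), 2, 1.0, (0.2, 0.01)),
            (1j, 1, 1.0, (0.25, 0.0)),
        ],
    )
    def test_undecimate_examples(self, lam, D, fs, expected):
        f, d = undecimate_pole(lam, D, fs)
        assert (f, d) == pytest.approx(expected, abs=1e-12)

    def test_undecimate_zero_pole_rejected(self):
        with pytest.raises(ValueError):
            undecimate_pole(0.0, 1, 1.0)

    def test_decimation_multiplies_angular_separation(self):
        # Two close poles: decimated angular gap is exactly D times larger.
        f1, f2, fs = 0.10, 0.11, 1.0
        for D in (1, 2, 3):
            z1 = pole_from_params(f1, 0.01, fs, D)
            z2 = pole_from_params(f2, 0.01, fs, D)
            gap = np.angle(z2) - np.angle(z1)
            assert gap == pytest.approx(D * 2 * np.pi * (f2 - f1), rel=1e-12)


class TestLinearFit:
    def test_two_peak_unit_amplitudes(self, clean_series, two_peak):
        z = [pole_from_params(pk.f, pk.d, 1.0) for pk in two_peak.model.peaks]
        g = fit_linear_params(clean_series["two_peak"], np.array(z))
        np.testing.assert_allclose(g, [1.0, 1.0], atol=1e-9)

    def test_single_pole_constant_signal(self):
        from decspec import TimeSeries

        ts = TimeSeries(samples=np.full(8, 3.0 - 1.0j), fs=1.0)
        g = fit_linear_params(ts, np.array([1.0 + 0j]))
        assert g[0] == pytest.approx(3.0 - 1.0j)

    def test_five_peak_amplitudes_and_phases(self, clean_series, five_peak):
        m = five_peak.model
        z = np.array([pole_from_params(pk.f, pk.d, m.fs) for pk in m.peaks])
        g = fit_linear_params(clean_series["five_peak_31p"], z)
        np.testing.assert_allclose(np.abs(g), [6.1, 9.9, 6.0, 2.8, 17.0], rtol=1e-6)
        np.testing.assert_allclose(np.rad2deg(np.angle(g)), [15] * 5, rtol=1e-6)

    def test_duplicate_poles_rejected(self, clean_series):
        with pytest.raises(np.linalg.LinAlgError):
            fit_linear_params(
                clean_series["two_peak"], np.array([0.5 + 0.5j, 0.5 + 0.5j])
            )


@settings(deadline=None, max_examples=20, derandomize=True)
@given(
    st.integers(min_value=1, max_value=4),
    st.integers(min_value=1, max_value=3),
    st.integers(min_value=0, max_value=10_000),
)
def test_theorem_exactness_on_random_models(p, D, seed):
    """Noise-free shift-equation eigenvalues equal the decimated poles z_i^D."""
    rng = np.random.default_rng(seed)
    # distinct alias-free frequencies: D * |f| < 0.5
    f = rng.uniform(-0.45 / D, 0.45 / D, size=p)
    while np.min(np.abs(np.subtract.outer(f, f) + np.eye(p))) < 0.01 / D:
        f = rng.uniform(-0.45 / D, 0.45 / D, size=p)
    d = rng.uniform(0.005, 0.05, size=p)
    b = rng.uniform(0.5, 2.0, size=p)
    psi = rng.uniform(-180, 180, size=p)
    model = SinusoidModel(
        peaks=tuple(Peak(*row) for row in zip(f, d, b, psi)), fs=1.0
    )
    ts = synthesize(model, 64)
    spec = default_dims(64, D)
    pair = shift_pair(build_hankel(ts, spec), D, spec)
    up_e, usv = rank_truncate(pair.up, p, return_svd=True)
    X = solve_shift_ls(up_e, pair.down, svd=usv)
    lam = dominant_eigenvalues(X, p).poles
    expected = np.array([pole_from_params(fi, di, 1.0, D) for fi, di in zip(f, d)])
    key = lambda z: (np.round(np.angle(z), 9), np.abs(z))
    lam = np.array(sorted(lam, key=key))
    expected = np.array(sorted(expected, key=key))
    np.testing.assert_allclose(lam, expected, rtol=1e-8, atol=1e-10)
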