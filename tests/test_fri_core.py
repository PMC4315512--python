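"""Moments, Prony recovery, decaying-exponential reduction, order estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import frispike as fs
from frispike.errors import InsufficientMomentsError
from tests.conftest import draw_times


def _grid_kernel(P, N):
    grid = fs.FrequencyGrid.for_window(P, N)
    return grid, fs.make_espline(grid.alphas)


def _dirac_moments(tk, ak, grid, T):
    """Closed-form oracle: x_hat(-omega_m/T) = sum_k a_k e^{i omega_m t_k / T}."""
    return np.array([np.sum(ak * np.exp(1j * w * np.asarray(tk) / T)) for w in grid.omegas])


def _sample_and_moments(tk, ak, P=7, N=32, T=1.0):
    grid, kernel = _grid_kernel(P, N)
    y = fs.sample_diracs(fs.DiracStream(tk, ak), kernel, T)
    tab = fs.reproduction_coeffs(kernel, grid, (int(y.n_index[0]), int(y.n_index[-1])))
    return fs.compute_moments(y, tab), grid, T


class TestComputeMoments:
    def test_zero_samples_zero_moments(self, order6_grid, order6_kernel):
        tab = fs.reproduction_coeffs(order6_kernel, order6_grid, (0, 10))
        y = fs.SampleSequence(values=np.zeros(11), T=1.0)
        mom = fs.compute_moments(y, tab)
        assert np.all(mom.s == 0)

    def test_single_dirac_moments_have_constant_modulus(self):
        mom, _, _ = _sample_and_moments([5.37], [1.8])
        np.testing.assert_allclose(np.abs(mom.s), 1.8, rtol=1e-9)

    def test_moments_match_fourier_oracle_k4(self, rng):
        tk = draw_times(rng, 4, 0.0, 32.0, 1.0)
        ak = rng.uniform(0.5, 2.0, 4)
        mom, grid, T = _sample_and_moments(tk, ak)
        oracle = _dirac_moments(tk, ak, grid, T)
        assert np.max(np.abs(mom.s - oracle)) < 1e-6 * np.max(np.abs(oracle))

    def test_conjugate_symmetry_for_real_input(self, rng):
        tk = draw_times(rng, 3, 0.0, 30.0, 1.5)
        mom, _, _ = _sample_and_moments(tk, np.ones(3))
        assert mom.conjugate_symmetry_defect() < 1e-9

    def test_index_range_mismatch_rejected(self, order6_grid, order6_kernel):
        tab = fs.reproduction_coeffs(order6_kernel, order6_grid, (0, 5))
        y = fs.SampleSequence(values=np.zeros(11), T=1.0, n_start=3)
        with pytest.raises(ValueError):
            fs.compute_moments(y, tab)


class TestFiniteDifference:
    def test_pure_exponential_telescopes_to_zero(self):
        alpha, T = 0.5, 0.25
        y = fs.SampleSequence(values=3.0 * np.exp(-alpha * T * np.arange(20)), T=T)
        z = fs.finite_difference(y, alpha)
        assert np.max(np.abs(z.values[1:])) < 1e-12

    def test_zero_input_zero_output(self):
        y = fs.SampleSequence(values=np.zeros(10), T=1.0)
        assert np.all(fs.finite_difference(y, 1.0).values == 0)

    def test_equals_dirac_sampling_with_effective_kernel(self):
        # oracle from the reduction identity: z_n = <s(t), psi(t/T - n)>
        P, N, T, alpha = 7, 32, 0.25, 1.2
        grid, kernel = _grid_kernel(P, N)
        tk = np.array([0.8, 2.4, 3.7525, 6.2]) * T * 4 / 4
        ak = np.array([1.0, 0.8, 1.3, 0.6])
        y = fs.sample_stream(fs.ExponentialStream(tk, ak, alpha=alpha), kernel, T)
        z = fs.finite_difference(y, alpha)
        psi = fs.effective_kernel(kernel, alpha, T)
        direct = fs.sample_diracs(fs.DiracStream(tk, ak), psi, T,
                                  n_range=(int(z.n_index[0]), int(z.n_index[-1])))
        assert np.max(np.abs(z.values - direct.values)) < 1e-8


class TestEffectiveKernel:
    def test_effective_kernel_support_extends_one_left(self, order6_kernel):
        psi = fs.effective_kernel(order6_kernel, 0.5, 1.0)
        assert psi.support == (-1.0, 7.0)

    def test_effective_coeffs_reproduce_exponentials(self, order6_grid, order6_kernel):
        T, alpha = 1.0, 0.5
        psi = fs.effective_kernel(order6_kernel, alpha, T)
        tab = fs.effective_coeffs(order6_kernel, alpha, T, order6_grid, (0, 40))
        lo, hi = tab.interior_interval(psi)
        t = np.linspace(lo, hi, 3001, endpoint=False)
        rep = tab.reproduce(psi, t)
        target = np.exp(1j * np.outer(order6_grid.omegas, t))
        assert np.max(np.abs(rep - target)) < 1e-6

    def test_moment_paths_agree_dirac_vs_finite_difference(self, rng):
        # same events seen through the direct path and through the reduction
        P, N, T, alpha = 7, 32, 0.5, 0.7
        grid, kernel = _grid_kernel(P, N)
        tk = draw_times(rng, 3, 2 * T, 25 * T, 2 * T)
        ak = rng.uniform(0.5, 1.5, 3)
        y = fs.sample_stream(fs.ExponentialStream(tk, ak, alpha=alpha), kernel, T)
        z = fs.finite_difference(y, alpha)
        d_tab = fs.effective_coeffs(kernel, alpha, T, grid, (int(z.n_index[0]), int(z.n_index[-1])))
        s_z = fs.compute_moments(z, d_tab).s
        yd = fs.sample_diracs(fs.DiracStream(tk, ak), kernel, T)
        c_tab = fs.reproduction_coeffs(kernel, grid, (int(yd.n_index[0]), int(yd.n_index[-1])))
        s_d = fs.compute_moments(yd, c_tab).s
        assert np.max(np.abs(s_z - s_d)) < 1e-8 * max(1.0, np.max(np.abs(s_d)))


class TestProny:
    def test_single_geometric_sequence(self):
        theta = 0.9
        grid = fs.FrequencyGrid.for_window(3, 16)
        s = 3.0 * np.exp(1j * theta) ** np.arange(4)
        sol = fs.prony(fs.MomentVector(s=s, grid=grid, T=1.0), 1)
        assert abs(sol.h[0] + np.exp(1j * theta)) < 1e-12
        assert abs(sol.u[0] - np.exp(1j * theta)) < 1e-12
        assert abs(sol.b[0] - 3.0) < 1e-12

    def test_two_component_synthesis_recovered(self):
        grid = fs.FrequencyGrid.for_window(5, 16)
        u = np.exp(1j * np.array([0.4, 1.7]))
        b = np.array([1.0 + 0.2j, 0.5 - 0.1j])
        s = (u[None, :] ** np.arange(6)[:, None]) @ b
        sol = fs.prony(fs.MomentVector(s=s, grid=grid, T=1.0), 2)
        assert np.max(np.abs(np.sort_complex(sol.u) - np.sort_complex(u))) < 1e-10

    def test_insufficient_moments_rejected(self):
        grid = fs.FrequencyGrid.for_window(4, 16)
        mom = fs.MomentVector(s=np.ones(5), grid=grid, T=1.0)
        with pytest.raises(InsufficientMomentsError):
            fs.prony(mom, 3)

    def test_noiseless_toeplitz_rank_equals_K(self, rng):
        tk = draw_times(rng, 4, 0.0, 32.0, 1.0)
        mom, _, _ = _sample_and_moments(tk, np.ones(4), P=9)
        sv = np.linalg.svd(fs.moment_toeplitz(mom.s), compute_uv=False)
        assert np.count_nonzero(sv / sv[0] > 1e-8) == 4

    def test_amplitude_scaling_invariance(self, rng):
        tk = draw_times(rng, 3, 0.0, 30.0, 1.5)
        ak = rng.uniform(0.5, 1.5, 3)
        mom, grid, T = _sample_and_moments(tk, ak)
        scaled = fs.MomentVector(s=7.0 * mom.s, grid=grid, T=T)
        sol = fs.prony(mom, 3)
        sol2 = fs.prony(scaled, 3)
        assert np.max(np.abs(np.sort_complex(sol.u) - np.sort_complex(sol2.u))) < 1e-9
        assert np.max(np.abs(np.sort_complex(7 * sol.b) - np.sort_complex(sol2.b))) < 1e-8


class TestSolutionToEvents:
    def test_unit_root_maps_to_time_zero(self):
        grid = fs.FrequencyGrid.for_window(3, 16)
        sol = fs.PronySolution(u=np.array([1.0 + 0j]), b=np.array([2.5 + 0j]),
                               h=np.array([]), residual=0.0, singular_values=np.array([]))
        res = fs.solution_to_events(sol, grid, T=1.0)
        assert res.times[0] == pytest.approx(0.0)
        assert res.amplitudes[0] == pytest.approx(2.5)

    def test_critical_rate_roundtrip_k4(self, rng):
        # end-to-end identity at the critical sampling rate P + 1 = 2K
        T = 0.25
        grid, kernel = _grid_kernel(7, 32)
        tk = draw_times(rng, 4, 0.0, 32 * T, T)
        ak = rng.uniform(0.5, 2.0, 4)
        y = fs.sample_diracs(fs.DiracStream(tk, ak), kernel, T)
        tab = fs.reproduction_coeffs(kernel, grid, (int(y.n_index[0]), int(y.n_index[-1])))
        res = fs.solution_to_events(fs.prony(fs.compute_moments(y, tab), 4), grid, T)
        assert np.max(np.abs(res.times - tk)) < 1e-9
        assert np.max(np.abs(res.amplitudes - ak)) < 1e-9
        assert res.diagnostics["max_imag_amplitude"] < 1e-9


class TestEstimateK:
    @pytest.mark.parametrize("K", [1, 2, 3, 4, 5])
    def test_noiseless_rank_detection(self, K, rng):
        N = 32
        P = max(2 * K + 1, 5)
        grid, kernel = _grid_kernel(P, N)
        tk = draw_times(rng, K, 0.0, float(N), 1.5)
        mom, _, _ = _sample_and_moments(tk, np.ones(K), P=P, N=N)
        assert fs.estimate_K(mom, 0.01) == K

    def test_single_event(self):
        mom, _, _ = _sample_and_moments([11.3], [1.0])
        for mu0 in (0.01, 0.3, 0.9):
            assert fs.estimate_K(mom, mu0) == 1

    def test_noise_only_never_returns_zero(self, rng):
        grid = fs.FrequencyGrid.for_window(9, 32)
        s = rng.normal(size=10) + 1j * rng.normal(size=10)
        mom = fs.MomentVector(s=s, grid=grid, T=1.0)
        assert fs.estimate_K(mom, 0.3) >= 1


@settings(deadline=None, max_examples=15, derandomize=True)
@given(seed=st.integers(min_value=0, max_value=10_000),
       K=st.integers(min_value=1, max_value=4))
def test_perfect_reconstruction_theorem(seed, K):
    """Any K <= floor((P+1)/2) distinct events are exactly recoverable."""
    rng = np.random.default_rng(seed)
    T = 1.0
    grid, kernel = _grid_kernel(7, 32)
    tk = draw_times(rng, K, 0.0, 32.0, 1.0)
    ak = rng.uniform(0.2, 2.0, K) * np.sign(rng.uniform(-1, 1, K))
    ak[ak == 0] = 1.0
    y = fs.sample_diracs(fs.DiracStream(tk, ak), kernel, T)
    tab = fs.reproduction_coeffs(kernel, grid, (int(y.n_index[0]), int(y.n_index[-1])))
    res = fs.solution_to_events(fs.prony(fs.compute_moments(y, tab), K), grid, T)
    assert np.max(np.abs(res.times - tk)) / T < 1e-6
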