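"""Moment computation and Prony-type parameter recovery.

With an exponential-reproducing kernel, the weighted sums
``s_m = sum_n c_{m,n} y_n`` equal samples of the input's Fourier transform,
``s_m = x_hat(-omega_m / T)``.  For a stream of K Diracs these moments are a
sum of K geometric progressions,

    s_m = sum_k b_k u_k^m,   b_k = a_k e^{i omega_0 t_k / T},
                             u_k = e^{i lambda t_k / T},

so the locations and amplitudes follow from classical spectral estimation:
the annihilating-filter (Prony) system yields the ``u_k`` as roots of a
degree-K polynomial, and the ``b_k`` by linear least squares.  Streams of
decaying exponentials reduce to the Dirac case through the finite
difference ``z_n = y_n - y_{n-1} e^{-alpha T}``, which is equivalent to
having sampled the underlying Diracs with the effective kernel
``psi(t) = beta_{alpha T}(-t) * phi(t)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.linalg

from .errors import InsufficientMomentsError
from .kernels import CoeffTable, ESplineKernel, FrequencyGrid, reproduction_coeffs
from .sampling import SampleSequence

__all__ = [
    "MomentVector",
    "PronySolution",
    "ReconstructionResult",
    "compute_moments",
    "finite_difference",
    "effective_kernel",
    "effective_coeffs",
    "prony",
    "roots_from_annihilator",
    "fit_amplitudes",
    "solution_to_events",
    "estimate_K",
    "moment_toeplitz",
    "reconstruct_events",
]


@dataclass(frozen=True)
class MomentVector:
    """Fourier-domain measurements ``s_m``, ``m = 0..P``, on a frequency grid."""

    s: np.ndarray
    grid: FrequencyGrid
    T: float

    def __post_init__(self) -> None:
        s = np.atleast_1d(np.asarray(self.s, dtype=complex))
        if s.size != self.grid.P + 1:
            raise ValueError("moment vector length must equal grid order P + 1")
        object.__setattr__(self, "s", s)

    @property
    def P(self) -> int:
        return self.grid.P

    def conjugate_symmetry_defect(self) -> float:
        """``max_m |s_{P-m} - conj(s_m)|``; ~0 for real-valued inputs."""
        return float(np.max(np.abs(self.s[::-1] - np.conj(self.s))))


@dataclass(frozen=True)
class PronySolution:
    u: np.ndarray
    b: np.ndarray
    h: np.ndarray
    residual: float
    singular_values: np.ndarray
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class ReconstructionResult:
    times: np.ndarray
    amplitudes: np.ndarray
    K: int
    residual: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def events(self) -> list[tuple[float, float]]:
        return list(zip(self.times.tolist(), self.amplitudes.tolist()))


def compute_moments(samples: SampleSequence, coeffs: CoeffTable, T: Optional[float] = None) -> MomentVector:
    """``s_m = sum_n c_{m,n} y_n`` over the samples' absolute index range."""
    n = samples.n_index
    if n[0] < coeffs.n0 or n[-1] > coeffs.nf:
        raise ValueError(
            f"coefficient table covers n in [{coeffs.n0}, {coeffs.nf}] but samples "
            f"span [{n[0]}, {n[-1]}]"
        )
    idx = n - coeffs.n0
    s = coeffs.c[:, idx] @ samples.values
    return MomentVector(s=s, grid=coeffs.grid, T=samples.T if T is None else T)


def finite_difference(samples: SampleSequence, alpha: float, T: Optional[float] = None) -> SampleSequence:
    """``z_n = y_n - y_{n-1} e^{-alpha T}``; the sample before the record is taken as 0.

    For a finite stream of decaying exponentials the output has finitely many
    nonzero entries: it equals the sequence obtained by sampling the
    underlying Diracs with the effective kernel ``psi``.
    """
    T = samples.T if T is None else T
    decay = math.exp(-alpha * T)
    y = np.asarray(samples.values)
    z = y.astype(float if np.isrealobj(y) else complex).copy()
    z[1:] -= decay * y[:-1]
    return samples.with_values(z)


def effective_kernel(kernel: ESplineKernel, alpha: float, T: float) -> ESplineKernel:
    """Effective kernel of the decaying-exponential reduction.

    Writing the stream as innovation Diracs convolved with
    ``rho_alpha(t) = e^{-alpha t} 1_{t>=0}``, the finite difference of the
    samples satisfies ``z_n = <s(t), psi(t/T - n)>`` with

        psi(t) = T * (beta_{-alpha T}(-.) * phi)(t),

    because ``rho_alpha(w) - e^{-alpha T} rho_alpha(w - T)`` collapses to the
    compact one-sided factor ``e^{-alpha w} 1_{0 <= w < T}``.  Using
    ``beta_{-a}(-t) = e^{-a} beta_{a}(t + 1)``, ``psi`` is itself an E-spline
    with one extra real exponent ``+alpha T``, shifted left by one and scaled
    by ``T e^{-alpha T}``; its support is ``[shift - 1, shift + P + 2)``.
    Convolution preserves the reproduction property, so ``psi`` reproduces
    the same exponentials as ``phi``.
    """
    if not isinstance(kernel, ESplineKernel):
        raise TypeError("effective kernel reduction is implemented for E-splines")
    a = alpha * T
    return ESplineKernel(
        np.concatenate([kernel.alphas, [a]]),
        shift=kernel.shift - 1.0,
        scale=kernel.scale * T * math.exp(-a),
    )


def effective_coeffs(
    kernel: ESplineKernel,
    alpha: float,
    T: float,
    grid: FrequencyGrid,
    n_range: tuple[int, int],
    **kwargs,
) -> CoeffTable:
    """Reproduction coefficients ``d_{m,n}`` of the effective kernel ``psi``."""
    return reproduction_coeffs(effective_kernel(kernel, alpha, T), grid, n_range, **kwargs)


def _toeplitz_system(s: np.ndarray, K: int) -> tuple[np.ndarray, np.ndarray]:
    """All-rows annihilating system ``A h = -rhs`` with ``A[i, j] = s[K-1+i-j]``."""
    P = s.size - 1
    A = scipy.linalg.toeplitz(s[K - 1 : P], s[K - 1 :: -1])
    rhs = -s[K : P + 1]
    return A, rhs


def prony(moments: MomentVector, K: int) -> PronySolution:
    """Annihilating-filter recovery of ``(u_k, b_k)`` from ``s_m = sum b_k u_k^m``.

    The annihilator coefficients solve the Toeplitz system using all
    available rows (least squares; identical to the square system at the
    critical rate ``P + 1 = 2K``).  Roots are extracted from the companion
    matrix of ``z^K + h_1 z^{K-1} + ... + h_K``; amplitudes by least squares
    on the Vandermonde system.
    """
    s = moments.s
    P = s.size - 1
    if K < 1:
        raise InsufficientMomentsError("K must be >= 1")
    if 2 * K > P + 1:
        raise InsufficientMomentsError(f"need P+1 >= 2K moments (P={P}, K={K})")
    A, rhs = _toeplitz_system(s, K)
    h, _, rank, sv = np.linalg.lstsq(A, rhs, rcond=None)
    warnings: list[str] = []
    if rank < K:
        warnings.append("annihilating system numerically rank deficient")
    u = np.roots(np.concatenate([[1.0 + 0.0j], h]))
    if u.size > 1:
        du = np.abs(u[:, None] - u[None, :]) + np.eye(u.size)
        if float(du.min()) < 1e-8:
            warnings.append("near-coincident roots; degenerate event configuration")
    b, residual = fit_amplitudes(s, u)
    return PronySolution(u=u, b=b, h=h, residual=residual,
                         singular_values=sv, warnings=tuple(warnings))


def roots_from_annihilator(h: np.ndarray) -> np.ndarray:
    """Roots ``u_k`` of ``H(z) = 1 + h_1 z^{-1} + ... + h_K z^{-K}``."""
    h = np.atleast_1d(np.asarray(h, dtype=complex))
    return np.roots(np.concatenate([[1.0 + 0.0j], h]))

def fit_amplitudes(s: np.ndarray, u: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares weights ``b`` of ``s_m = sum_k b_k u_k^m`` and the fit residual."""
    m = np.arange(s.size)
    V = u[None, :] ** m[:, None]
    b, *_ = np.linalg.lstsq(V, s, rcond=None)
    residual = float(np.linalg.norm(V @ b - s))
    return b, residual


def solution_to_events(
    sol: PronySolution, grid: FrequencyGrid, T: float, *, u_dev_tol: float = 0.2
) -> ReconstructionResult:
    """Map roots/weights to event parameters ``(t_k, a_k)``.

    ``t_k = T arg(u_k)/lambda`` with the argument taken in ``[0, 2 pi)``
    (unique for locations within one window length) and
    ``a_k = b_k e^{-i omega_0 t_k / T}``.  Roots far from the unit circle
    are flagged in the diagnostics as a noise/border indicator, not fatal.
    """
    if grid.lam == 0:
        raise ValueError("grid spacing lambda must be nonzero")
    ang = np.mod(np.angle(sol.u), 2.0 * np.pi)
    t = T * ang / grid.lam
    a_complex = sol.b * np.exp(-1j * grid.omega0 * t / T)
    order = np.argsort(t)
    t = t[order]
    a_complex = a_complex[order]
    u_mod = np.abs(sol.u)[order]
    diagnostics = {
        "residual": sol.residual,
        "singular_values": sol.singular_values,
        "u_moduli": u_mod,
        "offcircle": bool(np.any(np.abs(u_mod - 1.0) > u_dev_tol)),
        "max_imag_amplitude": float(np.max(np.abs(a_complex.imag))) if a_complex.size else 0.0,
        "warnings": sol.warnings,
    }
    return ReconstructionResult(
        times=t, amplitudes=a_complex.real, K=int(t.size),
        residual=sol.residual, diagnostics=diagnostics,
    )


def moment_toeplitz(s: np.ndarray) -> np.ndarray:
    """Toeplitz moment matrix with ``ceil(P/2)+1`` columns and ``floor(P/2)+1`` rows.

    Entry ``(i, j)`` is ``s_{ceil(P/2) + i - j}``; in the noiseless case its
    rank equals the number of events K.
    """
    s = np.atleast_1d(np.asarray(s, dtype=complex))
    P = s.size - 1
    c = math.ceil(P / 2)
    return scipy.linalg.toeplitz(s[c:], s[c::-1])


def estimate_K(moments: MomentVector | np.ndarray, mu0: float = 0.3, k_max: Optional[int] = None) -> int:
    """Model-order estimate from normalised singular values of the moment matrix.

    Counts singular values with ``mu_i / mu_1 >= mu0``.  Never returns 0
    (with noise the leading singular value is always nonzero), and tends to
    overestimate K in noise; ``mu0`` should be adjusted to the noise level.
    """
    s = moments.s if isinstance(moments, MomentVector) else np.asarray(moments, dtype=complex)
    if s.size < 2:
        raise ValueError("need at least two moments")
    if not 0.0 < mu0 < 1.0:
        raise ValueError("mu0 must lie in (0, 1)")
    sv = np.linalg.svd(moment_toeplitz(s), compute_uv=False)
    if sv[0] == 0.0:
        return 1
    K = int(np.count_nonzero(sv / sv[0] >= mu0))
    K = max(K, 1)
    if k_max is not None:
        K = min(K, int(k_max))
    return K


def reconstruct_events(
    samples: SampleSequence,
    kernel: ESplineKernel,
    grid: FrequencyGrid,
    K: Optional[int] = None,
    *,
    alpha: Optional[float] = None,
    mu0: float = 0.3,
    cadzow_iterations: int = 0,
    method: str = "prony",
) -> ReconstructionResult:
    """Single-window pipeline: samples -> moments -> Prony -> events.

    If ``alpha`` is given the input is treated as a kernel-acquired stream of
    decaying exponentials: the finite difference is applied and the
    effective-kernel coefficients are used.  ``K=None`` estimates the model
    order from the moment matrix.  ``method`` selects the root solver:
    ``prony`` (least-squares annihilator), ``tls`` (total-least-squares
    annihilator) or ``pencil`` (matrix pencil); Cadzow denoising may be
    applied first.
    """
    from . import denoise  # local import to avoid a cycle

    n_lo, n_hi = int(samples.n_index[0]), int(samples.n_index[-1])
    if alpha is not None:
        work = finite_difference(samples, alpha)
        table = effective_coeffs(kernel, alpha, samples.T, grid, (n_lo, n_hi))
    else:
        work = samples
        table = reproduction_coeffs(kernel, grid, (n_lo, n_hi))
    moments = compute_moments(work, table)
    if K is None:
        K = estimate_K(moments, mu0=mu0, k_max=(grid.P + 1) // 2)
    if cadzow_iterations > 0:
        moments = denoise.cadzow(moments, K, max_iter=cadzow_iterations)
    if method == "prony":
        sol = prony(moments, K)
    elif method == "tls":
        h = denoise.tls_annihilator(moments, K)
        u = roots_from_annihilator(h[1:])
        b, residual = fit_amplitudes(moments.s, u)
        sol = PronySolution(u=u, b=b, h=h[1:], residual=residual,
                            singular_values=np.array([]))
    elif method == "pencil":
        u = denoise.matrix_pencil(moments, K)
        b, residual = fit_amplitudes(moments.s, u)
        sol = PronySolution(u=u, b=b, h=np.array([]), residual=residual,
                            singular_values=np.array([]))
    else:
        raise ValueError(f"unknown method {method!r}")
    return solution_to_events(sol, grid, samples.T)
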