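"""Exponential-reproducing sampling kernels.

The acquisition model filters the continuous-time input with a sampling
kernel ``phi`` before taking uniform samples.  Perfect reconstruction of
sparse pulse streams requires ``phi`` to reproduce a set of complex
exponentials ``e^{i omega_m t}`` through integer shifts,

    sum_n c_{m,n} phi(t - n) = e^{i omega_m t},   m = 0..P,

which holds exactly if and only if ``phi`` satisfies the generalised
Strang-Fix conditions: ``phi_hat(omega_m) != 0`` and
``phi_hat(omega_m + 2*pi*l) = 0`` for every nonzero integer ``l``.

Two kernel families are provided:

* :class:`ESplineKernel` -- exponential B-splines, the canonical family
  satisfying the conditions exactly.  An E-spline of order ``P`` is the
  convolution of ``P + 1`` zero-order factors ``e^{alpha_m t} 1_[0,1)`` and
  has compact support of length ``P + 1``.
* :class:`GaussianKernel` -- does not satisfy the conditions exactly but its
  transform is negligibly small at the off-grid frequencies, so the
  constant-least-squares coefficients give a very accurate approximate
  reproduction.

E-splines are evaluated in closed form: the Fourier transform is a rational
function times a polynomial in ``e^{-i omega}``; expanding the polynomial and
partial-fractioning the rational part (with multiplicities, so repeated
exponents are exact) expresses the kernel as a finite sum of one-sided
terms ``(t - j)^p e^{alpha (t - j)} 1_{t >= j}``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateKernelError

__all__ = [
    "FrequencyGrid",
    "ESplineKernel",
    "GaussianKernel",
    "CoeffTable",
    "StrangFixReport",
    "make_espline",
    "make_gaussian",
    "kernel_fourier",
    "verify_strang_fix",
    "reproduction_coeffs",
    "approx_coeffs",
]

_ROOT_CLUSTER_TOL = 1e-9
_SINGULARITY_TOL = 1e-8


@dataclass(frozen=True)
class FrequencyGrid:
    """Equispaced symmetric frequency grid ``omega_m = omega0 + lam * m``.

    The symmetry ``omega_m = -omega_{P-m}`` (hence ``omega0 = -lam*P/2``)
    makes the purely imaginary exponent vector conjugate-symmetric, so the
    associated E-spline is real-valued.  Distinct frequencies must not differ
    by a nonzero multiple of ``2*pi``, otherwise a frequency would sit on a
    Strang-Fix zero introduced by another one.
    """

    omega0: float
    lam: float
    P: int

    def __post_init__(self) -> None:
        if self.P < 0:
            raise ValueError("grid order P must be >= 0")
        if self.P > 0 and self.lam == 0.0:
            raise ValueError("lam must be nonzero for P > 0")
        if abs(self.omega0 + self.lam * self.P / 2.0) > 1e-9 * max(1.0, abs(self.lam)):
            raise ValueError(
                "grid must be symmetric: omega0 = -lam*P/2 "
                f"(got omega0={self.omega0}, lam={self.lam}, P={self.P})"
            )
        # omega_m - omega_n = lam*(m-n) must never be a nonzero multiple of 2*pi
        for d in range(1, self.P + 1):
            r = (self.lam * d) / (2.0 * np.pi)
            if abs(r - round(r)) < 1e-9 and round(r) != 0:
                raise ValueError(
                    f"frequencies {d} steps apart differ by {round(r)}*2*pi; "
                    "grid violates the Strang-Fix compatibility condition"
                )

    @classmethod
    def for_window(cls, P: int, N: int) -> "FrequencyGrid":
        """Default grid for order ``P`` and an ``N``-sample window.

        ``lam = 2*pi/N`` keeps the phase ``lam * t/T`` within one period for
        locations inside the window, so the mapping root -> location is
        unambiguous on ``[0, N*T)``.
        """
        lam = 2.0 * np.pi / N
        return cls(omega0=-lam * P / 2.0, lam=lam, P=P)

    @property
    def omegas(self) -> np.ndarray:
        return self.omega0 + self.lam * np.arange(self.P + 1)

    @property
    def alphas(self) -> np.ndarray:
        """Purely imaginary exponent vector ``i*omega_m``."""
        return 1j * self.omegas


def _zero_order_ft(omega: np.ndarray, alpha: complex) -> np.ndarray:
    """Transform of ``e^{alpha t} 1_[0,1)``: ``(1 - e^{alpha - i w}) / (i w - alpha)``.

    The singularity at ``i*omega = alpha`` is removable with limit value 1;
    near it the quotient is evaluated by its Taylor series.
    """
    omega = np.asarray(omega, dtype=float)
    e = 1j * omega - alpha
    out = np.empty(np.shape(e), dtype=complex)
    small = np.abs(e) < _SINGULARITY_TOL
    es = np.where(small, 0.0, e)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (1.0 - np.exp(-es)) / es
    if np.any(small):
        z = e[small] if e.ndim else e
        out[small] = 1.0 - z / 2.0 + z**2 / 6.0 - z**3 / 24.0
    return out


def _cluster_roots(alphas: np.ndarray) -> list[tuple[complex, int]]:
    """Group (approximately) equal exponents into (value, multiplicity) pairs."""
    groups: list[list[complex]] = []
    for a in sorted(alphas, key=lambda z: (z.real, z.imag)):
        if groups and abs(a - groups[-1][0]) < _ROOT_CLUSTER_TOL:
            groups[-1].append(a)
        else:
            groups.append([a])
    return [(complex(np.mean(g)), len(g)) for g in groups]


def _partial_fractions(groups: Sequence[tuple[complex, int]]) -> list[tuple[complex, np.ndarray]]:
    """Partial-fraction coefficients of ``1 / prod_j (s - a_j)^{mu_j}``.

    Returns, per distinct root ``a_j``, the coefficients ``c_{j,p}`` of
    ``1/(s - a_j)^p`` for ``p = 1..mu_j`` (index ``p-1`` in the array).
    Residues are obtained by Taylor-expanding the remaining factors around
    the root and inverting the power series.
    """
    terms: list[tuple[complex, np.ndarray]] = []
    for j, (aj, mj) in enumerate(groups):
        # Taylor coefficients of h(aj + e) = prod_{l != j} (e + (aj - a_l))^{mu_l};
        # extended precision: the residues are large and later cancel
        h = np.array([1.0 + 0.0j], dtype=np.clongdouble)
        for l, (al, ml) in enumerate(groups):
            if l == j:
                continue
            base = np.array([aj - al, 1.0 + 0.0j], dtype=np.clongdouble)
            for _ in range(ml):
                h = np.convolve(h, base)
        h = h[:mj] if len(h) >= mj else np.pad(h, (0, mj - len(h)))
        inv = np.zeros(mj, dtype=np.clongdouble)
        inv[0] = 1.0 / h[0]
        for q in range(1, mj):
            inv[q] = -np.dot(h[1 : q + 1], inv[q - 1 :: -1]) / h[0]
        # c_{j,p} = inv[mj - p]
        coeffs = np.array([inv[mj - p] for p in range(1, mj + 1)])
        terms.append((aj, coeffs))
    return terms


def _is_conjugate_symmetric(alphas: np.ndarray) -> bool:
    a = np.sort_complex(np.asarray(alphas, dtype=complex))
    b = np.sort_complex(np.conj(a))
    return bool(np.allclose(a, b, atol=1e-12))


class ESplineKernel:
    """Exponential B-spline with exponent vector ``alpha_vec``.

    ``phi(t) = scale * beta_alpha(t - shift)`` where ``beta_alpha`` is the
    convolution of the zero-order factors ``e^{alpha_m t} 1_[0,1)``.  The
    support is the half-open interval ``[shift, shift + P + 1)``.  ``shift``
    and ``scale`` allow derived kernels (e.g. the effective kernel of the
    decaying-exponential reduction) to share the same machinery.
    """

    family = "espline"

    def __init__(self, alpha_vec: Sequence[complex], *, shift: float = 0.0, scale: complex = 1.0):
        alphas = np.atleast_1d(np.asarray(alpha_vec, dtype=complex))
        if alphas.size == 0:
            raise ValueError("E-spline needs at least one exponent")
        self.alphas = alphas
        self.shift = float(shift)
        self.scale = complex(scale)
        self.P = alphas.size - 1
        self.is_real = _is_conjugate_symmetric(alphas) and abs(self.scale.imag) < 1e-14
        # numerator of the transform as a polynomial in e^{-i omega}
        q = np.array([1.0 + 0.0j], dtype=np.clongdouble)
        for a in alphas:
            q = np.convolve(q, np.array([1.0, -np.exp(np.clongdouble(a))], dtype=np.clongdouble))
        self._q = q
        self._pf = _partial_fractions(_cluster_roots(alphas))

    @property
    def support(self) -> tuple[float, float]:
        return (self.shift, self.shift + self.P + 1)

    @property
    def support_length(self) -> float:
        return float(self.P + 1)

    def knots(self) -> np.ndarray:
        """Breakpoints between the polynomial-exponential pieces."""
        return self.shift + np.arange(self.P + 2, dtype=float)

    def __call__(self, t) -> np.ndarray:
        # The one-sided terms largely cancel (residues can exceed the kernel
        # amplitude by orders of magnitude), so the sum is accumulated in
        # extended precision and rounded once at the end.
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        tt = np.atleast_1d(t) - self.shift
        out = np.zeros(tt.shape, dtype=complex)
        inside = (tt >= 0.0) & (tt < self.P + 1)
        if np.any(inside):
            s_all = tt[inside].astype(np.longdouble)
            acc = np.zeros(s_all.shape, dtype=np.clongdouble)
            for aj, coeffs in self._pf:
                aj = np.clongdouble(aj)
                for p, cjp in enumerate(coeffs, start=1):
                    if cjp == 0:
                        continue
                    fac = np.clongdouble(cjp) / math.factorial(p - 1)
                    for i, qi in enumerate(self._q):
                        if qi == 0:
                            continue
                        s = s_all - i
                        mask = s >= 0.0
                        if not mask.any():
                            continue
                        sv = s[mask]
                        acc[mask] += fac * np.clongdouble(qi) * sv ** (p - 1) * np.exp(aj * sv)
            out[inside] = acc.astype(complex)
        out *= self.scale
        if self.is_real:
            out = out.real
        return out[0] if scalar else out

    def fourier(self, omega) -> np.ndarray:
        omega = np.asarray(omega, dtype=float)
        scalar = omega.ndim == 0
        w = np.atleast_1d(omega)
        val = np.ones(w.shape, dtype=complex)
        for a in self.alphas:
            val = val * _zero_order_ft(w, a)
        val *= self.scale * np.exp(-1j * w * self.shift)
        return val[0] if scalar else val


class GaussianKernel:
    """Normalised Gaussian ``exp(-t^2/2 sigma^2)/sqrt(2 pi sigma^2)``.

    Its transform ``exp(-omega^2 sigma^2 / 2)`` never vanishes, so the
    Strang-Fix conditions only hold approximately; the support is clipped
    where the amplitude falls below ``trunc_tol`` (about ``7.4 sigma`` for
    the default tolerance) so that discrete reproduction sums are finite.
    """

    family = "gaussian"

    def __init__(self, sigma: float, *, trunc_tol: float = 1e-12):
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        self.sigma = float(sigma)
        self.trunc_tol = float(trunc_tol)
        peak = 1.0 / math.sqrt(2.0 * math.pi * sigma**2)
        # clip where |phi| < trunc_tol: peak * exp(-r^2 / 2 sigma^2) = trunc_tol
        self._radius = sigma * math.sqrt(max(2.0 * math.log(peak / trunc_tol), 0.0))
        self.is_real = True

    @property
    def support(self) -> tuple[float, float]:
        return (-self._radius, self._radius)

    @property
    def support_length(self) -> float:
        return 2.0 * self._radius

    def knots(self) -> np.ndarray:
        # no true breakpoints; unit subdivision keeps quadrature pieces short
        return np.arange(-math.ceil(self._radius), math.ceil(self._radius) + 1, dtype=float)

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        peak = 1.0 / math.sqrt(2.0 * math.pi * self.sigma**2)
        val = peak * np.exp(-(t**2) / (2.0 * self.sigma**2))
        return np.where(np.abs(t) <= self._radius, val, 0.0)

    def fourier(self, omega) -> np.ndarray:
        omega = np.asarray(omega, dtype=float)
        return np.exp(-(omega**2) * self.sigma**2 / 2.0) + 0.0j


Kernel = ESplineKernel | GaussianKernel


def make_espline(alpha_vec: Sequence[complex]) -> ESplineKernel:
    """E-spline with the given exponent vector (support ``[0, P+1)``)."""
    return ESplineKernel(alpha_vec)


def make_gaussian(sigma: float, *, trunc_tol: float = 1e-12) -> GaussianKernel:
    return GaussianKernel(sigma, trunc_tol=trunc_tol)


def kernel_fourier(kernel: Kernel, omega) -> np.ndarray:
    """Fourier transform of the kernel at ``omega`` (closed form)."""
    return kernel.fourier(omega)


@dataclass(frozen=True)
class StrangFixEntry:
    omega: float
    on_grid_magnitude: float
    max_offgrid_magnitude: float
    passes_exact: bool


@dataclass(frozen=True)
class StrangFixReport:
    entries: tuple[StrangFixEntry, ...]

    @property
    def all_pass(self) -> bool:
        return all(e.passes_exact for e in self.entries)


def verify_strang_fix(
    kernel: Kernel, grid: FrequencyGrid, l_max: int = 10, tol: float = 1e-9
) -> StrangFixReport:
    """Check the generalised Strang-Fix conditions on the grid frequencies.

    For each ``omega_m`` the report carries ``|phi_hat(omega_m)|`` and the
    largest ``|phi_hat(omega_m + 2*pi*l)|`` over ``1 <= |l| <= l_max``; the
    frequency passes exactly when the former exceeds ``tol`` and the latter
    stays below it.
    """
    if l_max < 1:
        raise ValueError("l_max must be >= 1")
    ls = np.concatenate([np.arange(-l_max, 0), np.arange(1, l_max + 1)])
    entries = []
    for wm in grid.omegas:
        on = abs(complex(kernel.fourier(wm)))
        off = float(np.max(np.abs(kernel.fourier(wm + 2.0 * np.pi * ls))))
        entries.append(
            StrangFixEntry(
                omega=float(wm),
                on_grid_magnitude=on,
                max_offgrid_magnitude=off,
                passes_exact=bool(on > tol and off < tol),
            )
        )
    return StrangFixReport(entries=tuple(entries))


@dataclass(frozen=True)
class CoeffTable:
    """Exponential-reproduction coefficients ``c_{m,n}`` on a finite index range.

    The ``n`` dependence is a pure phase, ``c_{m,n} = e^{i omega_m n} c_{m,0}``;
    only ``c_{m,0}`` and the index range are stored.  In exact mode
    ``c_{m,0} = 1/phi_hat(omega_m)``; in constant-least-squares mode
    ``c_{m,n} = phi_hat(omega_m) e^{i omega_m n}``.
    """

    grid: FrequencyGrid
    n0: int
    nf: int
    c0: np.ndarray = field(repr=False)
    mode: str = "exact"

    @property
    def n_values(self) -> np.ndarray:
        return np.arange(self.n0, self.nf + 1)

    @property
    def c(self) -> np.ndarray:
        """Full coefficient matrix, shape ``(P+1, nf-n0+1)``."""
        return self.c0[:, None] * np.exp(1j * np.outer(self.grid.omegas, self.n_values))

    def coeff(self, m: int, n: int) -> complex:
        return complex(self.c0[m] * np.exp(1j * self.grid.omegas[m] * n))

    def reproduce(self, kernel: Kernel, t) -> np.ndarray:
        """Evaluate ``sum_n c_{m,n} phi(t - n)`` for every ``m``; shape ``(P+1, len(t))``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros((self.grid.P + 1, t.size), dtype=complex)
        for n in self.n_values:
            vals = np.asarray(kernel(t - n), dtype=complex)
            out += np.exp(1j * self.grid.omegas * n)[:, None] * vals[None, :]
        return out * self.c0[:, None]

    def interior_interval(self, kernel: Kernel) -> tuple[float, float]:
        """Interval on which the truncated reproduction sum is complete.

        With kernel support ``[s_lo, s_hi)`` and shifts ``n0..nf``, every
        shifted copy overlapping ``t`` is included when
        ``t`` lies in ``[n0 - 1 + s_hi, nf + 1 + s_lo)``.
        """
        s_lo, s_hi = kernel.support
        return (self.n0 - 1 + s_hi, self.nf + 1 + s_lo)


def reproduction_coeffs(
    kernel: Kernel,
    grid: FrequencyGrid,
    n_range: tuple[int, int],
    *,
    tol: float = 1e-9,
    l_max: int = 10,
    check: bool = True,
) -> CoeffTable:
    """Exact reproduction coefficients ``c_{m,0} = 1/phi_hat(omega_m)``.

    Requires the kernel to satisfy the generalised Strang-Fix conditions on
    the grid (checked unless ``check=False``).
    """
    n0, nf = int(n_range[0]), int(n_range[1])
    if nf < n0:
        raise ValueError("empty n_range")
    phat = np.asarray(kernel.fourier(grid.omegas), dtype=complex)
    if np.any(np.abs(phat) <= tol):
        bad = grid.omegas[np.abs(phat) <= tol]
        raise DegenerateKernelError(
            f"|phi_hat| <= {tol} at omega={bad}; cannot invert for exact coefficients"
        )
    if check:
        report = verify_strang_fix(kernel, grid, l_max=l_max, tol=tol)
        if not report.all_pass:
            raise DegenerateKernelError(
                "kernel does not satisfy the generalised Strang-Fix conditions "
                "on this grid; use approx_coeffs for approximate reproduction"
            )
    return CoeffTable(grid=grid, n0=n0, nf=nf, c0=1.0 / phat, mode="exact")


def approx_coeffs(
    kernel: Kernel,
    grid: FrequencyGrid,
    n_range: tuple[int, int],
    *,
    tol: float = 1e-9,
    l_max: int = 10,
) -> CoeffTable:
    """Constant-least-squares approximate-reproduction coefficients.

    For a kernel that satisfies the Strang-Fix conditions only approximately
    (e.g. a Gaussian), the best constant coefficient in the least-squares
    sense is the projection weight

        c_{m,0} = conj(phi_hat(omega_m)) / sum_l |phi_hat(omega_m + 2*pi*l)|^2,

    obtained by minimising the periodised reproduction error over one period
    (the alias sum is truncated at ``|l| <= l_max``).  When the off-grid
    aliases vanish this reduces exactly to the Strang-Fix value
    ``1/phi_hat(omega_m)``; the residual of the reproduction is governed by
    the alias magnitudes.
    """
    n0, nf = int(n_range[0]), int(n_range[1])
    if nf < n0:
        raise ValueError("empty n_range")
    phat = np.asarray(kernel.fourier(grid.omegas), dtype=complex)
    if np.any(np.abs(phat) <= tol):
        raise DegenerateKernelError("kernel transform vanishes at a grid frequency")
    ls = np.arange(-l_max, l_max + 1)
    alias_power = np.array(
        [np.sum(np.abs(kernel.fourier(wm + 2.0 * np.pi * ls)) ** 2) for wm in grid.omegas]
    )
    c0 = np.conj(phat) / alias_power
    return CoeffTable(grid=grid, n0=n0, nf=nf, c0=c0, mode="constant_least_squares")
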