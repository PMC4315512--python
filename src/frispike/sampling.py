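"""Acquisition model: filter with ``h(t) = phi(-t/T)``, sample at ``t = nT``.

Filtering then sampling is equivalent to the inner products
``y_n = <x(t), phi(t/T - n)>``.  For a stream of Diracs the sifting property
collapses the integral to kernel evaluations; for decaying-exponential
streams the inner product is computed by piecewise Gauss-Legendre
quadrature, partitioned at the kernel knots and at the event times where the
integrand has kinks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["SampleSequence", "sample_diracs", "sample_stream", "add_noise"]

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(24)


@dataclass(frozen=True)
class SampleSequence:
    """Uniform samples ``y_n`` with period ``T`` starting at index ``n_start``."""

    values: np.ndarray
    T: float
    n_start: int = 0
    noise_sigma: Optional[float] = None

    def __post_init__(self) -> None:
        v = np.atleast_1d(np.asarray(self.values))
        if not self.T > 0:
            raise ValueError("sampling period T must be positive")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def n_index(self) -> np.ndarray:
        return self.n_start + np.arange(len(self))

    @property
    def times(self) -> np.ndarray:
        return self.n_index * self.T

    def with_values(self, values, noise_sigma=None) -> "SampleSequence":
        return SampleSequence(values=values, T=self.T, n_start=self.n_start,
                              noise_sigma=self.noise_sigma if noise_sigma is None else noise_sigma)


def _dirac_n_range(times: np.ndarray, kernel, T: float) -> tuple[int, int]:
    """Indices of samples a Dirac can influence: ``t/T - s_hi < n <= t/T - s_lo``."""
    s_lo, s_hi = kernel.support
    n_lo = math.floor(np.min(times) / T - s_hi) + 1
    n_hi = math.floor(np.max(times) / T - s_lo)
    return n_lo, n_hi


def sample_diracs(stream, kernel, T: float, n_range: Optional[tuple[int, int]] = None) -> SampleSequence:
    """Samples of a Dirac stream: ``y_n = sum_k a_k phi(t_k/T - n)``.

    ``n_range`` defaults to the minimal index set with any kernel overlap;
    each Dirac influences at most ``ceil(support length)`` consecutive samples.
    """
    if not T > 0:
        raise ValueError("T must be positive")
    if n_range is None:
        n_range = _dirac_n_range(stream.times, kernel, T)
    n0, nf = int(n_range[0]), int(n_range[1])
    n = np.arange(n0, nf + 1)
    y = np.zeros(n.size, dtype=float if getattr(kernel, "is_real", False) else complex)
    for tk, ak in zip(stream.times, stream.amplitudes):
        y = y + ak * kernel(tk / T - n)
    return SampleSequence(values=y, T=T, n_start=n0)


def _integrate_smooth(f, a: float, b: float) -> float:
    mid = 0.5 * (a + b)
    half = 0.5 * (b - a)
    return half * float(np.dot(_GL_WEIGHTS, f(mid + half * _GL_NODES)))


def sample_stream(
    stream,
    kernel,
    T: float,
    n_range: Optional[tuple[int, int]] = None,
    *,
    tail_decades: float = 8.0,
) -> SampleSequence:
    """Samples of a decaying-exponential stream by piecewise quadrature.

    The integrand ``x(t) phi(t/T - n)`` is integrated over the kernel
    support, split at the kernel's internal knots and at event times (kinks
    of ``x``).  The default index range covers every sample with kernel
    overlap, extended along the exponential tail until it has decayed by
    ``e^{-tail_decades}``.
    """
    if not T > 0:
        raise ValueError("T must be positive")
    s_lo, s_hi = kernel.support
    if stream.K == 0:
        n0, nf = (0, 0) if n_range is None else (int(n_range[0]), int(n_range[1]))
        return SampleSequence(values=np.zeros(nf - n0 + 1), T=T, n_start=n0)
    if n_range is None:
        n_lo = math.floor(np.min(stream.times) / T - s_hi) + 1
        tail = math.ceil(tail_decades / (stream.alpha * T))
        n_hi = math.floor(np.max(stream.times) / T - s_lo) + tail
        n_range = (n_lo, n_hi)
    n0, nf = int(n_range[0]), int(n_range[1])
    knots = kernel.knots()
    y = np.zeros(nf - n0 + 1)
    t_first = float(stream.times[0])
    for i, n in enumerate(range(n0, nf + 1)):
        a = max((n + s_lo) * T, t_first)
        b = (n + s_hi) * T
        if b <= a:
            continue
        pts = [a, b]
        pts.extend(k_t for k_t in (knots + n) * T if a < k_t < b)
        pts.extend(tk for tk in stream.times if a < tk < b)
        pts = sorted(set(pts))
        total = 0.0
        f = lambda t, nn=n: stream.evaluate(t) * np.real(kernel(t / T - nn))
        for lo, hi in zip(pts[:-1], pts[1:]):
            if hi - lo < 1e-15:
                continue
            total += _integrate_smooth(f, lo, hi)
        y[i] = total
    return SampleSequence(values=y, T=T, n_start=n0)


def add_noise(samples: SampleSequence, snr_db: float, seed=None) -> SampleSequence:
    """Add white Gaussian noise at the requested SNR (``inf`` = no noise).

    SNR convention: ``10 log10(mean(y^2) / sigma^2)`` over the stored
    samples.  Deterministic under a fixed seed.
    """
    if len(samples) == 0:
        raise ValueError("samples must be nonempty")
    if math.isinf(snr_db):
        return samples.with_values(samples.values.copy(), noise_sigma=0.0)
    power = float(np.mean(np.abs(samples.values) ** 2))
    if power == 0.0:
        raise ValueError("SNR is undefined for an all-zero sequence")
    sigma = math.sqrt(power / 10.0 ** (snr_db / 10.0))
    rng = np.random.default_rng(seed)
    noisy = samples.values + rng.normal(0.0, sigma, size=samples.values.shape)
    return samples.with_values(noisy, noise_sigma=sigma)
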