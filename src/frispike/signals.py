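"""Sparse signal models and synthetic ground-truth generation.

The continuous-time inputs handled by the package are streams of events:
either ideal Diracs ``x(t) = sum_k a_k delta(t - t_k)`` or one-sided
decaying exponentials ``x(t) = sum_k a_k e^{-alpha (t - t_k)} 1_{t >= t_k}``.
Both are finite-rate-of-innovation signals: each event contributes two
degrees of freedom (location and amplitude), so K events over a duration
``tau`` give an innovation rate of ``2 K / tau``.

The decaying-exponential model is the standard description of somatic
calcium fluorescence in two-photon imaging: each action potential at time
``t_k`` produces an instantaneous jump of amplitude ``A`` that relaxes back
with time constant ``tau_ca``, and the recorded trace is this transient
plus white Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .sampling import SampleSequence

__all__ = [
    "DiracStream",
    "ExponentialStream",
    "SpikeTrain",
    "CalciumModel",
    "gen_poisson_spikes",
    "gen_calcium_trace",
]


def _validate_times(times: np.ndarray) -> None:
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("event times must be strictly increasing (and distinct)")


@dataclass(frozen=True)
class DiracStream:
    """Finite stream of weighted Diracs, parameterised by ``{(t_k, a_k)}``."""

    times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.times, dtype=float))
        a = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        if t.shape != a.shape:
            raise ValueError("times and amplitudes must have equal length")
        _validate_times(t)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "amplitudes", a)

    @property
    def K(self) -> int:
        return int(self.times.size)

    def innovation_rate(self, duration: float) -> float:
        """Degrees of freedom per unit time over ``[0, duration)``: ``2K/duration``."""
        return 2.0 * self.K / float(duration)

    def evaluate(self, t):
        raise TypeError("a Dirac stream is distributional and cannot be evaluated pointwise")


@dataclass(frozen=True)
class ExponentialStream:
    """Stream of one-sided decaying exponentials with common decay ``alpha`` (1/s)."""

    times: np.ndarray
    amplitudes: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.times, dtype=float))
        a = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        if t.shape != a.shape:
            raise ValueError("times and amplitudes must have equal length")
        _validate_times(t)
        if not self.alpha > 0:
            raise ValueError("decay exponent alpha must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "amplitudes", a)

    @property
    def K(self) -> int:
        return int(self.times.size)

    def as_diracs(self) -> DiracStream:
        """Innovation part of the stream: the Diracs driving the exponentials."""
        return DiracStream(self.times, self.amplitudes)

    def evaluate(self, t) -> np.ndarray:
        """Pointwise value ``sum_k a_k e^{-alpha (t - t_k)} 1_{t >= t_k}``."""
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        tt = np.atleast_1d(t)
        dt = tt[None, :] - self.times[:, None]
        vals = np.where(dt >= 0.0, np.exp(-self.alpha * np.clip(dt, 0.0, None)), 0.0)
        out = self.amplitudes @ vals
        return float(out[0]) if scalar else out


def evaluate_stream(stream, t):
    """Pointwise evaluation; only defined for exponential streams."""
    return stream.evaluate(t)


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted event times, optionally with amplitudes (e.g. histogram support)."""

    times: np.ndarray
    amplitudes: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.times, dtype=float))
        if t.size > 1 and not np.all(np.diff(t) >= 0):
            raise ValueError("spike times must be sorted ascending")
        object.__setattr__(self, "times", t)
        if self.amplitudes is not None:
            a = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
            if a.shape != t.shape:
                raise ValueError("amplitudes must match times in length")
            object.__setattr__(self, "amplitudes", a)

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class CalciumModel:
    """Calcium transient parameters: jump amplitude ``A`` and decay ``tau_ca``.

    Noise is specified either as an absolute standard deviation
    ``noise_sigma`` or through a target ``snr_db``; the SNR convention is
    ``10 log10(mean(clean^2) / sigma^2)`` over the generated samples.
    """

    A: float = 1.0
    tau_ca: float = 0.5
    noise_sigma: Optional[float] = None
    snr_db: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise ValueError("A must be positive")
        if not self.tau_ca > 0:
            raise ValueError("tau_ca must be positive")

    @property
    def alpha(self) -> float:
        """Decay exponent ``1 / tau_ca``."""
        return 1.0 / self.tau_ca


def gen_poisson_spikes(
    rate: float,
    duration: float,
    refractory: float = 0.0,
    seed=None,
) -> SpikeTrain:
    """Homogeneous Poisson spike train on ``[0, duration)`` with a refractory gap.

    Arrivals are thinned so consecutive kept spikes are at least
    ``refractory`` seconds apart; on a conflict the earlier spike is kept,
    which is deterministic and order-preserving.
    """
    if not rate > 0:
        raise ValueError("rate must be positive")
    if refractory < 0:
        raise ValueError("refractory must be non-negative")
    rng = np.random.default_rng(seed)
    # draw gaps until past the horizon; expected count is rate*duration
    times = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / rate)
        if t >= duration:
            break
        times.append(t)
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= refractory:
            kept.append(t)
    return SpikeTrain(np.asarray(kept, dtype=float))


def gen_calcium_trace(
    spikes: SpikeTrain,
    model: CalciumModel,
    T: float,
    n_samples: int,
    seed=None,
) -> tuple[SampleSequence, np.ndarray]:
    """Instantaneous samples of the calcium transient driven by ``spikes``.

    Returns the (possibly noisy) trace as a :class:`SampleSequence` together
    with the noiseless samples.  The clean samples are
    ``c(nT) = A sum_k e^{-(nT - t_k)/tau_ca} 1_{nT >= t_k}``; the baseline is
    zero (baseline removal is regarded as preprocessing of real data).
    """
    if not T > 0:
        raise ValueError("sampling period T must be positive")
    t_grid = np.arange(int(n_samples)) * T
    if len(spikes) == 0:
        clean = np.zeros(int(n_samples))
    else:
        stream = ExponentialStream(
            spikes.times,
            np.ones_like(spikes.times) if spikes.amplitudes is None else spikes.amplitudes,
            alpha=model.alpha,
        )
        clean = model.A * stream.evaluate(t_grid)
    sigma = model.noise_sigma
    if sigma is None and model.snr_db is not None and math.isfinite(model.snr_db):
        power = float(np.mean(clean**2))
        if power == 0.0:
            raise ValueError("cannot set a finite SNR on an all-zero trace")
        sigma = math.sqrt(power / 10.0 ** (model.snr_db / 10.0))
    if sigma:
        rng = np.random.default_rng(seed)
        values = clean + rng.normal(0.0, sigma, size=clean.shape)
    else:
        values = clean.copy()
        sigma = 0.0
    return SampleSequence(values=values, T=T, n_start=0, noise_sigma=sigma), clean
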