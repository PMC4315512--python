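"""File formats: traces and spike trains as CSV, configs and results as JSON.

Trace CSV carries metadata in ``# key=value`` header lines (at least ``T``,
optionally ``n_start``), followed by either a single ``value`` column or two
``time,value`` columns.  Timestamps must be uniform to within ``1e-6 * T``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TraceFormatError
from .fri_core import ReconstructionResult
from .kernels import CoeffTable, ESplineKernel, GaussianKernel, make_espline, make_gaussian
from .sampling import SampleSequence
from .signals import SpikeTrain
from .streaming import LocationHistogram

__all__ = [
    "read_trace",
    "write_trace",
    "read_spike_train",
    "write_spike_train",
    "write_histogram",
    "write_coeff_table",
    "write_result",
    "kernel_from_spec",
    "kernel_to_spec",
]

_JITTER_TOL = 1e-6


def _parse_header(path: Path) -> tuple[dict, int]:
    meta: dict[str, float] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = float(val.strip())
    return meta, n_header


def read_trace(path) -> SampleSequence:
    """Read a uniformly sampled trace; validates timestamp uniformity."""
    path = Path(path)
    meta, n_header = _parse_header(path)
    df = pd.read_csv(path, skiprows=n_header, float_precision="round_trip")
    cols = [c.strip().lower() for c in df.columns]
    if "value" not in cols:
        raise TraceFormatError(f"{path}: expected a 'value' column, got {list(df.columns)}")
    values = df[df.columns[cols.index("value")]].to_numpy(dtype=float)
    if "time" in cols:
        t = df[df.columns[cols.index("time")]].to_numpy(dtype=float)
        if t.size < 2:
            T = meta.get("T")
            if T is None:
                raise TraceFormatError(f"{path}: cannot infer T from fewer than 2 samples")
        else:
            T = meta.get("T", float(np.median(np.diff(t))))
        if not T or T <= 0:
            raise TraceFormatError(f"{path}: non-positive sampling period")
        expected = t[0] + T * np.arange(t.size)
        bad = np.nonzero(np.abs(t - expected) > _JITTER_TOL * T)[0]
        if bad.size:
            row = int(bad[0]) + n_header + 2  # 1-based, after header and column line
            raise TraceFormatError(
                f"{path}: non-uniform timestamp at data row {row} "
                f"(t={t[bad[0]]}, expected {expected[bad[0]]})"
            )
        n_start = int(round(t[0] / T))
        if abs(t[0] - n_start * T) > _JITTER_TOL * T:
            raise TraceFormatError(f"{path}: first timestamp is not a multiple of T")
    else:
        if "T" not in meta:
            raise TraceFormatError(f"{path}: value-only trace needs '# T=...' in the header")
        T = meta["T"]
        n_start = int(meta.get("n_start", 0))
    sigma = meta.get("noise_sigma")
    return SampleSequence(values=values, T=float(T), n_start=n_start, noise_sigma=sigma)


def write_trace(samples: SampleSequence, path, *, with_time: bool = True) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# T={samples.T!r}\n")
        fh.write(f"# n_start={samples.n_start}\n")
        if samples.noise_sigma is not None:
            fh.write(f"# noise_sigma={samples.noise_sigma!r}\n")
        if with_time:
            fh.write("time,value\n")
            for t, v in zip(samples.times, samples.values):
                fh.write(f"{float(t)!r},{float(v)!r}\n")
        else:
            fh.write("value\n")
            for v in samples.values:
                fh.write(f"{float(v)!r}\n")


def read_spike_train(path) -> SpikeTrain:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    times = df["time"].to_numpy(dtype=float)
    amps = df["amplitude"].to_numpy(dtype=float) if "amplitude" in df.columns else None
    return SpikeTrain(times, amps)


def write_spike_train(spikes: SpikeTrain, path) -> None:
    amps = spikes.amplitudes if spikes.amplitudes is not None else np.ones_like(spikes.times)
    with open(path, "w") as fh:
        fh.write("time,amplitude\n")
        for t, a in zip(spikes.times, amps):
            fh.write(f"{float(t)!r},{float(a)!r}\n")


def write_histogram(hist: LocationHistogram, path) -> None:
    with open(path, "w") as fh:
        fh.write("bin_center,count\n")
        for c, n in zip(hist.centers, hist.counts):
            fh.write(f"{float(c)!r},{int(n)}\n")


def write_coeff_table(table: CoeffTable, path) -> None:
    """Coefficients as CSV with columns m, n, re, im."""
    c = table.c
    with open(path, "w") as fh:
        fh.write("m,n,re,im\n")
        for m in range(table.grid.P + 1):
            for j, n in enumerate(table.n_values):
                fh.write(f"{m},{n},{float(c[m, j].real)!r},{float(c[m, j].imag)!r}\n")


def write_result(result: ReconstructionResult, path) -> None:
    payload = {
        "events": [{"t": t, "a": a} for t, a in result.events],
        "K": result.K,
        "residual": result.residual,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def kernel_from_spec(spec: dict):
    """Kernel from ``{"family": "espline", "alphas": [[re, im], ...]}`` or
    ``{"family": "gaussian", "sigma": s}``."""
    family = spec.get("family")
    if family == "espline":
        alphas = [complex(re, im) for re, im in spec["alphas"]]
        return make_espline(alphas)
    if family == "gaussian":
        return make_gaussian(float(spec["sigma"]))
    raise ValueError(f"unknown kernel family {family!r}")


def kernel_to_spec(kernel) -> dict:
    if isinstance(kernel, ESplineKernel):
        return {
            "family": "espline",
            "alphas": [[a.real, a.imag] for a in kernel.alphas],
        }
    if isinstance(kernel, GaussianKernel):
        return {"family": "gaussian", "sigma": kernel.sigma}
    raise TypeError(f"cannot serialise kernel of type {type(kernel).__name__}")
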