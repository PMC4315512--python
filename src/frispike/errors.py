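"""Package-specific exceptions."""

from __future__ import annotations

import numpy as np


class FriError(Exception):
    """Base class for errors raised by this package."""


class DegenerateKernelError(FriError):
    """Kernel transform (near-)vanishes where it must be inverted."""


class InsufficientMomentsError(FriError):
    """Too few moments for the requested model order (need P+1 >= 2K)."""


class AnnihilatorNormalizationError(FriError):
    """Total-least-squares annihilator cannot be normalised by its first element.

    The raw (unit-norm) singular vector is attached so callers can fall back
    to another solver.
    """

    def __init__(self, message: str, h_raw: "np.ndarray"):
        super().__init__(message)
        self.h_raw = h_raw


class DegeneratePencilError(FriError):
    """Matrix pencil has fewer well-conditioned eigenvalues than requested."""


class TraceFormatError(FriError):
    """Input trace file violates the expected uniform-sampling CSV format."""
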