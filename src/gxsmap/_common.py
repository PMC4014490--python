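"""Shared helpers and exception types."""

from __future__ import annotations

import numpy as np


class ParameterError(ValueError):
    """An argument is outside its documented domain."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but carries no usable signal (e.g. constant)."""


class CovariateError(ValueError):
    """Covariate design problem; carries the offending column labels."""

    def __init__(self, message: str, columns=()):
        super().__init__(message)
        self.columns = list(columns)


class MatrixError(ValueError):
    """A matrix argument violates a structural requirement (symmetry, PSD-ness)."""


class SchemaError(ValueError):
    """Inputs that should align (ids, shapes, chromosome naming) do not."""


def standardize(y: np.ndarray) -> np.ndarray:
    """Return ``y`` centred to mean 0 and scaled to variance 1 (ddof=0)."""
    y = np.asarray(y, dtype=float)
    s = y.std()
    if s == 0 or not np.isfinite(s):
        raise DegenerateInputError("cannot standardize a constant or non-finite vector")
    return (y - y.mean()) / s


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]
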