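"""Positive-signal containers and affine preprocessing.

The Lehmer transform is defined on strictly positive samples, while raw
EEG traces (mV) routinely cross zero.  Every pipeline therefore starts by
mapping the raw trace onto a positive target range with an invertible
affine map whose parameters are kept so the original scale can be
restored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DomainError",
    "PositiveSignal",
    "AffinePreprocess",
    "preprocess_to_positive",
]


class DomainError(ValueError):
    """Input lies outside the domain of an operation."""


def as_positive_values(x) -> np.ndarray:
    """Coerce ``x`` to a 1-d float array of strictly positive values.

    Raises
    ------
    DomainError
        If the array is empty, contains non-finite entries, or contains a
        non-positive element (the message names the offending index).
    """
    if isinstance(x, PositiveSignal):
        return x.values
    v = np.asarray(x, dtype=float).ravel()
    if v.size == 0:
        raise DomainError("signal is empty")
    if not np.all(np.isfinite(v)):
        idx = int(np.flatnonzero(~np.isfinite(v))[0])
        raise DomainError(f"signal contains a non-finite value at index {idx}")
    if np.any(v <= 0):
        idx = int(np.flatnonzero(v <= 0)[0])
        raise DomainError(
            f"signal must be strictly positive; element at index {idx} is {v[idx]!r}"
        )
    return v


@dataclass(frozen=True)
class PositiveSignal:
    """An ordered sample of strictly positive reals.

    This is the domain of the Lehmer transform.  Construction validates
    positivity; ``n`` is the sample count.
    """

    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", as_positive_values(np.asarray(self.values)))

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def n_distinct(self) -> int:
        return np.unique(self.values).size

    def __len__(self) -> int:
        return self.n

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


@dataclass(frozen=True)
class AffinePreprocess:
    """Invertible affine map ``y = scale * x + offset`` used to force positivity.

    ``scale`` is strictly positive so sample ordering is preserved.
    """

    offset: float
    scale: float
    target_min: float
    target_max: float

    def __post_init__(self):
        if not (self.scale > 0):
            raise ValueError("scale must be strictly positive")
        if not (0 < self.target_min < self.target_max):
            raise ValueError("require 0 < target_min < target_max")

    def apply(self, raw) -> np.ndarray:
        return self.scale * np.asarray(raw, dtype=float) + self.offset

    def invert(self, positive) -> np.ndarray:
        return (np.asarray(positive, dtype=float) - self.offset) / self.scale


def preprocess_to_positive(
    raw, target_min: float = 1.0, target_max: float = 2.0
) -> tuple[PositiveSignal, AffinePreprocess]:
    """Affinely map a raw trace onto ``[target_min, target_max]``.

    The raw minimum maps exactly to ``target_min`` and the raw maximum to
    ``target_max``; the returned :class:`AffinePreprocess` inverts the map.

    Raises
    ------
    DomainError
        If the raw input has fewer than two distinct values (the map would
        be degenerate).
    """
    if not (0 < target_min < target_max):
        raise ValueError("require 0 < target_min < target_max")
    r = np.asarray(raw, dtype=float).ravel()
    if r.size < 2 or not np.all(np.isfinite(r)):
        raise DomainError("raw signal must contain at least two finite values")
    lo, hi = float(r.min()), float(r.max())
    if lo == hi:
        raise DomainError("raw signal is constant; affine positivization is degenerate")
    scale = (target_max - target_min) / (hi - lo)
    offset = target_min - scale * lo
    pre = AffinePreprocess(offset=offset, scale=scale, target_min=target_min, target_max=target_max)
    return PositiveSignal(pre.apply(r)), pre
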