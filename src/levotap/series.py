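"""Sampled time series: the common container for concentrations and tapping rates.

A :class:`SampledSeries` holds a strictly increasing time grid (minutes
post-dose) and the values sampled on it.  The same container is used for
plasma concentration (mg/l), effect-site concentration (mg/l), dopaminergic
input (dimensionless) and tapping frequency (taps/min); units live in the
surrounding code, not in the object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

__all__ = ["SampledSeries"]


@dataclass(frozen=True)
class SampledSeries:
    """An irregularly sampled signal ``(times, values)``.

    Parameters
    ----------
    times
        Sampling instants in minutes, strictly increasing.
    values
        Sample values, same length as ``times``, all finite.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1:
            raise InputError("times and values must be one-dimensional")
        if t.size != v.size:
            raise InputError(
                f"length mismatch: {t.size} times vs {v.size} values"
            )
        if t.size == 0:
            raise InputError("empty series")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(v)):
            raise InputError("times and values must be finite")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise InputError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.times.size)

    def interp(self, at: np.ndarray, left: float | None = None,
               right: float | None = None) -> np.ndarray:
        """Linear interpolation of the series at arbitrary times."""
        return np.interp(np.asarray(at, dtype=float), self.times, self.values,
                         left=left, right=right)

    def with_values(self, values: np.ndarray) -> "SampledSeries":
        """A new series on the same time grid with different values."""
        return SampledSeries(self.times, np.asarray(values, dtype=float))
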