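"""Ordered (time, value) sample series — the universal exchange type.

Concentrations, fractions dissolved/absorbed and plasma curves all travel
through the package as :class:`TimeSeries`. Times must be strictly
increasing; units are carried as metadata and converted explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError

_TIME_UNIT_MINUTES = {"min": 1.0, "h": 60.0}


@dataclass(frozen=True)
class TimeSeries:
    """A strictly time-ordered series of scalar samples.

    Parameters
    ----------
    time : array-like
        Sample times, strictly increasing.
    value : array-like
        Sample values, same length as ``time``.
    time_unit : {"min", "h"}
        Unit of the time axis.
    value_unit : str
        Free-form unit label for the values (e.g. ``"ug/mL"``).
    label : str
        Optional series label (group, phase, ...).
    """

    time: np.ndarray
    value: np.ndarray
    time_unit: str = "min"
    value_unit: str = ""
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.value, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValidationError("time and value must be 1-D arrays of equal length")
        if t.size == 0:
            raise ValidationError("empty series")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValidationError("times must be strictly increasing")
        if not np.all(np.isfinite(t)):
            raise ValidationError("non-finite times")
        if self.time_unit not in _TIME_UNIT_MINUTES:
            raise ValidationError(f"unsupported time unit {self.time_unit!r}")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "value", v)
        self.time.setflags(write=False)
        self.value.setflags(write=False)

    def __len__(self) -> int:
        return self.time.size

    def with_values(self, value) -> "TimeSeries":
        return replace(self, value=np.asarray(value, dtype=float))

    def to_unit(self, unit: str) -> "TimeSeries":
        """Return the series with the time axis converted to ``unit``."""
        if unit == self.time_unit:
            return self
        factor = _TIME_UNIT_MINUTES[self.time_unit] / _TIME_UNIT_MINUTES[unit]
        return replace(self, time=self.time * factor, time_unit=unit)

    def interp(self, t) -> np.ndarray:
        """Linear interpolation; errors outside the observed range."""
        t = np.asarray(t, dtype=float)
        if np.any(t < self.time[0] - 1e-12) or np.any(t > self.time[-1] + 1e-12):
            raise ValidationError(
                f"interpolation target outside observed range "
                f"[{self.time[0]}, {self.time[-1]}] {self.time_unit}"
            )
        return np.interp(t, self.time, self.value)
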