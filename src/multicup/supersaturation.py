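"""Degree-of-supersaturation (DS) metrics.

DS is the ratio of the apparent dissolved concentration to the equilibrium
solubility at the prevailing pH; its peak quantifies the intensity and its
time integral the endurance of a supersaturated state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ValidationError
from .solubility import PHSolubilityFit, eval_solubility
from .timeseries import TimeSeries


@dataclass(frozen=True)
class DSMetrics:
    DS_max: float
    DS_auc: float        # dimensionless * h
    t_at_DSmax: float    # in the unit of the input series

    def __post_init__(self):
        if self.DS_max < 0 or self.DS_auc < 0:
            raise ValidationError("DS metrics must be non-negative")


def degree_of_supersaturation(C, Cs):
    """C / Cs; requires Cs > 0 and C >= 0."""
    c_arr = np.asarray(C, dtype=float)
    cs_arr = np.asarray(Cs, dtype=float)
    if np.any(cs_arr <= 0):
        raise DomainError("equilibrium solubility must be > 0")
    if np.any(c_arr < 0):
        raise DomainError("concentration must be >= 0")
    out = c_arr / cs_arr
    return float(out) if np.ndim(C) == 0 and np.ndim(Cs) == 0 else out


def ds_profile(conc: TimeSeries, pH: TimeSeries, fit: PHSolubilityFit) -> TimeSeries:
    """Pointwise DS on the concentration grid; pH interpolated if needed."""
    if pH.time_unit != conc.time_unit:
        pH = pH.to_unit(conc.time_unit)
    ph_on_grid = pH.interp(conc.time)
    cs = eval_solubility(fit, ph_on_grid)
    return TimeSeries(
        conc.time,
        degree_of_supersaturation(conc.value, cs),
        time_unit=conc.time_unit,
        value_unit="",
        label=conc.label,
    )


def ds_metrics(ds: TimeSeries) -> DSMetrics:
    """Peak (earliest on ties) and trapezoid time-integral of a DS curve.

    The integral is reported in dimensionless-hours regardless of the input
    time unit.
    """
    i = int(np.argmax(ds.value))  # argmax returns the first maximum
    t_h = ds.to_unit("h").time
    auc = float(np.trapezoid(ds.value, t_h))
    return DSMetrics(
        DS_max=float(ds.value[i]),
        DS_auc=auc,
        t_at_DSmax=float(ds.time[i]),
    )
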