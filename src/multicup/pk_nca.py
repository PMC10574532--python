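"""Non-compartmental analysis of plasma profiles.

AUC is computed by the linear trapezoidal rule up to the last measurable
point only — no terminal-slope extrapolation to infinity.  At this boundary
time is in hours and concentration in ng/mL; upstream minute-based series
must be converted explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DomainError, InsufficientDataError
from .timeseries import TimeSeries


@dataclass(frozen=True)
class NCAResult:
    Cmax: float           # ng/mL
    Tmax: float           # h
    AUC_last: float       # h*ng/mL
    F_abs_percent: Optional[float] = None


def auc_linear_trapezoid(ts: TimeSeries) -> float:
    """Linear-trapezoid AUC over the observed window."""
    if len(ts) < 2:
        raise InsufficientDataError("AUC needs >= 2 points")
    return float(np.trapezoid(ts.value, ts.time))


def cmax_tmax(ts: TimeSeries):
    """Maximum value and its earliest time."""
    i = int(np.argmax(ts.value))
    return float(ts.value[i]), float(ts.time[i])


def absolute_bioavailability(auc_po, dose_po, auc_iv, dose_iv) -> float:
    """100 * (AUC_po / dose_po) / (AUC_iv / dose_iv)."""
    for name, val in (
        ("auc_po", auc_po),
        ("dose_po", dose_po),
        ("auc_iv", auc_iv),
        ("dose_iv", dose_iv),
    ):
        if not (val > 0):
            raise DomainError(f"{name} must be > 0, got {val}")
    return 100.0 * (auc_po / dose_po) / (auc_iv / dose_iv)


def nca(
    ts: TimeSeries,
    dose: Optional[float] = None,
    iv_reference: Optional[TimeSeries] = None,
    dose_iv: Optional[float] = None,
) -> NCAResult:
    """Cmax/Tmax/AUC_last, plus absolute bioavailability when an i.v.
    reference profile and both doses are supplied."""
    ts_h = ts.to_unit("h")
    cmax, tmax = cmax_tmax(ts_h)
    auc = auc_linear_trapezoid(ts_h)
    f_pct = None
    if iv_reference is not None:
        if dose is None or dose_iv is None:
            raise DomainError("bioavailability needs both doses")
        auc_iv = auc_linear_trapezoid(iv_reference.to_unit("h"))
        f_pct = absolute_bioavailability(auc, dose, auc_iv, dose_iv)
    return NCAResult(Cmax=cmax, Tmax=tmax, AUC_last=auc, F_abs_percent=f_pct)
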