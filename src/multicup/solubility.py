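"""pH-dependent equilibrium solubility of a weakly basic drug.

The solubility of a monobasic drug rises steeply below its pKa because the
ionized fraction grows as 10^(pKa - pH).  The model used throughout is

    Cs(pH) = C_U * (1 + 10**(pKa - pH))

where ``C_U`` is the intrinsic (unionized-form) solubility.  Fitting is by
least squares on log-solubility, which equalizes weights across the two or
more orders of magnitude the data typically span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import DomainError, FitError, InsufficientDataError, ValidationError

#: pH values measured in strongly acidic buffers are prone to assay bias for
#: very soluble ionized species; callers may exclude them via this preset.
BIASED_ACIDIC_PH_PRESET = (2.4, 3.2)

_DEFAULT_PKA_BOUNDS = (2.0, 10.0)
# 10**x overflows float64 near x = 308; refuse well before that.
_MAX_EXPONENT = 300.0


@dataclass(frozen=True)
class SolubilityPoint:
    """A single measured (pH, solubility) pair, solubility in ug/mL."""

    pH: float
    solubility: float

    def __post_init__(self):
        if not (0.0 < self.pH < 14.0):
            raise ValidationError(f"pH {self.pH} outside (0, 14)")
        if not (self.solubility > 0.0):
            raise ValidationError(f"solubility must be > 0, got {self.solubility}")


@dataclass(frozen=True)
class PHSolubilityFit:
    """Fitted (C_U, pKa) pair; evaluates equilibrium solubility at any pH."""

    C_U: float
    pKa: float
    pKa_bounds: tuple = _DEFAULT_PKA_BOUNDS

    def __post_init__(self):
        if not (self.C_U > 0.0):
            raise ValidationError(f"C_U must be > 0, got {self.C_U}")
        lo, hi = self.pKa_bounds
        if not (lo <= self.pKa <= hi):
            raise ValidationError(f"pKa {self.pKa} outside bounds {self.pKa_bounds}")

    def __call__(self, pH):
        return eval_solubility(self, pH)


@dataclass(frozen=True)
class SolubilityFitDiagnostics:
    rss: float
    residuals: np.ndarray          # on log scale, model - data
    pH_used: np.ndarray
    n_excluded: int
    pKa_at_bound: bool
    message: str = ""


def eval_solubility(fit: PHSolubilityFit, pH):
    """Equilibrium solubility (ug/mL) at ``pH``.

    Strictly decreasing in pH; approaches ``C_U`` as pH -> infinity.
    Raises :class:`DomainError` on out-of-range pH or float overflow.
    """
    pH_arr = np.asarray(pH, dtype=float)
    if np.any(pH_arr <= 0.0) or np.any(pH_arr >= 14.0):
        bad = pH_arr[(pH_arr <= 0.0) | (pH_arr >= 14.0)]
        raise DomainError(f"pH outside (0, 14): {np.atleast_1d(bad)[0]}")
    expo = fit.pKa - pH_arr
    if np.any(expo > _MAX_EXPONENT):
        bad = pH_arr[expo > _MAX_EXPONENT]
        raise DomainError(
            f"ionized term overflows at pH {np.atleast_1d(bad)[0]} (pKa - pH too large)"
        )
    out = fit.C_U * (1.0 + 10.0 ** expo)
    if np.isscalar(pH) or pH_arr.ndim == 0:
        return float(out)
    return out


def _log_residuals(theta, pH, log_s):
    log_cu, pka = theta
    # log10 Cs = log10 C_U + log10(1 + 10**(pKa - pH))
    return log_cu + np.log10(1.0 + 10.0 ** (pka - pH)) - log_s


def fit_ph_solubility(
    points: Iterable[SolubilityPoint],
    exclude_pH: Sequence[float] = (),
    pH_tolerance: float = 0.05,
    pKa_bounds: tuple = _DEFAULT_PKA_BOUNDS,
):
    """Least-squares fit of (C_U, pKa) on log-solubility.

    Parameters
    ----------
    points : iterable of SolubilityPoint
    exclude_pH : sequence of float
        pH values to drop, matched within ``pH_tolerance``.  Use
        :data:`BIASED_ACIDIC_PH_PRESET` for the documented acidic preset.
    pKa_bounds : (low, high)
        Box constraint on pKa.

    Returns
    -------
    (PHSolubilityFit, SolubilityFitDiagnostics)
    """
    pts = list(points)
    n_before = len(pts)
    if exclude_pH:
        excl = np.asarray(list(exclude_pH), dtype=float)
        pts = [p for p in pts if np.min(np.abs(excl - p.pH)) > pH_tolerance]
    n_excluded = n_before - len(pts)
    if len(pts) < 3:
        raise InsufficientDataError(
            f"need >= 3 points after exclusion, have {len(pts)}"
        )

    pH = np.array([p.pH for p in pts])
    sol = np.array([p.solubility for p in pts])
    log_s = np.log10(sol)

    x0 = np.array([np.log10(sol.min()), float(np.median(pH))])
    lo, hi = pKa_bounds
    x0[1] = np.clip(x0[1], lo, hi)
    res = least_squares(
        _log_residuals,
        x0,
        bounds=([-np.inf, lo], [np.inf, hi]),
        args=(pH, log_s),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not res.success:
        raise FitError(
            f"pH-solubility fit did not converge: {res.message}",
            last_iterate={"log10_C_U": res.x[0], "pKa": res.x[1]},
        )
    c_u = 10.0 ** res.x[0]
    pka = float(res.x[1])
    at_bound = bool(abs(pka - lo) < 1e-9 or abs(pka - hi) < 1e-9)
    diag = SolubilityFitDiagnostics(
        rss=float(np.sum(res.fun ** 2)),
        residuals=res.fun.copy(),
        pH_used=pH,
        n_excluded=n_excluded,
        pKa_at_bound=at_bound,
        message="pKa at bound; data may lack pH dependence" if at_bound else "ok",
    )
    return PHSolubilityFit(C_U=float(c_u), pKa=pka, pKa_bounds=tuple(pKa_bounds)), diag
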