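"""Level-A in vitro - in vivo correlation engine.

Chain: fit a polyexponential unit impulse response (UIR, <= 3 terms) to
dose-normalized i.v. plasma data; deconvolve oral plasma curves into
absorbed-fraction profiles with a non-negative staircase input-rate least
squares; fit the correlation

    Fabs(t) = AbsScale * Diss(Tscale * t - Tshift)

pooled across training groups against closed-form Weibull dissolution
curves; predict plasma by exact convolution of the predicted input with the
UIR; and score prediction errors against the regulatory qualification
limits (mean |PE| <= 10 %, individual |PE| <= 15 %).

Time at this boundary is in hours; fraction-dissolved models fitted on
minutes must be rescaled via ``DoubleWeibullParams.with_time_scale(1/60)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares, nnls

from .dissolution_models import DoubleWeibullParams, aic_least_squares, eval_double_weibull
from .errors import DomainError, FitError, InsufficientDataError, ValidationError
from .kernels import convolve_pwl_cumulative, polyexp, response_matrix
from .timeseries import TimeSeries

QUALIFICATION_MEAN_LIMIT = 10.0
QUALIFICATION_INDIVIDUAL_LIMIT = 15.0


@dataclass(frozen=True)
class UIRParams:
    """Dose-normalized i.v. kernel: sum of (A_i, lambda_i) exponentials."""

    terms: Tuple[Tuple[float, float], ...]

    def __post_init__(self):
        if not (1 <= len(self.terms) <= 3):
            raise ValidationError("UIR needs 1-3 exponential terms")
        for _, lam in self.terms:
            if lam <= 0:
                raise ValidationError("lambda_i must be > 0")

    def __call__(self, t):
        return polyexp(self.terms, t)


@dataclass(frozen=True)
class IVIVCParams:
    AbsScale: float
    Tscale: float
    Tshift: float = 0.0   # hours

    def __post_init__(self):
        if self.AbsScale <= 0 or self.Tscale <= 0:
            raise ValidationError("AbsScale and Tscale must be > 0")


@dataclass(frozen=True)
class GroupPE:
    group: str
    observed_cmax: float
    predicted_cmax: float
    pe_cmax: float
    observed_auc: float
    predicted_auc: float
    pe_auc: float
    external: bool = False


@dataclass(frozen=True)
class PEReport:
    groups: Tuple[GroupPE, ...]
    mean_abs_pe_cmax: float
    mean_abs_pe_auc: float


# ---------------------------------------------------------------------------
# UIR fitting
# ---------------------------------------------------------------------------

def _fit_polyexp_order(t, c, w, n_terms, n_starts, rng):
    """Weighted LS fit of n_terms exponentials; rates via log transform."""
    span = t[-1] - t[0] if t[-1] > t[0] else 1.0
    lam_guess = np.log(np.geomspace(0.5 / span, 20.0 / span, n_terms))
    amp_guess = np.full(n_terms, max(c.max(), 1e-12) / n_terms)
    n = n_terms

    def resid(theta):
        model = (theta[:n][None, :]
                 * np.exp(-np.exp(theta[n:])[None, :] * t[:, None])).sum(axis=1)
        return w * (model - c)

    def jac(theta):
        lam = np.exp(theta[n:])
        e = np.exp(-lam[None, :] * t[:, None])
        out = np.empty((t.size, 2 * n))
        out[:, :n] = e
        out[:, n:] = -theta[:n][None, :] * t[:, None] * lam[None, :] * e
        return w[:, None] * out

    lo = np.concatenate((np.full(n, -np.inf), np.full(n, -12.0)))
    hi = np.concatenate((np.full(n, np.inf), np.full(n, 12.0)))
    best = None
    for i in range(n_starts):
        if i == 0:
            x0 = np.concatenate((amp_guess, lam_guess))
        else:
            x0 = np.concatenate((
                amp_guess * rng.lognormal(0, 0.5, n),
                lam_guess + rng.normal(0, 0.7, n),
            ))
        try:
            res = least_squares(
                resid, np.clip(x0, lo, hi), jac=jac, bounds=(lo, hi),
                xtol=1e-11, ftol=1e-11, gtol=1e-11, max_nfev=150,
            )
        except Exception:
            continue
        rss = float(np.sum(res.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, res.x)
    return best


def fit_uir(
    iv_plasma: TimeSeries,
    dose_iv: float,
    max_terms: int = 3,
    n_starts: int = 10,
    seed: int = 0,
    weighting: str = "relative",
) -> Tuple[UIRParams, dict]:
    """Fit the dose-normalized i.v. kernel; model order chosen by AIC.

    ``weighting="relative"`` (default) minimizes relative residuals, the
    right scale for multiplicative assay error; ``"none"`` uses absolute
    residuals.  Returns (UIRParams, diagnostics with per-order AIC).
    """
    if dose_iv <= 0:
        raise DomainError("dose_iv must be > 0")
    ts = iv_plasma.to_unit("h")
    t, c = ts.time, ts.value / dose_iv
    if weighting == "relative":
        w = 1.0 / np.maximum(np.abs(c), 1e-12 * max(np.max(np.abs(c)), 1e-300))
    elif weighting == "none":
        w = np.ones_like(c)
    else:
        raise DomainError(f"unknown weighting {weighting!r}")
    rng = np.random.default_rng(seed)
    # floor RSS at numerical-noise scale so exact fits of different orders
    # tie and parsimony decides; small-sample corrected AIC for the order
    rss_floor = t.size * (1e-8 * max(np.max(np.abs(w * c)), 1e-300)) ** 2
    candidates = {}
    for n_terms in range(1, max_terms + 1):
        k = 2 * n_terms
        if len(ts) < 2 * k or t.size - k - 1 <= 0:
            continue
        best = _fit_polyexp_order(t, c, w, n_terms, n_starts, rng)
        if best is not None:
            rss, x = best
            aicc = (aic_least_squares(t.size, max(rss, rss_floor), k)
                    + 2 * k * (k + 1) / (t.size - k - 1))
            candidates[n_terms] = (aicc, rss, x)
    if not candidates:
        raise FitError("no polyexponential order converged")
    order = min(candidates, key=lambda n: candidates[n][0])
    _, rss, x = candidates[order]
    terms = tuple(
        sorted(
            ((float(a), float(np.exp(l))) for a, l in zip(x[:order], x[order:])),
            key=lambda al: -al[1],
        )
    )
    diagnostics = {
        "order": order,
        "rss": rss,
        "aic_by_order": {n: v[0] for n, v in candidates.items()},
    }
    return UIRParams(terms=terms), diagnostics


# ---------------------------------------------------------------------------
# deconvolution
# ---------------------------------------------------------------------------

def deconvolve(
    oral_plasma: TimeSeries,
    uir: UIRParams,
    dose_oral: float,
    ridge: float = 0.0,
) -> TimeSeries:
    """Absorbed fraction vs time by staircase-input least squares.

    A non-negative constant input rate is estimated on each observation
    interval so that its convolution with the UIR matches the oral curve in
    least squares; Fabs is the cumulative input divided by ``dose_oral``.
    """
    if dose_oral <= 0:
        raise DomainError("dose_oral must be > 0")
    ts = oral_plasma.to_unit("h")
    t, c = ts.time, ts.value
    if t[0] < 0:
        raise DomainError("oral plasma times must be >= 0")
    if t[0] == 0:
        # a zero-time sample constrains nothing; drop its zero row
        t, c = t[1:], c[1:]
    m, edges = response_matrix(t, uir.terms)
    cond = np.linalg.cond(m)
    if cond > 1e12:
        raise FitError(
            f"deconvolution system ill-conditioned (cond={cond:.2e}); "
            "coarsen the grid or use ridge regularization"
        )
    if ridge > 0:
        m_aug = np.vstack((m, np.sqrt(ridge) * np.eye(m.shape[1])))
        c_aug = np.concatenate((c, np.zeros(m.shape[1])))
        rates, _ = nnls(m_aug, c_aug)
    else:
        rates, _ = nnls(m, c)
    amounts = rates * np.diff(edges)
    fabs_at_edges = np.concatenate(([0.0], np.cumsum(amounts))) / dose_oral
    # report on the edge grid (0 plus observation times): Fabs(0) = 0
    return TimeSeries(edges, fabs_at_edges, time_unit="h",
                      value_unit="fraction", label=f"Fabs:{oral_plasma.label}")


# ---------------------------------------------------------------------------
# correlation model
# ---------------------------------------------------------------------------

def predict_fabs(
    p: IVIVCParams,
    diss: DoubleWeibullParams,
    t_grid: Sequence[float],
) -> TimeSeries:
    """AbsScale * Diss(Tscale * t - Tshift) on ``t_grid`` (hours); negative
    transformed times evaluate to 0."""
    t = np.asarray(t_grid, dtype=float)
    tau = p.Tscale * t - p.Tshift
    vals = np.where(tau > 0, eval_double_weibull(diss, np.maximum(tau, 0.0)), 0.0)
    return TimeSeries(t, p.AbsScale * vals, time_unit="h",
                      value_unit="fraction", label="Fabs_pred")


def fit_correlation(
    fabs_list: Sequence[TimeSeries],
    diss_list: Sequence[DoubleWeibullParams],
    x0: Tuple[float, float, float] = (1.0, 1.0, 0.0),
    allow_negative_tshift: bool = True,
) -> Tuple[IVIVCParams, dict]:
    """Pooled least-squares fit of (AbsScale, Tscale, Tshift).

    Each training group contributes residuals Fabs_obs(t) - AbsScale *
    Diss_g(Tscale * t - Tshift) at its own observation times; the
    dissolution models are evaluated in closed form (hour time base).
    """
    if len(fabs_list) < 1 or len(fabs_list) != len(diss_list):
        raise InsufficientDataError("need >= 1 training group with matching models")
    data = [(f.to_unit("h").time, f.to_unit("h").value, d)
            for f, d in zip(fabs_list, diss_list)]

    def residuals(theta):
        absc, tsc, tsh = np.exp(theta[0]), np.exp(theta[1]), theta[2]
        out = []
        for t, v, d in data:
            tau = tsc * t - tsh
            pred = np.where(tau > 0, eval_double_weibull(d, np.maximum(tau, 0.0)), 0.0)
            out.append(absc * pred - v)
        return np.concatenate(out)

    tsh_lo = -np.inf if allow_negative_tshift else 0.0
    theta0 = np.array([np.log(x0[0]), np.log(x0[1]), x0[2]])
    res = least_squares(
        residuals, theta0,
        bounds=([-10.0, -10.0, tsh_lo], [10.0, 10.0, np.inf]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not res.success:
        raise FitError(f"correlation fit failed: {res.message}",
                       last_iterate=res.x)
    rss = float(np.sum(res.fun ** 2))
    n = sum(len(t) for t, _, _ in data)
    params = IVIVCParams(
        AbsScale=float(np.exp(res.x[0])),
        Tscale=float(np.exp(res.x[1])),
        Tshift=float(res.x[2]),
    )
    return params, {"rss": rss, "n_obs": n, "aic": aic_least_squares(n, rss, 3)}


# ---------------------------------------------------------------------------
# forward convolution and prediction errors
# ---------------------------------------------------------------------------

def convolve_predict_plasma(
    fabs_pred: TimeSeries,
    uir: UIRParams,
    dose_oral: float,
    F_ref: float = 1.0,
    t_eval: Optional[Sequence[float]] = None,
) -> TimeSeries:
    """Plasma from a predicted absorbed-fraction profile.

    The input rate is the derivative of ``F_ref * dose_oral * Fabs``,
    piecewise constant between Fabs samples; its convolution with the
    exponential kernel is evaluated in closed form per segment.
    """
    ts = fabs_pred.to_unit("h")
    if np.any(np.diff(ts.value) < -1e-9):
        raise ValidationError("predicted Fabs must be non-decreasing")
    times, vals = ts.time, ts.value
    if times[0] > 0:
        times = np.concatenate(([0.0], times))
        vals = np.concatenate(([0.0], vals))
    if t_eval is None:
        t_eval = times
    t = np.asarray(t_eval, dtype=float)
    conc = convolve_pwl_cumulative(times, vals, uir.terms, t,
                                   scale=F_ref * dose_oral)
    return TimeSeries(t, np.atleast_1d(conc), time_unit="h",
                      value_unit="ng/mL", label="plasma_pred")


def prediction_error(observed: float, predicted: float,
                     convention: str = "pred-obs") -> float:
    """Signed percent prediction error.

    Default convention is 100*(predicted - observed)/observed; pass
    ``convention="obs-pred"`` for the opposite sign.
    """
    if observed <= 0:
        raise DomainError("observed must be > 0")
    pe = 100.0 * (predicted - observed) / observed
    if convention == "obs-pred":
        return -pe
    if convention != "pred-obs":
        raise DomainError(f"unknown convention {convention!r}")
    return pe


def mean_absolute_pe(pe_list: Iterable[float]) -> float:
    """Arithmetic mean of |PE| values."""
    pes = list(pe_list)
    if not pes:
        raise InsufficientDataError("empty PE list")
    return float(np.mean(np.abs(pes)))


def pe_report(
    observed: Dict[str, Tuple[float, float]],
    predicted: Dict[str, Tuple[float, float]],
    external_groups: Sequence[str] = (),
    convention: str = "pred-obs",
) -> PEReport:
    """Build the group-by-group PE table from (Cmax, AUC) pairs."""
    if set(observed) != set(predicted):
        raise ValidationError("observed and predicted groups differ")
    rows = []
    for group in observed:
        ocmax, oauc = observed[group]
        pcmax, pauc = predicted[group]
        rows.append(GroupPE(
            group=group,
            observed_cmax=ocmax, predicted_cmax=pcmax,
            pe_cmax=prediction_error(ocmax, pcmax, convention),
            observed_auc=oauc, predicted_auc=pauc,
            pe_auc=prediction_error(oauc, pauc, convention),
            external=group in external_groups,
        ))
    return PEReport(
        groups=tuple(rows),
        mean_abs_pe_cmax=mean_absolute_pe([r.pe_cmax for r in rows]),
        mean_abs_pe_auc=mean_absolute_pe([r.pe_auc for r in rows]),
    )


def validate_ivivc(
    report: PEReport,
    mean_limit: float = QUALIFICATION_MEAN_LIMIT,
    individual_limit: float = QUALIFICATION_INDIVIDUAL_LIMIT,
) -> Dict[str, bool]:
    """Per-metric pass flags against the qualification limits."""
    out = {}
    for metric, mean_pe, pes in (
        ("cmax", report.mean_abs_pe_cmax, [r.pe_cmax for r in report.groups]),
        ("auc", report.mean_abs_pe_auc, [r.pe_auc for r in report.groups]),
    ):
        out[metric] = bool(
            mean_pe <= mean_limit
            and all(abs(pe) <= individual_limit for pe in pes)
        )
    return out
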