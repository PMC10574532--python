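"""Single and double Weibull dissolution/absorption-fraction models.

The double Weibull is a two-process mixture with a shared lag,

    F(t) = F_inf * [ f1 * (1 - exp(-((t - Tlag)/MDT1)**b1))
                   + (1 - f1) * (1 - exp(-((t - Tlag)/MDT2)**b2)) ]

zero for t <= Tlag.  Fitting is least squares with seeded multistart from
quantile heuristics; model choice uses the least-squares AIC
n*ln(RSS/n) + 2k.  A per-process-lag variant is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, InsufficientDataError, ValidationError
from .timeseries import TimeSeries


@dataclass(frozen=True)
class DoubleWeibullParams:
    F_inf: float
    f1: float
    MDT1: float
    b1: float
    MDT2: float
    b2: float
    Tlag: float = 0.0
    Tlag2: float = None  # per-process lag for the second term (optional)

    def __post_init__(self):
        if not (0.0 < self.F_inf <= 1.05):
            raise ValidationError(f"F_inf {self.F_inf} outside (0, 1.05]")
        if not (0.0 <= self.f1 <= 1.0):
            raise ValidationError(f"f1 {self.f1} outside [0, 1]")
        for name in ("MDT1", "b1", "MDT2", "b2"):
            if not (getattr(self, name) > 0):
                raise ValidationError(f"{name} must be > 0")
        if self.Tlag < 0:
            raise ValidationError("Tlag must be >= 0")
        if self.Tlag2 is not None and self.Tlag2 < 0:
            raise ValidationError("Tlag2 must be >= 0")

    def with_time_scale(self, factor: float) -> "DoubleWeibullParams":
        """Return parameters expressed on a time axis multiplied by ``factor``
        (e.g. factor=1/60 converts a minutes fit to hours)."""
        return replace(
            self,
            MDT1=self.MDT1 * factor,
            MDT2=self.MDT2 * factor,
            Tlag=self.Tlag * factor,
            Tlag2=None if self.Tlag2 is None else self.Tlag2 * factor,
        )

    def __call__(self, t):
        return eval_double_weibull(self, t)


@dataclass(frozen=True)
class SingleWeibullParams:
    F_inf: float
    MDT: float
    b: float
    Tlag: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.F_inf <= 1.05):
            raise ValidationError(f"F_inf {self.F_inf} outside (0, 1.05]")
        if self.MDT <= 0 or self.b <= 0:
            raise ValidationError("MDT and b must be > 0")
        if self.Tlag < 0:
            raise ValidationError("Tlag must be >= 0")

    def as_double(self) -> DoubleWeibullParams:
        return DoubleWeibullParams(
            F_inf=self.F_inf, f1=1.0, MDT1=self.MDT, b1=self.b,
            MDT2=self.MDT, b2=self.b, Tlag=self.Tlag,
        )

    def __call__(self, t):
        return eval_double_weibull(self.as_double(), t)


@dataclass(frozen=True)
class FitReport:
    params: object
    rss: float
    n_obs: int
    k_params: int
    aic: float
    model: str
    flags: tuple = ()

    def __post_init__(self):
        if not np.isfinite(self.aic):
            raise ValidationError("AIC must be finite")
        if self.n_obs <= self.k_params:
            raise ValidationError("n_obs must exceed k_params")


def _weibull_term(t, lag, mdt, b):
    out = np.zeros_like(t)
    pos = t > lag
    out[pos] = 1.0 - np.exp(-(((t[pos] - lag) / mdt) ** b))
    return out


def eval_double_weibull(p: DoubleWeibullParams, t):
    """Fraction released at time(s) t; 0 at/before the lag, -> F_inf."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    lag2 = p.Tlag if p.Tlag2 is None else p.Tlag2
    out = p.F_inf * (
        p.f1 * _weibull_term(t_arr, p.Tlag, p.MDT1, p.b1)
        + (1.0 - p.f1) * _weibull_term(t_arr, lag2, p.MDT2, p.b2)
    )
    return out if np.ndim(t) else float(out[0])


def aic_least_squares(n: int, rss: float, k: int) -> float:
    """AIC for a Gaussian least-squares fit: n*ln(RSS/n) + 2k."""
    rss = max(rss, 1e-300)  # guard log(0) for exact fits
    return n * np.log(rss / n) + 2 * k


# parameter vectors used internally: single = (F_inf, MDT, b, Tlag),
# double = (F_inf, f1, MDT1, b1, MDT2, b2, Tlag)

def _init_heuristic(t, y, model):
    f_inf = min(max(float(np.max(y)), 1e-3), 1.05)
    target35 = 0.35 * f_inf
    target70 = 0.70 * f_inf
    t35 = float(np.interp(target35, y, t)) if np.any(y >= target35) else t[len(t) // 3]
    t70 = float(np.interp(target70, y, t)) if np.any(y >= target70) else t[2 * len(t) // 3]
    t35 = max(t35, t[1] if len(t) > 1 else 1.0)
    t70 = max(t70, t35 * 1.5)
    if model == "weibull1":
        return np.array([f_inf, 0.5 * (t35 + t70), 1.0, 0.0])
    return np.array([f_inf, 0.5, t35, 1.0, t70, 1.0, 0.0])


def _bounds(model, t_max):
    if model == "weibull1":
        lo = [1e-3, 1e-3, 0.05, 0.0]
        hi = [1.05, 50 * t_max, 10.0, t_max]
    else:
        lo = [1e-3, 0.0, 1e-3, 0.05, 1e-3, 0.05, 0.0]
        hi = [1.05, 1.0, 50 * t_max, 10.0, 50 * t_max, 10.0, t_max]
    return np.array(lo), np.array(hi)


def _predict(theta, t, model):
    if model == "weibull1":
        f_inf, mdt, b, lag = theta
        return f_inf * _weibull_term(t, lag, mdt, b)
    f_inf, f1, m1, b1, m2, b2, lag = theta
    return f_inf * (f1 * _weibull_term(t, lag, m1, b1)
                    + (1 - f1) * _weibull_term(t, lag, m2, b2))


def fit_dissolution(
    ts: TimeSeries,
    model: str = "weibull2",
    n_starts: int = 20,
    seed: int = 0,
) -> FitReport:
    """Multistart least-squares fit of a Weibull release model.

    ``model`` is ``"weibull1"`` or ``"weibull2"``.  Raises
    :class:`FitError` if no start converges.
    """
    if model not in ("weibull1", "weibull2"):
        raise ValidationError(f"unknown model {model!r}")
    t = ts.time
    y = ts.value
    k = 4 if model == "weibull1" else 7
    if len(ts) < 2 * k:
        raise InsufficientDataError(f"need >= {2 * k} points for {model}")
    if np.any(y < -1e-9) or np.any(y > 1.05 + 1e-9):
        raise ValidationError("fraction values must lie in [0, 1.05]")

    lo, hi = _bounds(model, float(t[-1]))
    x0 = np.clip(_init_heuristic(t, y, model), lo, hi)
    rng = np.random.default_rng(seed)

    best = None
    best_failed = None
    for i in range(max(1, n_starts)):
        if i == 0:
            xi = x0
        else:
            xi = np.clip(x0 * rng.lognormal(0.0, 0.4, size=x0.size), lo, hi)
            if model == "weibull2":
                xi[1] = rng.uniform(0.1, 0.9)
        try:
            res = least_squares(
                lambda th: _predict(th, t, model) - y,
                xi, bounds=(lo, hi), xtol=1e-10, ftol=1e-10, gtol=1e-10,
                max_nfev=3000,
            )
        except Exception:
            continue
        rss = float(np.sum(res.fun ** 2))
        if res.success and np.isfinite(rss) and (best is None or rss < best[0]):
            best = (rss, res.x)
        elif np.isfinite(rss) and (best_failed is None or rss < best_failed):
            best_failed = rss
    if best is None:
        raise FitError(
            f"no start converged for {model}",
            best_rss=best_failed,
        )

    rss, theta = best
    flags = []
    if model == "weibull1":
        params = SingleWeibullParams(*theta)
        if params.F_inf < 0.01:
            flags.append("F_inf near zero: degenerate series")
    else:
        params = DoubleWeibullParams(
            F_inf=theta[0], f1=theta[1], MDT1=theta[2], b1=theta[3],
            MDT2=theta[4], b2=theta[5], Tlag=theta[6],
        )
        if params.F_inf < 0.01:
            flags.append("F_inf near zero: degenerate series")
    return FitReport(
        params=params, rss=rss, n_obs=len(ts), k_params=k,
        aic=aic_least_squares(len(ts), rss, k), model=model, flags=tuple(flags),
    )


def select_dissolution_model(ts: TimeSeries, n_starts: int = 20, seed: int = 0):
    """Fit both Weibull forms and return (best report, all reports) by AIC."""
    reports = [fit_dissolution(ts, m, n_starts=n_starts, seed=seed)
               for m in ("weibull1", "weibull2")]
    best = min(reports, key=lambda r: r.aic)
    return best, reports
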