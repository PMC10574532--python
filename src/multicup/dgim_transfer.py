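"""Deterministic hydraulics of the three-cup transfer dissolution model.

Three stirred vessels (gastric, duodenal, jejunal) are connected by two
pumps.  Pump A empties the gastric cup first-order with half-emptying time
``th`` while secretion streams (1 mL/min each) feed the gastric and duodenal
cups; pump B forwards the duodenal excess so its aqueous volume stays
constant.  All flows stop at ``pump_stop`` and volumes freeze.

The first-order pump-A rate is implemented in the dimensionally consistent
form

    va(t) = (ln 2 / th) * Vg0 * exp(-ln 2 * t / th) + secretion_rate

which reproduces Vg(t) = Vg0 * 2**(-t/th) exactly when the gastric secretion
offsets the "+secretion_rate" term.  A literal variant without the 1/th
factor is available behind ``as_printed=True`` for comparison only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ValidationError

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class DGIMConfig:
    """Apparatus geometry and pumping programme.

    Volumes in mL, times in minutes, rates in mL/min.
    """

    Vg0: float = 300.0          # initial gastric aqueous volume
    Vd: float = 50.0            # constant duodenal aqueous volume
    Vj0: float = 100.0          # initial jejunal aqueous volume
    th: float = 8.0             # gastric half-emptying time
    secretion_rate: float = 1.0             # per secreted cup
    secretion_concentration_factor: float = 4.0
    pump_stop: float = 40.0
    duration: float = 180.0
    octanol_d: float = 100.0    # duodenal organic-phase volume
    octanol_j: float = 100.0    # jejunal organic-phase volume
    pH_gastric: float = 2.0
    pH_duodenal: float = 5.9
    pH_jejunal: float = 6.1
    paddle_rpm: float = 50.0    # metadata only

    #: cups receiving a secretion stream (gastric + duodenal)
    n_secreted_cups: int = 2

    def __post_init__(self):
        for name in ("Vg0", "Vd", "Vj0", "octanol_d", "octanol_j"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.th <= 0:
            raise ValidationError("th must be > 0")
        if not (0 < self.pump_stop <= self.duration):
            raise ValidationError("need 0 < pump_stop <= duration")
        if self.secretion_rate < 0:
            raise ValidationError("secretion_rate must be >= 0")


@dataclass(frozen=True)
class FlowState:
    """Instantaneous pump rates and aqueous volumes."""

    t: float
    va: float
    vb: float
    Vg: float
    Vd: float
    Vj: float


def _check_t(t, upper=None):
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("time must be >= 0")
    if upper is not None and np.any(t_arr > upper):
        raise DomainError(f"time must be <= {upper} min")
    return t_arr


def pump_rate_a(t, cfg: DGIMConfig, as_printed: bool = False):
    """Pump A (gastric -> duodenal) rate in mL/min; 0 after ``pump_stop``."""
    t_arr = _check_t(t)
    if as_printed:
        # literal textbook form, dimensionally inconsistent; comparison only
        empty = _LN2 * cfg.Vg0 * np.exp(-_LN2 * t_arr / cfg.th)
    else:
        empty = (_LN2 / cfg.th) * cfg.Vg0 * np.exp(-_LN2 * t_arr / cfg.th)
    out = np.where(t_arr <= cfg.pump_stop, empty + cfg.secretion_rate, 0.0)
    return float(out) if np.ndim(t) == 0 else out


def pump_rate_b(t, cfg: DGIMConfig, as_printed: bool = False):
    """Pump B (duodenal -> jejunal) rate: va + secretion while running."""
    t_arr = _check_t(t)
    va = pump_rate_a(t_arr, cfg, as_printed=as_printed)
    out = np.where(t_arr <= cfg.pump_stop, va + cfg.secretion_rate, 0.0)
    return float(out) if np.ndim(t) == 0 else out


def gastric_volume(t, cfg: DGIMConfig):
    """Closed-form Vg(t) = Vg0 * 2**(-t/th), frozen after ``pump_stop``."""
    t_arr = _check_t(t)
    te = np.minimum(t_arr, cfg.pump_stop)
    out = cfg.Vg0 * 2.0 ** (-te / cfg.th)
    return float(out) if np.ndim(t) == 0 else out


def jejunal_volume(t, cfg: DGIMConfig):
    """Closed-form Vj(t) = Vj0 + integral of vb, frozen after ``pump_stop``."""
    t_arr = _check_t(t)
    te = np.minimum(t_arr, cfg.pump_stop)
    emptied = cfg.Vg0 * (1.0 - 2.0 ** (-te / cfg.th))
    out = cfg.Vj0 + emptied + 2.0 * cfg.secretion_rate * te
    return float(out) if np.ndim(t) == 0 else out


def volumes(t: float, cfg: DGIMConfig) -> FlowState:
    """Full flow state at time ``t`` (must lie in [0, duration])."""
    _check_t(t, upper=cfg.duration)
    return FlowState(
        t=float(t),
        va=pump_rate_a(t, cfg),
        vb=pump_rate_b(t, cfg),
        Vg=gastric_volume(t, cfg),
        Vd=cfg.Vd,
        Vj=jejunal_volume(t, cfg),
    )


def volume_table(t_grid, cfg: DGIMConfig):
    """Vectorized trajectories: dict of arrays keyed t, va, vb, Vg, Vd, Vj."""
    t_arr = _check_t(t_grid, upper=cfg.duration)
    return {
        "t": t_arr,
        "va": pump_rate_a(t_arr, cfg),
        "vb": pump_rate_b(t_arr, cfg),
        "Vg": gastric_volume(t_arr, cfg),
        "Vd": np.full_like(t_arr, cfg.Vd),
        "Vj": jejunal_volume(t_arr, cfg),
    }


def _origin_rhs(t, y, cfg: DGIMConfig):
    """d/dt of (fd, gj): gastric-origin fraction in duodenum and
    gastric-origin volume in jejunum, while pumps run."""
    fd, gj = y
    va = (_LN2 / cfg.th) * cfg.Vg0 * np.exp(-_LN2 * t / cfg.th) + cfg.secretion_rate
    vb = va + cfg.secretion_rate
    dfd = (va - vb * fd) / cfg.Vd
    dgj = vb * fd
    return [dfd, dgj]


def origin_fraction_solution(cfg: DGIMConfig):
    """Dense solution of the well-mixed fluid-origin balance on [0, pump_stop].

    Returns a callable ``f(t, cup)`` valid on [0, duration]; fractions are
    frozen at their pump-stop values afterwards.
    """
    from scipy.integrate import solve_ivp

    sol = solve_ivp(
        _origin_rhs,
        (0.0, cfg.pump_stop),
        [0.0, 0.0],
        args=(cfg,),
        method="LSODA",
        dense_output=True,
        rtol=1e-10,
        atol=1e-12,
        max_step=1.0,
    )
    if not sol.success:  # pragma: no cover - LSODA is robust here
        raise RuntimeError(f"origin-fraction ODE failed: {sol.message}")

    def fraction(t, cup):
        # tolerant of tiny solver overshoot; the public wrapper is strict
        t_arr = np.clip(np.asarray(t, dtype=float), 0.0, None)
        te = np.minimum(t_arr, cfg.pump_stop)
        fd, gj = sol.sol(np.atleast_1d(te))
        if cup == "duodenum":
            out = fd
        elif cup == "jejunum":
            out = gj / jejunal_volume(np.atleast_1d(te), cfg)
        else:
            raise DomainError(f"unknown cup {cup!r}")
        out = np.clip(out, 0.0, 1.0)
        return float(out[0]) if np.ndim(t) == 0 else out

    return fraction


def gastric_origin_fraction(t, cfg: DGIMConfig, cup: str):
    """Fraction of a cup's aqueous volume that originated in the gastric cup.

    ``cup`` is ``"duodenum"`` or ``"jejunum"``.  For repeated evaluation use
    :func:`origin_fraction_solution` once and call it on a grid.
    """
    _check_t(t, upper=cfg.duration)
    return origin_fraction_solution(cfg)(t, cup)
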