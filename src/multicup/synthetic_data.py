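"""Mechanistic generator of every input the analysis consumes.

Produces, with known ground truth:

* three-cup transfer-model concentration curves (aqueous + organic) showing
  the spring-and-parachute supersaturation/precipitation shape,
* single-vessel pH-shift curves with the instantaneous dilution event,
* oral and i.v. plasma profiles from a linear-disposition polyexponential
  kernel,
* reproducible multiplicative lognormal noise.

The luminal kinetics are deliberately simple: precipitation is first-order
in the supersaturation excess (no redissolution, no nucleation lag) and
aqueous->octanol transfer is one-way first-order.  pH in each intestinal
cup is an affine function of the gastric-origin volume fraction, clamped to
[1.5, 7].  These rate laws are synthetic devices tuned to qualitative curve
shapes only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .dgim_transfer import (
    DGIMConfig,
    gastric_volume,
    jejunal_volume,
    origin_fraction_solution,
    pump_rate_a,
    pump_rate_b,
)
from .errors import DomainError, IntegrationError, ValidationError
from .kernels import convolve_pwl_cumulative, polyexp
from .solubility import PHSolubilityFit, eval_solubility
from .timeseries import TimeSeries

_PH_CLAMP = (1.5, 7.0)


@dataclass(frozen=True)
class LuminalKineticsParams:
    """Synthetic luminal rate constants (all 1/min)."""

    kp: float = 0.15          # precipitation rate toward solubility
    ka_d: float = 0.012       # aqueous -> octanol, duodenal cup
    ka_j: float = 0.010       # aqueous -> octanol, jejunal cup
    pH_dip_gain: float = 1.0  # gastric-fraction -> pH depression
    noise_sigma: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self):
        for name in ("kp", "ka_d", "ka_j", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class GroupScenario:
    """A dosing group: inhibitor label, its solubility curve and doses."""

    label: str
    solubility_fit: PHSolubilityFit
    dose_conc_gastric: float = 5.2   # mg/mL in the gastric cup
    inhibitor_conc: float = 0.0      # mg/mL

    def __post_init__(self):
        if self.dose_conc_gastric <= 0:
            raise ValidationError("dose_conc_gastric must be > 0")


@dataclass(frozen=True)
class PKDispositionParams:
    """Linear-disposition i.v. kernel and dose/bioavailability ground truth.

    ``terms`` are (A_i, lambda_i) with A_i in (ng/mL) per (mg/kg) dose and
    lambda_i in 1/h; doses in mg/kg.
    """

    terms: Tuple[Tuple[float, float], ...] = ((6500.0, 1.1), (2800.0, 0.28))
    dose_oral: float = 10.0
    dose_iv: float = 2.5
    F_true: float = 0.70

    def __post_init__(self):
        if not self.terms or len(self.terms) > 3:
            raise ValidationError("kernel needs 1-3 exponential terms")
        for _, lam in self.terms:
            if lam <= 0:
                raise ValidationError("lambda_i must be > 0")
        if not (0.0 < self.F_true <= 1.0):
            raise ValidationError("F_true must be in (0, 1]")


# ---------------------------------------------------------------------------
# presets: per-group solubility fits (pKa reduced by inhibitors) and
# precipitation strength control > HPMC > PVPVA
# ---------------------------------------------------------------------------

DEFAULT_SOLUBILITY_FITS = {
    "control": PHSolubilityFit(C_U=18.0, pKa=6.322),
    "PVPVA": PHSolubilityFit(C_U=24.0, pKa=6.077),
    "HPMC": PHSolubilityFit(C_U=21.0, pKa=6.087),
}

DEFAULT_KP = {"control": 0.15, "PVPVA": 0.03, "HPMC": 0.06}

DEFAULT_F_TRUE = {"control": 0.70, "PVPVA": 0.92, "HPMC": 0.85}


def default_scenario(label: str) -> GroupScenario:
    if label not in DEFAULT_SOLUBILITY_FITS:
        raise DomainError(f"unknown group {label!r}")
    return GroupScenario(
        label=label,
        solubility_fit=DEFAULT_SOLUBILITY_FITS[label],
        inhibitor_conc=0.0 if label == "control" else 10.0,
    )


def default_kinetics(label: str, seed: Optional[int] = None) -> LuminalKineticsParams:
    if label not in DEFAULT_KP:
        raise DomainError(f"unknown group {label!r}")
    return LuminalKineticsParams(kp=DEFAULT_KP[label], seed=seed)


# ---------------------------------------------------------------------------
# three-cup transfer simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DGIMSimResult:
    """Bundle of simulated series; aqueous/organic values in ug/mL, masses
    in ug, time in minutes."""

    duodenal_aq: TimeSeries
    jejunal_aq: TimeSeries
    duodenal_org: TimeSeries
    jejunal_org: TimeSeries
    pH_d: TimeSeries
    pH_j: TimeSeries
    precipitated_mass_d: TimeSeries
    precipitated_mass_j: TimeSeries
    gastric_aq: TimeSeries
    organic_amount_d: TimeSeries
    organic_amount_j: TimeSeries
    absorbed_fraction: TimeSeries
    total_mass: TimeSeries
    dose_ug: float


def _ph_in_cup(set_point, gain, frac):
    return np.clip(set_point - gain * frac, *_PH_CLAMP)


def simulate_dgim(
    cfg: DGIMConfig,
    scenario: GroupScenario,
    kin: LuminalKineticsParams,
    grid: Sequence[float],
) -> DGIMSimResult:
    """Integrate the per-cup drug mass balance on the caller's time grid.

    State: dissolved mass in each cup, precipitated mass and organic-phase
    amount in the intestinal cups.  Total drug mass is conserved by
    construction; the result carries the audit series.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise DomainError("grid must be a 1-D vector with >= 2 points")
    if grid[0] < 0 or grid[-1] > cfg.duration:
        raise DomainError(f"grid must lie within [0, {cfg.duration}] min")

    dose_ug = scenario.dose_conc_gastric * 1000.0 * cfg.Vg0  # mg/mL -> ug
    frac = origin_fraction_solution(cfg)
    fit = scenario.solubility_fit
    solub_inf = np.isinf(fit.C_U)

    def cs_at(ph):
        if solub_inf:
            return np.inf
        return eval_solubility(fit, float(ph))

    def rhs(t, y):
        mg, md, mj, pd_, pj, od, oj = y
        va = pump_rate_a(t, cfg)
        vb = pump_rate_b(t, cfg)
        vg = gastric_volume(t, cfg)
        vj = jejunal_volume(t, cfg)
        cg = mg / vg
        cd = md / cfg.Vd
        cj = mj / vj
        fd = frac(t, "duodenum")
        fj = frac(t, "jejunum")
        ph_d = _ph_in_cup(cfg.pH_duodenal, kin.pH_dip_gain, fd)
        ph_j = _ph_in_cup(cfg.pH_jejunal, kin.pH_dip_gain, fj)
        prec_d = kin.kp * cfg.Vd * max(cd - cs_at(ph_d), 0.0) if not solub_inf else 0.0
        prec_j = kin.kp * vj * max(cj - cs_at(ph_j), 0.0) if not solub_inf else 0.0
        abs_d = kin.ka_d * cfg.Vd * cd
        abs_j = kin.ka_j * vj * cj
        return [
            -va * cg,
            va * cg - vb * cd - prec_d - abs_d,
            vb * cd - prec_j - abs_j,
            prec_d,
            prec_j,
            abs_d,
            abs_j,
        ]

    y0 = [dose_ug, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
    # pump stop is an exact breakpoint: integrate the two regimes separately
    seg_edges = [grid[0], cfg.pump_stop, grid[-1]]
    seg_edges = sorted({e for e in seg_edges if grid[0] <= e <= grid[-1]})
    ys = []
    y = y0
    for a, b in zip(seg_edges[:-1], seg_edges[1:]):
        t_eval = grid[(grid >= a) & (grid <= b)]
        if t_eval.size == 0 or t_eval[0] > a:
            t_eval = np.concatenate(([a], t_eval))
        sol = solve_ivp(
            rhs, (a, b), y, t_eval=t_eval, method="LSODA",
            rtol=1e-9, atol=dose_ug * 1e-12, max_step=0.25,
        )
        if not sol.success:
            raise IntegrationError(
                f"transfer-model integration failed on [{a}, {b}]: {sol.message}",
                state=sol,
            )
        ys.append((sol.t, sol.y))
        y = sol.y[:, -1]

    t_all = np.concatenate([t for t, _ in ys])
    y_all = np.concatenate([yy for _, yy in ys], axis=1)
    # drop the duplicated/auxiliary breakpoints not on the caller's grid
    keep = np.isin(t_all, grid)
    # keep first occurrence of each grid time only
    _, first = np.unique(t_all[keep], return_index=True)
    t_out = t_all[keep][first]
    y_out = y_all[:, keep][:, first]

    mg, md, mj, pd_, pj, od, oj = y_out
    vg = gastric_volume(t_out, cfg)
    vj = jejunal_volume(t_out, cfg)
    fd = frac(t_out, "duodenum")
    fj = frac(t_out, "jejunum")
    ph_d = _ph_in_cup(cfg.pH_duodenal, kin.pH_dip_gain, fd)
    ph_j = _ph_in_cup(cfg.pH_jejunal, kin.pH_dip_gain, fj)
    total = mg + md + mj + pd_ + pj + od + oj

    def ts(v, unit, label):
        return TimeSeries(t_out, v, time_unit="min", value_unit=unit,
                          label=f"{scenario.label}:{label}")

    return DGIMSimResult(
        duodenal_aq=ts(md / cfg.Vd, "ug/mL", "duodenal_aq"),
        jejunal_aq=ts(mj / vj, "ug/mL", "jejunal_aq"),
        duodenal_org=ts(od / cfg.octanol_d, "ug/mL", "duodenal_org"),
        jejunal_org=ts(oj / cfg.octanol_j, "ug/mL", "jejunal_org"),
        pH_d=ts(ph_d, "pH", "pH_d"),
        pH_j=ts(ph_j, "pH", "pH_j"),
        precipitated_mass_d=ts(pd_, "ug", "precipitated_d"),
        precipitated_mass_j=ts(pj, "ug", "precipitated_j"),
        gastric_aq=ts(mg / vg, "ug/mL", "gastric_aq"),
        organic_amount_d=ts(od, "ug", "organic_amount_d"),
        organic_amount_j=ts(oj, "ug", "organic_amount_j"),
        absorbed_fraction=ts((od + oj) / dose_ug, "fraction", "absorbed_fraction"),
        total_mass=ts(total, "ug", "total_mass"),
        dose_ug=dose_ug,
    )


# ---------------------------------------------------------------------------
# single-vessel pH-shift simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class USP2SimResult:
    aqueous: TimeSeries          # ug/mL
    organic: TimeSeries          # ug/mL in octanol
    organic_amount: TimeSeries   # ug
    precipitated_mass: TimeSeries
    absorbed_fraction: TimeSeries
    total_mass: TimeSeries
    shift_time: float
    c_before_shift: float
    c_after_shift: float
    dose_ug: float


def simulate_usp2_ph_shift(
    scenario: GroupScenario,
    kin: LuminalKineticsParams,
    grid: Sequence[float],
    shift_time: float = 20.0,
    volume_pre: float = 250.0,
    volume_post: float = 750.0,
    octanol_volume: float = 200.0,
    pH_pre: float = 2.0,
    pH_post: float = 6.1,
) -> USP2SimResult:
    """Single-vessel pH-shift test with an instantaneous dilution event.

    Before ``shift_time`` the drug sits fully dissolved at gastric pH (no
    precipitation, no octanol transfer).  At the shift the aqueous phase is
    diluted ``volume_pre/volume_post``-fold and the pH jumps to the
    intestinal set point; precipitation/absorption kinetics then run as in
    the transfer simulator.  At exactly the shift instant the post-dilution
    value is reported.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise DomainError("grid must be a 1-D vector with >= 2 points")
    if not (grid[0] <= shift_time <= grid[-1]):
        raise DomainError("shift_time must lie inside the grid")

    dose_ug = scenario.dose_conc_gastric * 1000.0 * volume_pre
    c0 = scenario.dose_conc_gastric * 1000.0               # ug/mL
    c_post = c0 * volume_pre / volume_post
    fit = scenario.solubility_fit
    cs_post = np.inf if np.isinf(fit.C_U) else eval_solubility(fit, pH_post)
    ka = kin.ka_d  # single-vessel test uses one transfer rate

    def rhs(t, y):
        m, p, o = y
        c = m / volume_post
        prec = kin.kp * volume_post * max(c - cs_post, 0.0) if np.isfinite(cs_post) else 0.0
        absorb = ka * volume_post * c
        return [-prec - absorb, prec, absorb]

    pre_mask = grid < shift_time
    post_times = grid[~pre_mask]
    t_eval = post_times
    if t_eval.size == 0 or t_eval[0] > shift_time:
        t_eval = np.concatenate(([shift_time], t_eval))
    sol = solve_ivp(
        rhs, (shift_time, grid[-1]), [c_post * volume_post, 0.0, 0.0],
        t_eval=t_eval, method="LSODA",
        rtol=1e-9, atol=dose_ug * 1e-12, max_step=0.25,
    )
    if not sol.success:
        raise IntegrationError(f"pH-shift integration failed: {sol.message}", state=sol)
    keep = np.isin(sol.t, post_times)
    m_post, p_post, o_post = sol.y[:, keep]

    n_pre = int(pre_mask.sum())
    aqueous = np.concatenate((np.full(n_pre, c0), m_post / volume_post))
    precip = np.concatenate((np.zeros(n_pre), p_post))
    organic = np.concatenate((np.zeros(n_pre), o_post))
    total = np.concatenate((np.full(n_pre, dose_ug), m_post + p_post + o_post))

    def ts(v, unit, label):
        return TimeSeries(grid, v, time_unit="min", value_unit=unit,
                          label=f"{scenario.label}:{label}")

    return USP2SimResult(
        aqueous=ts(aqueous, "ug/mL", "usp2_aqueous"),
        organic=ts(organic / octanol_volume, "ug/mL", "usp2_organic"),
        organic_amount=ts(organic, "ug", "usp2_organic_amount"),
        precipitated_mass=ts(precip, "ug", "usp2_precipitated"),
        absorbed_fraction=ts(organic / dose_ug, "fraction", "usp2_absorbed_fraction"),
        total_mass=ts(total, "ug", "usp2_total_mass"),
        shift_time=float(shift_time),
        c_before_shift=float(c0),
        c_after_shift=float(c_post),
        dose_ug=dose_ug,
    )


# ---------------------------------------------------------------------------
# plasma profiles
# ---------------------------------------------------------------------------

def simulate_plasma(
    input_fraction: Optional[TimeSeries],
    pk: PKDispositionParams,
    route: str = "oral",
    t_eval: Optional[Sequence[float]] = None,
) -> TimeSeries:
    """Plasma concentration from the linear-disposition kernel.

    ``oral``: convolution of the input rate d/dt(F_true * dose * Fabs) with
    the dose-normalized kernel, exact per linear Fabs segment.  ``iv``:
    dose-scaled kernel; ``input_fraction`` is ignored.
    Times are hours, concentrations ng/mL.
    """
    if route == "iv":
        if t_eval is None:
            t_eval = np.arange(0.0, 24.0 + 1e-9, 0.05)
        t = np.asarray(t_eval, dtype=float)
        return TimeSeries(t, pk.dose_iv * polyexp(pk.terms, t),
                          time_unit="h", value_unit="ng/mL", label="iv")
    if route != "oral":
        raise DomainError(f"unknown route {route!r}")
    if input_fraction is None:
        raise DomainError("oral route requires an input fraction series")

    fabs = input_fraction.to_unit("h")
    v = fabs.value
    if np.any(np.diff(v) < -1e-9):
        raise ValidationError("Fabs must be non-decreasing")
    if np.any(v < -1e-9) or np.any(v > 1.05 + 1e-9):
        raise ValidationError("Fabs must lie in [0, 1.05]")
    times = fabs.time
    if times[0] > 0:
        times = np.concatenate(([0.0], times))
        v = np.concatenate(([0.0], v))
    if t_eval is None:
        t_eval = times
    t = np.asarray(t_eval, dtype=float)
    conc = convolve_pwl_cumulative(
        times, v, pk.terms, t, scale=pk.F_true * pk.dose_oral
    )
    return TimeSeries(t, np.atleast_1d(conc), time_unit="h",
                      value_unit="ng/mL", label="oral")


def add_noise(ts: TimeSeries, sigma: float, seed: Optional[int] = None) -> TimeSeries:
    """Multiplicative lognormal noise with unit mean and CV = ``sigma``."""
    if sigma < 0:
        raise DomainError("sigma must be >= 0")
    if sigma == 0:
        return ts
    rng = np.random.default_rng(seed)
    s_ln = np.sqrt(np.log1p(sigma ** 2))
    factors = rng.lognormal(mean=-0.5 * s_ln ** 2, sigma=s_ln, size=len(ts))
    return ts.with_values(ts.value * factors)
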