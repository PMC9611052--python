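"""Isothermal titration calorimetry: thermogram integration and one-site fitting.

A VP-ITC experiment titrates copolymer micelles (syringe, amine
concentration basis) into siRNA (cell, phosphate concentration basis).  The
differential-power trace is integrated per injection to molar heats; the
binding isotherm is then fitted with the single-site (Wiseman) model with
``n`` identical independent sites per macromolecule:

    Theta^2 - Theta [1 + Xt/(n Mt) + 1/(n Ka Mt)] + Xt/(n Mt) = 0

where ``Xt``/``Mt`` are total ligand/macromolecule concentrations in the
cell after the perfusion dilution correction, ``Theta`` the fractional
occupancy, and the cumulative heat content is ``Q = n Theta Mt dH V0``.
Fitted parameters are n (stoichiometry on the charge basis), Ka (1/M) and
dH (kJ per mol of injectant); dG = -RT ln Ka and dS = (dH - dG)/T follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

R_GAS = 8.314  # J/(K mol)
J_PER_UCAL = 4.184e-6  # exact thermochemical calorie

__all__ = [
    "InjectionSchedule",
    "Thermogram",
    "InjectionHeats",
    "DerivedThermo",
    "integrate_injections",
    "site_occupancy",
    "one_site_heat_curve",
    "OneSiteBindingModel",
    "OneSiteBindingResults",
    "derive_thermo",
]


class ScheduleError(ValueError):
    """Injection schedule inconsistent with the trace."""


class NonIdentifiableError(RuntimeError):
    """The heats carry no binding transition; the one-site fit is undetermined."""


@dataclass(frozen=True)
class InjectionSchedule:
    """Injection program of a titration.

    Defaults follow the micelle-into-siRNA run: 1.8 mL cell holding 0.05 mM
    siRNA phosphate, syringe at 3 mM amine, an initial 2 uL aliquot (to
    guard against syringe backlash; discarded from fitting) then 10 uL
    injections every 180 s.
    """

    cell_volume: float = 1.8e-3  # L
    initial_aliquot_volume: float = 2e-6  # L
    injection_volume: float = 10e-6  # L
    n_injections: int = 28  # includes the initial aliquot
    spacing: float = 180.0  # s
    syringe_ligand_conc: float = 3e-3  # mol/L, amine basis
    cell_macromolecule_conc: float = 5e-5  # mol/L, phosphate basis
    first_injection_time: float = 120.0  # s of pre-titration baseline

    def __post_init__(self) -> None:
        if min(self.cell_volume, self.injection_volume, self.spacing) <= 0:
            raise ScheduleError("volumes and spacing must be positive")
        if self.n_injections < 1:
            raise ScheduleError("need at least one injection")

    @property
    def injection_volumes(self) -> np.ndarray:
        """Per-injection volumes (L); index 0 is the initial aliquot."""
        v = np.full(self.n_injections, self.injection_volume)
        v[0] = self.initial_aliquot_volume
        return v

    @property
    def injection_times(self) -> np.ndarray:
        return self.first_injection_time + self.spacing * np.arange(self.n_injections)

    def cell_concentrations(self) -> tuple[np.ndarray, np.ndarray]:
        """(ligand, macromolecule) totals in the cell after each injection.

        Standard perfusion-cell correction: injected volume displaces an
        equal volume of cell content, so after cumulative injected volume
        dV the macromolecule is diluted by (1 - dV/2V0)/(1 + dV/2V0) and
        the delivered ligand by 1/(1 + dV/2V0).
        """
        dv = np.cumsum(self.injection_volumes)
        v0 = self.cell_volume
        mt = self.cell_macromolecule_conc * (1 - dv / (2 * v0)) / (1 + dv / (2 * v0))
        xt = self.syringe_ligand_conc * (dv / v0) / (1 + dv / (2 * v0))
        return xt, mt


@dataclass(frozen=True)
class Thermogram:
    """Raw differential-power trace with its injection schedule."""

    time: np.ndarray  # s
    dp: np.ndarray  # ucal/s
    schedule: InjectionSchedule

    def __post_init__(self) -> None:
        t = np.asarray(self.time, float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ScheduleError("time grid must be strictly increasing")
        if len(t) != len(self.dp):
            raise ScheduleError("time and dp must have equal length")
        end = self.schedule.injection_times[-1] + self.schedule.spacing
        if t[0] > self.schedule.first_injection_time or t[-1] < end:
            raise ScheduleError("trace does not cover all injection windows")


@dataclass(frozen=True)
class InjectionHeats:
    """Integrated per-injection molar heats (kJ per mol of injectant).

    ``includes_first_aliquot`` records whether index 0 is the small initial
    aliquot, which is excluded from fitting by default.
    """

    heats: np.ndarray  # kJ/mol injectant
    schedule: InjectionSchedule
    includes_first_aliquot: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "heats", np.asarray(self.heats, float))

    @property
    def molar_ratio(self) -> np.ndarray:
        """Ligand:macromolecule total molar ratio in the cell (charge basis)."""
        xt, mt = self.schedule.cell_concentrations()
        return xt / mt

    def usable(self, skip_first: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """(indices, heats) entering a fit; drops the initial aliquot."""
        idx = np.arange(len(self.heats))
        if skip_first and self.includes_first_aliquot:
            idx = idx[1:]
        return idx, self.heats[idx]


def _window_bounds(schedule: InjectionSchedule) -> np.ndarray:
    starts = schedule.injection_times
    return np.column_stack([starts, starts + schedule.spacing])


def integrate_injections(tg: Thermogram, baseline_fraction: float = 0.2) -> InjectionHeats:
    """Integrate a differential-power trace into per-injection molar heats.

    Each injection window is [injection start, start + spacing].  A linear
    baseline is drawn through the quiet segments — the trailing
    ``baseline_fraction`` of the preceding window (or pre-titration
    baseline) and of the window itself — then the baseline-subtracted trace
    is integrated (trapezoid) and divided by the moles injected.
    """
    t = np.asarray(tg.time, float)
    dp = np.asarray(tg.dp, float)
    sched = tg.schedule
    windows = _window_bounds(sched)
    if np.any(windows[1:, 0] < windows[:-1, 1] - 1e-9):
        raise ScheduleError("injection windows overlap")
    vols = sched.injection_volumes
    heats_kj = np.empty(len(windows))
    frac = baseline_fraction
    for i, (t0, t1) in enumerate(windows):
        pre0 = t0 - frac * sched.spacing if i else max(t[0], t0 - frac * t0)
        pre = (t >= pre0) & (t < t0)
        tail = (t >= t1 - frac * sched.spacing) & (t <= t1)
        if not (pre.any() and tail.any()):
            raise ScheduleError(f"no baseline samples around injection {i}")
        # line through the mean points of the two quiet segments
        tp, yp = t[pre].mean(), dp[pre].mean()
        tq, yq = t[tail].mean(), dp[tail].mean()
        slope = (yq - yp) / (tq - tp)
        in_win = (t >= t0) & (t <= t1)
        base = yp + slope * (t[in_win] - tp)
        area_ucal = np.trapezoid(dp[in_win] - base, t[in_win])
        moles = vols[i] * sched.syringe_ligand_conc
        heats_kj[i] = area_ucal * J_PER_UCAL / moles / 1e3
    return InjectionHeats(heats=heats_kj, schedule=sched, includes_first_aliquot=True)


def site_occupancy(
    n_sites: float, ka: float, schedule: InjectionSchedule
) -> np.ndarray:
    """Fractional site occupancy after each injection.

    Physical root of the one-site mass-action quadratic; lies in [0, 1]
    for any positive parameters (up to floating rounding).
    """
    if ka <= 0 or n_sites <= 0:
        raise ValueError("n_sites and ka must be positive")
    xt, mt = schedule.cell_concentrations()
    ratio = xt / (n_sites * mt)
    b = 1.0 + ratio + 1.0 / (n_sites * ka * mt)
    return (b - np.sqrt(b * b - 4.0 * ratio)) / 2.0


def one_site_heat_curve(
    n_sites: float,
    ka: float,
    dh: float,
    schedule: InjectionSchedule,
    dilution_offset: float = 0.0,
) -> np.ndarray:
    """Per-injection molar heats (kJ/mol injectant) of the one-site model.

    Fractional occupancy solves the mass-action quadratic per injection;
    the heat of injection i is the change in cell heat content plus the
    displacement half-correction for the volume pushed out, divided by the
    moles delivered.  ``dilution_offset`` adds a constant heat of dilution
    per mole of injectant.
    """
    theta = np.clip(site_occupancy(n_sites, ka, schedule), 0.0, 1.0)
    _, mt = schedule.cell_concentrations()
    q = n_sites * theta * mt * dh * schedule.cell_volume  # kJ (dh in kJ/mol)
    vols = schedule.injection_volumes
    q_prev = np.concatenate([[0.0], q[:-1]])
    dq = q + (vols / schedule.cell_volume) * (q + q_prev) / 2.0 - q_prev
    moles = vols * schedule.syringe_ligand_conc
    return dq / moles + dilution_offset


@dataclass(frozen=True)
class DerivedThermo:
    """Thermodynamic state functions derived from a one-site fit.

    kd = 1/Ka; dG = -RT ln Ka; dS = (dH - dG)/T.  Energies in kJ/mol,
    entropy in kJ/(K mol); ``kd_nM`` is the nanomolar reporting helper.
    """

    ka: float
    dh: float  # kJ/mol
    temperature: float = 298.0
    kd: float = field(init=False)
    dg: float = field(init=False)
    ds: float = field(init=False)

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.temperature <= 0:
            raise ValueError("ka and temperature must be positive")
        object.__setattr__(self, "kd", 1.0 / self.ka)
        dg = -R_GAS * self.temperature * np.log(self.ka) / 1e3
        object.__setattr__(self, "dg", dg)
        object.__setattr__(self, "ds", (self.dh - dg) / self.temperature)

    @property
    def kd_nM(self) -> float:
        return self.kd * 1e9


def derive_thermo(ka: float, dh: float, temperature: float = 298.0) -> DerivedThermo:
    """Kd, dG and dS from the fitted association constant and enthalpy."""
    return DerivedThermo(ka=ka, dh=dh, temperature=temperature)


class OneSiteBindingModel:
    """One-site binding isotherm fitted to integrated injection heats.

    Parameters
    ----------
    heats : InjectionHeats
        Integrated molar heats with their schedule.
    temperature : float
        Cell temperature in K (default 298).
    fit_dilution_offset : bool
        Add a constant heat-of-dilution parameter (default off).
    skip_first : bool
        Exclude the initial small aliquot from the fit (default True).

    ``fit()`` runs damped least squares from a deterministic 3x3x3
    multi-start grid over (n, log10 Ka, dH) seeded from the data and
    returns :class:`OneSiteBindingResults`.
    """

    def __init__(
        self,
        heats: InjectionHeats,
        temperature: float = 298.0,
        fit_dilution_offset: bool = False,
        skip_first: bool = True,
    ):
        self.heats = heats
        self.temperature = temperature
        self.fit_dilution_offset = fit_dilution_offset
        self.skip_first = skip_first
        self._idx, self._y = heats.usable(skip_first)
        if len(self._y) < 5:
            raise NonIdentifiableError(
                f"need at least 5 usable injections, got {len(self._y)}"
            )
        if np.ptp(self._y) < 1e-12 * max(1.0, np.abs(self._y).max()):
            raise NonIdentifiableError(
                "all heats are equal: no binding transition to fit"
            )

    # -- internal -----------------------------------------------------------
    def _predict(self, params: np.ndarray) -> np.ndarray:
        n, log10ka, dh = params[:3]
        offset = params[3] if len(params) > 3 else 0.0
        full = one_site_heat_curve(n, 10.0**log10ka, dh, self.heats.schedule, offset)
        return full[self._idx]

    def _residuals(self, params: np.ndarray) -> np.ndarray:
        if params[0] <= 0:
            return np.full_like(self._y, 1e6)
        return self._predict(params) - self._y

    def _starting_grid(self) -> list[np.ndarray]:
        ratio = self.heats.molar_ratio[self._idx]
        y = self._y
        dh0 = y[0] if abs(y[0]) > 1e-12 else (y[np.argmax(np.abs(y))] or -10.0)
        # equivalence guess: molar ratio where |heat| first drops below half
        half = np.abs(y) < 0.5 * np.abs(dh0)
        n0 = ratio[np.argmax(half)] if half.any() else ratio[len(ratio) // 2]
        n0 = max(n0, 1e-3)
        starts = []
        for fn in (0.5, 1.0, 2.0):
            for lk in (5.0, 7.0, 9.0):
                for fd in (0.5, 1.0, 2.0):
                    p = [n0 * fn, lk, dh0 * fd if dh0 else -10.0 * fd]
                    if self.fit_dilution_offset:
                        p.append(0.0)
                    starts.append(np.array(p))
        return starts

    def fit(self) -> "OneSiteBindingResults":
        best = None
        for x0 in self._starting_grid():
            lower = [1e-6, 0.0, -np.inf] + ([-np.inf] if self.fit_dilution_offset else [])
            upper = [np.inf, 15.0, np.inf] + ([np.inf] if self.fit_dilution_offset else [])
            try:
                sol = optimize.least_squares(
                    self._residuals, x0, bounds=(lower, upper), method="trf"
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not np.all(np.isfinite(best.x)):
            raise RuntimeError("one-site fit failed to converge from every start")
        return OneSiteBindingResults(self, best)


class OneSiteBindingResults:
    """Estimates, uncertainties and derived thermodynamics of a one-site fit."""

    def __init__(self, model: OneSiteBindingModel, solution) -> None:
        self.model = model
        p = solution.x
        self.n_sites = float(p[0])
        self.ka = float(10.0 ** p[1])
        self.dh = float(p[2])
        self.dilution_offset = float(p[3]) if len(p) > 3 else 0.0
        res = solution.fun
        self.rss = float(res @ res)
        self.nobs = len(res)
        self.df_resid = self.nobs - len(p)
        self._cov = self._covariance(solution)
        self.bse = self._standard_errors(p)

    def _covariance(self, sol) -> np.ndarray | None:
        if self.df_resid <= 0:
            return None
        jtj = sol.jac.T @ sol.jac
        try:
            return np.linalg.inv(jtj) * self.rss / self.df_resid
        except np.linalg.LinAlgError:
            return None

    def _standard_errors(self, p: np.ndarray) -> dict[str, float]:
        if self._cov is None:
            return {}
        se = np.sqrt(np.clip(np.diag(self._cov), 0, None))
        out = {"n_sites": se[0], "ka": se[1] * self.ka * np.log(10.0), "dh": se[2]}
        if len(p) > 3:
            out["dilution_offset"] = se[3]
        return out

    # -- derived quantities --------------------------------------------------
    @property
    def thermo(self) -> DerivedThermo:
        return derive_thermo(self.ka, self.dh, self.model.temperature)

    def stoichiometry_per_sirna(
        self, phosphates_per_duplex: int = 40, amines_per_chain: int = 10
    ) -> float:
        """Copolymer chains bound per siRNA duplex.

        The fit runs on the amine/phosphate charge basis; n amines bound
        per phosphate times 40 phosphates per duplex over 10 amines per
        chain gives chains per duplex.
        """
        return self.n_sites * phosphates_per_duplex / amines_per_chain

    def predict(self) -> np.ndarray:
        """Model heats for every injection of the schedule (kJ/mol)."""
        return one_site_heat_curve(
            self.n_sites, self.ka, self.dh, self.model.heats.schedule,
            self.dilution_offset,
        )

    def summary(self) -> str:
        th = self.thermo
        se = self.bse
        lines = [
            "One-site binding fit",
            "=" * 46,
            f"n injections fitted     {self.nobs}",
            f"residual sum of squares {self.rss:.4g} (kJ/mol)^2",
            "-" * 46,
            f"n (charge basis)   {self.n_sites:10.4f} +/- {se.get('n_sites', float('nan')):.4f}",
            f"n (per siRNA)      {self.stoichiometry_per_sirna():10.3f}",
            f"Ka (1/M)           {self.ka:10.3e} +/- {se.get('ka', float('nan')):.2e}",
            f"dH (kJ/mol)        {self.dh:10.3f} +/- {se.get('dh', float('nan')):.3f}",
            "-" * 46,
            f"Kd (nM)            {th.kd_nM:10.1f}",
            f"dG (kJ/mol)        {th.dg:10.1f}",
            f"dS (kJ/(K mol))    {th.ds:10.3f}",
            f"T (K)              {self.model.temperature:10.1f}",
        ]
        if self.model.fit_dilution_offset:
            lines.insert(9, f"dilution (kJ/mol)  {self.dilution_offset:10.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        th = self.thermo
        return {
            "n": self.n_sites,
            "n_per_sirna": self.stoichiometry_per_sirna(),
            "ka": self.ka,
            "kd_nM": th.kd_nM,
            "dh_kj": self.dh,
            "dg_kj": th.dg,
            "ds_kj_per_K": th.ds,
            "uncertainties": self.bse,
            "rss": self.rss,
        }
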