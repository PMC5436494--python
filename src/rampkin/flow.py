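"""Pump ramp schedules, reactor geometry and the clock-time to
residence-time transform.

Under a linear flow ramp the mean tube velocity is

    u(t) = beta(T) * (u0 - alpha_u * t)

where beta(T) = 1 + alpha_v (T1 - T0) corrects for the thermal expansion
of the solvent between ambient and the reactor temperature.  A fluid
element leaving the coil at clock time t has resided for tau_res such
that the swept length equals the tube length,

    L = integral_{t - tau_res}^{t} u(t') dt',

which for linear u(t) is a quadratic in tau_res; the physically
meaningful root is the smaller positive one (the larger root sweeps
through zero flow).  Elements that entered during the pre-ramp steady
hold see the constant start velocity for t' < 0.

All internal computation is SI (s, K, m, m^3); mL/min and minutes appear
only at the interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, ScheduleError

ML_MIN_TO_M3_S = 1e-6 / 60.0
#: volumetric thermal expansion of ethanol near ambient, K^-1
ALPHA_V_ETHANOL = 1.1e-3


@dataclass(frozen=True)
class ReactorGeometry:
    """Coiled tubular reactor: internal volume, tube ID, coil winding
    diameter.  Length is derived from volume and cross-section."""

    volume_mL: float = 5.0
    d_t: float = 0.79e-3  # tube internal diameter, m
    d_c: float | None = None  # coil (winding) diameter, m; needed for Dean number

    def __post_init__(self):
        if self.volume_mL <= 0:
            raise ConfigError(f"reactor volume must be positive, got {self.volume_mL} mL")
        if self.d_t <= 0:
            raise ConfigError(f"tube diameter must be positive, got {self.d_t} m")
        if self.d_c is not None and self.d_c < self.d_t:
            raise ConfigError("coil diameter d_c cannot be smaller than tube diameter d_t")

    @property
    def volume_m3(self) -> float:
        return self.volume_mL * 1e-6

    @property
    def cross_section(self) -> float:
        """Tube cross-sectional area, m^2."""
        return math.pi * self.d_t**2 / 4.0

    @property
    def length(self) -> float:
        """Tube length L = V / A, m."""
        return self.volume_m3 / self.cross_section


@dataclass(frozen=True)
class ThermalExpansionModel:
    alpha_v: float = ALPHA_V_ETHANOL  # volumetric expansion coefficient, K^-1
    T0: float = 298.15  # ambient reference, K

    def __post_init__(self):
        if self.alpha_v < 0:
            raise ConfigError("alpha_v must be non-negative")


def thermal_expansion_factor(model: ThermalExpansionModel, T1: float) -> float:
    """beta = 1 + alpha_v (T1 - T0); equals 1 at ambient."""
    if T1 < model.T0 - 50.0:
        raise ConfigError(
            f"temperature {T1} K more than 50 K below the ambient reference"
        )
    beta = 1.0 + model.alpha_v * (T1 - model.T0)
    if beta <= 0:
        raise ConfigError(f"non-physical expansion factor beta = {beta}")
    return beta


@dataclass(frozen=True)
class RampProgram:
    """One linear deceleration ramp.

    Three pumps (P1 substrate stock, P2 solvent, P3 nucleophile stock)
    start at ``pump_flows_start`` (mL/min) and decelerate together so
    that their ratios — and hence the inlet concentrations — stay
    constant while the total flow drops linearly at ``alpha``
    (mL/min^2) from ``Q_start`` down to ``Q_end``.
    """

    pump_flows_start: dict[str, float]  # mL/min per pump id
    Q_end: float  # mL/min
    alpha: float  # mL/min^2, >= 0
    injection_interval_min: float = 2.0
    hold_min: float = 2.0
    temperature_C: float = 25.0
    equivalents: float = 0.0
    ramp_id: str = ""

    def __post_init__(self):
        if any(q < 0 for q in self.pump_flows_start.values()):
            raise ConfigError("pump flows must be non-negative")
        if self.Q_start <= 0:
            raise ConfigError("total start flow must be positive")
        if self.alpha < 0:
            raise ConfigError("deceleration alpha must be non-negative")
        if self.alpha > 0 and self.Q_end <= 0:
            raise ScheduleError("ramp end flow must stay positive (flow would stall)")
        if self.Q_end > self.Q_start:
            raise ConfigError("Q_end exceeds Q_start; ramps decelerate")
        if self.injection_interval_min <= 0:
            raise ConfigError("injection interval must be positive")

    @property
    def Q_start(self) -> float:
        return sum(self.pump_flows_start.values())

    @property
    def duration_min(self) -> float:
        if self.alpha == 0:
            return math.inf
        return (self.Q_start - self.Q_end) / self.alpha

    @property
    def temperature_K(self) -> float:
        return self.temperature_C + 273.15

    def Q_total(self, t_s: float) -> float:
        """Total pumped flow (mL/min) at clock time t (s, from ramp onset);
        constant at Q_start during the pre-ramp hold (t < 0)."""
        t_min = t_s / 60.0
        if t_min < 0:
            return self.Q_start
        if t_min > self.duration_min:
            raise ScheduleError(
                f"t = {t_min:.3g} min is past the ramp end ({self.duration_min:.3g} min)"
            )
        return self.Q_start - self.alpha * t_min

    def pump_flows(self, t_s: float) -> dict[str, float]:
        scale = self.Q_total(t_s) / self.Q_start
        return {p: q * scale for p, q in self.pump_flows_start.items()}


@dataclass
class SamplePoint:
    """One scheduled HPLC injection: where and when it was taken and the
    reaction conditions the exiting fluid element experienced."""

    ramp_id: str
    t: float  # sampling clock time since ramp onset, s
    tau_res: float  # residence time, s
    T: float  # reactor temperature, K
    equivalents: float  # C2,0 / C1,0
    inlet_concentrations: dict[str, float]  # M, at pumping (ambient) conditions
    Q_total: float  # total flow at exit, mL/min


def velocity_at_time(
    geom: ReactorGeometry,
    ramp: RampProgram,
    thermal: ThermalExpansionModel,
    T1: float,
    t: float,
) -> float:
    """Mean tube velocity u(t) = beta(T1) (u0 - alpha_u t), m/s."""
    beta = thermal_expansion_factor(thermal, T1)
    Q = ramp.Q_total(t) * ML_MIN_TO_M3_S
    u = beta * Q / geom.cross_section
    if u <= 0:
        raise ScheduleError(f"non-positive velocity at t = {t} s")
    return u


def residence_time_of_sample(
    geom: ReactorGeometry,
    ramp: RampProgram,
    thermal: ThermalExpansionModel,
    T1: float,
    t_exit: float,
) -> float:
    """Residence time (s) of the fluid element exiting at clock time
    ``t_exit`` (s from ramp onset).

    Solves the swept-volume condition  beta * int_{t-tau}^{t} Q(t') dt' = V
    in closed form: a quadratic during the ramp (smaller positive tau
    root), linear for elements that entered during the constant pre-ramp
    hold, and exactly V/(beta*Q) when alpha = 0.
    """
    beta = thermal_expansion_factor(thermal, T1)
    Q0 = ramp.Q_start * ML_MIN_TO_M3_S  # m^3/s
    alpha = ramp.alpha * ML_MIN_TO_M3_S / 60.0  # m^3/s^2
    V_eff = geom.volume_m3 / beta  # pumped volume to sweep
    t = float(t_exit)
    if t < 0:
        raise ConfigError("samples are taken at t >= 0 (from ramp onset)")
    ramp.Q_total(t)  # bounds check

    # cumulative pumped volume since ramp onset
    G_t = Q0 * t - 0.5 * alpha * t * t

    if G_t >= V_eff and alpha > 0:
        # entry during the ramp: (alpha/2) s^2 - Q0 s + (G_t - V_eff) = 0
        disc = Q0 * Q0 - 2.0 * alpha * (G_t - V_eff)
        if disc < 0:
            raise ScheduleError("reactor not fully swept within the schedule")
        s_entry = (Q0 - math.sqrt(disc)) / alpha
    else:
        # entry during the pre-ramp hold (or alpha == 0): constant Q0
        s_entry = (G_t - V_eff) / Q0
    tau = t - s_entry
    if tau <= 0:
        raise ScheduleError("non-positive residence time (inconsistent schedule)")
    hold_s = ramp.hold_min * 60.0
    if s_entry < -hold_s - 1e-9:
        raise ScheduleError(
            f"element exiting at t = {t:.1f} s entered {-s_entry:.1f} s before "
            f"ramp onset, beyond the {hold_s:.0f} s steady hold"
        )
    return tau


def inlet_concentrations(
    ramp: RampProgram, stock_concentrations: dict[str, float]
) -> tuple[float, float, float]:
    """Reactor-inlet concentrations from pump flow ratios.

    ``stock_concentrations`` maps pump id -> stock molarity (pumps
    delivering pure solvent may be omitted).  Returns (C1_0, C2_0,
    equivalents); ratios are constant within a ramp, so any time works.
    """
    flows = ramp.pump_flows_start
    Q_tot = sum(flows.values())
    conc = {p: stock_concentrations.get(p, 0.0) * q / Q_tot for p, q in flows.items()}
    c1 = conc.get("P1", 0.0)
    c2 = conc.get("P3", 0.0)
    if c1 == 0.0 and c2 > 0.0:
        raise ConfigError("substrate inlet concentration is zero but the "
                          "nucleophile feed is active; equivalents undefined")
    equivalents = c2 / c1 if c1 > 0 else 0.0
    return c1, c2, equivalents


@dataclass(frozen=True)
class CampaignDesign:
    """Full-factorial transient campaign: one ramp per (equivalents,
    temperature) pair, identical flow program for all ramps."""

    geometry: ReactorGeometry = ReactorGeometry()
    thermal: ThermalExpansionModel = ThermalExpansionModel()
    Q_start: float = 10.0  # mL/min
    Q_end: float = 1.5  # mL/min
    alpha: float = 0.836  # mL/min^2
    injection_interval_min: float = 2.0
    hold_min: float = 2.0
    equivalents_levels: tuple[float, ...] = (1.5, 4.0, 7.0)
    temperatures_C: tuple[float, ...] = (30.0, 60.0, 90.0, 120.0)
    C1_stock: float = 0.4  # substrate stock (pump P1), M
    C2_stock: float = 2.0  # nucleophile stock (pump P3), M
    substrate_fraction: float = 0.25  # Q_P1 / Q_total, constant across ramps
    first_injection_at_onset: bool = True

    def stock_concentrations(self) -> dict[str, float]:
        return {"P1": self.C1_stock, "P3": self.C2_stock}

    @property
    def C1_0(self) -> float:
        return self.C1_stock * self.substrate_fraction

    def ramp_for(self, equivalents: float, temperature_C: float) -> RampProgram:
        """Solve the pump split delivering the requested molar equivalents
        at constant substrate fraction."""
        f1 = self.substrate_fraction
        f3 = equivalents * self.C1_0 / self.C2_stock
        f2 = 1.0 - f1 - f3
        if f3 < 0 or f2 < 0:
            raise ConfigError(
                f"equivalents level {equivalents} is unreachable with stocks "
                f"C1 = {self.C1_stock} M, C2 = {self.C2_stock} M"
            )
        return RampProgram(
            pump_flows_start={
                "P1": f1 * self.Q_start,
                "P2": f2 * self.Q_start,
                "P3": f3 * self.Q_start,
            },
            Q_end=self.Q_end,
            alpha=self.alpha,
            injection_interval_min=self.injection_interval_min,
            hold_min=self.hold_min,
            temperature_C=temperature_C,
            equivalents=equivalents,
            ramp_id=f"eq{equivalents:g}_T{temperature_C:g}",
        )

    def ramps(self) -> list[RampProgram]:
        return [
            self.ramp_for(eq, T)
            for eq in self.equivalents_levels
            for T in self.temperatures_C
        ]


def build_injection_schedule(design: CampaignDesign) -> list[SamplePoint]:
    """Scheduled injections for the whole campaign.

    Injections run from ramp onset (t = 0) every ``injection_interval_min``
    while the ramp is active, full factorial over equivalents and
    temperature levels.
    """
    points: list[SamplePoint] = []
    stocks = design.stock_concentrations()
    for ramp in design.ramps():
        duration_s = ramp.duration_min * 60.0
        if not math.isfinite(duration_s):
            raise ConfigError("ramps with alpha = 0 have no natural end; "
                              "injection schedule undefined")
        dt = ramp.injection_interval_min * 60.0
        c1, c2, eq = inlet_concentrations(ramp, stocks)
        T = ramp.temperature_K
        t0 = 0.0 if design.first_injection_at_onset else dt
        t = t0
        while t <= duration_s + 1e-9:
            tau = residence_time_of_sample(design.geometry, ramp, design.thermal, T, t)
            points.append(
                SamplePoint(
                    ramp_id=ramp.ramp_id,
                    t=t,
                    tau_res=tau,
                    T=T,
                    equivalents=eq,
                    inlet_concentrations={"1": c1, "2": c2},
                    Q_total=ramp.Q_total(t),
                )
            )
            t += dt
    return points
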