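"""Lumped-parameter (0D) resistance-compliance outlet boundary model.

Each airway outlet is one branch of an RC circuit: flow accumulating a
volume V against a compliance C while dropping pressure over a resistance
R.  The global circuit uses adult respiratory parameters
R_global = 7e-3 cmH2O.s/mL and C_global = 59 mL/cmH2O; per-outlet values
are distributed by outlet area within each lung and by the lung's static
volume fraction so that the outlet compliances sum to C_global and the
outlet resistances combine in parallel to R_global.

Units are fixed throughout: pressures in cmH2O, volumes in mL, time in
seconds, outlet areas in mm^2.

Sign convention: Eq-style driving pressure ``p_d = R_global Q + V/C_global``
is positive during inhalation (it is the magnitude of the pleural pressure
drop).  The standalone quasi-static network solver uses pleural pressure
``-p_d`` so that a single outlet with matched R and C sits at p = 0, and
applies the backflow stabilisation clamps (outlet pressure capped at 0,
outlet flux floored at 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("aerolung")

__all__ = [
    "GlobalRC",
    "Outlet",
    "OutletNetwork",
    "BreathingProfile",
    "inhaled_volume",
    "driving_pressure",
    "distribute_rc",
    "outlet_pressure",
    "simulate_0d",
]


@dataclass
class GlobalRC:
    """Global respiratory resistance and compliance (adult defaults)."""

    resistance: float = 7e-3   # cmH2O.s/mL
    compliance: float = 59.0   # mL/cmH2O
    p_atm: float = 0.0         # incompressible flow: atmospheric term drops

    def __post_init__(self):
        if self.resistance <= 0 or self.compliance <= 0:
            raise ValueError("R_global and C_global must be positive")


@dataclass
class Outlet:
    area: float                # mm^2
    lung: str
    resistance: float = 0.0
    compliance: float = 0.0
    flux: float = 0.0          # mL/s
    volume: float = 0.0        # mL
    pressure: float = 0.0      # cmH2O


@dataclass
class OutletNetwork:
    outlets: list[Outlet]
    alpha: dict[str, float]    # per-lung static volume fraction
    global_rc: GlobalRC = field(default_factory=GlobalRC)

    def __post_init__(self):
        if abs(sum(self.alpha.values()) - 1.0) > 1e-9:
            raise ValueError("lung volume fractions must sum to 1")
        for o in self.outlets:
            if o.area <= 0:
                raise ValueError("outlet areas must be positive")

    def lung_area(self, lung: str) -> float:
        return sum(o.area for o in self.outlets if o.lung == lung)


@dataclass
class BreathingProfile:
    """Inhaled-volume profile: sinusoidal tidal breath or constant flow.

    ``tidal``: V(t) = -(1/2)[V_T cos(2 pi t / T_B) - V_T] over one breath of
    duration T_B.  ``constant``: V(t) = V_T t / T_inhale with
    T_inhale = T_B/2 (breath-actuated nebuliser delivery).
    """

    kind: str
    tidal_volume: float        # mL
    breath_period: float       # s
    t_inhale: float | None = None

    def __post_init__(self):
        if self.kind not in ("tidal", "constant"):
            raise ValueError("kind must be 'tidal' or 'constant'")
        if self.tidal_volume <= 0 or self.breath_period <= 0:
            raise ValueError("V_T and T_B must be positive")
        if self.kind == "constant":
            if self.t_inhale is None:
                self.t_inhale = self.breath_period / 2
        else:
            self.t_inhale = self.breath_period / 2


def inhaled_volume(profile: BreathingProfile, t):
    """Inhaled volume V(t) [mL] and flow rate Q(t)=dV/dt [mL/s].

    Accepts scalars or arrays; t must lie in [0, T_B] for tidal profiles and
    [0, T_inhale] for constant-flow profiles.
    """
    t = np.asarray(t, dtype=float)
    vt, tb = profile.tidal_volume, profile.breath_period
    if profile.kind == "tidal":
        if np.any(t < 0) or np.any(t > tb + 1e-12):
            raise ValueError("t outside [0, T_B]")
        volume = -0.5 * (vt * np.cos(2 * np.pi * t / tb) - vt)
        flow = vt * np.pi / tb * np.sin(2 * np.pi * t / tb)
    else:
        ti = profile.t_inhale
        if np.any(t < 0) or np.any(t > ti + 1e-12):
            raise ValueError("t outside [0, T_inhale]")
        volume = vt * t / ti
        flow = np.broadcast_to(vt / ti, t.shape).copy()
    if t.ndim == 0:
        return float(volume), float(flow)
    return volume, flow


def driving_pressure(global_rc: GlobalRC, flow: float, volume: float) -> float:
    """Driving (pleural-drop) pressure ``p_d = R_global Q + V/C_global - p_atm``."""
    return global_rc.resistance * flow + volume / global_rc.compliance \
        - global_rc.p_atm


def distribute_rc(areas, lungs, alpha: dict[str, float],
                  global_rc: GlobalRC | None = None) -> OutletNetwork:
    """Distribute global R and C over outlets by area share and lung fraction.

    ``C_i = (A_i / A_L) alpha_L C_global`` and
    ``R_i = (A_L / (A_i alpha_L)) R_global`` — the unique grouping for which
    the outlet compliances sum to C_global and the outlet resistances
    combine in parallel to R_global for any outlet configuration.
    """
    global_rc = global_rc or GlobalRC()
    areas = np.asarray(areas, dtype=float)
    lungs = list(lungs)
    if len(areas) != len(lungs):
        raise ValueError("areas and lung labels must align")
    outlets = [Outlet(area=float(a), lung=l) for a, l in zip(areas, lungs)]
    net = OutletNetwork(outlets=outlets, alpha=dict(alpha), global_rc=global_rc)
    for lung in set(lungs):
        if net.lung_area(lung) <= 0:
            raise ValueError(f"zero total outlet area in lung {lung!r}")
    for o in net.outlets:
        a_l = net.lung_area(o.lung)
        al = net.alpha[o.lung]
        o.compliance = (o.area / a_l) * al * global_rc.compliance
        o.resistance = (a_l / (o.area * al)) * global_rc.resistance
    return net


def outlet_pressure(net: OutletNetwork, i: int, p_d: float,
                    clamp: bool = True) -> float:
    """Outlet pressure ``p_i = R_i phi_i + V_i/C_i + p_d`` with clamps.

    The backflow stabilisation sets the maximum pressure and minimum flux at
    each outlet to zero: ``p_i <- min(p_i, 0)`` and ``phi_i <- max(phi_i, 0)``
    (a negative candidate flux is clamped in place and logged).
    """
    o = net.outlets[i]
    if clamp and o.flux < 0:
        logger.info("outlet %d: negative flux %.3g clamped to 0", i, o.flux)
        o.flux = 0.0
    p = o.resistance * o.flux + o.volume / o.compliance + p_d
    if clamp:
        p = min(p, 0.0)
    o.pressure = p
    return p


def simulate_0d(net: OutletNetwork, profile: BreathingProfile, dt: float,
                t_end: float | None = None) -> pd.DataFrame:
    """Quasi-static 0D simulation of one inhalation.

    At each step the total inlet flow Q(t) is distributed across outlets by
    requiring a common junction pressure (the desk-scale surrogate for the
    3D solver's flux distribution): with pleural pressure ``-p_d`` the
    outlet fluxes are ``phi_i = (p_bar + p_d - V_i/C_i)/R_i`` with
    ``sum phi_i = Q``.  Volumes advance by forward Euler.  Flux conservation
    holds exactly at every step; total delivered volume converges to V_T at
    first order in dt.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    r = np.array([o.resistance for o in net.outlets])
    c = np.array([o.compliance for o in net.outlets])
    if np.any(r <= 0):
        raise ValueError("all outlet resistances must be positive")
    if t_end is None:
        t_end = profile.t_inhale
    times = np.arange(0.0, t_end + dt / 2, dt)
    vol = np.array([o.volume for o in net.outlets], dtype=float)
    inv_r = 1.0 / r
    rows = []
    for step, t in enumerate(times):
        v_tot, q = inhaled_volume(profile, min(t, t_end))
        p_d = driving_pressure(net.global_rc, q, v_tot)
        # common junction pressure from flux conservation
        p_bar = (q - p_d * inv_r.sum() + (vol / c * inv_r).sum()) / inv_r.sum()
        flux = (p_bar + p_d - vol / c) * inv_r
        # report Eq-14 pressure with pleural sign: p_i = R phi + V/C - p_d
        p_out = np.minimum(r * flux + vol / c - p_d, 0.0)
        row = {"t": t, "Q": q, "V": v_tot, "p_d": p_d}
        for j in range(len(net.outlets)):
            row[f"flux_{j}"] = flux[j]
            row[f"volume_{j}"] = vol[j]
            row[f"pressure_{j}"] = p_out[j]
        rows.append(row)
        if step < len(times) - 1:  # forward-Euler update over [t, t+dt)
            vol = vol + flux * dt
    for j, o in enumerate(net.outlets):
        o.volume = float(vol[j])
        o.flux = float(rows[-1][f"flux_{j}"])
        o.pressure = float(rows[-1][f"pressure_{j}"])
    return pd.DataFrame(rows)
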