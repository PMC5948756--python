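"""Gravitational settling of blood cells in a tall counting chamber.

Cells must reach the chamber floor before in-focus imaging, so the wait
time before counting is set by the settling velocity v and the chamber
height h_c: t_s = h_c / v.  The velocity follows Stokes' law on the
volume-equivalent sphere,

    r = (3 V_c / 4 pi)^(1/3),    v = 2 (rho_c - rho_m) g r^2 / (9 mu_m),

computed in SI and reported in μm/s.  With the default RBC parameters
(V_c = 90 μm^3, rho_c = 1.09 g/mL, rho_m = 1.04 g/mL, mu_m = 1.05 cP)
this formula gives ~0.80 μm/s; the instrument protocol's cited velocity
is 0.92 μm/s, which is kept as the default ``v_override`` so downstream
wait-time predictions match the protocol.  Both values are always
available and the discrepancy is logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable

from .config import ChamberSpec, SedimentationParams, StainingCondition
from .errors import SedimentationError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SedimentationResult:
    """Settling velocity, complete-sedimentation time, and arrival curve."""

    v: float  # μm/s
    t_s_s: float  # seconds
    t_s_min: float  # minutes
    settled_fraction_curve: Callable[[float], float]


def stokes_velocity(p: SedimentationParams) -> float:
    """First-principles Stokes settling velocity in μm/s (override ignored).

    Unit conversions: g/mL -> kg/m^3 (x1000), cP -> Pa.s (x1e-3),
    μm^3 -> m^3 (x1e-18); the SI result is returned in μm/s.  A negative
    density difference yields v <= 0 (flotation) with a warning.
    """
    if p.mu_m <= 0:
        raise ValidationError("mu_m", "must be > 0")
    r_m = (3.0 * p.v_c * 1e-18 / (4.0 * math.pi)) ** (1.0 / 3.0)
    delta_rho = (p.rho_c - p.rho_m) * 1000.0
    mu = p.mu_m * 1e-3
    v_m_s = 2.0 * delta_rho * p.g * r_m**2 / (9.0 * mu)
    v = v_m_s * 1e6
    if v <= 0:
        logger.warning("settling velocity %.3f μm/s <= 0: cells do not settle", v)
    return v


def settling_velocity(p: SedimentationParams | None = None) -> float:
    """Effective settling velocity (μm/s): ``v_override`` if set, else Stokes."""
    p = p or SedimentationParams()
    if p.v_override is not None:
        computed = stokes_velocity(p)
        if abs(computed - p.v_override) / max(abs(p.v_override), 1e-12) > 0.05:
            logger.info(
                "using v_override = %.2f μm/s (Stokes computation gives %.2f μm/s)",
                p.v_override, computed,
            )
        return float(p.v_override)
    return stokes_velocity(p)


def sedimentation_time(h_c: float, v: float) -> float:
    """Complete-sedimentation time t_s = h_c / v, in seconds."""
    if h_c <= 0:
        raise ValidationError("h_c", "must be > 0")
    if v <= 0:
        raise SedimentationError(f"settling velocity {v:.3g} μm/s <= 0: t_s undefined")
    return h_c / v


def settled_fraction(t: float, h_c: float, v: float) -> float:
    """Fraction of cells on the floor at time t, for uniform initial heights.

    Cells start uniformly distributed over [0, h_c] and descend at constant
    v, so arrivals are linear in time: min(1, v*t/h_c).
    """
    if t < 0:
        raise ValidationError("t", "must be >= 0")
    if h_c <= 0:
        raise ValidationError("h_c", "must be > 0")
    if v <= 0:
        raise SedimentationError("settling velocity <= 0")
    return min(1.0, v * t / h_c)


def predict(chamber: ChamberSpec | None = None, p: SedimentationParams | None = None) -> SedimentationResult:
    """Settling velocity and t_s for a chamber, with the arrival curve."""
    chamber = chamber or ChamberSpec()
    p = p or SedimentationParams()
    v = settling_velocity(p)
    t_s = sedimentation_time(chamber.h_c, v)
    return SedimentationResult(
        v=v,
        t_s_s=t_s,
        t_s_min=t_s / 60.0,
        settled_fraction_curve=lambda t, h=chamber.h_c, vv=v: settled_fraction(t, h, vv),
    )


def plan_wait_time(
    chamber: ChamberSpec | None = None,
    p: SedimentationParams | None = None,
    extra: StainingCondition | None = None,
) -> float:
    """Recommended minutes before imaging: max(t_s, staining time t_i).

    Imaging must wait for both complete sedimentation and the staining
    incubation; with the default protocol (v = 0.92 μm/s, h_c = 532 μm,
    t_i = 10 min) staining dominates and the answer is 10 min.
    """
    chamber = chamber or ChamberSpec()
    extra = extra or StainingCondition()
    result = predict(chamber, p)
    return max(result.t_s_min, extra.t_i)
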