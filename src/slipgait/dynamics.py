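"""Roller-foot bipedal spring-mass walking dynamics.

The model is a point mass (the body centre of mass, CoM) riding on two
massless linear leg springs.  Each foot is a circular roller of radius
``r0`` that rolls on the ground without slipping, so the centre of
pressure travels forward during stance.  Everything here is
dimensionless: mass, leg length and gravity are scaled to one, so forces
are in body weights, lengths in leg lengths and time in units of
``sqrt(l0/g)``.

Coordinates and conventions
---------------------------
``x`` points in the walking direction, ``y`` up.  A leg's angle ``phi``
is measured from the vertical and is negative while the foot is ahead of
the CoM; the touchdown angle ``phi_TD`` is therefore negative, and the
trailing leg has positive angle at foot-off.  The spring of an active
leg acts between the CoM and the roller centre with rest length
``1 - r0``; the roller centre sits at height ``r0`` and its abscissa
advances by ``r0 * (phi - phi_TD)`` from the touchdown contact point
(rolling without slipping).

Hybrid events
-------------
* FC (foot contact): during single support, when the CoM height drops to
  ``r0 + (1 - r0) * cos(phi_TD)`` the swing leg is placed at the
  touchdown angle with zero compression and double support begins.  A
  short reactivation delay after each foot-off stands in for the swing
  phase of the massless leg.
* FO (foot off): double support ends when the trailing spring returns to
  rest length (compression ``s <= 0``).
* VLC (vertical leg condition): the stance leg passing through vertical;
  one "step" runs from one VLC to the next and the VLC is also the
  Poincare section used by :mod:`slipgait.limit_cycle`.

Integration is fixed-step classical Runge-Kutta with bisection
refinement of every event time; the system is conservative, so total
mechanical energy is a sharp correctness diagnostic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from numba import njit

DEFAULT_ROLLER_RADIUS = 0.3
DEFAULT_SWING_DELAY = 0.05
DEFAULT_DT = 1e-3
DEFAULT_MAX_TIME = 8.0
EVENT_TOL = 1e-9
NEWTON_TOL = 1e-10

# termination status codes of the step kernel
STATUS_OK = 0
STATUS_FALL = 1
STATUS_STALL = 2
STATUS_TIMEOUT = 3
STATUS_EVENT_ORDER = 4

STATUS_LABELS = {
    STATUS_OK: "ok",
    STATUS_FALL: "fall",
    STATUS_STALL: "stall",
    STATUS_TIMEOUT: "timeout",
    STATUS_EVENT_ORDER: "event-order",
}

EVENT_NAMES = {1: "FC", 2: "FO", 3: "VLC"}


class InvalidStateError(ValueError):
    """A simulation state violates the model's validity assumptions."""


class GeometryError(RuntimeError):
    """Leg geometry could not be solved (Newton iteration failed)."""


class IntegrationError(RuntimeError):
    """The hybrid event sequence was violated during integration."""


@dataclass(frozen=True)
class NormalizedParameters:
    """Dimensionless configuration that fully determines one simulation.

    Parameters
    ----------
    leg_stiffness : float
        Spring stiffness ``k0`` in units of body weight per leg length.
    touchdown_angle : float
        Touchdown angle ``phi_TD`` in radians (negative: foot lands ahead
        of the CoM).
    roller_radius : float
        Roller-foot radius ``r0`` in leg lengths, ``0 <= r0 < 1``.
        ``r0 = 0`` reduces the model to the point-foot template.
    swing_delay : float
        Dimensionless time after foot-off before the swung leg may touch
        down again.
    """

    leg_stiffness: float
    touchdown_angle: float
    roller_radius: float = DEFAULT_ROLLER_RADIUS
    swing_delay: float = DEFAULT_SWING_DELAY
    mass: float = 1.0
    leg_length: float = 1.0
    gravity: float = 1.0

    def __post_init__(self) -> None:
        if not (self.mass == 1.0 and self.leg_length == 1.0 and self.gravity == 1.0):
            raise ValueError("mass, leg_length and gravity are fixed to 1 "
                             "by the normalization convention")
        if self.leg_stiffness <= 0:
            raise ValueError(f"leg_stiffness must be positive, got {self.leg_stiffness}")
        if not 0.0 <= self.roller_radius < 1.0:
            raise ValueError(f"roller_radius must be in [0, 1), got {self.roller_radius}")
        if self.swing_delay < 0:
            raise ValueError("swing_delay must be non-negative")

    @property
    def contact_threshold(self) -> float:
        """CoM height below which the swing leg can engage the ground."""
        r0 = self.roller_radius
        return r0 + (1.0 - r0) * math.cos(self.touchdown_angle)


@dataclass(frozen=True)
class LegState:
    """Geometry of one leg at an instant."""

    active: bool
    compression: float
    angle: float
    roller_center: Tuple[float, float]
    contact_point_x: float


@dataclass(frozen=True)
class SimulationState:
    """CoM state plus per-leg geometry at one instant."""

    time: float
    com_position: Tuple[float, float]
    com_velocity: Tuple[float, float]
    legs: Tuple[LegState, LegState]

    @property
    def valid(self) -> bool:
        return self.com_position[1] > 0 and self.com_velocity[0] > 0


# ---------------------------------------------------------------------------
# Jitted kernels


@njit(cache=True)
def _solve_phi(x, y, a, r0, phi_td, phi0):
    """Newton solve for the leg angle of an active rolling foot.

    Residual: the roller-centre abscissa implied by the leg orientation,
    ``x - L(phi) * sin(phi)`` with ``L = (y - r0)/cos(phi)``, must equal
    the rolling abscissa ``a + r0*(phi - phi_td)``.  The derivative
    ``-( (y-r0)/cos^2 phi + r0 )`` is strictly negative, so the iteration
    is monotone and converges in a handful of steps.
    """
    phi = phi0
    for _ in range(100):
        c = math.cos(phi)
        if c < 1e-6:
            return phi, False
        ym = y - r0
        f = x - ym / c * math.sin(phi) - a - r0 * (phi - phi_td)
        fp = -(ym / (c * c) + r0)
        d = f / fp
        phi -= d
        if -1e-11 < d < 1e-11:
            return phi, True
    return phi, False


@njit(cache=True)
def _leg_vals(x, y, a, p_guess, r0, phi_td):
    """(angle, compression, contact abscissa, converged) of an active leg."""
    p, ok = _solve_phi(x, y, a, r0, phi_td, p_guess)
    s = (1.0 - r0) - (y - r0) / math.cos(p)
    cop = a + r0 * (p - phi_td)
    return p, s, cop, ok


@njit(cache=True)
def _accel(x, y, b1, a1, p1, b2, a2, p2, k, phi_td, r0):
    """CoM acceleration from gravity and the active leg springs.

    The equations of motion are the Lagrangian (gradient) form: each
    spring contributes ``-k * s * grad(s)`` with the gradient taken with
    respect to the CoM coordinates under the rolling constraint.  That
    force is directed along the line from the ground contact point to
    the CoM (it degenerates to the leg axis for a point foot), which
    keeps the hybrid dynamics exactly conservative.  A spring whose
    computed compression is negative is force-clamped to zero (a leg can
    never pull on the ground).
    """
    ax = 0.0
    ay = -1.0
    ok = True
    if b1:
        p1n, c1 = _solve_phi(x, y, a1, r0, phi_td, p1)
        if not c1:
            ok = False
        p1 = p1n
        c = math.cos(p1)
        L = (y - r0) / c
        s = (1.0 - r0) - L
        if s > 0.0:
            f = k * s / (L + r0 * c)
            ax += f * L * math.sin(p1)
            ay += f * (r0 + L * c)
    if b2:
        p2n, c2 = _solve_phi(x, y, a2, r0, phi_td, p2)
        if not c2:
            ok = False
        p2 = p2n
        c = math.cos(p2)
        L = (y - r0) / c
        s = (1.0 - r0) - L
        if s > 0.0:
            f = k * s / (L + r0 * c)
            ax += f * L * math.sin(p2)
            ay += f * (r0 + L * c)
    return ax, ay, p1, p2, ok


@njit(cache=True)
def _rk4(x, y, vx, vy, h, b1, a1, p1, b2, a2, p2, k, phi_td, r0):
    """One classical Runge-Kutta step of size ``h``."""
    ax1, ay1, p1, p2, o1 = _accel(x, y, b1, a1, p1, b2, a2, p2, k, phi_td, r0)
    x2 = x + 0.5 * h * vx
    y2 = y + 0.5 * h * vy
    vx2 = vx + 0.5 * h * ax1
    vy2 = vy + 0.5 * h * ay1
    ax2, ay2, p1, p2, o2 = _accel(x2, y2, b1, a1, p1, b2, a2, p2, k, phi_td, r0)
    x3 = x + 0.5 * h * vx2
    y3 = y + 0.5 * h * vy2
    vx3 = vx + 0.5 * h * ax2
    vy3 = vy + 0.5 * h * ay2
    ax3, ay3, p1, p2, o3 = _accel(x3, y3, b1, a1, p1, b2, a2, p2, k, phi_td, r0)
    x4 = x + h * vx3
    y4 = y + h * vy3
    vx4 = vx + h * ax3
    vy4 = vy + h * ay3
    ax4, ay4, p1, p2, o4 = _accel(x4, y4, b1, a1, p1, b2, a2, p2, k, phi_td, r0)
    xn = x + h * (vx + 2.0 * (vx2 + vx3) + vx4) / 6.0
    yn = y + h * (vy + 2.0 * (vy2 + vy3) + vy4) / 6.0
    vxn = vx + h * (ax1 + 2.0 * (ax2 + ax3) + ax4) / 6.0
    vyn = vy + h * (ay1 + 2.0 * (ay2 + ay3) + ay4) / 6.0
    return xn, yn, vxn, vyn, p1, p2, (o1 and o2 and o3 and o4)


@njit(cache=True)
def _step_kernel(y0, vx0, k, phi_td, r0, delay, dt, max_time, record, rec, ev):
    """Integrate one full step: VLC -> FC -> FO -> next VLC.

    Starts at the vertical-leg condition (leg 1 vertical, single support,
    vertical CoM speed zero is the caller's responsibility via vy0 = 0).
    Events are refined by bisection to |residual| < 1e-9.

    ``rec`` (n, 13) receives rows (t, x, y, vx, vy, b1, phi1, s1, cop1,
    b2, phi2, s2, cop2) when ``record``; ``ev`` (8, 2) receives
    (time, code) with codes 1=FC, 2=FO, 3=VLC.

    Returns (status, n_rows, n_events, y, vx, vy, ts, ls, t_fc, t_fo).
    """
    x = 0.0
    y = y0
    vx = vx0
    vy = 0.0
    b1 = True
    a1 = r0 * phi_td
    p1 = 0.0
    b2 = False
    a2 = 0.0
    p2 = phi_td
    thr = r0 + (1.0 - r0) * math.cos(phi_td)
    arm = delay
    t = 0.0
    t_fc = -1.0
    t_fo = -1.0
    phase = 0  # 0 single support pre-FC, 1 double support, 2 single support pre-VLC
    nev = 0
    n = 0
    nmax = rec.shape[0]
    status = STATUS_OK

    if record:
        p1v, s1v, c1v, _ = _leg_vals(x, y, a1, p1, r0, phi_td)
        rec[n, 0] = t
        rec[n, 1] = x
        rec[n, 2] = y
        rec[n, 3] = vx
        rec[n, 4] = vy
        rec[n, 5] = 1.0
        rec[n, 6] = p1v
        rec[n, 7] = s1v
        rec[n, 8] = c1v
        rec[n, 9] = 0.0
        rec[n, 10] = 0.0
        rec[n, 11] = 0.0
        rec[n, 12] = np.nan
        n += 1

    g_fc = y - thr
    g_fo = 0.0
    g_vlc = 0.0

    while True:
        if y - r0 <= 1e-9:
            status = STATUS_FALL
            break
        if vx <= 0.0:
            status = STATUS_STALL
            break
        if t >= max_time or (record and n >= nmax - 2):
            status = STATUS_TIMEOUT
            break

        xn, yn, vxn, vyn, p1, p2, ok = _rk4(
            x, y, vx, vy, dt, b1, a1, p1, b2, a2, p2, k, phi_td, r0)
        if not ok:
            status = STATUS_EVENT_ORDER
            break

        event = 0
        if phase == 0:
            g_new = yn - thr
            if g_fc > 0.0 and g_new <= 0.0 and t + dt >= arm:
                event = 1
            g_fc = g_new
        elif phase == 1:
            _, s1n, _, ok1 = _leg_vals(xn, yn, a1, p1, r0, phi_td)
            if not ok1:
                status = STATUS_EVENT_ORDER
                break
            g_new = s1n
            if g_fo > 0.0 and g_new <= 0.0:
                event = 2
            g_fo = g_new
        else:
            p2n, _, _, ok2 = _leg_vals(xn, yn, a2, p2, r0, phi_td)
            if not ok2:
                status = STATUS_EVENT_ORDER
                break
            gf_new = yn - thr
            if g_vlc < 0.0 and p2n >= 0.0:
                event = 3
            elif g_fc > 0.0 and gf_new <= 0.0 and t + dt >= arm:
                # a second foot contact before the stance leg reaches
                # vertical breaks the assumed FC -> FO -> VLC ordering
                status = STATUS_EVENT_ORDER
                break
            g_vlc = p2n
            g_fc = gf_new

        if event == 0:
            x, y, vx, vy = xn, yn, vxn, vyn
            t += dt
            if record:
                rec[n, 0] = t
                rec[n, 1] = x
                rec[n, 2] = y
                rec[n, 3] = vx
                rec[n, 4] = vy
                if b1:
                    p1v, s1v, c1v, _ = _leg_vals(x, y, a1, p1, r0, phi_td)
                    rec[n, 5] = 1.0
                    rec[n, 6] = p1v
                    rec[n, 7] = s1v
                    rec[n, 8] = c1v
                else:
                    rec[n, 5] = 0.0
                    rec[n, 6] = 0.0
                    rec[n, 7] = 0.0
                    rec[n, 8] = np.nan
                if b2:
                    p2v, s2v, c2v, _ = _leg_vals(x, y, a2, p2, r0, phi_td)
                    rec[n, 9] = 1.0
                    rec[n, 10] = p2v
                    rec[n, 11] = s2v
                    rec[n, 12] = c2v
                else:
                    rec[n, 9] = 0.0
                    rec[n, 10] = 0.0
                    rec[n, 11] = 0.0
                    rec[n, 12] = np.nan
                n += 1
            continue

        # --- bisection refinement of the event time within [t, t + dt]
        lo = 0.0
        hi = dt
        if event == 1:
            glo = (y - thr)
        elif event == 2:
            _, s1c, _, _ = _leg_vals(x, y, a1, p1, r0, phi_td)
            glo = s1c
        else:
            p2c, _, _, _ = _leg_vals(x, y, a2, p2, r0, phi_td)
            glo = p2c
        xm, ym, vxm, vym = xn, yn, vxn, vyn
        mid = dt
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            xm, ym, vxm, vym, p1m, p2m, okm = _rk4(
                x, y, vx, vy, mid, b1, a1, p1, b2, a2, p2, k, phi_td, r0)
            if event == 1:
                g = ym - thr
            elif event == 2:
                _, s1m, _, _ = _leg_vals(xm, ym, a1, p1m, r0, phi_td)
                g = s1m
            else:
                p2s, _, _, _ = _leg_vals(xm, ym, a2, p2m, r0, phi_td)
                g = p2s
            if (-EVENT_TOL < g < EVENT_TOL) or (hi - lo) < 1e-14:
                break
            if (g > 0.0) == (glo > 0.0):
                lo = mid
                glo = g
            else:
                hi = mid
        x, y, vx, vy = xm, ym, vxm, vym
        t += mid

        if event == 1:  # foot contact of the leading leg
            t_fc = t
            b2 = True
            a2 = x - (1.0 - r0) * math.sin(phi_td)
            p2 = phi_td
            phase = 1
            if nev < ev.shape[0]:
                ev[nev, 0] = t
                ev[nev, 1] = 1.0
                nev += 1
            _, g_fo, _, _ = _leg_vals(x, y, a1, p1, r0, phi_td)
            if g_fo <= 0.0:
                # trailing spring already at rest length: immediate FO
                event = 2

        if event == 2:  # foot off of the trailing leg
            t_fo = t
            b1 = False
            arm = t + delay
            phase = 2
            if nev < ev.shape[0]:
                ev[nev, 0] = t
                ev[nev, 1] = 2.0
                nev += 1
            p2v, _, _, ok2 = _leg_vals(x, y, a2, p2, r0, phi_td)
            if not ok2 or p2v >= 0.0:
                status = STATUS_EVENT_ORDER
                break
            g_vlc = p2v
            g_fc = y - thr

        if record:
            rec[n, 0] = t
            rec[n, 1] = x
            rec[n, 2] = y
            rec[n, 3] = vx
            rec[n, 4] = vy
            if b1:
                p1v, s1v, c1v, _ = _leg_vals(x, y, a1, p1, r0, phi_td)
                rec[n, 5] = 1.0
                rec[n, 6] = p1v
                rec[n, 7] = s1v
                rec[n, 8] = c1v
            else:
                rec[n, 5] = 0.0
                rec[n, 6] = 0.0
                rec[n, 7] = 0.0
                rec[n, 8] = np.nan
            if b2:
                p2v, s2v, c2v, _ = _leg_vals(x, y, a2, p2, r0, phi_td)
                rec[n, 9] = 1.0
                rec[n, 10] = p2v
                rec[n, 11] = s2v
                rec[n, 12] = c2v
            else:
                rec[n, 9] = 0.0
                rec[n, 10] = 0.0
                rec[n, 11] = 0.0
                rec[n, 12] = np.nan
            n += 1

        if event == 3:  # vertical leg condition: step complete
            if nev < ev.shape[0]:
                ev[nev, 0] = t
                ev[nev, 1] = 3.0
                nev += 1
            status = STATUS_OK
            break

    return status, n, nev, y, vx, vy, t, x, t_fc, t_fo


_DUMMY_REC = np.empty((1, 13))
_DUMMY_EV = np.empty((8, 2))


def poincare_return(y0: float, vx0: float, params: NormalizedParameters,
                    dt: float = DEFAULT_DT,
                    max_time: float = DEFAULT_MAX_TIME):
    """Fast one-step return without trajectory recording.

    Returns ``(status, yR, vxR, vyR, ts, ls, t_fc, t_fo)``.
    """
    ev = np.empty((8, 2))
    status, _, _, y, vx, vy, ts, ls, t_fc, t_fo = _step_kernel(
        y0, vx0, params.leg_stiffness, params.touchdown_angle,
        params.roller_radius, params.swing_delay, dt, max_time,
        False, _DUMMY_REC, ev)
    return status, y, vx, vy, ts, ls, t_fc, t_fo


# ---------------------------------------------------------------------------
# Python-level operations


def solve_leg_geometry(com_position, contact_x: float,
                       params: NormalizedParameters,
                       angle_guess: Optional[float] = None) -> LegState:
    """Leg angle and compression consistent with the rolling-foot kinematics.

    ``contact_x`` is the contact abscissa recorded at this leg's touchdown.
    The roller centre sits at height ``r0`` with abscissa advanced by
    ``r0 * (phi - phi_TD)``; compression is rest length ``1 - r0`` minus
    the CoM-to-centre distance.
    """
    x, y = float(com_position[0]), float(com_position[1])
    r0 = params.roller_radius
    if y <= r0:
        raise InvalidStateError(f"CoM height {y} is not above the roller centre plane")
    guess = params.touchdown_angle if angle_guess is None else angle_guess
    phi, s, cop, ok = _leg_vals(x, y, contact_x, guess, r0, params.touchdown_angle)
    if not ok:
        raise GeometryError(
            f"leg-geometry Newton iteration did not converge (com=({x}, {y}), "
            f"contact_x={contact_x})")
    center = (cop, r0)
    return LegState(active=True, compression=s, angle=phi,
                    roller_center=center, contact_point_x=cop)


def grf_from_leg(leg: LegState, params: NormalizedParameters) -> Tuple[float, float]:
    """(vertical, anteroposterior) ground reaction force of one leg.

    The reaction is the spring force actually transmitted to the CoM,
    i.e. ``k0 * s`` times the gradient of the compression: it acts along
    the line from the ground contact point to the CoM.  For a point foot
    this is the familiar axial decomposition (vertical with the cosine
    of the leg inclination, anteroposterior with the sine, negative
    while braking).  The anteroposterior component is positive while
    propelling.  Moments about the roller centre are deliberately not
    translated to the centre of pressure.
    """
    if not leg.active or leg.compression <= 0.0:
        return (0.0, 0.0)
    r0 = params.roller_radius
    L = (1.0 - r0) - leg.compression
    c = math.cos(leg.angle)
    f = params.leg_stiffness * leg.compression / (L + r0 * c)
    return (f * (r0 + L * c), f * L * math.sin(leg.angle))


def accelerations(state: SimulationState,
                  params: NormalizedParameters) -> np.ndarray:
    """Dimensionless CoM acceleration under gravity and active leg springs."""
    r0 = params.roller_radius
    x, y = state.com_position
    acc = np.array([0.0, -1.0])
    for leg in state.legs:
        if not leg.active:
            continue
        cx, cy = leg.roller_center
        if abs(cy - r0) > 1e-9:
            raise InvalidStateError(
                f"active leg roller centre at height {cy}, expected {r0}")
        L = math.hypot(x - cx, y - cy)
        expected = (1.0 - r0) - leg.compression
        if abs(L - expected) > 1e-6:
            raise InvalidStateError(
                "leg geometry inconsistent with stored compression "
                f"(distance {L}, expected {expected})")
        if leg.compression > 0.0 and L > 0.0:
            # gradient force: along contact point -> CoM
            f = params.leg_stiffness * leg.compression * L / (L * L + r0 * (y - r0))
            acc += f * np.array([x - leg.contact_point_x, y])
    return acc


def check_foot_contact(state: SimulationState, params: NormalizedParameters,
                       time_since_foot_off: Optional[float] = None) -> bool:
    """Touchdown condition of the swing leg during single support.

    True when the CoM height has dropped to
    ``r0 + (1 - r0)*cos(phi_TD)`` and, if ``time_since_foot_off`` is
    given, the swing leg is past its reactivation delay.
    """
    if time_since_foot_off is not None and time_since_foot_off < params.swing_delay:
        return False
    return state.com_position[1] <= params.contact_threshold


def check_foot_off(state: SimulationState, trailing: LegState) -> bool:
    """Trailing-leg release: its spring is back at rest length (s <= 0)."""
    return trailing.compression <= 0.0


def vlc_state(y0: float, vx0: float,
              params: NormalizedParameters) -> SimulationState:
    """Canonical vertical-leg-condition state (the Poincare embedding).

    Single support on leg 1 standing exactly vertical with compression
    ``1 - y0``, zero vertical CoM speed and forward speed ``vx0``.
    """
    r0 = params.roller_radius
    if not (r0 < y0 <= 1.0):
        raise InvalidStateError(
            f"VLC CoM height must lie in ({r0}, 1], got {y0}")
    if vx0 <= 0:
        raise InvalidStateError(f"forward speed must be positive, got {vx0}")
    s = 1.0 - y0
    stance = LegState(active=True, compression=s, angle=0.0,
                      roller_center=(0.0, r0), contact_point_x=0.0)
    swing = LegState(active=False, compression=0.0, angle=params.touchdown_angle,
                     roller_center=(math.nan, math.nan), contact_point_x=math.nan)
    return SimulationState(time=0.0, com_position=(0.0, y0),
                           com_velocity=(vx0, 0.0), legs=(stance, swing))


@dataclass
class Trajectory:
    """One simulated step sampled on the integration grid.

    Arrays run from the initial VLC to the next VLC (or to the failure
    point).  Per-leg force series are derived from the recorded spring
    compressions and angles; leg 1 is the initial stance leg, leg 2 the
    leg that touches down during the step.
    """

    params: NormalizedParameters
    dt: float
    status: int
    time: np.ndarray
    com_position: np.ndarray      # (n, 2)
    com_velocity: np.ndarray      # (n, 2)
    leg_active: np.ndarray        # (n, 2) 0/1
    leg_angle: np.ndarray         # (n, 2)
    leg_compression: np.ndarray   # (n, 2)
    cop_x: np.ndarray             # (n, 2), nan while airborne
    events: list                  # [(time, "FC"|"FO"|"VLC"), ...]
    step_duration: float
    step_length: float
    t_fc: float
    t_fo: float
    final_state: Tuple[float, float, float]  # (y, vx, vy)

    @property
    def failed(self) -> bool:
        return self.status != STATUS_OK

    @property
    def status_label(self) -> str:
        return STATUS_LABELS.get(self.status, str(self.status))

    @property
    def contact_time(self) -> float:
        """Per-leg ground contact FC -> FO, using step periodicity."""
        if self.failed or self.t_fc < 0 or self.t_fo < 0:
            return math.nan
        return self.step_duration + self.t_fo - self.t_fc

    @property
    def grf_legs(self) -> np.ndarray:
        """(n, 2, 2) array of per-leg (vertical, anteroposterior) force."""
        k = self.params.leg_stiffness
        r0 = self.params.roller_radius
        s = np.maximum(self.leg_compression, 0.0) * self.leg_active
        L = (1.0 - r0) - self.leg_compression
        c = np.cos(self.leg_angle)
        f = k * s / (L + r0 * c)
        out = np.empty(self.leg_angle.shape + (2,))
        out[:, :, 0] = f * (r0 + L * c)
        out[:, :, 1] = f * L * np.sin(self.leg_angle)
        return out

    @property
    def grf_total(self) -> np.ndarray:
        """(n, 2) summed (vertical, anteroposterior) force."""
        return self.grf_legs.sum(axis=1)

    def energy(self) -> np.ndarray:
        """Total mechanical energy along the trajectory (conserved)."""
        k = self.params.leg_stiffness
        kin = 0.5 * (self.com_velocity**2).sum(axis=1)
        pot = self.com_position[:, 1]
        s = np.maximum(self.leg_compression, 0.0) * self.leg_active
        spring = 0.5 * k * (s**2).sum(axis=1)
        return kin + pot + spring

    def states(self) -> Sequence[SimulationState]:
        """Materialize :class:`SimulationState` objects (for inspection)."""
        r0 = self.params.roller_radius
        out = []
        for i in range(self.time.size):
            legs = tuple(
                LegState(
                    active=bool(self.leg_active[i, j]),
                    compression=float(self.leg_compression[i, j]),
                    angle=float(self.leg_angle[i, j]),
                    roller_center=(float(self.cop_x[i, j]), r0)
                    if self.leg_active[i, j] else (math.nan, math.nan),
                    contact_point_x=float(self.cop_x[i, j]),
                )
                for j in (0, 1))
            out.append(SimulationState(
                time=float(self.time[i]),
                com_position=tuple(self.com_position[i]),
                com_velocity=tuple(self.com_velocity[i]),
                legs=legs))
        return out

    def stance_curves(self):
        """GRF and CoP over one full ground contact of one leg.

        Assembled from the periodic step: leg 2 from its touchdown to the
        end of the step, continued by leg 1's recorded first part shifted
        one period (one step length forward, one step duration later).
        Returns ``(tau, fv, fap, cop_x)`` with ``tau`` starting at 0 at
        foot contact and ending at the contact time.
        """
        if self.failed:
            raise IntegrationError("stance assembly requires a completed step")
        grf = self.grf_legs
        t = self.time
        ts = self.step_duration
        mask2 = (t >= self.t_fc - 1e-12) & (self.leg_active[:, 1] > 0)
        tau_a = t[mask2] - self.t_fc
        fv_a = grf[mask2, 1, 0]
        fap_a = grf[mask2, 1, 1]
        cop_a = self.cop_x[mask2, 1]
        mask1 = (t <= self.t_fo + 1e-12) & (self.leg_active[:, 0] > 0)
        tau_b = (ts - self.t_fc) + t[mask1]
        fv_b = grf[mask1, 0, 0]
        fap_b = grf[mask1, 0, 1]
        cop_b = self.cop_x[mask1, 0] + self.step_length
        if tau_b.size and tau_a.size and abs(tau_b[0] - tau_a[-1]) < 1e-12:
            tau_b = tau_b[1:]
            fv_b = fv_b[1:]
            fap_b = fap_b[1:]
            cop_b = cop_b[1:]
        tau = np.concatenate([tau_a, tau_b])
        fv = np.concatenate([fv_a, fv_b])
        fap = np.concatenate([fap_a, fap_b])
        cop = np.concatenate([cop_a, cop_b])
        order = np.argsort(tau, kind="stable")
        return tau[order], fv[order], fap[order], cop[order]

    # -- serialization ------------------------------------------------------

    def to_csv(self, path, sidecar: bool = True) -> None:
        """Write the trajectory as CSV plus a JSON parameter sidecar."""
        import pandas as pd

        grf = self.grf_legs
        total = grf.sum(axis=1)
        event_col = np.full(self.time.size, "", dtype=object)
        for t_ev, kind in self.events:
            i = int(np.argmin(np.abs(self.time - t_ev)))
            event_col[i] = kind if not event_col[i] else event_col[i] + "+" + kind
        df = pd.DataFrame({
            "time": self.time,
            "x0": self.com_position[:, 0],
            "y0": self.com_position[:, 1],
            "xd0": self.com_velocity[:, 0],
            "yd0": self.com_velocity[:, 1],
            "Fv_leg1": grf[:, 0, 0],
            "Fap_leg1": grf[:, 0, 1],
            "Fv_leg2": grf[:, 1, 0],
            "Fap_leg2": grf[:, 1, 1],
            "Fv_total": total[:, 0],
            "Fap_total": total[:, 1],
            "cop_x_leg1": self.cop_x[:, 0],
            "cop_x_leg2": self.cop_x[:, 1],
            "event": event_col,
        })
        df.to_csv(path, index=False)
        if sidecar:
            meta = {
                "parameters": {
                    "leg_stiffness": self.params.leg_stiffness,
                    "touchdown_angle": self.params.touchdown_angle,
                    "roller_radius": self.params.roller_radius,
                    "swing_delay": self.params.swing_delay,
                },
                "dt": self.dt,
                "status": self.status_label,
                "events": [[t, kind] for t, kind in self.events],
                "step_duration": self.step_duration,
                "step_length": self.step_length,
            }
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh, indent=2)


def simulate_step(initial, params: NormalizedParameters,
                  dt: float = DEFAULT_DT,
                  max_time: float = DEFAULT_MAX_TIME) -> Trajectory:
    """Simulate one full step (VLC to VLC) with trajectory recording.

    ``initial`` is either a :class:`SimulationState` at the vertical-leg
    condition (as built by :func:`vlc_state`) or a ``(y0, vx0)`` pair.
    The returned trajectory carries a failure status instead of raising
    when locomotion becomes invalid (fall or stall).
    """
    if isinstance(initial, SimulationState):
        stance = initial.legs[0]
        if not stance.active or abs(stance.angle) > 1e-9 or initial.legs[1].active:
            raise InvalidStateError(
                "simulate_step expects single support with leg 1 vertical")
        if abs(initial.com_velocity[1]) > 1e-12:
            raise InvalidStateError("vertical CoM speed must be zero at the VLC")
        y0 = float(initial.com_position[1])
        vx0 = float(initial.com_velocity[0])
    else:
        y0, vx0 = float(initial[0]), float(initial[1])
    if dt <= 0:
        raise ValueError("dt must be positive")
    nmax = int(max_time / dt) + 16
    rec = np.empty((nmax, 13))
    ev = np.empty((8, 2))
    status, n, nev, y, vx, vy, ts, ls, t_fc, t_fo = _step_kernel(
        y0, vx0, params.leg_stiffness, params.touchdown_angle,
        params.roller_radius, params.swing_delay, dt, max_time,
        True, rec, ev)
    rows = rec[:n]
    events = [(float(ev[i, 0]), EVENT_NAMES[int(ev[i, 1])]) for i in range(nev)]
    return Trajectory(
        params=params, dt=dt, status=status,
        time=rows[:, 0].copy(),
        com_position=rows[:, 1:3].copy(),
        com_velocity=rows[:, 3:5].copy(),
        leg_active=rows[:, [5, 9]].copy(),
        leg_angle=rows[:, [6, 10]].copy(),
        leg_compression=rows[:, [7, 11]].copy(),
        cop_x=rows[:, [8, 12]].copy(),
        events=events,
        step_duration=ts if status == STATUS_OK else math.nan,
        step_length=ls if status == STATUS_OK else math.nan,
        t_fc=t_fc, t_fo=t_fo,
        final_state=(y, vx, vy))
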