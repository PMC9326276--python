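"""Periodic walking solutions on the Poincare section.

A step of the roller-foot spring-mass walker maps the state at one
vertical-leg condition (VLC) to the state at the next.  With energy
conserved and the vertical CoM speed set to zero on the section, the
Poincare state is ``zp = (y0, xdot0)`` -- CoM height and forward speed.
A configuration is periodic when the return deviation
``dzp = |zp_R - zp_0|`` stays below a small limit (1e-3 by default).

The search space is spanned by three dimensionless quantities:

* ``v_G0`` -- initial gait speed, coupled to the touchdown angle by the
  linear relation ``phi_TD = -0.262 v_G0 - 0.180``;
* ``F_v_min0`` -- vertical-GRF trough value at the VLC, which encodes the
  initial CoM height via ``F = k * (1 - y0)``;
* ``p_phi_k`` -- step parameter scaling the leg stiffness through
  ``k = p / ((1 - r0) * sin^2 phi_TD)``.

Two parameter constraints reduce the sweep to a 2-D lattice: constraint V
fixes ``v_G0`` (kinematic match to a subject), constraint F fixes
``F_v_min0`` (kinetic match).  Among converged lattice points the walker
configuration is chosen by local stability, a preference for the common
two-peak ("double hump") vertical GRF pattern and maximal step length.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

from .dynamics import (
    DEFAULT_DT,
    DEFAULT_MAX_TIME,
    DEFAULT_ROLLER_RADIUS,
    DEFAULT_SWING_DELAY,
    STATUS_OK,
    NormalizedParameters,
    SimulationState,
    Trajectory,
    poincare_return,
    simulate_step,
    vlc_state,
)

logger = logging.getLogger(__name__)

#: convergence limit on the Poincare return deviation
DELTA_ZP_LIM = 1e-3

#: finite-difference perturbation for the return-map Jacobian
STABILITY_EPS = 1e-4

#: margin below unit magnitude for the stability flag
STABILITY_TOL = 1e-3

#: Table-style search domains of the three sweep parameters
V_G0_DOMAIN = (0.15, 0.8)
F_V_MIN0_DOMAIN = (0.0, 1.2)   # open at 0
P_PHI_K_DOMAIN = (0.0, 10.5)   # open at 0

#: peak prominence (fraction of the curve maximum) for pattern counting
PATTERN_PROMINENCE = 0.01


class DomainError(ValueError):
    """A sweep parameter lies outside its allowed domain."""


class NoSolutionError(RuntimeError):
    """No periodic walking solution was found in the searched domain."""


@dataclass(frozen=True)
class PoincareState:
    """State on the Poincare section: CoM height and forward speed."""

    com_height: float
    forward_speed: float

    def as_array(self) -> np.ndarray:
        return np.array([self.com_height, self.forward_speed])


@dataclass(frozen=True)
class SearchPoint:
    """One lattice point of the parameter sweep with derived quantities."""

    initial_speed: float       # v_G0
    initial_trough: float      # F_v_min0
    step_parameter: float      # p_phi_k
    touchdown_angle: float     # derived via the speed coupling
    leg_stiffness: float       # derived via the step parameter


@dataclass(frozen=True)
class StabilityResult:
    eigenvalue_magnitudes: Tuple[float, float]
    stable: bool
    note: str = ""


@dataclass
class FixedPoint:
    """A periodic walking solution found by the grid search."""

    search_point: SearchPoint
    poincare_state: PoincareState
    deviation: float                       # dzp at the lattice point
    stable: bool
    eigenvalue_magnitudes: Tuple[float, float]
    pattern_label: Optional[str]           # double_hump | multi_peak | other
    step_length: float
    step_duration: float
    contact_time: float
    average_speed: float


# ---------------------------------------------------------------------------
# Parameter couplings


def touchdown_angle_from_speed(v_g: float, check_domain: bool = True) -> float:
    """Touchdown angle (radians, negative) from the speed coupling.

    ``phi_TD = -0.262 * v_G - 0.180``.
    """
    if check_domain and not (V_G0_DOMAIN[0] <= v_g <= V_G0_DOMAIN[1]):
        raise DomainError(
            f"normalized gait speed {v_g} outside domain {V_G0_DOMAIN}")
    return -0.262 * v_g - 0.180


def stiffness_from_step_parameter(p_phi_k: float, phi_td: float,
                                  roller_radius: float = DEFAULT_ROLLER_RADIUS) -> float:
    """Leg stiffness from the step parameter.

    ``k = p / ((1 - r0) * sin^2 phi_TD)``; the step parameter keeps the
    swept stiffness in a useful range across touchdown angles.
    """
    if p_phi_k <= 0:
        raise DomainError(f"step parameter must be positive, got {p_phi_k}")
    s = math.sin(phi_td)
    if s == 0.0:
        raise DomainError("touchdown angle of zero makes the stiffness singular")
    return p_phi_k / ((1.0 - roller_radius) * s * s)


def initial_state_at_vlc(f_v_min0: float, leg_stiffness: float, v_g0: float,
                         params: Optional[NormalizedParameters] = None
                         ) -> SimulationState:
    """Canonical initial state encoding the GRF trough value.

    At the VLC the stance spring carries exactly the trough force, so its
    compression is ``s = F/k`` and the CoM height ``y0 = 1 - s``.
    """
    if params is None:
        params = NormalizedParameters(
            leg_stiffness=leg_stiffness,
            touchdown_angle=touchdown_angle_from_speed(v_g0, check_domain=False))
    s0 = f_v_min0 / leg_stiffness
    if s0 >= 1.0 - params.roller_radius:
        raise DomainError(
            f"initial compression {s0} reaches the roller radius; "
            "the trough value is infeasible at this stiffness")
    return vlc_state(1.0 - s0, v_g0, params)


def _params_for(point: SearchPoint, roller_radius: float,
                swing_delay: float) -> NormalizedParameters:
    return NormalizedParameters(
        leg_stiffness=point.leg_stiffness,
        touchdown_angle=point.touchdown_angle,
        roller_radius=roller_radius,
        swing_delay=swing_delay)


def make_search_point(v_g0: float, f_v_min0: float, p_phi_k: float,
                      roller_radius: float = DEFAULT_ROLLER_RADIUS) -> SearchPoint:
    """Assemble a search point, deriving touchdown angle and stiffness."""
    phi_td = touchdown_angle_from_speed(v_g0, check_domain=False)
    k = stiffness_from_step_parameter(p_phi_k, phi_td, roller_radius)
    return SearchPoint(initial_speed=v_g0, initial_trough=f_v_min0,
                       step_parameter=p_phi_k, touchdown_angle=phi_td,
                       leg_stiffness=k)


# ---------------------------------------------------------------------------
# Return map and stability


def return_map(zp0: PoincareState, params: NormalizedParameters,
               dt: float = DEFAULT_DT, record: bool = True):
    """One application of the step-to-step return map.

    Returns ``(zpR, trajectory)``; ``(None, trajectory)`` on invalid
    locomotion (fall or stall), with the failure status on the
    trajectory.  With ``record=False`` the trajectory is ``None`` and
    failures return ``(None, None)``.
    """
    if record:
        traj = simulate_step((zp0.com_height, zp0.forward_speed), params, dt=dt)
        if traj.failed:
            return None, traj
        y, vx, _ = traj.final_state
        return PoincareState(y, vx), traj
    status, y, vx, _, _, _, _, _ = poincare_return(
        zp0.com_height, zp0.forward_speed, params, dt=dt)
    if status != STATUS_OK:
        return None, None
    return PoincareState(y, vx), None


def assess_stability(zp: PoincareState, params: NormalizedParameters,
                     eps: float = STABILITY_EPS, dt: float = DEFAULT_DT,
                     tol: float = STABILITY_TOL) -> StabilityResult:
    """Local stability from the finite-difference return-map Jacobian.

    Central differences with perturbation ``eps`` on each Poincare
    coordinate give a 2x2 Jacobian; the solution counts as stable when
    both eigenvalue magnitudes fall below ``1 - tol``.  The conservative
    dynamics put one eigenvalue near unit magnitude; the margin ``tol``
    decides how that neutral direction is treated.
    """
    cols = []
    for j, base in enumerate((zp.com_height, zp.forward_speed)):
        results = []
        for sign in (1.0, -1.0):
            y0, vx0 = zp.com_height, zp.forward_speed
            if j == 0:
                y0 = base + sign * eps
            else:
                vx0 = base + sign * eps
            status, y, vx, _, _, _, _, _ = poincare_return(y0, vx0, params, dt=dt)
            if status != STATUS_OK:
                return StabilityResult(
                    eigenvalue_magnitudes=(math.nan, math.nan), stable=False,
                    note=f"perturbed trajectory failed (status {status})")
            results.append((y, vx))
        (yp, vxp), (ym, vxm) = results
        cols.append([(yp - ym) / (2 * eps), (vxp - vxm) / (2 * eps)])
    jac = np.array(cols).T
    mags = np.sort(np.abs(np.linalg.eigvals(jac)))[::-1]
    stable = bool(np.all(mags < 1.0 - tol))
    return StabilityResult(eigenvalue_magnitudes=(float(mags[0]), float(mags[1])),
                           stable=stable)


# ---------------------------------------------------------------------------
# GRF pattern classification


def classify_pattern(fv_stance: np.ndarray,
                     prominence: float = PATTERN_PROMINENCE) -> str:
    """Label a vertical-GRF stance curve by its number of main peaks.

    Exactly two strict local maxima (above a prominence floor of
    ``prominence`` times the curve maximum): ``double_hump`` -- the
    common walking pattern.  More: ``multi_peak`` -- a higher oscillation
    mode.  Anything else: ``other``.
    """
    fv = np.asarray(fv_stance, dtype=float)
    if fv.size < 5 or not np.all(np.isfinite(fv)):
        raise ValueError("pattern classification needs a finite GRF series")
    top = float(fv.max())
    if top <= 0:
        raise ValueError("pattern classification needs a positive GRF series")
    peaks, _ = find_peaks(fv, prominence=prominence * top)
    if peaks.size == 2:
        return "double_hump"
    if peaks.size > 2:
        return "multi_peak"
    return "other"


def _classify_fixed_point(point: SearchPoint, zp: PoincareState,
                          roller_radius: float, swing_delay: float,
                          dt: float) -> Optional[str]:
    params = _params_for(point, roller_radius, swing_delay)
    traj = simulate_step((zp.com_height, zp.forward_speed), params, dt=dt)
    if traj.failed:
        return None
    _, fv, _, _ = traj.stance_curves()
    return classify_pattern(fv)


# ---------------------------------------------------------------------------
# Grid search


@dataclass(frozen=True)
class SweepGrid:
    """Lattices of the three sweep parameters.

    Defaults follow the documented search domains with spacings 0.01
    (speeds and troughs) and 0.1 (step parameter).
    """

    v_g0: np.ndarray
    f_v_min0: np.ndarray
    p_phi_k: np.ndarray

    @classmethod
    def default(cls, v_step: float = 0.01, f_step: float = 0.01,
                p_step: float = 0.1) -> "SweepGrid":
        v = np.round(np.arange(V_G0_DOMAIN[0], V_G0_DOMAIN[1] + v_step / 2, v_step), 10)
        f = np.round(np.arange(f_step, F_V_MIN0_DOMAIN[1] + f_step / 2, f_step), 10)
        p = np.round(np.arange(p_step, P_PHI_K_DOMAIN[1] + p_step / 2, p_step), 10)
        return cls(v_g0=v, f_v_min0=f, p_phi_k=p)


def _evaluate_point(point: SearchPoint, roller_radius: float, swing_delay: float,
                    dt: float, dz_lim: float):
    """Run one lattice point; return (dzp, zp0, zpR, metrics) or None."""
    k = point.leg_stiffness
    s0 = point.initial_trough / k
    if s0 >= 1.0 - roller_radius or s0 >= 1.0:
        return None
    y0 = 1.0 - s0
    if y0 <= roller_radius:
        return None
    params = _params_for(point, roller_radius, swing_delay)
    status, y, vx, vy, ts, ls, t_fc, t_fo = poincare_return(
        y0, point.initial_speed, params, dt=dt)
    if status != STATUS_OK:
        return None
    dzp = math.hypot(y - y0, vx - point.initial_speed)
    return dzp, PoincareState(y0, point.initial_speed), PoincareState(y, vx), \
        (ts, ls, t_fc, t_fo)


def find_fixed_points(constraint: str, fixed_value: float,
                      grid: Optional[SweepGrid] = None,
                      roller_radius: float = DEFAULT_ROLLER_RADIUS,
                      swing_delay: float = DEFAULT_SWING_DELAY,
                      dt: float = DEFAULT_DT,
                      dz_lim: float = DELTA_ZP_LIM,
                      stability: bool = True,
                      classify: bool = True) -> List[FixedPoint]:
    """Sweep a 2-D parameter lattice for periodic walking solutions.

    Under constraint ``"V"`` the initial speed is fixed at ``fixed_value``
    and the lattice spans trough value x step parameter; under ``"F"``
    the trough is fixed and the lattice spans speed x step parameter.
    Every lattice point whose return deviation stays below ``dz_lim`` is
    reported; an empty result is a legal outcome.  Deterministic for a
    fixed lattice.
    """
    if grid is None:
        grid = SweepGrid.default()
    if constraint == "V":
        if not (V_G0_DOMAIN[0] <= fixed_value <= V_G0_DOMAIN[1]):
            raise DomainError(
                f"constraint V speed {fixed_value} outside domain {V_G0_DOMAIN}")
        combos = [(fixed_value, f, p) for f in grid.f_v_min0 for p in grid.p_phi_k]
    elif constraint == "F":
        if not (F_V_MIN0_DOMAIN[0] < fixed_value <= F_V_MIN0_DOMAIN[1]):
            raise DomainError(
                f"constraint F trough {fixed_value} outside domain {F_V_MIN0_DOMAIN}")
        combos = [(v, fixed_value, p) for v in grid.v_g0 for p in grid.p_phi_k]
    else:
        raise ValueError(f"constraint must be 'V' or 'F', got {constraint!r}")

    found: List[FixedPoint] = []
    for v, f, p in combos:
        point = make_search_point(v, f, p, roller_radius)
        res = _evaluate_point(point, roller_radius, swing_delay, dt, dz_lim)
        if res is None:
            continue
        dzp, zp0, zpR, (ts, ls, t_fc, t_fo) = res
        if dzp >= dz_lim:
            continue
        params = _params_for(point, roller_radius, swing_delay)
        if stability:
            stab = assess_stability(zp0, params, dt=dt)
        else:
            stab = StabilityResult((math.nan, math.nan), False, "not assessed")
        label = None
        if classify:
            label = _classify_fixed_point(point, zp0, roller_radius,
                                          swing_delay, dt)
        found.append(FixedPoint(
            search_point=point, poincare_state=zp0, deviation=dzp,
            stable=stab.stable, eigenvalue_magnitudes=stab.eigenvalue_magnitudes,
            pattern_label=label, step_length=ls, step_duration=ts,
            contact_time=ts + t_fo - t_fc, average_speed=ls / ts))
    logger.info("constraint %s sweep at %.3g: %d fixed points (%d stable)",
                constraint, fixed_value, len(found),
                sum(fp.stable for fp in found))
    return found


_PATTERN_RANK = {"double_hump": 0, "multi_peak": 1, "other": 1, None: 2}


def select_solution(candidates: Sequence[FixedPoint]) -> FixedPoint:
    """Choose the representative walking solution from a candidate set.

    Locally stable candidates are preferred; among those the common
    double-hump pattern, then the largest step length; ties break by
    smaller return deviation and then smaller step parameter so the
    choice is deterministic.  When no stable candidate exists the same
    ordering runs over the unstable ones and a warning is emitted.
    """
    if not candidates:
        raise NoSolutionError("no periodic walking solution among candidates")
    pool = [fp for fp in candidates if fp.stable]
    if not pool:
        pool = list(candidates)
        warnings.warn("no locally stable periodic solution; selecting from "
                      "unstable candidates", stacklevel=2)

    def key(fp: FixedPoint):
        return (_PATTERN_RANK.get(fp.pattern_label, 2), -fp.step_length,
                fp.deviation, fp.search_point.step_parameter)

    best = min(pool, key=key)
    if best.pattern_label != "double_hump":
        warnings.warn(
            f"selected solution has pattern {best.pattern_label!r}, not the "
            "common double-hump", stacklevel=2)
    return best


def step_deviations(zp: PoincareState, params: NormalizedParameters,
                    n_steps: int, dt: float = DEFAULT_DT) -> List[float]:
    """Per-step return deviations over ``n_steps`` consecutive steps.

    Re-embeds the returned Poincare state after every step (vertical CoM
    speed reset on the section), so the list measures step-to-step drift
    near a fixed point.  Stops early on invalid locomotion.
    """
    devs: List[float] = []
    y, vx = zp.com_height, zp.forward_speed
    for _ in range(n_steps):
        status, yR, vxR, _, _, _, _, _ = poincare_return(y, vx, params, dt=dt)
        if status != STATUS_OK:
            break
        devs.append(math.hypot(yR - y, vxR - vx))
        y, vx = yR, vxR
    return devs


def refine_fixed_point(zp: PoincareState, params: NormalizedParameters,
                       dt: float = DEFAULT_DT,
                       hold: Optional[str] = None) -> PoincareState:
    """Polish a grid fixed point to a sharply periodic solution.

    Least-squares minimization of the return deviation; used when a
    truly periodic orbit is needed (e.g. verifying impulse balance),
    since grid points are only periodic to the sweep tolerance.

    Periodic solutions come in a one-parameter (energy) family, so an
    unconstrained polish can slide along it.  ``hold="height"`` keeps the
    CoM height (hence the encoded trough value) fixed and varies only the
    speed; ``hold="speed"`` does the converse.
    """
    from scipy.optimize import least_squares

    def embed(x):
        if hold == "height":
            return zp.com_height, float(x[0])
        if hold == "speed":
            return float(x[0]), zp.forward_speed
        return float(x[0]), float(x[1])

    def residual(x):
        y0, vx0 = embed(x)
        status, y, vx, _, _, _, _, _ = poincare_return(y0, vx0, params, dt=dt)
        if status != STATUS_OK:
            return np.array([1.0, 1.0])
        return np.array([y - y0, vx - vx0])

    if hold == "height":
        x0 = np.array([zp.forward_speed])
    elif hold == "speed":
        x0 = np.array([zp.com_height])
    elif hold is None:
        x0 = zp.as_array()
    else:
        raise ValueError(f"hold must be 'height', 'speed' or None, got {hold!r}")
    sol = least_squares(residual, x0, diff_step=1e-6,
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    return PoincareState(*embed(sol.x))


# ---------------------------------------------------------------------------
# Survey helpers (speed limit, pattern boundary, sweep export)


def _lazy_select(stable_fps: List[FixedPoint], all_fps: List[FixedPoint],
                 classifier: Callable[[FixedPoint], Optional[str]]) -> FixedPoint:
    """Selection with on-demand pattern labelling, largest step first."""
    pool = stable_fps if stable_fps else all_fps
    ordered = sorted(pool, key=lambda fp: (-fp.step_length, fp.deviation,
                                           fp.search_point.step_parameter))
    best_fallback = None
    for fp in ordered:
        if fp.pattern_label is None:
            fp.pattern_label = classifier(fp)
        if fp.pattern_label == "double_hump":
            return fp
        if best_fallback is None:
            best_fallback = fp
    return best_fallback


def max_stable_speed(roller_radius: float = DEFAULT_ROLLER_RADIUS,
                     grid: Optional[SweepGrid] = None,
                     swing_delay: float = DEFAULT_SWING_DELAY,
                     dt: float = DEFAULT_DT,
                     dz_lim: float = DELTA_ZP_LIM) -> float:
    """Largest initial gait speed admitting a locally stable periodic gait.

    Scans the speed lattice from fast to slow; for each speed the
    (trough x step-parameter) lattice is searched until the first stable
    fixed point, at which point that speed is the answer.
    """
    if grid is None:
        grid = SweepGrid.default()
    for v in sorted(grid.v_g0, reverse=True):
        point0 = None
        for f in grid.f_v_min0:
            for p in grid.p_phi_k:
                point = make_search_point(v, f, p, roller_radius)
                res = _evaluate_point(point, roller_radius, swing_delay, dt, dz_lim)
                if res is None:
                    continue
                dzp, zp0, _, _ = res
                if dzp >= dz_lim:
                    continue
                params = _params_for(point, roller_radius, swing_delay)
                stab = assess_stability(zp0, params, dt=dt)
                if stab.stable:
                    logger.info("max stable speed for r0=%.2f: v=%.3f "
                                "(F=%.2f, p=%.2f)", roller_radius, v, f, p)
                    return float(v)
    raise NoSolutionError(
        f"no stable periodic solution in the searched domain (r0={roller_radius})")


def pattern_boundary_speed(f_levels: Iterable[float] = (0.5, 0.6, 0.7),
                           roller_radius: float = DEFAULT_ROLLER_RADIUS,
                           grid: Optional[SweepGrid] = None,
                           swing_delay: float = DEFAULT_SWING_DELAY,
                           dt: float = DEFAULT_DT,
                           dz_lim: float = DELTA_ZP_LIM) -> float:
    """Speed boundary between multi-peak and double-hump selected gaits.

    For each trough level the selected solution is determined at every
    speed of the lattice (constraint F sweeps); the boundary is the
    midpoint between the fastest speed whose selected gait is multi-peak
    and the slowest faster speed whose selected gait is double-hump.
    The reported value is the median boundary across trough levels.
    """
    if grid is None:
        grid = SweepGrid.default()
    boundaries = []
    for f in f_levels:
        labels = {}
        for v in grid.v_g0:
            fps = find_fixed_points(
                "F", f, grid=SweepGrid(v_g0=np.array([v]),
                                       f_v_min0=grid.f_v_min0,
                                       p_phi_k=grid.p_phi_k),
                roller_radius=roller_radius, swing_delay=swing_delay, dt=dt,
                dz_lim=dz_lim, stability=True, classify=False)
            if not fps:
                continue
            stable = [fp for fp in fps if fp.stable]

            def classifier(fp):
                return _classify_fixed_point(fp.search_point, fp.poincare_state,
                                             roller_radius, swing_delay, dt)

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sel = _lazy_select(stable, fps, classifier)
            if sel is not None:
                labels[float(v)] = sel.pattern_label
        multis = [v for v, lab in labels.items() if lab != "double_hump"]
        doubles = [v for v, lab in labels.items() if lab == "double_hump"]
        if not multis or not doubles:
            continue
        v_multi = max(multis)
        above = [v for v in doubles if v > v_multi]
        if not above:
            continue
        boundaries.append(0.5 * (v_multi + min(above)))
    if not boundaries:
        raise NoSolutionError("no pattern transition found in the searched domain")
    return float(np.median(boundaries))


def sweep_to_records(constraint: str, fixed_value: float,
                     grid: Optional[SweepGrid] = None, **kwargs) -> "list[dict]":
    """Full sweep as one record per converged lattice point (CSV-ready)."""
    fps = find_fixed_points(constraint, fixed_value, grid=grid, **kwargs)
    rows = []
    for fp in fps:
        sp = fp.search_point
        rows.append({
            "v_g0": sp.initial_speed, "f_v_min0": sp.initial_trough,
            "p_phi_k": sp.step_parameter, "phi_td": sp.touchdown_angle,
            "k0": sp.leg_stiffness, "y0": fp.poincare_state.com_height,
            "delta_zp": fp.deviation, "stable": fp.stable,
            "eig1": fp.eigenvalue_magnitudes[0],
            "eig2": fp.eigenvalue_magnitudes[1],
            "pattern": fp.pattern_label, "step_length": fp.step_length,
            "step_duration": fp.step_duration, "contact_time": fp.contact_time,
            "average_speed": fp.average_speed,
        })
    return rows
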