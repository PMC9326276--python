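"""End-to-end ground-reaction-force prediction ("SLIP+" pipeline).

From three easily estimated subject descriptors -- gait speed, body
height, body mass (plus sex for the leg-length ratio) -- to full
dimensional vertical and anteroposterior GRF curves of one stance:

1. model leg length from body height, Hof normalization of the speed;
2. constraint setup: V fixes the normalized initial speed (kinematic
   match), F fixes the vertical-GRF trough value predicted by the
   calibrated regression (kinetic match);
3. lattice search for periodic walking solutions, selection by
   stability, double-hump preference and maximal step length;
4. one simulated step, assembled into a full single-leg stance;
5. time axis stretched by the contact-time factor ``Atc`` (the
   calibrated ratio of experimental to simulated contact time; force
   amplitudes untouched), then re-dimensionalized and resampled.

A direct regression predictor (single descriptors, no curves) serves as
the reference method.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from . import regression
from .dynamics import NormalizedParameters, simulate_step
from .grf_processing import GRFSummary, GRFTrial, extract_summary
from .limit_cycle import (
    DELTA_ZP_LIM,
    FixedPoint,
    NoSolutionError,
    SweepGrid,
    V_G0_DOMAIN,
    F_V_MIN0_DOMAIN,
    _classify_fixed_point,
    _lazy_select,
    find_fixed_points,
    refine_fixed_point,
    select_solution,
)
from .scaling import ReferenceDimensions, SubjectProfile, normalize

logger = logging.getLogger(__name__)

#: normalized speed above which predictions carry a near-limit warning
#: (the model loses stable solutions at about 0.6)
NEAR_LIMIT_SPEED = 0.5


@dataclass(frozen=True)
class PredictionConfig:
    """Configuration of one GRF prediction run."""

    constraint: str = "V"                     # "V" or "F"
    grid: Optional[SweepGrid] = None
    atc_model: Optional[str] = None           # default: Atc_V / Atc_F
    fv_min_model: str = "Fv_min"
    output_rate: float = 1000.0
    roller_radius: float = 0.3
    dt: float = 1e-3
    swing_delay: float = 0.05

    def __post_init__(self) -> None:
        if self.constraint not in ("V", "F"):
            raise ValueError(f"constraint must be 'V' or 'F', got {self.constraint!r}")

    @property
    def atc_model_name(self) -> str:
        return self.atc_model or ("Atc_V" if self.constraint == "V" else "Atc_F")


@dataclass
class PredictedGait:
    """A dimensional GRF prediction for one subject and constraint."""

    subject: SubjectProfile
    constraint: str
    curves: pd.DataFrame                 # time_s, fv_N, fap_N, cop_x_m
    summary: GRFSummary                  # extracted from the emitted curves
    contact_time_s: float                # Atc * simulated contact time (exact)
    atc: float
    v_g_model: float                     # normalized speed of the solution
    gait_speed_mps: float                # dimensional model gait speed
    fixed_point: FixedPoint
    warnings: List[str] = field(default_factory=list)

    def as_trial(self) -> GRFTrial:
        """The prediction in the common trial container (plate dialect)."""
        fs = 1.0 / float(np.median(np.diff(self.curves["time_s"])))
        return GRFTrial(sampling_rate=fs,
                        fv=self.curves["fv_N"].to_numpy(),
                        fap=self.curves["fap_N"].to_numpy(),
                        subject_id=None,
                        meta={"constraint": self.constraint, "atc": self.atc,
                              "v_g_model": self.v_g_model})


def predict_grf(subject: SubjectProfile,
                config: PredictionConfig = PredictionConfig()) -> PredictedGait:
    """Predict full GRF curves and gait descriptors for a subject.

    Raises :class:`NoSolutionError` when the subject's normalized speed
    exceeds the model's feasible range (about 0.6 at roller radius 0.3)
    or when the searched lattice contains no periodic solution.
    """
    refs = ReferenceDimensions.for_subject(subject)
    v_g = normalize(subject.gait_speed, "speed", refs)
    grid = config.grid or SweepGrid.default()
    notes: List[str] = []

    models = regression.builtin_models()
    if config.constraint == "V":
        if not (V_G0_DOMAIN[0] <= v_g <= V_G0_DOMAIN[1]):
            raise NoSolutionError(
                f"normalized gait speed {v_g:.3f} outside the searchable domain "
                f"{V_G0_DOMAIN}; stable walking ends near 0.6 at roller radius "
                f"{config.roller_radius}")
        fixed_value = v_g
    else:
        fixed_value = regression.predict(models[config.fv_min_model], subject)
        if not (F_V_MIN0_DOMAIN[0] < fixed_value <= F_V_MIN0_DOMAIN[1]):
            raise NoSolutionError(
                f"predicted trough value {fixed_value:.3f} outside the domain "
                f"{F_V_MIN0_DOMAIN}")
        notes.append(f"constraint F trough from regression: {fixed_value:.4f} BW")

    candidates = find_fixed_points(
        config.constraint, fixed_value, grid=grid,
        roller_radius=config.roller_radius, swing_delay=config.swing_delay,
        dt=config.dt, classify=False)
    if not candidates:
        raise NoSolutionError(
            f"no periodic walking solution under constraint {config.constraint} "
            f"at fixed value {fixed_value:.3f} in the searched lattice")
    stable = [fp for fp in candidates if fp.stable]
    if not stable:
        notes.append("no locally stable periodic solution; selecting from "
                     "unstable candidates")

    def _label(fp: FixedPoint):
        return _classify_fixed_point(fp.search_point, fp.poincare_state,
                                     config.roller_radius, config.swing_delay,
                                     config.dt)

    fp = _lazy_select(stable, candidates, _label)
    if fp.pattern_label != "double_hump":
        notes.append(f"selected solution has pattern {fp.pattern_label!r}, "
                     "not the common double-hump")

    if max(v_g, fp.search_point.initial_speed) > NEAR_LIMIT_SPEED:
        notes.append(
            f"normalized speed {max(v_g, fp.search_point.initial_speed):.3f} "
            "is near the model's feasible limit (~0.6); prediction accuracy "
            "degrades toward the limit")

    params = NormalizedParameters(
        leg_stiffness=fp.search_point.leg_stiffness,
        touchdown_angle=fp.search_point.touchdown_angle,
        roller_radius=config.roller_radius,
        swing_delay=config.swing_delay)
    # polish the grid point to a sharply periodic orbit so the emitted
    # curve closes on itself (the trough would otherwise inherit the
    # lattice periodicity error amplified by the leg stiffness); the
    # constrained coordinate stays exactly at its prescribed value
    hold = "speed" if config.constraint == "V" else "height"
    zp = refine_fixed_point(fp.poincare_state, params, dt=config.dt, hold=hold)
    traj = simulate_step((zp.com_height, zp.forward_speed), params,
                         dt=config.dt)
    if traj.failed:
        raise NoSolutionError("selected solution failed to re-simulate")
    tau, fv, fap, cop = traj.stance_curves()

    atc = regression.predict(models[config.atc_model_name], subject)
    time_s = tau * refs.time * atc
    fv_n = fv * refs.force
    fap_n = fap * refs.force
    cop_m = (cop - cop[0]) * refs.leg_length

    # resample onto the uniform output grid
    t_out = np.arange(0.0, time_s[-1] + 0.5 / config.output_rate,
                      1.0 / config.output_rate)
    curves = pd.DataFrame({
        "time_s": t_out,
        "fv_N": np.interp(t_out, time_s, fv_n),
        "fap_N": np.interp(t_out, time_s, fap_n),
        "cop_x_m": np.interp(t_out, time_s, cop_m),
    })

    pad = np.zeros(int(round(0.05 * config.output_rate)))
    trial = GRFTrial(sampling_rate=config.output_rate,
                     fv=np.concatenate([pad, curves["fv_N"], pad]),
                     fap=np.concatenate([pad, curves["fap_N"], pad]))
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        summary = extract_summary(trial, threshold=0.005 * refs.force)
    notes.extend(str(w.message) for w in caught)

    for note in notes:
        logger.info("prediction note: %s", note)
    return PredictedGait(
        subject=subject, constraint=config.constraint, curves=curves,
        summary=summary, contact_time_s=atc * traj.contact_time * refs.time,
        atc=atc, v_g_model=fp.average_speed,
        gait_speed_mps=fp.average_speed * refs.speed,
        fixed_point=fp, warnings=notes)


def predict_direct(subject: SubjectProfile) -> GRFSummary:
    """Reference prediction: single descriptors straight from regression.

    Forces are dimensionalized with the subject's body weight; no curves
    are produced.  Subjects differing only in mass get identical force
    predictions in body-weight units (the force models carry no mass
    term).
    """
    models = regression.builtin_models()
    bw = subject.body_mass * ReferenceDimensions.for_subject(subject).gravity
    return GRFSummary(
        fv_max=regression.predict(models["Fv_max"], subject) * bw,
        fv_min=regression.predict(models["Fv_min"], subject) * bw,
        fap_max=regression.predict(models["Fap_max"], subject) * bw,
        contact_time=regression.predict(models["tc"], subject))


# ---------------------------------------------------------------------------
# User-class demonstrations


@dataclass(frozen=True)
class UserClassDemo:
    """A demonstration load case: representative subject plus context."""

    user_class: str
    subject_id: int
    subject: SubjectProfile
    criticality: str


_USER_CLASSES = {
    # masses/heights of the representing study subjects; speeds from the
    # class definitions (test-data averages)
    "A": UserClassDemo("A", 2, SubjectProfile(95.6, 1.89, "male", 1.58),
                       "single load"),
    "B": UserClassDemo("B", 12, SubjectProfile(89.3, 1.84, "male", 1.45),
                       "fatigue load"),
    "C": UserClassDemo("C", 4, SubjectProfile(61.6, 1.58, "female", 1.63),
                       "heel pressure"),
}


def user_class_demo(user_class: str,
                    constraint: str = "V") -> Tuple[SubjectProfile,
                                                    PredictionConfig,
                                                    UserClassDemo]:
    """Demo subject and configuration for one critical load-case class.

    ``A``: tall, heavy, fast (largest single load); ``B``: average build
    and speed (fatigue load case); ``C``: small, light, fast (high heel
    pressure).
    """
    try:
        demo = _USER_CLASSES[user_class.upper()]
    except KeyError:
        raise ValueError(
            f"unknown user class {user_class!r}; expected one of "
            f"{sorted(_USER_CLASSES)}") from None
    return demo.subject, PredictionConfig(constraint=constraint), demo
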