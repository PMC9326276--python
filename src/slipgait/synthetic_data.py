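"""Synthetic subject populations and force-plate trials.

Emulates the structure of a twelve-subject walking study: subjects with
masses truncated to the 60--100 kg inclusion band, two prescribed gait
speed bands, a fully crossed condition layout (2 speed bands x 2 shoe
types x 2 floor panels x 2 bearing conditions x 3 repeats = 48 trials
per subject) and double-hump vertical GRF curves with a high-frequency
load-response burst at the start of stance.

The trial curves are parametric (a two-term sine series for the vertical
component, a single antisymmetric lobe pair for the anteroposterior
one), with target descriptors drawn from the calibrated regression
models plus multiplicative jitter; every generated trial carries its
exact ground-truth descriptors so extraction and calibration pipelines
can be validated end to end.  Trial curves can alternatively be sourced
from walking-model simulations via :mod:`slipgait.prediction`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.signal import butter, filtfilt
from scipy.stats import truncnorm

from . import regression
from .grf_processing import GRFSummary, GRFTrial
from .scaling import STANDARD_GRAVITY, SUBJECT_COLUMNS

#: default per-subject dropout counts emulating the study's 26 exclusions;
#: the composition keeps the stratified 2/3 split at exactly 365/185
DEFAULT_DROPOUT_PATTERN = (4, 4, 4, 4, 4, 3, 3, 0, 0, 0, 0, 0)


@dataclass(frozen=True)
class PopulationConfig:
    """Sampling configuration of the synthetic subject population."""

    n_subjects: int = 12
    mass_mean: float = 82.4
    mass_sd: float = 11.7
    mass_bounds: Tuple[float, float] = (60.0, 100.0)
    height_mean: float = 1.78
    height_sd: float = 0.10
    n_female: int = 4
    speed_bands: Tuple[Tuple[float, float], ...] = ((1.3, 1.5), (1.5, 1.7))
    trials_per_condition: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.mass_bounds
        if not lo < hi:
            raise ValueError(f"infeasible mass truncation bounds {self.mass_bounds}")
        if not 0 <= self.n_female <= self.n_subjects:
            raise ValueError("n_female must lie between 0 and n_subjects")


@dataclass(frozen=True)
class TrialGenerationConfig:
    """Configuration of one synthetic force-plate trial."""

    source: str = "parametric"            # or "slip"
    sampling_rate: float = 1000.0
    jitter_sd: float = 0.03               # multiplicative descriptor jitter
    noise_amplitude_bw: float = 0.05      # load-response noise, body weights
    noise_band_hz: Tuple[float, float] = (80.0, 150.0)
    noise_window_frac: float = 0.15       # fraction of stance carrying noise
    pad_s: float = 0.1                    # zero padding before/after stance
    seed: int = 0


def generate_population(config: PopulationConfig = PopulationConfig()) -> pd.DataFrame:
    """Draw a seeded synthetic subject table.

    Masses come from a normal distribution truncated to the inclusion
    band; heights from an untruncated normal.  Each subject gets one
    gait speed per band, uniform within the band.  Identical seeds give
    identical tables.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    lo, hi = config.mass_bounds
    a = (lo - config.mass_mean) / config.mass_sd
    b = (hi - config.mass_mean) / config.mass_sd
    mass = truncnorm.rvs(a, b, loc=config.mass_mean, scale=config.mass_sd,
                         size=n, random_state=rng)
    height = rng.normal(config.height_mean, config.height_sd, size=n)
    sexes = np.array(["female"] * config.n_female
                     + ["male"] * (n - config.n_female), dtype=object)
    rng.shuffle(sexes)
    rows = {
        "subject_id": [f"S{i + 1:02d}" for i in range(n)],
        "mass_kg": np.round(mass, 1),
        "height_m": np.round(height, 2),
        "sex": sexes,
        # overall gait speed: midpoint of the band means, per subject
        "gait_speed_mps": np.zeros(n),
    }
    for bi, (blo, bhi) in enumerate(config.speed_bands):
        rows[f"gait_speed_band{bi + 1}_mps"] = np.round(
            rng.uniform(blo, bhi, size=n), 3)
    band_cols = [c for c in rows if c.startswith("gait_speed_band")]
    rows["gait_speed_mps"] = np.round(
        np.mean([rows[c] for c in band_cols], axis=0), 3)
    return pd.DataFrame(rows, columns=SUBJECT_COLUMNS + band_cols)


# ---------------------------------------------------------------------------
# Parametric double-hump curve


def _double_hump_coefficients(peak: float, trough: float) -> Tuple[float, float]:
    """Amplitudes (a1, a3) of ``a1 sin(pi u) + a3 sin(3 pi u)``.

    The series has peaks flanking a central trough when ``a3 > a1/9``;
    the amplitudes are solved so the curve's maximum equals ``peak`` and
    its central value equals ``trough``.
    """
    if trough >= peak:
        raise ValueError(f"trough {trough} must lie below the peak {peak}")
    u = np.linspace(0.0, 1.0, 2001)

    def peak_value(a3: float) -> float:
        a1 = trough + a3
        return float((a1 * np.sin(np.pi * u) + a3 * np.sin(3 * np.pi * u)).max())

    lo = trough / 8.0 + 1e-9
    hi = 5.0 * peak
    if peak_value(lo) > peak:
        raise ValueError("peak/trough combination is not representable")
    a3 = brentq(lambda a: peak_value(a) - peak, lo, hi, xtol=1e-12)
    return trough + a3, a3


def double_hump_curve(n: int, peak: float, trough: float) -> np.ndarray:
    """A smooth two-peak stance curve on ``n`` samples, zero at both ends."""
    a1, a3 = _double_hump_coefficients(peak, trough)
    u = np.linspace(0.0, 1.0, n)
    return a1 * np.sin(np.pi * u) + a3 * np.sin(3 * np.pi * u)


def generate_trial_grf(subject, gait_speed: float,
                       config: TrialGenerationConfig = TrialGenerationConfig(),
                       rng: Optional[np.random.Generator] = None
                       ) -> Tuple[GRFTrial, GRFSummary]:
    """One synthetic trial with known ground-truth descriptors.

    Target descriptors (``Fv_max``, ``Fv_min``, ``Fap_max`` in body
    weights, ``tc`` in s) are the calibrated regression predictions at
    the trial speed, each jittered multiplicatively.  The vertical curve
    is a double hump through those targets, the anteroposterior curve an
    antisymmetric lobe pair integrating to zero (steady speed).  A
    band-limited noise burst in the first part of stance emulates the
    load-response variability seen on real plates.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    mass = float(subject["mass_kg"] if isinstance(subject, (dict, pd.Series))
                 else subject.body_mass)
    height = float(subject["height_m"] if isinstance(subject, (dict, pd.Series))
                   else subject.body_height)
    models = regression.builtin_models()
    feats = {"vG": gait_speed, "h0": height, "m0": mass}
    jit = lambda: 1.0 + config.jitter_sd * rng.standard_normal()
    tc = regression.predict(models["tc"], feats) * jit()
    fv_max_bw = regression.predict(models["Fv_max"], feats) * jit()
    fv_min_bw = regression.predict(models["Fv_min"], feats) * jit()
    fap_max_bw = regression.predict(models["Fap_max"], feats) * jit()
    if fv_min_bw >= fv_max_bw:
        raise ValueError(
            f"inconsistent targets: trough {fv_min_bw} >= peak {fv_max_bw}")

    fs = config.sampling_rate
    bw = mass * STANDARD_GRAVITY
    n_stance = max(int(round(tc * fs)), 32)
    n_pad = int(round(config.pad_s * fs))
    fv_st = double_hump_curve(n_stance, fv_max_bw, fv_min_bw) * bw
    u = np.linspace(0.0, 1.0, n_stance)
    fap_st = -fap_max_bw * bw * np.sin(2 * np.pi * u)

    if config.noise_amplitude_bw > 0:
        white = rng.standard_normal(n_stance)
        b, a = butter(4, config.noise_band_hz, btype="band", fs=fs)
        band = filtfilt(b, a, white)
        band /= max(band.std(), 1e-12)
        n_win = max(int(round(config.noise_window_frac * n_stance)), 8)
        env = np.zeros(n_stance)
        env[:n_win] = np.hanning(n_win)
        fv_st = fv_st + config.noise_amplitude_bw * bw * band * env

    fv = np.concatenate([np.zeros(n_pad), fv_st, np.zeros(n_pad)])
    fap = np.concatenate([np.zeros(n_pad), fap_st, np.zeros(n_pad)])
    truth = GRFSummary(fv_max=fv_max_bw * bw, fv_min=fv_min_bw * bw,
                       fap_max=fap_max_bw * bw, contact_time=n_stance / fs)
    sid = (subject["subject_id"] if isinstance(subject, (dict, pd.Series))
           and "subject_id" in subject else None)
    trial = GRFTrial(sampling_rate=fs, fv=fv, fap=fap, subject_id=sid,
                     meta={"gait_speed_mps": gait_speed, "mass_kg": mass,
                           "height_m": height,
                           "truth": truth.as_dict()})
    return trial, truth


def generate_dataset(population: pd.DataFrame,
                     config: TrialGenerationConfig = TrialGenerationConfig(),
                     dropout: int = 0,
                     speed_bands: Sequence[Tuple[float, float]] = ((1.3, 1.5),
                                                                   (1.5, 1.7)),
                     trials_per_condition: int = 3) -> List[GRFTrial]:
    """The full crossed trial layout, optionally with seeded dropout.

    Per subject: 2 speed bands x 2 shoes x 2 panels x 2 bearings x the
    repeat count (48 trials at the defaults).  Condition labels carry no
    force effect -- panel and shoe influences are not modelled
    separately.  ``dropout`` removes that many trials; at the default
    study layout (12 subjects, dropout 26) the removal follows a fixed
    per-subject pattern chosen so the stratified two-thirds split of the
    550 survivors is exactly 365/185.
    """
    rng = np.random.default_rng(config.seed)
    trials: List[GRFTrial] = []
    for _, subj in population.iterrows():
        for bi, (blo, bhi) in enumerate(speed_bands):
            for shoe in ("casual", "business"):
                for panel in ("stiff", "compliant"):
                    for bearing in ("load-bearing", "cantilevered"):
                        for rep in range(trials_per_condition):
                            speed = float(rng.uniform(blo, bhi))
                            trial, _ = generate_trial_grf(subj, speed, config,
                                                          rng=rng)
                            trial.condition = {
                                "speed_band": f"{blo}-{bhi}", "shoe": shoe,
                                "panel": panel, "bearing": bearing,
                                "repeat": rep + 1,
                            }
                            trials.append(trial)
    if dropout:
        trials = _apply_dropout(trials, population, dropout, rng)
    return trials


def _apply_dropout(trials: List[GRFTrial], population: pd.DataFrame,
                   dropout: int, rng: np.random.Generator) -> List[GRFTrial]:
    subjects = list(population["subject_id"])
    if dropout == sum(DEFAULT_DROPOUT_PATTERN) and len(subjects) == len(
            DEFAULT_DROPOUT_PATTERN):
        counts = list(DEFAULT_DROPOUT_PATTERN)
        rng.shuffle(counts)
        per_subject = dict(zip(subjects, counts))
        drop_idx: set = set()
        for sid, cnt in per_subject.items():
            idx = [i for i, t in enumerate(trials) if t.subject_id == sid]
            drop_idx.update(rng.choice(idx, size=cnt, replace=False).tolist())
    else:
        drop_idx = set(rng.choice(len(trials), size=dropout,
                                  replace=False).tolist())
    return [t for i, t in enumerate(trials) if i not in drop_idx]
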