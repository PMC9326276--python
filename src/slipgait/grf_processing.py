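"""Ground-reaction-force signal processing and error bookkeeping.

Measured (or synthetic) force-plate trials are low-pass filtered, the
scalar gait descriptors are extracted from one stance phase, and
predicted and observed descriptors are compared as relative errors.
Everything works on either dimensional signals (N, s) or dimensionless
ones (body weights, normalized time) -- units are whatever the trial
carries.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, find_peaks

#: default low-pass cut-off, Hz
DEFAULT_CUTOFF_HZ = 67.0

#: default Butterworth design order (applied forward-backward, zero phase)
DEFAULT_FILTER_ORDER = 4

#: default stance-detection threshold on the vertical force, N
DEFAULT_CONTACT_THRESHOLD = 10.0

TRIAL_COLUMNS = ["time_s", "fv_N", "fap_N"]


class ExtractionError(RuntimeError):
    """No usable stance phase was found in a trial."""


@dataclass
class GRFTrial:
    """One force-plate trial: vertical and anteroposterior force series."""

    sampling_rate: float
    fv: np.ndarray
    fap: np.ndarray
    subject_id: Optional[str] = None
    condition: Dict[str, object] = field(default_factory=dict)
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fv = np.asarray(self.fv, dtype=float)
        self.fap = np.asarray(self.fap, dtype=float)
        if self.fv.shape != self.fap.shape:
            raise ValueError("force series must have equal length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.fv.size) / self.sampling_rate


@dataclass(frozen=True)
class GRFSummary:
    """Scalar gait descriptors of one stance (simulated or measured).

    Force units follow the source curve (N or body weights); times in
    seconds (or dimensionless for normalized curves).  ``fv_min`` is
    ``None`` when the curve has no two-peak structure.
    """

    fv_max: float
    fv_min: Optional[float]
    fap_max: float
    contact_time: float
    step_duration: Optional[float] = None
    step_length: Optional[float] = None

    @property
    def step_frequency(self) -> Optional[float]:
        return None if not self.step_duration else 1.0 / self.step_duration

    @property
    def contact_frequency(self) -> float:
        return 1.0 / self.contact_time

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {
            "tc": self.contact_time, "Fv_max": self.fv_max,
            "Fv_min": self.fv_min, "Fap_max": self.fap_max,
            "ts": self.step_duration, "ls": self.step_length,
        }


# ---------------------------------------------------------------------------
# Filtering


def lowpass_filter(trial: GRFTrial, cutoff: float = DEFAULT_CUTOFF_HZ,
                   order: int = DEFAULT_FILTER_ORDER) -> GRFTrial:
    """Zero-phase Butterworth low-pass of both force components.

    The filter is designed at ``order`` and applied forward-backward
    (``filtfilt``), so extracted timings are not phase shifted.  Output
    length equals input length.
    """
    fs = trial.sampling_rate
    if cutoff >= fs / 2:
        raise ValueError(
            f"cut-off {cutoff} Hz is not below the Nyquist frequency {fs / 2} Hz")
    if fs < 200:
        raise ValueError(f"sampling rate {fs} Hz is too low for {cutoff} Hz filtering")
    b, a = butter(order, cutoff, btype="low", fs=fs)
    return replace(trial, fv=filtfilt(b, a, trial.fv),
                   fap=filtfilt(b, a, trial.fap))


# ---------------------------------------------------------------------------
# Descriptor extraction


def _stance_bounds(fv: np.ndarray, threshold: float) -> Tuple[int, int]:
    above = fv > threshold
    if not above.any():
        raise ExtractionError("vertical force never exceeds the contact threshold")
    # use the contiguous supra-threshold run containing the global maximum
    imax = int(np.argmax(fv))
    if not above[imax]:
        raise ExtractionError("force maximum below the contact threshold")
    i0 = imax
    while i0 > 0 and above[i0 - 1]:
        i0 -= 1
    i1 = imax
    while i1 < fv.size - 1 and above[i1 + 1]:
        i1 += 1
    return i0, i1


def extract_summary(trial: GRFTrial,
                    threshold: float = DEFAULT_CONTACT_THRESHOLD) -> GRFSummary:
    """Extract the scalar descriptors of one stance phase.

    Stance is bounded by the vertical force crossing ``threshold`` upward
    and back downward.  ``fv_max``/``fap_max`` are the maxima of the
    vertical and absolute anteroposterior force within stance; the trough
    ``fv_min`` is the minimum between the two principal vertical peaks.
    With more than two peaks the interior minimum between the two highest
    is reported with a pattern warning; with fewer than two, ``fv_min``
    is undefined (``None``) with a warning.
    """
    fv = trial.fv
    i0, i1 = _stance_bounds(fv, threshold)
    stance = fv[i0:i1 + 1]
    tc = (i1 - i0 + 1) / trial.sampling_rate
    fv_max = float(stance.max())
    fap_max = float(np.abs(trial.fap[i0:i1 + 1]).max())
    peaks, props = find_peaks(stance, prominence=0.01 * fv_max)
    fv_min: Optional[float] = None
    if peaks.size >= 2:
        if peaks.size > 2:
            warnings.warn(
                f"vertical force has {peaks.size} peaks (multi-peak pattern); "
                "trough taken between the two most prominent", stacklevel=2)
        top2 = peaks[np.argsort(props["prominences"])[-2:]]
        lo, hi = int(top2.min()), int(top2.max())
        fv_min = float(stance[lo:hi + 1].min())
    else:
        warnings.warn("vertical force has no two-peak structure; trough "
                      "undefined", stacklevel=2)
    return GRFSummary(fv_max=fv_max, fv_min=fv_min, fap_max=fap_max,
                      contact_time=tc)


# ---------------------------------------------------------------------------
# Error metrics


ERROR_PARAMETERS = ("tc", "Fv_max", "Fap_max", "Fv_min", "vG")


def relative_errors(predicted, observed) -> Dict[str, Optional[float]]:
    """Per-parameter relative error ``100*(predicted - observed)/observed``.

    Accepts :class:`GRFSummary` objects or mappings.  A zero or missing
    observed value leaves that parameter ``None``.
    """
    p = predicted.as_dict() if isinstance(predicted, GRFSummary) else dict(predicted)
    o = observed.as_dict() if isinstance(observed, GRFSummary) else dict(observed)
    out: Dict[str, Optional[float]] = {}
    for key in set(p) | set(o):
        pv, ov = p.get(key), o.get(key)
        if pv is None or ov is None or ov == 0:
            out[key] = None
        else:
            out[key] = 100.0 * (pv - ov) / ov
    return out


def aggregate_errors(errors: Sequence[Dict[str, Optional[float]]]) -> pd.DataFrame:
    """Mean, s.d., min and max of relative errors over trials.

    One column per parameter, rows ``mean``/``sd``/``min``/``max`` --
    the usual calibration-error table layout.
    """
    df = pd.DataFrame(list(errors))
    stats = pd.DataFrame({
        "mean": df.mean(), "sd": df.std(ddof=1), "min": df.min(), "max": df.max(),
    }).T
    return stats


# ---------------------------------------------------------------------------
# Train/test split


def split_train_test(trials: Sequence, fraction: float = 2.0 / 3.0,
                     seed: int = 0) -> Tuple[list, list]:
    """Seeded subject-stratified random partition into train and test.

    Within each subject the train share is ``round(fraction * n)``;
    trials without a subject id form one stratum.  Deterministic for a
    fixed seed.
    """
    n = len(trials)
    if n < 3:
        raise ValueError(f"need at least 3 trials to split, got {n}")
    rng = np.random.default_rng(seed)
    groups: Dict[object, List[int]] = {}
    for i, tr in enumerate(trials):
        sid = getattr(tr, "subject_id", None)
        groups.setdefault(sid, []).append(i)
    train_idx: List[int] = []
    test_idx: List[int] = []
    for sid in sorted(groups, key=str):
        idx = np.array(groups[sid])
        n_tr = int(math.floor(fraction * idx.size + 0.5))
        perm = rng.permutation(idx.size)
        train_idx.extend(idx[perm[:n_tr]])
        test_idx.extend(idx[perm[n_tr:]])
    train_idx.sort()
    test_idx.sort()
    return [trials[i] for i in train_idx], [trials[i] for i in test_idx]


# ---------------------------------------------------------------------------
# Trial CSV dialect (shared with the synthetic generator and predictions)


def write_trial(trial: GRFTrial, path, sidecar: bool = True) -> None:
    """Write a trial as CSV (time_s, fv_N, fap_N) plus a JSON sidecar."""
    df = pd.DataFrame({"time_s": trial.time, "fv_N": trial.fv,
                       "fap_N": trial.fap})
    df.to_csv(path, index=False)
    if sidecar:
        meta = {"subject_id": trial.subject_id,
                "sampling_rate": trial.sampling_rate,
                "condition": trial.condition,
                "meta": {k: v for k, v in trial.meta.items()
                         if isinstance(v, (str, int, float, bool, list, dict,
                                           type(None)))}}
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)


def read_trial(path) -> GRFTrial:
    """Read a trial CSV and, if present, its JSON sidecar."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial {path} is missing columns {missing}")
    t = df["time_s"].to_numpy()
    if t.size > 1:
        fs = 1.0 / float(np.median(np.diff(t)))
    else:
        fs = 1000.0
    subject_id = None
    condition: Dict[str, object] = {}
    meta: Dict[str, object] = {}
    try:
        with open(str(path) + ".json") as fh:
            side = json.load(fh)
        subject_id = side.get("subject_id")
        condition = side.get("condition", {})
        meta = side.get("meta", {})
        fs = side.get("sampling_rate", fs)
    except FileNotFoundError:
        pass
    return GRFTrial(sampling_rate=fs, fv=df["fv_N"].to_numpy(),
                    fap=df["fap_N"].to_numpy(), subject_id=subject_id,
                    condition=condition, meta=meta)
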