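"""Force-platform postural-sway pipeline and group effect sizes.

Center-of-pressure (COP) series are derived from force/moment channels
(cop_ml = -My/Fz, cop_ap = Mx/Fz), trimmed to the 20 s window starting
5 s into the trial, down-sampled to 100 Hz, and low-pass filtered with a
fourth-order Butterworth (6 Hz cutoff) applied forward and backward
(zero phase; squared magnitude response). Sway is summarized by the COP
path length over the window and the log-transformed SDs of the ML and AP
components. Group contrasts report Cohen's d with the study's sign
convention: control minus affected over the unweighted root-mean-square
of the two group SDs, so negative d means greater sway in the affected
group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

#: Default pipeline settings (trim seconds, analysis window, target rate,
#: filter order and cutoff).
TRIM_SECONDS = 5.0
WINDOW_SECONDS = 20.0
TARGET_RATE_HZ = 100.0
FILTER_ORDER = 4
CUTOFF_HZ = 6.0
MIN_TRIAL_SECONDS = TRIM_SECONDS + WINDOW_SECONDS
FZ_EPSILON = 1.0  # N; vertical load below this marks the trial unusable


@dataclass
class SwayTrial:
    """One force-platform recording.

    Either force/moment channels (``forces`` with columns Fx, Fy, Fz, Mx,
    My, Mz; N and N·m) or COP channels (``cop`` with columns cop_ml,
    cop_ap; cm) must be provided. ``usable`` starts True and is cleared
    with a reason when a processing step disqualifies the trial.
    """

    participant_id: str
    sample_rate: float
    forces: Optional[pd.DataFrame] = None
    cop: Optional[pd.DataFrame] = None
    usable: bool = True
    reason: str = ""
    provenance: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        df = self.cop if self.cop is not None else self.forces
        return 0 if df is None else len(df)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def mark_unusable(self, reason: str) -> "SwayTrial":
        self.usable = False
        self.reason = reason
        return self


@dataclass(frozen=True)
class SwayMetrics:
    cop_length: float  # cm over the analyzed window
    ml_sd_log: float
    ap_sd_log: float

    def as_array(self) -> np.ndarray:
        return np.array([self.cop_length, self.ml_sd_log, self.ap_sd_log])


METRIC_NAMES = ("cop_length", "ml_sd_log", "ap_sd_log")


def read_trial_csv(path, participant_id: str, sample_rate: Optional[float] = None) -> SwayTrial:
    """Read a trial CSV with columns ``t,Fx,Fy,Fz,Mx,My,Mz`` or ``t,cop_ml,cop_ap``.

    The sample rate is inferred from the time column unless given.
    """
    df = pd.read_csv(path)
    if sample_rate is None:
        if "t" not in df.columns or len(df) < 2:
            raise ValueError(f"{path}: cannot infer sample rate without a time column")
        dt = float(np.median(np.diff(df["t"].to_numpy())))
        sample_rate = 1.0 / dt
    force_cols = {"Fx", "Fy", "Fz", "Mx", "My", "Mz"}
    cop_cols = {"cop_ml", "cop_ap"}
    if force_cols <= set(df.columns):
        return SwayTrial(participant_id, sample_rate, forces=df[sorted(force_cols)].copy())
    if cop_cols <= set(df.columns):
        return SwayTrial(participant_id, sample_rate, cop=df[["cop_ml", "cop_ap"]].copy())
    raise ValueError(f"{path}: expected force/moment or COP columns, got {list(df.columns)}")


def cop_from_forces(trial: SwayTrial, ml_offset_cm: float = 0.0, ap_offset_cm: float = 0.0) -> SwayTrial:
    """Derive COP (cm) from force/moment channels: cop_ml = -My/Fz, cop_ap = Mx/Fz.

    Moments in N·m over forces in N give meters; the result is converted
    to cm. A vertical load at or below ``FZ_EPSILON`` anywhere in the
    trial (participant stepping off the plate) marks the trial unusable.
    """
    if trial.cop is not None:
        return trial
    if trial.forces is None:
        raise ValueError("trial has neither force nor COP channels")
    fz = trial.forces["Fz"].to_numpy(dtype=float)
    if np.any(fz <= FZ_EPSILON):
        return trial.mark_unusable("vertical load dropped to ~0 (left the plate)")
    cop_ml = -trial.forces["My"].to_numpy(dtype=float) / fz * 100.0 + ml_offset_cm
    cop_ap = trial.forces["Mx"].to_numpy(dtype=float) / fz * 100.0 + ap_offset_cm
    trial.cop = pd.DataFrame({"cop_ml": cop_ml, "cop_ap": cop_ap})
    trial.provenance.append("cop_from_forces")
    return trial


def _resample(x: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    if math.isclose(rate_in, rate_out):
        return x.astype(float)
    ratio = rate_in / rate_out
    if math.isclose(ratio, round(ratio)):
        # integral ratio: anti-aliased decimation
        return signal.decimate(x, int(round(ratio)), ftype="fir", zero_phase=True)
    frac = Fraction(rate_out / rate_in).limit_denominator(1000)
    return signal.resample_poly(x, frac.numerator, frac.denominator)


def lowpass_zero_phase(
    x: np.ndarray,
    sample_rate: float,
    cutoff_hz: float = CUTOFF_HZ,
    order: int = FILTER_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass: ``order``-th design run forward and
    backward (squared magnitude), reflective padding of 3x the order."""
    b, a = signal.butter(order, cutoff_hz, btype="low", fs=sample_rate)
    return signal.filtfilt(b, a, x, padtype="even", padlen=3 * order)


def preprocess(trial: SwayTrial) -> SwayTrial:
    """Trim, resample and filter a trial's COP series.

    Drops the first 5 s, keeps the next 20 s, resamples to 100 Hz and
    applies the zero-phase low-pass; output is exactly 2,000 samples per
    channel. Trials shorter than 25 s are marked unusable.
    """
    trial = cop_from_forces(trial)
    if not trial.usable:
        return trial
    if trial.duration < MIN_TRIAL_SECONDS - 1e-9:
        return trial.mark_unusable(
            f"trial too short ({trial.duration:.1f} s < {MIN_TRIAL_SECONDS:.0f} s)"
        )
    assert trial.cop is not None
    start = int(round(TRIM_SECONDS * trial.sample_rate))
    stop = start + int(round(WINDOW_SECONDS * trial.sample_rate))
    n_out = int(round(WINDOW_SECONDS * TARGET_RATE_HZ))
    processed = {}
    for col in ("cop_ml", "cop_ap"):
        x = trial.cop[col].to_numpy(dtype=float)[start:stop]
        x = _resample(x, trial.sample_rate, TARGET_RATE_HZ)
        x = x[:n_out]
        if len(x) != n_out:
            return trial.mark_unusable(
                f"resampling produced {len(x)} samples; expected {n_out}"
            )
        processed[col] = lowpass_zero_phase(x, TARGET_RATE_HZ)
    trial.cop = pd.DataFrame(processed)
    trial.sample_rate = TARGET_RATE_HZ
    trial.provenance.extend(["trim_5s_keep_20s", "resample_100hz", "butterworth_4_6hz_zero_phase"])
    return trial


def sway_metrics(trial: SwayTrial) -> Optional[SwayMetrics]:
    """COP path length and log-SD sway metrics on a processed trial.

    Returns None (marking the trial unusable) for unusable trials or
    zero-variance channels, whose log-SD is undefined.
    """
    if not trial.usable or trial.cop is None:
        return None
    ml = trial.cop["cop_ml"].to_numpy(dtype=float)
    ap = trial.cop["cop_ap"].to_numpy(dtype=float)
    ml_sd = float(np.std(ml, ddof=1))
    ap_sd = float(np.std(ap, ddof=1))
    if ml_sd == 0.0 or ap_sd == 0.0:
        trial.mark_unusable("zero-variance COP channel; log-SD undefined")
        return None
    length = float(np.sum(np.hypot(np.diff(ml), np.diff(ap))))
    return SwayMetrics(cop_length=length, ml_sd_log=math.log(ml_sd), ap_sd_log=math.log(ap_sd))


def aggregate_participant(trials: Sequence[SwayTrial]) -> Optional[SwayMetrics]:
    """Mean of per-trial metrics; participants with < 2 usable trials are
    excluded (returns None)."""
    metrics = [m for m in (sway_metrics(t) for t in trials) if m is not None]
    if len(metrics) < 2:
        return None
    stacked = np.vstack([m.as_array() for m in metrics]).mean(axis=0)
    return SwayMetrics(*stacked)


def cohens_d(
    mean_affected: float,
    sd_affected: float,
    n_affected: int,
    mean_control: float,
    sd_control: float,
    n_control: int,
) -> float:
    """Cohen's d, study convention: (control - affected) / RMS of the SDs.

    The denominator is the *unweighted* root-mean-square of the two group
    SDs, sqrt((sd_a^2 + sd_c^2) / 2); negative d means the affected group
    mean exceeds the control mean.
    """
    if sd_affected < 0 or sd_control < 0:
        raise ValueError("standard deviations must be non-negative")
    if n_affected < 2 or n_control < 2:
        raise ValueError("each group needs n >= 2")
    denom = math.sqrt((sd_affected**2 + sd_control**2) / 2.0)
    if denom == 0.0:
        raise ValueError("Cohen's d undefined when both group SDs are zero")
    return (mean_control - mean_affected) / denom


@dataclass
class GroupComparison:
    """Group summary table and effect sizes for one cohort (e.g. children)."""

    table: pd.DataFrame  # index metric; affected/control mean, sd; cohen_d
    n_affected: int
    n_control: int


def compare_groups(
    affected: Sequence[SwayMetrics], control: Sequence[SwayMetrics]
) -> GroupComparison:
    """Build the per-metric group means/SDs and Cohen's d from participant
    metric vectors."""
    a = np.vstack([m.as_array() for m in affected])
    c = np.vstack([m.as_array() for m in control])
    rows = []
    for i, name in enumerate(METRIC_NAMES):
        ma, sa = float(a[:, i].mean()), float(a[:, i].std(ddof=1))
        mc, sc = float(c[:, i].mean()), float(c[:, i].std(ddof=1))
        rows.append(
            {
                "metric": name,
                "affected_mean": ma,
                "affected_sd": sa,
                "control_mean": mc,
                "control_sd": sc,
                "cohen_d": cohens_d(ma, sa, len(a), mc, sc, len(c)),
            }
        )
    return GroupComparison(
        table=pd.DataFrame(rows).set_index("metric"),
        n_affected=len(a),
        n_control=len(c),
    )
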