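"""Drift-angle trajectories and kinematic features from 3-axis accelerometry.

A drift test asks the patient to hold a limb extended while a wrist/ankle
accelerometer records gravity.  When the limb is still, the accelerometer
reads the gravity direction; as the limb drifts or oscillates, the measured
gravity direction tilts away from the initial reference orientation.  The
angle between the per-sample acceleration direction and the reference
direction is the *drift angle*, from which three kinematic features are
computed over the observation window:

``MeanDrift``
    mean drift angle (degrees),
``MaxDrift``
    maximum drift angle (degrees),
``SumOsc``
    accumulated oscillation, implemented as the total variation of the
    drift-angle trajectory (degrees).

Only static tilt is used — no gyroscope fusion.  This makes the conversion
exactly invertible for a limb whose tilt follows a known trajectory, which
the synthetic cohort exploits for closed-form checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

#: samples with acceleration magnitude below this are treated as free-fall
#: artifacts (the accelerometer cannot indicate gravity direction there)
FREE_FALL_G = 0.1

#: maximum tolerated fraction of free-fall-flagged samples per trace
MAX_FLAGGED_FRACTION = 0.1

#: duration used to estimate the "auto" reference orientation
AUTO_REFERENCE_S = 0.5


@dataclass
class DriftTrace:
    """One rating session's raw 3-axis accelerometer recording for one limb.

    Parameters
    ----------
    t_s:
        Sample timestamps in seconds, uniformly spaced.
    acc_g:
        ``(n, 3)`` array of acceleration in units of g.
    sample_rate_hz:
        Sampling rate in Hz.
    patient_id, limb, rater_id:
        Session metadata; optional.
    """

    t_s: np.ndarray
    acc_g: np.ndarray
    sample_rate_hz: float
    patient_id: Optional[str] = None
    limb: Optional[str] = None
    rater_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.acc_g = np.asarray(self.acc_g, dtype=float)
        if self.t_s.ndim != 1 or self.t_s.size < 2:
            raise ValueError("trace needs at least 2 samples")
        if self.acc_g.shape != (self.t_s.size, 3):
            raise ValueError(
                f"acc_g shape {self.acc_g.shape} does not match {self.t_s.size} samples x 3 axes"
            )
        dt = np.diff(self.t_s)
        if np.any(dt <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > 1e-9:
            raise ValueError("timestamps must be uniform within 1e-9 s")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.t_s.size

    def to_frame(self) -> pd.DataFrame:
        """Long CSV layout: one row per sample (t_s, ax_g, ay_g, az_g)."""
        return pd.DataFrame(
            {
                "t_s": self.t_s,
                "ax_g": self.acc_g[:, 0],
                "ay_g": self.acc_g[:, 1],
                "az_g": self.acc_g[:, 2],
            }
        )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        sample_rate_hz: Optional[float] = None,
        **meta: Optional[str],
    ) -> "DriftTrace":
        t = frame["t_s"].to_numpy(dtype=float)
        acc = frame[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float)
        if sample_rate_hz is None:
            sample_rate_hz = 1.0 / float(t[1] - t[0])
        return cls(t, acc, sample_rate_hz, **meta)


@dataclass
class DriftTrajectory:
    """Per-sample angular deviation (degrees) from a reference orientation."""

    drift_deg: np.ndarray
    reference: np.ndarray
    t_s: Optional[np.ndarray] = None
    flagged: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.drift_deg = np.asarray(self.drift_deg, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.flagged is None:
            self.flagged = np.zeros(self.drift_deg.size, dtype=bool)
        if self.drift_deg.size == 0:
            raise ValueError("empty trajectory")
        if np.any(self.drift_deg < -1e-9) or np.any(self.drift_deg > 180 + 1e-9):
            raise ValueError("drift angles must lie in [0, 180] degrees")


@dataclass
class KinematicFeatures:
    """MeanDrift / MaxDrift / SumOsc plus demographics for one observation."""

    mean_drift: float
    max_drift: float
    sum_osc: float
    age: Optional[float] = None
    gender: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_drift <= self.max_drift + 1e-12):
            raise ValueError("need 0 <= mean_drift <= max_drift")
        if self.sum_osc < 0:
            raise ValueError("sum_osc must be nonnegative")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def to_drift_trajectory(
    trace: DriftTrace,
    reference: Union[str, Sequence[float]] = "auto",
    lowpass_hz: Optional[float] = None,
) -> DriftTrajectory:
    """Convert a 3-axis trace to the drift-angle trajectory.

    The drift angle at sample ``k`` is
    ``arccos(clip(<a_k / ||a_k||, ref>, -1, 1))`` in degrees.

    Parameters
    ----------
    reference:
        Unit 3-vector giving the reference gravity direction, or ``"auto"``
        to use the normalized mean of the first 0.5 s of samples (the limb is
        assumed still at test onset).
    lowpass_hz:
        Optional cutoff for a 4th-order zero-phase Butterworth low-pass
        applied to each axis before the angle computation.  ``None`` (the
        default) leaves the signal untouched so the conversion stays exactly
        invertible.

    Samples with ``||a_k|| < 0.1 g`` are flagged as free-fall artifacts and
    their angle is linearly interpolated from neighbors; more than 10%
    flagged samples raises ``ValueError``.
    """
    acc = trace.acc_g
    if lowpass_hz is not None:
        nyq = trace.sample_rate_hz / 2.0
        if not 0 < lowpass_hz < nyq:
            raise ValueError("lowpass_hz must lie in (0, Nyquist)")
        b, a = butter(4, lowpass_hz / nyq)
        acc = filtfilt(b, a, acc, axis=0)

    norms = np.linalg.norm(acc, axis=1)
    flagged = norms < FREE_FALL_G
    if flagged.mean() > MAX_FLAGGED_FRACTION:
        raise ValueError(
            f"{flagged.sum()}/{flagged.size} samples below {FREE_FALL_G} g: "
            "free-fall artifact fraction exceeds 10%"
        )

    if isinstance(reference, str):
        if reference != "auto":
            raise ValueError("reference must be a 3-vector or 'auto'")
        n_ref = max(1, int(round(AUTO_REFERENCE_S * trace.sample_rate_hz)))
        ref_samples = acc[:n_ref][~flagged[:n_ref]]
        if ref_samples.size == 0:
            raise ValueError("cannot estimate auto reference: initial samples all flagged")
        ref = _unit(ref_samples.mean(axis=0))
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (3,) or abs(np.linalg.norm(ref) - 1.0) > 1e-6:
            raise ValueError("reference must be a unit 3-vector")

    ok = ~flagged
    cosang = np.clip(acc[ok] @ ref / norms[ok], -1.0, 1.0)
    ang_ok = np.degrees(np.arccos(cosang))
    drift = np.empty(norms.size, dtype=float)
    drift[ok] = ang_ok
    if flagged.any():
        idx = np.arange(norms.size)
        drift[flagged] = np.interp(idx[flagged], idx[ok], ang_ok)
    return DriftTrajectory(drift, ref, t_s=trace.t_s, flagged=flagged)


def extract_features(
    traj: DriftTrajectory,
    age: Optional[float] = None,
    gender: Optional[str] = None,
) -> KinematicFeatures:
    """Compute MeanDrift, MaxDrift and SumOsc from a drift trajectory.

    ``SumOsc`` is the total variation ``sum_k |d[k] - d[k-1]|`` of the drift
    angle over the window.
    """
    d = traj.drift_deg
    if d.size == 0:
        raise ValueError("empty trajectory")
    return KinematicFeatures(
        mean_drift=float(np.mean(d)),
        max_drift=float(np.max(d)),
        sum_osc=float(np.sum(np.abs(np.diff(d)))) if d.size > 1 else 0.0,
        age=age,
        gender=gender,
    )


def features_from_trace(
    trace: DriftTrace,
    reference: Union[str, Sequence[float]] = "auto",
    lowpass_hz: Optional[float] = None,
    age: Optional[float] = None,
    gender: Optional[str] = None,
) -> KinematicFeatures:
    """Convenience: trace → trajectory → features in one call."""
    return extract_features(to_drift_trajectory(trace, reference, lowpass_hz), age, gender)


def tilt_trace(
    drift_deg: np.ndarray,
    t_s: np.ndarray,
    sample_rate_hz: float,
    noise_sd_g: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    **meta: Optional[str],
) -> DriftTrace:
    """Forward model: build the 3-axis trace of a limb tilting by ``drift_deg``.

    The limb tilts in the x–z plane away from the reference gravity direction
    ``(0, 0, 1)``; isotropic Gaussian sensor noise of standard deviation
    ``noise_sd_g`` is added per axis.  ``to_drift_trajectory`` with reference
    ``(0, 0, 1)`` inverts this exactly (up to the sign of the angle) when the
    noise is zero.
    """
    theta = np.radians(np.asarray(drift_deg, dtype=float))
    acc = np.column_stack([np.sin(theta), np.zeros_like(theta), np.cos(theta)])
    if noise_sd_g > 0:
        if rng is None:
            rng = np.random.default_rng()
        acc = acc + rng.normal(0.0, noise_sd_g, size=acc.shape)
    return DriftTrace(t_s, acc, sample_rate_hz, **meta)


REFERENCE_GRAVITY = np.array([0.0, 0.0, 1.0])
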