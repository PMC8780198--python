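"""Synthetic drift-test cohort generator.

Emulates a neurological ICU cohort in which each patient performs a limb
drift test (4 limbs) under three rating sessions: one expert gold standard
(GS) and two non-expert testers (TS1, TS2).  Each session yields a 20 s
3-axis accelerometer trace and a manual ordinal rating on a modified 9-point
MRC muscle-strength scale, of which grades {5, 7, 8, 9} occur in practice
with a strongly skewed composition (grade 9 ≈ 54% of observations).

Forward model per session
-------------------------
The limb's tilt angle follows

    drift(t) = rate * t + amplitude * sin(2*pi*f*t)        [degrees]

with per-grade rate/amplitude/frequency (weaker limb -> lower grade -> more
drift and oscillation), optional per-session lognormal jitter on rate and
amplitude (the patient never performs twice identically), and Gaussian
sensor noise on the 3-axis gravity projection.  Manual ratings are drawn
from a rater-specific confusion kernel that decays exponentially with
ordinal distance from the true grade.

Random streams are split per (observation, rater) via ``SeedSequence`` so
that adding a rater never perturbs existing draws.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .drift_features import DriftTrace, tilt_trace

# ---------------------------------------------------------------------------
# grade scale
# ---------------------------------------------------------------------------

#: full modified MRC scale (integer codes 1..9)
FULL_GRADES: Tuple[int, ...] = tuple(range(1, 10))

#: grades observed in an acute proximal-weakness cohort
DEFAULT_OBSERVED_GRADES: Tuple[int, ...] = (5, 7, 8, 9)

#: skewed class composition over the observed grades (grade -> probability)
DEFAULT_GRADE_PROBS: Dict[int, float] = {9: 0.542, 8: 0.271, 7: 0.152, 5: 0.035}


@dataclass(frozen=True)
class GradeScale:
    """Ordered set of admissible modified-MRC grades.

    The class index of a grade is its 0-based position in the ascending
    ``grades`` tuple; index 0 is the most severe observed grade.  Cost
    matrices and classifiers operate on these indices, so grades 5 and 7
    are adjacent classes even though their raw codes differ by 2.
    """

    grades: Tuple[int, ...] = DEFAULT_OBSERVED_GRADES

    def __post_init__(self) -> None:
        g = tuple(int(x) for x in self.grades)
        if len(g) == 0:
            raise ValueError("grade scale must be nonempty")
        if any(x < 1 or x > 9 for x in g):
            raise ValueError("grades must lie in 1..9")
        if any(b <= a for a, b in zip(g, g[1:])):
            raise ValueError("grades must be strictly increasing")
        object.__setattr__(self, "grades", g)

    @property
    def n_classes(self) -> int:
        return len(self.grades)

    def index(self, grade: int) -> int:
        """0-based class index of ``grade``; raises for unknown grades."""
        try:
            return self.grades.index(int(grade))
        except ValueError:
            raise ValueError(f"grade {grade} not in scale {self.grades}") from None

    def indices(self, grades: Sequence[int]) -> np.ndarray:
        return np.array([self.index(g) for g in grades], dtype=int)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Cohort size, class composition, demographics and recording protocol."""

    n_patients: int = 36
    limbs_per_patient: int = 4
    grade_probs: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_GRADE_PROBS)
    )
    age_mean: float = 65.4
    age_sd: float = 16.02
    window_s: float = 20.0
    sample_rate_hz: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.limbs_per_patient < 1:
            raise ValueError("n_patients and limbs_per_patient must be >= 1")
        if self.window_s <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("window_s and sample_rate_hz must be positive")
        probs = np.array(list(self.grade_probs.values()), dtype=float)
        if np.any(probs < 0):
            raise ValueError("grade probabilities must be nonnegative")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"grade probabilities must sum to 1 (got {probs.sum():.12f})"
            )

    @property
    def n_observations(self) -> int:
        return self.n_patients * self.limbs_per_patient

    @property
    def scale(self) -> GradeScale:
        return GradeScale(tuple(sorted(int(g) for g in self.grade_probs)))

    def prob_vector(self) -> np.ndarray:
        """Probabilities aligned with ``scale.grades`` (ascending)."""
        return np.array([self.grade_probs[g] for g in self.scale.grades], dtype=float)


@dataclass
class GradeKinematicsModel:
    """Maps a true grade to drift/oscillation kinematics.

    Defaults are calibrated so that, under the default class composition,
    cohort-level MeanDrift / MaxDrift / SumOsc land at the magnitudes seen
    in acute stroke drift tests (a few degrees mean drift, tens of degrees
    accumulated oscillation over 20 s).  Total drift and oscillation are
    non-increasing in grade: a weaker limb (lower grade) moves more.
    """

    drift_rate_deg_s: Mapping[int, float] = field(
        default_factory=lambda: {9: 0.05, 8: 0.3, 7: 0.8, 5: 2.5}
    )
    osc_amp_deg: Mapping[int, float] = field(
        default_factory=lambda: {9: 0.5, 8: 0.7, 7: 1.0, 5: 1.5}
    )
    osc_freq_hz: Mapping[int, float] = field(
        default_factory=lambda: {9: 1.0, 8: 1.0, 7: 1.2, 5: 1.5}
    )
    noise_sd_g: float = 1e-4

    def __post_init__(self) -> None:
        if self.noise_sd_g < 0:
            raise ValueError("noise_sd_g must be nonnegative")
        for name, table in (
            ("drift_rate_deg_s", self.drift_rate_deg_s),
            ("osc_amp_deg", self.osc_amp_deg),
            ("osc_freq_hz", self.osc_freq_hz),
        ):
            if any(v < 0 for v in table.values()):
                raise ValueError(f"{name} entries must be nonnegative")

    def params(self, grade: int) -> Tuple[float, float, float]:
        try:
            return (
                float(self.drift_rate_deg_s[grade]),
                float(self.osc_amp_deg[grade]),
                float(self.osc_freq_hz[grade]),
            )
        except KeyError:
            raise ValueError(f"no kinematics defined for grade {grade}") from None


@dataclass
class RaterProfile:
    """How one rater's session differs from the truth.

    ``confusion_spread`` controls the manual-rating confusion kernel
    ``P(rated | true) ∝ exp(-|Δindex| / spread)``; 0 means perfect rating.
    ``session_noise_scale`` multiplies the sensor noise in that rater's
    session; ``kinematic_jitter`` is the s.d. of a lognormal multiplier
    applied to the drift rate and oscillation amplitude per session
    (session-to-session variability of the patient's performance).
    """

    rater_id: str
    confusion_spread: float = 0.0
    session_noise_scale: float = 1.0
    kinematic_jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.confusion_spread < 0:
            raise ValueError("confusion_spread must be nonnegative")
        if self.session_noise_scale < 0 or self.kinematic_jitter < 0:
            raise ValueError("noise scale and jitter must be nonnegative")


def default_raters() -> List[RaterProfile]:
    """GS expert plus two noisier non-expert testers (TS1, TS2)."""
    return [
        RaterProfile("GS", confusion_spread=0.35, session_noise_scale=1.0, kinematic_jitter=0.12),
        RaterProfile("TS1", confusion_spread=0.90, session_noise_scale=1.5, kinematic_jitter=0.18),
        RaterProfile("TS2", confusion_spread=1.00, session_noise_scale=1.5, kinematic_jitter=0.18),
    ]


# ---------------------------------------------------------------------------
# sampling primitives
# ---------------------------------------------------------------------------


def confusion_kernel(profile: RaterProfile, scale: GradeScale) -> np.ndarray:
    """Row-stochastic M×M kernel ``P(rated class | true class)``.

    Discretized exponential in ordinal distance on class indices; spread 0
    degenerates to the identity, spread → ∞ tends to the uniform kernel.
    """
    m = scale.n_classes
    idx = np.arange(m)
    dist = np.abs(idx[:, None] - idx[None, :]).astype(float)
    if profile.confusion_spread == 0:
        return np.eye(m)
    k = np.exp(-dist / profile.confusion_spread)
    return k / k.sum(axis=1, keepdims=True)


def sample_true_grades(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw one true grade per observation, i.i.d. from the composition."""
    scale = config.scale
    return rng.choice(np.array(scale.grades), size=config.n_observations, p=config.prob_vector())


def drift_curve(
    rate_deg_s: float, amp_deg: float, freq_hz: float, t_s: np.ndarray
) -> np.ndarray:
    """Analytic tilt trajectory ``rate*t + amp*sin(2 pi f t)`` in degrees."""
    return rate_deg_s * t_s + amp_deg * np.sin(2.0 * np.pi * freq_hz * t_s)


def simulate_trace(
    true_grade: int,
    kinematics: GradeKinematicsModel,
    rater: RaterProfile,
    window_s: float,
    sample_rate_hz: float,
    seed: "int | np.random.SeedSequence | np.random.Generator" = 0,
    scale: Optional[GradeScale] = None,
    **meta: Optional[str],
) -> DriftTrace:
    """Simulate one rating session's accelerometer trace for one limb.

    The trace is the 3-axis gravity projection of a limb whose tilt follows
    the per-grade drift curve (optionally jittered per session), plus
    Gaussian sensor noise scaled by the rater's ``session_noise_scale``.
    """
    if scale is not None:
        scale.index(true_grade)  # validates membership
    if window_s <= 0 or sample_rate_hz <= 0:
        raise ValueError("window_s and sample_rate_hz must be positive")
    rate, amp, freq = kinematics.params(true_grade)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if rater.kinematic_jitter > 0:
        rate = rate * float(np.exp(rng.normal(0.0, rater.kinematic_jitter)))
        amp = amp * float(np.exp(rng.normal(0.0, rater.kinematic_jitter)))
    n = int(round(window_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    drift = drift_curve(rate, amp, freq, t)
    return tilt_trace(
        drift,
        t,
        sample_rate_hz,
        noise_sd_g=kinematics.noise_sd_g * rater.session_noise_scale,
        rng=rng,
        rater_id=rater.rater_id,
        **meta,
    )


def simulate_manual_rating(
    true_grade: int,
    rater: RaterProfile,
    scale: GradeScale = GradeScale(),
    seed: "int | np.random.Generator" = 0,
) -> int:
    """Draw one manual rating from the rater's confusion kernel row."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    row = confusion_kernel(rater, scale)[scale.index(true_grade)]
    return int(rng.choice(np.array(scale.grades), p=row))


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

LIMBS = ("left_arm", "right_arm", "left_leg", "right_leg")


@dataclass
class Cohort:
    """Observations, per-session traces, and manual ratings.

    ``observations``: one row per (patient, limb) with the true grade and
    demographics.  ``ratings``: long format, one row per (observation,
    rater).  ``traces``: dict keyed by (patient_id, limb, rater_id).
    """

    observations: pd.DataFrame
    ratings: pd.DataFrame
    traces: Dict[Tuple[str, str, str], DriftTrace]
    scale: GradeScale
    config: Optional[CohortConfig] = None

    @property
    def rater_ids(self) -> List[str]:
        return list(pd.unique(self.ratings["rater_id"]))

    def rating_matrix(self, raters: Optional[Sequence[str]] = None) -> pd.DataFrame:
        """Wide subjects × raters matrix of manual ratings."""
        wide = self.ratings.pivot_table(
            index=["patient_id", "limb"],
            columns="rater_id",
            values="mrc_grade",
            aggfunc="first",
        )
        if raters is not None:
            wide = wide[list(raters)]
        return wide

    def checksum(self) -> str:
        """SHA-256 over the serialized cohort (determinism / identity checks)."""
        h = hashlib.sha256()
        h.update(self.observations.to_csv(index=False).encode())
        h.update(self.ratings.to_csv(index=False).encode())
        for key in sorted(self.traces):
            h.update(repr(key).encode())
            h.update(np.ascontiguousarray(self.traces[key].acc_g).tobytes())
        return h.hexdigest()


def _rater_stream_key(rater_id: str) -> int:
    # stable across runs/platforms, unlike hash()
    return zlib.crc32(rater_id.encode())


def generate_cohort(
    config: CohortConfig,
    kinematics: Optional[GradeKinematicsModel] = None,
    raters: Optional[List[RaterProfile]] = None,
) -> Cohort:
    """Generate a full synthetic cohort: truths, traces and manual ratings.

    Deterministic given ``config.seed``.  Per-(observation, rater) streams
    are derived with ``SeedSequence([seed, tag, obs, crc32(rater_id)])`` so
    each rater's draws are independent of the rater list.
    """
    if kinematics is None:
        kinematics = GradeKinematicsModel()
    if raters is None:
        raters = default_raters()
    if len(raters) == 0:
        raise ValueError("at least one rater profile is required")
    if len({r.rater_id for r in raters}) != len(raters):
        raise ValueError("rater_ids must be unique")

    scale = config.scale
    root = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    grades = sample_true_grades(config, root)

    demo_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ages = np.clip(
        demo_rng.normal(config.age_mean, config.age_sd, size=config.n_patients), 18, 100
    )
    genders = demo_rng.choice(np.array(["F", "M"]), size=config.n_patients)

    obs_rows = []
    rating_rows = []
    traces: Dict[Tuple[str, str, str], DriftTrace] = {}
    for i in range(config.n_observations):
        p = i // config.limbs_per_patient
        l = i % config.limbs_per_patient
        patient_id = f"P{p + 1:03d}"
        limb = LIMBS[l] if config.limbs_per_patient <= len(LIMBS) else f"limb{l + 1}"
        true_grade = int(grades[i])
        obs_rows.append(
            {
                "patient_id": patient_id,
                "limb": limb,
                "true_grade": true_grade,
                "age": float(ages[p]),
                "gender": str(genders[p]),
            }
        )
        for rater in raters:
            key = _rater_stream_key(rater.rater_id)
            trace_rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 2, i, key])
            )
            trace = simulate_trace(
                true_grade,
                kinematics,
                rater,
                config.window_s,
                config.sample_rate_hz,
                seed=trace_rng,
                scale=scale,
                patient_id=patient_id,
                limb=limb,
            )
            traces[(patient_id, limb, rater.rater_id)] = trace
            rating_rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 3, i, key])
            )
            rating_rows.append(
                {
                    "patient_id": patient_id,
                    "limb": limb,
                    "rater_id": rater.rater_id,
                    "mrc_grade": simulate_manual_rating(
                        true_grade, rater, scale, seed=rating_rng
                    ),
                }
            )

    return Cohort(
        observations=pd.DataFrame(obs_rows),
        ratings=pd.DataFrame(rating_rows),
        traces=traces,
        scale=scale,
        config=replace(config),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_cohort(cohort: Cohort, out_dir: "str | Path") -> Path:
    """Write a cohort as CSVs plus a manifest JSON tying files to sessions."""
    out = Path(out_dir)
    (out / "traces").mkdir(parents=True, exist_ok=True)
    cohort.observations.to_csv(out / "observations.csv", index=False)
    cohort.ratings.to_csv(out / "ratings.csv", index=False)
    manifest = {"grades": list(cohort.scale.grades), "sessions": []}
    for (pid, limb, rid), trace in sorted(cohort.traces.items()):
        fname = f"traces/{pid}_{limb}_{rid}.csv"
        trace.to_frame().to_csv(out / fname, index=False)
        manifest["sessions"].append(
            {
                "patient_id": pid,
                "limb": limb,
                "rater_id": rid,
                "file": fname,
                "sample_rate_hz": trace.sample_rate_hz,
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def read_cohort(in_dir: "str | Path") -> Cohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    observations = pd.read_csv(src / "observations.csv")
    ratings = pd.read_csv(src / "ratings.csv")
    traces: Dict[Tuple[str, str, str], DriftTrace] = {}
    for s in manifest["sessions"]:
        frame = pd.read_csv(src / s["file"])
        traces[(s["patient_id"], s["limb"], s["rater_id"])] = DriftTrace.from_frame(
            frame,
            sample_rate_hz=s["sample_rate_hz"],
            patient_id=s["patient_id"],
            limb=s["limb"],
            rater_id=s["rater_id"],
        )
    return Cohort(
        observations=observations,
        ratings=ratings,
        traces=traces,
        scale=GradeScale(tuple(manifest["grades"])),
    )
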