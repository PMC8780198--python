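"""End-to-end experiment: cohort → features → manual vs ML grading → report.

The experiment mirrors a three-session drift-test protocol: an expert gold
standard (GS) session and two non-expert test sessions (TS1, TS2) per limb
observation.  A cost-sensitive ensemble is trained on the GS session's
kinematic+demographic features, labeled by the GS manual grades (the expert
rating is the operational ground truth; training on simulated true grades is
available for oracle studies).  The trained model then grades the TS1 and
TS2 sessions from their sensor features alone, yielding machine gradings
AI_TS1 and AI_TS2.  The reliability report compares the manual rater set
(GS, TS1, TS2) with the machine set (GS, AI_TS1, AI_TS2): percent
agreements and confusion matrices vs GS, Krippendorff's alpha and Fleiss'
kappa per rater subset, and per-feature Bland–Altman + ICC(2,k) between
sessions.

The ablation runs three method rows on one shared cohort: manual only,
balanced training (DataAug), and balanced + ordinal cost-adjusted training
(DataAug + CostAdj).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .agreement_stats import (
    ReliabilityReport,
    bland_altman,
    icc_2k,
    rater_set_statistics,
)
from .class_balancing import ORIGIN_ORIGINAL, balance_table
from .drift_features import features_from_trace
from .mrc_classifier import (
    EnsembleSpec,
    predict_grade,
    select_model,
    train_ensemble,
)
from .ordinal_costs import (
    CostMatrix,
    imbalance_cost_matrix,
    linear_cost_matrix,
    zero_one_cost_matrix,
)
from .synthetic_cohort import (
    Cohort,
    CohortConfig,
    GradeKinematicsModel,
    RaterProfile,
    default_raters,
    generate_cohort,
)

logger = logging.getLogger("proxiscale")

FEATURE_COLS = ["mean_drift", "max_drift", "sum_osc", "age", "gender_code"]
KINEMATIC_COLS = ["mean_drift", "max_drift", "sum_osc"]


@dataclass
class ExperimentConfig:
    """Everything one run needs: cohort source, balancing, costs, selection."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    kinematics: GradeKinematicsModel = field(default_factory=GradeKinematicsModel)
    raters: List[RaterProfile] = field(default_factory=default_raters)
    gs_rater: str = "GS"
    test_raters: List[str] = field(default_factory=lambda: ["TS1", "TS2"])
    balance_n: int = 600
    augment: bool = True
    cost_mode: str = "linear"  # linear | imbalance | none
    smote_k: int = 5
    selection_iterations: int = 50
    fixed_spec: EnsembleSpec = field(default_factory=EnsembleSpec)
    train_on_truth: bool = False
    alpha_metric: str = "nominal"
    seed: int = 7

    def __post_init__(self) -> None:
        if self.gs_rater in self.test_raters:
            raise ValueError("gold-standard rater must be distinct from test raters")
        if self.cost_mode not in ("linear", "imbalance", "none"):
            raise ValueError("cost_mode must be linear, imbalance or none")

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "ExperimentConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(doc)
        if "cohort" in kwargs:
            kwargs["cohort"] = CohortConfig(**kwargs["cohort"])
        if "kinematics" in kwargs:
            kin = {
                k: ({int(g): float(v) for g, v in val.items()} if isinstance(val, dict) else val)
                for k, val in kwargs["kinematics"].items()
            }
            kwargs["kinematics"] = GradeKinematicsModel(**kin)
        if "raters" in kwargs:
            kwargs["raters"] = [RaterProfile(**r) for r in kwargs["raters"]]
        if "fixed_spec" in kwargs:
            kwargs["fixed_spec"] = EnsembleSpec(**kwargs["fixed_spec"])
        return cls(**kwargs)


def cohort_feature_table(cohort: Cohort, reference: "str | Sequence[float]" = "auto") -> pd.DataFrame:
    """Kinematic + demographic features per (observation, rater session)."""
    obs = cohort.observations.set_index(["patient_id", "limb"])
    ratings = cohort.ratings.set_index(["patient_id", "limb", "rater_id"])["mrc_grade"]
    rows = []
    for (pid, limb, rid), trace in sorted(cohort.traces.items()):
        meta = obs.loc[(pid, limb)]
        feats = features_from_trace(
            trace, reference=reference, age=float(meta["age"]), gender=str(meta["gender"])
        )
        rows.append(
            {
                "patient_id": pid,
                "limb": limb,
                "rater_id": rid,
                "mean_drift": feats.mean_drift,
                "max_drift": feats.max_drift,
                "sum_osc": feats.sum_osc,
                "age": feats.age,
                "gender": feats.gender,
                "gender_code": 1.0 if feats.gender == "M" else 0.0,
                "mrc_manual": int(ratings.loc[(pid, limb, rid)]),
                "true_grade": int(meta["true_grade"]),
            }
        )
    return pd.DataFrame(rows)


def _build_cost(mode: str, label_counts: Sequence[int], grades: Sequence[int]) -> CostMatrix:
    if mode == "linear":
        return linear_cost_matrix(grades=grades)
    if mode == "imbalance":
        return imbalance_cost_matrix(label_counts, grades=grades)
    return zero_one_cost_matrix(grades=grades)


def _train_from_config(config: ExperimentConfig, gs_features: pd.DataFrame):
    """Balance, build costs, and train/select the grading model."""
    label_col = "true_grade" if config.train_on_truth else "mrc_manual"
    train = gs_features[FEATURE_COLS + [label_col]].rename(columns={label_col: "grade"})
    grades = np.sort(train["grade"].unique())

    if config.augment:
        sbt = balance_table(
            train, FEATURE_COLS, "grade", config.balance_n,
            k=config.smote_k, seed=config.seed,
        )
    else:
        sbt = train.copy()
        sbt["origin"] = ORIGIN_ORIGINAL

    counts = [int((sbt["grade"] == g).sum()) for g in grades]
    cost = _build_cost(config.cost_mode, counts, [int(g) for g in grades])
    X = sbt[FEATURE_COLS].to_numpy(float)
    y = sbt["grade"].to_numpy()
    origin = sbt["origin"].to_numpy()
    cost_in_boosting = config.cost_mode != "none"

    if config.selection_iterations > 0:
        model, state = select_model(
            X, y, origin, cost,
            iterations=config.selection_iterations,
            seed=config.seed,
            cost_in_boosting=cost_in_boosting,
        )
        logger.info(
            "selected %s (objective %.4f over %d iterations)",
            model.spec.family, state.best[1], len(state.history),
        )
    else:
        spec = dataclasses.replace(config.fixed_spec, seed=config.seed)
        model = train_ensemble(X, y, spec, cost, cost_in_boosting=cost_in_boosting)
        logger.info("trained fixed spec %s", spec)
    return model


def run_experiment(
    config: ExperimentConfig, cohort: Optional[Cohort] = None, skip_ml: bool = False
) -> ReliabilityReport:
    """Run the full manual-vs-ML grading experiment on one cohort.

    Fully deterministic given the config's master seed.  ``cohort`` may be
    supplied to share one cohort across ablation rows; ``skip_ml`` produces
    the manual-only report row.
    """
    if cohort is None:
        cohort = generate_cohort(config.cohort, config.kinematics, config.raters)
    scale = cohort.scale
    raters = [config.gs_rater, *config.test_raters]
    missing = [r for r in raters if r not in cohort.rater_ids]
    if missing:
        raise ValueError(f"cohort lacks sessions for raters: {missing}")

    feats = cohort_feature_table(cohort)
    logger.info("cohort %s: %d observations x %d sessions",
                cohort.checksum()[:12], len(cohort.observations), len(raters))

    # manual rating table (subjects x raters)
    wide = feats.pivot_table(
        index=["patient_id", "limb"], columns="rater_id", values="mrc_manual",
        aggfunc="first",
    )[raters]

    report = ReliabilityReport()
    report.meta = {
        "seed": config.seed,
        "cohort_sha256": cohort.checksum(),
        "n_observations": int(len(cohort.observations)),
        "cost_mode": config.cost_mode,
        "augment": bool(config.augment),
        "gs_rater": config.gs_rater,
        "test_raters": list(config.test_raters),
    }
    report.manual = rater_set_statistics(
        wide, config.gs_rater, config.test_raters, scale, config.alpha_metric
    )

    # feature-level agreement between sessions (sensor reliability)
    icc_stats: Dict[str, object] = {}
    ba_stats: Dict[str, object] = {}
    by_rater = {
        r: feats[feats["rater_id"] == r].set_index(["patient_id", "limb"]) for r in raters
    }
    index = by_rater[config.gs_rater].index
    for col in KINEMATIC_COLS:
        mat = np.column_stack([by_rater[r].loc[index, col].to_numpy(float) for r in raters])
        res = icc_2k(mat)
        icc_stats[col] = {
            "icc": res.icc, "ci_low": res.ci_low, "ci_high": res.ci_high,
            "p_value": res.p_value,
        }
        ba_stats[col] = {}
        for t in config.test_raters:
            ba = bland_altman(mat[:, 0], mat[:, raters.index(t)])
            ba_stats[col][f"{config.gs_rater}-{t}"] = {
                "mean_diff": ba.mean_diff, "sd_diff": ba.sd_diff,
                "loa_low": ba.loa_low, "loa_high": ba.loa_high,
            }
    report.features = {"icc_2k": icc_stats, "bland_altman": ba_stats}

    if skip_ml:
        report.ml = None
        return report

    gs_features = by_rater[config.gs_rater].loc[index].reset_index()
    model = _train_from_config(config, gs_features)

    # machine gradings of the non-expert sessions (their sensor data only;
    # TS manual ratings are never shown to the model)
    ml_wide = pd.DataFrame(index=index)
    ml_wide[config.gs_rater] = wide[config.gs_rater]
    ml_names = []
    for t in config.test_raters:
        name = f"AI_{t}"
        ml_names.append(name)
        Xt = by_rater[t].loc[index, FEATURE_COLS].to_numpy(float)
        ml_wide[name] = predict_grade(model, Xt)
    report.ml = rater_set_statistics(
        ml_wide, config.gs_rater, ml_names, scale, config.alpha_metric
    )
    report.ml["model"] = {
        "family": model.spec.family,
        "n_learners": model.spec.n_learners,
        "max_depth": model.spec.max_depth,
        "learning_rate": model.spec.learning_rate,
        **{k: v for k, v in model.meta.items()},
    }
    return report


ABLATION_ROWS = ("manual", "dataaug", "dataaug_costadj")


def run_ablation(config: ExperimentConfig) -> Dict[str, ReliabilityReport]:
    """Three method rows sharing one cohort: manual, DataAug, DataAug+CostAdj."""
    cohort = generate_cohort(config.cohort, config.kinematics, config.raters)
    rows: Dict[str, ReliabilityReport] = {}
    rows["manual"] = run_experiment(config, cohort=cohort, skip_ml=True)
    rows["dataaug"] = run_experiment(
        dataclasses.replace(config, augment=True, cost_mode="none"), cohort=cohort
    )
    rows["dataaug_costadj"] = run_experiment(
        dataclasses.replace(config, augment=True, cost_mode="linear"), cohort=cohort
    )
    return rows


def ablation_to_frame(rows: Dict[str, ReliabilityReport]) -> pd.DataFrame:
    """Flatten ablation rows to a methods × metrics × rater-set table."""
    method_labels = {
        "manual": "Manual",
        "dataaug": "Machine Learning (DataAug)",
        "dataaug_costadj": "Machine Learning (DataAug + CostAdj)",
    }
    out = []
    for key, report in rows.items():
        stats = report.manual if key == "manual" else report.ml
        for metric in ("alpha", "fleiss_kappa"):
            rec = {"method": method_labels.get(key, key), "metric": metric}
            rec.update(stats[metric])
            out.append(rec)
    return pd.DataFrame(out)


def report_to_json(report: ReliabilityReport) -> str:
    """Canonical (sorted-keys) JSON serialization; byte-stable given a seed."""
    return json.dumps(report.to_dict(), sort_keys=True, indent=1)


def write_report(report: ReliabilityReport, out_dir: "str | Path") -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report_to_json(report))
    flat = []
    for section in ("manual", "ml"):
        stats = getattr(report, section)
        if stats is None:
            continue
        for metric in ("percent_agreement", "alpha", "fleiss_kappa"):
            for key, val in stats[metric].items():
                flat.append({"section": section, "metric": metric, "raters": key, "value": val})
    pd.DataFrame(flat).to_csv(out / "report.csv", index=False)
    return out
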