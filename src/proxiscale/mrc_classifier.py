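"""Cost-sensitive ensemble classifiers for ordinal MRC grading.

Three ensemble families over CART decision trees:

bagging
    bootstrap-resampled trees, posterior = mean of tree class probabilities;
adaboost
    multiclass (SAMME) boosting; on each round the weights of misclassified
    instances are additionally multiplied by the cost of the committed
    misclassification, so ordinally distant errors are corrected harder;
rusboost
    the same boosted loop, but each round's tree is fitted on a random
    undersample that caps every class at (roughly) the minority class size.

Prediction is by minimum expected misclassification cost: with posterior
``p`` and cost matrix ``c``, the predicted class is
``argmin_i sum_j c_ij p_j``; ties break toward the lower class index, i.e.
the more severe grade.  Model selection searches family × hyperparameters
with a Gaussian-process surrogate and expected-improvement acquisition
(seeded random search available as a fallback), minimizing a cross-validated
mean expected cost in which synthetic (SMOTE) instances are used for
training only and never appear in validation folds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier
from scipy.stats import norm

from .class_balancing import ORIGIN_ORIGINAL
from .ordinal_costs import CostMatrix

FAMILIES = ("bagging", "adaboost", "rusboost")


@dataclass(frozen=True)
class EnsembleSpec:
    """Hyperparameters identifying one candidate ensemble."""

    family: str = "adaboost"
    n_learners: int = 60
    max_depth: int = 3
    learning_rate: float = 0.5
    undersample_ratio: float = 1.0  # rusboost: per-class cap / minority size
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.n_learners < 1:
            raise ValueError("n_learners must be >= 1")
        if not (0.0 < self.learning_rate <= 1.0):
            raise ValueError("learning_rate must lie in (0, 1]")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.undersample_ratio <= 0:
            raise ValueError("undersample_ratio must be positive")


@dataclass
class EnsembleModel:
    """Fitted base learners, combination weights, and the attached costs."""

    learners: List[DecisionTreeClassifier]
    weights: np.ndarray
    classes: np.ndarray  # class labels in ascending order
    cost: CostMatrix
    spec: EnsembleSpec
    meta: Dict[str, float] = field(default_factory=dict)

    @property
    def is_fitted(self) -> bool:
        return len(self.learners) > 0


def _aligned_proba(
    tree: DecisionTreeClassifier, X: np.ndarray, classes: np.ndarray
) -> np.ndarray:
    """Tree probabilities re-indexed onto the full class list."""
    p = np.zeros((X.shape[0], classes.size))
    proba = tree.predict_proba(X)
    cols = np.searchsorted(classes, tree.classes_)
    p[:, cols] = proba
    return p


def train_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    spec: EnsembleSpec,
    cost: CostMatrix,
    cost_in_boosting: bool = True,
) -> EnsembleModel:
    """Fit one cost-sensitive ensemble. Deterministic given ``spec.seed``.

    ``cost_in_boosting=False`` ablates the cost-sensitive weight update
    (costs then act only through the prediction rule).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, d) with matching labels")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite (no NaN/inf)")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training set must contain at least 2 classes")
    if cost.n_classes != classes.size:
        raise ValueError(
            f"cost matrix has {cost.n_classes} classes, data has {classes.size}"
        )
    rng = np.random.default_rng(spec.seed)
    n = X.shape[0]
    m = classes.size
    y_idx = np.searchsorted(classes, y)

    learners: List[DecisionTreeClassifier] = []
    alphas: List[float] = []

    if spec.family == "bagging":
        for b in range(spec.n_learners):
            idx = rng.integers(0, n, size=n)
            tree = DecisionTreeClassifier(
                max_depth=spec.max_depth,
                random_state=int(rng.integers(0, 2**31 - 1)),
            ).fit(X[idx], y[idx])
            learners.append(tree)
            alphas.append(1.0)
    else:
        w = np.full(n, 1.0 / n)
        min_count = int(np.bincount(y_idx, minlength=m).min())
        cap = max(1, int(round(spec.undersample_ratio * min_count)))
        for b in range(spec.n_learners):
            if spec.family == "rusboost":
                fit_idx = _rus_sample(y_idx, w, cap, m, rng)
            else:
                fit_idx = np.arange(n)
            tree = DecisionTreeClassifier(
                max_depth=spec.max_depth,
                random_state=int(rng.integers(0, 2**31 - 1)),
            ).fit(X[fit_idx], y[fit_idx], sample_weight=w[fit_idx] * n)
            pred_idx = np.searchsorted(classes, tree.predict(X))
            miss = pred_idx != y_idx
            err = float(w[miss].sum())
            if err >= 1.0 - 1.0 / m:
                # weak learner no better than chance: discard, reset weights
                w = np.full(n, 1.0 / n)
                continue
            err = max(err, 1e-12)
            alpha = spec.learning_rate * (math.log((1.0 - err) / err) + math.log(m - 1.0))
            upd = np.ones(n)
            upd[miss] = np.exp(alpha)
            if cost_in_boosting and miss.any():
                # errors are re-weighted by the committed misclassification cost
                upd[miss] *= cost.costs[pred_idx[miss], y_idx[miss]]
            w = w * upd
            w = w / w.sum()
            learners.append(tree)
            alphas.append(alpha)
        if not learners:
            # all rounds degenerate; fall back to one plain tree
            tree = DecisionTreeClassifier(
                max_depth=spec.max_depth,
                random_state=int(rng.integers(0, 2**31 - 1)),
            ).fit(X, y)
            learners.append(tree)
            alphas.append(1.0)

    return EnsembleModel(
        learners=learners,
        weights=np.asarray(alphas, dtype=float),
        classes=classes,
        cost=cost,
        spec=spec,
    )


def _rus_sample(
    y_idx: np.ndarray, w: np.ndarray, cap: int, m: int, rng: np.random.Generator
) -> np.ndarray:
    """Random undersampling: at most ``cap`` instances per class, drawn
    without replacement with probability proportional to boosting weight."""
    picks = []
    for c in range(m):
        members = np.flatnonzero(y_idx == c)
        if members.size <= cap:
            picks.append(members)
            continue
        p = w[members]
        total = p.sum()
        p = p / total if total > 0 else None
        picks.append(rng.choice(members, size=cap, replace=False, p=p))
    return np.concatenate(picks)


def predict_posterior(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Weight-normalized average of per-tree class probabilities, ``(n, M)``."""
    if not model.is_fitted:
        raise ValueError("model has no fitted learners")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    acc = np.zeros((X.shape[0], model.classes.size))
    for tree, a in zip(model.learners, model.weights):
        acc += a * _aligned_proba(tree, X, model.classes)
    return acc / model.weights.sum()


def min_expected_cost_index(posterior: np.ndarray, cost: CostMatrix) -> np.ndarray:
    """argmin_i sum_j c_ij p_j; ties break to the lower (more severe) index."""
    ec = cost.expected_costs(np.atleast_2d(posterior))
    return np.argmin(ec, axis=1)  # np.argmin returns the first minimum


def predict_grade(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Minimum-expected-cost grades for a batch of feature rows."""
    idx = min_expected_cost_index(predict_posterior(model, X), model.cost)
    return model.classes[idx]


def resubstitution_expected_cost(model: EnsembleModel, X: np.ndarray, y: np.ndarray) -> float:
    """Mean realized cost ``c[pred, true]`` of the model on (X, y)."""
    pred_idx = min_expected_cost_index(predict_posterior(model, X), model.cost)
    true_idx = np.searchsorted(model.classes, np.asarray(y))
    return float(model.cost.costs[pred_idx, true_idx].mean())


def constant_predictor_cost(y: np.ndarray, cost: CostMatrix, classes: np.ndarray) -> float:
    """Best achievable mean cost by always predicting one fixed class."""
    true_idx = np.searchsorted(classes, np.asarray(y))
    per_class = cost.costs[:, true_idx].mean(axis=1)
    return float(per_class.min())


# ---------------------------------------------------------------------------
# cross-validated objective and model selection
# ---------------------------------------------------------------------------


def cv_cost_objective(
    X: np.ndarray,
    y: np.ndarray,
    origin: Sequence[str],
    spec: EnsembleSpec,
    cost: CostMatrix,
    folds: int = 5,
    seed: int = 0,
    cost_in_boosting: bool = True,
) -> float:
    """Cross-validated mean expected misclassification cost.

    Folds are stratified over the *original* instances only; synthetic
    instances join every training fold but are never validated on (SMOTE
    leakage guard).  Returns the mean over folds of the mean realized cost
    ``c[pred, true]`` on the held-out originals.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    origin = np.asarray(origin)
    orig_idx = np.flatnonzero(origin == ORIGIN_ORIGINAL)
    syn_idx = np.flatnonzero(origin != ORIGIN_ORIGINAL)
    if orig_idx.size < folds:
        raise ValueError("fewer original instances than folds")
    classes = np.unique(y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    costs = []
    for f, (tr, va) in enumerate(skf.split(X[orig_idx], y[orig_idx])):
        train_rows = np.concatenate([orig_idx[tr], syn_idx])
        val_rows = orig_idx[va]
        model = train_ensemble(
            X[train_rows],
            y[train_rows],
            replace(spec, seed=spec.seed + f),
            cost,
            cost_in_boosting=cost_in_boosting,
        )
        pred_idx = min_expected_cost_index(predict_posterior(model, X[val_rows]), cost)
        # validation labels indexed on the full class list (training folds
        # keep all classes by stratification)
        true_idx = np.searchsorted(classes, y[val_rows])
        pred_full = np.searchsorted(classes, model.classes[pred_idx])
        costs.append(float(cost.costs[pred_full, true_idx].mean()))
    return float(np.mean(costs))


@dataclass
class OptimizerState:
    """Search history of (spec, objective); incumbent is non-increasing."""

    history: List[Tuple[EnsembleSpec, float]] = field(default_factory=list)
    seed: int = 0

    @property
    def best(self) -> Tuple[EnsembleSpec, float]:
        if not self.history:
            raise ValueError("empty optimizer history")
        return min(self.history, key=lambda t: t[1])

    @property
    def incumbent_trace(self) -> List[float]:
        trace, best = [], math.inf
        for _, obj in self.history:
            best = min(best, obj)
            trace.append(best)
        return trace


# search space bounds: n_learners, max_depth, log10(learning_rate)
_N_RANGE = (10, 300)
_DEPTH_RANGE = (1, 8)
_LOG_LR_RANGE = (math.log10(0.01), math.log10(1.0))


def _random_spec(families: Sequence[str], rng: np.random.Generator, seed: int) -> EnsembleSpec:
    return EnsembleSpec(
        family=str(rng.choice(list(families))),
        n_learners=int(rng.integers(_N_RANGE[0], _N_RANGE[1] + 1)),
        max_depth=int(rng.integers(_DEPTH_RANGE[0], _DEPTH_RANGE[1] + 1)),
        learning_rate=float(10 ** rng.uniform(*_LOG_LR_RANGE)),
        seed=seed,
    )


def _encode(spec: EnsembleSpec, families: Sequence[str]) -> np.ndarray:
    onehot = [1.0 if spec.family == f else 0.0 for f in families]
    return np.array(
        onehot
        + [
            (spec.n_learners - _N_RANGE[0]) / (_N_RANGE[1] - _N_RANGE[0]),
            (spec.max_depth - _DEPTH_RANGE[0]) / (_DEPTH_RANGE[1] - _DEPTH_RANGE[0]),
            (math.log10(spec.learning_rate) - _LOG_LR_RANGE[0])
            / (_LOG_LR_RANGE[1] - _LOG_LR_RANGE[0]),
        ]
    )


def select_model(
    X: np.ndarray,
    y: np.ndarray,
    origin: Sequence[str],
    cost: CostMatrix,
    families: Sequence[str] = FAMILIES,
    iterations: int = 50,
    folds: int = 5,
    seed: int = 0,
    engine: str = "gp",
    cost_in_boosting: bool = True,
) -> Tuple[EnsembleModel, OptimizerState]:
    """Iterative model selection minimizing :func:`cv_cost_objective`.

    ``engine="gp"`` fits a Gaussian-process surrogate (Matern 5/2 + white
    noise on a continuous encoding with one-hot family) and picks the next
    spec by expected improvement over random candidates; ``engine="random"``
    is pure seeded random search.  Returns the incumbent retrained on the
    full training set and the search history.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if len(families) == 0:
        raise ValueError("need at least one candidate family")
    for f in families:
        if f not in FAMILIES:
            raise ValueError(f"unknown family {f!r}")
    if engine not in ("gp", "random"):
        raise ValueError("engine must be 'gp' or 'random'")

    rng = np.random.default_rng(seed)
    state = OptimizerState(seed=seed)
    n_init = min(max(4, len(families)), iterations) if engine == "gp" else iterations

    def evaluate(spec: EnsembleSpec) -> None:
        obj = cv_cost_objective(
            X, y, origin, spec, cost, folds=folds, seed=seed,
            cost_in_boosting=cost_in_boosting,
        )
        state.history.append((spec, obj))

    for _ in range(n_init):
        evaluate(_random_spec(families, rng, seed))

    while len(state.history) < iterations:
        Xh = np.vstack([_encode(s, families) for s, _ in state.history])
        yh = np.array([o for _, o in state.history])
        kernel = ConstantKernel(1.0) * Matern(length_scale=np.ones(Xh.shape[1]), nu=2.5) \
            + WhiteKernel(noise_level=1e-4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp = GaussianProcessRegressor(
                kernel=kernel, normalize_y=True, random_state=seed
            ).fit(Xh, yh)
        cands = [_random_spec(families, rng, seed) for _ in range(256)]
        Xc = np.vstack([_encode(s, families) for s in cands])
        mu, sd = gp.predict(Xc, return_std=True)
        best = yh.min()
        sd = np.maximum(sd, 1e-12)
        z = (best - mu) / sd
        ei = (best - mu) * norm.cdf(z) + sd * norm.pdf(z)
        evaluate(cands[int(np.argmax(ei))])

    best_spec, best_obj = state.best
    model = train_ensemble(X, y, best_spec, cost, cost_in_boosting=cost_in_boosting)
    model.meta["objective"] = best_obj
    model.meta["iterations"] = float(len(state.history))
    return model, state
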