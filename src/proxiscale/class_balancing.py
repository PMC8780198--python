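"""Boosting-factor class balancing with SMOTE-style interpolation.

An ordinal cohort with a long-tailed class composition (most limbs graded
normal, few severely weak) is brought to a balanced training set of ``N``
instances, ``N/M`` per class, by synthesizing minority-class instances.

For class ``i`` with ``n(T_i)`` original instances, the boosting factor is

    SBF_i = (N/M - n(T_i)) / n(T_i)

and the number of synthetic instances is ``n(SB_i) = n(T_i) * SBF_i =
N/M - n(T_i)`` (exact when ``N`` is divisible by ``M``; divisibility is
enforced rather than silently rounded).  Classes already at or above the
quota get a factor clamped to 0 — no undersampling.  Synthetic instances
are SMOTE interpolations ``x + u*(x_nn - x)``, ``u ~ U(0, 1)``, between an
original and one of its k nearest same-class neighbors (Euclidean distance
on z-scored features).  The balanced set SBT is the shuffled union of the
originals T and the synthetics SB.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

ORIGIN_ORIGINAL = "original"
ORIGIN_SYNTHETIC = "synthetic"


@dataclass(frozen=True)
class BalancingPlan:
    """Per-class boosting factors and synthetic counts for a target size."""

    counts: Tuple[int, ...]
    n_target: int
    sbf: Tuple[float, ...]
    n_synthetic: Tuple[int, ...]

    @property
    def n_classes(self) -> int:
        return len(self.counts)

    @property
    def total_synthetic(self) -> int:
        return int(sum(self.n_synthetic))

    @property
    def total_balanced(self) -> int:
        return int(sum(self.counts) + self.total_synthetic)


def boosting_factors(
    counts: Sequence[int], n_target: int, n_classes: Optional[int] = None
) -> BalancingPlan:
    """Compute per-class boosting factors SBF_i and synthetic counts n(SB_i).

    Raises if any class count is zero (factor undefined) or if ``n_target``
    is not divisible by the class count.  Negative factors (class already
    above quota) are clamped to zero with a warning.
    """
    counts = tuple(int(c) for c in counts)
    m = len(counts)
    if n_classes is not None and n_classes != m:
        raise ValueError(f"n_classes={n_classes} does not match {m} counts")
    if m < 1 or sum(counts) < 1:
        raise ValueError("need at least one class and one instance")
    if any(c < 0 for c in counts):
        raise ValueError("class counts must be nonnegative")
    if any(c == 0 for c in counts):
        raise ValueError("boosting factor undefined for empty classes")
    if n_target % m != 0:
        raise ValueError(f"target size {n_target} not divisible by {m} classes")
    quota = n_target // m
    sbf = []
    n_syn = []
    for c in counts:
        f = (quota - c) / c
        if f < 0:
            warnings.warn(
                f"class with {c} instances exceeds quota {quota}; "
                "boosting factor clamped to 0 (no undersampling)",
                stacklevel=2,
            )
            f = 0.0
        sbf.append(f)
        n_syn.append(int(round(c * f)))
    return BalancingPlan(counts, int(n_target), tuple(sbf), tuple(n_syn))


def smote_augment(
    X: np.ndarray,
    y: np.ndarray,
    n_synthetic: Sequence[int],
    classes: Optional[Sequence[int]] = None,
    k: int = 5,
    seed: "int | np.random.Generator" = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Generate SMOTE synthetics per class.

    Parameters
    ----------
    X, y:
        Original feature matrix ``(n, d)`` and class labels ``(n,)``.
    n_synthetic:
        Number of synthetics per class, aligned with ``classes`` (defaults
        to the sorted unique labels of ``y``).
    k:
        Neighbor count; silently reduced to ``n_class - 1`` for small
        classes.  A singleton class falls back to jitter-duplication
        (Gaussian, s.d. 1% of each feature's scale) with a warning.

    Returns ``(X_syn, y_syn)``; deterministic given ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if classes is None:
        classes = np.unique(y)
    n_synthetic = [int(n) for n in n_synthetic]
    if len(n_synthetic) != len(classes):
        raise ValueError("n_synthetic must align with classes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # z-score on the originals before neighbor search; interpolation is
    # affine-invariant so synthetics are built in the original space
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    xs, ys = [], []
    for cls, n_syn in zip(classes, n_synthetic):
        if n_syn == 0:
            continue
        idx = np.flatnonzero(y == cls)
        if idx.size == 0:
            raise ValueError(f"no original instances for class {cls}")
        if idx.size == 1:
            warnings.warn(
                f"class {cls} has a single instance; using jitter-duplication",
                stacklevel=2,
            )
            jitter_sd = 0.01 * sd
            xs.append(X[idx[0]] + rng.normal(0.0, 1.0, size=(n_syn, X.shape[1])) * jitter_sd)
            ys.append(np.full(n_syn, cls, dtype=y.dtype))
            continue
        kk = min(k, idx.size - 1)
        nn = NearestNeighbors(n_neighbors=kk + 1).fit(Z[idx])
        _, nbr = nn.kneighbors(Z[idx])  # column 0 is the point itself
        base = rng.integers(0, idx.size, size=n_syn)
        pick = rng.integers(1, kk + 1, size=n_syn)
        u = rng.uniform(0.0, 1.0, size=n_syn)
        x0 = X[idx[base]]
        x1 = X[idx[nbr[base, pick]]]
        xs.append(x0 + u[:, None] * (x1 - x0))
        ys.append(np.full(n_syn, cls, dtype=y.dtype))

    if not xs:
        return np.empty((0, X.shape[1])), np.empty(0, dtype=y.dtype)
    return np.vstack(xs), np.concatenate(ys)


def build_balanced_set(
    originals: pd.DataFrame,
    synthetics: pd.DataFrame,
    seed: "int | np.random.Generator" = 0,
) -> pd.DataFrame:
    """Union of originals and synthetics, shuffled deterministically.

    Adds/preserves an ``origin`` column ("original" | "synthetic").
    """
    originals = originals.copy()
    synthetics = synthetics.copy()
    if "origin" not in originals.columns:
        originals["origin"] = ORIGIN_ORIGINAL
    if "origin" not in synthetics.columns:
        synthetics["origin"] = ORIGIN_SYNTHETIC
    sbt = pd.concat([originals, synthetics], ignore_index=True)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.permutation(len(sbt))
    return sbt.iloc[order].reset_index(drop=True)


def balance_table(
    table: pd.DataFrame,
    feature_cols: Sequence[str],
    label_col: str,
    n_target: int,
    k: int = 5,
    seed: "int | np.random.Generator" = 0,
) -> pd.DataFrame:
    """Balance a feature table to ``n_target`` instances (quota per label).

    Convenience wrapper chaining :func:`boosting_factors`,
    :func:`smote_augment` and :func:`build_balanced_set` on a DataFrame with
    feature columns and an ordinal label column.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.sort(table[label_col].unique())
    counts = [int((table[label_col] == c).sum()) for c in labels]
    plan = boosting_factors(counts, n_target)
    X = table[list(feature_cols)].to_numpy(dtype=float)
    y = table[label_col].to_numpy()
    X_syn, y_syn = smote_augment(X, y, plan.n_synthetic, classes=labels, k=k, seed=rng)
    synthetics = pd.DataFrame(X_syn, columns=list(feature_cols))
    synthetics[label_col] = y_syn
    originals = table[list(feature_cols) + [label_col]].copy()
    return build_balanced_set(originals, synthetics, seed=rng)
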