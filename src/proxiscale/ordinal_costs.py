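"""Misclassification cost matrices for ordinal, imbalance-aware grading.

``c[i, j]`` is the penalty for predicting class ``i`` when the truth is
class ``j``.  Two constructions:

linear
    ``c[i, j] = |j - i|`` on class indices — penalties grow with ordinal
    distance, so grading a severely weak limb as normal costs more than an
    adjacent-grade slip.

imbalance-weighted
    the linear distance scaled per predicted class by an imbalance factor
    ``(sum of instances outside class i) / (instances in class i)`` — rows
    for rare classes carry larger penalties.

Both operate by default on class *indices* of the observed-grade scale
(grades 5 and 7 are adjacent classes); distances on raw grade values are
available via ``distance="grade"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np


@dataclass(frozen=True)
class CostMatrix:
    """M×M nonnegative penalties with zero diagonal, plus the class order."""

    costs: np.ndarray
    grades: Optional[Tuple[int, ...]] = None

    def __post_init__(self) -> None:
        c = np.asarray(self.costs, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("cost matrix must be square")
        if np.any(c < 0):
            raise ValueError("costs must be nonnegative")
        if np.any(np.diag(c) != 0):
            raise ValueError("diagonal costs must be zero")
        object.__setattr__(self, "costs", c)
        if self.grades is not None:
            g = tuple(int(x) for x in self.grades)
            if len(g) != c.shape[0]:
                raise ValueError("grades length must match matrix size")
            object.__setattr__(self, "grades", g)

    @property
    def n_classes(self) -> int:
        return self.costs.shape[0]

    def expected_costs(self, posterior: np.ndarray) -> np.ndarray:
        """Expected cost of each prediction: ``ec_i = sum_j c_ij p_j``.

        Accepts one posterior ``(M,)`` or a batch ``(n, M)``.
        """
        p = np.asarray(posterior, dtype=float)
        return p @ self.costs.T

    def to_json(self) -> str:
        return json.dumps(
            {
                "costs": self.costs.tolist(),
                "grades": list(self.grades) if self.grades is not None else None,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "CostMatrix":
        obj = json.loads(text)
        grades = tuple(obj["grades"]) if obj.get("grades") is not None else None
        return cls(np.array(obj["costs"], dtype=float), grades)


def _distances(
    m: int, grades: Optional[Sequence[int]], distance: str
) -> np.ndarray:
    if distance == "index":
        v = np.arange(m, dtype=float)
    elif distance == "grade":
        if grades is None:
            raise ValueError("distance='grade' requires the grade values")
        v = np.asarray(grades, dtype=float)
    else:
        raise ValueError("distance must be 'index' or 'grade'")
    return np.abs(v[:, None] - v[None, :])


def linear_cost_matrix(
    m: Optional[int] = None,
    grades: Optional[Sequence[int]] = None,
    distance: str = "index",
) -> CostMatrix:
    """Linear-weight cost matrix ``c[i, j] = |j - i|``."""
    if m is None:
        if grades is None:
            raise ValueError("give m or grades")
        m = len(grades)
    if m < 2:
        raise ValueError("need at least 2 classes")
    g = tuple(grades) if grades is not None else None
    return CostMatrix(_distances(m, g, distance), g)


def zero_one_cost_matrix(
    m: Optional[int] = None, grades: Optional[Sequence[int]] = None
) -> CostMatrix:
    """0/1 cost: minimum expected cost reduces to argmax posterior."""
    if m is None:
        if grades is None:
            raise ValueError("give m or grades")
        m = len(grades)
    if m < 2:
        raise ValueError("need at least 2 classes")
    c = 1.0 - np.eye(m)
    return CostMatrix(c, tuple(grades) if grades is not None else None)


def imbalance_cost_matrix(
    counts: Sequence[int],
    grades: Optional[Sequence[int]] = None,
    distance: str = "index",
) -> CostMatrix:
    """Imbalance-weighted cost matrix.

    ``c[i, j] = ((sum_k n_k - n_i) / n_i) * |j - i|`` with per-class counts
    ``n_i`` of the (balanced) training set: the row for a rare predicted
    class is scaled up.  With equal counts this is ``(M - 1)`` times the
    linear matrix, leaving minimum-expected-cost decisions unchanged.
    """
    n = np.asarray(counts, dtype=float)
    if n.ndim != 1 or n.size < 2:
        raise ValueError("need counts for at least 2 classes")
    if np.any(n < 1):
        raise ValueError("all class counts must be >= 1")
    factor = (n.sum() - n) / n
    g = tuple(grades) if grades is not None else None
    c = factor[:, None] * _distances(n.size, g, distance)
    return CostMatrix(c, g)
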